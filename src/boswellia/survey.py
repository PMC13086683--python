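"""Social-capital survey instrument: scoring and determinants.

The instrument has 13 Likert items on a 1-4 scale: 9 *cognitive* items
(trust, reciprocity, social norms) and 4 *structural bonding* items
(participation in local activities, organisational membership). Each item
is standardised to a z-score across respondents; the unweighted mean of a
dimension's item z-scores is the individual's dimension index, and the
aggregate index is cognitive + bonding. Group-level indices are means of
member indices (dimension-wise), keeping the group scale comparable to
the individual scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SurveyItem",
    "SCIndex",
    "DegenerateItemError",
    "IncompleteResponseError",
    "InvalidGroupError",
    "load_catalog",
    "item_ids",
    "standardize_items",
    "individual_index",
    "score_respondents",
    "group_index",
    "group_indices",
    "sc_determinants",
]

GROUP_SIZE = 5

#: Demographic covariates used in the determinants regression (Table-3 style).
DETERMINANT_COLS = [
    "age",
    "schooling",
    "landholding",
    "social_class",
    "log_income",
    "family_size",
    "female",
]


class DegenerateItemError(ValueError):
    """An item has zero sample variance and cannot be standardised."""


class IncompleteResponseError(ValueError):
    """A respondent is missing one or more catalog items."""


class InvalidGroupError(ValueError):
    """A group does not have exactly GROUP_SIZE members."""


@dataclass(frozen=True)
class SurveyItem:
    item_id: str
    dimension: str  # "cognitive" | "bonding"
    subdomain: str  # trust / reciprocity / social_norms / participation / membership
    text: str
    calib_mean: float
    calib_sd: float
    negative_keyed: bool = False


@dataclass(frozen=True)
class SCIndex:
    """Cognitive, bonding and aggregate (= cognitive + bonding) indices."""

    cognitive: float
    bonding: float

    @property
    def aggregate(self) -> float:
        return self.cognitive + self.bonding


def load_catalog(path: str | None = None) -> list[SurveyItem]:
    """Load the item catalog (the packaged default, or a JSON file)."""
    if path is None:
        raw = resources.files("boswellia.data").joinpath("items.json").read_text()
    else:
        with open(path) as fh:
            raw = fh.read()
    items = [SurveyItem(**rec) for rec in json.loads(raw)["items"]]
    cog = [i for i in items if i.dimension == "cognitive"]
    bond = [i for i in items if i.dimension == "bonding"]
    if not cog or not bond:
        raise ValueError("catalog must contain both cognitive and bonding items")
    return items


def item_ids(catalog: list[SurveyItem], dimension: str | None = None) -> list[str]:
    return [i.item_id for i in catalog if dimension is None or i.dimension == dimension]


def standardize_items(
    responses: pd.DataFrame,
    catalog: list[SurveyItem],
    reverse_negative_items: bool = False,
    on_degenerate: str = "raise",
) -> pd.DataFrame:
    """Z-score every catalog item across respondents (n-1 denominator).

    ``reverse_negative_items`` flips negatively keyed items (score 5 - x)
    before standardising; the default scores all items as printed.

    ``on_degenerate``: a zero-variance item either raises (default) or,
    with "drop", is omitted from the output — a sample-constant item
    carries no between-respondent signal, so dropping it leaves the
    remaining index intact (relevant for near-ceiling items in small
    samples).
    """
    if on_degenerate not in ("raise", "drop"):
        raise ValueError("on_degenerate must be 'raise' or 'drop'")
    if len(responses) < 2:
        raise ValueError("need at least 2 respondents to standardise")
    ids = item_ids(catalog)
    missing = [c for c in ids if c not in responses.columns]
    if missing:
        raise IncompleteResponseError(f"missing item columns: {missing}")
    if responses[ids].isna().any().any():
        raise IncompleteResponseError("missing item responses")
    out = {}
    for item in catalog:
        x = responses[item.item_id].astype(float)
        if reverse_negative_items and item.negative_keyed:
            x = 5.0 - x
        sd = x.std(ddof=1)
        if sd == 0:
            if on_degenerate == "drop":
                continue
            raise DegenerateItemError(
                f"item {item.item_id!r} has zero variance across respondents"
            )
        out[item.item_id] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=responses.index)


def individual_index(zscores: pd.DataFrame, catalog: list[SurveyItem]) -> pd.DataFrame:
    """Per-respondent indices: unweighted means of dimension item z-scores."""
    cog_ids = item_ids(catalog, "cognitive")
    bond_ids = item_ids(catalog, "bonding")
    if not cog_ids or not bond_ids:
        raise DegenerateItemError("a dimension has no usable items")
    missing = [c for c in cog_ids + bond_ids if c not in zscores.columns]
    if missing:
        raise IncompleteResponseError(f"missing standardised items: {missing}")
    cognitive = zscores[cog_ids].mean(axis=1)
    bonding = zscores[bond_ids].mean(axis=1)
    return pd.DataFrame(
        {
            "sc_cognitive": cognitive,
            "sc_bonding": bonding,
            "sc_aggregate": cognitive + bonding,
        },
        index=zscores.index,
    )


def score_respondents(
    respondents: pd.DataFrame,
    catalog: list[SurveyItem] | None = None,
    reverse_negative_items: bool = False,
    on_degenerate: str = "raise",
) -> pd.DataFrame:
    """Append sc_cognitive / sc_bonding / sc_aggregate columns to a cohort table."""
    catalog = catalog or load_catalog()
    z = standardize_items(respondents, catalog, reverse_negative_items, on_degenerate)
    idx = individual_index(z, [i for i in catalog if i.item_id in z.columns])
    out = respondents.copy()
    for col in idx.columns:
        out[col] = idx[col]
    return out


def group_index(members: pd.DataFrame) -> SCIndex:
    """Group-level index: mean of the five members' dimension indices."""
    if len(members) != GROUP_SIZE:
        raise InvalidGroupError(
            f"group must have exactly {GROUP_SIZE} members, got {len(members)}"
        )
    return SCIndex(
        cognitive=float(members["sc_cognitive"].mean()),
        bonding=float(members["sc_bonding"].mean()),
    )


def group_indices(scored: pd.DataFrame, group_col: str = "group_id") -> pd.DataFrame:
    """Group-level indices for every group in a scored cohort table."""
    sizes = scored.groupby(group_col).size()
    bad = sizes[sizes != GROUP_SIZE]
    if len(bad):
        raise InvalidGroupError(f"groups with size != {GROUP_SIZE}: {list(bad.index)}")
    g = scored.groupby(group_col)[["sc_cognitive", "sc_bonding"]].mean()
    g = g.rename(
        columns={"sc_cognitive": "group_sc_cognitive", "sc_bonding": "group_sc_bonding"}
    )
    g["group_sc_aggregate"] = g["group_sc_cognitive"] + g["group_sc_bonding"]
    return g.reset_index()


def sc_determinants(scored: pd.DataFrame) -> dict[str, "sm.regression.linear_model.RegressionResultsWrapper"]:
    """OLS of each social-capital index on demographics (Table-3 style).

    Income enters in logs. Returns a dict of statsmodels results keyed by
    index name. Raises on rank-deficient covariates.
    """
    if len(scored) < 20:
        raise ValueError("need at least 20 respondents with full covariates")
    X = scored.copy()
    X["log_income"] = np.log(X["income"].astype(float))
    design = sm.add_constant(X[DETERMINANT_COLS].astype(float))
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise np.linalg.LinAlgError("collinear covariates in determinants design")
    fits = {}
    for outcome in ("sc_cognitive", "sc_bonding", "sc_aggregate"):
        fits[outcome] = sm.OLS(scored[outcome].astype(float), design).fit()
    return fits


def determinants_table(fits: dict) -> pd.DataFrame:
    """Tidy coefficient table (one column pair per index) from sc_determinants."""
    frames = []
    for name, res in fits.items():
        frames.append(
            pd.DataFrame(
                {
                    "outcome": name,
                    "term": res.params.index,
                    "coef": res.params.to_numpy(),
                    "se": res.bse.to_numpy(),
                    "pvalue": res.pvalues.to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
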