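"""Random-effects panel analysis of the experiment.

Builds round- and session-level panels from simulated (or field-format)
round records and estimates the four linear specifications the study
uses: group target and individual extraction, each at round and session
level, with a group random intercept and standard errors clustered by
group.

The random-effects estimator is feasible GLS (Swamy-Arora): the
idiosyncratic variance comes from the within (fixed-effects) regression,
the between-group variance from the group-means regression, and the
quasi-demeaning weight theta = 1 - sqrt(sigma_e^2 / (sigma_e^2 + n_g *
sigma_u^2)). A maximum-likelihood route via statsmodels MixedLM is
offered for cross-checking; both give the same estimates up to
small-sample differences in the variance components. Cluster-robust
covariance is the usual sandwich over group score sums on the
quasi-demeaned data, with t(G-1) reference distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import ModelParams, optimal_constant_integer

__all__ = [
    "PanelSpec",
    "FitResult",
    "EmptyPanelError",
    "InvalidComparisonError",
    "build_panel",
    "fit_random_effects",
    "gap_test",
    "summarize_rounds",
]

VOTING_SCENARIOS = ("voting_shuffling", "voting_shuffling_reputation")

CONTROL_COLS = [
    "female", "age", "schooling", "social_class", "landholding",
    "log_income", "family_size",
]


class EmptyPanelError(ValueError):
    """No analysable records after exclusions."""


class InvalidComparisonError(ValueError):
    """The gap test needs both voting scenarios present."""


@dataclass(frozen=True)
class PanelSpec:
    """One regression specification.

    level: group_round | group_session | individual_round | individual_session.
    Individual-level specs include the group target as a regressor;
    group-level specs do not. Round-level specs carry period dummies and
    social-capital x period interactions; session-level specs carry
    session dummies (reference: the first voting session).
    """

    level: str
    include_controls: bool = False
    sc_x_reputation: bool = False

    def __post_init__(self) -> None:
        if self.level not in (
            "group_round", "group_session", "individual_round", "individual_session"
        ):
            raise ValueError(f"unknown panel level {self.level!r}")

    @property
    def individual(self) -> bool:
        return self.level.startswith("individual")

    @property
    def round_level(self) -> bool:
        return self.level.endswith("_round")

    @property
    def outcome(self) -> str:
        return "extraction" if self.individual else "group_target"

    def regressors(self, panel: pd.DataFrame) -> list[str]:
        cols = ["reputation", "cognitive", "bonding"]
        if self.round_level:
            cols += [
                "period_2", "period_3",
                "cognitive_x_period_2", "cognitive_x_period_3",
                "bonding_x_period_2", "bonding_x_period_3",
            ]
        else:
            cols += [c for c in panel.columns if c.startswith("session_")]
        if self.sc_x_reputation:
            cols += ["cognitive_x_reputation", "bonding_x_reputation"]
        if self.individual:
            cols.append("group_target")
        if self.include_controls:
            cols += [c for c in CONTROL_COLS if c in panel.columns]
        return cols


# Named specifications, round/session x group/individual.
SPEC_GROUP_ROUND = PanelSpec("group_round")
SPEC_GROUP_SESSION = PanelSpec("group_session")
SPEC_INDIVIDUAL_ROUND = PanelSpec("individual_round")
SPEC_INDIVIDUAL_SESSION = PanelSpec("individual_session")

SPECS = {
    "group_round": SPEC_GROUP_ROUND,
    "group_session": SPEC_GROUP_SESSION,
    "individual_round": SPEC_INDIVIDUAL_ROUND,
    "individual_session": SPEC_INDIVIDUAL_SESSION,
}


def _sc_columns(df: pd.DataFrame, individual: bool) -> pd.DataFrame:
    out = df.copy()
    if individual:
        out["cognitive"] = out["sc_cognitive"]
        out["bonding"] = out["sc_bonding"]
    else:
        out["cognitive"] = out["group_sc_cognitive"]
        out["bonding"] = out["group_sc_bonding"]
    return out


def build_panel(
    records: pd.DataFrame,
    spec: PanelSpec,
    cohort: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Design table for one specification from raw round records.

    Drops ``analysis_excluded`` rows (the opening shuffling sessions).
    Group-level panels keep one row per group x session x round; session
    panels aggregate the outcome (and the target regressor) as the
    session SUM over rounds. Period dummies reference round 1; session
    dummies reference the first voting session present. Interactions use
    the level-appropriate social-capital index. ``cohort`` supplies the
    demographic controls when ``spec.include_controls``.
    """
    df = records[~records["analysis_excluded"].astype(bool)].copy()
    if df.empty:
        raise EmptyPanelError("no records remain after dropping excluded sessions")
    df["reputation"] = (df["scenario"] == "voting_shuffling_reputation").astype(float)

    if not spec.individual:
        keys = ["group_id", "sequence", "session", "scenario", "reputation", "round"]
        df = (
            df.groupby(keys, as_index=False)
            .agg(
                group_target=("group_target", "first"),
                group_sc_cognitive=("group_sc_cognitive", "first"),
                group_sc_bonding=("group_sc_bonding", "first"),
            )
        )
    df = _sc_columns(df, spec.individual)

    if spec.round_level:
        for r in (2, 3):
            df[f"period_{r}"] = (df["round"] == r).astype(float)
            df[f"cognitive_x_period_{r}"] = df["cognitive"] * df[f"period_{r}"]
            df[f"bonding_x_period_{r}"] = df["bonding"] * df[f"period_{r}"]
        panel = df
    else:
        keys = ["group_id", "sequence", "session", "scenario", "reputation",
                "cognitive", "bonding"]
        if spec.individual:
            keys.insert(1, "individual_id")
            panel = df.groupby(keys, as_index=False).agg(
                extraction=("extraction", "sum"), group_target=("group_target", "sum")
            )
        else:
            panel = df.groupby(keys, as_index=False).agg(
                group_target=("group_target", "sum")
            )
        ref = int(panel["session"].min())
        for s in sorted(panel["session"].unique()):
            if s != ref:
                panel[f"session_{s}"] = (panel["session"] == s).astype(float)

    panel["cognitive_x_reputation"] = panel["cognitive"] * panel["reputation"]
    panel["bonding_x_reputation"] = panel["bonding"] * panel["reputation"]

    if spec.include_controls:
        if cohort is None:
            raise ValueError("include_controls requires the cohort table")
        ctrl = cohort.copy()
        ctrl["log_income"] = np.log(ctrl["income"].astype(float))
        if spec.individual:
            ctrl = ctrl.rename(columns={"respondent_id": "individual_id"})
            panel = panel.merge(
                ctrl[["individual_id"] + CONTROL_COLS], on="individual_id", how="left"
            )
        else:
            gmeans = ctrl.groupby("group_id")[CONTROL_COLS].mean().reset_index()
            panel = panel.merge(gmeans, on="group_id", how="left")
    return panel


@dataclass
class FitResult:
    """Estimates, clustered SEs, variance components, fit statistics."""

    params: pd.Series
    se: pd.Series
    se_classical: pd.Series
    pvalues: pd.Series
    sigma_u: float
    sigma_e: float
    theta: float
    r2_overall: float
    nobs: int
    n_groups: int
    method: str

    @property
    def stars(self) -> pd.Series:
        def star(p: float) -> str:
            return "***" if p < 0.01 else "**" if p < 0.05 else "*" if p < 0.1 else ""
        return self.pvalues.map(star)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        crit = stats.t.ppf(1 - alpha / 2, df=max(self.n_groups - 1, 1))
        return pd.DataFrame(
            {"lower": self.params - crit * self.se, "upper": self.params + crit * self.se}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": self.se, "pvalue": self.pvalues,
             "stars": self.stars}
        )

    def summary(self) -> str:
        lines = []
        for name in self.params.index:
            lines.append(f"{name:>28s}  {self.params[name]:9.3f}{self.stars[name]:<3s}")
            lines.append(f"{'':>28s}  ({self.se[name]:.3f})")
        lines.append(f"{'R2 (overall)':>28s}  {self.r2_overall:9.3f}")
        lines.append(f"{'sigma_u / sigma_e':>28s}  {self.sigma_u:.3f} / {self.sigma_e:.3f}")
        lines.append(f"{'Observations':>28s}  {self.nobs:9d}")
        lines.append(f"{'Groups':>28s}  {self.n_groups:9d}")
        lines.append("Clustered (group) SEs in parentheses; *** 1%, ** 5%, * 10%")
        return "\n".join(lines)


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta, y - X @ beta


def fit_random_effects(
    panel: pd.DataFrame,
    spec: PanelSpec,
    method: str = "fgls",
    group_col: str = "group_id",
) -> FitResult:
    """Group random-intercept fit with group-clustered robust SEs.

    method="fgls": Swamy-Arora quasi-demeaning (default).
    method="mle": statsmodels MixedLM variance components, then the same
    GLS transform and clustered sandwich.
    """
    cols = spec.regressors(panel)
    y_col = spec.outcome
    X = panel[cols].to_numpy(dtype=float)
    names = ["const"] + cols
    X = np.column_stack([np.ones(len(X)), X])
    y = panel[y_col].to_numpy(dtype=float)
    groups = panel[group_col].to_numpy()
    uniq, gindex = np.unique(groups, return_inverse=True)
    G = len(uniq)
    n, k = X.shape
    if G < 2:
        raise ValueError("need at least 2 groups")
    if np.linalg.matrix_rank(X) < k:
        raise np.linalg.LinAlgError(
            f"rank-deficient design: collinearity among {names}"
        )

    counts = np.bincount(gindex)
    if method == "mle":
        import statsmodels.api as sm

        mlm = sm.MixedLM(y, X, groups=groups).fit(reml=True, method="lbfgs")
        sigma_e2 = float(mlm.scale)
        sigma_u2 = float(np.asarray(mlm.cov_re)[0, 0])
    elif method == "fgls":
        # Within regression for sigma_e^2 (time-invariant columns drop out).
        gm_y = np.bincount(gindex, weights=y) / counts
        y_w = y - gm_y[gindex]
        Xw = np.empty_like(X)
        for j in range(k):
            gm = np.bincount(gindex, weights=X[:, j]) / counts
            Xw[:, j] = X[:, j] - gm[gindex]
        keep = np.std(Xw, axis=0) > 1e-10
        kw = int(keep.sum())
        if kw:
            _, resid_w = _ols(y_w, Xw[:, keep])
        else:
            resid_w = y_w
        dof_w = max(n - G - kw, 1)
        sigma_e2 = float(resid_w @ resid_w) / dof_w
        # Between regression for sigma_u^2.
        Xb_full = np.column_stack(
            [np.bincount(gindex, weights=X[:, j]) / counts for j in range(k)]
        )
        yb = gm_y
        keep_b = [0] + [j for j in range(1, k) if np.std(Xb_full[:, j]) > 1e-10]
        kb = len(keep_b)
        if G > kb:
            _, resid_b = _ols(yb, Xb_full[:, keep_b])
            s2_between = float(resid_b @ resid_b) / (G - kb)
        else:
            s2_between = 0.0
        n_bar = n / G
        sigma_u2 = max(0.0, s2_between - sigma_e2 / n_bar)
    else:
        raise ValueError(f"unknown method {method!r}")

    sigma_e2 = max(sigma_e2, 1e-12)
    theta_g = 1.0 - np.sqrt(sigma_e2 / (sigma_e2 + counts * sigma_u2))
    gm_y = np.bincount(gindex, weights=y) / counts
    y_t = y - theta_g[gindex] * gm_y[gindex]
    X_t = np.empty_like(X)
    for j in range(k):
        gm = np.bincount(gindex, weights=X[:, j]) / counts
        X_t[:, j] = X[:, j] - theta_g[gindex] * gm[gindex]

    XtX_inv = np.linalg.inv(X_t.T @ X_t)
    beta = XtX_inv @ (X_t.T @ y_t)
    resid = y_t - X_t @ beta

    # Cluster-robust sandwich over group score sums, small-sample corrected.
    meat = np.zeros((k, k))
    for g in range(G):
        m = gindex == g
        s = X_t[m].T @ resid[m]
        meat += np.outer(s, s)
    c = (G / (G - 1)) * ((n - 1) / max(n - k, 1))
    V = c * XtX_inv @ meat @ XtX_inv
    se = np.sqrt(np.diag(V))
    # Model-based (classical) GLS SEs: transformed errors are ~iid sigma_e.
    s2 = float(resid @ resid) / max(n - k, 1)
    se_classical = np.sqrt(s2 * np.diag(XtX_inv))
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df=G - 1)

    fitted = X @ beta
    r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2) if np.std(fitted) > 0 else 0.0
    return FitResult(
        params=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        se_classical=pd.Series(se_classical, index=names),
        pvalues=pd.Series(pvals, index=names),
        sigma_u=math.sqrt(sigma_u2),
        sigma_e=math.sqrt(sigma_e2),
        theta=float(np.mean(theta_g)),
        r2_overall=r2,
        nobs=n,
        n_groups=G,
        method=method,
    )


def gap_test(records: pd.DataFrame) -> tuple[float, float]:
    """Welch t statistic for the target-extraction gap across scenarios.

    Positive t means the gap (target minus extraction) is wider under the
    reputation scenario.
    """
    df = records[~records["analysis_excluded"].astype(bool)]
    df = df.dropna(subset=["group_target"])
    gaps = {}
    for scen in VOTING_SCENARIOS:
        sub = df[df["scenario"] == scen]
        if sub.empty:
            raise InvalidComparisonError(f"no records for scenario {scen!r}")
        gaps[scen] = (sub["group_target"] - sub["extraction"]).to_numpy(dtype=float)
    a = gaps["voting_shuffling_reputation"]
    b = gaps["voting_shuffling"]
    if np.var(a) == 0 and np.var(b) == 0:
        raise InvalidComparisonError("degenerate zero-variance gaps in both scenarios")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def summarize_rounds(
    records: pd.DataFrame, params: ModelParams | None = None
) -> pd.DataFrame:
    """Per-scenario, per-round mean target and extraction with the benchmark.

    The benchmark column is the long-term (lifetime-optimal) integer wound
    level from exhaustive search — the sustainability reference line.
    """
    params = params or ModelParams()
    df = records[~records["analysis_excluded"].astype(bool)]
    if df.empty:
        raise EmptyPanelError("no analysable records")
    out = (
        df.groupby(["scenario", "round"], as_index=False)
        .agg(
            mean_target=("group_target", "mean"),
            mean_extraction=("extraction", "mean"),
            n=("extraction", "size"),
        )
    )
    bench = optimal_constant_integer(params)
    out["benchmark"] = [
        bench.wounds_per_period[r - 1] for r in out["round"].astype(int)
    ]
    return out


def plot_round_summary(summary: pd.DataFrame, path: str) -> None:
    """Line plot of mean targets and extraction per round, by scenario."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for scen, sub in summary.groupby("scenario"):
        ax.plot(sub["round"], sub["mean_target"], marker="o", label=f"{scen}: target")
        ax.plot(
            sub["round"], sub["mean_extraction"], marker="s", linestyle="--",
            label=f"{scen}: extraction",
        )
    ax.axhline(
        summary["benchmark"].iloc[0], color="grey", linestyle=":",
        label="long-term optimum",
    )
    ax.set_xlabel("round")
    ax.set_ylabel("wounds")
    ax.set_xticks(sorted(summary["round"].unique()))
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
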