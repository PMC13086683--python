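"""Bioeconomic model of frankincense tapping.

A *Boswellia papyrifera* tree is wounded (tapped) to release resin. Health
declines linearly in cumulative wounds; the per-period harvest is
proportional to the number of fresh wounds times the tree's remaining
health, so the payoff is quadratic in extraction effort.

The two benchmarks implemented here bracket the experiment's behaviour:

* **Long-term property rights** (no shuffling): one harvester keeps the
  same tree over its whole productive life and internalises the damage of
  every cut. The lifetime-payoff maximum is a *constant* wound level each
  period.
* **Short-term property rights** (shuffling): trees are randomly
  reassigned each period, so a harvester maximises the one-period payoff
  from whatever tree they hold. The myopic path is strictly decreasing
  and, in the continuous model, each period's optimum is exactly half the
  previous one.

Wound levels are continuous in the theory and integer (cards) in the
experiment; both solutions are exposed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "ModelParams",
    "TreeState",
    "HarvestOutcome",
    "ExtractionPlan",
    "InfeasibleExtractionError",
    "tree_health",
    "harvest",
    "period_payoff",
    "lifetime_payoff",
    "optimal_constant_extraction",
    "optimal_constant_integer",
    "optimal_integer_plan",
    "myopic_extraction",
    "myopic_path",
    "feasibility_condition",
]


class InfeasibleExtractionError(ValueError):
    """Raised when a plan exceeds the card cap or violates feasibility."""


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the tapping model.

    Defaults are the experiment's token economy: price P = 5 tokens per
    harvest unit, production coefficient z = 0.7, initial tree health
    a = 21, health decline b = 0.5 per wound, marginal effort cost
    c = 0.5 tokens per wound, three harvest periods per tree lifetime and
    a 40-card cap on cumulative wounds.
    """

    price: float = 5.0
    prod_coeff: float = 0.7
    initial_health: float = 21.0
    decline_rate: float = 0.5
    unit_cost: float = 0.5
    horizon: int = 3
    card_cap: int = 40

    def __post_init__(self) -> None:
        if self.price < 0:
            raise ValueError("price must be non-negative")
        if self.prod_coeff <= 0:
            raise ValueError("prod_coeff must be positive")
        if self.initial_health <= 0:
            raise ValueError("initial_health must be positive")
        if self.decline_rate < 0:
            raise ValueError("decline_rate must be non-negative")
        if self.unit_cost < 0:
            raise ValueError("unit_cost must be non-negative")
        if self.horizon < 1:
            raise ValueError("horizon must be at least 1")
        if self.card_cap < 0:
            raise ValueError("card_cap must be non-negative")

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**{k: v for k, v in d.items()})

    def to_dict(self) -> dict:
        return {
            "price": self.price,
            "prod_coeff": self.prod_coeff,
            "initial_health": self.initial_health,
            "decline_rate": self.decline_rate,
            "unit_cost": self.unit_cost,
            "horizon": self.horizon,
            "card_cap": self.card_cap,
        }


@dataclass
class TreeState:
    """One tree's wound history within a harvesting cycle (session)."""

    cumulative_wounds: int = 0
    period: int = 1

    def health(self, params: ModelParams) -> float:
        return tree_health(params, self.cumulative_wounds)

    def remaining_cards(self, params: ModelParams) -> int:
        return params.card_cap - self.cumulative_wounds


@dataclass(frozen=True)
class HarvestOutcome:
    """Result of applying ``wounds`` fresh cuts to a tree in one period."""

    wounds: int
    harvest: float
    cost: float
    payoff: float


@dataclass(frozen=True)
class ExtractionPlan:
    """A wounds-per-period vector with its lifetime payoff.

    ``boundary`` flags a corner solution (extraction driven to zero
    because profitable extraction is infeasible).
    """

    wounds_per_period: tuple
    total_payoff: float
    boundary: bool = False

    @property
    def total_wounds(self) -> float:
        return sum(self.wounds_per_period)


def tree_health(params: ModelParams, cumulative_wounds: float) -> float:
    """Health of a tree after ``cumulative_wounds`` lifetime wounds.

    Health declines linearly: V = a - b * Q.
    """
    if cumulative_wounds < 0:
        raise ValueError("cumulative_wounds must be non-negative")
    return params.initial_health - params.decline_rate * cumulative_wounds


def harvest(params: ModelParams, wounds: float, prior_wounds: float = 0.0) -> float:
    """Harvest from ``wounds`` fresh cuts given ``prior_wounds`` already applied.

    h = z * q * (a - b * Q) where Q includes the current period's wounds.
    """
    q_total = prior_wounds + wounds
    return params.prod_coeff * wounds * tree_health(params, q_total)


def period_payoff(
    params: ModelParams, wounds: float, prior_wounds: float = 0.0
) -> float:
    """One-period payoff: pi = P * z * q * (a - b*(Qprev + q)) - c * q.

    The cumulative-wound term includes the current period's own wounds,
    so the marginal cut damages the very harvest it produces.
    """
    if wounds < 0:
        raise ValueError("wounds must be non-negative")
    if prior_wounds < 0:
        raise ValueError("prior_wounds must be non-negative")
    if prior_wounds + wounds > params.card_cap:
        raise InfeasibleExtractionError(
            f"cumulative wounds {prior_wounds + wounds} exceed card cap "
            f"{params.card_cap}"
        )
    return params.price * harvest(params, wounds, prior_wounds) - params.unit_cost * wounds


def period_outcome(
    params: ModelParams, wounds: int, prior_wounds: int = 0
) -> HarvestOutcome:
    """Full accounting for a single period's extraction."""
    h = harvest(params, wounds, prior_wounds)
    cost = params.unit_cost * wounds
    return HarvestOutcome(
        wounds=wounds, harvest=h, cost=cost, payoff=params.price * h - cost
    )


def lifetime_payoff(params: ModelParams, plan: Sequence[float]) -> float:
    """Total payoff of a wounds-per-period plan over the tree's lifetime.

    Wounds accumulate: period t's payoff is evaluated at the cumulative
    wound count up to and including t.
    """
    if len(plan) != params.horizon:
        raise InfeasibleExtractionError(
            f"plan length {len(plan)} != horizon {params.horizon}"
        )
    total = 0.0
    prior = 0.0
    for q in plan:
        total += period_payoff(params, q, prior)
        prior += q
    return total


def feasibility_condition(params: ModelParams) -> bool:
    """True iff positive extraction is profitable: P * z * a > c."""
    return params.price * params.prod_coeff * params.initial_health > params.unit_cost


def optimal_constant_extraction(params: ModelParams) -> ExtractionPlan:
    """Lifetime-optimal constant wound level under long-term rights.

    The first-order conditions of the lifetime payoff imply equal wounds
    each period, q* = (P*z*a - c) / (P*z*b*(T+1)), clipped to the card
    cap. If profitable extraction is infeasible (P*z*a <= c) the plan is
    zero with ``boundary=True``.
    """
    if not feasibility_condition(params):
        plan = (0.0,) * params.horizon
        return ExtractionPlan(plan, 0.0, boundary=True)
    p, z, a, b, c, T = (
        params.price,
        params.prod_coeff,
        params.initial_health,
        params.decline_rate,
        params.unit_cost,
        params.horizon,
    )
    if b == 0:
        # No health decline: payoff linear in q, optimum at the cap.
        q = params.card_cap / T
        return ExtractionPlan(
            (q,) * T, lifetime_payoff(params, (q,) * T), boundary=True
        )
    q = (p * z * a - c) / (p * z * b * (T + 1))
    q = min(q, params.card_cap / T)
    plan = (q,) * T
    return ExtractionPlan(plan, lifetime_payoff(params, plan))


def optimal_constant_integer(params: ModelParams) -> ExtractionPlan:
    """Best *constant* integer wound level, by enumeration.

    The continuous lifetime optimum is constant across periods; this is
    its integer counterpart and the social benchmark quoted per round
    (10 wounds under the experiment defaults). Note the unconstrained
    integer optimum need not be exactly constant — see
    :func:`optimal_integer_plan`.
    """
    best_q, best_pay = 0, -math.inf
    for q in range(params.card_cap // params.horizon + 1):
        pay = lifetime_payoff(params, (q,) * params.horizon)
        if pay > best_pay + 1e-12:
            best_q, best_pay = q, pay
    return ExtractionPlan((best_q,) * params.horizon, best_pay)


def optimal_integer_plan(params: ModelParams) -> ExtractionPlan:
    """Exhaustive search over feasible integer plans (oracle-grade).

    Enumerates every integer wounds-per-period vector whose total stays
    within the card cap and returns the payoff maximiser; ties go to the
    plan with fewer total wounds (then lexicographically smallest).
    Intended for short horizons (<= 4). Because the lifetime payoff is
    permutation-symmetric in the wound vector, maximisers come in
    permutation ties; under the experiment defaults the maximum is
    (10, 10, 11) up to ordering, one unit above the constant benchmark.
    """
    if params.horizon > 4:
        raise ValueError("exhaustive search supported only for horizon <= 4")
    best_plan: tuple | None = None
    best_payoff = -math.inf
    cap = params.card_cap
    for plan in itertools.product(range(cap + 1), repeat=params.horizon):
        if sum(plan) > cap:
            continue
        payoff = lifetime_payoff(params, plan)
        if payoff > best_payoff + 1e-12:
            best_payoff, best_plan = payoff, plan
        elif abs(payoff - best_payoff) <= 1e-12 and best_plan is not None:
            if (sum(plan), plan) < (sum(best_plan), best_plan):
                best_plan = plan
    assert best_plan is not None
    return ExtractionPlan(best_plan, best_payoff)


def myopic_extraction(params: ModelParams, prior_wounds: float = 0.0) -> float:
    """Single-period payoff-maximising wound level given the tree's state.

    Under shuffling a harvester ignores future damage; the one-period
    first-order condition gives
    q = max(0, (P*z*(a - b*Qprev) - c) / (2*P*z*b)).
    """
    if prior_wounds < 0:
        raise ValueError("prior_wounds must be non-negative")
    p, z, b, c = params.price, params.prod_coeff, params.decline_rate, params.unit_cost
    health = tree_health(params, prior_wounds)
    if p == 0 or p * z * health <= c:
        return 0.0
    if b == 0:
        return float(params.card_cap - prior_wounds)
    q = (p * z * health - c) / (2 * p * z * b)
    return max(0.0, min(q, params.card_cap - prior_wounds))


def _best_integer_single_period(params: ModelParams, prior_wounds: int) -> int:
    best_q, best_pay = 0, 0.0
    for q in range(int(params.card_cap - prior_wounds) + 1):
        pay = period_payoff(params, q, prior_wounds)
        if pay > best_pay + 1e-12:
            best_q, best_pay = q, pay
    return best_q


def myopic_path(params: ModelParams, integer: bool = False) -> ExtractionPlan:
    """Iterate the myopic rule over the horizon, accumulating wounds.

    In continuous mode each interior optimum is exactly half the previous
    one; integer mode takes the per-period integer argmax subject to the
    remaining-card constraint (as the experiment's card mechanic forces).
    """
    wounds: list = []
    prior: float = 0.0
    for _ in range(params.horizon):
        if integer:
            q: float = _best_integer_single_period(params, int(prior))
        else:
            q = myopic_extraction(params, prior)
        wounds.append(q)
        prior += q
    plan = tuple(wounds)
    return ExtractionPlan(plan, lifetime_payoff(params, plan))
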