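"""Costs, QALYs, ICERs and the cost-effectiveness frontier.

Health outcomes are quality-adjusted life-years: each year lived contributes
the utility weight of the occupied state (cancer-free 0.94; diagnosed
colorectal cancer 0.80 in every stage; preclinical cancer carries the
cancer-free weight).  Costs are per-event amounts in 2008 euro plus a
stage- and detection-route-specific lifetime cancer-management cost charged
once, at the cycle of diagnosis.  Both streams are discounted at an annual
rate from a reference age (base case 4% from age 55; flows before the
reference age are carried undiscounted, which cancels in increments because
screening starts at or after it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

STAGES = ("I", "II", "III", "IV")


class UndefinedICERError(ArithmeticError):
    """Incremental QALYs are zero; the ratio is undefined."""


@dataclass
class CostSchedule:
    """Per-event costs in 2008 euro."""

    gfobt_kit: float = 1.70  # per kit dispatched (per invitee)
    gfobt_processing: float = 7.81  # per kit returned (per participant)
    fit_kit: float = 3.75
    fit_processing: float = 11.60
    fsig: float = 150.0  # with or without polypectomy
    colonoscopy: float = 650.0
    ctc: float = 550.0
    perforation: float = 10_200.0
    bleed: float = 3_079.0
    pathology_adenoma: float = 65.0  # per adenoma examined
    pathology_cancer: float = 530.0
    adenomas_per_polypectomy: float = 1.9  # mean adenomas removed per person
    # lifetime stage-specific CRC management, by detection route
    crc_symptomatic: tuple = (23_688.0, 37_180.0, 48_835.0, 36_602.0)
    crc_screen_detected: tuple = (22_885.0, 36_377.0, 48_032.0, 35_799.0)

    def validate(self) -> None:
        for name, v in self.__dict__.items():
            vals = v if isinstance(v, (tuple, list)) else (v,)
            if any(x < 0 for x in vals):
                raise ValueError(f"cost {name} must be non-negative")

    @property
    def polypectomy_pathology(self) -> float:
        """Pathology cost of one polypectomy episode (1.9 adenomas on average)."""
        return self.pathology_adenoma * self.adenomas_per_polypectomy


@dataclass
class UtilitySchedule:
    u_cancer_free: float = 0.94
    u_cancer: tuple = (0.80, 0.80, 0.80, 0.80)  # stage I..IV

    def validate(self) -> None:
        vals = (self.u_cancer_free, *self.u_cancer)
        if any(not (0.0 <= u <= 1.0) for u in vals):
            raise ValueError("utility weights must lie in [0, 1]")


def discount_factor(age: float, rate: float, ref_age: float = 55.0) -> float:
    """Present-value factor at ``age`` for an annual ``rate`` from ``ref_age``.

    Flows before the reference age are carried undiscounted (factor 1).
    """
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    if age < ref_age:
        return 1.0
    return (1.0 + rate) ** -(age - ref_age)


def discount_vector(ages: Sequence[float], rate: float, ref_age: float = 55.0) -> np.ndarray:
    return np.array([discount_factor(a, rate, ref_age) for a in ages])


class Dominance(str, Enum):
    ON_FRONTIER = "on_frontier"
    DOMINATED = "dominated"
    EXTENDED_DOMINATED = "extended_dominated"


@dataclass
class StrategyResult:
    """Discounted per-person economics plus lifetime tallies for one strategy."""

    id: str
    cost: float  # discounted euro per person
    qalys: float  # discounted QALYs per person
    cost_undiscounted: float = math.nan
    qalys_undiscounted: float = math.nan
    life_years: float = math.nan  # discounted
    tally: Optional[dict] = None  # per-100k event counts
    lifetime_incidence: float = math.nan  # per 100k
    lifetime_mortality: float = math.nan
    stage_by_route: Optional[pd.DataFrame] = None

    def as_point(self) -> tuple:
        return (self.qalys, self.cost)


def accumulate(
    qaly_weights_by_age: np.ndarray,
    event_costs_by_age: np.ndarray,
    ages: np.ndarray,
    rate: float,
    ref_age: float = 55.0,
) -> tuple:
    """Discount and sum per-age QALY and cost streams.

    ``qaly_weights_by_age`` holds the cohort-mean utility-weighted life-years
    accrued during each cycle; ``event_costs_by_age`` the per-person euro
    flows (events plus lifetime management charged at diagnosis).
    """
    df = discount_vector(ages, rate, ref_age)
    return float(df @ event_costs_by_age), float(df @ qaly_weights_by_age)


COST_SAVING = "cost-saving"


def compute_icer(a: StrategyResult, b: StrategyResult) -> float:
    """ICER of ``a`` versus comparator ``b`` in euro per QALY gained.

    A negative ratio with a positive QALY gain means ``a`` is cheaper and
    more effective ("cost-saving"); the signed value is returned and callers
    may label it via :func:`icer_label`.
    """
    dq = a.qalys - b.qalys
    if dq == 0.0:
        raise UndefinedICERError(f"{a.id} vs {b.id}: zero QALY difference")
    return (a.cost - b.cost) / dq


def icer_label(icer: float, dq: float) -> str:
    if icer < 0 and dq > 0:
        return COST_SAVING
    return f"{icer:.0f}"


@dataclass
class FrontierResult:
    """Strategies ordered by effectiveness with dominance classification."""

    order: list  # strategy ids sorted by QALYs ascending
    status: dict  # id -> Dominance
    frontier: list  # ids on the frontier, by QALYs ascending
    icers: dict = field(default_factory=dict)  # id -> ICER vs previous frontier point

    def on_frontier(self, sid: str) -> bool:
        return self.status[sid] is Dominance.ON_FRONTIER


def efficiency_frontier(results: Sequence[StrategyResult]) -> FrontierResult:
    """Classify strategies by strict and extended dominance.

    Strategies are sorted by QALYs; a strategy is strictly dominated when
    another is at least as effective and no more costly (with at least one
    strict inequality); extended dominance then iteratively removes
    strategies whose ICER against the previous frontier point exceeds the
    ICER of a later frontier point.  The surviving frontier is the lower
    convex hull of the (QALY, cost) cloud.
    """
    if len(results) < 2:
        raise ValueError("need at least two strategies")
    by_q = sorted(results, key=lambda r: (r.qalys, r.cost))
    status: dict = {}
    # strict dominance
    for r in by_q:
        dominated = any(
            (o.qalys >= r.qalys and o.cost <= r.cost)
            and (o.qalys > r.qalys or o.cost < r.cost)
            for o in by_q
            if o.id != r.id
        )
        status[r.id] = Dominance.DOMINATED if dominated else Dominance.ON_FRONTIER
    # extended dominance: prune until ICERs strictly increase along the chain
    candidates = [r for r in by_q if status[r.id] is Dominance.ON_FRONTIER]
    changed = True
    while changed and len(candidates) > 2:
        changed = False
        for i in range(1, len(candidates) - 1):
            prev, cur, nxt = candidates[i - 1], candidates[i], candidates[i + 1]
            icer_cur = compute_icer(cur, prev)
            icer_nxt = compute_icer(nxt, cur)
            if icer_cur >= icer_nxt:
                status[cur.id] = Dominance.EXTENDED_DOMINATED
                candidates.pop(i)
                changed = True
                break
    icers = {}
    for i in range(1, len(candidates)):
        icers[candidates[i].id] = compute_icer(candidates[i], candidates[i - 1])
    return FrontierResult(
        order=[r.id for r in by_q],
        status=status,
        frontier=[r.id for r in candidates],
        icers=icers,
    )


def results_table(
    results: Sequence[StrategyResult], comparator_id: str = "no_screening"
) -> pd.DataFrame:
    """Cost-effectiveness summary with increments and ICERs vs no screening."""
    frontier = efficiency_frontier(results)
    base = next(r for r in results if r.id == comparator_id)
    rows = []
    for r in sorted(results, key=lambda r: r.qalys):
        dq = r.qalys - base.qalys
        dc = r.cost - base.cost
        icer = math.nan if r.id == comparator_id else (dc / dq if dq != 0 else math.inf)
        rows.append(
            {
                "strategy": r.id,
                "cost_per_person": r.cost,
                "qalys_per_person": r.qalys,
                "inc_cost_vs_no_screening": dc,
                "inc_qalys_vs_no_screening": dq,
                "icer_vs_no_screening": icer,
                "dominance": frontier.status[r.id].value,
            }
        )
    return pd.DataFrame(rows)
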