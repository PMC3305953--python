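"""Screening and surveillance overlay on the natural-history model.

Strategies (biennial gFOBT with reflex FIT, biennial FIT, once-only
flexible sigmoidoscopy) are superimposed on the Markov cohort by
redistributing occupancy at screening time points, in expectation (no
Monte Carlo at the cohort level).  The overlay tracks:

* a routine *attender pool* and a *never-attender* block (the population is
  partitioned once when screening begins; potential attenders attend each
  round independently with probability uptake / (1 - never_fraction));
* the diagnostic cascade -- positive faecal test (after reflex testing where
  configured), colonoscopy compliance, a configurable fraction routed to CT
  colonography, colonoscopy sensitivity per lesion class;
* polypectomy and adenoma surveillance with tunnel states encoding the
  exam clock and the clear-exam count (annual exams for high-risk findings,
  3-yearly for intermediate-risk, exit after two clear exams 3 years
  apart);
* endoscopy complications (major bleeds, perforations, perforation deaths)
  applied per procedure.

State vector layout (196 cells): routine pool (21 pre-diagnosis lesion
states), never-attenders (21), surveillance (7 tunnel cells x 21 lesion
states), clinical cancer (4 stages), dead (CRC, perforation, other).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

from .economics import CostSchedule, StrategyResult, UtilitySchedule, accumulate
from .natural_history import (
    END_AGE,
    START_AGE,
    LifeTable,
    NaturalHistoryParams,
    resolve_direct_rates,
)
from .states import HealthState, Location

# -- overlay vector layout ----------------------------------------------------

N_PD = 21  # pre-diagnosis lesion states (== extended indices 0..20)
OFF_POOL = 0  # routine attender pool
OFF_NEVER = 21
OFF_SURV = 42
N_SCELLS = 7  # cell 0: high-risk tier; 1..6: intermediate (clears 0/1 x clock 0/1/2)
OFF_CLIN = OFF_SURV + N_SCELLS * N_PD  # 189
OFF_DEAD_CRC, OFF_DEAD_PERF, OFF_DEAD_OTHER = 193, 194, 195
N_OV = 196

# lesion classes within the 21-state pre-diagnosis block
J_NORMAL = 0
J_AD_LOW = (1, 2)  # distal, proximal
J_AD_HIGH = (3, 4)
J_DISTAL = frozenset({1, 3} | {5 + 4 * s + 0 for s in range(4)} | {5 + 4 * s + 1 for s in range(4)})


def _preclin_stage(j: int) -> int:
    """Stage (1..4) of pre-diagnosis index j in 5..20."""
    return (j - 5) // 4 + 1


def _is_distal(j: int) -> bool:
    if j in (1, 3):
        return True
    if j in (2, 4):
        return False
    return (j - 5) % 4 < 2


def _surv_cell(off: int) -> slice:
    return slice(OFF_SURV + N_PD * off, OFF_SURV + N_PD * (off + 1))


class Reach(str, Enum):
    WHOLE_COLON = "whole_colon"
    DISTAL_ONLY = "distal_only"


@dataclass(frozen=True)
class TestPerformance:
    """Operating characteristics of a screening or diagnostic test."""

    name: str
    sens_adenoma_low: float
    sens_adenoma_high: float
    sens_crc: float
    specificity: float
    reach: Reach = Reach.WHOLE_COLON

    def __post_init__(self) -> None:
        for f in ("sens_adenoma_low", "sens_adenoma_high", "sens_crc", "specificity"):
            v = getattr(self, f)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{self.name}.{f}={v} outside [0, 1]")

    def positivity_vector(self) -> np.ndarray:
        """P(test positive | true state) over the 21 pre-diagnosis states.

        Lesions outside the test's reach behave like disease-free states
        (positivity 1 - specificity).
        """
        p = np.empty(N_PD)
        for j in range(N_PD):
            p[j] = self._positivity(j)
        return p

    def _positivity(self, j: int) -> float:
        in_reach = self.reach is Reach.WHOLE_COLON or _is_distal(j)
        if j == J_NORMAL or not in_reach:
            return 1.0 - self.specificity
        if j in J_AD_LOW:
            return self.sens_adenoma_low
        if j in J_AD_HIGH:
            return self.sens_adenoma_high
        return self.sens_crc


def test_positivity(test: TestPerformance, state: HealthState) -> float:
    """P(positive result) for a live, pre-diagnosis health state."""
    if state.is_dead or state.is_clinical:
        raise ValueError(f"{state} is not a screenable state")
    in_reach = test.reach is Reach.WHOLE_COLON or state.location is Location.DISTAL
    if state.is_preclinical:
        return test.sens_crc if in_reach else 1.0 - test.specificity
    if state.is_adenoma:
        if not in_reach:
            return 1.0 - test.specificity
        from .states import Compartment

        if state.compartment is Compartment.ADENOMA_LOW:
            return test.sens_adenoma_low
        return test.sens_adenoma_high
    return 1.0 - test.specificity


# base-case operating characteristics
TEST_PRESETS = {
    "gFOBT": TestPerformance("gFOBT", 0.11, 0.11, 0.36, 0.97),
    "FIT": TestPerformance("FIT", 0.21, 0.21, 0.71, 0.95),
    "FSIG": TestPerformance("FSIG", 0.65, 0.74, 0.90, 0.92, Reach.DISTAL_ONLY),
    "COL": TestPerformance("COL", 0.77, 0.98, 0.98, 0.97),
    "CTC": TestPerformance("CTC", 0.53, 0.85, 0.85, 0.86),
}


@dataclass
class ComplicationRisks:
    """Per-procedure complication probabilities (base-case values)."""

    fsig_perforation: float = 0.00002
    fsig_perforation_death: float = 0.06452
    fsig_bleed: float = 0.00029
    col_perforation_polypectomy: float = 0.00216
    col_perforation_no_polypectomy: float = 0.00107
    col_perforation_death: float = 0.05195
    col_bleed: float = 0.00379


@dataclass
class SurveillanceRule:
    frac_high_among_intermediate_high: float = 0.29
    interval_high: int = 1
    interval_intermediate: int = 3
    clear_exams_to_exit: int = 2
    compliance: float = 0.86

    def __post_init__(self) -> None:
        if self.interval_high < 1 or self.interval_intermediate < 1:
            raise ValueError("surveillance intervals must be positive")
        for f in ("frac_high_among_intermediate_high", "compliance"):
            if not (0.0 <= getattr(self, f) <= 1.0):
                raise ValueError(f"{f} outside [0, 1]")


@dataclass
class StrategyConfig:
    id: str
    primary_test: Optional[str]  # None disables screening (comparator)
    reflex_test: Optional[str] = None
    start_age: int = 55
    end_age: int = 74
    interval: Optional[int] = 2  # None = once-only
    uptake: float = 0.53
    never_attender_fraction: float = 0.13
    colonoscopy_compliance: float = 0.86
    ctc_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.start_age > self.end_age:
            raise ValueError("start_age must not exceed end_age")
        if self.interval is not None and self.interval < 1:
            raise ValueError("interval must be >= 1 or None for once-only")
        for f in ("uptake", "never_attender_fraction", "colonoscopy_compliance", "ctc_fraction"):
            if not (0.0 <= getattr(self, f) <= 1.0):
                raise ValueError(f"{f} outside [0, 1]")
        if self.never_attender_fraction >= 1.0 and self.primary_test is not None:
            raise ValueError("never_attender_fraction must be < 1")


def strategy_presets() -> dict:
    """The eight evaluated scenarios plus the no-screening comparator."""
    mk = StrategyConfig
    return {
        "no_screening": mk("no_screening", None, uptake=0.0, never_attender_fraction=0.0),
        "gFOBT_55_74": mk("gFOBT_55_74", "gFOBT", "FIT", 55, 74),
        "FIT_55_74": mk("FIT_55_74", "FIT", None, 55, 74),
        "FSIG_60": mk("FSIG_60", "FSIG", None, 60, 60, None, 0.39, 0.0),
        "gFOBT_55_64": mk("gFOBT_55_64", "gFOBT", "FIT", 55, 64),
        "gFOBT_65_74": mk("gFOBT_65_74", "gFOBT", "FIT", 65, 74),
        "FIT_55_64": mk("FIT_55_64", "FIT", None, 55, 64),
        "FIT_65_74": mk("FIT_65_74", "FIT", None, 65, 74),
        "FSIG_55": mk("FSIG_55", "FSIG", None, 55, 55, None, 0.39, 0.0),
    }


def round_schedule(strategy: StrategyConfig) -> list:
    """Scheduled screening ages; biennial rounds run while age <= end_age - 1."""
    if strategy.primary_test is None:
        return []
    if strategy.interval is None:
        return [strategy.start_age]
    return list(range(strategy.start_age, strategy.end_age, strategy.interval))


TALLY_KEYS = (
    "kits_gfobt_dispatched",
    "kits_fit_dispatched",
    "tests_gfobt",
    "tests_fit",
    "tests_fit_reflex",
    "fsig_screens",
    "colonoscopies_diagnostic",
    "colonoscopies_surveillance",
    "ctc",
    "polypectomies",
    "bleeds",
    "perforations",
    "perforation_deaths",
    "crc_screen_detected_I",
    "crc_screen_detected_II",
    "crc_screen_detected_III",
    "crc_screen_detected_IV",
    "crc_surveillance_detected_I",
    "crc_surveillance_detected_II",
    "crc_surveillance_detected_III",
    "crc_surveillance_detected_IV",
    "crc_symptomatic_I",
    "crc_symptomatic_II",
    "crc_symptomatic_III",
    "crc_symptomatic_IV",
    "crc_deaths",
)


class EventTally:
    """Event counts per cohort member; report per 100,000 via :meth:`per_100k`."""

    __slots__ = ("counts", "cost")

    def __init__(self) -> None:
        self.counts = {k: 0.0 for k in TALLY_KEYS}
        self.cost = 0.0  # undiscounted euro accrued by the tallied events

    def add(self, key: str, amount: float) -> None:
        self.counts[key] += amount

    def merge(self, other: "EventTally") -> None:
        for k, v in other.counts.items():
            self.counts[k] += v
        self.cost += other.cost

    def per_100k(self) -> dict:
        return {k: v * 1e5 for k, v in self.counts.items()}

    def detected(self, route: str) -> float:
        return sum(self.counts[f"crc_{route}_{s}"] for s in ("I", "II", "III", "IV"))

    def to_frame(self) -> pd.DataFrame:
        d = self.per_100k()
        d["colonoscopies_total"] = (
            d["colonoscopies_diagnostic"] + d["colonoscopies_surveillance"]
        )
        return pd.DataFrame(
            {"event": list(d.keys()), "rate_per_100k": list(d.values())}
        )


@dataclass
class OverlayCohort:
    """Occupancy over the 196-cell overlay space at one age."""

    age: int
    occupancy: np.ndarray

    @classmethod
    def initial(cls, never_fraction: float, age: int = START_AGE) -> "OverlayCohort":
        occ = np.zeros(N_OV)
        occ[OFF_POOL + J_NORMAL] = 1.0 - never_fraction
        occ[OFF_NEVER + J_NORMAL] = never_fraction
        return cls(age=age, occupancy=occ)

    @property
    def total(self) -> float:
        return float(self.occupancy.sum())


STAGE_KEYS = ("I", "II", "III", "IV")


class _Procedures:
    """Expected-value colonoscopy work-up shared by all referral routes."""

    def __init__(
        self,
        col: TestPerformance,
        ctc: TestPerformance,
        risks: ComplicationRisks,
        costs: CostSchedule,
        rule: SurveillanceRule,
        route: str,
        surveillance_col: bool = False,
    ) -> None:
        self.col, self.ctc, self.risks, self.costs = col, ctc, risks, costs
        self.rule, self.route = rule, route
        self.col_key = (
            "colonoscopies_surveillance" if surveillance_col else "colonoscopies_diagnostic"
        )

    def colonoscopy(self, j: int, mass: float, out: np.ndarray, tally: EventTally) -> None:
        """Colonoscopy on ``mass`` people with true lesion state ``j``.

        Detected low-risk adenomas are removed and the person returns to the
        routine pool; detected intermediate/high-risk adenomas are removed
        and the person enters surveillance (29% high-risk tier); detected
        cancers move to the clinical state of their stage.  Missed lesions
        and true normals return to the routine pool.  Perforation, bleed and
        perforation-death risks apply per procedure.
        """
        if mass <= 0.0:
            return
        tally.add(self.col_key, mass)
        tally.cost += mass * self.costs.colonoscopy
        tally.add("bleeds", mass * self.risks.col_bleed)
        tally.cost += mass * self.risks.col_bleed * self.costs.bleed
        if j == J_NORMAL:
            self._deliver(mass, OFF_POOL + J_NORMAL, False, out, tally)
        elif j in J_AD_LOW:
            det = mass * self.col.sens_adenoma_low
            self._polypectomy(det, tally)
            self._deliver(det, OFF_POOL + J_NORMAL, True, out, tally)
            self._deliver(mass - det, OFF_POOL + j, False, out, tally)
        elif j in J_AD_HIGH:
            det = mass * self.col.sens_adenoma_high
            self._polypectomy(det, tally)
            f_high = self.rule.frac_high_among_intermediate_high
            self._deliver(det * f_high, OFF_SURV + 0 * N_PD + J_NORMAL, True, out, tally)
            self._deliver(det * (1 - f_high), OFF_SURV + 1 * N_PD + J_NORMAL, True, out, tally)
            self._deliver(mass - det, OFF_POOL + j, False, out, tally)
        else:
            s = _preclin_stage(j)
            det = mass * self.col.sens_crc
            tally.add(f"crc_{self.route}_{STAGE_KEYS[s - 1]}", det)
            tally.cost += det * (
                self.costs.pathology_cancer + self.costs.crc_screen_detected[s - 1]
            )
            self._deliver(det, OFF_CLIN + (s - 1), False, out, tally)
            self._deliver(mass - det, OFF_POOL + j, False, out, tally)

    def ct_colonography(self, j: int, mass: float, out: np.ndarray, tally: EventTally) -> None:
        """CT colonography; positives proceed to colonoscopy for work-up."""
        if mass <= 0.0:
            return
        tally.add("ctc", mass)
        tally.cost += mass * self.costs.ctc
        pos = mass * self.ctc._positivity(j)
        self.colonoscopy(j, pos, out, tally)
        out[OFF_POOL + j] += mass - pos

    def _polypectomy(self, mass: float, tally: EventTally) -> None:
        tally.add("polypectomies", mass)
        tally.cost += mass * self.costs.polypectomy_pathology

    def _deliver(
        self, mass: float, dest: int, polypectomy: bool, out: np.ndarray, tally: EventTally
    ) -> None:
        """Route mass to its destination, net of perforation deaths."""
        if mass <= 0.0:
            return
        p_perf = (
            self.risks.col_perforation_polypectomy
            if polypectomy
            else self.risks.col_perforation_no_polypectomy
        )
        perf = mass * p_perf
        dead = perf * self.risks.col_perforation_death
        tally.add("perforations", perf)
        tally.add("perforation_deaths", dead)
        tally.cost += perf * self.costs.perforation
        out[OFF_DEAD_PERF] += dead
        out[dest] += mass - dead


def apply_screening_round(
    cohort: OverlayCohort,
    strategy: StrategyConfig,
    tests: Optional[dict] = None,
    surveillance_rule: Optional[SurveillanceRule] = None,
    risks: Optional[ComplicationRisks] = None,
    costs: Optional[CostSchedule] = None,
) -> tuple:
    """One screening round, as a deterministic redistribution of the cohort.

    Returns the redistributed cohort (same age) and the round's
    :class:`EventTally`.  ``cohort.age`` must be one of the strategy's
    scheduled round ages.
    """
    tests = tests or TEST_PRESETS
    rule = surveillance_rule or SurveillanceRule()
    risks = risks or ComplicationRisks()
    costs = costs or CostSchedule()
    if cohort.age not in round_schedule(strategy):
        raise ValueError(f"age {cohort.age} is not a scheduled round for {strategy.id}")
    occ = cohort.occupancy.copy()
    tally = EventTally()
    if strategy.primary_test == "FSIG":
        _fsig_round(occ, strategy, tests, rule, risks, costs, tally)
    else:
        _faecal_round(occ, strategy, tests, rule, risks, costs, tally)
    return OverlayCohort(age=cohort.age, occupancy=occ), tally


def _faecal_round(occ, strategy, tests, rule, risks, costs, tally) -> None:
    primary = tests[strategy.primary_test]
    reflex = tests[strategy.reflex_test] if strategy.reflex_test else None
    col, ctc = tests["COL"], tests["CTC"]
    never = strategy.never_attender_fraction
    att = strategy.uptake / (1.0 - never) if never < 1.0 else 0.0
    if att > 1.0 + 1e-12:
        raise ValueError("uptake exceeds the potential-attender fraction")
    att = min(att, 1.0)
    invited = occ[OFF_POOL : OFF_POOL + N_PD].sum() + occ[OFF_NEVER : OFF_NEVER + N_PD].sum()
    kit_key = "kits_gfobt_dispatched" if primary.name == "gFOBT" else "kits_fit_dispatched"
    kit_cost = costs.gfobt_kit if primary.name == "gFOBT" else costs.fit_kit
    proc_cost = costs.gfobt_processing if primary.name == "gFOBT" else costs.fit_processing
    test_key = "tests_gfobt" if primary.name == "gFOBT" else "tests_fit"
    tally.add(kit_key, invited)
    tally.cost += invited * kit_cost
    p1 = primary.positivity_vector()
    p2 = reflex.positivity_vector() if reflex else np.ones(N_PD)
    proc = _Procedures(col, ctc, risks, costs, rule, route="screen_detected")
    pool = occ[OFF_POOL : OFF_POOL + N_PD].copy()
    occ[OFF_POOL : OFF_POOL + N_PD] = pool * (1.0 - att)  # non-attenders this round
    attenders = pool * att
    tally.add(test_key, attenders.sum())
    tally.cost += attenders.sum() * proc_cost
    primary_pos = attenders * p1
    if reflex is not None:
        # everyone positive on the primary test completes a reflex FIT
        # (full processing cost, no extra kit dispatch)
        tally.add("tests_fit_reflex", primary_pos.sum())
        tally.cost += primary_pos.sum() * costs.fit_processing
    positives = primary_pos * p2
    negatives = attenders - positives
    occ[OFF_POOL : OFF_POOL + N_PD] += negatives
    c = strategy.colonoscopy_compliance
    occ[OFF_POOL : OFF_POOL + N_PD] += positives * (1.0 - c)  # return to routine pool
    referred = positives * c
    for j in range(N_PD):
        m = referred[j]
        if m <= 0.0:
            continue
        proc.ct_colonography(j, m * strategy.ctc_fraction, occ, tally)
        proc.colonoscopy(j, m * (1.0 - strategy.ctc_fraction), occ, tally)


def _fsig_round(occ, strategy, tests, rule, risks, costs, tally) -> None:
    fsig, col, ctc = tests["FSIG"], tests["COL"], tests["CTC"]
    att = strategy.uptake
    proc = _Procedures(col, ctc, risks, costs, rule, route="screen_detected")
    pool = occ[OFF_POOL : OFF_POOL + N_PD].copy()
    occ[OFF_POOL : OFF_POOL + N_PD] = pool * (1.0 - att)
    attenders = pool * att
    n_att = attenders.sum()
    tally.add("fsig_screens", n_att)
    tally.cost += n_att * costs.fsig
    # FSIG complications apply per examination
    perf = n_att * risks.fsig_perforation
    dead = perf * risks.fsig_perforation_death
    tally.add("perforations", perf)
    tally.add("perforation_deaths", dead)
    tally.cost += perf * costs.perforation
    tally.add("bleeds", n_att * risks.fsig_bleed)
    tally.cost += n_att * risks.fsig_bleed * costs.bleed
    death_share = dead / n_att if n_att > 0 else 0.0
    c = strategy.colonoscopy_compliance
    for j in range(N_PD):
        m = attenders[j] * (1.0 - death_share)
        occ[OFF_DEAD_PERF] += attenders[j] * death_share
        if m <= 0.0:
            continue
        pos = m * fsig._positivity(j)
        occ[OFF_POOL + j] += m - pos
        if j in J_AD_LOW and _is_distal(j):
            # low-risk distal adenomas are removed at the screening FSIG
            # (polypectomy within the FSIG visit); person returns to routine
            tally.add("polypectomies", pos)
            tally.cost += pos * costs.polypectomy_pathology
            occ[OFF_POOL + J_NORMAL] += pos
            continue
        # cancer-positive, high-risk-positive and false-positive findings
        # are referred for colonoscopy work-up
        occ[OFF_POOL + j] += pos * (1.0 - c)
        referred = pos * c
        proc.ct_colonography(j, referred * strategy.ctc_fraction, occ, tally)
        proc.colonoscopy(j, referred * (1.0 - strategy.ctc_fraction), occ, tally)


# surveillance cell semantics: 0 -> high tier (annual exam);
# 1..3 -> intermediate, clears=0, clock 0/1/2; 4..6 -> intermediate, clears=1
_INT_C0 = (1, 2, 3)
_INT_C1 = (4, 5, 6)


def apply_surveillance(
    cohort: OverlayCohort,
    surveillance_rule: Optional[SurveillanceRule] = None,
    col_performance: Optional[TestPerformance] = None,
    risks: Optional[ComplicationRisks] = None,
    costs: Optional[CostSchedule] = None,
    ctc_performance: Optional[TestPerformance] = None,
) -> tuple:
    """Annual surveillance step: advance exam clocks and examine due cells.

    High-risk-tier members are examined every year; intermediate-tier
    members every 3 years.  A clear exam moves high-tier members to the
    intermediate tier with one clear exam banked; a second clear exam 3
    years after the first returns the member to the routine screening pool.
    Lesions found are removed (adenomas, with tier reassignment) or
    diagnosed (cancers, surveillance-detected).  Non-compliant members have
    their exam deferred by a full interval.
    """
    rule = surveillance_rule or SurveillanceRule()
    col = col_performance or TEST_PRESETS["COL"]
    ctc = ctc_performance or TEST_PRESETS["CTC"]
    risks = risks or ComplicationRisks()
    costs = costs or CostSchedule()
    occ = cohort.occupancy.copy()
    tally = EventTally()
    proc = _Procedures(
        col, ctc, risks, costs, rule, route="surveillance_detected", surveillance_col=True
    )
    # advance intermediate-tier clocks; mass leaving clock 2 is due for exam
    due_c0 = occ[_surv_cell(3)].copy()
    due_c1 = occ[_surv_cell(6)].copy()
    occ[_surv_cell(3)] = occ[_surv_cell(2)]
    occ[_surv_cell(2)] = occ[_surv_cell(1)]
    occ[_surv_cell(1)] = 0.0
    occ[_surv_cell(6)] = occ[_surv_cell(5)]
    occ[_surv_cell(5)] = occ[_surv_cell(4)]
    occ[_surv_cell(4)] = 0.0
    due_high = occ[_surv_cell(0)].copy()
    occ[_surv_cell(0)] = 0.0
    comp = rule.compliance
    f_high = rule.frac_high_among_intermediate_high

    def exam(due: np.ndarray, clear_dest: Optional[int], tier_cell: int) -> None:
        """Examine ``due`` lesion-state mass; clear_dest None means exit."""
        for j in range(N_PD):
            m = due[j] * comp
            skip = due[j] - m
            # non-compliant: deferred a full interval, clock restarts
            occ[OFF_SURV + tier_cell * N_PD + j] += skip
            if m <= 0.0:
                continue
            tally.add("colonoscopies_surveillance", m)
            tally.cost += m * costs.colonoscopy
            tally.add("bleeds", m * risks.col_bleed)
            tally.cost += m * risks.col_bleed * costs.bleed
            if j == J_NORMAL:
                dest = OFF_POOL + J_NORMAL if clear_dest is None else clear_dest + J_NORMAL
                proc._deliver(m, dest, False, occ, tally)
            elif j in J_AD_LOW:
                det = m * col.sens_adenoma_low
                proc._polypectomy(det, tally)
                # low-risk recurrence: removed, clear count resets,
                # intermediate tier
                proc._deliver(det, OFF_SURV + 1 * N_PD + J_NORMAL, True, occ, tally)
                miss_dest = OFF_POOL + j if clear_dest is None else clear_dest + j
                proc._deliver(m - det, miss_dest, False, occ, tally)
            elif j in J_AD_HIGH:
                det = m * col.sens_adenoma_high
                proc._polypectomy(det, tally)
                proc._deliver(det * f_high, OFF_SURV + 0 * N_PD + J_NORMAL, True, occ, tally)
                proc._deliver(
                    det * (1 - f_high), OFF_SURV + 1 * N_PD + J_NORMAL, True, occ, tally
                )
                miss_dest = OFF_POOL + j if clear_dest is None else clear_dest + j
                proc._deliver(m - det, miss_dest, False, occ, tally)
            else:
                s = _preclin_stage(j)
                det = m * col.sens_crc
                tally.add(f"crc_surveillance_detected_{STAGE_KEYS[s - 1]}", det)
                tally.cost += det * (
                    costs.pathology_cancer + costs.crc_screen_detected[s - 1]
                )
                proc._deliver(det, OFF_CLIN + (s - 1), False, occ, tally)
                miss_dest = OFF_POOL + j if clear_dest is None else clear_dest + j
                proc._deliver(m - det, miss_dest, False, occ, tally)

    # high tier: clear exam banks one clear and moves to intermediate tier
    exam(due_high, OFF_SURV + 4 * N_PD, tier_cell=0)
    # intermediate, no clears banked: clear exam banks the first clear
    exam(due_c0, OFF_SURV + 4 * N_PD, tier_cell=1)
    # intermediate, one clear banked: second clear exam exits surveillance
    exam(due_c1, None, tier_cell=1)
    return OverlayCohort(age=cohort.age, occupancy=occ), tally


def _overlay_progression_ops(
    params: NaturalHistoryParams, life_table: LifeTable, ages: np.ndarray
) -> list:
    """Per-age blocks of the extended natural-history matrix.

    Returns, for each age, (P_pd, P_pd_clin, P_pd_dead3, clin_stay) where
    the pre-diagnosis block P_pd is 21x21, flows to the four clinical states
    and the three dead states are separate, and clinical-state rows carry
    (stay, to dead_crc, to dead_other).
    """
    if params.direct_rates is None:
        params.direct_rates = resolve_direct_rates(params, life_table)
    from .natural_history import transition_matrix

    ops = []
    for age in ages:
        m = transition_matrix(params, life_table, int(age))
        ops.append(
            (
                m[0:21, 0:21].copy(),
                m[0:21, 21:25].copy(),
                m[0:21, 25:28].copy(),
                m[21:25, 21:28].copy(),
            )
        )
    return ops


def simulate_strategy(
    strategy: StrategyConfig,
    params: NaturalHistoryParams,
    tests: Optional[dict] = None,
    life_table: Optional[LifeTable] = None,
    costs: Optional[CostSchedule] = None,
    utilities: Optional[UtilitySchedule] = None,
    surveillance_rule: Optional[SurveillanceRule] = None,
    risks: Optional[ComplicationRisks] = None,
    discount_rate: float = 0.04,
    discount_ref_age: float = 55.0,
    half_cycle: bool = False,
    start_age: int = START_AGE,
    end_age: int = END_AGE,
) -> StrategyResult:
    """Full 30->100 cohort run with the screening overlay.

    Within each cycle: (1) screening round if scheduled and the annual
    surveillance step, (2) natural-history progression, (3) competing
    other-cause death.  Returns discounted per-person cost and QALYs, the
    lifetime event tally, and incidence/mortality by detection route.
    """
    if life_table is None:
        raise ValueError("a life table is required")
    tests = tests or TEST_PRESETS
    costs = costs or CostSchedule()
    utilities = utilities or UtilitySchedule()
    rule = surveillance_rule or SurveillanceRule()
    risks = risks or ComplicationRisks()
    params.validate()
    costs.validate()
    utilities.validate()
    n_cycles = end_age - start_age
    ages = np.arange(start_age, end_age)
    ops = _overlay_progression_ops(params, life_table, ages)
    schedule = set(round_schedule(strategy))
    never = strategy.never_attender_fraction if strategy.primary_test else 0.0
    cohort = OverlayCohort.initial(never, age=start_age)
    qaly_stream = np.zeros(n_cycles)
    ly_stream = np.zeros(n_cycles)
    cost_stream = np.zeros(n_cycles)
    lifetime = EventTally()
    per_age_tallies: list = []
    u_clin = np.asarray(utilities.u_cancer, float)
    for k, age in enumerate(ages):
        age = int(age)
        cycle_tally = EventTally()
        if cohort.occupancy[OFF_SURV:OFF_CLIN].sum() > 0.0:
            cohort, t_surv = apply_surveillance(
                cohort, rule, tests["COL"], risks, costs, tests["CTC"]
            )
            cycle_tally.merge(t_surv)
        if age in schedule:
            cohort, t_scr = apply_screening_round(cohort, strategy, tests, rule, risks, costs)
            cycle_tally.merge(t_scr)
        occ = cohort.occupancy
        # utilities accrue on the post-intervention, pre-progression state
        alive_free = occ[:OFF_CLIN].sum()
        clin = occ[OFF_CLIN : OFF_CLIN + 4]
        qaly_now = alive_free * utilities.u_cancer_free + float(clin @ u_clin)
        ly_now = alive_free + clin.sum()
        # progression + competing death
        P_pd, P_pd_clin, P_pd_dead, clin_rows = ops[k]
        new = np.zeros(N_OV)
        clin_inflow = np.zeros(4)
        sym_inflow = np.zeros(4)
        for off in (OFF_POOL, OFF_NEVER, *range(OFF_SURV, OFF_CLIN, N_PD)):
            v = occ[off : off + N_PD]
            if v.sum() <= 0.0:
                continue
            new[off : off + N_PD] += v @ P_pd
            flow_clin = v @ P_pd_clin
            clin_inflow += flow_clin
            sym_inflow += flow_clin
            new[OFF_DEAD_CRC:] += v @ P_pd_dead
        v_clin = occ[OFF_CLIN : OFF_CLIN + 4]
        new[OFF_CLIN : OFF_CLIN + 4] += v_clin * np.diag(clin_rows[:, 0:4])
        new[OFF_DEAD_CRC] += float(v_clin @ clin_rows[:, 4])
        new[OFF_DEAD_PERF] += occ[OFF_DEAD_PERF] + float(v_clin @ clin_rows[:, 5])
        new[OFF_DEAD_OTHER] += occ[OFF_DEAD_OTHER] + float(v_clin @ clin_rows[:, 6])
        new[OFF_DEAD_CRC] += occ[OFF_DEAD_CRC]
        new[OFF_CLIN : OFF_CLIN + 4] += clin_inflow
        cycle_tally.add("crc_deaths", float(v_clin @ clin_rows[:, 4]))
        for s, key in enumerate(STAGE_KEYS):
            cycle_tally.add(f"crc_symptomatic_{key}", sym_inflow[s])
        cycle_tally.cost += float(sym_inflow @ np.asarray(costs.crc_symptomatic))
        if half_cycle:
            alive_free_end = new[:OFF_CLIN].sum()
            clin_end = new[OFF_CLIN : OFF_CLIN + 4]
            qaly_end = alive_free_end * utilities.u_cancer_free + float(clin_end @ u_clin)
            qaly_now = 0.5 * (qaly_now + qaly_end)
            ly_now = 0.5 * (ly_now + alive_free_end + clin_end.sum())
        qaly_stream[k] = qaly_now
        ly_stream[k] = ly_now
        cost_stream[k] = cycle_tally.cost
        lifetime.merge(cycle_tally)
        per_age_tallies.append(cycle_tally)
        cohort = OverlayCohort(age=age + 1, occupancy=new)
    cost_disc, qalys_disc = accumulate(
        qaly_stream, cost_stream, ages, discount_rate, discount_ref_age
    )
    _, ly_disc = accumulate(ly_stream, cost_stream, ages, discount_rate, discount_ref_age)
    inc_by_route = {
        route: lifetime.detected(route) * 1e5
        for route in ("screen_detected", "surveillance_detected", "symptomatic")
    }
    stage_by_route = pd.DataFrame(
        {
            route: [
                lifetime.counts[f"crc_{route}_{s}"] * 1e5 for s in STAGE_KEYS
            ]
            for route in ("screen_detected", "surveillance_detected", "symptomatic")
        },
        index=list(STAGE_KEYS),
    )
    return StrategyResult(
        id=strategy.id,
        cost=cost_disc,
        qalys=qalys_disc,
        cost_undiscounted=float(cost_stream.sum()),
        qalys_undiscounted=float(qaly_stream.sum()),
        life_years=ly_disc,
        tally=lifetime.per_100k(),
        lifetime_incidence=sum(inc_by_route.values()),
        lifetime_mortality=lifetime.counts["crc_deaths"] * 1e5,
        stage_by_route=stage_by_route,
    )
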