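"""Annual-cycle Markov cohort model of colorectal neoplasia natural history.

A closed cohort enters at age 30 free of adenomas and preclinical cancer and
is followed to age 100.  Each year, normal epithelium can give rise to a
low-risk adenoma (age-band-dependent probability) which may progress to an
intermediate/high-risk adenoma and on to preclinical stage I cancer;
preclinical cancers progress through AJCC stages and present clinically with
stage-specific probabilities; clinically diagnosed cancers face
stage-specific annual cancer-death probabilities.  A fraction ``p_direct``
(base case 14%) of incident cancers arises directly from normal epithelium
without a prior adenoma; new lesions split distal:proximal 70:30.  All live
states face an age-dependent competing other-cause death probability taken
from a life table, applied multiplicatively after the disease transitions.

The event order within a cycle is: (1) screening/surveillance interventions
when an overlay is active (see ``screening.py``), (2) natural-history
progression, (3) competing other-cause death folded into the same transition
matrix as a (1 - q_other) scaling of live destinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .states import (
    IDX_AD_HIGH_D,
    IDX_AD_HIGH_P,
    IDX_AD_LOW_D,
    IDX_AD_LOW_P,
    IDX_ADENOMA,
    IDX_CLIN,
    IDX_DEAD_CRC,
    IDX_DEAD_OTHER,
    IDX_NORMAL,
    IDX_PRECLIN_ALL,
    N_EXT,
    idx_preclin,
)

START_AGE = 30
END_AGE = 100
AGE_BANDS = ((30, 39), (40, 49), (50, 59), (60, 69), (70, 120))


class InvalidParameterError(ValueError):
    """A transition probability left [0, 1] or rows failed to compose."""


@dataclass
class LifeTable:
    """Annual other-cause death probability ``q_other`` by integer age.

    ``ages[i]`` maps to ``q[i]``; must cover every integer age 30..100 and
    satisfy ``q(100) == 1`` (conventional absorption at the horizon).
    """

    ages: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.q = np.asarray(self.q, dtype=float)
        if self.ages.shape != self.q.shape:
            raise ValueError("ages and q must align")
        if np.any((self.q < 0) | (self.q > 1)):
            raise ValueError("q_other must lie in [0, 1]")
        missing = set(range(START_AGE, END_AGE + 1)) - set(self.ages.tolist())
        if missing:
            raise ValueError(f"life table missing ages {sorted(missing)[:5]}...")
        self._lookup = dict(zip(self.ages.tolist(), self.q.tolist()))
        if self._lookup[END_AGE] != 1.0:
            raise ValueError("q_other(100) must equal 1")

    def q_other(self, age: int) -> float:
        return self._lookup[int(age)]

    def q_vector(self, lo: int = START_AGE, hi: int = END_AGE) -> np.ndarray:
        return np.array([self._lookup[a] for a in range(lo, hi + 1)])

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(df["age"].to_numpy(), df["q_other"].to_numpy())

    def to_csv(self, path) -> None:
        # %.17g keeps the round trip bit-exact
        pd.DataFrame({"age": self.ages, "q_other": self.q}).to_csv(
            path, index=False, float_format="%.17g"
        )


# ordered names of the calibratable scalar parameters (flat vector layout)
PARAM_NAMES = (
    "p_normal_to_lowrisk_30_39",
    "p_normal_to_lowrisk_40_49",
    "p_normal_to_lowrisk_50_59",
    "p_normal_to_lowrisk_60_69",
    "p_normal_to_lowrisk_70plus",
    "p_low_to_high",
    "p_high_to_crcI",
    "p_stage_progress_I_II",
    "p_stage_progress_II_III",
    "p_stage_progress_III_IV",
    "p_symptomatic_I",
    "p_symptomatic_II",
    "p_symptomatic_III",
    "p_symptomatic_IV",
    "p_crc_death_I",
    "p_crc_death_II",
    "p_crc_death_III",
    "p_crc_death_IV",
)


@dataclass
class NaturalHistoryParams:
    """Annual transition probabilities of the natural-history model.

    ``p_normal_to_lowrisk`` is indexed by 10-year age band (30-39, 40-49,
    50-59, 60-69, 70+).  ``p_direct`` is the fraction of incident cancers
    arising without a prior adenoma; it is enforced as a flow-ratio
    constraint when the age-specific direct-entry rates are resolved (see
    :func:`resolve_direct_rates`), not by per-cycle renormalisation.
    """

    p_normal_to_lowrisk: np.ndarray  # (5,) by age band
    p_low_to_high: float
    p_high_to_crcI: float
    p_stage_progress: np.ndarray  # (3,) I->II, II->III, III->IV
    p_symptomatic: np.ndarray  # (4,) stage I..IV
    p_crc_death: np.ndarray  # (4,) stage I..IV, annual in clinical states
    p_direct: float = 0.14
    frac_distal: float = 0.70
    # resolved age-specific normal -> preclinical-I direct rates (ages 30..100)
    direct_rates: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.p_normal_to_lowrisk = np.asarray(self.p_normal_to_lowrisk, float)
        self.p_stage_progress = np.asarray(self.p_stage_progress, float)
        self.p_symptomatic = np.asarray(self.p_symptomatic, float)
        self.p_crc_death = np.asarray(self.p_crc_death, float)

    def validate(self) -> None:
        for name, arr in (
            ("p_normal_to_lowrisk", self.p_normal_to_lowrisk),
            ("p_stage_progress", self.p_stage_progress),
            ("p_symptomatic", self.p_symptomatic),
            ("p_crc_death", self.p_crc_death),
        ):
            a = np.asarray(arr, float)
            if np.any((a < 0) | (a > 1)) or not np.all(np.isfinite(a)):
                raise InvalidParameterError(f"{name} outside [0, 1]")
        for name, v in (
            ("p_low_to_high", self.p_low_to_high),
            ("p_high_to_crcI", self.p_high_to_crcI),
            ("p_direct", self.p_direct),
            ("frac_distal", self.frac_distal),
        ):
            if not (0.0 <= v <= 1.0):
                raise InvalidParameterError(f"{name}={v} outside [0, 1]")
        if np.any(self.p_crc_death[1:] + 1e-12 < self.p_crc_death[:-1]):
            raise InvalidParameterError("p_crc_death must be non-decreasing in stage")
        exits = self.p_stage_progress + self.p_symptomatic[:3]
        if np.any(exits > 1.0):
            raise InvalidParameterError("stage progression + presentation exceeds 1")

    def onset(self, age: int) -> float:
        for i, (lo, hi) in enumerate(AGE_BANDS):
            if lo <= age <= hi:
                return float(self.p_normal_to_lowrisk[i])
        return float(self.p_normal_to_lowrisk[-1])

    # -- flat-vector view used by the calibration layer ----------------------

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [
                self.p_normal_to_lowrisk,
                [self.p_low_to_high, self.p_high_to_crcI],
                self.p_stage_progress,
                self.p_symptomatic,
                self.p_crc_death,
            ]
        )

    @classmethod
    def from_vector(
        cls, vec: np.ndarray, p_direct: float = 0.14, frac_distal: float = 0.70
    ) -> "NaturalHistoryParams":
        vec = np.asarray(vec, float)
        if vec.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected vector of length {len(PARAM_NAMES)}")
        return cls(
            p_normal_to_lowrisk=vec[0:5].copy(),
            p_low_to_high=float(vec[5]),
            p_high_to_crcI=float(vec[6]),
            p_stage_progress=vec[7:10].copy(),
            p_symptomatic=vec[10:14].copy(),
            p_crc_death=vec[14:18].copy(),
            p_direct=p_direct,
            frac_distal=frac_distal,
        )

    def to_dict(self) -> dict:
        d = dict(zip(PARAM_NAMES, self.to_vector().tolist()))
        d["p_direct"] = self.p_direct
        d["frac_distal"] = self.frac_distal
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NaturalHistoryParams":
        vec = np.array([d[name] for name in PARAM_NAMES])
        return cls.from_vector(
            vec,
            p_direct=float(d.get("p_direct", 0.14)),
            frac_distal=float(d.get("frac_distal", 0.70)),
        )


@dataclass
class CohortState:
    """Occupancy distribution over the extended state space at one age."""

    age: int
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=float)

    @property
    def total(self) -> float:
        return float(self.occupancy.sum())

    @property
    def alive(self) -> float:
        occ = self.occupancy
        return float(occ.sum() - occ[IDX_DEAD_CRC] - occ[IDX_DEAD_OTHER] - occ[26])

    @classmethod
    def initial(cls, age: int = START_AGE, n: int = N_EXT) -> "CohortState":
        occ = np.zeros(n)
        occ[IDX_NORMAL] = 1.0
        return cls(age=age, occupancy=occ)


def _progression_matrix(params: NaturalHistoryParams, age: int, direct_rate: float) -> np.ndarray:
    """Disease-transition matrix for one age, before other-cause death."""
    m = np.eye(N_EXT)
    f = params.frac_distal
    onset = params.onset(age)
    if onset + direct_rate > 1.0:
        raise InvalidParameterError(
            f"normal-state outflow {onset + direct_rate:.3f} exceeds 1 at age {age}"
        )
    # normal -> new low-risk adenoma / direct preclinical stage I
    m[IDX_NORMAL, IDX_NORMAL] = 1.0 - onset - direct_rate
    m[IDX_NORMAL, IDX_AD_LOW_D] = onset * f
    m[IDX_NORMAL, IDX_AD_LOW_P] = onset * (1.0 - f)
    m[IDX_NORMAL, idx_preclin(1, True, True)] = direct_rate * f
    m[IDX_NORMAL, idx_preclin(1, False, True)] = direct_rate * (1.0 - f)
    # adenoma progression (location preserved)
    for lo_idx, hi_idx in ((IDX_AD_LOW_D, IDX_AD_HIGH_D), (IDX_AD_LOW_P, IDX_AD_HIGH_P)):
        m[lo_idx, lo_idx] = 1.0 - params.p_low_to_high
        m[lo_idx, hi_idx] = params.p_low_to_high
    for hi_idx, distal in ((IDX_AD_HIGH_D, True), (IDX_AD_HIGH_P, False)):
        m[hi_idx, hi_idx] = 1.0 - params.p_high_to_crcI
        m[hi_idx, idx_preclin(1, distal, False)] = params.p_high_to_crcI
    # preclinical: stage progression competes with clinical presentation
    for s in range(1, 5):
        p_prog = params.p_stage_progress[s - 1] if s < 4 else 0.0
        p_sym = params.p_symptomatic[s - 1]
        for distal in (True, False):
            for direct in (False, True):
                i = idx_preclin(s, distal, direct)
                m[i, i] = 1.0 - p_prog - p_sym
                if s < 4:
                    m[i, idx_preclin(s + 1, distal, direct)] = p_prog
                m[i, IDX_CLIN[s - 1]] = p_sym
    # clinical: stage-specific cancer death
    for s in range(1, 5):
        i = IDX_CLIN[s - 1]
        m[i, i] = 1.0 - params.p_crc_death[s - 1]
        m[i, IDX_DEAD_CRC] = params.p_crc_death[s - 1]
    return m


def apply_other_cause_death(m: np.ndarray, q: float) -> np.ndarray:
    """Fold competing other-cause mortality into a disease matrix in place.

    Live destinations of every live row are scaled by ``1 - q``; the removed
    mass accrues to ``dead_other``.  Transitions already bound for a death
    state are left unscaled.
    """
    live = [i for i in range(m.shape[0]) if i not in (IDX_DEAD_CRC, 26, IDX_DEAD_OTHER)]
    live_mass = m[np.ix_(live, live)].sum(axis=1)
    m[np.ix_(live, live)] *= 1.0 - q
    m[live, IDX_DEAD_OTHER] += q * live_mass
    return m


def transition_matrix(
    params: NaturalHistoryParams,
    life_table: LifeTable,
    age: int,
    direct_rate: Optional[float] = None,
) -> np.ndarray:
    """Row-stochastic annual transition matrix over the extended state space.

    ``direct_rate`` is the age-specific normal -> preclinical-I probability
    of the direct (non-adenoma) pathway; when ``None`` it is taken from
    ``params.direct_rates`` (resolved via :func:`resolve_direct_rates`) or
    zero if unresolved.
    """
    if not (START_AGE <= age <= END_AGE):
        raise ValueError(f"age {age} outside [{START_AGE}, {END_AGE}]")
    params.validate()
    if direct_rate is None:
        if params.direct_rates is not None:
            direct_rate = float(params.direct_rates[age - START_AGE])
        else:
            direct_rate = 0.0
    m = _progression_matrix(params, age, direct_rate)
    apply_other_cause_death(m, life_table.q_other(age))
    sums = m.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-12) or np.any(m < -1e-15):
        raise InvalidParameterError("transition matrix rows failed to compose")
    return m


def advance_cycle(cohort: CohortState, matrix: np.ndarray) -> CohortState:
    """One annual cycle: postmultiply occupancy by the matrix, age + 1."""
    if matrix.shape != (cohort.occupancy.size, cohort.occupancy.size):
        raise ValueError(
            f"matrix shape {matrix.shape} does not match occupancy "
            f"size {cohort.occupancy.size}"
        )
    return CohortState(age=cohort.age + 1, occupancy=cohort.occupancy @ matrix)


@dataclass
class NaturalHistoryResult:
    """Trajectory and derived epidemiological series from a cohort run.

    Rates are per 100,000 cohort members entering at age 30.  ``ages`` holds
    cycle start ages (30..99); ``occupancy`` has one extra row for the final
    age.  Prevalence series are proportions among the surviving cohort.
    """

    ages: np.ndarray  # (n_cycles,)
    occupancy: np.ndarray  # (n_cycles + 1, N_EXT)
    incidence_by_stage: np.ndarray  # (n_cycles, 4) flow into clinical, per 100k
    incidence_direct: np.ndarray  # (n_cycles,) direct-provenance part, per 100k
    crc_deaths: np.ndarray  # (n_cycles,) flow into dead_crc, per 100k
    adenoma_prevalence: np.ndarray  # (n_cycles,) proportion among alive
    preclin_prevalence: np.ndarray  # (n_cycles,)

    @property
    def incidence(self) -> np.ndarray:
        return self.incidence_by_stage.sum(axis=1)

    @property
    def lifetime_incidence(self) -> float:
        """Cumulative clinical CRC incidence per 100,000 cohort members."""
        return float(self.incidence_by_stage.sum())

    @property
    def lifetime_mortality(self) -> float:
        return float(self.crc_deaths.sum())

    @property
    def stage_distribution(self) -> np.ndarray:
        """Share of lifetime incident cancers by stage at diagnosis."""
        tot = self.incidence_by_stage.sum()
        if tot == 0:
            return np.zeros(4)
        return self.incidence_by_stage.sum(axis=0) / tot

    @property
    def direct_fraction(self) -> float:
        """Fraction of lifetime incident cancers arising without an adenoma."""
        tot = self.incidence_by_stage.sum()
        return float(self.incidence_direct.sum() / tot) if tot > 0 else 0.0

    def to_frame(self) -> pd.DataFrame:
        from .states import build_extended_states

        cols = [str(s) + ("" if s.provenance is None else f"/{s.provenance.value}")
                for s in build_extended_states()]
        df = pd.DataFrame(
            self.occupancy[:-1], columns=cols, index=pd.Index(self.ages, name="age")
        )
        df["incidence_per_100k"] = self.incidence
        for s in range(4):
            df[f"incidence_stage_{'I' * (s + 1) if s < 3 else 'IV'}_per_100k"] = (
                self.incidence_by_stage[:, s]
            )
        df["crc_mortality_per_100k"] = self.crc_deaths
        df["adenoma_prevalence"] = self.adenoma_prevalence
        df["preclin_cancer_prevalence"] = self.preclin_prevalence
        return df


_LIVE = np.array([i for i in range(N_EXT) if i not in (IDX_DEAD_CRC, 26, IDX_DEAD_OTHER)])
_STAGE_COLS = np.array(
    [[idx_preclin(s, d, dr) for d in (True, False) for dr in (False, True)] for s in (1, 2, 3, 4)]
)
_DIRECT_COLS = np.array([idx_preclin(s, d, True) for s in (1, 2, 3, 4) for d in (True, False)])
_DIRECT_SYM = np.array([s for s in range(4) for _ in (0, 1)])


def _run(
    params: NaturalHistoryParams,
    life_table: LifeTable,
    direct_rates: np.ndarray,
    start_age: int,
    end_age: int,
) -> NaturalHistoryResult:
    n_cycles = end_age - start_age
    ages = np.arange(start_age, end_age)
    occ = np.zeros((n_cycles + 1, N_EXT))
    occ[0, IDX_NORMAL] = 1.0
    inc = np.zeros((n_cycles, 4))
    inc_direct = np.zeros(n_cycles)
    deaths = np.zeros(n_cycles)
    ad_prev = np.zeros(n_cycles)
    pc_prev = np.zeros(n_cycles)
    scale = 1e5
    p_sym = params.p_symptomatic
    f = params.frac_distal
    qs = life_table.q_vector(start_age, end_age - 1)
    # one disease matrix per age band; the direct rate and competing
    # other-cause death are folded in vectorised over the whole age stack
    # (live states occupy the contiguous index block 0..24)
    band_mats = np.stack(
        [_progression_matrix(params, lo, 0.0) for lo, hi in AGE_BANDS]
    )
    band_of_age = np.array(
        [
            next(i for i, (lo, hi) in enumerate(AGE_BANDS) if lo <= a <= hi)
            for a in ages
        ]
    )
    i_dd, i_dp = idx_preclin(1, True, True), idx_preclin(1, False, True)
    rates = np.zeros(n_cycles)
    rates[: min(n_cycles, len(direct_rates))] = direct_rates[:n_cycles]
    mats = band_mats[band_of_age]  # (n_cycles, 28, 28) fresh copy
    mats[:, IDX_NORMAL, IDX_NORMAL] -= rates
    mats[:, IDX_NORMAL, i_dd] = rates * f
    mats[:, IDX_NORMAL, i_dp] = rates * (1.0 - f)
    mats[:, :25, IDX_DEAD_OTHER] += qs[:, None] * mats[:, :25, :25].sum(axis=2)
    mats[:, :25, :25] *= (1.0 - qs)[:, None, None]
    for k in range(n_cycles):
        occ[k + 1] = occ[k] @ mats[k]
    # flows counted as arrivals in the destination state of each cycle
    pre = occ[:-1]
    stage_mass = pre[:, _STAGE_COLS].sum(axis=2)  # (n_cycles, 4)
    inc[:] = stage_mass * p_sym[None, :] * (1.0 - qs)[:, None] * scale
    inc_direct[:] = (
        (pre[:, _DIRECT_COLS] * p_sym[_DIRECT_SYM][None, :]).sum(axis=1)
        * (1.0 - qs)
        * scale
    )
    deaths[:] = (pre[:, IDX_CLIN] * params.p_crc_death[None, :]).sum(axis=1) * scale
    alive = pre[:, :25].sum(axis=1)
    ok = alive > 0
    ad_prev[ok] = pre[ok][:, IDX_ADENOMA].sum(axis=1) / alive[ok]
    pc_prev[ok] = pre[ok][:, IDX_PRECLIN_ALL].sum(axis=1) / alive[ok]
    return NaturalHistoryResult(
        ages=ages,
        occupancy=occ,
        incidence_by_stage=inc,
        incidence_direct=inc_direct,
        crc_deaths=deaths,
        adenoma_prevalence=ad_prev,
        preclin_prevalence=pc_prev,
    )


def resolve_direct_rates(
    params: NaturalHistoryParams,
    life_table: LifeTable,
    start_age: int = START_AGE,
    end_age: int = END_AGE,
) -> np.ndarray:
    """Age-specific direct-pathway entry rates enforcing the flow ratio.

    A preliminary run with the direct pathway switched off yields, at each
    age, the via-adenoma flow into preclinical stage I and the occupancy of
    the normal state.  The direct rate is then set so that direct entrants
    form the fraction ``p_direct`` of all preclinical-I entrants at that
    age: ``r(age) = p_direct / (1 - p_direct) * via_flow(age) / normal(age)``.
    """
    n_cycles = end_age - start_age
    zeros = np.zeros(n_cycles)
    base = _run(params, life_table, zeros, start_age, end_age)
    rates = np.zeros(n_cycles + 1)
    if params.p_direct <= 0:
        return rates
    ratio = params.p_direct / (1.0 - params.p_direct)
    hi_cols = [IDX_AD_HIGH_D, IDX_AD_HIGH_P]
    for k in range(n_cycles):
        v = base.occupancy[k]
        via_flow = v[hi_cols].sum() * params.p_high_to_crcI
        normal = v[IDX_NORMAL]
        if normal > 1e-12:
            r = ratio * via_flow / normal
            rates[k] = min(r, 1.0 - params.onset(start_age + k))
    return rates


def run_natural_history(
    params: NaturalHistoryParams,
    life_table: LifeTable,
    start_age: int = START_AGE,
    end_age: int = END_AGE,
) -> NaturalHistoryResult:
    """Full cohort run absent screening; resolves the direct pathway first."""
    params.validate()
    if params.direct_rates is not None:
        rates = params.direct_rates
    else:
        rates = resolve_direct_rates(params, life_table, start_age, end_age)
        params.direct_rates = rates
    return _run(params, life_table, rates, start_age, end_age)


def with_resolved_direct(
    params: NaturalHistoryParams, life_table: LifeTable
) -> NaturalHistoryParams:
    """Copy of ``params`` with direct-pathway rates resolved and cached."""
    p = replace(params, direct_rates=None)
    p.direct_rates = resolve_direct_rates(p, life_table)
    return p
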