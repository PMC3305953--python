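"""Synthetic study inputs: life tables, calibration targets, parameter registry.

No deposited data accompany the analysis this package implements, so every
input can be generated here: a Gompertz life table emulating national
all-cause mortality, calibration targets produced by running the
natural-history model forward under a known "true" parameter set with
additive normal observation noise, and the full base-case / range /
distribution registry of the uncertain model parameters.

The reference "true" natural-history parameter set is synthetic: it was
chosen once so that the no-screening model reproduces the scale of the
population outcomes the analysis is anchored to (lifetime clinical CRC
incidence about 5,000-5,500 and CRC mortality about 2,200-2,400 per
100,000 cohort members entering at age 30; stage distribution at diagnosis
near 12/25/35/29%; adenoma prevalence rising through 15-22% over ages
55-65; preclinical cancer prevalence around 0.4%), with clinically
plausible dwell times.  It stands in for a national registry calibration
and is not a published transition set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .calibration import CalibrationTargets
from .natural_history import (
    LifeTable,
    NaturalHistoryParams,
    resolve_direct_rates,
    run_natural_history,
)
from .uncertainty import DistributionSpec


def reference_params() -> NaturalHistoryParams:
    """The synthetic reference ("true") natural-history parameter set."""
    return NaturalHistoryParams(
        p_normal_to_lowrisk=np.array([0.00094, 0.01007, 0.01007, 0.01007, 0.01290]),
        p_low_to_high=0.02102,
        p_high_to_crcI=0.04223,
        p_stage_progress=np.array([0.68640, 0.59640, 0.32796]),
        p_symptomatic=np.array([0.08472, 0.22150, 0.41456, 0.67879]),
        p_crc_death=np.array([0.01865, 0.03391, 0.03391, 0.35172]),
        p_direct=0.14,
        frac_distal=0.70,
    )


@dataclass
class SyntheticScenario:
    """Generator configuration: truth, life-table shape, noise level, seed."""

    true_params: NaturalHistoryParams = field(default_factory=reference_params)
    gompertz_a: float = 3e-5
    gompertz_b: float = 0.095
    observation_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gompertz_a <= 0 or self.gompertz_b <= 0:
            raise ValueError("Gompertz hazard parameters must be positive")
        if self.observation_cv <= 0:
            raise ValueError("observation CV must be positive")


def generate_life_table(
    a: float = 3e-5, b: float = 0.095, seed: int = 0
) -> LifeTable:
    """Gompertz-like life table: q(age) = 1 - exp(-a * exp(b * age)).

    Deterministic given the shape parameters (``seed`` is accepted for
    interface symmetry); q is clipped to [0, 1] and forced to 1 at age 100.
    """
    ages = np.arange(0, 101)
    q = 1.0 - np.exp(-a * np.exp(b * ages))
    q = np.clip(q, 0.0, 1.0)
    q[-1] = 1.0
    return LifeTable(ages, q)


INCIDENCE_BANDS = tuple((lo, lo + 4) for lo in range(50, 85, 5))  # 50-54 .. 80-84
PREVALENCE_AGES = (55, 60, 65)


def generate_targets(scenario: SyntheticScenario) -> tuple:
    """Calibration targets from a forward run under the scenario's truth.

    Emits stage-specific incidence and total CRC mortality (annual rates
    per 100,000 alive, 5-year bands 50-84) plus adenoma and preclinical
    cancer prevalence at ages 55/60/65, each perturbed by
    N(0, (CV * value)^2) with the sd column set to CV * value (floored to
    keep sds positive for near-zero observations).  Returns
    (CalibrationTargets, truth params with direct rates resolved).
    """
    rng = np.random.default_rng(scenario.seed)
    lt = generate_life_table(scenario.gompertz_a, scenario.gompertz_b)
    truth = scenario.true_params
    res = run_natural_history(truth, lt)
    alive = res.occupancy[:-1, :25].sum(axis=1)
    inc_rate = res.incidence_by_stage / alive[:, None]
    mort_rate = res.crc_deaths / alive
    cv = scenario.observation_cv
    rows = []

    def emit(quantity, lo, hi, stage, value, floor):
        sd = max(cv * value, cv * floor)
        noisy = max(value + rng.normal(0.0, sd), 0.0)
        rows.append(
            {"quantity": quantity, "age_lo": lo, "age_hi": hi, "stage": stage,
             "value": noisy, "sd": sd}
        )

    for lo, hi in INCIDENCE_BANDS:
        k0, k1 = lo - 30, hi - 30 + 1
        for s in range(1, 5):
            emit("incidence_by_stage", lo, hi, s, float(inc_rate[k0:k1, s - 1].mean()), 1.0)
        emit("mortality", lo, hi, 0, float(mort_rate[k0:k1].mean()), 1.0)
    for age in PREVALENCE_AGES:
        k = age - 30
        emit("adenoma_prevalence", age, age, 0, float(res.adenoma_prevalence[k]), 1e-3)
        emit("preclin_cancer_prevalence", age, age, 0, float(res.preclin_prevalence[k]), 1e-4)
    return CalibrationTargets(pd.DataFrame(rows)), truth


# -- base-case parameter registry -----------------------------------------


@dataclass(frozen=True)
class ParameterSpec:
    """Base-case value, sensitivity-analysis range, and PSA distribution."""

    name: str
    base: float
    lo: Optional[float] = None  # one-way SA range
    hi: Optional[float] = None
    dist: Optional[DistributionSpec] = None
    label: str = ""


def _beta(name, a, b, group=None):
    return DistributionSpec(name, "beta", alpha=a, beta=b, corr_group=group)


def _unif(name, lo, hi, group=None):
    return DistributionSpec(name, "uniform", lo=lo, hi=hi, corr_group=group)


def _fixed(name):
    return DistributionSpec(name, "fixed")


def _moment_matched_beta(name, mean, lo, hi, group=None):
    """Beta with the given mean and sd = (hi - lo) / 3.92 (range as 95% CI)."""
    sd = (hi - lo) / 3.92
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    return _beta(name, mean * nu, (1.0 - mean) * nu, group)


def default_parameter_registry(reparameterise_fit_crc_beta: bool = True) -> dict:
    """Registry of every uncertain parameter: base case, SA range, PSA dist.

    The distribution printed for the FIT cancer sensitivity, Beta(35.29,
    143.08), has mean ~0.198 -- inconsistent with its 71% base case and
    67-75% range.  By default that row is re-parameterised by moment
    matching to mean 0.71 with the printed range read as a 95% interval;
    pass ``reparameterise_fit_crc_beta=False`` to use the printed shape
    verbatim.
    """
    P = ParameterSpec
    fit_crc_dist = (
        _moment_matched_beta("fit_sens_crc", 0.71, 0.67, 0.75, "fit_sens")
        if reparameterise_fit_crc_beta
        else _beta("fit_sens_crc", 35.29, 143.08, "fit_sens")
    )
    specs = [
        # screening test performance
        P("gfobt_sens_adenoma", 0.11, 0.10, 0.12, _beta("gfobt_sens_adenoma", 11.40, 92.10, "gfobt_sens"),
          "gFOBT sensitivity for adenomas"),
        P("gfobt_sens_crc", 0.36, 0.31, 0.42, _beta("gfobt_sens_crc", 105.00, 186.60, "gfobt_sens"),
          "gFOBT sensitivity for CRC"),
        P("gfobt_spec", 0.97, 0.96, 0.98, _beta("gfobt_spec", 1083.40, 33.50),
          "gFOBT specificity for adenomas and CRC"),
        P("fit_sens_adenoma", 0.21, 0.19, 0.22, _beta("fit_sens_adenoma", 594.62, 2236.92, "fit_sens"),
          "FIT sensitivity for adenomas"),
        P("fit_sens_crc", 0.71, 0.67, 0.75, fit_crc_dist, "FIT sensitivity for CRC"),
        P("fit_spec", 0.95, 0.94, 0.96, _beta("fit_spec", 1732.57, 91.19),
          "FIT specificity for adenomas and CRC"),
        P("fsig_sens_adenoma_low", 0.65, 0.60, 0.70, _beta("fsig_sens_adenoma_low", 235.00, 126.54, "fsig_sens"),
          "FSIG sensitivity for low-risk distal adenomas"),
        P("fsig_sens_adenoma_high", 0.74, 0.68, 0.78, _beta("fsig_sens_adenoma_high", 180.00, 63.24, "fsig_sens"),
          "FSIG sensitivity for intermediate/high-risk distal adenomas"),
        P("fsig_sens_crc", 0.90, 0.85, 0.95, _beta("fsig_sens_crc", 90.00, 10.00, "fsig_sens"),
          "FSIG sensitivity for distal CRC"),
        P("fsig_spec", 0.92, 0.90, 0.95, _beta("fsig_spec", 250.00, 21.74),
          "FSIG specificity for distal adenomas and CRC"),
        # uptake and compliance
        P("gfobt_uptake", 0.53, 0.32, 0.70, _unif("gfobt_uptake", 0.32, 0.70), "gFOBT uptake"),
        P("fit_uptake", 0.53, 0.32, 0.70, _unif("fit_uptake", 0.32, 0.70), "FIT uptake"),
        P("fsig_uptake", 0.39, 0.24, 0.67, _unif("fsig_uptake", 0.24, 0.67), "FSIG uptake"),
        P("never_attender_fraction", 0.13, 0.0, 0.41, _fixed("never_attender_fraction"),
          "% of individuals who never accept an offer of screening"),
        P("col_compliance", 0.86, 0.81, 0.90, _unif("col_compliance", 0.81, 0.90),
          "COL compliance (diagnostic test)"),
        # diagnostic test performance
        P("col_sens_adenoma_low", 0.77, 0.73, 0.80, _beta("col_sens_adenoma_low", 350.00, 104.55, "col_sens"),
          "COL sensitivity for low-risk adenomas"),
        P("col_sens_adenoma_high", 0.98, 0.93, 0.99, _unif("col_sens_adenoma_high", 0.93, 0.99, "col_sens"),
          "COL sensitivity for intermediate/high-risk adenomas"),
        P("col_sens_crc", 0.98, 0.95, 0.99, _unif("col_sens_crc", 0.95, 0.99, "col_sens"),
          "COL sensitivity for CRC"),
        P("col_spec", 0.97, 0.96, 0.98, _beta("col_spec", 970.00, 30.00),
          "COL specificity for adenomas and CRC"),
        P("ctc_sens_adenoma_low", 0.53, 0.45, 0.60, _beta("ctc_sens_adenoma_low", 80.00, 70.94, "ctc_sens"),
          "CTC sensitivity for low-risk adenomas"),
        P("ctc_sens_adenoma_high", 0.85, 0.48, 1.00, _beta("ctc_sens_adenoma_high", 4.50, 0.79, "ctc_sens"),
          "CTC sensitivity for intermediate/high-risk adenomas"),
        P("ctc_sens_crc", 0.85, 0.75, 0.95, _beta("ctc_sens_crc", 50.00, 8.82, "ctc_sens"),
          "CTC sensitivity for CRC"),
        P("ctc_spec", 0.86, 0.80, 0.90, _beta("ctc_spec", 140.00, 22.79),
          "CTC specificity for adenomas and CRC"),
        P("adenomas_per_polypectomy", 1.9, None, None, _fixed("adenomas_per_polypectomy"),
          "Average number of adenomas removed per person"),
        # surveillance
        P("frac_high_risk_surveillance", 0.29, None, None, _fixed("frac_high_risk_surveillance"),
          "% of intermediate/high-risk adenomas that were high-risk"),
        P("surveillance_compliance", 0.86, 0.81, 0.90, _unif("surveillance_compliance", 0.81, 0.90),
          "COL compliance (surveillance)"),
        # harms
        P("fsig_perforation", 0.00002, 0.0, 0.00051, _unif("fsig_perforation", 0.0, 0.00051),
          "FSIG probability of perforation"),
        P("fsig_perforation_death", 0.06452, 0.0, 0.0907, _unif("fsig_perforation_death", 0.0, 0.0907),
          "FSIG probability of death following perforation"),
        P("fsig_bleed", 0.00029, 0.00002, 0.00054, _unif("fsig_bleed", 0.00002, 0.00054),
          "Probability of major bleeding following FSIG"),
        P("col_perforation_polypectomy", 0.00216, 0.00168, 0.00298,
          _unif("col_perforation_polypectomy", 0.00168, 0.00298),
          "COL probability of perforation (with polypectomy)"),
        P("col_perforation_no_polypectomy", 0.00107, 0.00010, 0.00249,
          _unif("col_perforation_no_polypectomy", 0.00010, 0.00249),
          "COL probability of perforation (without polypectomy)"),
        P("col_perforation_death", 0.05195, 0.0, 0.0907, _unif("col_perforation_death", 0.0, 0.0907),
          "COL probability of death following perforation"),
        P("col_bleed", 0.00379, 0.00065, 0.00412, _unif("col_bleed", 0.00065, 0.00412),
          "Probability of major bleeding following COL"),
        # health-related quality of life
        P("u_cancer_free", 0.94, None, None, _fixed("u_cancer_free"), "Utility: cancer free"),
        P("u_cancer", 0.80, 0.43, 0.94,
          DistributionSpec("u_cancer", "scaled_beta", alpha=3.92, beta=0.69, scale=0.94),
          "Utility: stage I-IV cancer"),
        # costs (2008 euro)
        P("cost_gfobt_kit", 1.70, 1.36, 2.04, _unif("cost_gfobt_kit", 1.36, 2.04), "gFOBT kit"),
        P("cost_gfobt_processing", 7.81, 6.25, 9.37, _unif("cost_gfobt_processing", 6.25, 9.37),
          "gFOBT processing/analysis"),
        P("cost_fit_kit", 3.75, 3.00, 4.50, _unif("cost_fit_kit", 3.00, 4.50), "FIT kit"),
        P("cost_fit_processing", 11.60, 9.28, 13.92, _unif("cost_fit_processing", 9.28, 13.92),
          "FIT processing/analysis"),
        P("cost_fsig", 150.0, 120.0, 180.0, _unif("cost_fsig", 120.0, 180.0), "Cost of FSIG"),
        P("cost_col", 650.0, 520.0, 780.0, _unif("cost_col", 520.0, 780.0), "Cost of COL"),
        P("cost_ctc", 550.0, 440.0, 660.0, _unif("cost_ctc", 440.0, 660.0), "Cost of CTC"),
        P("cost_perforation", 10_200.0, 8_160.0, 12_240.0,
          _unif("cost_perforation", 8_160.0, 12_240.0), "Cost of treating bowel perforation"),
        P("cost_bleed", 3_079.0, 2_463.0, 3_695.0, _unif("cost_bleed", 2_463.0, 3_695.0),
          "Cost of admittance for bleeding"),
        P("cost_pathology_adenoma", 65.0, 52.0, 78.0, _unif("cost_pathology_adenoma", 52.0, 78.0),
          "Pathology cost for adenoma"),
        P("cost_pathology_cancer", 530.0, 424.0, 636.0, _unif("cost_pathology_cancer", 424.0, 636.0),
          "Pathology cost for cancer"),
        P("cost_crc_sympt_I", 23_688.0, 18_950.0, 28_425.0,
          _unif("cost_crc_sympt_I", 18_950.0, 28_425.0), "Lifetime cost stage I CRC - symptomatic"),
        P("cost_crc_sympt_II", 37_180.0, 29_744.0, 44_616.0,
          _unif("cost_crc_sympt_II", 29_744.0, 44_616.0), "Lifetime cost stage II CRC - symptomatic"),
        P("cost_crc_sympt_III", 48_835.0, 39_068.0, 58_602.0,
          _unif("cost_crc_sympt_III", 39_068.0, 58_602.0), "Lifetime cost stage III CRC - symptomatic"),
        P("cost_crc_sympt_IV", 36_602.0, 29_281.0, 43_922.0,
          _unif("cost_crc_sympt_IV", 29_281.0, 43_922.0), "Lifetime cost stage IV CRC - symptomatic"),
        P("cost_crc_screen_I", 22_885.0, 18_308.0, 27_462.0,
          _unif("cost_crc_screen_I", 18_308.0, 27_462.0), "Lifetime cost stage I CRC - screen-detected"),
        P("cost_crc_screen_II", 36_377.0, 29_102.0, 43_652.0,
          _unif("cost_crc_screen_II", 29_102.0, 43_652.0), "Lifetime cost stage II CRC - screen-detected"),
        P("cost_crc_screen_III", 48_032.0, 38_426.0, 57_638.0,
          _unif("cost_crc_screen_III", 38_426.0, 57_638.0), "Lifetime cost stage III CRC - screen-detected"),
        P("cost_crc_screen_IV", 35_799.0, 28_639.0, 42_959.0,
          _unif("cost_crc_screen_IV", 28_639.0, 42_959.0), "Lifetime cost stage IV CRC - screen-detected"),
        # discounting
        P("discount_rate", 0.04, 0.0, 0.06, _fixed("discount_rate"),
          "Discount rate for costs and benefits"),
    ]
    return {p.name: p for p in specs}


def base_case_values(registry: Optional[dict] = None) -> dict:
    reg = registry or default_parameter_registry()
    return {name: p.base for name, p in reg.items()}


def psa_specs(registry: Optional[dict] = None) -> list:
    """Distribution specs for the PSA plus the joint natural-history draw."""
    reg = registry or default_parameter_registry()
    specs = [p.dist for p in reg.values() if p.dist is not None]
    specs.append(DistributionSpec("natural_history", "posterior_set"))
    return specs


def sa_ranges(registry: Optional[dict] = None) -> dict:
    """Parameter -> (lo, hi) one-way sensitivity-analysis ranges."""
    reg = registry or default_parameter_registry()
    return {
        name: (p.lo, p.hi) for name, p in reg.items() if p.lo is not None and p.hi is not None
    }
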