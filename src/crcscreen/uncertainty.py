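"""One-way and probabilistic sensitivity analysis.

Every uncertain model parameter carries a :class:`DistributionSpec` (beta,
uniform, or a scaled beta such as the cancer utility 0.94 x Beta(3.92,
0.69)).  Parameters judged inter-dependent (a test's sensitivities for
adenomas and for cancer) belong to a correlation group: one shared uniform
quantile per draw is mapped through each member's inverse CDF, giving
perfectly rank-correlated samples.  Natural-history parameter vectors are
drawn jointly from the calibration posterior, preserving their
correlation.  Each PSA iteration propagates one joint draw through every
strategy (common random parameters), yielding incremental cost/QALY clouds,
95% confidence ellipses, and cost-effectiveness acceptability curves based
on net monetary benefit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import PosteriorSample, sample_posterior_params
from .economics import CostSchedule, StrategyResult, UtilitySchedule, compute_icer
from .natural_history import LifeTable, NaturalHistoryParams
from .screening import (
    ComplicationRisks,
    StrategyConfig,
    SurveillanceRule,
    TestPerformance,
    TEST_PRESETS,
    simulate_strategy,
)


class UnsupportedDistributionError(ValueError):
    pass


@dataclass(frozen=True)
class DistributionSpec:
    """PSA distribution of one parameter.

    kinds: ``beta`` (alpha, beta), ``uniform`` (lo, hi), ``scaled_beta``
    (scale x Beta(alpha, beta)), ``posterior_set`` (drawn jointly from the
    calibration posterior), ``fixed`` (not varied).
    """

    name: str
    kind: str
    alpha: float = math.nan
    beta: float = math.nan
    lo: float = math.nan
    hi: float = math.nan
    scale: float = 1.0
    corr_group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("beta", "uniform", "scaled_beta", "posterior_set", "fixed"):
            raise ValueError(f"unknown distribution kind {self.kind}")
        if self.kind in ("beta", "scaled_beta"):
            if not (self.alpha > 0 and self.beta > 0):
                raise ValueError(f"{self.name}: beta parameters must be positive")
        if self.kind == "scaled_beta" and not (0.0 < self.scale <= 1.0):
            raise ValueError(f"{self.name}: scale must lie in (0, 1]")
        if self.kind == "uniform" and not (self.lo < self.hi):
            raise ValueError(f"{self.name}: need lo < hi")

    def ppf(self, u: float) -> float:
        if self.kind == "beta":
            return float(stats.beta.ppf(u, self.alpha, self.beta))
        if self.kind == "uniform":
            return self.lo + u * (self.hi - self.lo)
        if self.kind == "scaled_beta":
            return self.scale * float(stats.beta.ppf(u, self.alpha, self.beta))
        raise UnsupportedDistributionError(f"{self.name}: no quantile for {self.kind}")


def dist_mean(spec: DistributionSpec) -> float:
    """Analytic mean of a beta/uniform/scaled-beta specification."""
    if spec.kind == "beta":
        return spec.alpha / (spec.alpha + spec.beta)
    if spec.kind == "uniform":
        return 0.5 * (spec.lo + spec.hi)
    if spec.kind == "scaled_beta":
        return spec.scale * spec.alpha / (spec.alpha + spec.beta)
    raise UnsupportedDistributionError(f"no analytic mean for kind {spec.kind}")


@dataclass
class PSADraw:
    values: dict  # parameter name -> sampled value
    nh_params: Optional[NaturalHistoryParams] = None
    iteration: int = 0


def sample_draw(
    specs: Sequence[DistributionSpec],
    posterior: Optional[Sequence[PosteriorSample]],
    rng: np.random.Generator,
    base_values: Optional[dict] = None,
) -> PSADraw:
    """One joint parameter draw.

    Members of a correlation group share a single uniform quantile; all
    other varied parameters are independent.  ``fixed`` parameters take
    their base-case value.  The natural-history vector is one joint draw
    from the calibration posterior (required when any spec has kind
    ``posterior_set``).
    """
    base_values = base_values or {}
    group_u: dict = {}
    values: dict = {}
    nh = None
    needs_posterior = any(s.kind == "posterior_set" for s in specs)
    if needs_posterior:
        if not posterior:
            raise ValueError("posterior samples required but none supplied")
        nh = sample_posterior_params(posterior, rng)
    for spec in specs:
        if spec.kind == "fixed":
            values[spec.name] = base_values.get(spec.name, math.nan)
        elif spec.kind == "posterior_set":
            continue
        else:
            if spec.corr_group is not None:
                if spec.corr_group not in group_u:
                    group_u[spec.corr_group] = rng.uniform()
                u = group_u[spec.corr_group]
            else:
                u = rng.uniform()
            values[spec.name] = spec.ppf(u)
    return PSADraw(values=values, nh_params=nh)


# -- mapping sampled parameter values onto model input objects ----------------


def build_model_inputs(values: dict) -> dict:
    """Assemble test/cost/utility/risk objects from named parameter values.

    Unspecified names fall back to the registry's base-case defaults.
    """
    v = dict(values)

    def g(name, default):
        x = v.get(name, default)
        return default if x is None or (isinstance(x, float) and math.isnan(x)) else x

    tests = {
        "gFOBT": TestPerformance(
            "gFOBT",
            g("gfobt_sens_adenoma", 0.11),
            g("gfobt_sens_adenoma", 0.11),
            g("gfobt_sens_crc", 0.36),
            g("gfobt_spec", 0.97),
        ),
        "FIT": TestPerformance(
            "FIT",
            g("fit_sens_adenoma", 0.21),
            g("fit_sens_adenoma", 0.21),
            g("fit_sens_crc", 0.71),
            g("fit_spec", 0.95),
        ),
        "FSIG": TestPerformance(
            "FSIG",
            g("fsig_sens_adenoma_low", 0.65),
            g("fsig_sens_adenoma_high", 0.74),
            g("fsig_sens_crc", 0.90),
            g("fsig_spec", 0.92),
            TEST_PRESETS["FSIG"].reach,
        ),
        "COL": TestPerformance(
            "COL",
            g("col_sens_adenoma_low", 0.77),
            g("col_sens_adenoma_high", 0.98),
            g("col_sens_crc", 0.98),
            g("col_spec", 0.97),
        ),
        "CTC": TestPerformance(
            "CTC",
            g("ctc_sens_adenoma_low", 0.53),
            g("ctc_sens_adenoma_high", 0.85),
            g("ctc_sens_crc", 0.85),
            g("ctc_spec", 0.86),
        ),
    }
    costs = CostSchedule(
        gfobt_kit=g("cost_gfobt_kit", 1.70),
        gfobt_processing=g("cost_gfobt_processing", 7.81),
        fit_kit=g("cost_fit_kit", 3.75),
        fit_processing=g("cost_fit_processing", 11.60),
        fsig=g("cost_fsig", 150.0),
        colonoscopy=g("cost_col", 650.0),
        ctc=g("cost_ctc", 550.0),
        perforation=g("cost_perforation", 10_200.0),
        bleed=g("cost_bleed", 3_079.0),
        pathology_adenoma=g("cost_pathology_adenoma", 65.0),
        pathology_cancer=g("cost_pathology_cancer", 530.0),
        adenomas_per_polypectomy=g("adenomas_per_polypectomy", 1.9),
        crc_symptomatic=tuple(
            g(f"cost_crc_sympt_{s}", d)
            for s, d in zip(("I", "II", "III", "IV"), (23_688.0, 37_180.0, 48_835.0, 36_602.0))
        ),
        crc_screen_detected=tuple(
            g(f"cost_crc_screen_{s}", d)
            for s, d in zip(("I", "II", "III", "IV"), (22_885.0, 36_377.0, 48_032.0, 35_799.0))
        ),
    )
    u_cancer = g("u_cancer", 0.80)
    utilities = UtilitySchedule(
        u_cancer_free=g("u_cancer_free", 0.94), u_cancer=(u_cancer,) * 4
    )
    risks = ComplicationRisks(
        fsig_perforation=g("fsig_perforation", 0.00002),
        fsig_perforation_death=g("fsig_perforation_death", 0.06452),
        fsig_bleed=g("fsig_bleed", 0.00029),
        col_perforation_polypectomy=g("col_perforation_polypectomy", 0.00216),
        col_perforation_no_polypectomy=g("col_perforation_no_polypectomy", 0.00107),
        col_perforation_death=g("col_perforation_death", 0.05195),
        col_bleed=g("col_bleed", 0.00379),
    )
    rule = SurveillanceRule(
        frac_high_among_intermediate_high=g("frac_high_risk_surveillance", 0.29),
        compliance=g("surveillance_compliance", 0.86),
    )
    uptake = {
        "gFOBT": g("gfobt_uptake", 0.53),
        "FIT": g("fit_uptake", 0.53),
        "FSIG": g("fsig_uptake", 0.39),
    }
    return {
        "tests": tests,
        "costs": costs,
        "utilities": utilities,
        "risks": risks,
        "surveillance_rule": rule,
        "uptake": uptake,
        "never_attender_fraction": g("never_attender_fraction", 0.13),
        "colonoscopy_compliance": g("col_compliance", 0.86),
        "discount_rate": g("discount_rate", 0.04),
    }


def _configure_strategy(strategy: StrategyConfig, inputs: dict) -> StrategyConfig:
    if strategy.primary_test is None:
        return strategy
    upd = dict(
        uptake=inputs["uptake"].get(strategy.primary_test, strategy.uptake),
        colonoscopy_compliance=inputs["colonoscopy_compliance"],
    )
    if strategy.primary_test != "FSIG":
        upd["never_attender_fraction"] = inputs["never_attender_fraction"]
    return replace(strategy, **upd)


def simulate_with_inputs(
    strategy: StrategyConfig,
    nh_params: NaturalHistoryParams,
    life_table: LifeTable,
    inputs: dict,
) -> StrategyResult:
    s = _configure_strategy(strategy, inputs)
    return simulate_strategy(
        s,
        nh_params,
        tests=inputs["tests"],
        life_table=life_table,
        costs=inputs["costs"],
        utilities=inputs["utilities"],
        surveillance_rule=inputs["surveillance_rule"],
        risks=inputs["risks"],
        discount_rate=inputs["discount_rate"],
    )


@dataclass
class CEACResult:
    """Probability each strategy is optimal (highest NMB) by WTP threshold."""

    wtp: np.ndarray
    probabilities: pd.DataFrame  # index aligned with wtp, one column per strategy

    def to_frame(self) -> pd.DataFrame:
        df = self.probabilities.copy()
        df.insert(0, "wtp", self.wtp)
        return df.melt(id_vars="wtp", var_name="strategy", value_name="probability")


def ceac(
    costs: np.ndarray, qalys: np.ndarray, strategy_ids: Sequence[str], wtp_grid: np.ndarray
) -> CEACResult:
    """CEAC from per-iteration (cost, QALY) arrays of shape (n_iter, n_strat)."""
    n_iter, n_strat = costs.shape
    probs = np.zeros((len(wtp_grid), n_strat))
    for w, lam in enumerate(wtp_grid):
        nmb = lam * qalys - costs
        best = np.argmax(nmb, axis=1)
        for s in range(n_strat):
            probs[w, s] = np.mean(best == s)
    return CEACResult(
        wtp=np.asarray(wtp_grid, float),
        probabilities=pd.DataFrame(probs, columns=list(strategy_ids)),
    )


def confidence_ellipse(dq: np.ndarray, dc: np.ndarray, level: float = 0.95) -> dict:
    """Bivariate-normal ellipse of incremental (QALY, cost) at given level."""
    mean = np.array([dq.mean(), dc.mean()])
    if dq.size < 2:
        cov = np.zeros((2, 2))
    else:
        cov = np.cov(np.vstack([dq, dc]))
    r2 = stats.chi2.ppf(level, df=2)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    angle = math.degrees(math.atan2(evecs[1, 0], evecs[0, 0]))
    return {
        "mean_dq": float(mean[0]),
        "mean_dc": float(mean[1]),
        "semi_axis_major": float(np.sqrt(max(evals[0], 0.0) * r2)),
        "semi_axis_minor": float(np.sqrt(max(evals[1], 0.0) * r2)),
        "angle_deg": float(angle),
    }


DEFAULT_WTP_GRID = np.arange(0.0, 50_000.0 + 1, 500.0)


@dataclass
class PSAResult:
    strategy_ids: list
    costs: np.ndarray  # (n_iter, n_strat) per-person discounted
    qalys: np.ndarray
    ceac: CEACResult
    ellipses: dict  # strategy id -> ellipse params vs comparator
    comparator: str = "no_screening"

    def cloud_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.costs.shape[0]):
            for s, sid in enumerate(self.strategy_ids):
                rows.append(
                    {"iteration": i, "strategy": sid, "cost": self.costs[i, s], "qaly": self.qalys[i, s]}
                )
        return pd.DataFrame(rows)


def run_psa(
    strategies: Sequence[StrategyConfig],
    specs: Sequence[DistributionSpec],
    posterior: Sequence[PosteriorSample],
    life_table: LifeTable,
    n_iter: int = 1200,
    seed: int = 0,
    wtp_grid: Optional[np.ndarray] = None,
    base_values: Optional[dict] = None,
    comparator: str = "no_screening",
) -> PSAResult:
    """Monte-Carlo propagation of joint parameter uncertainty.

    Every iteration draws one joint parameter set (shared across all
    strategies) and re-simulates each strategy, including the comparator.
    """
    rng = np.random.default_rng(seed)
    wtp = np.asarray(wtp_grid if wtp_grid is not None else DEFAULT_WTP_GRID, float)
    ids = [s.id for s in strategies]
    costs = np.zeros((n_iter, len(strategies)))
    qalys = np.zeros((n_iter, len(strategies)))
    for i in range(n_iter):
        draw = sample_draw(specs, posterior, rng, base_values)
        draw.iteration = i
        inputs = build_model_inputs(draw.values)
        nh = draw.nh_params
        if nh is None:
            raise ValueError("PSA requires posterior natural-history samples")
        for s, strat in enumerate(strategies):
            res = simulate_with_inputs(strat, nh, life_table, inputs)
            costs[i, s] = res.cost
            qalys[i, s] = res.qalys
    curve = ceac(costs, qalys, ids, wtp)
    ellipses = {}
    if comparator in ids:
        b = ids.index(comparator)
        for s, sid in enumerate(ids):
            if sid == comparator:
                continue
            ellipses[sid] = confidence_ellipse(
                qalys[:, s] - qalys[:, b], costs[:, s] - costs[:, b]
            )
    return PSAResult(ids, costs, qalys, curve, ellipses, comparator)


def one_way_sa(
    strategy: StrategyConfig,
    comparator: StrategyConfig,
    parameter: str,
    lo: float,
    hi: float,
    nh_params: NaturalHistoryParams,
    life_table: LifeTable,
    base_values: Optional[dict] = None,
) -> tuple:
    """ICER vs the comparator with one parameter at each range endpoint.

    All other parameters stay at base case.  ``discount_rate`` is handled
    like any other named parameter.
    """
    out = []
    for val in (lo, hi):
        values = dict(base_values or {})
        values[parameter] = val
        if parameter not in _KNOWN_PARAMETERS:
            raise KeyError(f"unknown parameter {parameter}")
        inputs = build_model_inputs(values)
        res = simulate_with_inputs(strategy, nh_params, life_table, inputs)
        base = simulate_with_inputs(comparator, nh_params, life_table, inputs)
        out.append(compute_icer(res, base))
    return tuple(out)


def tornado(
    strategy: StrategyConfig,
    comparator: StrategyConfig,
    parameter_ranges: dict,
    nh_params: NaturalHistoryParams,
    life_table: LifeTable,
    base_values: Optional[dict] = None,
) -> pd.DataFrame:
    """One-way SA over many parameters, ordered by ICER range width."""
    rows = []
    for name, (lo, hi) in parameter_ranges.items():
        icer_lo, icer_hi = one_way_sa(
            strategy, comparator, name, lo, hi, nh_params, life_table, base_values
        )
        rows.append(
            {"parameter": name, "icer_lo": icer_lo, "icer_hi": icer_hi,
             "width": abs(icer_hi - icer_lo)}
        )
    df = pd.DataFrame(rows).sort_values("width", ascending=False).reset_index(drop=True)
    return df.drop(columns="width")


_KNOWN_PARAMETERS = frozenset(
    {
        "gfobt_sens_adenoma", "gfobt_sens_crc", "gfobt_spec",
        "fit_sens_adenoma", "fit_sens_crc", "fit_spec",
        "fsig_sens_adenoma_low", "fsig_sens_adenoma_high", "fsig_sens_crc", "fsig_spec",
        "col_sens_adenoma_low", "col_sens_adenoma_high", "col_sens_crc", "col_spec",
        "ctc_sens_adenoma_low", "ctc_sens_adenoma_high", "ctc_sens_crc", "ctc_spec",
        "gfobt_uptake", "fit_uptake", "fsig_uptake", "never_attender_fraction",
        "col_compliance", "surveillance_compliance", "frac_high_risk_surveillance",
        "adenomas_per_polypectomy",
        "fsig_perforation", "fsig_perforation_death", "fsig_bleed",
        "col_perforation_polypectomy", "col_perforation_no_polypectomy",
        "col_perforation_death", "col_bleed",
        "u_cancer_free", "u_cancer",
        "cost_gfobt_kit", "cost_gfobt_processing", "cost_fit_kit", "cost_fit_processing",
        "cost_fsig", "cost_col", "cost_ctc", "cost_perforation", "cost_bleed",
        "cost_pathology_adenoma", "cost_pathology_cancer",
        "cost_crc_sympt_I", "cost_crc_sympt_II", "cost_crc_sympt_III", "cost_crc_sympt_IV",
        "cost_crc_screen_I", "cost_crc_screen_II", "cost_crc_screen_III", "cost_crc_screen_IV",
        "discount_rate",
    }
)
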