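"""Metropolis--Hastings calibration of the natural-history parameters.

The unobservable annual transition probabilities are estimated by fitting
the model's predicted colorectal cancer incidence (by AJCC stage), cancer
mortality, and adenoma / preclinical-cancer prevalence to target
observations, under an independent normal likelihood with
observation-specific standard deviations and flat Beta(1, 1) priors on
every probability.  Several independent chains are run with a burn-in;
the highest-likelihood sampled parameter set (the MAP set) is used for
base-case analyses and the pooled post-burn-in samples feed the
probabilistic sensitivity analysis, preserving between-parameter
correlation.

The proposal is an independent Gaussian random walk per coordinate in
probability space; proposals leaving [0, 1] (or violating the structural
parameter constraints) have zero prior support and are always rejected.
Proposal scales are adapted during burn-in toward a 20-40% acceptance rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .natural_history import (
    InvalidParameterError,
    LifeTable,
    NaturalHistoryParams,
    PARAM_NAMES,
    resolve_direct_rates,
    _run,
)

QUANTITIES = (
    "incidence_by_stage",
    "mortality",
    "adenoma_prevalence",
    "preclin_cancer_prevalence",
)

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class CalibrationTargets:
    """Observation table: quantity, age band, optional stage, value, sd.

    Incidence and mortality are annual rates per 100,000 alive, averaged
    over the ages of the band; prevalences are proportions among the
    surviving cohort at ``age_lo`` (use ``age_hi == age_lo``).
    """

    observations: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.observations
        required = {"quantity", "age_lo", "age_hi", "stage", "value", "sd"}
        if not required.issubset(df.columns):
            raise ValueError(f"targets need columns {sorted(required)}")
        if (df["sd"] <= 0).any():
            raise ValueError("every observation needs sd > 0")
        if (df["value"] < 0).any():
            raise ValueError("observed values must be non-negative")
        unknown = set(df["quantity"]) - set(QUANTITIES)
        if unknown:
            raise ValueError(f"unknown quantities {unknown}")
        for q in QUANTITIES:
            if not (df["quantity"] == q).any():
                raise ValueError(f"at least one observation per quantity; missing {q}")

    def __len__(self) -> int:
        return len(self.observations)

    @classmethod
    def from_csv(cls, path) -> "CalibrationTargets":
        return cls(pd.read_csv(path, float_precision="round_trip"))

    def to_csv(self, path) -> None:
        # %.17g keeps the round trip bit-exact
        self.observations.to_csv(path, index=False, float_format="%.17g")


def model_predictions(
    params: NaturalHistoryParams,
    targets: CalibrationTargets,
    life_table: LifeTable,
) -> np.ndarray:
    """Model-predicted value for every target observation, in target order."""
    rates = resolve_direct_rates(params, life_table)
    res = _run(params, life_table, rates, 30, 100)
    alive = res.occupancy[:-1, :25].sum(axis=1)
    alive = np.where(alive > 0, alive, np.nan)
    inc_rate = res.incidence_by_stage / alive[:, None]  # per 100k alive
    mort_rate = res.crc_deaths / alive
    out = np.empty(len(targets))
    df = targets.observations
    for i, row in enumerate(df.itertuples(index=False)):
        lo, hi = int(row.age_lo), int(row.age_hi)
        k0, k1 = lo - 30, hi - 30 + 1
        if row.quantity == "incidence_by_stage":
            s = int(row.stage)
            out[i] = float(np.nanmean(inc_rate[k0:k1, s - 1]))
        elif row.quantity == "mortality":
            out[i] = float(np.nanmean(mort_rate[k0:k1]))
        elif row.quantity == "adenoma_prevalence":
            out[i] = float(res.adenoma_prevalence[k0])
        else:  # preclin_cancer_prevalence
            out[i] = float(res.preclin_prevalence[k0])
    return out


def log_likelihood(
    params: NaturalHistoryParams,
    targets: CalibrationTargets,
    life_table: LifeTable,
) -> float:
    """Sum of normal log-densities of (model - observed) at each target's sd.

    Returns ``-inf`` for parameter sets outside the prior support (any
    probability outside [0, 1] or a structural constraint violated).
    """
    try:
        params.validate()
    except InvalidParameterError:
        return -math.inf
    try:
        pred = model_predictions(params, targets, life_table)
    except (InvalidParameterError, FloatingPointError):
        return -math.inf
    if not np.all(np.isfinite(pred)):
        return -math.inf
    obs = targets.observations["value"].to_numpy(float)
    sd = targets.observations["sd"].to_numpy(float)
    z = (pred - obs) / sd
    return float(-0.5 * np.sum(z * z) - np.sum(np.log(sd)) - 0.5 * len(obs) * _LOG_2PI)


@dataclass
class MCMCConfig:
    n_chains: int = 3
    burn_in: int = 2000
    n_samples: int = 5000  # total iterations per chain (including burn-in)
    proposal_scale: float = 0.02  # relative initial step per coordinate
    seed: int = 0
    free_params: Optional[Sequence[str]] = None  # None -> all 18
    adapt: bool = True

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.burn_in < 0 or self.n_samples <= self.burn_in:
            raise ValueError("need n_samples > burn_in >= 0")


@dataclass
class PosteriorSample:
    params: NaturalHistoryParams
    log_likelihood: float
    chain: int = 0
    iteration: int = 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_likelihood):
            raise ValueError("posterior samples require finite log-likelihood")


@dataclass
class MHState:
    """Generic random-walk MH state on a vector with [0, 1] support."""

    vector: np.ndarray
    log_likelihood: float


def mh_vector_step(
    current: MHState,
    proposal_scale: np.ndarray,
    rng: np.random.Generator,
    loglike,
    free_idx: Optional[np.ndarray] = None,
) -> tuple:
    """One Metropolis--Hastings step; returns (state, accepted flag).

    The symmetric Gaussian random-walk proposal perturbs the free
    coordinates; with flat Beta(1, 1) priors the acceptance probability is
    ``min(1, exp(delta log-likelihood))``, with proposals outside [0, 1]
    rejected outright (zero prior mass), as is any proposal whose
    log-likelihood is non-finite.
    """
    vec = current.vector
    free = free_idx if free_idx is not None else np.arange(len(vec))
    prop = vec.copy()
    prop[free] = prop[free] + rng.normal(0.0, proposal_scale, size=len(free))
    if np.any(prop[free] < 0.0) or np.any(prop[free] > 1.0):
        return current, False
    ll = loglike(prop)
    if not math.isfinite(ll):
        return current, False
    if ll >= current.log_likelihood or math.log(rng.uniform()) < ll - current.log_likelihood:
        return MHState(prop, ll), True
    return current, False


def mh_step(
    current: PosteriorSample,
    proposal_scale: np.ndarray,
    rng: np.random.Generator,
    targets: CalibrationTargets,
    life_table: LifeTable,
    free_idx: Optional[np.ndarray] = None,
) -> tuple:
    """MH step over the natural-history parameter vector.

    Wraps :func:`mh_vector_step` with the model log-likelihood; returns
    (PosteriorSample, accepted flag).
    """

    def loglike(vec: np.ndarray) -> float:
        cand = NaturalHistoryParams.from_vector(
            vec, p_direct=current.params.p_direct, frac_distal=current.params.frac_distal
        )
        return log_likelihood(cand, targets, life_table)

    state = MHState(current.params.to_vector(), current.log_likelihood)
    new, accepted = mh_vector_step(state, proposal_scale, rng, loglike, free_idx)
    if accepted:
        cand = NaturalHistoryParams.from_vector(
            new.vector, p_direct=current.params.p_direct, frac_distal=current.params.frac_distal
        )
        return PosteriorSample(cand, new.log_likelihood, current.chain, current.iteration + 1), True
    return (
        PosteriorSample(
            current.params, current.log_likelihood, current.chain, current.iteration + 1
        ),
        False,
    )


def run_calibration(
    targets: CalibrationTargets,
    config: MCMCConfig,
    life_table: LifeTable,
    init_params: NaturalHistoryParams,
) -> tuple:
    """Run the chains; return (MAP parameter set, pooled posterior samples).

    Each chain starts from a small random perturbation of ``init_params``,
    adapts its proposal scales during burn-in, and contributes its
    post-burn-in samples to the pool.  The MAP set is the sampled parameter
    vector with the highest likelihood over all retained samples.
    """
    rng_root = np.random.default_rng(config.seed)
    free_names = list(config.free_params) if config.free_params else list(PARAM_NAMES)
    unknown = set(free_names) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown free parameters {unknown}")
    free_idx = np.array([PARAM_NAMES.index(n) for n in free_names])
    samples: list = []
    best: Optional[PosteriorSample] = None
    for chain in range(config.n_chains):
        rng = np.random.default_rng(rng_root.integers(2**31 - 1))
        start = None
        for _attempt in range(50):
            vec = init_params.to_vector().copy()
            jitter = rng.normal(0.0, 0.05, size=len(free_idx))
            vec[free_idx] = np.clip(vec[free_idx] * (1.0 + jitter), 1e-6, 0.999)
            cand = NaturalHistoryParams.from_vector(
                vec, p_direct=init_params.p_direct, frac_distal=init_params.frac_distal
            )
            ll = log_likelihood(cand, targets, life_table)
            if math.isfinite(ll):
                start = PosteriorSample(cand, ll, chain, 0)
                break
        if start is None:
            raise RuntimeError("no finite-likelihood starting point found")
        scale = np.maximum(
            config.proposal_scale * start.params.to_vector()[free_idx], 1e-4
        )
        current = start
        accepted = 0
        window = 0
        for it in range(config.n_samples):
            current, acc = mh_step(current, scale, rng, targets, life_table, free_idx)
            accepted += acc
            window += 1
            if config.adapt and it < config.burn_in and window == 100:
                rate = accepted / window
                if rate < 0.20:
                    scale *= 0.7
                elif rate > 0.40:
                    scale *= 1.4
                accepted = 0
                window = 0
            if it >= config.burn_in:
                samples.append(current)
            if best is None or current.log_likelihood > best.log_likelihood:
                best = current
    return best.params, samples


def posterior_to_frame(samples: Sequence[PosteriorSample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        d = dict(zip(PARAM_NAMES, s.params.to_vector()))
        d["log_likelihood"] = s.log_likelihood
        d["chain"] = s.chain
        d["iteration"] = s.iteration
        rows.append(d)
    return pd.DataFrame(rows)


def sample_posterior_params(
    samples: Sequence[PosteriorSample], rng: np.random.Generator
) -> NaturalHistoryParams:
    """Uniform draw with replacement from pooled post-burn-in samples.

    Drawing whole parameter vectors preserves the between-parameter
    correlation induced by the calibration targets.
    """
    if len(samples) == 0:
        raise ValueError("empty posterior")
    return samples[int(rng.integers(len(samples)))].params
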