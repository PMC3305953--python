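"""MCMC calibration: likelihood, MH kernel, chains, conjugate cross-check."""

import math

import numpy as np
import pytest
from scipy import stats

from crcscreen.calibration import (
    CalibrationTargets,
    MCMCConfig,
    MHState,
    PosteriorSample,
    log_likelihood,
    mh_step,
    mh_vector_step,
    model_predictions,
    posterior_to_frame,
    run_calibration,
    sample_posterior_params,
)
from crcscreen.natural_history import PARAM_NAMES, NaturalHistoryParams
from crcscreen.synthetic import (
    SyntheticScenario,
    generate_life_table,
    generate_targets,
    reference_params,
)

FREE = [
    "p_low_to_high",
    "p_high_to_crcI",
    "p_stage_progress_I_II",
    "p_symptomatic_I",
    "p_crc_death_IV",
    "p_normal_to_lowrisk_50_59",
]


@pytest.fixture(scope="module")
def noisefree_targets(life_table):
    """Targets generated at vanishing observation noise from the reference set."""
    scen = SyntheticScenario(observation_cv=1e-9, seed=0)
    targets, truth = generate_targets(scen)
    # keep sds workable for likelihood arithmetic: rescale to 5% CV
    df = targets.observations.copy()
    df["sd"] = 0.05 * df["value"].clip(lower=1e-6)
    return CalibrationTargets(df), truth


class TestLogLikelihood:
    def test_zero_residuals_hit_normalisation_constant(self, life_table, noisefree_targets):
        targets, truth = noisefree_targets
        ll = log_likelihood(truth, targets, life_table)
        sd = targets.observations["sd"].to_numpy()
        expected = float(-np.sum(np.log(sd * math.sqrt(2 * math.pi))))
        assert ll == pytest.approx(expected, abs=1e-6)

    def test_doubling_a_residual_costs_three_halves_log_units(self):
        """Moving one observation from 1 sd to 2 sd lowers the log-density by
        (4-1)/2 = 1.5."""
        z1 = stats.norm.logpdf(1.0)
        z2 = stats.norm.logpdf(2.0)
        assert z1 - z2 == pytest.approx(1.5)

    def test_parameter_outside_unit_interval_is_rejected(self, life_table, noisefree_targets):
        targets, truth = noisefree_targets
        bad = NaturalHistoryParams.from_vector(truth.to_vector())
        bad.p_low_to_high = 1.4
        assert log_likelihood(bad, targets, life_table) == -math.inf

    def test_deterministic_given_params(self, life_table, noisefree_targets):
        targets, truth = noisefree_targets
        p = NaturalHistoryParams.from_vector(truth.to_vector())
        assert log_likelihood(p, targets, life_table) == log_likelihood(
            NaturalHistoryParams.from_vector(truth.to_vector()), targets, life_table
        )


class TestMHKernel:
    def test_equal_likelihood_proposal_always_accepted(self):
        rng = np.random.default_rng(0)
        state = MHState(np.array([0.5]), 0.0)
        accepted = 0
        for _ in range(200):
            _, acc = mh_vector_step(state, np.array([0.01]), rng, lambda v: 0.0)
            accepted += acc
        assert accepted == 200

    def test_out_of_support_proposal_always_rejected(self):
        rng = np.random.default_rng(1)
        state = MHState(np.array([0.999999]), 0.0)
        rejections = 0
        for _ in range(200):
            new, acc = mh_vector_step(state, np.array([5.0]), rng, lambda v: 0.0)
            if not acc:
                rejections += 1
            else:
                assert 0.0 <= new.vector[0] <= 1.0
        assert rejections > 0  # large steps from the boundary mostly leave [0,1]

    def test_acceptance_rate_reasonable_on_quadratic_target(self):
        """Random-walk MH on a Gaussian target restricted to [0,1] accepts in
        the usual 10-60% window with a tuned scale over 10,000 steps."""
        rng = np.random.default_rng(2)

        def loglike(v):
            return -0.5 * ((v[0] - 0.5) / 0.05) ** 2

        state = MHState(np.array([0.5]), loglike(np.array([0.5])))
        accepted = 0
        n = 10_000
        for _ in range(n):
            state, acc = mh_vector_step(state, np.array([0.12]), rng, loglike)
            accepted += acc
        assert 0.1 <= accepted / n <= 0.6

    def test_mh_step_counts_iterations(self, life_table, noisefree_targets):
        targets, truth = noisefree_targets
        ll = log_likelihood(truth, targets, life_table)
        cur = PosteriorSample(truth, ll, chain=0, iteration=0)
        rng = np.random.default_rng(3)
        new, _ = mh_step(cur, np.full(len(PARAM_NAMES), 1e-4), rng, targets, life_table)
        assert new.iteration == 1


class TestRunCalibration:
    def test_identical_seed_identical_chains(self, life_table, noisefree_targets):
        targets, _ = noisefree_targets
        cfg = MCMCConfig(n_chains=2, burn_in=20, n_samples=60, seed=11, free_params=FREE)
        map1, s1 = run_calibration(targets, cfg, life_table, reference_params())
        map2, s2 = run_calibration(targets, cfg, life_table, reference_params())
        assert np.array_equal(map1.to_vector(), map2.to_vector())
        assert np.array_equal(
            posterior_to_frame(s1).to_numpy(), posterior_to_frame(s2).to_numpy()
        )

    def test_retained_sample_count(self, life_table, noisefree_targets):
        targets, _ = noisefree_targets
        cfg = MCMCConfig(n_chains=3, burn_in=30, n_samples=80, seed=5, free_params=FREE)
        _, samples = run_calibration(targets, cfg, life_table, reference_params())
        assert len(samples) == 3 * (80 - 30)

    def test_map_improves_or_matches_start(self, life_table, noisefree_targets):
        targets, truth = noisefree_targets
        cfg = MCMCConfig(n_chains=1, burn_in=50, n_samples=300, seed=9, free_params=FREE)
        map_params, samples = run_calibration(targets, cfg, life_table, reference_params())
        best = max(s.log_likelihood for s in samples)
        assert log_likelihood(map_params, targets, life_table) >= best - 1e-9

    def test_posterior_draw_preserves_whole_vectors(self, life_table, noisefree_targets):
        targets, _ = noisefree_targets
        cfg = MCMCConfig(n_chains=1, burn_in=10, n_samples=40, seed=2, free_params=FREE)
        _, samples = run_calibration(targets, cfg, life_table, reference_params())
        rng = np.random.default_rng(0)
        drawn = sample_posterior_params(samples, rng)
        pool = {tuple(s.params.to_vector()) for s in samples}
        assert tuple(drawn.to_vector()) in pool


class TestConjugateCrossCheck:
    def test_posterior_matches_beta_closed_form(self):
        """On binomial data with a flat prior the MH kernel must reproduce the
        Beta(k+1, n-k+1) posterior: mean and sd within 3 Monte-Carlo SE at
        20,000 samples."""
        n_trials, k = 50, 18
        post = stats.beta(k + 1, n_trials - k + 1)

        def loglike(v):
            p = v[0]
            if not (0.0 < p < 1.0):
                return -math.inf
            return k * math.log(p) + (n_trials - k) * math.log(1.0 - p)

        rng = np.random.default_rng(42)
        state = MHState(np.array([0.5]), loglike(np.array([0.5])))
        draws = np.empty(20_000)
        for i in range(1_000):  # burn-in
            state, _ = mh_vector_step(state, np.array([0.15]), rng, loglike)
        for i in range(draws.size):
            state, _ = mh_vector_step(state, np.array([0.15]), rng, loglike)
            draws[i] = state.vector[0]
        # effective sample size from the lag-1 autocorrelation
        rho = np.corrcoef(draws[:-1], draws[1:])[0, 1]
        ess = draws.size * (1 - rho) / (1 + rho)
        se_mean = post.std() / math.sqrt(ess)
        assert draws.mean() == pytest.approx(post.mean(), abs=3 * se_mean)
        assert draws.std() == pytest.approx(post.std(), rel=0.15)

    def test_pooled_chains_agree_with_long_chain(self):
        """Three short chains pooled match one long chain on the toy target
        within Monte-Carlo error; split-chain Gelman-Rubin below 1.1."""
        n_trials, k = 40, 10

        def loglike(v):
            p = v[0]
            if not (0.0 < p < 1.0):
                return -math.inf
            return k * math.log(p) + (n_trials - k) * math.log(1.0 - p)

        def chain(seed, n):
            rng = np.random.default_rng(seed)
            state = MHState(np.array([0.3]), loglike(np.array([0.3])))
            out = np.empty(n)
            for i in range(500):
                state, _ = mh_vector_step(state, np.array([0.15]), rng, loglike)
            for i in range(n):
                state, _ = mh_vector_step(state, np.array([0.15]), rng, loglike)
                out[i] = state.vector[0]
            return out

        chains = [chain(s, 4000) for s in (1, 2, 3)]
        pooled = np.concatenate(chains)
        long = chain(99, 12_000)
        se = pooled.std() / 30  # generous MC error bound
        assert pooled.mean() == pytest.approx(long.mean(), abs=3 * se)
        # Gelman-Rubin over the three chains
        means = np.array([c.mean() for c in chains])
        n = chains[0].size
        w = np.mean([c.var(ddof=1) for c in chains])
        b = n * means.var(ddof=1)
        rhat = math.sqrt(((n - 1) / n * w + b / n) / w)
        assert rhat < 1.1


def test_targets_validation_rejects_bad_tables():
    import pandas as pd

    with pytest.raises(ValueError):
        CalibrationTargets(
            pd.DataFrame(
                {"quantity": ["mortality"], "age_lo": [50], "age_hi": [54],
                 "stage": [0], "value": [10.0], "sd": [0.0]}
            )
        )
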