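"""Binary Markov approximation: update rule, stationarity, response
statistics, SNR, capacity and the Monte-Carlo oracle."""

import math

import numpy as np
import pytest
from scipy import stats

from gamem.markov import (
    RANDOM,
    MarkovParams,
    capacity,
    mc_experiment,
    optimize_probs,
    probs_from_rates,
    response,
    response_stats,
    retention_factor,
    snr,
    snr_curve,
    stationary_fraction,
    update,
)
from gamem.stimuli import gen_pattern

PARAMS = MarkovParams(p=0.35, q=0.15, f=0.2, N=100)


class TestProbsFromRates:
    def test_zero_duration(self):
        assert probs_from_rates(1.0, 2.0, 0.0) == (0.0, 0.0)

    def test_half_life_rate(self):
        p, q = probs_from_rates(math.log(2) / 3.0, 0.0, 3.0)
        assert p == pytest.approx(0.5)
        assert q == 0.0


class TestUpdate:
    def test_frozen_chain_never_flips(self):
        rng = np.random.default_rng(0)
        m = rng.integers(0, 2, 50).astype(np.int8)
        xi = gen_pattern(50, 0.3, rng)
        out = update(m, xi, MarkovParams(0, 0, 0.3, 50), rng)
        assert np.array_equal(out, m)

    def test_certain_transitions_copy_the_pattern(self):
        rng = np.random.default_rng(1)
        m = rng.integers(0, 2, 200).astype(np.int8)
        xi = gen_pattern(200, 0.4, rng)
        out = update(m, xi, MarkovParams(1, 1, 0.4, 200), rng)
        assert np.array_equal(out, xi.bits)

    def test_flip_frequencies_match_p_and_q(self):
        p, q, n = 0.3, 0.12, 20_000
        params = MarkovParams(p, q, 0.5, n)
        rng = np.random.default_rng(2)
        m = np.zeros(n, dtype=np.int8)
        xi = np.ones(n, dtype=np.int8)
        up = update(m, xi, params, rng).mean()
        assert abs(up - p) < 3 * math.sqrt(p * (1 - p) / n)
        m = np.ones(n, dtype=np.int8)
        xi = np.zeros(n, dtype=np.int8)
        down = 1 - update(m, xi, params, rng).mean()
        assert abs(down - q) < 3 * math.sqrt(q * (1 - q) / n)


class TestStationaryFraction:
    def test_symmetric_case(self):
        assert stationary_fraction(MarkovParams(0.3, 0.3, 0.5, 10)) == 0.5

    def test_no_potentiation_gives_zero(self):
        assert stationary_fraction(MarkovParams(0.0, 0.3, 0.5, 10)) == 0.0

    def test_degenerate_chain_rejected(self):
        with pytest.raises(ValueError):
            stationary_fraction(MarkovParams(0.0, 0.0, 0.5, 10))

    def test_long_run_occupancy_matches_formula(self):
        params = MarkovParams(0.2, 0.1, 0.2, 1)
        rho = stationary_fraction(params)
        rng = np.random.default_rng(3)
        n_chains, n_steps = 2000, 500
        m = np.zeros((n_chains, 1), dtype=np.int8)
        for _ in range(n_steps):
            xi = (rng.random((n_chains, 1)) < params.f).astype(np.int8)
            m = update(m, xi, params, rng)
        occ = m.mean()
        se = math.sqrt(rho * (1 - rho) / n_chains)
        assert abs(occ - rho) < 3 * se

    def test_update_preserves_stationary_law(self):
        params = MarkovParams(0.25, 0.1, 0.3, 1)
        rho = stationary_fraction(params)
        rng = np.random.default_rng(4)
        n = 100_000
        m = (rng.random((n, 1)) < rho).astype(np.int8)
        for _ in range(10):
            xi = (rng.random((n, 1)) < params.f).astype(np.int8)
            m = update(m, xi, params, rng)
        k = int(m.sum())
        chi2, pval = stats.chisquare([k, n - k], [n * rho, n * (1 - rho)])
        assert pval > 1e-3


class TestResponse:
    def test_zero_probe_gives_zero(self):
        assert response(np.ones(5, dtype=int), np.zeros(5, dtype=int)) == 0

    def test_full_overlap_gives_n(self):
        assert response(np.ones(7, dtype=int), np.ones(7, dtype=int)) == 7

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            response(np.ones(5, dtype=int), np.ones(6, dtype=int))

    def test_conditional_distribution_is_hypergeometric(self):
        # brute force over all 2^10 x 2^10 (m, s) pairs, grouped by counts
        N = 10
        states = np.array(
            [[(i >> b) & 1 for b in range(N)] for i in range(2**N)], dtype=np.int8
        )
        pops = states.sum(axis=1)
        j, k = 4, 6  # |m| = 4, |s| = 6
        ms = states[pops == j]
        ss = states[pops == k]
        overlaps = (ms[:, None, :] * ss[None, :, :]).sum(axis=2).ravel()
        counts = np.bincount(overlaps, minlength=N + 1) / overlaps.size
        expected = stats.hypergeom(N, j, k).pmf(np.arange(N + 1))
        assert np.allclose(counts, expected, atol=1e-12)


class TestResponseStats:
    def test_most_recent_mean_formula(self):
        params = MarkovParams(0.5, 0.5, 0.3, 200)
        rho = stationary_fraction(params)
        st = response_stats(1, params)
        assert st.mean == pytest.approx(200 * 0.3 * (rho + (1 - rho) * 0.5))

    def test_random_probe_mean(self):
        st = response_stats(RANDOM, PARAMS)
        assert st.mean == pytest.approx(
            PARAMS.N * PARAMS.f * stationary_fraction(PARAMS)
        )

    def test_old_memories_forgotten(self):
        old = response_stats(5000, PARAMS)
        rand = response_stats(RANDOM, PARAMS)
        assert old.mean == pytest.approx(rand.mean, rel=1e-9)
        assert old.variance == pytest.approx(rand.variance, rel=1e-9)

    def test_invalid_age_rejected(self):
        with pytest.raises(ValueError):
            response_stats(0, PARAMS)


class TestSNR:
    def test_degenerate_chain_has_zero_signal(self):
        assert snr(1, MarkovParams(0, 0, 0.2, 100)) == 0.0

    def test_signal_decays_geometrically(self):
        lam = retention_factor(PARAMS)
        rand_mean = response_stats(RANDOM, PARAMS).mean
        sig = [response_stats(a, PARAMS).mean - rand_mean for a in (1, 2, 3, 6)]
        assert sig[1] / sig[0] == pytest.approx(lam, rel=1e-12)
        assert sig[2] / sig[1] == pytest.approx(lam, rel=1e-12)

    def test_snr_ratio_close_to_inverse_retention(self):
        # variance is only approximately age-independent, so the SNR ratio
        # tracks 1/lambda to a few percent
        lam = retention_factor(PARAMS)
        for a in (1, 2, 4):
            ratio = snr(a, PARAMS) / snr(a + 1, PARAMS)
            assert ratio == pytest.approx(1 / lam, rel=0.05)

    def test_strictly_decreasing_in_age(self):
        vals = [snr(a, PARAMS) for a in range(1, 30)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestCapacity:
    def test_zero_when_most_recent_unretrievable(self):
        res = capacity(MarkovParams(0.01, 0.01, 0.2, 20))
        assert snr(1, res.params) <= 1
        assert res.capacity == 0

    @pytest.mark.parametrize(
        "params",
        [
            MarkovParams(0.35, 0.15, 0.2, 100),
            MarkovParams(0.1, 0.05, 0.2, 1024),
            MarkovParams(0.6, 0.3, 0.1, 400),
        ],
    )
    def test_matches_exhaustive_scan(self, params):
        res = capacity(params)
        limit = int(10 * math.sqrt(params.N))
        scan = 0
        for age in range(1, limit + 1):
            if snr(age, params) > 1:
                scan = age
            else:
                break
        assert res.capacity == scan
        if res.capacity >= 1:
            assert snr(res.capacity, params) > 1
            assert snr(res.capacity + 1, params) <= 1

    def test_non_decreasing_in_network_size(self):
        caps = [capacity(MarkovParams(0.2, 0.1, 0.2, N)).capacity
                for N in (64, 256, 1024)]
        assert caps == sorted(caps)


class TestOptimizer:
    def test_beats_every_point_of_a_coarse_grid(self):
        f, N = 0.2, 1024
        p_opt, q_opt, res = optimize_probs(f, N, n_grid=25)
        grid = np.logspace(-4, 0, 15)
        best_grid = max(
            capacity(MarkovParams(p, q, f, N)).capacity for p in grid for q in grid
        )
        assert res.capacity >= best_grid

    def test_optimal_scale_decreases_with_n(self):
        _, q_small, _ = optimize_probs(0.2, 64, n_grid=30)
        _, q_large, _ = optimize_probs(0.2, 4096, n_grid=30)
        assert q_large < q_small


class TestMCExperiment:
    def test_single_association_regime(self):
        # p = q = 1: every pairing overwrites the whole network, so only
        # the most recent association is retrievable
        params = MarkovParams(1.0, 1.0, 0.3, 200)
        mc = mc_experiment(params, n_patterns=5, n_reps=2000, seed=11)
        assert mc.snr[0] > 5
        assert abs(mc.snr[1]) < 0.15

    def test_agrees_with_closed_form_snr(self):
        mc = mc_experiment(PARAMS, n_patterns=10, n_reps=1000, seed=12)
        for i, age in enumerate(mc.ages):
            assert abs(mc.snr[i] - snr(int(age), PARAMS)) < 3 * mc.snr_se[i]

    def test_random_responses_approximately_normal_at_large_n(self):
        params = MarkovParams(0.35, 0.15, 0.2, 1000)
        mc = mc_experiment(params, n_patterns=3, n_reps=3000, seed=13)
        _, pval = stats.normaltest(mc.responses[RANDOM])
        assert pval > 0.01

    def test_palimpsest_decay_is_log_linear(self):
        params = MarkovParams(0.35, 0.15, 0.2, 10_000)
        mc = mc_experiment(params, n_patterns=8, n_reps=400, seed=14)
        excess = mc.mean - mc.rand_mean
        lam = retention_factor(params)
        slope, intercept = np.polyfit(mc.ages, np.log(excess), 1)
        fit = np.polyval([slope, intercept], mc.ages)
        ss_res = np.sum((np.log(excess) - fit) ** 2)
        ss_tot = np.sum((np.log(excess) - np.log(excess).mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.99
        assert math.exp(slope) == pytest.approx(lam, rel=0.02)
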