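"""Population of non-interacting networks: response statistics, variance
decomposition, SNR and capacity."""

import math

import numpy as np
import pytest

from gamem.markov import (
    RANDOM,
    MarkovParams,
    capacity,
    optimize_probs,
    response,
    response_stats,
    snr,
    stationary_fraction,
)
from gamem.population import (
    INFINITE,
    PopulationParams,
    _aged_pi_moments,
    _stationary_pi_moments,
    mc_population_experiment,
    optimize_population_probs,
    population_capacity,
    population_response,
    population_snr,
    population_stats,
    population_update,
    shared_variance_scan,
)
from gamem.stimuli import gen_pattern

BASE = MarkovParams(p=0.35, q=0.15, f=0.2, N=100)


class TestPiMoments:
    """The conditional-probability process pi is the backbone of the
    population theory; its closed-form moments must match the recursion
    exactly and direct simulation statistically."""

    def test_two_step_recursion_matches_enumeration(self):
        p, q, f = 0.3, 0.2, 0.25
        pi0 = 0.4
        # enumerate the four (xi1, xi2) histories exactly
        def step(pi, bit):
            return (1 - p) * pi + p if bit else (1 - q) * pi
        m1 = m2 = 0.0
        for b1 in (0, 1):
            for b2 in (0, 1):
                w = (f if b1 else 1 - f) * (f if b2 else 1 - f)
                pi2 = step(step(pi0, b1), b2)
                m1 += w * pi2
                m2 += w * pi2**2
        # against the linear moment maps used by the closed forms
        lam = 1 - f * p - (1 - f) * q
        lam2 = f * (1 - p) ** 2 + (1 - f) * (1 - q) ** 2
        e1, e2 = pi0, pi0**2
        for _ in range(2):
            e2 = lam2 * e2 + 2 * f * p * (1 - p) * e1 + f * p * p
            e1 = lam * e1 + f * p
        assert m1 == pytest.approx(e1, abs=1e-14)
        assert m2 == pytest.approx(e2, abs=1e-14)

    def test_closed_form_is_fixed_point_of_recursion(self):
        params = MarkovParams(0.3, 0.2, 0.25, 10)
        rho, m2_st = _stationary_pi_moments(params)
        p, q, f = params.p, params.q, params.f
        lam = 1 - f * p - (1 - f) * q
        lam2 = f * (1 - p) ** 2 + (1 - f) * (1 - q) ** 2
        e1, e2 = 0.5, 0.25
        for _ in range(2000):
            e2 = lam2 * e2 + 2 * f * p * (1 - p) * e1 + f * p * p
            e1 = lam * e1 + f * p
        assert e1 == pytest.approx(rho, abs=1e-12)
        assert e2 == pytest.approx(m2_st, abs=1e-12)

    def test_moments_match_direct_simulation(self):
        params = MarkovParams(0.1, 0.1, 0.2, 1)
        rng = np.random.default_rng(42)
        R = 100_000
        rho, _ = _stationary_pi_moments(params)
        pi = np.full(R, rho)
        for _ in range(250):
            xi = rng.random(R) < params.f
            pi = np.where(xi, 0.9 * pi + 0.1, 0.9 * pi)
        _, m2_st = _stationary_pi_moments(params)
        assert abs((pi**2).mean() - m2_st) < 4 * (pi**2).std() / math.sqrt(R)
        # aged, conditioned on a learned active bit
        pc = 0.9 * pi + 0.1
        for _ in range(2):
            xi = rng.random(R) < params.f
            pc = np.where(xi, 0.9 * pc + 0.1, 0.9 * pc)
        m1_3, m2_3 = _aged_pi_moments(params, 3)
        assert abs(pc.mean() - m1_3) < 4 * pc.std() / math.sqrt(R)
        assert abs((pc**2).mean() - m2_3) < 4 * (pc**2).std() / math.sqrt(R)


class TestPopulationResponse:
    def test_single_cell_reduces_to_overlap(self):
        rng = np.random.default_rng(0)
        m = rng.integers(0, 2, (1, 20))
        s = gen_pattern(20, 0.3, rng)
        raw, _ = population_response(m, s)
        assert raw == response(m[0], s)

    def test_identical_cells_scale_linearly(self):
        rng = np.random.default_rng(1)
        row = rng.integers(0, 2, 15)
        m = np.tile(row, (8, 1))
        s = gen_pattern(15, 0.4, rng)
        raw, _ = population_response(m, s)
        assert raw == 8 * response(row, s)

    def test_exhaustive_enumeration_small_instance(self):
        # Z=2, N=6: every state/probe combination against a literal loop
        rng = np.random.default_rng(2)
        for _ in range(20):
            m = rng.integers(0, 2, (2, 6))
            s = rng.integers(0, 2, 6)
            brute = sum(int(s[i]) * int(m[z, i]) for z in range(2) for i in range(6))
            assert population_response(m, s)[0] == brute

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            population_response(np.zeros((2, 5), dtype=int), np.zeros(6, dtype=int))


class TestPopulationUpdate:
    def test_certain_transitions_collapse_population(self):
        rng = np.random.default_rng(3)
        pop = PopulationParams(5, MarkovParams(1, 1, 0.3, 30))
        state = rng.integers(0, 2, (5, 30)).astype(np.int8)
        xi = gen_pattern(30, 0.3, rng)
        out = population_update(state, xi, pop, rng)
        assert np.array_equal(out, np.tile(xi.bits, (5, 1)))

    def test_flips_uncorrelated_across_cells(self):
        pop = PopulationParams(2, MarkovParams(0.4, 0.2, 0.5, 1))
        rng = np.random.default_rng(4)
        n = 20_000
        m = np.zeros((n, 2, 1), dtype=np.int8)
        xi = np.ones((n, 1, 1), dtype=np.int8)
        u = rng.random((n, 2, 1))
        flip = (u < 0.4).astype(float)[:, :, 0]
        r = np.corrcoef(flip[:, 0], flip[:, 1])[0, 1]
        assert abs(r) < 3 / math.sqrt(n)


class TestPopulationStats:
    def test_single_cell_total_equals_single_network_variance(self):
        pop = PopulationParams(1, BASE)
        for age in (1, 3, RANDOM):
            st = population_stats(age, pop)
            ref = response_stats(age, BASE)
            assert st.mean_raw == pytest.approx(ref.mean, rel=1e-12)
            assert st.var_raw == pytest.approx(ref.variance, rel=1e-12)
            assert st.var_per_cell == pytest.approx(ref.variance, rel=1e-12)

    def test_normalized_variance_decreases_with_z(self):
        totals = [
            population_stats(2, PopulationParams(Z, BASE)).var_per_cell
            for Z in (1, 4, 16, 64)
        ]
        assert all(a > b for a, b in zip(totals, totals[1:]))

    def test_infinite_population_keeps_only_shared_component(self):
        st_inf = population_stats(2, PopulationParams(INFINITE, BASE))
        st_big = population_stats(2, PopulationParams(10_000, BASE))
        assert st_inf.decomposition.within_component == 0.0
        assert st_inf.var_per_cell == pytest.approx(
            st_big.decomposition.shared_component, rel=1e-12
        )
        assert st_big.var_per_cell == pytest.approx(st_inf.var_per_cell, rel=1e-2)

    def test_mean_per_cell_independent_of_z(self):
        means = {
            population_stats(1, PopulationParams(Z, BASE)).mean_per_cell
            for Z in (1, 7, INFINITE)
        }
        assert len(means) == 1


class TestPopulationSNR:
    def test_single_cell_reduces_to_single_network_snr(self):
        pop = PopulationParams(1, BASE)
        for age in (1, 2, 5):
            assert population_snr(age, pop) == pytest.approx(snr(age, BASE), rel=1e-12)

    def test_population_curve_dominates_single_curve(self):
        pop = PopulationParams(100, BASE)
        for age in range(1, 10):
            assert population_snr(age, pop) >= snr(age, BASE)

    def test_snr_increases_with_z_and_saturates(self):
        vals = [
            population_snr(3, PopulationParams(Z, BASE)) for Z in (1, 10, 100, 10_000)
        ]
        inf_val = population_snr(3, PopulationParams(INFINITE, BASE))
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(inf_val, rel=1e-2)


class TestPopulationCapacity:
    def test_single_cell_reduction(self):
        res = population_capacity(PopulationParams(1, BASE))
        assert res.capacity == capacity(BASE).capacity

    def test_infinite_population_beats_single_network(self):
        for N in (64, 256):
            f = 2.0 / N
            _, _, single = optimize_probs(f, N, n_grid=25)
            _, _, pop = optimize_population_probs(f, N, n_grid=25)
            assert pop.capacity > single.capacity

    def test_population_optimum_uses_smaller_transition_scale(self):
        f, N = 0.02, 1024
        _, q_single, _ = optimize_probs(f, N, n_grid=30)
        _, q_pop, _ = optimize_population_probs(f, N, n_grid=30)
        assert q_pop < q_single


class TestSharedVarianceScan:
    def test_components_sum_exactly_for_random_probe(self):
        df = shared_variance_scan(0.2, 0.05, ratios=[0.5, 1, 2, 5, 10])
        assert np.allclose(
            df["shared"], df["probe_term"] + df["encoding_term"], atol=1e-14
        )

    def test_probe_term_shrinks_as_depression_dominates(self):
        df = shared_variance_scan(0.2, 0.005, ratios=np.logspace(-1, 2, 10))
        assert (np.diff(df["rho"]) < 0).all()
        assert (np.diff(df["probe_term"]) < 0).all()


class TestPopulationMC:
    def test_binomial_and_explicit_modes_agree(self):
        pop = PopulationParams(4, BASE)
        a = mc_population_experiment(pop, 6, 3000, seed=5, mode="binomial").single
        b = mc_population_experiment(pop, 6, 3000, seed=6, mode="explicit").single
        for i in range(len(a.ages)):
            se = math.hypot(a.mean_se[i], b.mean_se[i])
            assert abs(a.mean[i] - b.mean[i]) < 3.5 * se
            se_v = math.hypot(a.var_se[i], b.var_se[i])
            assert abs(a.var[i] - b.var[i]) < 3.5 * se_v

    def test_law_of_total_variance_decomposition(self):
        pop = PopulationParams(16, BASE)
        mc = mc_population_experiment(pop, 6, 4000, seed=7)
        for i, age in enumerate(mc.single.ages):
            st = population_stats(int(age), pop)
            # shared component from between-sequence variance of
            # per-sequence conditional means
            assert abs(mc.shared_emp[i] - st.decomposition.shared_component) < (
                3 * mc.shared_se[i]
            )
        st_r = population_stats(RANDOM, pop)
        assert abs(mc.shared_emp_rand - st_r.decomposition.shared_component) < (
            3 * mc.shared_se_rand
        )

    def test_closed_form_snr_matches_mc_at_z_100(self):
        pop = PopulationParams(100, BASE)
        mc = mc_population_experiment(pop, 8, 4000, seed=8).single
        for i, age in enumerate(mc.ages):
            th = population_snr(int(age), pop)
            assert abs(mc.snr[i] - th) < 3 * mc.snr_se[i]

    def test_infinite_population_rejected(self):
        with pytest.raises(ValueError):
            mc_population_experiment(PopulationParams(INFINITE, BASE), 5, 10, seed=0)
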