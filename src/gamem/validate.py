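"""Oracle-agreement experiments.

These experiments check the package against itself in the way the science
demands: the binary Markov approximation against the full stochastic
dynamics, the closed-form retrieval statistics against Monte-Carlo, the
escape kinetics against the exponential barrier law, and the behavioral
signatures (acquisition/extinction, order effect) against ensemble
simulation.  They power the ``gamem validate`` command and the acceptance
tests.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np

from ._rng import root_sequence
from .bistable import (
    DEFAULT_PARAMS,
    G_MAINTENANCE,
    G_PAIRING,
    G_US_ALONE,
    TRIAL_DURATION,
    BistableParams,
    energy_gaps,
    estimate_switch_prob,
    find_fixed_points,
    mean_escape_time,
    simulate_paths,
)
from .markov import MarkovParams, _batch_stats, snr, stationary_fraction
from .network import ReadoutParams, pair_activation
from .population import PopulationParams, mc_population_experiment

__all__ = [
    "MarkovVsSDE",
    "markov_vs_sde",
    "acquisition_extinction",
    "order_effect",
    "escape_time_scaling",
    "oracle_agreement",
]

_GAP_DURATION = TRIAL_DURATION  # maintenance window between trials (30 min)


def _integrate_window(m, g, duration, dt, rng, p: BistableParams):
    return simulate_paths(p, g, m, duration, dt, rng)


@dataclass(frozen=True)
class MarkovVsSDE:
    p_hat: float
    q_hat: float
    ages: np.ndarray
    snr_markov: np.ndarray
    snr_sde: np.ndarray
    snr_sde_se: np.ndarray
    n_reps: int

    @property
    def max_abs_z(self) -> float:
        return float(np.max(np.abs(self.snr_markov - self.snr_sde) / self.snr_sde_se))


def markov_vs_sde(
    seed: int,
    n_reps: int = 300,
    N: int = 100,
    f: float = 0.2,
    max_age: int = 8,
    n_prelearn: int = 8,
    element: BistableParams = DEFAULT_PARAMS,
    dt: float = 0.02,
    switch_reps: int = 2000,
) -> MarkovVsSDE:
    """Closed-form Markov SNR versus the full-dynamics experiment.

    The per-trial flip probabilities (p, q) are first measured from the
    bistable element by direct simulation; the Markov theory built on these
    estimates is then compared with the empirical SNR of a population of
    full stochastic networks, each learning its own sequence of random
    patterns through pairing trials separated by maintenance windows.
    Probe responses are the steady-state readout sum_i s_i h(m_i)/delta_R
    (an affine map of the overlap, leaving the SNR unchanged).
    """
    ss = root_sequence(seed).spawn(3)
    p_est = estimate_switch_prob(
        element, G_PAIRING, TRIAL_DURATION, "low", switch_reps,
        seed=int(ss[1].generate_state(1)[0]), dt=dt,
    )
    q_est = estimate_switch_prob(
        element, G_US_ALONE, TRIAL_DURATION, "high", switch_reps,
        seed=int(ss[2].generate_state(1)[0]), dt=dt,
    )
    rng = np.random.default_rng(ss[0])
    p_hat, q_hat = p_est.prob, q_est.prob
    params = MarkovParams(p_hat, q_hat, f, N)
    rho = stationary_fraction(params)

    fps = find_fixed_points(G_MAINTENANCE, element)
    m_lo, m_hi = fps.m_low, fps.m_high
    readout = ReadoutParams()

    n_paths = n_reps * N
    high = rng.random(n_paths) < rho
    m = np.where(high, m_hi, m_lo)
    n_learn = max_age
    recent: list[np.ndarray] = []
    g_table = np.array([G_US_ALONE, G_PAIRING])
    for t in range(n_prelearn + n_learn):
        bits = (rng.random(n_paths) < f).astype(np.int8)
        g = g_table[bits]
        m = _integrate_window(m, g, TRIAL_DURATION, dt, rng, element)
        m = _integrate_window(m, G_MAINTENANCE, _GAP_DURATION, dt, rng, element)
        if t >= n_prelearn:
            recent.append(bits)
            if len(recent) > max_age:
                recent.pop(0)

    h = pair_activation(1, m, readout) / readout.delta_R
    h = h.reshape(n_reps, N)

    def probe(bits):
        return (bits.reshape(n_reps, N) * h).sum(axis=1)

    rand_bits = (rng.random(n_paths) < f).astype(np.int8)
    r_rand = probe(rand_bits)
    r_mean, _, r_var, _ = _batch_stats(r_rand, 20)
    ages = np.arange(1, max_age + 1)
    snr_sde, snr_se, snr_th = [], [], []
    rand_batches = np.array_split(r_rand, 20)
    for age in ages:
        x = probe(recent[-age])
        mu, _, v, _ = _batch_stats(x, 20)
        snr_sde.append((mu - r_mean) / math.sqrt(v + r_var))
        bs = []
        for xb, rb in zip(np.array_split(x, 20), rand_batches):
            noise2 = xb.var(ddof=1) + rb.var(ddof=1)
            bs.append((xb.mean() - rb.mean()) / math.sqrt(noise2) if noise2 else 0.0)
        snr_se.append(np.std(bs, ddof=1) / math.sqrt(len(bs)))
        snr_th.append(snr(int(age), params))
    return MarkovVsSDE(
        p_hat=p_hat,
        q_hat=q_hat,
        ages=ages,
        snr_markov=np.array(snr_th),
        snr_sde=np.array(snr_sde),
        snr_sde_se=np.array(snr_se),
        n_reps=n_reps,
    )


@dataclass(frozen=True)
class ConditioningResult:
    success_fraction: float
    acquired_fraction: float
    extinguished_fraction: float
    naive_silent_fraction: float
    n_seeds: int


def acquisition_extinction(
    seed: int,
    n_seeds: int = 100,
    element: BistableParams = DEFAULT_PARAMS,
    dt: float = 0.02,
    threshold: float = 0.5,
) -> ConditioningResult:
    """Classical-conditioning ensemble on a single-pathway network (N=1).

    Hourly schedule: US alone (1 h); CS probe (2 h); three CS+US pairings
    (3-5 h); CS probes (6-7 h); four US-alone trials (8-11 h); CS probes
    (12-13 h).  A run succeeds if the naive probe is silent, the
    post-pairing probes respond (acquisition), and the post-US-alone
    probes are silent again (extinction).  Responses are the steady-state
    readout h(m)/delta_R averaged over the second half of the probe.
    """
    rng = np.random.default_rng(root_sequence(seed))
    readout = ReadoutParams()
    fps = find_fixed_points(G_MAINTENANCE, element)
    m = np.full(n_seeds, fps.m_low)
    steps_half = int(round(TRIAL_DURATION / 2 / dt))

    def probe_window(m, g):
        """Integrate one trial window, returning second-half mean of h."""
        m = _integrate_window(m, g, TRIAL_DURATION / 2, dt, rng, element)
        acc = np.zeros_like(m)
        sqdt = math.sqrt(dt)
        from .bistable import drift

        for _ in range(steps_half):
            m = m + drift(m, 0.0, element) * dt + g * dt
            m = m + element.sigma * sqdt * rng.standard_normal(m.size)
            np.abs(m, out=m)
            acc += pair_activation(1, m, readout) / readout.delta_R
        return m, acc / steps_half

    def gap(m):
        return _integrate_window(m, G_MAINTENANCE, 2 * TRIAL_DURATION, dt, rng, element)

    # slot 1: US alone; slot 2: CS probe
    m = _integrate_window(m, G_US_ALONE, TRIAL_DURATION, dt, rng, element)
    m = gap(m)
    m, resp_naive = probe_window(m, G_MAINTENANCE)
    m = gap(m)
    for _ in range(3):  # pairings, slots 3-5
        m = _integrate_window(m, G_PAIRING, TRIAL_DURATION, dt, rng, element)
        m = gap(m)
    m, resp_acq1 = probe_window(m, G_MAINTENANCE)
    m = gap(m)
    m, resp_acq2 = probe_window(m, G_MAINTENANCE)
    m = gap(m)
    for _ in range(4):  # US alone, slots 8-11
        m = _integrate_window(m, G_US_ALONE, TRIAL_DURATION, dt, rng, element)
        m = gap(m)
    m, resp_ext1 = probe_window(m, G_MAINTENANCE)
    m = gap(m)
    m, resp_ext2 = probe_window(m, G_MAINTENANCE)

    naive_ok = resp_naive <= threshold
    acquired = (resp_acq1 > threshold) & (resp_acq2 > threshold)
    extinguished = (resp_ext1 <= threshold) & (resp_ext2 <= threshold)
    success = naive_ok & acquired & extinguished
    return ConditioningResult(
        float(success.mean()),
        float(acquired.mean()),
        float(extinguished.mean()),
        float(naive_ok.mean()),
        n_seeds,
    )


@dataclass(frozen=True)
class OrderEffectResult:
    means: dict  # label -> ensemble mean response
    ci_half: dict  # label -> 1.96 * SE
    n_seeds: int


def order_effect(
    seed: int,
    n_seeds: int = 200,
    N: int = 100,
    f: float = 0.2,
    element: BistableParams = DEFAULT_PARAMS,
    dt: float = 0.02,
) -> OrderEffectResult:
    """Sequentially pair patterns C, then B, then A; the ensemble-mean
    probe response must be ordered A >= B >= C (recency / order effect)."""
    rng = np.random.default_rng(root_sequence(seed))
    readout = ReadoutParams()
    fps = find_fixed_points(G_MAINTENANCE, element)
    n_paths = n_seeds * N
    m = np.full(n_paths, fps.m_low)
    g_table = np.array([G_US_ALONE, G_PAIRING])
    pats = {}
    for label in ("C", "B", "A"):
        bits = (rng.random(n_paths) < f).astype(np.int8)
        pats[label] = bits
        m = _integrate_window(m, g_table[bits], TRIAL_DURATION, dt, rng, element)
        m = _integrate_window(m, G_MAINTENANCE, _GAP_DURATION, dt, rng, element)
    h = (pair_activation(1, m, readout) / readout.delta_R).reshape(n_seeds, N)
    means, ci = {}, {}
    for label, bits in pats.items():
        resp = (bits.reshape(n_seeds, N) * h).sum(axis=1)
        means[label] = float(resp.mean())
        ci[label] = float(1.96 * resp.std(ddof=1) / math.sqrt(n_seeds))
    return OrderEffectResult(means, ci, n_seeds)


@dataclass(frozen=True)
class EscapeScaling:
    x_values: np.ndarray  # gap / sigma^2
    log_mean_escape: np.ndarray
    slope: float
    intercept: float
    gap: float


def escape_time_scaling(
    seed: int,
    x_values=(2.0, 2.5, 3.0, 3.5, 4.0),
    n_reps: int = 300,
    element: BistableParams = DEFAULT_PARAMS,
    g: float = G_MAINTENANCE,
    start: str = "low",
    dt: float = 0.01,
) -> EscapeScaling:
    """Mean first-passage time versus barrier-to-noise ratio.

    The weak-noise theory predicts escape rate ~ exp(-2 gap / sigma^2), so
    log(mean escape time) is affine in gap/sigma^2 with slope 2.  The sweep
    varies sigma at a fixed landscape.
    """
    gap_low, gap_high = energy_gaps(g, element)
    gap = gap_low if start == "low" else gap_high
    xs = np.asarray(x_values, dtype=float)
    logs = []
    for i, x in enumerate(xs):
        sigma = math.sqrt(gap / x)
        el = BistableParams(element.beta, element.K, element.n, element.delta, sigma)
        t_mean, _ = mean_escape_time(el, g, start, n_reps, seed + i, dt=dt)
        logs.append(math.log(t_mean))
    slope, intercept = np.polyfit(xs, logs, 1)
    return EscapeScaling(xs, np.array(logs), float(slope), float(intercept), gap)


def oracle_agreement(
    seed: int,
    params: MarkovParams | None = None,
    Z_values=(1, 16),
    n_reps: int = 3000,
    max_age: int = 10,
) -> dict:
    """Closed-form vs Monte-Carlo agreement summary (max |z| per block)."""
    from .markov import response_stats, RANDOM
    from .population import population_stats, population_snr

    if params is None:
        params = MarkovParams(0.35, 0.15, 0.2, 100)
    out = {}
    for Z in Z_values:
        pop = PopulationParams(Z, params)
        mc = mc_population_experiment(
            pop, n_patterns=max_age, n_reps=n_reps, seed=seed + Z, max_age=max_age
        ).single
        zmax = 0.0
        for i, age in enumerate(mc.ages):
            st = population_stats(int(age), pop)
            zmax = max(zmax, abs(mc.mean[i] - st.mean_per_cell) / mc.mean_se[i])
            zmax = max(zmax, abs(mc.var[i] - st.var_per_cell) / mc.var_se[i])
            th_snr = population_snr(int(age), pop)
            zmax = max(zmax, abs(mc.snr[i] - th_snr) / mc.snr_se[i])
        out[Z] = zmax
    return out
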