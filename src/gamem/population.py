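"""Capacity of a clonal population of non-interacting memory networks.

Z identical networks are exposed to the same stimulus sequence but flip
their synapses independently (private encoding noise).  The population
response to a probe is the accumulated response of all cells,
r = sum_z sum_i s_i m_i^z.

Conditioned on the shared pattern history, the state of synapse i is iid
across cells with conditional probability pi_i of being high, where pi_i
follows the random recursion driven by the shared pattern bits:

    bit 1 (prob f):    pi' = (1-p) pi + p
    bit 0 (prob 1-f):  pi' = (1-q) pi

The law of total variance then splits the response variance into a private
(within) part that averages out as 1/Z after normalization and a shared
part, set by the fluctuations of pi and of the probe realization, that no
amount of averaging removes:

    Var(r/Z) = N * E[s pi (1-pi)] / Z  +  N * Var(s pi)

First and second moments of pi (stationary, and conditioned on the probed
pattern's bit with ageing) follow from iterating the linear moment maps of
the recursion; they are in closed form below and validated against
Monte-Carlo in the tests.  The population SNR uses the same
signal/noise construction as the single network; Z -> infinity drops the
within term.  Because the mean response is Z times the single-cell mean
while the noise grows slower, the population SNR dominates the single-cell
SNR and the stored-memory capacity of even a non-interacting population
substantially exceeds that of one cell.
"""

from __future__ import annotations

from dataclasses import dataclass
import math
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from ._rng import rng_from
from .markov import (
    RANDOM,
    CapacityResult,
    MarkovParams,
    MCExperiment,
    SNRCurve,
    _batch_stats,
    capacity_search_bound,
    optimize_probs,
    response,
    retention_factor,
    stationary_fraction,
    update,
)
from .stimuli import Pattern

__all__ = [
    "PopulationParams",
    "PopulationStats",
    "VarianceDecomposition",
    "INFINITE",
    "population_response",
    "population_update",
    "population_stats",
    "population_snr",
    "population_capacity",
    "optimize_population_probs",
    "mc_population_experiment",
    "shared_variance_scan",
]

INFINITE: Literal["inf"] = "inf"


@dataclass(frozen=True)
class PopulationParams:
    """Z cells sharing stimuli, layered on single-network parameters."""

    Z: int | Literal["inf"]
    base: MarkovParams

    def __post_init__(self):
        if self.Z != INFINITE and (int(self.Z) != self.Z or self.Z < 1):
            raise ValueError('Z must be an integer >= 1 or "inf"')

    @property
    def infinite(self) -> bool:
        return self.Z == INFINITE


@dataclass(frozen=True)
class VarianceDecomposition:
    """Per-cell (response/Z) variance split.

    within_component : private encoding noise, scales as 1/Z
    shared_component : stimulus-realization noise, Z-independent
    """

    within_component: float
    shared_component: float

    @property
    def total(self) -> float:
        return self.within_component + self.shared_component


@dataclass(frozen=True)
class PopulationStats:
    age: float | Literal["random"]
    mean_per_cell: float
    decomposition: VarianceDecomposition
    mean_raw: float | None  # None for Z = inf
    var_raw: float | None

    @property
    def var_per_cell(self) -> float:
        return self.decomposition.total


# ---------------------------------------------------------------------------
# closed-form moments of the conditional-probability process


def _stationary_pi_moments(params: MarkovParams) -> tuple[float, float]:
    p, q, f = params.p, params.q, params.f
    rho = stationary_fraction(params)
    lam2 = f * (1 - p) ** 2 + (1 - f) * (1 - q) ** 2
    m2 = (2 * f * p * (1 - p) * rho + f * p * p) / (1 - lam2)
    return rho, m2


def _aged_pi_moments(params: MarkovParams, age: float) -> tuple[float, float]:
    """(E[pi], E[pi^2]) at probe time, conditioned on the probed pattern's
    bit being 1 at learning, after age-1 intervening random patterns."""
    p, q, f = params.p, params.q, params.f
    rho, m2_st = _stationary_pi_moments(params)
    lam = retention_factor(params)
    lam2 = f * (1 - p) ** 2 + (1 - f) * (1 - q) ** 2
    m1_0 = (1 - p) * rho + p
    m2_0 = (1 - p) ** 2 * m2_st + 2 * p * (1 - p) * rho + p * p
    k = age - 1.0
    m1_k = rho + (m1_0 - rho) * lam**k
    if abs(lam2 - lam) < 1e-13:
        geo = k * lam ** max(k - 1.0, 0.0)
    else:
        geo = (lam2**k - lam**k) / (lam2 - lam)
    m2_k = m2_st + (m2_0 - m2_st) * lam2**k + 2 * f * p * (1 - p) * (m1_0 - rho) * geo
    return m1_k, m2_k


def _per_synapse_components(
    params: MarkovParams, age: float | Literal["random"]
) -> tuple[float, float, float]:
    """(E[s pi], within, shared) per synapse for a probe of the given age."""
    f = params.f
    if age == RANDOM:
        m1, m2 = _stationary_pi_moments(params)
    else:
        if age < 1:
            raise ValueError("age must be >= 1")
        m1, m2 = _aged_pi_moments(params, age)
    mu = f * m1
    within = f * (m1 - m2)  # E[s pi (1 - pi)]
    shared = f * m2 - mu * mu  # Var(s pi)
    return mu, within, shared


# ---------------------------------------------------------------------------
# operations


def population_response(
    state: np.ndarray, s: Pattern | np.ndarray, params: PopulationParams | None = None
) -> tuple[int, float | None]:
    """Accumulated response sum_z sum_i s_i m_i^z of a (Z, N) state matrix.

    Returns (raw, normalized); the normalized form subtracts the
    closed-form random-probe mean and divides by its standard deviation
    (requires ``params``; otherwise None).
    """
    state = np.asarray(state)
    bits = s.bits if isinstance(s, Pattern) else np.asarray(s)
    if state.ndim != 2 or state.shape[1] != bits.shape[-1]:
        raise ValueError("state must be (Z, N) matching the pattern length")
    raw = int((state * bits).sum())
    if params is None:
        return raw, None
    st = population_stats(RANDOM, params)
    if st.mean_raw is None or st.var_raw is None or st.var_raw == 0:
        return raw, None
    return raw, (raw - st.mean_raw) / math.sqrt(st.var_raw)


def population_update(
    state: np.ndarray, xi: Pattern | np.ndarray, params: PopulationParams, rng
) -> np.ndarray:
    """One shared learning step: every cell sees the same pattern, flips
    independently (row-wise single-network update)."""
    return update(state, xi, params.base, rng)


def population_stats(
    age: float | Literal["random"], pop: PopulationParams
) -> PopulationStats:
    """Closed-form population response statistics with the within/shared
    variance decomposition (per-cell scale; raw scale when Z is finite)."""
    base = pop.base
    mu, within_syn, shared_syn = _per_synapse_components(base, age)
    N = base.N
    mean_pc = N * mu
    if pop.infinite:
        within = 0.0
        mean_raw = var_raw = None
    else:
        Z = int(pop.Z)
        within = N * within_syn / Z
        mean_raw = Z * mean_pc
        var_raw = Z * N * within_syn + Z * Z * N * shared_syn
    decomp = VarianceDecomposition(within, N * shared_syn)
    return PopulationStats(age, mean_pc, decomp, mean_raw, var_raw)


def population_snr(age: float, pop: PopulationParams) -> float:
    """Population signal-to-noise ratio at the given memory age."""
    if age < 1:
        raise ValueError("age must be >= 1")
    base = pop.base
    if base.p == 0 and base.q == 0:
        return 0.0
    learned = population_stats(age, pop)
    rand = population_stats(RANDOM, pop)
    noise2 = learned.var_per_cell + rand.var_per_cell
    if noise2 == 0:
        raise ZeroDivisionError("zero retrieval noise: SNR undefined")
    return (learned.mean_per_cell - rand.mean_per_cell) / math.sqrt(noise2)


def _threshold_age(pop: PopulationParams) -> float:
    if population_snr(1.0, pop) <= 1.0:
        return 0.0
    bound = capacity_search_bound(pop.base)
    hi = 2.0
    while population_snr(hi, pop) > 1.0:
        hi *= 2
        if hi > bound:
            return float(bound)
    lo = hi / 2
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if population_snr(mid, pop) > 1.0:
            lo = mid
        else:
            hi = mid
    return lo


def population_capacity(pop: PopulationParams) -> CapacityResult:
    """Oldest age with population SNR > 1."""
    base = pop.base
    if base.p == 0 and base.q == 0:
        cap = 0
    else:
        cap = int(math.floor(_threshold_age(pop)))
        while cap >= 1 and population_snr(cap, pop) <= 1.0:
            cap -= 1
        while (
            population_snr(cap + 1, pop) > 1.0
            and cap + 1 < capacity_search_bound(base)
        ):
            cap += 1
    ages = np.arange(1, max(cap + 1, 10) + 1)
    curve = SNRCurve(ages, np.array([population_snr(a, pop) for a in ages]), base)
    return CapacityResult(capacity=cap, params=base, snr_curve=curve)


def optimize_population_probs(
    f: float, N: int, Z: int | Literal["inf"] = INFINITE, n_grid: int = 50
) -> tuple[float, float, CapacityResult]:
    """(p, q) maximizing the population capacity; shares the single-network
    optimizer's grid/polish machinery and determinism rules."""

    def mk(p, q):
        return PopulationParams(Z, MarkovParams(p, q, f, N))

    return optimize_probs(
        f,
        N,
        n_grid=n_grid,
        threshold_age=lambda p, q: _threshold_age(mk(p, q)),
        capacity_of=lambda p, q: population_capacity(mk(p, q)),
    )


# ---------------------------------------------------------------------------
# Monte-Carlo oracle


@dataclass(frozen=True)
class PopulationMCExperiment:
    single: MCExperiment  # per-cell-scale statistics
    within_emp: np.ndarray  # law-of-total-variance estimates per age
    shared_emp: np.ndarray
    within_emp_rand: float
    shared_emp_rand: float
    shared_se: np.ndarray
    shared_se_rand: float


def _burn_in_steps(params: MarkovParams) -> int:
    lam2 = (
        params.f * (1 - params.p) ** 2 + (1 - params.f) * (1 - params.q) ** 2
    )
    lam = max(retention_factor(params), lam2)
    if lam >= 1.0:
        return 50
    return int(min(5000, math.ceil(12.0 / (1.0 - lam)) + 10))


def mc_population_experiment(
    pop: PopulationParams,
    n_patterns: int,
    n_reps: int,
    seed: int,
    max_age: int | None = None,
    n_batches: int = 25,
    mode: Literal["binomial", "explicit"] = "binomial",
    burn_in: int | None = None,
) -> PopulationMCExperiment:
    """Empirical population retrieval statistics over shared pattern
    sequences with independent per-cell transitions.

    ``mode="binomial"`` samples the response exactly through the
    conditional law (cells iid Bernoulli(pi_i) given the history, so the
    response is a sum of Binomial(Z, pi_i) draws); this also yields the
    law-of-total-variance decomposition, since the per-sequence conditional
    mean Z sum_i s_i pi_i is available.  ``mode="explicit"`` simulates every
    cell's bits (small Z only); both modes draw from the same law and are
    cross-checked in the test-suite.

    All statistics are returned on the per-cell scale (response / Z).
    """
    if pop.infinite:
        raise ValueError("Monte-Carlo requires a finite population size")
    base = pop.base
    Z, N, f = int(pop.Z), base.N, base.f
    if max_age is None:
        max_age = n_patterns
    if n_patterns < max_age:
        raise ValueError("n_patterns must cover the oldest probed age")
    if burn_in is None:
        burn_in = _burn_in_steps(base)
    rng = rng_from(seed)
    rho = stationary_fraction(base)

    if mode == "explicit":
        state = (rng.random((n_reps, Z, N)) < rho).astype(np.int8)
        recent: list[np.ndarray] = []
        for t in range(burn_in + n_patterns):
            xi = (rng.random((n_reps, 1, N)) < f).astype(np.int8)
            u = rng.random((n_reps, Z, N))
            up = (xi == 1) & (state == 0) & (u < base.p)
            down = (xi == 0) & (state == 1) & (u < base.q)
            state[up] = 1
            state[down] = 0
            if t >= burn_in:
                recent.append(xi[:, 0, :])
                if len(recent) > max_age:
                    recent.pop(0)
        responses = {}
        for age in range(1, max_age + 1):
            responses[age] = (state * recent[-age][:, None, :]).sum((1, 2)) / Z
        s = (rng.random((n_reps, 1, N)) < f).astype(np.int8)
        responses[RANDOM] = (state * s).sum((1, 2)) / Z
        cond_means = None
    else:
        pi = np.full((n_reps, N), rho)
        recent = []
        for t in range(burn_in + n_patterns):
            xi = rng.random((n_reps, N)) < f
            pi = np.where(xi, (1 - base.p) * pi + base.p, (1 - base.q) * pi)
            if t >= burn_in:
                recent.append(xi.astype(np.int8))
                if len(recent) > max_age:
                    recent.pop(0)
        responses = {}
        cond_means = {}
        def probe(s_bits):
            act = s_bits.astype(bool)
            r = np.zeros(n_reps)
            cm = np.zeros(n_reps)
            counts = rng.binomial(Z, np.where(act, pi, 0.0))
            r = counts.sum(axis=1) / Z
            cm = (np.where(act, pi, 0.0)).sum(axis=1)
            return r, cm
        for age in range(1, max_age + 1):
            responses[age], cond_means[age] = probe(recent[-age])
        s = (rng.random((n_reps, N)) < f).astype(np.int8)
        responses[RANDOM], cond_means[RANDOM] = probe(s)

    r_mean, r_mse, r_var, r_vse = _batch_stats(responses[RANDOM], n_batches)
    ages = np.arange(1, max_age + 1)
    means, mses, vars_, vses, snrs, sses = ([] for _ in range(6))
    rand_batches = np.array_split(np.asarray(responses[RANDOM], float), n_batches)
    for age in ages:
        x = np.asarray(responses[int(age)], float)
        m, mse, v, vse = _batch_stats(x, n_batches)
        means.append(m); mses.append(mse); vars_.append(v); vses.append(vse)
        snrs.append((m - r_mean) / math.sqrt(v + r_var))
        bs = []
        for xb, rb in zip(np.array_split(x, n_batches), rand_batches):
            noise2 = xb.var(ddof=1) + rb.var(ddof=1)
            bs.append((xb.mean() - rb.mean()) / math.sqrt(noise2) if noise2 > 0 else 0.0)
        sses.append(np.std(bs, ddof=1) / math.sqrt(len(bs)))
    single = MCExperiment(
        ages=ages,
        mean=np.array(means), mean_se=np.array(mses),
        var=np.array(vars_), var_se=np.array(vses),
        snr=np.array(snrs), snr_se=np.array(sses),
        rand_mean=r_mean, rand_mean_se=r_mse,
        rand_var=r_var, rand_var_se=r_vse,
        responses=responses, n_reps=n_reps,
    )

    # law-of-total-variance decomposition (binomial mode only)
    if cond_means is not None:
        w, sh, sh_se = [], [], []
        for age in ages:
            x = np.asarray(responses[int(age)], float)
            cm = cond_means[int(age)]
            sh_a = np.var(cm, ddof=1)
            sh.append(sh_a)
            w.append(np.var(x, ddof=1) - sh_a)
            bse = [np.var(b, ddof=1) for b in np.array_split(cm, n_batches)]
            sh_se.append(np.std(bse, ddof=1) / math.sqrt(n_batches))
        cmr = cond_means[RANDOM]
        sh_r = np.var(cmr, ddof=1)
        w_r = r_var - sh_r
        bse = [np.var(b, ddof=1) for b in np.array_split(cmr, n_batches)]
        sh_r_se = np.std(bse, ddof=1) / math.sqrt(n_batches)
        return PopulationMCExperiment(
            single, np.array(w), np.array(sh), w_r, sh_r,
            np.array(sh_se), sh_r_se,
        )
    nan = np.full(len(ages), np.nan)
    return PopulationMCExperiment(single, nan, nan, np.nan, np.nan, nan, np.nan)


def shared_variance_scan(
    f: float,
    p: float,
    ratios: np.ndarray | list[float],
    age: float | Literal["random"] = RANDOM,
    N: int = 1,
) -> pd.DataFrame:
    """Shared-variance component as a function of the q/p ratio at fixed f.

    Used to locate, numerically, the regime in which the stimulus-shared
    variance term stops dominating the population noise: the per-synapse
    shared component is approximately f(1-f) rho^2 + f Var(pi); the rho^2
    term (probe-realization noise) shrinks as q/p grows (rho -> 0), and
    becomes subdominant to the encoding-fluctuation term once
    (1-f) q >~ 2 f (1-f).  See docs/methods.md.
    """
    rows = []
    for ratio in ratios:
        q = min(p * ratio, 1.0)
        params = MarkovParams(p, q, f, N)
        mu, within, shared = _per_synapse_components(params, age)
        rho, m2 = _stationary_pi_moments(params)
        rows.append(
            {
                "ratio": ratio,
                "q": q,
                "rho": rho,
                "shared": N * shared,
                "within": N * within,
                "probe_term": N * f * (1 - f) * rho**2,
                "encoding_term": N * f * (m2 - rho**2),
            }
        )
    return pd.DataFrame(rows)
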