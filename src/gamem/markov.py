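"""Two-state Markov approximation of the pseudo-synapses and the
single-network memory-capacity theory.

Because each pseudo-synapse spends almost all its time near one of the two
stable expression levels, learning can be approximated by a binary Markov
chain driven by the stimulus sequence: during a pairing trial a synapse
whose receptor is active flips low->high with probability p, and a synapse
whose receptor is inactive flips high->low with probability q; all other
combinations leave the state unchanged.  Patterns are random with
sparseness f, so an *unconditioned* (pattern-averaged) synapse follows a
two-state chain with transition probabilities f*p (up) and (1-f)*q (down)
per learned pattern, giving

    rho    = f p / (f p + (1-f) q)          stationary high-state fraction
    lambda = 1 - f p - (1-f) q              per-pattern retention factor

The steady-state response to a probe pattern s is the overlap sum_i s_i m_i.
For the pattern learned x patterns ago, conditioning on its bit and ageing
the synapse through the x-1 subsequent (independent) patterns yields the
per-synapse law

    P(m_i = 1 | xi_i = 1) = rho + (1 - rho) p lambda^(x-1)

so the response is Binomial(N, mu_x) with mu_x = f * that probability; the
response to a fresh random pattern is Binomial(N, f*rho).  The signal is
the difference of means, N f (1-rho) p lambda^(x-1), decaying geometrically
with the age of the memory (palimpsest forgetting); the noise is the root
of the summed variances.  The capacity is the oldest age whose
signal-to-noise ratio still exceeds 1.

These closed forms were derived from the per-synapse joint law and are
validated against the Monte-Carlo experiment in this module (and, for
N <= 12, against exact enumeration in the test-suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from ._rng import rng_from
from .stimuli import Pattern

__all__ = [
    "MarkovParams",
    "ResponseStats",
    "SNRCurve",
    "CapacityResult",
    "MCExperiment",
    "RANDOM",
    "probs_from_rates",
    "update",
    "stationary_fraction",
    "retention_factor",
    "response",
    "response_stats",
    "snr",
    "snr_curve",
    "capacity",
    "capacity_search_bound",
    "optimize_probs",
    "mc_experiment",
]

#: Sentinel age for non-learned (fresh random) probe patterns.
RANDOM: Literal["random"] = "random"


@dataclass(frozen=True)
class MarkovParams:
    """Binary-approximation parameters.

    p : P(low->high flip) for a pairing with an active receptor
    q : P(high->low flip) for a pairing with an inactive receptor
    f : sparseness of the stimulus patterns
    N : number of pseudo-synapses
    """

    p: float
    q: float
    f: float
    N: int

    def __post_init__(self):
        if not (0 <= self.p <= 1 and 0 <= self.q <= 1):
            raise ValueError("p and q must lie in [0, 1]")
        if not 0 < self.f < 1:
            raise ValueError("f must lie in (0, 1)")
        if self.N < 1:
            raise ValueError("N must be >= 1")


def probs_from_rates(lambda_lh: float, lambda_hl: float, T: float) -> tuple[float, float]:
    """Per-trial flip probabilities from transition rates and duration:
    p = 1 - exp(-lambda_lh T), q = 1 - exp(-lambda_hl T)."""
    if lambda_lh < 0 or lambda_hl < 0 or T < 0:
        raise ValueError("rates and duration must be non-negative")
    return 1.0 - math.exp(-lambda_lh * T), 1.0 - math.exp(-lambda_hl * T)


def stationary_fraction(params: MarkovParams) -> float:
    """Stationary probability of the high state under random patterns."""
    denom = params.f * params.p + (1 - params.f) * params.q
    if denom == 0:
        raise ValueError("p = q = 0 has no unique stationary distribution")
    return params.f * params.p / denom


def retention_factor(params: MarkovParams) -> float:
    """Per-learned-pattern geometric decay factor 1 - f p - (1-f) q."""
    return 1.0 - params.f * params.p - (1 - params.f) * params.q


def update(
    m: np.ndarray, xi: Pattern | np.ndarray, params: MarkovParams, rng
) -> np.ndarray:
    """One learning step: flip 0->1 w.p. p where xi=1, 1->0 w.p. q where
    xi=0.  Works on a single state vector or a (reps, N) batch; returns a
    new array."""
    bits = xi.bits if isinstance(xi, Pattern) else np.asarray(xi)
    m = np.asarray(m, dtype=np.int8)
    if m.shape[-1] != bits.shape[-1]:
        raise ValueError("state and pattern lengths differ")
    rng = rng_from(rng)
    u = rng.random(m.shape)
    up = (bits == 1) & (m == 0) & (u < params.p)
    down = (bits == 0) & (m == 1) & (u < params.q)
    out = m.copy()
    out[up] = 1
    out[down] = 0
    return out


def response(m: np.ndarray, s: Pattern | np.ndarray) -> int:
    """Steady-state overlap response sum_i s_i m_i to a probe pattern."""
    bits = s.bits if isinstance(s, Pattern) else np.asarray(s)
    m = np.asarray(m)
    if m.shape[-1] != bits.shape[-1]:
        raise ValueError("state and pattern lengths differ")
    r = (m * bits).sum(axis=-1)
    return int(r) if np.ndim(r) == 0 else r


@dataclass(frozen=True)
class ResponseStats:
    mean: float
    variance: float
    age: int | float | Literal["random"]


def _aged_high_prob(params: MarkovParams, age: float) -> float:
    """P(synapse high at probe time | its bit in the learned pattern was 1),
    for a pattern of the given age at stationarity.  Real-valued ages are
    allowed (used for smooth capacity optimization)."""
    rho = stationary_fraction(params)
    lam = retention_factor(params)
    return rho + (1 - rho) * params.p * lam ** (age - 1.0)


def response_stats(
    age: float | Literal["random"], params: MarkovParams
) -> ResponseStats:
    """Closed-form mean and variance of the overlap response at
    stationarity, for a learned pattern of the given age (1 = most recent)
    or for a fresh random pattern (``age="random"``)."""
    if age == RANDOM:
        mu = params.f * stationary_fraction(params)
    else:
        if age < 1:
            raise ValueError("age must be >= 1 (1 = most recently learned)")
        mu = params.f * _aged_high_prob(params, age)
    return ResponseStats(
        mean=params.N * mu, variance=params.N * mu * (1 - mu), age=age
    )


def snr(age: float, params: MarkovParams) -> float:
    """Signal-to-noise ratio of retrieval for a memory of the given age:
    mean difference from random-probe responses over the root of summed
    variances.  Zero in the degenerate case p = q = 0 (no encoding)."""
    if age < 1:
        raise ValueError("age must be >= 1")
    if params.p == 0 and params.q == 0:
        return 0.0
    learned = response_stats(age, params)
    rand = response_stats(RANDOM, params)
    noise2 = learned.variance + rand.variance
    if noise2 == 0:
        raise ZeroDivisionError("zero retrieval noise: SNR undefined")
    return (learned.mean - rand.mean) / math.sqrt(noise2)


@dataclass(frozen=True)
class SNRCurve:
    ages: np.ndarray
    values: np.ndarray
    params: MarkovParams

    def as_dict(self) -> dict[int, float]:
        return {int(a): float(v) for a, v in zip(self.ages, self.values)}


def snr_curve(params: MarkovParams, max_age: int) -> SNRCurve:
    ages = np.arange(1, max_age + 1)
    return SNRCurve(ages, np.array([snr(a, params) for a in ages]), params)


@dataclass(frozen=True)
class CapacityResult:
    capacity: int
    params: MarkovParams
    snr_curve: SNRCurve
    meta: dict = field(default_factory=dict)


def capacity_search_bound(params: MarkovParams) -> int:
    """Upper bound for the capacity search: safely beyond the
    geometric-decay horizon, with an overflow guard."""
    denom = params.f * params.p + (1 - params.f) * params.q
    if denom == 0:
        return 1
    bound = 50 * math.sqrt(params.N) * (1 + 1 / denom)
    return int(min(bound, 1e8))


def _snr_threshold_age(params: MarkovParams) -> float:
    """Real-valued age at which SNR crosses 1 (0 if SNR(1) <= 1).

    SNR is monotone decreasing in age (the signal decays geometrically
    while the learned-probe variance shrinks toward the random-probe
    variance slower than the signal), so bisection applies.
    """
    if snr(1.0, params) <= 1.0:
        return 0.0
    hi = 2.0
    bound = capacity_search_bound(params)
    while snr(hi, params) > 1.0:
        hi *= 2
        if hi > bound:
            return float(bound)
    lo = hi / 2
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if snr(mid, params) > 1.0:
            lo = mid
        else:
            hi = mid
    return lo


def capacity(params: MarkovParams) -> CapacityResult:
    """Largest age whose SNR strictly exceeds 1 (0 if even the most recent
    memory is unretrievable).  Found by geometric bracketing of the SNR = 1
    crossing and verified on the integer grid."""
    if params.p == 0 and params.q == 0:
        cap = 0
    else:
        x = _snr_threshold_age(params)
        cap = int(math.floor(x))
        # guard against floating-point edge: verify on the integers
        while cap >= 1 and snr(cap, params) <= 1.0:
            cap -= 1
        while snr(cap + 1, params) > 1.0 and cap + 1 < capacity_search_bound(params):
            cap += 1
    curve = snr_curve(params, max(cap + 1, 10))
    return CapacityResult(capacity=cap, params=params, snr_curve=curve)


def _log_grid(n: int, lo: float = 1e-5, hi: float = 1.0) -> np.ndarray:
    return np.logspace(math.log10(lo), math.log10(hi), n)


def optimize_probs(
    f: float,
    N: int,
    n_grid: int = 50,
    threshold_age=None,
    capacity_of=None,
) -> tuple[float, float, CapacityResult]:
    """Transition probabilities maximizing the capacity at given (f, N).

    A log-spaced n_grid x n_grid scan over (p, q) in [1e-5, 1]^2 (ties
    broken toward smaller p+q), refined by Nelder-Mead on (log p, log q)
    maximizing the real-valued SNR = 1 crossing age.  Deterministic.

    ``threshold_age`` / ``capacity_of`` hooks let the population module
    reuse the same machinery with its own SNR.
    """
    if N < 4:
        raise ValueError("optimization requires N >= 4")
    if threshold_age is None:
        threshold_age = lambda p, q: _snr_threshold_age(MarkovParams(p, q, f, N))
    if capacity_of is None:
        capacity_of = lambda p, q: capacity(MarkovParams(p, q, f, N))

    grid = _log_grid(n_grid)
    best = (-1.0, math.inf, 0.0, 0.0)  # (age, p+q tiebreak, p, q)
    for p in grid:
        for q in grid:
            x = threshold_age(p, q)
            key = (x, -(p + q))
            if key > (best[0], -best[1]):
                best = (x, p + q, p, q)
    p0, q0 = best[2], best[3]

    def neg_age(logpq):
        p, q = np.exp(logpq)
        if p > 1 or q > 1:
            return 0.0
        return -threshold_age(p, q)

    res = minimize(
        neg_age,
        x0=np.log([p0, q0]),
        method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 200},
    )
    p1, q1 = np.exp(res.x)
    p1, q1 = min(p1, 1.0), min(q1, 1.0)
    cand = [(p0, q0), (p1, q1)]
    results = [(capacity_of(p, q), p, q) for p, q in cand]
    results.sort(key=lambda t: (-t[0].capacity, t[1] + t[2]))
    cap, p_opt, q_opt = results[0]
    meta = {"grid_points": n_grid, "grid_best": (p0, q0), "polished": (p1, q1)}
    return p_opt, q_opt, CapacityResult(cap.capacity, cap.params, cap.snr_curve, meta)


# ---------------------------------------------------------------------------
# Monte-Carlo oracle


@dataclass(frozen=True)
class MCExperiment:
    """Empirical retrieval statistics from simulated learning sequences."""

    ages: np.ndarray
    mean: np.ndarray
    mean_se: np.ndarray
    var: np.ndarray
    var_se: np.ndarray
    snr: np.ndarray
    snr_se: np.ndarray
    rand_mean: float
    rand_mean_se: float
    rand_var: float
    rand_var_se: float
    responses: Mapping  # age -> raw response samples (and "random")
    n_reps: int


def _batch_stats(x: np.ndarray, n_batches: int) -> tuple[float, float, float, float]:
    """(mean, se_mean, var, se_var) with SEs from batch means."""
    x = np.asarray(x, dtype=float)
    mean, var = x.mean(), x.var(ddof=1)
    batches = np.array_split(x, n_batches)
    bm = np.array([b.mean() for b in batches])
    bv = np.array([b.var(ddof=1) for b in batches])
    k = len(batches)
    return (
        mean,
        bm.std(ddof=1) / math.sqrt(k),
        var,
        bv.std(ddof=1) / math.sqrt(k),
    )


def mc_experiment(
    params: MarkovParams,
    n_patterns: int,
    n_reps: int,
    seed: int,
    max_age: int | None = None,
    n_batches: int = 25,
) -> MCExperiment:
    """Simulate full learning sequences and measure retrieval statistics.

    Each repetition starts every synapse at the stationary law (an exact
    stationary start for a single network), learns ``n_patterns`` fresh
    Bernoulli(f) patterns, then probes the stored patterns of each age and
    one fresh random pattern.  Returns empirical means/variances/SNR with
    batch-mean standard errors, plus the raw response samples.
    """
    if max_age is None:
        max_age = n_patterns
    if n_patterns < max_age:
        raise ValueError("n_patterns must cover the oldest probed age")
    rng = rng_from(seed)
    N, f = params.N, params.f
    rho = stationary_fraction(params)
    state = (rng.random((n_reps, N)) < rho).astype(np.int8)
    recent: list[np.ndarray] = []  # last max_age patterns, newest last
    for t in range(n_patterns):
        xi = (rng.random((n_reps, N)) < f).astype(np.int8)
        u = rng.random((n_reps, N))
        up = (xi == 1) & (state == 0) & (u < params.p)
        down = (xi == 0) & (state == 1) & (u < params.q)
        state[up] = 1
        state[down] = 0
        recent.append(xi)
        if len(recent) > max_age:
            recent.pop(0)
    ages = np.arange(1, max_age + 1)
    responses = {}
    for age in ages:
        responses[int(age)] = (state * recent[-age]).sum(axis=1)
    responses[RANDOM] = (
        state * (rng.random((n_reps, N)) < f).astype(np.int8)
    ).sum(axis=1)

    r_mean, r_mse, r_var, r_vse = _batch_stats(responses[RANDOM], n_batches)
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
    return MCExperiment(
        ages=ages,
        mean=np.array(means), mean_se=np.array(mses),
        var=np.array(vars_), var_se=np.array(vses),
        snr=np.array(snrs), snr_se=np.array(sses),
        rand_mean=r_mean, rand_mean_se=r_mse,
        rand_var=r_var, rand_var_se=r_vse,
        responses=responses, n_reps=n_reps,
    )
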