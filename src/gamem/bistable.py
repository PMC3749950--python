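"""Single bistable memory element (the "pseudo-synapse").

A protein M activates its own synthesis through a cooperative (Hill)
positive feedback loop and is degraded at a constant rate; external factors
contribute an additive synthesis rate ``g``:

    dM/dt = beta * M^n / (K^n + M^n) + g - delta * M + sigma * xi(t)

with ``xi`` Gaussian white noise.  For suitable parameters the deterministic
drift is N-shaped with three zero crossings: two stable expression levels
(M_low, M_high) separated by an unstable fixed point.  Writing the drift as
the negative gradient of an energy function E(M), the barrier heights
("energy gaps") between each well and the saddle control the noise-induced
transition rates exponentially — the physical basis for using the element as
a binary memory that external inputs can bias in either direction.

Units are dimensionless: concentrations in units of K, time in units of the
protein lifetime 1/delta.  The shipped defaults (see
:data:`DEFAULT_PARAMS`) give a balanced double well; with delta = 0.4/min
one time unit is 2.5 min and the default 12-unit trial is 30 min.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import math
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from statsmodels.stats.proportion import proportion_confint

from ._rng import rng_from, root_sequence

__all__ = [
    "BistableParams",
    "FixedPoint",
    "FixedPointSet",
    "EnergyProfile",
    "Trajectory1D",
    "SwitchEstimate",
    "BistabilityError",
    "DEFAULT_PARAMS",
    "G_MAINTENANCE",
    "G_PAIRING",
    "G_US_ALONE",
    "TRIAL_DURATION",
    "drift",
    "drift_slope",
    "find_fixed_points",
    "energy",
    "energy_profile",
    "energy_gaps",
    "energy_curvature",
    "kramers_escape_rate",
    "kramers_rates",
    "bistable_range",
    "symmetric_input",
    "calibrate_input",
    "simulate_element",
    "simulate_paths",
    "estimate_switch_prob",
    "mean_escape_time",
]


class BistabilityError(ValueError):
    """Raised when an operation requires a bistable landscape and the given
    input level makes the element monostable (or leaves no fixed point)."""


@dataclass(frozen=True)
class BistableParams:
    """Kinetic parameters of one memory element.

    beta : maximal feedback synthesis rate (concentration/time)
    K    : half-activation concentration
    n    : Hill coefficient (cooperativity of the feedback), n >= 2
    delta: degradation rate (1/time)
    sigma: noise magnitude (concentration/sqrt(time))
    """

    beta: float = 1.8
    K: float = 1.0
    n: int = 4
    delta: float = 1.0
    sigma: float = 0.18

    def __post_init__(self):
        if self.beta <= 0 or self.K <= 0 or self.delta <= 0:
            raise ValueError("beta, K and delta must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if int(self.n) != self.n or self.n < 2:
            # n >= 2 is necessary for the drift to admit three zero crossings
            raise ValueError("Hill coefficient n must be an integer >= 2")


#: Calibrated defaults.  The landscape beta=1.8, n=4 has a balanced double
#: well; the three input levels below encode the stochastic-multiplexer
#: logic (see gamem.network) and were found with calibrate_input /
#: symmetric_input so that one 12-unit pairing trial switches low->high with
#: probability ~0.59, one US-alone trial switches high->low with ~0.28, and
#: spontaneous switching at maintenance is ~3% over a 13-trial protocol.
DEFAULT_PARAMS = BistableParams()
G_MAINTENANCE = 0.163
G_PAIRING = 0.38
G_US_ALONE = 0.005
TRIAL_DURATION = 12.0


@dataclass(frozen=True)
class FixedPoint:
    m: float
    stability: Literal["stable", "unstable"]


@dataclass(frozen=True)
class FixedPointSet:
    points: tuple[FixedPoint, ...]

    def __post_init__(self):
        if not 1 <= len(self.points) <= 3:
            raise ValueError("expected 1-3 fixed points")

    @property
    def is_bistable(self) -> bool:
        return len(self.points) == 3

    @property
    def m_low(self) -> float:
        return self.points[0].m

    @property
    def m_high(self) -> float:
        return self.points[-1].m

    @property
    def m_unstable(self) -> float:
        if not self.is_bistable:
            raise BistabilityError("no unstable fixed point: system is monostable")
        return self.points[1].m


@dataclass(frozen=True)
class EnergyProfile:
    m_grid: np.ndarray
    e_values: np.ndarray
    gap_low: float
    gap_high: float


def drift(m, g: float, p: BistableParams = DEFAULT_PARAMS):
    """Deterministic drift: Hill feedback + external input - degradation."""
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise ValueError("concentration m must be non-negative")
    mn = m**p.n
    out = p.beta * mn / (p.K**p.n + mn) + g - p.delta * m
    return out if out.ndim else float(out)


def drift_slope(m, g: float, p: BistableParams = DEFAULT_PARAMS):
    """d(drift)/dm, analytic."""
    m = np.asarray(m, dtype=float)
    mn = m**p.n
    denom = (p.K**p.n + mn) ** 2
    out = p.beta * p.n * p.K**p.n * m ** (p.n - 1) / denom - p.delta
    return out if out.ndim else float(out)


def _default_m_max(g: float, p: BistableParams) -> float:
    return 1.2 * (p.beta + max(g, 0.0)) / p.delta + p.K


def find_fixed_points(
    g: float,
    p: BistableParams = DEFAULT_PARAMS,
    m_max: float | None = None,
    grid_step: float | None = None,
) -> FixedPointSet:
    """All roots of the drift in [0, m_max], with stability from the drift
    slope.  Roots are bracketed by a sign scan on a fine grid and polished
    with Brent's method (relative tolerance 1e-12)."""
    if m_max is None:
        m_max = _default_m_max(g, p)
    elif m_max <= (p.beta + max(g, 0.0)) / p.delta:
        raise ValueError("m_max must exceed (beta + max(g,0))/delta")
    step = 1e-3 * p.K if grid_step is None else grid_step
    ms = np.arange(0.0, m_max + step, step)
    d = drift(ms, g, p)
    roots: list[float] = []
    exact = np.flatnonzero(d == 0.0)
    roots.extend(ms[exact])
    sign_change = np.flatnonzero(np.sign(d[:-1]) * np.sign(d[1:]) < 0)
    for i in sign_change:
        roots.append(
            brentq(lambda m: drift(m, g, p), ms[i], ms[i + 1], xtol=1e-14, rtol=1e-12)
        )
    roots = sorted(roots)
    if not roots:
        raise BistabilityError(
            f"drift has no non-negative root for g={g!r}: nonphysical input level"
        )
    pts = tuple(
        FixedPoint(r, "stable" if drift_slope(r, g, p) < 0 or r == 0.0 else "unstable")
        for r in roots
    )
    return FixedPointSet(pts)


def energy(m, g: float, p: BistableParams = DEFAULT_PARAMS):
    """Energy function E with drift = -dE/dM and the convention E(0) = 0.

    E(m) = -integral_0^m drift(s) ds, evaluated by adaptive quadrature of
    the (smooth) Hill term plus the polynomial terms in closed form.
    """
    scalar = np.isscalar(m)
    ms = np.atleast_1d(np.asarray(m, dtype=float))
    if np.any(ms < 0):
        raise ValueError("concentration m must be non-negative")
    hill = np.array(
        [quad(lambda s: s**p.n / (p.K**p.n + s**p.n), 0.0, mi, limit=200)[0] for mi in ms]
    )
    e = -(p.beta * hill + g * ms - 0.5 * p.delta * ms**2)
    return float(e[0]) if scalar else e


def energy_curvature(m: float, g: float, p: BistableParams = DEFAULT_PARAMS) -> float:
    """E''(m) = -drift'(m); positive at minima, negative at the saddle."""
    return -drift_slope(m, g, p)


def energy_gaps(
    g: float, p: BistableParams = DEFAULT_PARAMS, fps: FixedPointSet | None = None
) -> tuple[float, float]:
    """Barrier heights (gap_low, gap_high) = E(saddle) - E(well).

    gap_low guards the low well against low->high transitions; raising g
    shrinks it and enlarges gap_high (and vice versa).
    """
    if fps is None:
        fps = find_fixed_points(g, p)
    if not fps.is_bistable:
        raise BistabilityError(f"element is monostable at g={g!r}")
    e_lo, e_un, e_hi = energy(
        np.array([fps.m_low, fps.m_unstable, fps.m_high]), g, p
    )
    return e_un - e_lo, e_un - e_hi


def energy_profile(
    g: float,
    p: BistableParams = DEFAULT_PARAMS,
    m_max: float | None = None,
    num: int = 801,
) -> EnergyProfile:
    if m_max is None:
        m_max = _default_m_max(g, p)
    grid = np.linspace(0.0, m_max, num)
    gap_low, gap_high = energy_gaps(g, p)
    return EnergyProfile(grid, energy(grid, g, p), gap_low, gap_high)


def kramers_escape_rate(
    gap: float, curv_min: float, curv_max: float, sigma: float
) -> float:
    """Weak-noise (Kramers) escape rate over a barrier.

    rate = sqrt(curv_min * |curv_max|) / (2 pi) * exp(-2 gap / sigma^2)

    ``curv_min`` is E'' at the well (positive), ``curv_max`` E'' at the
    saddle (negative).  sigma = 0 returns rate 0.  Only the exponential
    dependence on the gap is asserted by the theory used here; the
    prefactor is the standard curvature formula.
    """
    if gap <= 0:
        raise ValueError("gap must be positive")
    if curv_min <= 0 or curv_max >= 0:
        raise ValueError("expected curv_min > 0 (well) and curv_max < 0 (saddle)")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return 0.0
    return math.sqrt(curv_min * abs(curv_max)) / (2 * math.pi) * math.exp(
        -2.0 * gap / sigma**2
    )


def kramers_rates(
    g: float, p: BistableParams = DEFAULT_PARAMS
) -> tuple[float, float]:
    """(low->high, high->low) Kramers rates at input level g."""
    fps = find_fixed_points(g, p)
    gap_low, gap_high = energy_gaps(g, p, fps)
    c_un = energy_curvature(fps.m_unstable, g, p)
    r_lh = kramers_escape_rate(gap_low, energy_curvature(fps.m_low, g, p), c_un, p.sigma)
    r_hl = kramers_escape_rate(gap_high, energy_curvature(fps.m_high, g, p), c_un, p.sigma)
    return r_lh, r_hl


def bistable_range(
    p: BistableParams = DEFAULT_PARAMS, g_span: tuple[float, float] = (-2.0, 2.0)
) -> tuple[float, float]:
    """Interval of input levels g over which the element is bistable,
    located by scan plus bisection on the fixed-point count."""

    def nfp(g):
        try:
            return len(find_fixed_points(g, p).points)
        except BistabilityError:
            return 0

    gs = np.linspace(*g_span, 241)
    bist = [g for g in gs if nfp(g) == 3]
    if not bist:
        raise BistabilityError("no bistable input level found in span")
    lo, hi = min(bist), max(bist)
    step = gs[1] - gs[0]
    f_lo = brentq(lambda g: (1 if nfp(g) == 3 else -1), lo - step, lo, xtol=1e-9)
    f_hi = brentq(lambda g: (1 if nfp(g) == 3 else -1), hi, hi + step, xtol=1e-9)
    return f_lo, f_hi


def symmetric_input(p: BistableParams = DEFAULT_PARAMS) -> float:
    """Input level at which the two energy gaps are equal."""
    g_lo, g_hi = bistable_range(p)
    eps = 1e-4 * (g_hi - g_lo)

    def gap_diff(g):
        gl, gh = energy_gaps(g, p)
        return gl - gh

    return brentq(gap_diff, g_lo + eps, g_hi - eps, xtol=1e-10)


# ---------------------------------------------------------------------------
# stochastic simulation


@dataclass(frozen=True)
class Trajectory1D:
    times: np.ndarray
    values: np.ndarray
    dt: float
    seed: int

    def to_csv(self, path: str | Path, params: BistableParams | None = None) -> None:
        """Write `time,m` CSV plus a JSON sidecar with run metadata."""
        import pandas as pd

        path = Path(path)
        pd.DataFrame({"time": self.times, "m": self.values}).to_csv(path, index=False)
        meta = {"dt": self.dt, "seed": self.seed}
        if params is not None:
            meta["params"] = {
                "beta": params.beta, "K": params.K, "n": params.n,
                "delta": params.delta, "sigma": params.sigma,
            }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def _check_dt(dt: float, p: BistableParams) -> None:
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt * p.delta >= 0.1:
        raise ValueError(
            f"time step dt={dt} is too large for delta={p.delta} "
            f"(need dt*delta < 0.1; try dt={0.05 / p.delta:g})"
        )


def _normalize_schedule(
    g_schedule: float | Sequence[tuple[float, float]], t_end: float
) -> list[tuple[float, float]]:
    if np.isscalar(g_schedule):
        return [(t_end, float(g_schedule))]
    sched = [(float(d), float(g)) for d, g in g_schedule]
    if any(d <= 0 for d, _ in sched):
        raise ValueError("schedule durations must be positive")
    total = sum(d for d, _ in sched)
    if total < t_end - 1e-12:
        sched.append((t_end - total, sched[-1][1]))  # hold last level
    return sched


def simulate_paths(
    p: BistableParams,
    g,
    m0: np.ndarray,
    duration: float,
    dt: float,
    rng: np.random.Generator,
    chunk: int = 200,
) -> np.ndarray:
    """Euler-Maruyama integration of an ensemble of independent elements.

    ``g`` may be a scalar (shared input) or an array matching ``m0``
    (per-path input).  The boundary at 0 is reflecting.  Returns terminal
    values; mutates nothing.
    """
    _check_dt(dt, p)
    m = np.array(m0, dtype=float)
    n_steps = int(round(duration / dt))
    sqdt = math.sqrt(dt)
    done = 0
    while done < n_steps:
        k = min(chunk, n_steps - done)
        noise = rng.standard_normal((k, m.size)) if p.sigma > 0 else None
        for i in range(k):
            m = m + drift(m, g, p) * dt
            if noise is not None:
                m = m + p.sigma * sqdt * noise[i]
            np.abs(m, out=m)
        done += k
    return m


def simulate_element(
    p: BistableParams,
    g_schedule: float | Sequence[tuple[float, float]],
    t_end: float,
    dt: float,
    seed: int,
    m0: float | None = None,
) -> Trajectory1D:
    """Single stochastic trajectory under a piecewise-constant input.

    ``g_schedule`` is either one level or a list of ``(duration, g)``
    segments applied in order (the last level is held to ``t_end``).
    Identical (seed, dt, schedule) replays bit-identically.
    """
    _check_dt(dt, p)
    sched = _normalize_schedule(g_schedule, t_end)
    rng = rng_from(seed)
    if m0 is None:
        m0 = find_fixed_points(sched[0][1], p).m_low
    n_steps = int(round(t_end / dt))
    times = np.arange(n_steps + 1) * dt
    values = np.empty(n_steps + 1)
    values[0] = m0
    g_of_step = np.empty(n_steps)
    pos = 0
    t_acc = 0.0
    for dur, g in sched:
        k = min(int(round(dur / dt)), n_steps - pos)
        g_of_step[pos : pos + k] = g
        pos += k
        t_acc += dur
        if pos >= n_steps:
            break
    g_of_step[pos:] = sched[-1][1]
    sqdt = math.sqrt(dt)
    m = float(m0)
    noise = rng.standard_normal(n_steps) if p.sigma > 0 else np.zeros(n_steps)
    for i in range(n_steps):
        m = m + (drift(m, g_of_step[i], p)) * dt + p.sigma * sqdt * noise[i]
        m = abs(m)  # reflecting boundary: concentrations are non-negative
        values[i + 1] = m
    return Trajectory1D(times=times, values=values, dt=dt, seed=int(seed))


@dataclass(frozen=True)
class SwitchEstimate:
    prob: float
    ci_low: float
    ci_high: float
    n_reps: int


def estimate_switch_prob(
    p: BistableParams,
    g: float,
    T: float,
    start: Literal["low", "high"],
    n_reps: int,
    seed: int,
    dt: float = 0.02,
    g_maintenance: float = G_MAINTENANCE,
) -> SwitchEstimate:
    """Probability that one input window of duration T flips the element.

    Paths start at the maintenance-landscape stable point given by
    ``start``, evolve under input ``g`` for time T, and are classified by
    the side of the maintenance unstable point they end on.  Returns the
    point estimate with a 95% Wilson interval.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    fps = find_fixed_points(g_maintenance, p)
    m_start = fps.m_low if start == "low" else fps.m_high
    if T == 0:
        return SwitchEstimate(0.0, 0.0, 0.0, n_reps)
    rng = rng_from(seed)
    m = simulate_paths(p, g, np.full(n_reps, m_start), T, dt, rng)
    flipped = (m > fps.m_unstable) if start == "low" else (m < fps.m_unstable)
    k = int(flipped.sum())
    lo, hi = proportion_confint(k, n_reps, alpha=0.05, method="wilson")
    return SwitchEstimate(k / n_reps, float(lo), float(hi), n_reps)


def mean_escape_time(
    p: BistableParams,
    g: float,
    start: Literal["low", "high"],
    n_reps: int,
    seed: int,
    dt: float = 0.02,
    max_time: float = 5e5,
) -> tuple[float, float]:
    """Mean first-passage time from one well to the other, by simulation.

    A transition counts when the path first reaches the opposite stable
    fixed point (not merely the saddle), matching the well-to-well rate
    that the Kramers formula estimates.  Returns (mean, standard error).
    """
    from ._kernels import escape_times

    fps = find_fixed_points(g, p)
    m0 = fps.m_low if start == "low" else fps.m_high
    target = fps.m_high if start == "low" else fps.m_low
    seeds = root_sequence(seed).generate_state(n_reps, dtype=np.uint32)
    t = escape_times(
        float(m0), float(target), start == "low",
        p.beta, p.K, p.n, p.delta, p.sigma, float(g), dt,
        int(max_time / dt), seeds,
    )
    if np.any(t < 0):
        raise RuntimeError("some paths did not escape within max_time")
    return float(t.mean()), float(t.std(ddof=1) / math.sqrt(n_reps))


def calibrate_input(
    p: BistableParams,
    target_prob: float,
    T: float,
    start: Literal["low", "high"],
    g_bracket: tuple[float, float],
    seed: int,
    n_reps: int = 2000,
    tol: float = 0.02,
    max_iter: int = 12,
) -> float:
    """Find an input level whose one-trial switch probability hits a target.

    Bisection on g (switch probability is monotone in g for each
    direction); stops when the estimate is within ``tol`` of the target.
    This is the routine used to fix the shipped default input levels.
    """
    lo, hi = g_bracket
    increasing = start == "low"  # P(low->high) grows with g; P(high->low) falls
    for i in range(max_iter):
        mid = 0.5 * (lo + hi)
        est = estimate_switch_prob(p, mid, T, start, n_reps, seed + i).prob
        if abs(est - target_prob) <= tol:
            return mid
        too_low = est < target_prob
        if too_low == increasing:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
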