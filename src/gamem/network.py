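"""Full N-element associative memory network: encoding and retrieval.

Each of the N pseudo-synapses M_i is a bistable element
(:mod:`gamem.bistable`) whose external input depends on the stimulus
through a stochastic-multiplexer coupling: with no unconditioned stimulus
(US) the input stays at the maintenance level regardless of the receptor
state, so stored states persist; during a US the input is pushed toward the
low state where the receptor C_i is inactive and toward the high state
where C_i is active.  Repeated CS+US pairings therefore copy the receptor
pattern into the pseudo-synapses, stochastically.

Retrieval is a response protein R, produced either directly by the US
(unconditioned response) or by cooperative C_i AND M_i activation summed
over the N receptor/pseudo-synapse pairs (conditioned response):

    dR/dt = u * u_gain + sum_i c_i * h(M_i) - delta_R * R

with h a steep Hill function of M that is ~0 at the low state and
~cm_gain at the high state.  R carries no intrinsic noise; stochasticity
enters through the M_i only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import math
from pathlib import Path
from typing import Mapping

import numpy as np

from ._rng import rng_from
from .bistable import (
    DEFAULT_PARAMS,
    G_MAINTENANCE,
    G_PAIRING,
    G_US_ALONE,
    BistableParams,
    drift,
    find_fixed_points,
)
from .stimuli import Protocol, Trial

__all__ = [
    "ReadoutParams",
    "GAMParams",
    "GAMState",
    "ProtocolTrace",
    "input_level",
    "pair_activation",
    "readout_drift",
    "simulate_gam",
    "classify_response",
    "DEFAULT_COUPLING",
]

#: Calibrated multiplexer coupling: (c, u) -> input level g.  CS alone and
#: no stimulus share the maintenance level (a CS elicits no change before
#: learning); US alone biases high->low; CS+US biases low->high.
DEFAULT_COUPLING: Mapping[tuple[int, int], float] = {
    (0, 0): G_MAINTENANCE,
    (1, 0): G_MAINTENANCE,
    (0, 1): G_US_ALONE,
    (1, 1): G_PAIRING,
}


@dataclass(frozen=True)
class ReadoutParams:
    """Response-protein parameters.

    delta_R    : degradation rate of R (1/time)
    u_gain     : synthesis rate while the US is present
    cm_gain    : per-pair synthesis rate at full activation
    m_threshold: half-activation concentration of h(M)
    m_hill     : Hill steepness of h (calibrated so that
                 h(m_low)/h(m_high) < 0.02 for the default element)
    """

    delta_R: float = 1.0
    u_gain: float = 1.0
    cm_gain: float = 1.0
    m_threshold: float = 0.545
    m_hill: int = 8

    def __post_init__(self):
        if min(self.delta_R, self.u_gain, self.cm_gain, self.m_threshold) <= 0:
            raise ValueError("readout parameters must be positive")
        if self.m_hill < 1:
            raise ValueError("m_hill must be a positive integer")


@dataclass(frozen=True)
class GAMParams:
    """Homogeneous N-element network (all synapses share one element)."""

    N: int
    element: BistableParams = DEFAULT_PARAMS
    coupling: Mapping[tuple[int, int], float] = field(
        default_factory=lambda: dict(DEFAULT_COUPLING)
    )
    readout: ReadoutParams = ReadoutParams()

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")
        keys = {(0, 0), (1, 0), (0, 1), (1, 1)}
        if set(self.coupling) != keys:
            raise ValueError("coupling must map exactly the four (c, u) pairs")
        if self.coupling[(0, 0)] != self.coupling[(1, 0)]:
            raise ValueError(
                "CS alone must leave the landscape unchanged: "
                "coupling[(0,0)] must equal coupling[(1,0)]"
            )
        for key, g in self.coupling.items():
            if not find_fixed_points(g, self.element).is_bistable:
                raise ValueError(f"coupling level {key} -> g={g} is not bistable")

    @property
    def maintenance(self) -> float:
        return self.coupling[(0, 0)]


@dataclass
class GAMState:
    m: np.ndarray
    r: float

    def __post_init__(self):
        self.m = np.asarray(self.m, dtype=float)
        if np.any(self.m < 0) or self.r < 0:
            raise ValueError("concentrations must be non-negative")


def input_level(c_i: int, u: int, params: GAMParams) -> float:
    """Input level of one pseudo-synapse given its receptor and the US."""
    if c_i not in (0, 1) or u not in (0, 1):
        raise ValueError("c_i and u must be binary")
    return params.coupling[(c_i, u)]


def pair_activation(c, m, readout: ReadoutParams):
    """AND-gate synthesis rate h(c, M) of one receptor/pseudo-synapse pair."""
    c = np.asarray(c)
    m = np.asarray(m, dtype=float)
    mh = m**readout.m_hill
    out = c * readout.cm_gain * mh / (readout.m_threshold**readout.m_hill + mh)
    return float(out) if out.ndim == 0 else out


def readout_drift(state: GAMState, c: np.ndarray, u: int, params: GAMParams) -> float:
    """dR/dt: US pathway plus the sum of independent pair activations."""
    c = np.asarray(c)
    if c.shape != state.m.shape:
        raise ValueError("receptor vector length must equal N")
    ro = params.readout
    return float(
        u * ro.u_gain + pair_activation(c, state.m, ro).sum() - ro.delta_R * state.r
    )


@dataclass(frozen=True)
class ProtocolTrace:
    times: np.ndarray  # (T+1,)
    m: np.ndarray  # (T+1, N)
    r: np.ndarray  # (T+1,)
    c_applied: np.ndarray  # (T, N) int8
    u_applied: np.ndarray  # (T,) int8
    seed: int
    protocol: Protocol

    def to_csv(self, path: str | Path, meta: dict | None = None) -> None:
        import pandas as pd

        path = Path(path)
        n = self.m.shape[1]
        df = pd.DataFrame({"time": self.times, "r": self.r})
        for i in range(n):
            df[f"m_{i + 1}"] = self.m[:, i]
        df["u"] = np.concatenate([[0], self.u_applied])
        df["c_active_count"] = np.concatenate(
            [[0], self.c_applied.sum(axis=1)]
        )
        df.to_csv(path, index=False)
        sidecar = {"seed": self.seed, "n_synapses": n}
        if meta:
            sidecar.update(meta)
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def _steps_for(t: float, dt: float) -> int:
    return int(round(t / dt))


def simulate_gam(
    params: GAMParams,
    protocol: Protocol,
    dt: float,
    seed: int,
    m0: np.ndarray | None = None,
    r0: float = 0.0,
) -> ProtocolTrace:
    """Integrate the full network through a stimulus protocol.

    Each pseudo-synapse follows its Euler-Maruyama update with the
    time-varying input level selected by the multiplexer coupling
    (independent noise per synapse); R is integrated deterministically with
    the same step.  Bit-identical replay for identical (seed, dt,
    protocol).
    """
    el = params.element
    if dt * el.delta >= 0.1:
        raise ValueError(f"dt too large; need dt*delta < 0.1 (try {0.05 / el.delta:g})")
    for a, b in zip(protocol.trials, protocol.trials[1:]):
        if b.onset < a.end:
            raise ValueError("overlapping trials")
    rng = rng_from(seed)
    N = params.N
    if m0 is None:
        m0 = np.full(N, find_fixed_points(params.maintenance, el).m_low)
    n_steps = _steps_for(protocol.horizon, dt)
    times = np.arange(n_steps + 1) * dt
    m_out = np.empty((n_steps + 1, N))
    r_out = np.empty(n_steps + 1)
    c_applied = np.zeros((n_steps, N), dtype=np.int8)
    u_applied = np.zeros(n_steps, dtype=np.int8)
    for tr in protocol.trials:
        i0, i1 = _steps_for(tr.onset, dt), _steps_for(tr.end, dt)
        if tr.pattern is not None:
            c_applied[i0:i1] = tr.pattern.bits
        u_applied[i0:i1] = tr.us

    m = np.array(m0, dtype=float)
    r = float(r0)
    m_out[0] = m
    r_out[0] = r
    ro = params.readout
    sqdt = math.sqrt(dt)
    g_table = np.array(
        [
            [params.coupling[(0, 0)], params.coupling[(0, 1)]],
            [params.coupling[(1, 0)], params.coupling[(1, 1)]],
        ]
    )
    for i in range(n_steps):
        c = c_applied[i]
        u = int(u_applied[i])
        g = g_table[c, u]
        noise = rng.standard_normal(N) if el.sigma > 0 else 0.0
        dr = u * ro.u_gain + pair_activation(c, m, ro).sum() - ro.delta_R * r
        m = m + drift(m, 0.0, el) * dt + g * dt + el.sigma * sqdt * noise
        np.abs(m, out=m)
        r = max(r + dr * dt, 0.0)
        m_out[i + 1] = m
        r_out[i + 1] = r
    return ProtocolTrace(times, m_out, r_out, c_applied, u_applied, int(seed), protocol)


def classify_response(
    trace: ProtocolTrace, trial: Trial | int, threshold: float
) -> tuple[bool, float]:
    """Threshold readout of one trial: the mean of R over the second half
    of the stimulus window, compared against a fixed threshold."""
    if isinstance(trial, int):
        trial = trace.protocol.trials[trial]
    dt = trace.times[1] - trace.times[0]
    i0 = _steps_for(trial.onset + trial.duration / 2, dt)
    i1 = _steps_for(trial.end, dt)
    if i1 <= i0 or i1 > len(trace.r) - 1:
        raise ValueError("empty or out-of-range classification window")
    mean_r = float(trace.r[i0 : i1 + 1].mean())
    return mean_r > threshold, mean_r
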