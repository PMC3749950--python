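"""Numba kernels for the few hot loops that numpy vectorization does not
cover (first-passage simulations with path-dependent stopping)."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def escape_times(
    m0: float,
    barrier: float,
    upward: bool,
    beta: float,
    K: float,
    n: int,
    delta: float,
    sigma: float,
    g: float,
    dt: float,
    max_steps: int,
    seeds: np.ndarray,
) -> np.ndarray:
    """First-passage times of Euler-Maruyama paths from m0 to the barrier.

    Returns -1 for paths that did not cross within max_steps.
    """
    out = np.empty(len(seeds))
    sqdt = np.sqrt(dt)
    Kn = K**n
    for j in range(len(seeds)):
        np.random.seed(seeds[j])
        m = m0
        t = -1.0
        for i in range(max_steps):
            mn = m**n
            dr = beta * mn / (Kn + mn) + g - delta * m
            m = m + dr * dt + sigma * sqdt * np.random.normal()
            if m < 0.0:
                m = -m
            if (upward and m >= barrier) or ((not upward) and m <= barrier):
                t = (i + 1) * dt
                break
        out[j] = t
    return out
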