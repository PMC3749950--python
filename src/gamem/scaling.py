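"""Capacity-versus-network-size experiments.

Two regimes are exposed:

* ``single`` — one network, fixed sparseness (default f = 0.2).  With the
  flip probabilities optimized at each N, the capacity grows as sqrt(N)
  (log-log slope 1/2), the bounded-synapse palimpsest law.
* ``population`` — the Z -> infinity analytics.  The shared
  (stimulus-realization) variance dominates at fixed sparseness and caps
  the scaling below linear; in the sparse-stimulus regime f = c/N the
  shared term is subdominant, the optimal q scales as 1/N, and the
  capacity becomes proportional to N.  The default population experiment
  therefore runs f = sparse_c / N (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .markov import optimize_probs
from .population import INFINITE, optimize_population_probs

__all__ = ["capacity_scaling", "loglog_slope"]


def capacity_scaling(
    mode: str,
    N_list=(64, 256, 1024, 4096),
    f: float = 0.2,
    sparse_c: float = 2.0,
    sparse: bool | None = None,
    Z="inf",
    n_grid: int = 40,
) -> pd.DataFrame:
    """Optimized capacity at each network size.

    Returns a frame with columns N, f, p_opt, q_opt, capacity.  ``sparse``
    selects f = sparse_c / N per size (defaults to True for the population
    mode, False for single).
    """
    if mode not in ("single", "population"):
        raise ValueError('mode must be "single" or "population"')
    if sparse is None:
        sparse = mode == "population"
    rows = []
    for N in N_list:
        f_n = sparse_c / N if sparse else f
        if mode == "single":
            p, q, res = optimize_probs(f_n, N, n_grid=n_grid)
        else:
            p, q, res = optimize_population_probs(f_n, N, Z=Z, n_grid=n_grid)
        rows.append(
            {"N": N, "f": f_n, "p_opt": p, "q_opt": q, "capacity": res.capacity}
        )
    return pd.DataFrame(rows)


def loglog_slope(df: pd.DataFrame, y: str = "capacity") -> float:
    """Least-squares slope of log(y) versus log(N)."""
    vals = df[y].to_numpy(dtype=float)
    if np.any(vals <= 0):
        raise ValueError("slope undefined: non-positive values")
    return float(np.polyfit(np.log(df["N"].to_numpy(float)), np.log(vals), 1)[0])
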