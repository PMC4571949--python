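"""Deterministic 1-D λmax search: coarse grid scan + bounded refinement.

Both fitters reduce to minimizing a smooth SSE profile over λmax, with all
other parameters solved in closed form at each candidate.  A 1-nm grid
scan locates the basin (ties broken toward the smaller λmax because the
scan is ascending), then scipy's bounded scalar minimizer refines inside
the bracketing ±1 grid step to 0.001 nm.  No random initialization, so
results are bit-reproducible.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy.optimize import minimize_scalar


def grid_refine_minimize(
    objective: Callable[[float], float],
    search: tuple[float, float],
    step: float = 1.0,
    xatol: float = 1e-3,
) -> float:
    """Return the λ in ``search`` minimizing ``objective``."""
    lo, hi = float(search[0]), float(search[1])
    if not hi > lo:
        raise ValueError(f"search interval must satisfy lo < hi, got ({lo}, {hi})")
    grid = np.arange(lo, hi + 0.5 * step, step)
    grid[-1] = min(grid[-1], hi)
    sse = np.array([objective(lam) for lam in grid])
    i = int(np.argmin(sse))  # argmin takes the first (smallest λ) among ties
    blo = grid[max(i - 1, 0)]
    bhi = grid[min(i + 1, len(grid) - 1)]
    if bhi - blo <= 2 * xatol:
        return float(grid[i])
    res = minimize_scalar(
        objective, bounds=(blo, bhi), method="bounded", options={"xatol": xatol}
    )
    # keep the grid point if bounded refinement failed to improve on it
    return float(res.x) if res.fun <= sse[i] else float(grid[i])
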