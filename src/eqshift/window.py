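"""Experimental design window of the equilibrium-shift method.

The measurable signal of the method is the maximum apparent equilibrium
shift delta_c_max = c2_max - c1: the larger it is, the more resolvable the
hydrolysis time course.  It depends only on the equilibrium constant K and
the phosphate:nucleoside ratio P0/N0 (not on the absolute concentration
scale), with a unimodal profile over the ratio — too little phosphate
generates almost no sugar phosphate (c1 small), while a large excess drives
c1 so high that little headroom for a further shift remains.  This module
maps that window over (K, ratio) grids and inverts it to recommend
phosphate equivalents for a target shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .equilibrium import ReactionSystem, max_shift, solve_equilibrium_conversion
from .exceptions import InfeasibilityError, InvalidInputError

__all__ = ["WindowMap", "scan", "recommend_equivalents", "default_K_grid",
           "default_ratio_grid"]


def default_K_grid() -> np.ndarray:
    """31 log-spaced equilibrium constants spanning 0.01-1."""
    return np.logspace(np.log10(0.01), 0.0, 31)


def default_ratio_grid() -> np.ndarray:
    """100 phosphate:nucleoside ratios spanning 0.5-20."""
    return np.linspace(0.5, 20.0, 100)


@dataclass(frozen=True)
class WindowMap:
    """delta_c_max and its ingredients on a (K, ratio) grid; matrices are
    indexed [i_K, i_ratio]."""

    K_grid: np.ndarray
    ratio_grid: np.ndarray
    c1_grid: np.ndarray
    c2max_grid: np.ndarray
    delta_grid: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns K, ratio, c1, c2max, delta."""
        KK, RR = np.meshgrid(self.K_grid, self.ratio_grid, indexing="ij")
        return pd.DataFrame(
            {
                "K": KK.ravel(),
                "ratio": RR.ravel(),
                "c1": self.c1_grid.ravel(),
                "c2max": self.c2max_grid.ravel(),
                "delta": self.delta_grid.ravel(),
            }
        )

    def plot(self, ax=None):
        """Heat map of delta_c_max over (ratio, K); returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        mesh = ax.pcolormesh(
            self.ratio_grid, self.K_grid, self.delta_grid, shading="auto"
        )
        ax.set_yscale("log")
        ax.set_xlabel("phosphate equivalents P0/N0")
        ax.set_ylabel("equilibrium constant K")
        plt.colorbar(mesh, ax=ax, label=r"max apparent shift $\Delta c_{max}$")
        return ax


def _cell(K: float, ratio: float, N0: float) -> tuple[float, float, float]:
    system = ReactionSystem(N0=N0, P0=ratio * N0, K=K)
    c1 = solve_equilibrium_conversion(system)
    win = max_shift(c1, system)
    return c1, win.c2_max, win.delta_c_max


def scan(
    K_grid=None,
    ratio_grid=None,
    N0: float = 1.0,
) -> WindowMap:
    """Compute c1, c2_max and delta_c_max over a (K, ratio) grid.

    The result depends on the phosphate:nucleoside ratio only, never on the
    absolute concentration N0 — K is dimensionless, so scaling every
    concentration cancels from the mass-action ratio.
    """
    K_grid = default_K_grid() if K_grid is None else np.asarray(K_grid, dtype=float)
    ratio_grid = (
        default_ratio_grid() if ratio_grid is None
        else np.asarray(ratio_grid, dtype=float)
    )
    if K_grid.size == 0 or ratio_grid.size == 0:
        raise InvalidInputError("grids must be non-empty")
    if np.any(K_grid <= 0) or np.any(K_grid > 1):
        raise InvalidInputError("K grid must lie in (0, 1]")
    if np.any(ratio_grid <= 0):
        raise InvalidInputError("ratios must be positive")

    shape = (K_grid.size, ratio_grid.size)
    c1_grid = np.empty(shape)
    c2max_grid = np.empty(shape)
    delta_grid = np.empty(shape)
    for i, K in enumerate(K_grid):
        for j, ratio in enumerate(ratio_grid):
            try:
                c1_grid[i, j], c2max_grid[i, j], delta_grid[i, j] = _cell(
                    float(K), float(ratio), N0
                )
            except Exception as exc:
                raise type(exc)(
                    f"window cell K={K:g} (index {i}), ratio={ratio:g} "
                    f"(index {j}): {exc}"
                ) from exc
    return WindowMap(
        K_grid=K_grid,
        ratio_grid=ratio_grid,
        c1_grid=c1_grid,
        c2max_grid=c2max_grid,
        delta_grid=delta_grid,
    )


def recommend_equivalents(
    K: float,
    target_delta: float,
    *,
    ratio_range: tuple[float, float] = (0.5, 50.0),
    n_grid: int = 2001,
) -> tuple[float, float]:
    """Contiguous interval of phosphate equivalents over which the maximum
    apparent shift delta_c_max meets `target_delta`.

    delta_c_max(ratio) is unimodal on the scanned range; this is asserted
    on a dense grid before the two crossings are bracketed with a root
    finder.  Raises ``InfeasibilityError`` (reporting the attainable
    maximum) when the target exceeds the peak.
    """
    if not 0.0 < K <= 1.0:
        raise InvalidInputError(f"K must lie in (0, 1], got {K}")
    if target_delta <= 0.0:
        raise InvalidInputError("target_delta must be positive")

    ratios = np.linspace(ratio_range[0], ratio_range[1], n_grid)
    deltas = np.array([_cell(K, float(r), 1.0)[2] for r in ratios])

    # assert unimodality: the sign of the finite difference may change
    # from + to - at most once (tolerate roundoff-level wiggles)
    diffs = np.diff(deltas)
    signs = np.sign(np.where(np.abs(diffs) < 1e-12, 0.0, diffs))
    signs = signs[signs != 0]
    switches = int(np.sum(np.diff(signs) != 0))
    if switches > 1:
        raise InfeasibilityError(
            f"delta_c_max(ratio) is not unimodal on {ratio_range} for K={K}"
        )

    i_max = int(np.argmax(deltas))
    peak = float(deltas[i_max])
    if target_delta > peak:
        raise InfeasibilityError(
            f"target shift {target_delta:.4f} exceeds the attainable "
            f"maximum {peak:.4f} at K={K} "
            f"(peak near ratio {ratios[i_max]:.2f})"
        )

    def g(r: float) -> float:
        return _cell(K, r, 1.0)[2] - target_delta

    # left crossing
    if deltas[0] >= target_delta:
        lo = float(ratios[0])
    else:
        j = int(np.argmax(deltas[: i_max + 1] >= target_delta))
        lo = float(brentq(g, ratios[j - 1], ratios[j], xtol=1e-10))
    # right crossing
    if deltas[-1] >= target_delta:
        hi = float(ratios[-1])
    else:
        tail = deltas[i_max:]
        j = i_max + int(np.argmax(tail < target_delta))
        hi = float(brentq(g, ratios[j - 1], ratios[j], xtol=1e-10))
    return lo, hi
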