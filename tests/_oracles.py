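"""Independent brute-force oracles for the closed-form algebra.

The equilibrium conversion at any hydrolyzed amount h is re-derived here by
bisection on the mass-action residual

    f(c) = P1P(c) * B(c) - K * N(c) * P(c)

over the physically admissible interval, without using the package's
quadratic closed forms, so the two routes are independent.
"""

from __future__ import annotations

from scipy.optimize import brentq


def bisect_conversion(N0: float, P0: float, K: float, h: float = 0.0) -> float:
    """Equilibrium conversion by root bracketing of the mass-action
    residual; h is the hydrolyzed sugar phosphate (mM)."""

    def residual(c: float) -> float:
        B = c * N0
        P1P = B - h
        N = N0 - B
        P = P0 - B + h
        return P1P * B - K * N * P

    lo = h / N0  # P1P >= 0
    hi = min(1.0, (P0 + h) / N0)  # P >= 0 and N >= 0
    lo += 1e-15
    hi -= 1e-15
    assert residual(lo) < 0 < residual(hi)
    return brentq(residual, lo, hi, xtol=1e-14, rtol=8.9e-16)


def bisect_hydrolyzed(N0: float, P0: float, K: float, c2: float) -> float:
    """Hydrolyzed amount by bisection on h such that the equilibrium
    conversion at h equals the measured c2."""
    return brentq(
        lambda h: bisect_conversion(N0, P0, K, h) - c2,
        0.0,
        c2 * N0 - 1e-12,
        xtol=1e-13,
    )
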