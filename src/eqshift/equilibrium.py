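"""Closed-form mass-action algebra of nucleoside phosphorolysis.

Phosphorolysis cleaves a nucleoside (N) with inorganic phosphate (P) into a
nucleobase (B) and a pentose-1-phosphate (P1P):

    N + P  <=>  B + P1P,        K = [P1P][B] / ([N][P])

With zero initial product concentrations the stoichiometry reduces every
state of the system to a single degree of freedom, the conversion
c = B / N0.  Hydrolytic loss of an amount ``h`` of the sugar phosphate
(returning its phosphate to the pool) shifts the apparent equilibrium from
c1 to a higher c2; because every mass balance is linear in c and h, the
mass-action condition is a quadratic in c (or linear in h), and all
quantities of interest have closed forms:

* ``solve_equilibrium_conversion`` -- pre-hydrolysis conversion c1 from
  (N0, P0, K);
* ``hydrolyzed_amount`` -- hydrolyzed sugar phosphate h from a measured
  post-hydrolysis conversion c2;
* ``conversion_after_hydrolysis`` -- the forward map h -> c2 (exact inverse
  of the previous, used by the simulator);
* ``max_shift`` -- the ceiling c2_max reached when ALL initially generated
  sugar phosphate (c1*N0) has hydrolyzed, and the maximum apparent shift
  delta_c_max = c2_max - c1.

All concentrations are in mM, conversions are fractions in [0, 1); K is
dimensionless, so the algebra only depends on the ratio P0/N0 where noted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .exceptions import (
    InconsistentMeasurementError,
    InfeasibilityError,
    InvalidInputError,
)

__all__ = [
    "ReactionSystem",
    "EquilibriumState",
    "ShiftWindow",
    "solve_equilibrium_conversion",
    "estimate_K_from_equilibrium",
    "hydrolyzed_amount",
    "hydrolyzed_amount_joint",
    "max_shift",
    "conversion_after_hydrolysis",
    "equilibrium_state",
]

# relative tolerance for interval-membership root selection and the
# consistency self-checks below; well above float64 roundoff, far below
# any measurable effect
_RTOL = 1e-12


@dataclass(frozen=True)
class ReactionSystem:
    """One phosphorolysis experiment: initial nucleoside and phosphate
    concentrations (mM) and the dimensionless equilibrium constant.

    For uridine phosphorolysis K = 0.15 (37 degC, pH 7.5); natural
    nucleosides span roughly K = 0.01-0.8.
    """

    N0: float
    P0: float
    K: float

    def __post_init__(self) -> None:
        for name in ("N0", "P0", "K"):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0.0:
                raise InvalidInputError(
                    f"{name} must be a positive finite number, got {value!r}"
                )

    @property
    def ratio(self) -> float:
        """Phosphate equivalents P0/N0, the tunable design parameter."""
        return self.P0 / self.N0


@dataclass(frozen=True)
class EquilibriumState:
    """A fully resolved equilibrium: conversion plus all four reagent
    concentrations (mM) and the cumulative hydrolyzed amount h (mM).

    Satisfies B = c*N0, N = N0 - B, P1P = B - h, P = P0 - B + h; with
    h = 0 this is the pre-hydrolysis state.
    """

    c: float
    N: float
    B: float
    P: float
    P1P: float
    h: float

    def mass_action_ratio(self) -> float:
        """[P1P][B]/([N][P]) at this state; equals K at equilibrium."""
        return (self.P1P * self.B) / (self.N * self.P)


@dataclass(frozen=True)
class ShiftWindow:
    """Pre-hydrolysis conversion, full-hydrolysis ceiling, and the maximum
    apparent equilibrium shift delta_c_max = c2_max - c1."""

    c1: float
    c2_max: float
    delta_c_max: float


def _solve_conversion_quadratic(system: ReactionSystem, h: float) -> float:
    """Admissible root of the mass-action condition at hydrolyzed amount h.

    Substituting the (post-hydrolysis) mass balances into the mass-action
    law gives

        N0*(1-K)*c^2 + [K*(N0+P0) + h*(K-1)]*c - K*(P0+h) = 0

    which contains the pre-hydrolysis case as h = 0.  The root is selected
    by membership in the physical interval (all concentrations
    non-negative), not by a hard-coded branch, and uniqueness is asserted;
    K = 1 degenerates to a linear equation and is solved as such.
    """
    N0, P0, K = system.N0, system.P0, system.K
    a = N0 * (1.0 - K)
    b = K * (N0 + P0) + h * (K - 1.0)
    d = -K * (P0 + h)

    if abs(a) <= _RTOL * N0:  # K = 1 degeneracy: linear equation b*c + d = 0
        candidates = [-d / b]
    else:
        disc = b * b - 4.0 * a * d
        if disc < 0.0:
            raise InfeasibilityError(
                f"no real equilibrium conversion for {system} at h={h}"
            )
        sq = math.sqrt(disc)
        # numerically stable pair of roots
        q = -0.5 * (b + math.copysign(sq, b))
        candidates = [q / a]
        if q != 0.0:
            candidates.append(d / q)

    # physical admissibility: 0 <= c < 1, B <= P1P budget, P > 0, P1P >= 0
    tol = _RTOL * 10.0
    admissible = []
    for c in candidates:
        if not (-tol <= c < 1.0 + tol):
            continue
        c_cl = min(max(c, 0.0), 1.0)
        B = c_cl * N0
        P1P = B - h
        P = P0 - B + h
        if P1P >= -tol * N0 and P >= -tol * P0 and (N0 - B) >= -tol * N0:
            admissible.append(c_cl)
    if not admissible:
        raise InfeasibilityError(
            f"no admissible equilibrium conversion for {system} at h={h}"
        )
    if len(admissible) > 1 and abs(admissible[0] - admissible[1]) > tol:
        raise InfeasibilityError(
            f"ambiguous root selection for {system} at h={h}: {admissible}"
        )
    return admissible[0]


def solve_equilibrium_conversion(system: ReactionSystem) -> float:
    """Pre-hydrolysis equilibrium conversion c1 of a phosphorolysis system.

    Solves N0*(1-K)*c^2 + K*(N0+P0)*c - K*P0 = 0 for the unique root with
    all implied concentrations non-negative.

    Examples
    --------
    >>> round(solve_equilibrium_conversion(ReactionSystem(2.0, 8.0, 0.15)), 4)
    0.5078
    """
    return _solve_conversion_quadratic(system, 0.0)


def estimate_K_from_equilibrium(c1: float, N0: float, P0: float) -> float:
    """Equilibrium constant from a measured pre-hydrolysis conversion.

    K = c1^2*N0 / ((1-c1)*(P0 - c1*N0)); exact inverse of
    :func:`solve_equilibrium_conversion`.
    """
    if N0 <= 0 or P0 <= 0:
        raise InvalidInputError("N0 and P0 must be positive")
    if not 0.0 <= c1 < 1.0:
        raise InvalidInputError(f"c1 must lie in [0, 1), got {c1}")
    if c1 == 0.0:
        warnings.warn(
            "c1 = 0 carries no information about K; returning 0",
            stacklevel=2,
        )
        return 0.0
    if c1 * N0 >= P0:
        raise InfeasibilityError(
            f"c1*N0 = {c1 * N0} mM exceeds the phosphate supply P0 = {P0} mM"
        )
    return (c1 * c1 * N0) / ((1.0 - c1) * (P0 - c1 * N0))


def hydrolyzed_amount(
    c2: float,
    system: ReactionSystem,
    *,
    clamp_tol: float | None = None,
) -> float:
    """Hydrolyzed sugar phosphate (mM) from a measured post-hydrolysis
    equilibrium conversion c2.

    Closed form: h = [c2^2*N0 - K*(1-c2)*(P0 - c2*N0)] / [c2 + K*(1-c2)].
    h = 0 exactly when c2 equals the unshifted equilibrium conversion.

    Parameters
    ----------
    c2 : measured conversion, fraction in (0, 1).
    system : the reaction system (N0, P0, K).
    clamp_tol : measurements may sit slightly below the pre-hydrolysis
        equilibrium because of noise; h in [-clamp_tol, 0) is clamped to 0
        while h < -clamp_tol raises ``InconsistentMeasurementError``.
        Defaults to 1e-3 * N0.
    """
    if not 0.0 < c2 < 1.0:
        raise InvalidInputError(f"c2 must lie in (0, 1), got {c2}")
    if clamp_tol is None:
        clamp_tol = 1e-3 * system.N0
    N0, P0, K = system.N0, system.P0, system.K
    num = c2 * c2 * N0 - K * (1.0 - c2) * (P0 - c2 * N0)
    den = c2 + K * (1.0 - c2)
    h = num / den
    if h < 0.0:
        if h < -clamp_tol:
            raise InconsistentMeasurementError(
                f"c2 = {c2} lies below the equilibrium conversion of "
                f"{system} (implied h = {h:.4g} mM < -{clamp_tol:.4g} mM)"
            )
        h = 0.0
    if h > c2 * N0 * (1.0 + 1e-9):
        raise InconsistentMeasurementError(
            f"implied h = {h:.4g} mM exceeds the generated nucleobase "
            f"{c2 * N0:.4g} mM: measurement inconsistent with {system}"
        )
    return h


def hydrolyzed_amount_joint(
    c1: float,
    c2: float,
    N0: float,
    P0: float,
    *,
    clamp_tol: float | None = None,
) -> tuple[float, float]:
    """Simultaneous determination of K and the hydrolyzed amount from both
    measured equilibria (no independent K needed).

    Returns (K, h): K from c1 via :func:`estimate_K_from_equilibrium`,
    then h from c2 with that K.
    """
    if not 0.0 < c1 < 1.0:
        raise InvalidInputError(f"c1 must lie in (0, 1), got {c1}")
    if c2 < c1:
        raise InconsistentMeasurementError(
            f"c2 = {c2} < c1 = {c1}: the shifted equilibrium cannot lie "
            "below the unshifted one"
        )
    K = estimate_K_from_equilibrium(c1, N0, P0)
    system = ReactionSystem(N0=N0, P0=P0, K=K)
    h = hydrolyzed_amount(c2, system, clamp_tol=clamp_tol)
    return K, h


def conversion_after_hydrolysis(h: float, system: ReactionSystem) -> float:
    """Post-hydrolysis equilibrium conversion c2 for a known hydrolyzed
    amount h (mM); exact inverse of :func:`hydrolyzed_amount`.

    With h = 0 this returns the pre-hydrolysis conversion c1; h may not
    exceed the initially generated sugar phosphate c1*N0 (only that pool
    is exposed to hydrolysis in the discontinuous protocol).
    """
    if h < 0.0:
        raise InvalidInputError(f"h must be non-negative, got {h}")
    c1 = solve_equilibrium_conversion(system)
    bound = c1 * system.N0
    if h > bound * (1.0 + 1e-9):
        raise InfeasibilityError(
            f"h = {h} mM exceeds the full-hydrolysis bound c1*N0 = "
            f"{bound:.6g} mM for {system}"
        )
    c2 = _solve_conversion_quadratic(system, min(h, bound))
    # post hoc: residual sugar phosphate at the new state must be >= 0
    if c2 * system.N0 - h < -1e-9 * system.N0:
        raise InfeasibilityError(
            f"h = {h} mM exceeds the sugar phosphate present at the "
            f"resulting state (c2*N0 = {c2 * system.N0:.6g} mM)"
        )
    return c2


def max_shift(c1: float, system: ReactionSystem) -> ShiftWindow:
    """Ceiling of the apparent equilibrium shift under full hydrolysis.

    Assuming all initially generated sugar phosphate hydrolyzes
    (h = c1*N0), the post-hydrolysis conversion cannot exceed the
    admissible root c2_max of

        N0*(1-K)*c^2 + X*c - K*(P0 + c1*N0) = 0,
        X = c1*N0*K - c1*N0 + N0*K + K*P0,

    and the maximum apparent shift is delta_c_max = c2_max - c1.
    """
    if not 0.0 <= c1 < 1.0:
        raise InvalidInputError(f"c1 must lie in [0, 1), got {c1}")
    c2_max = _solve_conversion_quadratic(system, c1 * system.N0)
    return ShiftWindow(c1=c1, c2_max=c2_max, delta_c_max=c2_max - c1)


def equilibrium_state(system: ReactionSystem, h: float = 0.0) -> EquilibriumState:
    """Fully resolved equilibrium state at hydrolyzed amount h (mM).

    Convenience wrapper: solves for the conversion and evaluates all four
    mass balances B = c*N0, N = N0 - B, P1P = B - h, P = P0 - B + h.
    """
    c = conversion_after_hydrolysis(h, system) if h else solve_equilibrium_conversion(system)
    B = c * system.N0
    return EquilibriumState(
        c=c,
        N=system.N0 - B,
        B=B,
        P=system.P0 - B + h,
        P1P=B - h,
        h=h,
    )
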