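"""First-order hydrolysis kinetics of the sugar phosphate.

The residual (not yet hydrolyzed) pentose-1-phosphate after incubation time
t follows a first-order decay

    residual(t) = A * exp(-k * t),        t_half = ln(2) / k

where the amplitude A is the amount generated in the first equilibrium,
c1 * N0.  Because that amount is anchored by the measured first
equilibrium, A is fixed by default and only k is fitted; fitting A as a
second free parameter is available as an option.  The fit is nonlinear
least squares on the exponential itself (not a log-linear regression),
which avoids the bias a log transform introduces on near-zero residuals
late in the decay.  Uncertainty comes from a case-resampling bootstrap —
honest at the 4-6 time points these experiments typically have, where
asymptotic covariances are not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .equilibrium import ReactionSystem, hydrolyzed_amount, solve_equilibrium_conversion
from .exceptions import DegenerateFitError, InvalidInputError

__all__ = [
    "HydrolysisObservation",
    "DecayFit",
    "FirstOrderDecayModel",
    "FirstOrderDecayResults",
    "build_observations",
    "fit_first_order",
    "bootstrap_ci",
    "ph_rate_profile",
    "PhRateProfile",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class HydrolysisObservation:
    """One time point: measured post-hydrolysis conversion, the inferred
    hydrolyzed amount, and the residual sugar phosphate (all mM)."""

    time: float  # hours
    c2: float
    h: float
    residual_p1p: float
    pH: float | None = None


@dataclass(frozen=True)
class DecayFit:
    """First-order decay fit: rate constant (1/h), half-life (h), amplitude
    (mM), root-mean-square residual (mM)."""

    k: float
    t_half: float
    amplitude: float
    rms: float
    amplitude_fitted: bool = False
    stderr_k: float | None = None
    warning: str | None = None


@dataclass(frozen=True)
class PhRateProfile:
    """Straight line fitted to log10(k) versus pH."""

    slope: float
    intercept: float
    r_squared: float


def build_observations(
    times,
    conversions,
    system: ReactionSystem,
    *,
    pH: float | None = None,
    clamp_tol: float | None = None,
) -> list[HydrolysisObservation]:
    """Turn measured (time, c2) pairs into hydrolysis observations.

    For each measured conversion the hydrolyzed amount is computed from the
    closed-form mass-action solution and the residual sugar phosphate is
    c1*N0 - h.  `clamp_tol` bounds how far a noisy measurement may imply
    h < 0 before it is treated as inconsistent; noisy pipelines should set
    it to a few standard deviations of the propagated conversion noise.
    Inferred h is clipped into the physical range [0, c1*N0].
    """
    times = np.asarray(times, dtype=float)
    conversions = np.asarray(conversions, dtype=float)
    if times.shape != conversions.shape:
        raise InvalidInputError("times and conversions must have equal length")
    if np.any(times < 0):
        raise InvalidInputError("incubation times must be non-negative")
    c1 = solve_equilibrium_conversion(system)
    amplitude = c1 * system.N0
    obs = []
    for t, c2 in zip(times, conversions):
        h = hydrolyzed_amount(float(c2), system, clamp_tol=clamp_tol)
        h = min(h, amplitude)  # noise above the ceiling: clip to full hydrolysis
        obs.append(
            HydrolysisObservation(
                time=float(t), c2=float(c2), h=h,
                residual_p1p=amplitude - h, pH=pH,
            )
        )
    return obs


class FirstOrderDecayModel:
    """First-order exponential decay model for residual sugar phosphate.

    Parameters
    ----------
    times, residuals : observation times (h) and residual amounts (mM).
    amplitude : the initial amount A (mM).  Required when
        ``fix_amplitude`` is True; used as a starting value otherwise
        (defaults to the largest residual).
    fix_amplitude : fix A to the known initial sugar-phosphate amount
        (default) or fit it as a second parameter.
    """

    def __init__(
        self,
        times,
        residuals,
        *,
        amplitude: float | None = None,
        fix_amplitude: bool = True,
    ) -> None:
        self.times = np.asarray(times, dtype=float)
        self.residuals = np.asarray(residuals, dtype=float)
        if self.times.shape != self.residuals.shape or self.times.ndim != 1:
            raise InvalidInputError("times and residuals must be equal-length 1-D")
        if np.any(self.residuals < 0):
            raise InvalidInputError("residual amounts must be non-negative")
        n_distinct = np.unique(self.times).size
        min_needed = 2 if fix_amplitude else 3
        if n_distinct < min_needed:
            raise InvalidInputError(
                f"need >= {min_needed} distinct times "
                f"({'fixed' if fix_amplitude else 'fitted'} amplitude), "
                f"got {n_distinct}"
            )
        if np.ptp(self.residuals) == 0.0:
            raise DegenerateFitError(
                "all residual amounts are equal; the decay rate is "
                "unidentifiable (k ~ 0)"
            )
        self.fix_amplitude = bool(fix_amplitude)
        if fix_amplitude:
            if amplitude is None:
                raise InvalidInputError(
                    "amplitude is required when fix_amplitude=True"
                )
            if amplitude <= 0:
                raise InvalidInputError("amplitude must be positive")
        self.amplitude = float(amplitude) if amplitude is not None else float(
            np.max(self.residuals)
        )

    # -- fitting -----------------------------------------------------------

    def _initial_k(self) -> float:
        """Log-linear starting value, falling back to 1/time-span."""
        mask = self.residuals > 0
        if mask.sum() >= 2 and np.ptp(self.times[mask]) > 0:
            slope = np.polyfit(
                self.times[mask], np.log(self.residuals[mask]), 1
            )[0]
            if np.isfinite(slope) and slope < 0:
                return float(-slope)
        span = float(np.ptp(self.times))
        return 1.0 / span if span > 0 else 1.0

    def fit(self) -> "FirstOrderDecayResults":
        k0 = self._initial_k()
        if self.fix_amplitude:
            A = self.amplitude

            def f(t, k):
                return A * np.exp(-k * t)

            popt, _ = optimize.curve_fit(f, self.times, self.residuals, p0=[k0])
            k = float(popt[0])
            amplitude = A
        else:

            def f(t, A, k):
                return A * np.exp(-k * t)

            popt, _ = optimize.curve_fit(
                f, self.times, self.residuals, p0=[self.amplitude, k0]
            )
            amplitude, k = float(popt[0]), float(popt[1])

        pred = amplitude * np.exp(-k * self.times)
        rms = float(np.sqrt(np.mean((self.residuals - pred) ** 2)))
        warning = None
        if k <= 0:
            warning = (
                f"fitted rate constant is non-positive (k = {k:.4g}/h); "
                "half-life undefined"
            )
        decay = DecayFit(
            k=k,
            t_half=LN2 / k if k > 0 else math.nan,
            amplitude=amplitude,
            rms=rms,
            amplitude_fitted=not self.fix_amplitude,
            warning=warning,
        )
        return FirstOrderDecayResults(self, decay)


@dataclass
class FirstOrderDecayResults:
    """Fitted decay: point estimates plus bootstrap uncertainty and a
    summary table."""

    model: FirstOrderDecayModel
    decay: DecayFit
    _ci: dict = field(default_factory=dict, repr=False)

    @property
    def k(self) -> float:
        return self.decay.k

    @property
    def t_half(self) -> float:
        return self.decay.t_half

    @property
    def amplitude(self) -> float:
        return self.decay.amplitude

    @property
    def rms(self) -> float:
        return self.decay.rms

    def predict(self, times) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        return self.amplitude * np.exp(-self.k * t)

    def bootstrap_ci(
        self,
        n_resamples: int = 1000,
        seed: int | None = None,
        level: float = 0.95,
    ) -> dict:
        """Case-resampling percentile intervals for k and t_half."""
        ci = _bootstrap(
            self.model.times,
            self.model.residuals,
            amplitude=self.model.amplitude,
            fix_amplitude=self.model.fix_amplitude,
            n_resamples=n_resamples,
            seed=seed,
            level=level,
        )
        self._ci = ci
        return ci

    def summary(self) -> str:
        lines = [
            "First-order decay of residual sugar phosphate",
            "=" * 46,
            f"{'observations':<24}{self.model.times.size:>12d}",
            f"{'amplitude A (mM)':<24}{self.amplitude:>12.4f}"
            + ("  (fitted)" if self.decay.amplitude_fitted else "  (fixed)"),
            f"{'rate constant k (1/h)':<24}{self.k:>12.4f}",
            f"{'half-life t1/2 (h)':<24}{self.t_half:>12.4f}",
            f"{'rms residual (mM)':<24}{self.rms:>12.4g}",
        ]
        if self._ci:
            lo, hi = self._ci["k_ci"]
            lines.append(f"{'k 95% CI (1/h)':<24}[{lo:.4f}, {hi:.4f}]")
            lo, hi = self._ci["t_half_ci"]
            lines.append(f"{'t1/2 95% CI (h)':<24}[{lo:.4f}, {hi:.4f}]")
        if self.decay.warning:
            lines.append(f"WARNING: {self.decay.warning}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observations and fitted decay curve; returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.model.times
        grid = np.linspace(0.0, float(t.max()) * 1.05 if t.max() > 0 else 1.0, 200)
        ax.plot(t, self.model.residuals, "o", label="residual P1P (mM)")
        ax.plot(grid, self.predict(grid), "-",
                label=f"fit: t1/2 = {self.t_half:.2f} h")
        ax.set_xlabel("incubation time (h)")
        ax.set_ylabel("residual sugar phosphate (mM)")
        ax.legend()
        return ax


def fit_first_order(
    observations: list[HydrolysisObservation],
    fix_amplitude: bool = True,
    *,
    amplitude: float | None = None,
) -> DecayFit:
    """Fit residual_p1p(t) = A*exp(-k*t) to hydrolysis observations.

    With `fix_amplitude` (default) A is pinned to the initial
    sugar-phosphate amount, recovered from the observations themselves
    (h + residual is c1*N0 at every point) unless given explicitly.
    """
    if not observations:
        raise InvalidInputError("no observations supplied")
    times = [o.time for o in observations]
    residuals = [o.residual_p1p for o in observations]
    if amplitude is None and fix_amplitude:
        amplitude = observations[0].h + observations[0].residual_p1p
    model = FirstOrderDecayModel(
        times, residuals, amplitude=amplitude, fix_amplitude=fix_amplitude
    )
    return model.fit().decay


def _bootstrap(times, residuals, *, amplitude, fix_amplitude,
               n_resamples, seed, level):
    times = np.asarray(times, dtype=float)
    residuals = np.asarray(residuals, dtype=float)
    if n_resamples < 100:
        raise InvalidInputError("n_resamples must be >= 100")
    n = times.size
    if n < 4:
        raise InvalidInputError(
            f"case resampling needs >= 4 observations, got {n}"
        )
    rng = np.random.default_rng(seed)
    ks = []
    min_distinct = 2 if fix_amplitude else 3
    attempts = 0
    while len(ks) < n_resamples and attempts < 20 * n_resamples:
        attempts += 1
        idx = rng.integers(0, n, size=n)
        t_s, r_s = times[idx], residuals[idx]
        if np.unique(t_s).size < min_distinct or np.ptp(r_s) == 0.0:
            continue
        try:
            model = FirstOrderDecayModel(
                t_s, r_s, amplitude=amplitude, fix_amplitude=fix_amplitude
            )
            ks.append(model.fit().decay.k)
        except (DegenerateFitError, RuntimeError):
            continue
    ks = np.asarray(ks)
    alpha = 100.0 * (1.0 - level) / 2.0
    k_lo, k_hi = np.percentile(ks, [alpha, 100.0 - alpha])
    pos = ks[ks > 0]
    if pos.size:
        th = LN2 / pos
        th_lo, th_hi = np.percentile(th, [alpha, 100.0 - alpha])
    else:
        th_lo = th_hi = math.nan
    return {
        "k_ci": (float(k_lo), float(k_hi)),
        "t_half_ci": (float(th_lo), float(th_hi)),
        "n_resamples": int(ks.size),
        "level": level,
    }


def bootstrap_ci(
    observations: list[HydrolysisObservation],
    fit_options: dict | None = None,
    n_resamples: int = 1000,
    seed: int | None = None,
) -> dict:
    """Percentile bootstrap intervals for k and t_half by case resampling
    of the observations; reproducible per seed."""
    fit_options = dict(fit_options or {})
    fix_amplitude = bool(fit_options.get("fix_amplitude", True))
    amplitude = fit_options.get("amplitude")
    if amplitude is None and fix_amplitude:
        amplitude = observations[0].h + observations[0].residual_p1p
    return _bootstrap(
        [o.time for o in observations],
        [o.residual_p1p for o in observations],
        amplitude=amplitude,
        fix_amplitude=fix_amplitude,
        n_resamples=n_resamples,
        seed=seed,
        level=float(fit_options.get("level", 0.95)),
    )


def ph_rate_profile(fits: dict[float, DecayFit]) -> PhRateProfile:
    """Ordinary least-squares line through (pH, log10 k).

    The hydrolysis rate constant of ribose-1-phosphate decreases
    exponentially with pH well into the alkaline region, so the slope is
    expected to be negative for this system.
    """
    if len(fits) < 2:
        raise InvalidInputError("need >= 2 pH points")
    phs = np.array(sorted(fits), dtype=float)
    ks = np.array([fits[p].k for p in phs])
    if np.any(ks <= 0):
        raise InvalidInputError("all rate constants must be positive")
    res = stats.linregress(phs, np.log10(ks))
    return PhRateProfile(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )
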