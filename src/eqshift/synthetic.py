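"""Seeded generators for synthetic spectra and hydrolysis experiments.

Every stage of the analysis pipeline can be exercised without laboratory
data: Gaussian-band reference spectra stand in for measured
unit-concentration spectra of the nucleoside and nucleobase, mixtures at a
known conversion emulate quenched samples, and complete time courses are
generated by composing the first-order decay of the sugar phosphate with
the closed-form equilibrium response:

    h(t)  = c1 * N0 * (1 - exp(-k t))
    c2(t) = conversion_after_hydrolysis(h(t))

so c2(0) = c1 and c2 -> c2_max as t -> infinity.  Noise is applied to the
conversions (or to the spectra), never to hydrolyzed amounts directly,
mirroring what is actually measured; the phosphate released by hydrolysis
feeds back into the substrate pool implicitly through the mass balance
P = P0 - c2*N0 + h.

The default system mirrors the uridine demonstration conditions: K = 0.15,
N0 = 2 mM nucleoside, P0 = 8 mM phosphate (4 equivalents).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kinetics
from .equilibrium import (
    ReactionSystem,
    conversion_after_hydrolysis,
    solve_equilibrium_conversion,
)
from .exceptions import InvalidInputError
from .unmixing import ReferenceSet, Spectrum, unmix

__all__ = [
    "DEFAULT_SYSTEM",
    "SyntheticSpec",
    "SimulatedExperiment",
    "make_reference_spectra",
    "simulate_mixture",
    "simulate_experiment",
    "end_to_end_recovery",
]

DEFAULT_SYSTEM = ReactionSystem(N0=2.0, P0=8.0, K=0.15)

# Default band parameters: the nucleoside band sits near 262 nm and the
# deprotonated nucleobase near 284 nm, emulating the red shift of uracil in
# the alkaline quench; heights are absorbances at unit concentration.
_DEFAULT_NUCLEOSIDE_PEAKS = ((262.0, 11.0, 1.00),)
_DEFAULT_NUCLEOBASE_PEAKS = ((284.0, 13.0, 0.90),)


def _default_grid() -> np.ndarray:
    return np.arange(250.0, 351.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for synthetic reference/mixture spectra.

    Each species is a sum of Gaussian bands (center nm, sigma nm, height
    AU) on the wavelength grid; `noise_sigma` is the additive measurement
    noise (AU) for mixtures; `min_separation` is the required distance
    between the closest band centers of the two species.
    """

    nucleoside_peaks: tuple = _DEFAULT_NUCLEOSIDE_PEAKS
    nucleobase_peaks: tuple = _DEFAULT_NUCLEOBASE_PEAKS
    wavelengths: np.ndarray = field(default_factory=_default_grid)
    noise_sigma: float = 0.005
    seed: int | None = None
    min_separation: float = 5.0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        if self.noise_sigma < 0:
            raise InvalidInputError("noise_sigma must be >= 0")
        lo, hi = wl.min(), wl.max()
        for name, peaks in (
            ("nucleoside", self.nucleoside_peaks),
            ("nucleobase", self.nucleobase_peaks),
        ):
            for center, width, height in peaks:
                if not lo <= center <= hi:
                    raise InvalidInputError(
                        f"{name} band at {center} nm lies outside the "
                        f"grid [{lo}, {hi}] nm"
                    )
                if width <= 0 or height <= 0:
                    raise InvalidInputError(
                        f"{name} band widths and heights must be positive"
                    )
        sep = min(
            abs(cn - cb)
            for cn, _, _ in self.nucleoside_peaks
            for cb, _, _ in self.nucleobase_peaks
        )
        if sep < self.min_separation:
            raise InvalidInputError(
                f"closest band centers are {sep:g} nm apart; "
                f"need >= {self.min_separation:g} nm for distinct shapes "
                "(lower min_separation to override)"
            )


def _gaussian_sum(grid: np.ndarray, peaks) -> np.ndarray:
    out = np.zeros_like(grid)
    for center, width, height in peaks:
        out += height * np.exp(-0.5 * ((grid - center) / width) ** 2)
    return out


def make_reference_spectra(spec: SyntheticSpec | None = None) -> ReferenceSet:
    """Noise-free unit-concentration reference spectra of both species."""
    spec = spec or SyntheticSpec()
    grid = spec.wavelengths
    return ReferenceSet(
        nucleoside_ref=Spectrum(
            grid, _gaussian_sum(grid, spec.nucleoside_peaks), label="nucleoside"
        ),
        nucleobase_ref=Spectrum(
            grid, _gaussian_sum(grid, spec.nucleobase_peaks), label="nucleobase"
        ),
        medium="synthetic",
    )


def simulate_mixture(
    conversion: float,
    refs: ReferenceSet,
    sigma: float = 0.0,
    seed: int | None = None,
    *,
    scale: float = 1.0,
    label: str = "",
) -> Spectrum:
    """Mixture spectrum at a known conversion with additive Gaussian noise.

    absorbance = scale * [(1-c) * ref_N + c * ref_B] + N(0, sigma).
    """
    if not 0.0 <= conversion <= 1.0:
        raise InvalidInputError(f"conversion must lie in [0, 1], got {conversion}")
    if sigma < 0:
        raise InvalidInputError("sigma must be >= 0")
    grid = refs.nucleoside_ref.wavelengths
    clean = scale * (
        (1.0 - conversion) * refs.nucleoside_ref.absorbances
        + conversion * refs.nucleobase_ref.interpolated(grid)
    )
    if sigma > 0:
        rng = np.random.default_rng(seed)
        clean = clean + rng.normal(0.0, sigma, size=grid.size)
    return Spectrum(grid, clean, label=label or f"mix_c{conversion:g}")


@dataclass(frozen=True)
class SimulatedExperiment:
    """Recipe for a complete simulated hydrolysis time course."""

    system: ReactionSystem = DEFAULT_SYSTEM
    true_k: float = math.log(2.0) / 3.9  # 1/h; half-life 3.9 h
    times: tuple = (0.0, 1.25, 2.5, 3.75, 5.0)  # hours
    pH: float | None = None
    sigma_c: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.true_k < 0:
            raise InvalidInputError("true_k must be >= 0")
        if self.sigma_c < 0:
            raise InvalidInputError("sigma_c must be >= 0")
        if any(t < 0 for t in self.times):
            raise InvalidInputError("times must be non-negative")


def simulate_experiment(sim: SimulatedExperiment) -> pd.DataFrame:
    """Simulated (time, c2) observations of one hydrolysis experiment.

    Returns a tidy frame with columns time_h, pH, c2_true, c2 (noisy);
    noise is truncated so c2 stays strictly inside (0, 1).
    """
    c1 = solve_equilibrium_conversion(sim.system)
    amplitude = c1 * sim.system.N0
    rows = []
    rng = np.random.default_rng(sim.seed)
    eps = 1e-9
    for t in sim.times:
        h = amplitude * (1.0 - math.exp(-sim.true_k * t))
        c2 = conversion_after_hydrolysis(h, sim.system)
        c2_noisy = c2
        if sim.sigma_c > 0:
            c2_noisy = float(
                np.clip(c2 + rng.normal(0.0, sim.sigma_c), eps, 1.0 - eps)
            )
        rows.append(
            {"time_h": float(t), "pH": sim.pH, "c2_true": c2, "c2": c2_noisy}
        )
    return pd.DataFrame(rows)


def _clamp_tol_for_noise(system: ReactionSystem, sigma_c: float) -> float | None:
    """Map conversion noise to an h-space clamping tolerance.

    The sensitivity dh/dc2 near the unshifted equilibrium is of order
    N0 * a few; 6 standard deviations of propagated noise keeps honest
    measurements from being rejected while still catching gross
    inconsistencies.  None (package default) when noise-free.
    """
    if sigma_c <= 0:
        return None
    c1 = solve_equilibrium_conversion(system)
    dc = 1e-5
    from .equilibrium import hydrolyzed_amount as _h

    slope = (
        _h(c1 + dc, system, clamp_tol=system.N0) - 0.0
    ) / dc  # h(c1) = 0 by construction
    return 6.0 * sigma_c * max(slope, 1.0)


def end_to_end_recovery(
    n_replicates: int,
    true_params: SimulatedExperiment | None = None,
    seed: int | None = None,
    *,
    via_spectra: bool = False,
    spectra_sigma: float = 0.005,
    refs: ReferenceSet | None = None,
) -> dict:
    """Simulate -> (optionally spectra -> unmix) -> infer hydrolyzed
    amounts -> fit the decay, over seeded replicates; report recovery of
    k and t_half.

    Returns a dict with per-replicate estimates and bias/RMSE/median
    summaries for both parameters.
    """
    if n_replicates < 1:
        raise InvalidInputError("n_replicates must be >= 1")
    base = true_params or SimulatedExperiment()
    if via_spectra and refs is None:
        refs = make_reference_spectra()

    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n_replicates)
    clamp_tol = _clamp_tol_for_noise(base.system, base.sigma_c)
    if via_spectra and clamp_tol is None:
        # spectral noise propagates into the conversions too
        clamp_tol = _clamp_tol_for_noise(base.system, max(spectra_sigma, 1e-4))

    k_hats: list[float] = []
    for i in range(n_replicates):
        sim = SimulatedExperiment(
            system=base.system,
            true_k=base.true_k,
            times=base.times,
            pH=base.pH,
            sigma_c=base.sigma_c,
            seed=int(child_seeds[2 * i]),
        )
        try:
            df = simulate_experiment(sim)
            conversions = df["c2"].to_numpy()
            if via_spectra:
                rng = np.random.default_rng(int(child_seeds[2 * i + 1]))
                measured = []
                for c2 in conversions:
                    spectrum = simulate_mixture(
                        float(c2), refs, sigma=spectra_sigma,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                    measured.append(unmix(spectrum, refs).conversion)
                conversions = np.asarray(measured)
            obs = kinetics.build_observations(
                df["time_h"].to_numpy(), conversions, base.system,
                pH=base.pH, clamp_tol=clamp_tol,
            )
            fit = kinetics.fit_first_order(obs, fix_amplitude=True)
        except Exception as exc:
            raise type(exc)(f"replicate {i}: {exc}") from exc
        k_hats.append(fit.k)

    k_hats_arr = np.asarray(k_hats)
    true_k = base.true_k
    true_th = math.log(2.0) / true_k if true_k > 0 else math.inf
    th_hats = np.where(k_hats_arr > 0, math.log(2.0) / k_hats_arr, np.nan)
    return {
        "k_true": true_k,
        "t_half_true": true_th,
        "k_estimates": k_hats_arr,
        "t_half_estimates": th_hats,
        "k_bias": float(np.mean(k_hats_arr) - true_k),
        "k_rmse": float(np.sqrt(np.mean((k_hats_arr - true_k) ** 2))),
        "k_median": float(np.median(k_hats_arr)),
        "t_half_median": float(np.nanmedian(th_hats)),
        "n_replicates": n_replicates,
    }
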