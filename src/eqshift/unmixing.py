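"""Conversion from UV absorption spectra by linear spectral unmixing.

A quenched phosphorolysis sample contains only two UV-active species, the
nucleoside and the nucleobase, so its absorption spectrum (250-350 nm) is a
non-negative linear combination of the two unit-concentration reference
spectra (Beer-Lambert additivity).  Solving the least-squares problem

    A(lambda) ~ w_N * ref_N(lambda) + w_B * ref_B(lambda) [+ baseline]

with non-negative component weights and converting to mole fractions gives
the degree of conversion c = w_B / (w_N + w_B), since the stoichiometry
B + N = N0 makes mole fractions the natural readout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from .exceptions import (
    ConditioningError,
    FormatError,
    UndefinedConversionError,
)

__all__ = [
    "Spectrum",
    "ReferenceSet",
    "UnmixResult",
    "read_spectra",
    "read_reference_set",
    "unmix",
    "conversions_from_files",
]

WAVELENGTH_COLUMN = "wavelength_nm"

# defaults; all overridable per call or via the `config` dict
DEFAULT_RESIDUAL_THRESHOLD = 0.01  # AU
DEFAULT_CONDITION_CAP = 1e4


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-indexed absorbance trace (AU vs nm)."""

    wavelengths: np.ndarray
    absorbances: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbances, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbances", ab)
        if wl.ndim != 1 or ab.ndim != 1 or wl.size != ab.size:
            raise FormatError(
                f"spectrum {self.label!r}: wavelengths and absorbances must "
                "be 1-D arrays of equal length"
            )
        if wl.size < 2:
            raise FormatError(f"spectrum {self.label!r}: needs >= 2 points")
        if not np.all(np.diff(wl) > 0):
            raise FormatError(
                f"spectrum {self.label!r}: wavelengths must be strictly "
                "ascending"
            )
        if not np.all(np.isfinite(ab)) or not np.all(np.isfinite(wl)):
            raise FormatError(
                f"spectrum {self.label!r}: non-finite values present"
            )

    def interpolated(self, grid: np.ndarray) -> np.ndarray:
        """Absorbances linearly interpolated onto `grid`; extrapolation is
        forbidden (the band shape outside the recorded range is unknown)."""
        grid = np.asarray(grid, dtype=float)
        if grid.min() < self.wavelengths[0] or grid.max() > self.wavelengths[-1]:
            raise FormatError(
                f"spectrum {self.label!r}: requested grid "
                f"[{grid.min()}, {grid.max()}] nm extends beyond the "
                f"recorded range [{self.wavelengths[0]}, "
                f"{self.wavelengths[-1]}] nm"
            )
        return np.interp(grid, self.wavelengths, self.absorbances)


@dataclass(frozen=True)
class ReferenceSet:
    """Unit-concentration reference spectra of the nucleoside and the
    nucleobase, recorded in the same medium as the samples (e.g. the
    alkaline quench)."""

    nucleoside_ref: Spectrum
    nucleobase_ref: Spectrum
    medium: str = ""

    def design_matrix(self, grid: np.ndarray) -> np.ndarray:
        """n x 2 matrix [ref_N, ref_B] on the sample grid."""
        return np.column_stack(
            [
                self.nucleoside_ref.interpolated(grid),
                self.nucleobase_ref.interpolated(grid),
            ]
        )

    def condition_number(self, grid: np.ndarray | None = None) -> float:
        if grid is None:
            grid = self.nucleoside_ref.wavelengths
        return float(np.linalg.cond(self.design_matrix(grid)))


@dataclass(frozen=True)
class UnmixResult:
    """Outcome of unmixing one sample spectrum."""

    fraction_nucleoside: float
    fraction_nucleobase: float
    conversion: float
    residual_rms: float
    flag: bool = False
    baseline: float = 0.0
    label: str = ""


def read_spectra(path) -> list[Spectrum]:
    """Read sample spectra from a CSV with a `wavelength_nm` column and one
    absorbance column per sample; returns one Spectrum per sample column."""
    df = pd.read_csv(path)
    if df.empty or df.shape[1] < 2:
        raise FormatError(
            f"{path}: expected a '{WAVELENGTH_COLUMN}' column plus at least "
            "one absorbance column"
        )
    cols = list(df.columns)
    if cols.count(WAVELENGTH_COLUMN) != 1:
        raise FormatError(
            f"{path}: exactly one '{WAVELENGTH_COLUMN}' column required, "
            f"found {cols.count(WAVELENGTH_COLUMN)}"
        )
    for col in cols:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(np.argmax((bad | df[col].isna()).to_numpy()))
            raise FormatError(
                f"{path}: non-numeric or missing value in column {col!r}, "
                f"data row {row}"
            )
    wl = df[WAVELENGTH_COLUMN].to_numpy(dtype=float)
    return [
        Spectrum(wavelengths=wl, absorbances=df[col].to_numpy(dtype=float), label=str(col))
        for col in cols
        if col != WAVELENGTH_COLUMN
    ]


def read_reference_set(path, medium: str = "") -> ReferenceSet:
    """Read a reference CSV with columns wavelength_nm, nucleoside,
    nucleobase (unit-concentration normalized)."""
    spectra = {s.label: s for s in read_spectra(path)}
    missing = {"nucleoside", "nucleobase"} - spectra.keys()
    if missing:
        raise FormatError(
            f"{path}: reference CSV lacks column(s) {sorted(missing)}"
        )
    return ReferenceSet(
        nucleoside_ref=spectra["nucleoside"],
        nucleobase_ref=spectra["nucleobase"],
        medium=medium,
    )


def unmix(
    spectrum: Spectrum,
    refs: ReferenceSet,
    baseline: bool = True,
    *,
    nonneg: bool = True,
    residual_threshold: float = DEFAULT_RESIDUAL_THRESHOLD,
    condition_cap: float = DEFAULT_CONDITION_CAP,
) -> UnmixResult:
    """Estimate the degree of conversion of one sample spectrum.

    Solves the (optionally baseline-augmented) least-squares problem for
    the two component weights; weights are constrained non-negative by
    default (they are concentrations), while the baseline offset is always
    unconstrained.  The conversion is the nucleobase mole fraction
    w_B / (w_N + w_B).

    Raises ``ConditioningError`` when the two references are too collinear
    (condition number above `condition_cap`) and
    ``UndefinedConversionError`` for a blank spectrum (both weights ~ 0).
    """
    grid = spectrum.wavelengths
    design2 = refs.design_matrix(grid)
    cond = float(np.linalg.cond(design2))
    if not np.isfinite(cond) or cond > condition_cap:
        raise ConditioningError(
            f"reference spectra are ill-conditioned (condition number "
            f"{cond:.3g} > cap {condition_cap:.3g}); use references with "
            "distinct band shapes"
        )
    if baseline:
        design = np.column_stack([design2, np.ones(grid.size)])
        lo = np.array([0.0, 0.0, -np.inf])
    else:
        design = design2
        lo = np.zeros(2)

    y = spectrum.absorbances
    # unconstrained solution first: when the weights already satisfy the
    # bounds it is the constrained optimum too, and it is exact (the
    # iterative bounded solver is not)
    coefs, *_ = np.linalg.lstsq(design, y, rcond=None)
    if nonneg and np.any(coefs[:2] < 0.0):
        sol = lsq_linear(
            design, y, bounds=(lo, np.full(lo.shape, np.inf)), method="bvls"
        )
        coefs = sol.x

    w_n, w_b = float(coefs[0]), float(coefs[1])
    offset = float(coefs[2]) if baseline else 0.0
    resid = y - design @ coefs
    residual_rms = float(np.sqrt(np.mean(resid**2)))

    scale = max(float(np.max(np.abs(design2))), 1e-300)
    total = w_n + w_b
    if total * scale <= 1e-9 * max(1.0, float(np.max(np.abs(y)))):
        raise UndefinedConversionError(
            f"spectrum {spectrum.label!r}: both component weights are ~0 "
            "(blank or pure-baseline spectrum); conversion undefined"
        )
    conversion = min(max(w_b / total, 0.0), 1.0)
    return UnmixResult(
        fraction_nucleoside=w_n,
        fraction_nucleobase=w_b,
        conversion=conversion,
        residual_rms=residual_rms,
        flag=residual_rms > residual_threshold,
        baseline=offset,
        label=spectrum.label,
    )


def conversions_from_files(
    sample_path,
    ref_path,
    config: dict | None = None,
) -> pd.DataFrame:
    """Unmix every sample spectrum in `sample_path` against the references
    in `ref_path`; returns a tidy table (label, conversion, residual_rms,
    flag).

    `config` keys: ``baseline`` (bool, default True), ``nonneg`` (bool,
    default True), ``residual_threshold`` (AU, default 0.01).
    """
    config = dict(config or {})
    samples = read_spectra(sample_path)
    refs = read_reference_set(ref_path)
    rows = []
    for spec in samples:
        try:
            res = unmix(
                spec,
                refs,
                baseline=bool(config.get("baseline", True)),
                nonneg=bool(config.get("nonneg", True)),
                residual_threshold=float(
                    config.get("residual_threshold", DEFAULT_RESIDUAL_THRESHOLD)
                ),
            )
        except Exception as exc:
            raise type(exc)(f"sample {spec.label!r}: {exc}") from exc
        rows.append(
            {
                "label": res.label,
                "conversion": res.conversion,
                "residual_rms": res.residual_rms,
                "flag": res.flag,
            }
        )
    return pd.DataFrame(rows, columns=["label", "conversion", "residual_rms", "flag"])
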