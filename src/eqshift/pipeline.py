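"""End-to-end quantification: measured conversions -> hydrolysis kinetics.

`HydrolysisExperiment` is the modelling object tying the stages together:
it holds the reaction system and the measured (time, pH, c2) table, and its
``fit()`` infers the hydrolyzed amount at every time point from the
closed-form mass-action solution and fits the first-order decay of the
residual sugar phosphate per pH group, returning a results object with the
rate constants, half-lives, bootstrap intervals and a tidy export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import kinetics
from .equilibrium import (
    ReactionSystem,
    estimate_K_from_equilibrium,
    solve_equilibrium_conversion,
)
from .exceptions import EqshiftError, InvalidInputError
from .kinetics import DecayFit

__all__ = ["HydrolysisExperiment", "HydrolysisExperimentResults"]


class HydrolysisExperiment:
    """Sugar-phosphate hydrolysis experiment quantified via equilibrium
    shifts of nucleoside phosphorolysis.

    Parameters
    ----------
    data : frame with columns ``time_h`` and ``c2`` (conversion as a
        fraction) or ``c2_%`` (percent); an optional ``pH`` column splits
        the fits into one per pH.
    system : the reaction system.  Alternatively pass ``N0``, ``P0`` and
        either ``K`` or a measured first-equilibrium conversion ``c1``
        (from which K is estimated) — exactly one of the two.
    clamp_tol : tolerance (mM) for measurements implying slightly negative
        hydrolysis; see :func:`eqshift.kinetics.build_observations`.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        system: ReactionSystem | None = None,
        *,
        N0: float | None = None,
        P0: float | None = None,
        K: float | None = None,
        c1: float | None = None,
        clamp_tol: float | None = None,
    ) -> None:
        if system is None:
            if N0 is None or P0 is None:
                raise InvalidInputError("provide a ReactionSystem or N0 and P0")
            if (K is None) == (c1 is None):
                raise InvalidInputError(
                    "exactly one of K or a measured c1 must be given"
                )
            if K is None:
                K = estimate_K_from_equilibrium(c1, N0, P0)
            system = ReactionSystem(N0=N0, P0=P0, K=K)
        elif any(v is not None for v in (N0, P0, K, c1)):
            raise InvalidInputError(
                "give either a ReactionSystem or scalar parameters, not both"
            )
        self.system = system
        self.clamp_tol = clamp_tol
        self.data = self._validate_table(data)
        self.c1 = solve_equilibrium_conversion(system)
        self.amplitude = self.c1 * system.N0

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "HydrolysisExperiment":
        return cls(data, **kwargs)

    @staticmethod
    def _validate_table(data: pd.DataFrame) -> pd.DataFrame:
        df = data.copy()
        if "time_h" not in df.columns:
            raise InvalidInputError("data needs a 'time_h' column")
        has_frac = "c2" in df.columns
        has_pct = "c2_%" in df.columns
        if has_frac == has_pct:
            raise InvalidInputError(
                "data needs exactly one of 'c2' (fraction) or 'c2_%' (percent)"
            )
        if has_pct:
            df["c2"] = df["c2_%"].astype(float) / 100.0
        if "pH" not in df.columns:
            df["pH"] = np.nan
        df = df[["time_h", "pH", "c2"]].astype(float)
        if df[["time_h", "c2"]].isna().any().any():
            raise InvalidInputError("time_h and c2 must be numeric and complete")
        if ((df["c2"] <= 0) | (df["c2"] >= 1)).any():
            raise InvalidInputError("conversions must lie strictly in (0, 1)")
        return df

    def fit(
        self,
        fix_amplitude: bool = True,
        *,
        bootstrap: int = 0,
        seed: int | None = None,
    ) -> "HydrolysisExperimentResults":
        """Infer hydrolyzed amounts and fit the decay per pH group.

        Every row is validated and converted before any fit runs; errors
        are collected per row and reported together (no partial output).
        """
        rows = []
        errors = []
        for _, row in self.data.iterrows():
            try:
                obs = kinetics.build_observations(
                    [row["time_h"]],
                    [row["c2"]],
                    self.system,
                    pH=None if np.isnan(row["pH"]) else float(row["pH"]),
                    clamp_tol=self.clamp_tol,
                )[0]
                rows.append(obs)
            except EqshiftError as exc:
                errors.append(
                    f"t = {row['time_h']} h, pH = {row['pH']}: {exc}"
                )
        if errors:
            raise InvalidInputError(
                "some observations are inconsistent with the reaction "
                "system:\n  " + "\n  ".join(errors)
            )

        obs_table = pd.DataFrame(
            {
                "time_h": [o.time for o in rows],
                "pH": [np.nan if o.pH is None else o.pH for o in rows],
                "c2": [o.c2 for o in rows],
                "h_mM": [o.h for o in rows],
                "residual_p1p_mM": [o.residual_p1p for o in rows],
            }
        )

        fits: dict[float, DecayFit] = {}
        cis: dict[float, dict] = {}
        for ph, group in obs_table.groupby("pH", dropna=False):
            group_obs = [
                rows[i] for i in group.index
            ]
            fit = kinetics.fit_first_order(
                group_obs, fix_amplitude=fix_amplitude,
                amplitude=self.amplitude if fix_amplitude else None,
            )
            key = float(ph) if not pd.isna(ph) else float("nan")
            fits[key] = fit
            if bootstrap and len(group_obs) >= 4:
                cis[key] = kinetics.bootstrap_ci(
                    group_obs,
                    {"fix_amplitude": fix_amplitude, "amplitude": self.amplitude},
                    n_resamples=bootstrap,
                    seed=seed,
                )
        return HydrolysisExperimentResults(
            model=self, observations=obs_table, fits=fits, cis=cis
        )


@dataclass
class HydrolysisExperimentResults:
    """Per-pH decay fits plus the per-observation hydrolysis table."""

    model: HydrolysisExperiment
    observations: pd.DataFrame
    fits: dict[float, DecayFit]
    cis: dict[float, dict]

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-pH results: pH,k_per_h,t_half_h,rms,ci_lo,ci_hi."""
        rows = []
        for ph, fit in sorted(
            self.fits.items(), key=lambda kv: (np.isnan(kv[0]), kv[0])
        ):
            ci = self.cis.get(ph, {})
            lo, hi = ci.get("k_ci", (np.nan, np.nan))
            rows.append(
                {
                    "pH": ph,
                    "k_per_h": fit.k,
                    "t_half_h": fit.t_half,
                    "rms": fit.rms,
                    "ci_lo": lo,
                    "ci_hi": hi,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        sys_ = self.model.system
        lines = [
            "Hydrolysis quantified by phosphorolysis equilibrium shift",
            "=" * 58,
            f"system: N0 = {sys_.N0:g} mM, P0 = {sys_.P0:g} mM, "
            f"K = {sys_.K:.4g} ({sys_.ratio:g} phosphate equivalents)",
            f"first equilibrium: c1 = {self.model.c1:.4f} "
            f"({self.model.amplitude:.4f} mM sugar phosphate generated)",
            f"observations: {len(self.observations)}",
            "",
            f"{'pH':>6} {'k (1/h)':>10} {'t1/2 (h)':>10} {'rms (mM)':>10}",
        ]
        for ph, fit in sorted(
            self.fits.items(), key=lambda kv: (np.isnan(kv[0]), kv[0])
        ):
            label = "--" if np.isnan(ph) else f"{ph:g}"
            lines.append(
                f"{label:>6} {fit.k:>10.4f} {fit.t_half:>10.3f} "
                f"{fit.rms:>10.4g}"
            )
        for ph, fit in self.fits.items():
            if fit.warning:
                lines.append(f"WARNING (pH {ph}): {fit.warning}")
        return "\n".join(lines)
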