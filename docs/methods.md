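# Methods

## Model

Nucleoside phosphorolysis, `N + P <=> B + P1P`, with dimensionless
equilibrium constant `K = [P1P][B]/([N][P])`. All initial product
concentrations are zero, so stoichiometry reduces every state to one degree
of freedom, the conversion `c = [B]/N0`. Two regimes share one set of mass
balances parameterized by the cumulative hydrolyzed sugar phosphate `h`
(mM):

```
B = c·N0,   N = N0 − B,   P1P = B − h,   P = P0 − B + h
```

(`h = 0` before hydrolysis). Inserting these into the mass-action law gives
a single quadratic in `c`,

```
N0(1−K)·c² + [K(N0+P0) + h(K−1)]·c − K(P0+h) = 0,
```

whose admissible root is the equilibrium conversion at hydrolyzed amount
`h`; solved instead for `h` at measured conversion `c2` it yields the
closed-form quantification formula

```
h = [c2²N0 − K(1−c2)(P0 − c2·N0)] / [c2 + K(1−c2)].
```

The ceiling `c2,max` follows by setting `h = c1·N0` (full hydrolysis of the
initially generated pool) and `Δc_max = c2,max − c1` is the method's
measurable headroom. Ribose liberated by hydrolysis does not participate in
the equilibrium and is ignored; the released phosphate feeds back through
the `P` balance.

**Assumptions.** Both equilibria are fully attained (enzyme kinetics are
not modeled); `K` is constant across the incubation series (no
activity/ionic-strength or temperature corrections); hydrolysis only acts
on the sugar phosphate generated in the first equilibrium, so
`0 ≤ h ≤ c1·N0`; the quench leaves exactly two UV-active species.

**Root selection.** Both quadratics can have two real roots. The admissible
one is selected by membership in the physical interval (all four
concentrations non-negative, `0 ≤ c < 1`) with a uniqueness assertion —
not by a hard-coded sign branch, which fails for `K > 1`. `K = 1`
degenerates the quadratic to a linear equation and is solved analytically.
A numerically stable quadratic formula (`q = −(b + sign(b)·√disc)/2`)
avoids cancellation at small `K`.

## Kinetics

Residual sugar phosphate `r(t) = A·e^{−kt}` is fitted by nonlinear least
squares (`scipy.optimize.curve_fit`), not log-linear regression, because
late time points approach zero and a log transform would bias them. `A` is
fixed to `c1·N0` by default — the experiments anchor the first equilibrium,
so the initial amount is known — with a free-amplitude variant as an
option (then ≥3 distinct times are required). Uncertainty is a
case-resampling percentile bootstrap (default 95 %, ≥100 resamples,
refused below 4 observations); asymptotic covariances are not trusted at
n = 4–6. `t½·k = ln 2` holds exactly by construction; non-positive fitted
`k` is reported with a warning flag and an undefined half-life rather than
raised. An optional pH–rate profile fits an ordinary least-squares line to
`(pH, log10 k)`; its slope is expected to be negative for
ribose-1-phosphate, whose decay slows with increasing pH.

## Spectral unmixing

A sample spectrum is modeled as `w_N·ref_N + w_B·ref_B + b` with
unit-concentration references, non-negative component weights (they are
concentrations) and an unconstrained constant baseline `b` (cuvette/plate
offsets; on by default, and plain unconstrained least squares is available
for diagnostics). The solver takes the exact unconstrained solution when
it already satisfies the bounds and falls back to an active-set bounded
solver (`scipy.optimize.lsq_linear`, BVLS) otherwise, so noise-free
mixtures are recovered to machine precision. Conversion is the mole
fraction `w_B/(w_N + w_B)`, which the stoichiometry `B + N = N0` makes the
correct readout; it is scale-invariant in the overall intensity. Reference
grids are linearly interpolated onto the sample grid; extrapolation is an
error. A condition-number cap (default 10⁴ on the two-column design
matrix) rejects near-identical references, and a residual-RMS threshold
(default 0.01 AU) flags poor fits.

## Design window

`window.scan` evaluates `c1`, `c2,max` and `Δc_max` over a `(K, ratio)`
grid — defaults: 31 log-spaced `K` in [0.01, 1] and 100 ratios in
[0.5, 20], covering the operational range of natural nucleosides. The
result depends only on `P0/N0` (asserted: identical maps for
`N0 ∈ {0.1, 1, 10}` mM). `Δc_max(ratio)` is unimodal — tiny ratios
generate almost no sugar phosphate, large ratios push `c1 > 0.8` and leave
no headroom — which `recommend_equivalents` asserts on a dense grid before
bracketing the two crossings of a target shift with Brent's method.

## Synthetic data

The generators emulate the demonstration conditions: `K = 0.15`,
`N0 = 2 mM`, `P0 = 8 mM` (4 phosphate equivalents). Reference spectra are
sums of Gaussian bands on a 250–350 nm, 1 nm grid — nucleoside band at
262 nm (σ 11 nm, 1.0 AU), nucleobase at 284 nm (σ 13 nm, 0.9 AU),
emulating the alkaline red shift of the free base; band centers must be
≥5 nm apart by default. Mixture noise defaults to 0.005 AU and conversion
noise to σ_c = 0.01, both plausible for plate-reader UV data. Time courses
compose the first-order decay with the exact equilibrium response,
`c2(t) = conversion_after_hydrolysis(c1·N0·(1−e^{−kt}))`, so
`c2(0) = c1` and `c2(∞) = c2,max`; noise is added to conversions (or
spectra) — what is actually measured — never to hydrolyzed amounts, so
error propagation through the quantification formula is faithful. All
generators are deterministic per seed and the seed changes only the noise.

What the generators do **not** emulate: slow approach to equilibrium,
enzyme inactivation, pH drift during incubation, spectral shape changes
with pH or temperature, correlated (non-Gaussian) instrument noise, and
pipetting/dilution errors. Passing recovery tests therefore demonstrate
that the *algebra and fitting* are correct and well-conditioned under
realistic noise — not that any particular laboratory data set meets the
model's assumptions.

## Numerical and design choices

- **Units.** Concentrations in mM, conversions as fractions internally;
  percent appears only at I/O boundaries with `%`-suffixed column names.
- **Tolerances.** Interval-membership root checks at 1e-11 relative;
  round-trip/bijection guarantees at 1e-9; bisection-oracle agreement at
  1e-8 (test-side).
- **Clamping near zero shift.** Measurement noise can put `c2` slightly
  below `c1`, implying small negative `h`. `hydrolyzed_amount` clamps
  `h ∈ [−ε, 0)` to 0 and raises below `−ε` (default `ε = 1e-3·N0`, strict,
  for single measurements). Pipelines that ingest noisy series pass a
  noise-aware `clamp_tol` — around 6 standard deviations of the propagated
  conversion noise (`dh/dc2 ≈ 5.5 mM` per conversion unit near `c1` for
  the default system) — and clip `h` into `[0, c1·N0]`; the clipped points
  carry negligible weight in the fit because the decay's sensitivity to
  `k` vanishes at `t = 0`.
- **Degenerate inputs.** Constant residual series raise a degenerate-fit
  error (k unidentifiable); blank spectra raise an undefined-conversion
  error; `c1 = 0` makes `K` unidentifiable (returned as 0 with a warning).
- **Problem sizes.** Property and recovery tests use 200 replicates of
  5-point series, 100-seed unmixing ensembles, 23×23–31×100 scan grids and
  1000-draw bijection checks; these sizes put Monte-Carlo error well below
  the asserted tolerances while the full suite runs in seconds.
- **Fit accuracy limit.** With 5 points over 5 h, the observable decay at
  the slow end of the practical regime (t½ ≈ 11.7 h) is only ~0.26 mM, so
  the attainable relative accuracy of `k` degrades quickly with noise; the
  recovery guarantees are stated at σ_c = 0.01 (median within 10 %) and at
  0.01 mM residual noise (95 % within 10 %).

## Limitations

Two-component unmixing only (no third chromophore); no Arrhenius/Eyring
temperature extrapolation of `K` or `k`; no activity-coefficient
corrections; the simultaneous `(K, h)` determination from both equilibria
propagates the full measurement error of `c1` into `h` and is therefore
noisier than using an independently known `K`.
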