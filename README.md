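# eqshift

Quantifying the hydrolytic decay of pentose-1-phosphates from **apparent
equilibrium shifts of nucleoside phosphorolysis** — closed-form mass-action
algebra, UV spectral unmixing, first-order decay kinetics, and the method's
experimental design window.

## The problem

Nucleoside phosphorylases reversibly cleave a nucleoside (N) with inorganic
phosphate (P) into a nucleobase (B) and a pentose-1-phosphate (P1P):

```
N + P  <=>  B + P1P,      K = [P1P][B] / ([N][P])
```

Sugar phosphates such as ribose-1-phosphate are hard to quantify directly,
and their hydrolytic stability matters for any biocatalytic cascade that
routes through them. But the phosphorolysis equilibrium itself can serve as
the probe: if some of the sugar phosphate hydrolyzes (returning its
phosphate to the pool), the reaction compensates by consuming more
nucleoside (Le Chatelier), and the conversion shifts from its first
equilibrium value c1 to a higher apparent value c2. Because the system has
a single degree of freedom, the measured shift determines the hydrolyzed
amount *in closed form*:

```
h = [c2²·N0 − K(1−c2)(P0 − c2·N0)] / [c2 + K(1−c2)]        (mM)
```

where N0 and P0 are the initial nucleoside and phosphate concentrations.
Repeating the measurement after different incubation times under
hydrolyzing conditions and fitting the residual sugar phosphate
`A·exp(−k·t)` (A = c1·N0) yields the first-order rate constant and
half-life t½ = ln 2 / k. Both UV-active species (nucleoside, nucleobase)
are read out together by least-squares unmixing of the 250–350 nm
absorption spectrum against unit-concentration reference spectra.

The package's audience: enzyme-cascade and biocatalysis groups who run
phosphorolysis/transglycosylation reactions and need sugar-phosphate decay
rates without isolating the sugar phosphate.

## Worked example

Simulate a hydrolysis time course at pH 8 for the demonstration system
(2 mM uridine, 8 mM phosphate, K = 0.15, true t½ = 3.9 h, conversion noise
0.005) and quantify it:

```python
import math
import pandas as pd
from eqshift import HydrolysisExperiment, ReactionSystem
from eqshift.synthetic import SimulatedExperiment, simulate_experiment

sim = SimulatedExperiment(
    true_k=math.log(2) / 3.9, times=(0, 1.5, 2.5, 3.5, 5.0),
    pH=8.0, sigma_c=0.005, seed=42,
)
data = simulate_experiment(sim)[["time_h", "pH", "c2"]]

model = HydrolysisExperiment(data, ReactionSystem(N0=2.0, P0=8.0, K=0.15),
                             clamp_tol=0.3)
results = model.fit(bootstrap=1000, seed=1)
print(results.summary())
```

```
Hydrolysis quantified by phosphorolysis equilibrium shift
==========================================================
system: N0 = 2 mM, P0 = 8 mM, K = 0.15 (4 phosphate equivalents)
first equilibrium: c1 = 0.5078 (1.0156 mM sugar phosphate generated)
observations: 5

    pH    k (1/h)   t1/2 (h)   rms (mM)
     8     0.1734      3.998    0.02612
```

The first equilibrium sits at 50.8 % conversion, so 1.016 mM sugar
phosphate was generated; the conversions measured after incubation
(50.9 % → 61.7 %) translate into hydrolyzed amounts of 0.008 → 0.553 mM,
and the decay fit recovers a half-life of 4.0 h (truth: 3.9 h; bootstrap
95 % CI for k: 0.157–0.189 h⁻¹, from `results.to_frame()`). As hydrolysis
runs to completion the conversion approaches — but never exceeds — the
ceiling c2,max ≈ 72 % corresponding to full loss of the generated 1 mM.

The same pipeline runs from the shell:

```bash
eqshift simulate --t-half 3.9 --ph 8 --sigma-c 0.005 --seed 42 --out course.csv
eqshift quantify --data course.csv --n0 2 --p0 8 --k 0.15 \
                 --clamp-tol 0.3 --out fits.csv
eqshift window --k 0.15 --out window.csv     # design-space scan
eqshift unmix --samples spectra.csv --refs refs.csv --out conversions.csv
```

`eqshift window` maps the design space: at K = 0.15 any phosphate excess of
2.5–10 equivalents keeps the maximum apparent shift above 20 percentage
points, with the optimum at 4–6 equivalents.

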