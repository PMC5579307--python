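# azeoblend

Analysis toolkit for **double pseudo-azeotropy in binary repellent
blends**, built around the IR3535 (ethyl butylacetylaminopropionate) /
nonanoic acid system at 50&nbsp;°C.

Topical mosquito repellents evaporate from the skin at a rate that is,
for fixed convection, proportional to the liquid's vapour pressure. A
blend whose components attract each other strongly enough can form a
*negative pseudo-azeotrope*: a composition with the lowest vapour
pressure of any mixture — lower than either pure compound — that
evaporates *without changing composition*. Such a blend releases
repellent slowly and steadily, extending protection time. The IR3535 /
nonanoic acid pair is remarkable in showing **two** pseudo-azeotropes: an
unstable (positive) one near 10 mol% IR3535 and an attracting (negative)
one near 77 mol% IR3535.

## What the package computes

Writing `x_A`, `y_A` for the liquid and vapour mole fractions of IR3535,
`γ_i` for activity coefficients (Redlich–Kister excess Gibbs energy) and
`P_i^sat` for Antoine vapour pressures, the package implements:

* **Vapour–liquid equilibrium** under modified Raoult's law,
  `y_A P = x_A γ_A P_A^sat`, with location of all azeotropes (interior
  roots of `y(x) = x`) and their classification — a crossing with
  `dy/dx > 1` is a stable node of the open-evaporation dynamics
  `dx/d ln n = y − x` (attractor, bubble-pressure minimum, negative
  azeotrope); `dy/dx < 1` marks the positive azeotrope.
* **Open (Rayleigh) evaporation**: `dn_i/dt = −k x_i γ_i P_i^sat`,
  giving composition-drift trajectories, TGA-style mass-loss curves and
  aliquot-corrected gravimetric logs.
* **FTIR chemometrics**: mixing residuals
  `ΔA_mix = A_mix − [x A_A + (1−x) A_B]`, baseline-corrected band
  intensities, and inverse composition identification by **PLS1
  (NIPALS)** with leave-one-out cross-validated selection of the number
  of latent directions.
* **Azeotrope-composition estimation** from drift data via the
  stretched-exponential law `x(m) = x_az + (x_0 − x_az) e^{−k m^n}`
  (released mass fraction `m`), with `x_az` shared across trajectories
  and a residual-bootstrap percentile confidence interval.
* **Repellence statistics** for the WHO cup-on-arm assay: protection
  `P = 1 − T/C` from treated/control probing counts, decreasing-logistic
  fits `P(t) = P_max / (1 + e^{(t − t50)/s})` and closed-form protection
  durations.
* **Seeded synthetic-data generators** reproducing the whole measurement
  campaign (oven evaporation runs, mass logs, speciation-driven FTIR
  spectra with acid-dimer and acid–amide-complex bands, binomial probing
  counts), so the entire pipeline runs and tests without any download.

## Worked example

The reference equilibrium (shipped as
`azeoblend/data/ir3535_nonanoic_50C.yaml`) is calibrated so the two
azeotropes sit exactly at 10 and 77 mol% IR3535:

```console
$ azeoblend vle azeotropes
x_a_molpct  pressure_pa     sign  stability
   10.0000    12.571090 positive   repeller
   77.0000     5.186667 negative  attractor
```

The positive azeotrope exerts the highest bubble pressure (12.57 Pa,
above both pure components at 8.0 and 11.6 Pa) and repels the liquid
composition; the negative azeotrope has the lowest (5.19 Pa) and attracts
it. Running the whole pipeline on synthetic data:

```console
$ azeoblend run --out demo --seed 42
```

writes `demo/report.json` and a summary:

```text
Azeotropes (mol% IR3535, Pa, sign, stability):
   10.000   12.5711  positive  repeller
   77.000    5.1867  negative  attractor

PLS1 calibration: 2 directions (LOO mean 0.037 / max 0.088 mol%)
Azeotrope composition estimate: 77.0 mol% (95% CI 76.9, 77.2; B=500)

Protection fits:
  blend    P_max=0.990 t50=5.02 h s=0.61 h protection>0.8: 4.14 h
  IR3535   P_max=0.987 t50=3.81 h s=0.99 h protection>0.8: 2.37 h
  DEET     P_max=0.971 t50=3.11 h s=0.19 h protection>0.8: 2.82 h
```

Reading the numbers: 14 simulated oven mixtures drift toward the
attractor as they evaporate; their FTIR spectra are inverted to
compositions by the PLS1 model (two latent directions suffice at the
default noise level; leave-one-out mean error 0.04 mol%), and the shared
stretched-exponential fit recovers the attractor at 77.0 mol% with a
0.3 mol%-wide bootstrap interval. In the simulated cup-on-arm assay the
azeotropic blend keeps protection above 80% for ~4.1 h, outlasting both
single-agent references.

Other subcommands (`evaporate`, `spectra residual`, `calibrate`,
`predict`, `azeofit`, `repellence`, `genfixtures`) expose the individual
stages; see `azeoblend --help`.

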