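# Methods

This note documents the models implemented in `azeoblend`, the defaults
and units of their parameters, the design of the synthetic-data
generators, and the numerical choices that matter for reproducing the
package's outputs.

## Vapour–liquid equilibrium and azeotrope classification

A binary liquid at fixed temperature is described by modified Raoult's
law with an ideal gas phase (pressures here are a few pascal):

    P(x)  = x γ_A(x) P_A^sat + (1−x) γ_B(x) P_B^sat
    y(x)  = x γ_A(x) P_A^sat / P(x)

Pure-component vapour pressures follow an ln-form Antoine correlation
`ln P[Pa] = A − B/(T[K] + C)`, validated over a declared temperature
range. Non-ideality is an isothermal Redlich–Kister expansion

    g(x) = G_E/RT = x(1−x) Σ_k A_k (2x−1)^k ,

from which `ln γ_A = g + (1−x) g′` and `ln γ_B = g − x g′`; Gibbs–Duhem
consistency is automatic, and the test suite verifies the numerical
residual stays below 1e−6 on a 1000-point grid.

Azeotropes are interior roots of `y(x) − x`, found by a sign-change scan
on a 1001-point grid followed by bisection to 1e−10. Classification
rests on residue-curve theory: open evaporation obeys
`dx/d ln n = y − x`, so a diagonal crossing with `dy/dx > 1` is a stable
node — the composition attractor, which coincides with the
bubble-pressure *minimum* (negative azeotrope) — while `dy/dx < 1` gives
the unstable positive azeotrope at a pressure *maximum*. Both
characterisations are computed (slope by central difference with step
1e−6; extremum type from pressures at ±1e−4) and must agree; a
disagreement is only possible for a liquid that would demix and raises
an error. Crossings with `|dy/dx − 1| < 1e−4` are flagged degenerate.

### The reference fixture

No measured vapour pressures or activity data exist for the IR3535 /
nonanoic acid pair, so the shipped model is a phenomenological stand-in
constructed to reproduce the system's *signature*: exactly two
azeotropes at 10.0 and 77.0 mol% IR3535 at 323.15 K, the negative one an
attractor and the global pressure minimum. Writing
`r = ln(P_B^sat/P_A^sat)`, the azeotrope condition is `g′(x) = r`, so we
set

    g′(x) − r = (x − 0.10)(x − 0.77) · s(x),  s(x) > 0 on (0,1),

which pins the two crossings *exactly* and nowhere else. The polynomial
`s` (degree 6) was then chosen by linear programming — every constraint
is linear in its coefficients — to maximise the crossing slope at 0.77
subject to (i) `∫₀¹ g′ = 0` (so `g(0) = g(1) = 0`), (ii) the
single-liquid stability condition `1 + x(1−x) g″ ≥ 0.08` everywhere, and
(iii) bounds on `s`. The result is an order-8 Redlich–Kister
coefficient set giving `dy/dx ≈ 5.1` at the attractor. The steep
crossing matters: with a shallow attractor the simulated drift curves
never visibly saturate within the released-mass range a real oven run
can sample, and the drift regression inherits a ~1 mol% extrapolation
bias; with the steep crossing trajectories reach the attractor to
<0.01 mol% well before exhaustion.

Antoine constants are pinned so that at 323.15 K the acid is the more
volatile (11.6 vs 8.0 Pa). The ratio 1.45 exceeds the molar-mass ratio
215.29/158.24 ≈ 1.36, so the neat acid also loses *mass* faster in a
TGA-style comparison — the ordering the gravimetric module's tests
check. Substantially larger ratios are incompatible with Gibbs
stability in polynomial excess-Gibbs families of moderate order.

## Open evaporation

Convection-swept evaporation removes the equilibrium vapour
continuously; each component leaves with molar flux proportional to its
partial pressure with a single mass-transfer coefficient `k`
(mol Pa⁻¹ h⁻¹, default 2e−5 in the generators — sized so a 13.5 mL dish
evaporates over a few weeks):

    dn_i/dt = −k x_i γ_i P_i^sat .

The ODE is integrated with an adaptive stiff-capable method (LSODA,
relative tolerance 1e−8, absolute tolerance 1e−15·n₀); composition is
always recomputed from the mole amounts, never integrated directly. A
run terminates at `t_end` or when total moles fall below 1e−9·n₀ (the
mole floor avoids 0/0 at exhaustion). For an ideal binary the
trajectories satisfy the closed-form Rayleigh relation
`ln(n_A/n_A0) = α ln(n_B/n_B0)` to better than 1e−6, which the test
suite checks across random volatility ratios.

Sampling-loss correction of gravimetric logs assumes the aliquot
recorded at a time is withdrawn *after* the balance reading, so
`evap_loss(t_i) = m(0) − gross(t_i) − Σ_{j<i} aliquot_j`; negative or
decreasing corrected losses indicate inconsistent records and raise an
error.

## FTIR statistics and inverse calibration

Spectra live on a uniform ascending grid within 600–4000 cm⁻¹ (default
resolution 2 cm⁻¹). The mixing residual is defined verbatim as
`ΔA_mix = A_mix − [x A_A + (1−x) A_B]` with no resampling — grids must
match exactly. Band intensity is the baseline-corrected *peak height*
inside an explicit window, the baseline being the straight line through
the window's edge points (integrated area is available as an option);
the measure is exactly invariant to adding any straight line. Relative
absorbance is intensity divided by the mole fraction of the absorbing
species — constant under Beer–Lambert behaviour, so deviations track
speciation.

Composition is inverted from spectra by PLS1 (NIPALS) on mean-centred,
unscaled data; absorbance units are homogeneous across channels, so
variance scaling would only amplify noise. The regression vector for
`k` components is `b_k = W_k (P_kᵀ W_k)⁻¹ q_k`; degenerate deflation
stops early with a warning. The number of directions is chosen by
leave-one-out cross-validation over 1..15 (configurable), minimising the
mean absolute error in mol% with ties broken toward fewer directions
(parsimony). Predictions are reported in mol%, clipped to [0, 100] with
a flag. Full-component fits agree with a minimum-norm least-squares
oracle to 1e−8, and the implementation is cross-checked against an
independent PLS implementation to 1e−6 in the test suite.

## Drift regression and bootstrap

Composition drift versus released mass fraction `m ∈ [0, 1)` is
summarised by the stretched-exponential saturation law

    x(m) = x_az + (x₀ − x_az) e^{−k mⁿ} ,

with the asymptote `x_az` (mol%) *shared* across trajectories and
per-trajectory `k, n > 0`; `x₀` is pinned to each trajectory's first
observation. Only trajectories starting at or above the inclusion
threshold (default 40 mol%) join the shared fit — below the positive
azeotrope the dynamics run to pure acid, not to the attractor. Fitting
uses bounded trust-region least squares on `(x_az, log k, log n)` with
an analytic Jacobian and a fixed deterministic multistart; noise-free
data are recovered to 1e−6. Constant data (a trajectory already at the
attractor) short-circuit to a degenerate fit pinned at the common value.

Uncertainty comes from a residual bootstrap: fitted residuals are
rescaled by the standard leverage factor `1/√(1−h_ii)` (h from the fit
Jacobian), centred, resampled with replacement *within* each trajectory
(preserving its design points), added to the fitted values and refit
from the original solution; the 95% interval is the 2.5/97.5 percentile
of the replicate asymptotes (default B = 1000; the pipeline default is
500). Observations at `m = 0` are structurally exact — the model passes
through `x₀` there — and are excluded from the residual pool and left
unperturbed. Both refinements are needed for calibrated intervals: in a
simulation with 3 trajectories × 20 points and 0.5 mol% noise the
measured 95% CI coverage is ≈95%, against ≈83–88% with naive raw-residual
resampling.

## Repellence statistics

Protection is `P = 1 − T/C` (treated/control probing counts; undefined
at `C = 0`, clipped to 0 with a flag when `T > C`). Protection versus
time is fitted with the decreasing three-parameter logistic
`P(t) = P_max/(1 + e^{(t−t50)/s})`, `P_max ∈ (0, 1]`, `s > 0`, by
bounded least squares with deterministic multistart; all-zero data,
midpoints beyond the observation window, parameters on bounds and
upward-trending data are flagged rather than silently fitted. The
protection duration at threshold `θ < P_max` has the closed form
`t = t50 + s ln(P_max/θ − 1)`.

With the assay protocol (20 mosquitoes per cup, 4 subjects, hourly to
6 h) a single assay determines `P_max` and `t50` to a few percent but
the steepness `s` only to ~20–35%: six time points straddle the decay
with binomial counting noise. Estimator *accuracy* is therefore
verified in Monte Carlo — the mean of the fitted parameters over 40
replicate assays lies within 10% of truth for all three parameters (the
estimator is unbiased to ~1–2%).

## Synthetic-data generators

All generators are pure functions of their parameters and a seed or an
explicit `numpy.random.Generator`; no global state is used. Defaults
follow the laboratory protocol: 14 oven mixtures of 13.5 mL at 50 °C
(initial compositions an even 5–95 mol% spread, the exact values being
unpublished), 10 µL FTIR aliquots whose masses are bookkept (but, at ~1%
of the charge in total, not fed back into the ODE), a 24-mixture
calibration set on the 600–4000 cm⁻¹ / 2 cm⁻¹ grid, and hourly 6-h
assays with 20 mosquitoes and baseline probing probability 0.8
(beta-binomial overdispersion optional). Oven sampling runs every 6–12 h
for up to four weeks and stops for a dish once its remaining content
cannot support another aliquot.

Spectral structure comes from mass-action speciation rather than ad-hoc
band scaling: acid dimerisation (`K_dimer = 50`) and 1:1 acid–amide
complexation (`K_complex = 200`, both mole-fraction based — values that
make the dimer and complex the dominant acid forms at low acid
fraction). Band amplitudes are species amounts times fixed extinction
scales: ester 1735 cm⁻¹ ∝ total IR3535, free amide 1638 ∝ uncomplexed
IR3535, composite acid carbonyl 1705 ∝ monomer + dimer, the H-bonded
complex at 1608, and the dimer marker at 932; carbonyls are narrow,
mostly Gaussian pseudo-Voigts (fwhm 10–26 cm⁻¹) so the region is
resolved, plus broad unspecific C–H/skeletal bands. This construction
yields the observed signatures *emergently*: ΔA_mix is positive at
1608 cm⁻¹ and negative at 1705/1638 cm⁻¹, and at low acid fraction the
932 cm⁻¹ relative absorbance flattens near zero while the composite
1705 cm⁻¹ curve keeps falling.

What the generators do *not* emulate: instrument artifacts (CO₂/H₂O
lines, detector drift, baseline wander), matrix effects linking the
speciation constants to the activity model, day-to-day assay
heterogeneity beyond binomial/beta-binomial counting noise, and
temperature fluctuations of the oven. Passing tests therefore
demonstrate correctness of the *analysis chain* under the stated
statistical structure, not robustness to real instrument pathology.

## Pipeline, problem sizes and determinism

`run_pipeline` chains the stages end to end: equilibrium analysis →
synthetic oven campaign → PLS1 calibration with LOO selection → inverse
identification of the oven samples (compositions are *predicted from
the spectra*, not copied from the simulator) → shared drift fit with
bootstrap CI → assay sigmoid fits. Stage seeds are spawned from one
run seed; reports (`report.json`, `report.txt`) are written atomically
and are byte-identical across re-runs with the same config and seed.

Simulation sizes used by the shipped tests and the acceptance script —
oven campaigns of 6–14 mixtures, bootstrap B of 120–500, a coverage
study of 200 datasets at B = 500, 40-replicate assay Monte Carlo — were
chosen so the whole suite completes in a few minutes on one CPU while
keeping Monte-Carlo error well inside the asserted tolerances (e.g.
±1.5% binomial error on the coverage estimate against a ±4% band).

## Known limitations

* The activity model is a calibrated stand-in, not a measured one; its
  γ ranges (≈0.35–12) are plausible for a strongly associating pair but
  unvalidated. Temperature dependence of the coefficients is out of
  scope.
* The stretched-exponential drift law is a declared, configurable choice
  of summary model; the ODE drift is not exactly of this form, and with
  weakly-attracting systems the shared-asymptote extrapolation can be
  biased (see the fixture discussion above).
* Band intensities by windowed baseline-corrected peak height degrade
  in crowded regions (a small band on a large neighbour's shoulder can
  fall below the chord); curve resolution / deconvolution is explicitly
  out of scope.
* Per-subject pooling in the repellence module is a reported mean over
  pooled counts, not a mixed model; inter-treatment hypothesis testing
  is out of scope.
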