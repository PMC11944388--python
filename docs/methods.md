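# Methods

This note documents the model as implemented: equations, parameter
provenance, the calibration that was done (once) and then frozen, numerical
settings, what the synthetic-data generators do and do not emulate, and
known limitations.

## In vitro dissolution

Dissolution of a monodisperse powder follows the Noyes–Whitney form

    dSolid/dt = −Z · (3·CD)/(ρ·h·Size) · Solid · (Cs − Soluble/V)

with the complementary gain on the dissolved side. Units are internal
mg / mL / h / cm throughout; `Size` is the particle **diameter** in cm
(D90 µm × 10⁻⁴). The diameter reading was fixed by an independent check
before the build: with Z = 31 it reproduces the known 60-minute anchors for
the 160 and 210 µm lots (≈67% and ≈57% dissolved), whereas a radius reading
doubles the rate and does not. Particle size is constant during dissolution
(no shrinking sphere — the equation is first order in the solid mass with a
fixed size), and D90 stands in for the whole size distribution as a single
representative size.

Drug constants (apixaban): CD = 0.018 cm²/h, ρ = 1200 mg/cm³,
h = 0.003 cm, Cs = 40 µg/mL. Solubility is treated as identical in the
pH 6.8 + SDS and 0.1 N HCl media — the surfactant acts as a wetting aid, and
apixaban's solubility is pH-independent — so medium effects live entirely in
the Z covariate model:

    Z = Z_wet + A·ΔZ_dry + B·ΔZ_HCl      (A: dry granulation, B: HCl medium)

with reference values Z_wet = 44.8, ΔZ_dry = +8.6, ΔZ_HCl = −22.5, i.e.
Z = 53.4 for dry granulation in pH 6.8 + SDS and 22.3 (wet) / 30.9 ≈ 31
(dry) in HCl. ΔZ_dry is implied by the difference of the two reported
medium-matched values rather than printed as a standalone number.

### Fitting

`ZFactorDissolution` estimates (Z_wet, ΔZ_dry, ΔZ_HCl) by pooled maximum
likelihood under a single additive Gaussian residual on % dissolved across
all profiles. No random effects are estimated: the data this emulates are
*mean* profiles, and per-profile effects are unidentifiable from one curve
per condition. Single-point profiles enter the likelihood as one observation
each. The forward model inside the fitter is the exact closed-form solution
of the two-state system (a Bernoulli/logistic ODE), which makes objective
evaluations cheap; the public `simulate_dissolution` keeps the numerical
ODE path, and agreement between the two routes is exercised by the test
suite. Optimization is multi-start local least squares (default 6 starts:
the best coarse-grid candidates, jittered with a seeded generator), ties
broken by lowest −2 log-likelihood then lowest Z_wet. −2LL is reported for
comparability, but its absolute value depends on the dataset actually fitted
and is not a reproduction target. The design must contain wet and dry
profiles and both media, otherwise the covariates are unidentifiable and the
fit raises.

## IV disposition

Mammillary 2- and 3-compartment models in micro-constant form,
d**x**/dt = A**x**, solved analytically via the eigendecomposition of A
(mammillary rate matrices are similar to symmetric ones, so the eigenvalues
are real); an LSODA path is kept for cross-checking. Central concentration
is x₁/V₁, converted to ng/mL. Fitting log-transforms all parameters to
enforce positivity, uses multi-start Levenberg–Marquardt (a heuristic start
from C(0) and the trapezoidal AUC, plus seeded log-normal perturbations),
and supports additive (default) and proportional Gaussian error — the
variance model behind the original mean-profile fits is unstated, so both
are provided and the choice is explicit at every call. Model selection uses
the least-squares AIC, n·ln(RSS/n) + 2p, with p = 4 (2-compartment) or 6;
near-ties (ΔAIC < 10⁻⁶) resolve to fewer compartments. Absolute AIC values
depend on the dataset and are not reproduction targets; what is tested is
selection behaviour on synthetic data, where the matched-likelihood fit
recovers the generating model in ≥80% of replicates at 2% noise.

Packaged apixaban disposition (from the 5 mg IV mean profile):
K₁₀ = 0.5409 h⁻¹, k₁₂ = 0.086, k₂₁ = 0.0441, k₁₃ = 4.319, k₃₁ = 2.24 h⁻¹,
V₁ = 4.756 L; CL = K₁₀·V₁ ≈ 2.57 L/h.

## GI PBBM

Segments: one stomach (no absorption), 7 small-intestinal compartments,
one colon (no absorption, no dissolution — drug reaching it is counted, not
processed). All transfers are first order: gastric emptying
ks = ln 2 / 0.25 h ≈ 2.77 h⁻¹ (fasting), per-compartment intestinal transit
kT = 7/3.32 ≈ 2.108 h⁻¹ (the classic 3.32 h total small-intestinal transit
split over seven equal-residence compartments). Solid and dissolved drug
transit with the same rate constants; the alternative (advecting dissolved
drug with the water flow) is not used because transfers are specified as
first order. Tablets disintegrate instantaneously (the dose starts as solid
in the stomach); solutions start fully dissolved. For tablets the in vivo
Z is the HCl-medium value of the covariate model (31 dry / 22.3 wet) in all
compartments — the acidic medium is the biorelevant one since no surfactant
is involved and solubility is pH-independent.

Absorption: passive first order from the intestinal compartments,
ka,ᵢ = 2·Peff/radiusᵢ, radii at the midpoints of the linear 1.75 → 1.0 cm
taper (1.696 … 1.054 cm, so ka rises from 0.185 to 0.298 h⁻¹ distally).
Peff comes from the Caco-2 extrapolation
log₁₀Peff = 0.932 + 0.763·log₁₀Papp + 0.0324·RBN (cm/h). RBN = 5 was fixed
by inverting this formula against the tabulated Peff = 1.57 × 10⁻¹ cm/h
(RBN 4 or 6 miss it) and matches apixaban's rotatable-bond count. With these
values the closed-form escape product for fully dissolved drug,
Foral = 1 − Π kT/(kT + ka,ᵢ) = 0.520, already reproduces the ~52% absolute
bioavailability of an oral solution; the ODE model agrees to <0.5%.

### Luminal water submodel

Water follows a parallel chain: stomach fed by salivary+gastric secretion
R₁ and the 250 mL dose water, intestinal compartment 1 by gastric outflow
plus duodenal secretion R₂, compartments 2–7 by upstream transit plus an
even split of mucous secretion R₃; all compartments drain by transit (kT,
ks) and first-order reabsorption kH₂O. Initial volumes are the fasted
steady state (plus the dose water in the stomach). Local volumes define the
local dissolved concentration that drives in-lumen dissolution — this is
what makes Fd dose-dependent.

The four water parameters are the model's only calibrated quantities. They
were tuned **once** against the two dissolved-fraction anchors
Fd(2.5 mg tablet) = 0.99 and Fd(25 mg tablet) = 0.63, then frozen:
R₁ = 90, R₂ = 150, R₃ = 30 mL/h and kH₂O = 0.80 h⁻¹ (middle-out, mirroring
the strategy used for the rest of the model). The calibration was rerun when
the precipitation operator (below) was added, which is why kH₂O is 0.80
rather than the 0.85 of the precipitation-free draft. The resulting fasted
steady-state intestinal water is ≈292 mL total, tapering from ≈83 mL
proximally to ≈17 mL distally — at the generous end of fasted-state imaging
estimates, which cluster around 50–300 mL depending on whether freely
mobile water only is counted. A leaner water pool cannot dissolve 63% of a
25 mg dose in this geometry; the calibration target takes precedence over
any single literature volume.

### Supersaturation handling

The Noyes–Whitney term reverses sign when the local concentration exceeds
Cs, but that reversal is proportional to the *local solid mass*, so it
cannot cap concentrations where solid is scarce — and water reabsorption
concentrates dissolved drug by up to ~15% above Cs at ≥20 mg doses if
nothing else intervenes. Physically this excess would precipitate. The model
therefore adds a first-order relaxation of the supersaturated excess,
rate = k_prec·max(0, Ms − Cs·Vᵢ) returning dissolved drug to the solid
pool, with k_prec = 1000 h⁻¹ (relaxation time ≈ 3.6 s). This leaves a
bounded overshoot ≤ ~0.06% of Cs — invariant tests allow 0.2% headroom —
and moves the bioavailability anchors by ≲0.03. Solutions cannot
precipitate below saturation and the operator is inert for them.

### Outputs

Fd = 1 − (solid reaching the colon + residual gut solid)/dose,
Foral = total absorbed/dose, Fabs = Foral/Fd. Plasma concentration is the
central-compartment amount over V₁. Default horizon 72 h with 0.05 h output
steps (Tmax granularity well below clinical sampling); LSODA with
rtol 10⁻⁸ / atol 10⁻¹⁰. A mass ledger (gut solid/dissolved, colon, body,
eliminated) is checked against the dose at every output time; violation
beyond 10⁻⁶ relative aborts the run with the ledger attached.

## Exposure metrics, bioequivalence and sweeps

Cmax is the profile maximum, Tmax its earliest attainment time on the
output grid, AUC(0–t) the linear trapezoid to the last time point (72 h for
all simulated comparisons; ratios are insensitive to the horizon beyond
~48 h because the terminal phases cancel). %PE = (obs − pred)/obs × 100,
kept unrounded internally and rounded only for display. Mean-profile BE
gates on Cmax and AUC only — Tmax ratios are reported, never gated — with
the regulatory 80–125% window plus a stricter ±10% flag reflecting
point-estimate practice. The safe-space sweep simulates a particle-size
ladder at 5 mg (dry granulation, Z = 31) against two references (oral
solution; 83 µm tablet) and reports the largest size passing BE per
reference: 160 µm against the solution, 210 µm against the 83 µm tablet.
The dissolution-space sweep runs the same ladder through the in vitro model
(0.1 N HCl, 900 mL) and labels each profile very_fast (≥85% at 15 min),
fast (≥85% at 30 min) or not_fast.

## Synthetic data

The dissolution generator emulates the 16-profile mean dataset behind the
Z model: full profiles for 20 mg wet/dry tablets (83.9 µm) and 5 mg wet
tablets (50/89 µm) in both media, plus eight single 30-min points for 5 mg
dry tablets (11–129 µm), 58 observations in all. Per-profile sampling times
are not documented for the original dataset, so the generator uses
{10, 15, 20, 30, 45, 60} min grids with an extra 5-min point for the two
fast 5 mg HCl profiles — a package choice, made once. Noise is additive
Gaussian, clipped to [0, 105]% (clipping, not resampling; the bias is
negligible at SD ≤ 3%). The default SD of 2% dissolved is a placeholder —
the original residual SD is not reported. The PK generator adds additive or
proportional noise to exact multi-exponential profiles, scaled by 1/√n for
a mean over n subjects.

What passing the recovery tests shows: the fitters are consistent and
unbiased *under the generating model* (Gaussian error, correct structural
model, the stated design). Real dissolution data carry disintegration and
coning artifacts, inter-lot variability and non-Gaussian reads that the
generator does not emulate, so recovery here validates the estimation
machinery, not the adequacy of the Z model for any particular dataset.

## Problem sizes and determinism

The pipeline and tests run at desk scale: 58-point dissolution fits,
19-point IV profiles, 100-replicate selection studies, 9-run safe-space
sweeps; an end-to-end pipeline run takes seconds. Every stochastic stage
takes an explicit integer seed (numpy `default_rng`), and repeated runs are
bit-identical — run manifests record config hash, seed and output checksums
to make that checkable.

## Known limitations

* No disintegration step, coning or surfactant-dependent solubility in the
  dissolution model; these are real confounders the Z-factor absorbs only
  on average (visible as mild bias in goodness-of-fit plots).
* Linear disposition everywhere: the less-than-proportional exposure above
  25 mg (possibly saturable efflux or metabolism) is deliberately not
  modeled — there are no IV data at those doses to parameterize it — so
  high-dose AUC is underpredicted.
* No first-pass extraction, colon absorption, enterohepatic recirculation,
  transporter kinetics or fed-state physiology.
* Mean-profile BE only: no between/within-subject variability, no 90%
  confidence intervals, no virtual-population sampling.
* The water submodel is a calibrated physiological sketch: two anchors
  constrain four parameters, so the individual secretion rates are not
  separately identified — only their joint effect on luminal volumes is.
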