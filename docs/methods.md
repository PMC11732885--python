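# Methods

## Scope and model

`y90dosim` implements pre-treatment multicompartment dosimetry for ⁹⁰Y
glass-microsphere radioembolization of hepatocellular carcinoma, together
with the statistical battery used to relate absorbed dose to response,
survival, toxicity, and pre/post-treatment agreement. Because no patient
images or tables ship with the package, every analysis runs on synthetic
inputs from two generators: a voxel phantom emulating the imaging chain and
a cohort simulator emulating the patient-level outcome models. The point of
the package is therefore *self-consistency*: the estimators must recover the
known generating parameters, and the dosimetry must agree with brute-force
voxel arithmetic.

## Phantom generator

The phantom is a liver ellipsoid containing a perfused sub-ellipsoid (the
infusion territory) and spherical lesions placed by center and diameter
("diameter" is the longest axis, recomputable from the mask, matching the
longest-diameter convention of radiologic response criteria). The ideal
tracer concentration is: 0 outside the perfused volume, 1 unit per normal
perfused voxel, and T/N units per tumor voxel; hepatocellular tumors are
typically hypervascular, so T/N defaults to 5 (configurable, T/N ≥ 0).

The imaging chain applies, in order:

1. **PSF blur** — Gaussian, FWHM 8 mm by default (SPECT-like); applied
   before noise, as blur is a property of the imaging system response.
   Blurred counts are re-confined to the liver and renormalized so the
   total is conserved: lung shunt and extrahepatic deposition are not
   modeled, so all activity is intrahepatic by construction.
2. **Poisson noise** — per-voxel counts, on by default; the baseline level
   (100 counts per normal perfused voxel) is a stated default, not a value
   inferred from any published acquisition protocol.
3. **Post-treatment activity map** — the pre-treatment distribution rescaled
   so the perfused volume carries the administered activity (GBq), times a
   voxelwise multiplicative log-normal discordance field (mean-one, sigma
   configurable), optionally translated by a rigid whole-voxel shift.

Misregistration is simulated as a known integer-voxel translation with
zero fill at the border (content is truncated, so counts are conserved only
for interior-supported images); registration *algorithms* are out of scope.

Default grid: 64×64×48 voxels at 4 mm isotropic. One top-level seed feeds
named `SeedSequence` substreams per stage, so equal configs give
bit-identical grids.

## Segmentation

The isocontour operation keeps voxels whose counts are ≥ t × the maximum
inside a user-defined, half-open, 0-based voxel box, intersected with a clip
mask (the reproducible stand-in for manual edits that keep volumes inside
the liver/perfused volume). The comparison is inclusive, so ties at the
threshold are kept; masks nest monotonically as t grows. Defaults t = 0.30
for tumor isocontours and t = 0.10 for the perfused volume follow common
nuclear-medicine practice; they are package choices, not values taken from
any specific study, whose operators chose thresholds case by case. No
connected-component filtering is applied by default (a
`largest_component` helper is available).

Compartment algebra: perfused normal = perfused − (tumors ≥ 2 cm); total
perfused tumor = ∪(tumors ≥ 3 cm) ∩ perfused; whole-liver normal =
whole liver − (tumors ≥ 2 cm). The whole-liver rule mirrors the perfused
rule; whether clinical practice applies a size cutoff there is genuinely
ambiguous, and this choice is recorded as a design decision. Lesion
diameters are the maximum pairwise distance between voxel centers
(computed on convex-hull vertices for large masks — an exact shortcut).

## Dosimetry

The relative calibration factor is f = A / Σ counts over the perfused
volume (GBq per count); counts outside the perfused volume never affect f.
Local deposition assigns each voxel the full decay energy of its own
activity:

    D(v) = counts(v) · f · E / (ρ · V_voxel)

* **E = 49.67 J/GBq** — energy released per GBq over complete decay,
  A₀·Ē/λ with Ē the mean β energy (~0.93 MeV) and λ = ln2/64.05 h. This is
  the conventional permanent-implant constant behind the familiar
  D[Gy] ≈ 49.67 · A[GBq] / M[kg]; it is configurable because commercial
  dosimetry tools do not publish their exact constant, and numerical parity
  with any specific product is not claimed.
* **ρ = 1.05 g/cm³**, uniform — soft-tissue convention. Uniform density
  makes mass-weighted compartment means equal plain voxel means.

Σ D·m over voxels equals A·E exactly whenever the counts are supported on
the perfused volume (energy conservation), and doses are linear in both
counts and administered activity. Post-treatment dose maps reuse the same
pipeline on the PET-like activity grid with the anatomic compartments.
Reports round to 0.1 Gy; internals keep full precision.

## Cohort simulator

Per patient: anatomic-method TAD is log-normal (median 216 Gy, log-sigma
0.7 — matching the reported anatomic dose distribution's median and
right skew); the threshold-method TAD is a correlated rescaling with median
ratio 302/216. Binary response follows a logistic model in TAD with
generating slope ln(1.22)/100 per Gy (mRECIST; ln(1.21)/100 for RECIST 1.1);
the intercept is calibrated by Gauss–Hermite quadrature so the marginal
response rate is 61.7% (34.4% for RECIST 1.1). Survival is exponential
proportional hazards with log-hazard slope ln(0.826)/100 per Gy; the
baseline hazard (0.0516/month) is set so median OS at the median dose is
≈ 20.3 months. Censoring is an independent uniform time whose horizon is
solved so the expected censored share equals the target (30% by default) —
the closed form P(C < T) = (1 − e^(−rc))/(rc) is averaged over patients and
inverted by bisection. Toxicity (grade ≥ 3 hyperbilirubinemia) is logistic
in perfused-volume NTAD with zero slope and 4.8% marginal rate by default,
reflecting that no normal-tissue dose–toxicity relationship was detected at
this event rate; named covariate effects can be injected for selection
experiments.

Paired pre/post tumor doses for agreement analyses are generated as
post ~ log-normal (median 263.1 Gy) with pre = post + N(+11.5,
((250.0 − 11.5)/1.96)²) Gy — differences independent of the post value,
which is the structure a Bland–Altman analysis assumes. Differences are not
clipped; with these parameters a pre value can in rare draws be
non-physical (≤ 0), a deliberate trade against biasing the recovered bias
and limits.

## Statistical choices

* **Binomial CI**: Wilson score. Chosen because it reproduces the printed
  intervals for 129/209 and 72/209 to 0.1 percentage points, which the
  normal-approximation and exact (Clopper–Pearson) intervals do not.
* **Logistic CIs**: Wald on the slope, exponentiated; effects reported per
  100 Gy as exp(100·slope). Perfect separation raises an error rather than
  returning a divergent estimate.
* **Cox**: partial likelihood with Efron tie handling (lifelines default);
  Wald CIs; monotone-likelihood symptoms are flagged on the fit object.
* **Kaplan–Meier**: product-limit estimate; the median is the earliest time
  with S(t) ≤ 0.5, reported as not reached when the curve stays above 0.5;
  the median CI uses the log-log-transformed band.
* **Bland–Altman**: differences are pre − post; limits are bias ± 1.96 ×
  sample (n−1) SD (a fixed 1.96, not a t-quantile — consistent with
  symmetric printed limits and conventional practice). The plot abscissa
  defaults to the post-treatment value, matching the study design this
  package emulates, with the conventional mean-of-pair mode available; the
  statistics are abscissa-independent.
* **Multivariable selection**: candidates are screened one at a time
  alongside the forced dose term (enter if two-sided p < 0.1), then backward
  elimination removes the worst remaining candidate until all have p < 0.1.
  The forced term is never removed; non-estimable or collinear candidates
  are dropped with a logged reason, and the full audit trail is returned.
  The procedure is deterministic given the data.
* **Missing data**: listwise deletion per model, with the dropped count
  reported on the fit.

## Problem sizes

The recovery experiments run at the study's own scale: 200 replicate
cohorts of n = 209 for the odds- and hazard-ratio recoveries, 10,000 pairs
for Bland–Altman, and 500 replicates of n = 52 for the Pearson recovery.
Unit tests use 32³ phantoms and random ≤ 10³-voxel grids, which exercise
every code path at interactive speeds.

## What the generators do and do not emulate

The phantoms capture compartment geometry, uptake contrast, PSF blur,
Poisson noise, pre/post discordance and rigid misregistration — enough to
study how segmentation choices propagate into compartment doses. They do
not model SPECT projection/reconstruction physics, attenuation or scatter,
respiratory motion, lung shunt, microsphere-scale heterogeneity, or
deformable anatomy; passing tests therefore demonstrate correctness of the
dosimetry and statistics pipeline under idealized imaging, not clinical
accuracy on real SPECT data. Likewise the cohort simulator draws outcomes
from exactly the model families the estimators assume, so recovery results
certify the estimation code, not the adequacy of logistic/proportional-
hazards models for real patients. Real cohort tables with the documented
column schema can be analyzed directly with the same functions.
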