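# Methods

This note records the models implemented in `bacekit`, the defaults and
why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices that affect results.

## Non-compartmental analysis

AUC uses the **linear trapezoid only**.  Preclinical profiles of the
kind this package targets are sparsely sampled, and a single auditable
rule is preferred over lin-log switching; window endpoints are obtained
by linear interpolation on the observed grid, which makes the area
exactly additive over adjacent windows.

**BLQ handling** follows the common sparse-sampling convention: censored
samples before the first quantifiable point are treated as 0, censored
samples embedded in or after the quantifiable range as LLOQ/2 for area
purposes; censored samples are always excluded from the terminal
regression.

**Terminal phase selection**: quantifiable points strictly after Tmax;
the regression starts from the last three points and extends backwards
while the adjusted R² improves.  This is the usual "best adjusted-R²"
heuristic, deterministic and overridable via `min_points`.

**Extrapolation** to infinity uses the regression-predicted last
concentration, C_last_pred/λz, which is less noise-sensitive than the
observed last sample.  Results carry a warning when more than 20 % of
AUC∞ is extrapolated, and when F falls outside [0, 1.05] (the 5 % head
room allows sampling noise).

Unit conventions: dose μmol/kg and concentration μM give CL in l/h/kg
natively; reported as ml/min/kg (×1000/60) and Vz in l/kg.  Values are
rounded only at the reporting layer.

Known limitation: a terminal-phase Vz is the only volume computed.
Steady-state volumes (e.g. from moment analysis) are out of scope, so a
tabulated Vd that was derived differently will not be reproduced by
CL·t½/ln 2 — notably the case for species with very low clearance.

## Dose–response

Fits are performed in log10(dose); a vehicle group (dose 0) only enters
through the percent-inhibition normalization and is never a fitted
point, avoiding log(0).  Under the parameterization
`y = bottom + (top−bottom)/(1+(x/mid)^h)`, a positive Hill gives a
decreasing curve; inhibition-vs-dose data therefore fit with negative
h, and the starting sign is taken from the data trend (other starts:
top = max y, bottom = min y, midpoint at the dose nearest half-range).

For in vivo ED50 the bottom is fixed at 0 (no inhibition at zero dose,
by construction of the percent-inhibition scale); all four parameters
are free for in vitro curves.  Standard errors are asymptotic
(Jacobian-based, with the midpoint SE obtained from the log-midpoint SE
by the delta method), matching the conventional "estimate ± SE" style
of potency reporting.

Degenerate designs: a study whose groups all sit within 5 percentage
points of vehicle is rejected as "no response"; a study saturated at
every dose (minimum inhibition above 80 % of the maximum, maximum above
50 %) is flagged `unidentifiable_midpoint` because the midpoint lies
below the tested range.  These cutoffs are coarse screens for clearly
degenerate inputs, not statistical tests.

## Turnover PK/PD

The model is **inhibition of production**: a BACE-1 inhibitor blocks
synthesis of Aβ, while the biomarker's own clearance (kout) is drug
independent.  Imax defaults to 1 (complete enzyme blockade at
saturating concentration).  The PK forcing is the one-compartment oral
closed form (Bateman); at ka = ke the closed form degenerates and ka is
perturbed by 1e-9.

Fitting is **sequential** (PK first, then PD) rather than simultaneous:
it mirrors how the data are collected, keeps the PD fit a 2-parameter
problem (kout, IC50 on the log scale), and makes identifiability easy
to reason about.  kin is not free: it is constrained to kout·R0 with R0
the mean of all predose samples (−24 h and −1 h in the dog design),
exactly the baseline used for percent-of-predose normalization.

Integration uses an adaptive stiff-capable stepper (LSODA) at relative
tolerance 1e-8 (1e-7 inside the fit for speed), absolute tolerance
scaled to the baseline.  Measured concentration series used as forcing
are linearly interpolated and clipped at 0.

A consequence of the fitted constants worth stating: the complete-
blockade closed form and the biomarker half-life are two views of the
same kout, t½ = ln 2/kout, and the package reports both without forcing
them to agree with any externally quoted half-life.  Likewise, with an
IC50 of 59 nM and a drug with a ~36 h blood half-life, the model
predicts only partial return to baseline by 168 h; the synthetic dog
study inherits this property of the model.

Whether the in vivo IC50 refers to total or unbound blood concentration
is left to the caller: the model is agnostic, and the IC50 is reported
in the units of the concentration input (total blood μM here).

## Effect metrics

Percent-of-predose normalization divides by the mean of the named
predose samples and records that baseline, making the transform exactly
invertible.  AUEC over a dosing interval is the linear-trapezoid area
of the reduction-vs-time curve divided by the window length — a
time-averaged percent reduction.  At once-daily steady state the t = 0
value is taken equal to the trough (24 h) value
(`auec_24h_steady_state`), since immediately before a dose the system
sits at trough.  Group summaries use arithmetic means.  Group
comparison statistics (ANOVA and post-hoc tests) are deliberately out
of scope; only the Pearson correlation used by the imaging module is
implemented.

## Plaque imaging

Color deconvolution uses the standard H-DAB absorbance basis
(`skimage.color.hdx_from_rgb`); unmixed densities are clipped at 0 and
saturated pixels can never produce NaN.  Note the stain "densities" are
on skimage's normalized scale (1.0 ≈ the full dynamic range of an 8-bit
pixel); densities above ~1.3 for mixed stains leave the invertible
range, which bounds the reconstruction fidelity, not the segmentation.

Defaults, all configurable:

* nuclei: Otsu threshold on the hematoxylin channel, hole fill, minimum
  size 30 px; **exclusion radius 5 px** dilation.
* deposits: mean local threshold, **window 101 px, offset 0.05 OD**,
  plus a global floor of 0.15 OD to suppress background; 8-connected
  components; **granule floor 25 px** (the lower bound of the
  intracellular class — no shape criterion is applied).
* classification: intracellular 25–200 px (inclusive bounds) or within
  nuclear vicinity; small plaque 201–1000 px detached from nuclei;
  large plaque > 1000 px regardless of proximity.  **Nuclear vicinity
  radius 10 px** — deliberately larger than the exclusion radius, so an
  object abutting the exclusion zone still counts as nucleus-associated.
  "Within vicinity" and "sufficiently detached" are not quantified
  standards; both radii are exposed as parameters.
* area fraction counts all retained deposit pixels by default; a
  `categories` argument restricts it (e.g. plaques only).  ROI edges
  clip objects and the clipped area counts as-is.
* glia clusters: Otsu within the ROI on each single fluorescence
  channel independently (no spectral unmixing), components ≥ 20 px.
* pixel-area thresholds are defined at the pipeline's native export
  scale; `scale_thresholds` rescales them when pixel-size metadata
  differs.

## Synthetic data

Generators are pure functions of (parameters, seed) using
`numpy.random.default_rng`; every dataset is returned with a
`SyntheticGroundTruth` naming the generator, its full parameter set and
the per-dataset truth.

* **PK presets** encode species regimes by (CL, t½, F): mouse
  16 ml/min/kg / 3.6 h / 37 %, rat 52 / 2.7 h / 92 %, dog
  0.4 / 36.2 h / 62 %.  V is derived as CL·t½/ln 2 so the preset is
  internally consistent and NCA closes the loop; sampling is a fixed
  20-point grid densified near the peak and scaled to each species'
  observation window (24 / 48 / 408 h).
* **Dose–response** uses the dose grid 0.3/1/3/10/30 μmol/kg, true
  ED50 1.6 μmol/kg, Hill 1, groups of 5 animals with 10 % lognormal CV
  per animal, group means returned.
* **Dog study**: predose samples at −24/−1 h, post-dose to 168 h;
  baseline lognormal around 6000 pg/ml (10 % CV across subjects),
  blood forcing peaking at ≈ 0.7 μM with a 36 h terminal half-life,
  turnover truth kout = 0.26 h⁻¹, IC50 = 0.059 μM, Imax = 1; 10 %
  lognormal measurement noise on blood and CSF.
* **Sections**: nuclei and deposits are uniform-density disks placed
  with minimum-separation (Poisson-disk style) sampling; deposit radii
  are drawn per class and nudged until the rasterized pixel count falls
  in the requested class, so planted truth and the pipeline's area rule
  agree by construction.  Deposits are kept detached from nuclei beyond
  the vicinity radius (nucleus-proximity classification is exercised by
  dedicated crafted fixtures instead).  Glia channels plant one cluster
  adjacent to each plaque with probability `glia_coupling` plus a
  Poisson number of background clusters, so coupling 0 statistically
  decouples glia counts from plaque burden.

What the generators do **not** emulate — and hence what passing
recovery tests do not demonstrate about real data: staining and scanner
variability, anti-aliased or textured object boundaries, overlapping
and confluent deposits, uneven illumination, subject-level PK parameter
variability (only measurement noise and baseline spread are modelled),
assay drift, and real sampling irregularities.  Recovery results should
be read as verifying the estimators against their own generating
model, not as accuracy claims for tissue sections or in-life studies.

## Problem sizes

Defaults used by the test suite and the acceptance script: 200 seeds
for ED50 recovery, 50 cohorts of 4 dogs for the turnover recovery,
768×768 px sections (512×512 within cohort sweeps, 8–10 animals per
cohort).  These sizes give stable medians (repeat runs across seeds
move the recovered medians by ≲ 3 %) while keeping a full run in the
tens of seconds on one CPU.
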