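# bacekit

Analysis toolkit for the preclinical characterization of brain-penetrant
BACE-1 (β-secretase) inhibitors — the drug class that suppresses
amyloid-β (Aβ) production in Alzheimer's-disease models.  It is written
for DMPK and pharmacology scientists who need to turn raw
concentration–time tables, dose–response group means and stained brain
sections into the standard reported quantities: exposure summaries,
in vivo potency, biomarker turnover parameters and amyloid-plaque /
neuroinflammation burdens.

## What it computes

**Non-compartmental PK** (`bacekit.nca`) — Cmax/Tmax, linear-trapezoid
AUC with standard BLQ substitution, terminal log-linear half-life
(t½ = ln 2/λz), clearance CL = D_iv/AUC∞, Vz = CL/λz, oral
bioavailability F = (AUC_po/D_po)/(AUC_iv/D_iv), unbound exposure
AUC_u = AUC·fu, and the MDR1-MDCK efflux ratio.

**Dose–response potency** (`bacekit.dose_response`) — percent inhibition
of vehicle and a four-parameter logistic fit

    y = bottom + (top − bottom) / (1 + (x / ED50)^h)

on log dose, exposed as a scikit-learn-style estimator
(`FourParamLogistic`) with asymptotic standard errors; for in vivo ED50
the bottom asymptote is fixed at 0 on the inhibition scale.

**Turnover PK/PD** (`bacekit.turnover`) — the indirect-response model
for a synthesis inhibitor,

    dR/dt = kin · (1 − Imax·C(t)/(IC50 + C(t))) − kout · R,

with a one-compartment oral forcing C(t), closed-form limits (complete
blockade gives 100·(1 − e^(−kout·t)) percent reduction; biomarker
t½ = ln 2/kout) and a sequential PK-then-PD least-squares fit
(`TurnoverEstimator`) returning the in vivo IC50 and the biomarker
clearance rate kout with standard errors.

**Effect summaries** (`bacekit.effect`) — percent-of-predose
normalization, time-averaged area under the effect curve (AUEC) over a
dosing interval, signed group percent changes.

**Plaque imaging** (`bacekit.imaging`) — H-DAB color deconvolution,
nuclei detection with an exclusion zone, adaptive thresholding of the
DAB channel, rejection of sub-25 px granular noise, classification of
deposits into intracellular (25–200 px or within nuclear vicinity),
small plaques (200–1000 px, detached from nuclei) and large plaques
(> 1000 px), ROI area fraction, GFAP⁺/Iba1⁺ glia-cluster counting and
the plaque–glia Pearson correlation with a 95 % confidence band.

**Synthetic data** (`bacekit.synthetic`) — seeded generators for every
input above (species PK presets, rat dose-ranging studies, dog CSF Aβ40
turnover cohorts, H-DAB-like section images), each returning its ground
truth for closed-loop recovery testing.

## Worked example: in vivo IC50 from a dog turnover study

```python
from bacekit import gen_dog_study, fit_turnover, half_life_from_kout

study = gen_dog_study(n_subjects=4, noise_cv=0.10, seed=7)
fit = fit_turnover(study.mean_blood(), *study.mean_csf())
print(f"in vivo IC50 : {fit.model.ic50*1000:.1f} +/- {fit.se['ic50']*1000:.1f} nM")
print(f"kout         : {fit.model.kout:.3f} +/- {fit.se['kout']:.3f} 1/h")
print(f"biomarker t1/2: {half_life_from_kout(fit.model.kout):.2f} h")
print(f"baseline     : {fit.r0:.0f} pg/ml")
```

prints

```
in vivo IC50 : 57.7 +/- 2.8 nM
kout         : 0.277 +/- 0.012 1/h
biomarker t1/2: 2.51 h
baseline     : 6041 pg/ml
```

The cohort was generated with a true IC50 of 59 nM and a CSF Aβ40
clearance rate of 0.26 h⁻¹ under 10 % measurement noise; the sequential
fit recovers both within a few percent, and the quoted ± values are the
asymptotic standard errors of the fit.

A command-line surface mirrors the library:
`bacekit nca`, `bacekit fit-dose-response`, `bacekit fit-turnover`,
`bacekit effect-summary`, `bacekit quantify-plaques` and
`bacekit simulate pk|dose-response|dog-study|section`.

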