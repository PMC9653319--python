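# rgcest

Structure–function estimation of retinal ganglion cell (RGC) counts in early
glaucoma, from optical coherence tomography (OCT), standard automated
perimetry (SAP) and steady-state pattern electroretinography (ssPERG).

Glaucoma kills RGCs years before visual-field tests turn abnormal. Two
families of estimators make that silent loss quantifiable:

**The combined structure–function index (CSFI)** (Medeiros et al., building
on the Harwerth model) estimates an eye's RGC count twice and blends the two
by disease stage. Functionally, each of the 52 analysed 24-2 visual-field
locations at eccentricity *ec* with sensitivity *s* (dB) contributes

```
m  = 0.054·ec^1.32 + 0.9          b  = −1.5·ec^1.32 − 14.8
gc = ((s − 1) − b)/m + 4.7        SAPrgc = Σ 10^(0.1·gc)
```

Structurally, the average RNFL thickness (ARNFLT, µm) converts to an axon
count via an age-dependent axonal density *d* = −0.007·age + 1.4 axons/µm²,
with a remodelling correction *c* = −0.26·MD + 0.12:

```
a = ARNFLT · 10870 · d            OCTrgc = 10^{0.1·(10·log10(a) − c)}
eRGC_CSFI = (1 + MD/30)·OCTrgc + (−MD/30)·SAPrgc
```

A `variant="as_printed"` flag additionally evaluates the arithmetic
re-transcriptions of these formulas found in parts of the clinical
literature (e.g. `0.54·(ec·1.32)`), which are off the physiologic ~10⁶ count
scale by orders of magnitude — useful for making the discrepancy explicit.

**Linear ssPERG+OCT estimators.** The CSFI needs 57 data points per eye; a
three-covariate mixed-model estimator needs three. Two bundled reference
models predict eRGC_CSFI from age, ARNFLT and one ssPERG amplitude (Mag, or
the phase-consistency-adjusted MagD):

```
eRGC_Mag  = 401,342 − 6268·Age + 8899·ARNFLT + 58,610·Mag
eRGC_MagD = 405,529 − 6092·Age + 9019·ARNFLT + 53,493·MagD
```

`fit_glmm` derives such models on any bilateral cohort by REML, with a
per-subject random intercept so the two correlated eyes of each subject are
handled as repeated measures. Around this sit the cohort statistics used to
evaluate them (one-way ANOVA with eta², Games-Howell post hoc comparisons,
Welch t, Pearson r², ROC/AUC) and a synthetic-cohort generator with known
ground truth.

## Worked example

`python examples/02_builtin_models_and_losses.py` prints:

```
eRGC_Mag = 401,342 - (6,268*Age) + (8,899*ARNFLT) + (58,610*Mag)
eRGC_MagD = 405,529 - (6,092*Age) + (9,019*ARNFLT) + (53,493*MagD)

Mag-model prediction at healthy-group means: 1,069,952 RGCs

percent loss relative to healthy eyes (GS = glaucoma suspect,
PPG = preperimetric glaucoma):
  ARNFLT   GS  12%   PPG  18%
  Mag      GS  31%   PPG  36%
  MagD     GS  37%   PPG  54%
  eRGC_Mag   GS  13%   PPG  32%   (0.59%/year with age)
  eRGC_MagD  GS  13%   PPG  33%   (0.57%/year with age)
```

Reading: a healthy eye carries ~1.07 million estimated RGCs. In glaucoma
suspects the ssPERG amplitudes are down 31–37% while RNFL thickness and the
RGC estimates have lost only 12–13% — function degrades before cells die. In
preperimetric glaucoma the Mag loss (36%) and count loss (32%) converge, and
both models put age-related attrition at 0.57–0.59% of the healthy count per
year. The other examples walk through the CSFI for a single eye
(`01_csfi_single_eye.py`), deriving and cross-validating a new estimator on
a simulated cohort (`03_simulate_fit_validate.py`), and the full study
pipeline with all report tables (`04_full_study_report.py`).

A thin CLI wraps the same pipeline:

```
rgcest simulate --out cohort.csv --seed 1
rgcest report --cohort cohort.csv --seed 1 --out report/
```

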