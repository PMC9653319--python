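# Methods

## The estimation problem

Retinal ganglion cell (RGC) loss is the substrate of glaucoma, but no
clinical instrument counts RGCs directly. Two indirect routes exist:
perimetry (function) and OCT RNFL thickness (structure), combined in the
CSFI; and electrophysiology (ssPERG), which measures RGC *activity* and
degrades before structure does. This package implements the CSFI chain, the
linear ssPERG+OCT estimators distilled from it, and the statistical
machinery to derive and evaluate such estimators on bilateral cohorts.

## CSFI chain

`rgcest.csfi` evaluates, per eye:

1. **SAPrgc.** The 24-2 pattern is the standard 54-point, 6°-spaced grid
   (odd multiples of 3°), extended to 27° on the nasal side of the
   horizontal rows, minus the two blind-spot points at 15° temporal,
   y = ±3° — 52 analysed locations. Eccentricity is the Euclidean distance
   of the location's centre from fixation; RGC density is treated as uniform
   within each 6°×6° patch, so no sub-location integration is performed.
   Each location's sensitivity maps to a log-scaled ganglion-cell quantity
   through the eccentricity-dependent slope/intercept pair, and location
   contributions `10^(0.1·gc)` sum to the field total. Sensitivities below
   1 dB are allowed: the contribution simply decays smoothly toward zero.
2. **OCTrgc.** ARNFLT × 10,870 axons/µm of thickness × the age-dependent
   axonal density `d = −0.007·age + 1.4`, then the remodelling correction
   `c = −0.26·MD + 0.12` applied on the 10·log10 scale. The logarithm is
   base 10 — required for the `10^{·}` inversion to preserve the axon-count
   scale (`OCTrgc = a·10^(−c/10)`).
3. **Blend.** Weights `1 + MD/30` (structure) and `−MD/30` (function) sum
   to one for every MD, meeting the boundary identities at MD = 0 (pure
   structure) and MD = −30 dB (pure function) exactly.

**Formula variants.** The forms above (`variant="corrected"`, the default)
are the originating model's. Some clinical re-statements of the chain
render the slope as `0.54·(ec·1.32)`, the intercept as `−1.5·(ec + 1.32)`
and the density as `(−0.007 + age) + 1.4`; evaluated literally these are
inconsistent with the ~10⁶ count scale by orders of magnitude (a single
28-dB location contributes ~56 RGCs instead of ~3.8×10⁴). Both readings are
implemented behind an explicit `variant` flag rather than silently choosing
one; every result object carries its variant tag.

## Linear mixed-model estimators

`fit_glmm` estimates `eRGC = β₀ + β₁·age + β₂·ARNFLT + β₃·PERG` by REML
with a Gaussian random intercept per subject, shared by both eyes
(statsmodels `MixedLM`). With at most two eyes per subject, a random
intercept is the identifiable reading of "repeated measures with
within-subject correlation"; no richer covariance structure is fitted.
Design-matrix rank is checked before fitting (duplicated covariates raise a
singular-design error); optimiser non-convergence raises with the trace,
except for exact zero-residual interpolations (noise-free outcomes), which
drive the variance components to the boundary and are accepted with their
exact fixed effects.

The bundled reference models store full-precision coefficients, standard
errors and p-values; the familiar rounded display formulas are derived at
render time (all rounding in this package is half-away-from-zero, the
convention of the clinical tables it mirrors).

Splits (`split_cohort`) partition analysis units uniformly at random with a
fixed seed; the default unit is the *eye* (a 0.6 fraction of 50 eyes gives
the canonical 30/20 training/validation split), with `unit="subject"`
available to preclude within-subject leakage between splits. Validation and
training R² are defined as the squared Pearson correlation between the
fixed-effects prediction and the outcome (a marginal, not conditional, R²;
the conditional one would credit the random intercepts, which do not
transfer to new subjects).

Loss accounting: `proportional_loss` reports `100·(healthy − group)/healthy`
rounded to integer percent; `annual_loss_rate` reports `100·|β_age|/healthy
mean` to two decimals. Unrounded values are retained on the result objects.

## Cohort statistics

All group tests assume neither equal variances nor equal group sizes:

- **ANOVA + eta².** Classical between/within decomposition;
  `eta² = SS_between/SS_total`. The effect size accompanying the omnibus
  test is implemented as eta² (consistent in magnitude with the reference
  tables; the label there is unstated).
- **Games-Howell.** Per pair: Welch standard error `√(s²ᵢ/nᵢ + s²ⱼ/nⱼ)`,
  Welch–Satterthwaite df, statistic `q = |Δ|·√2/se` referred to the
  studentized-range distribution with k groups (scipy
  `studentized_range`). With k = 2 this reduces numerically to Welch's
  two-sided t — a property test asserts the identity to 10⁻⁶. The procedure
  itself is eye-level; inter-eye correlation can be addressed by aggregating
  to one mean per subject before testing, at the cost of the printed Ns.
- **Welch t, Pearson r²** via scipy, with the strict degenerate-input error
  contracts stated in the docstrings.
- **ROC.** AUC through the Mann-Whitney concordance identity (ties counted
  half); p-value from the tie-corrected normal approximation to U, the
  assumption-light default since no distributional model of the scores is
  available. Orientation is chosen so the reported AUC ≥ 0.5 unless the
  positive class is pinned; the direction is recorded on the result.

## Synthetic cohorts

`generate_cohort` emulates the reference study's design: 15/5/5 subjects
per group (30/10/10 eyes) by default, bilateral eyes sharing subject ID and
age, and 20% discordant subjects (the reference cohort had 5 of 25) whose
second eye is drawn from — and labelled with — an adjacent group (healthy↔GS
or GS↔PPG; a GS subject's discordant eye moves either way with equal
probability, so eye-level group counts vary stochastically around
2·n_subjects).

Marginals are Gaussian at the reference group means/SDs, truncated (by
clipping) to measurement bounds: ARNFLT 40–130 µm, Mag/MagD ≥ 0 µV, MD
−35…+3 dB. Age and IOP are validated but drawn untruncated so configured
group means are preserved (the PPG age profile, 73 ± 16, would otherwise be
biased several years downward). Inter-eye correlation ρ (default 0.6,
typical for ocular structural measures; the true value is unreported and
configurable) is induced per measurement by `μ + σ(√ρ·z_subject +
√(1−ρ)·z_eye)`. The joint correlation *among* different measurements within
an eye arises only through group membership and the shared subject deviate;
real within-eye cross-correlations (e.g. ARNFLT with Mag) are not separately
modelled — a caveat on how far simulated R² generalises to real cohorts.

The latent outcome is `outcome_model.predict(age, ARNFLT, PERG) + subject
noise (SD 50,000) + eye noise (SD 40,000)` RGCs; by default it populates
`ergc_csfi`, giving fits a known truth and cohort R² in the high-0.8s —
comparable to, without claiming, the reference study's 0.90/0.89. The noise
SDs were chosen once to place the subject:eye variance split near the
mixed-model literature's typical ~60/40 for ocular measures at this scale.

The visual-field generator draws 52 sensitivities from a synthetic normative
surface — linear decline from 33 dB at 4.24° to 27 dB at 27°, noise
SD 1.5 dB — then shifts to the target MD exactly and clips to the 0–50 dB
instrument range (re-checking the achieved MD to 0.05 dB; unreachable
targets raise). The surface is a test fixture, not a normative database: it
supports monotonicity and plumbing checks, not clinical interpretation.

## Pipeline and reporting

`run_study` chains validation → split → two mixed-model fits (or the
bundled estimators) → prediction and R² → ANOVA/Games-Howell/Welch/ROC →
loss accounting, logging record counts per stage. Report tables hold
unrounded values; rounding happens only at render time, and regeneration
under the same seed and config is byte-identical (no timestamps enter the
report). Within `run_study`, a variable whose test is degenerate in the
given cohort (for instance zero variance in a pair of groups) yields NaN
entries in that table instead of aborting the run; the strict error
contracts live on the individual statistical functions.

## Problem sizes and checks

The test suite and `scripts/acceptance.py` use 25-subject (reference-sized)
cohorts for pipeline checks, 200-subject cohorts for estimation accuracy,
1000 subjects per group for marginal/correlation calibration, and 30–50
replicates for parameter-recovery summaries — sizes at which Monte-Carlo
error is well inside the asserted bounds while the whole suite runs in well
under a minute. Independent oracles back the implementations: a scalar
per-location loop for the vectorised CSFI, direct quadrature of the
studentized-range CDF and `pingouin` for Games-Howell, `scipy.stats.f_oneway`
for ANOVA, exhaustive pair counting and `sklearn` for AUC, and generating
coefficients for mixed-model recovery.

## Known limitations

- The CSFI itself overestimates absolute RGC counts post mortem; estimates
  are comparative indices, not histologic counts.
- The bundled linear models were derived in early disease (suspects and
  preperimetric glaucoma); they are not expected to extrapolate to moderate
  or severe field loss, where the CSFI's functional arm dominates.
- Real-cohort R², AUCs and p-values depend on the unavailable raw data;
  the simulation reproduces the cohort's *structure*, so such quantities are
  checked as properties (recovery, identities, determinism), not as values.
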