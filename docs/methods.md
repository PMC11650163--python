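# Methods

## The analysis in one paragraph

`rewarddfh` implements a normative-modelling alternative to case-control
classification for task fMRI. Instead of training a classifier to separate
patients from controls — fragile when diagnostic labels are unreliable — a
linear max-margin classifier is trained on typically-developing (TD)
adolescents to separate two *conditions within person*: the parcel-level
BOLD response to received reward versus received punishment in a
probabilistic instrumental-learning (passive avoidance) task. The trained
hyperplane then serves as a functional yardstick: any individual's
reward-condition response can be scored by its signed Euclidean distance
from the hyperplane (DFH), a one-number index of how robustly that person's
brain distinguishes reward from punishment. DFH values are normed against
the TD training distribution (z-scored by the training mean and s.d.) and
binned into five categories; a reward response more than 2 training s.d.
*below* the training mean — toward or past the hyperplane — is called
deficient. Downstream analyses ask whether clinical groups are
over-represented in the low bins (contingency chi-square), whether DFH
tracks symptom severity (Pearson correlations), and whether deficient
responders carry heavier symptom burdens (Welch t, with OLS
covariate-adjusted sensitivity checks).

## Data model

A **feature table** has one row per subject × condition over a fixed set of
region columns: by default 400 Schaefer cortical parcels plus 12 bilateral
subcortical structures (thalamus, caudate, putamen, nucleus accumbens,
hippocampus, amygdala × hemisphere), 412 features, values in arbitrary GLM
units. The package consumes already-parcellated tables; surface
reconstruction and first-level GLMs are out of scope. A **phenotype table**
carries group membership (TD_train / TD_test / clinical), demographics
(age, sex, IQ), four diagnosis flags (CD, ADHD, MDD, GAD — comorbidity
allowed) and fifteen symptom scale scores with missingness permitted.
Validation is strict: both condition rows per subject, no missing feature
cells, unique subject ids; malformed inputs raise typed errors rather than
dropping rows silently. Missing scale values propagate to
pairwise-complete statistics, so degrees of freedom vary by measure.

## Pipeline stages

**Standardization.** Per-region mean and s.d. are estimated from the TD
training observations only, both conditions pooled (per-condition scaling
would hand the classifier the condition difference). Test and clinical
rows are transformed with the training parameters — nothing leaks.

**Feature selection.** The lasso stage is an L1-penalized logistic
classification of condition. Because the design is paired (each subject
contributes exactly one row per condition), the fit is conditional on
subject: within-subject reward-minus-punishment difference vectors,
symmetrized (±d with labels ±1) and fit without an intercept — the
matched-pairs conditional-logistic form. This cancels the subject-level
additive effect exactly, so a region can only enter through its
reward/punishment contrast; a region that merely tracks a subject's
overall responsiveness cannot be selected. (Fit on raw rows instead, the
L1 model demonstrably recruits non-discriminative regions with negative
summed weights as a common-mode reference for the subject effect,
polluting the selection.) The penalty is chosen over 50 log-spaced inverse
penalties C ∈ [10⁻³, 10] by 10-fold subject-grouped cross-validated
log-loss with the one-standard-error rule — the most-penalized model
within one s.e. of the best. Selected regions are those with nonzero
coefficients; the sign records the direction (positive = reward-preferring,
negative = punishment-preferring). An empty selection at the chosen
penalty is returned flagged; an all-zero path over a grid that probed weak
penalties is an error (no separable signal). The selected-set *size* is a
dataset property, not a target.

**Classifier.** A soft-margin linear SVM (objective ½‖w‖² + C·Σhinge,
C = 1 default, tolerance 1e-6, bounded iterations with non-convergence an
error) on the standardized selected rows. Orientation is enforced after
every fit: (w, b) are negated if needed so the mean training
reward-condition decision value is positive — "below the hyperplane"
always means a weaker reward response. Out-of-sample performance is
estimated by k-fold (default 10) subject-grouped CV with the full
preprocessing chain (standardizer, selection, SVM) refit inside every
fold; a subject's two rows never straddle folds. Confusion counts are
pooled with reward as the positive class. A fold whose training split
yields an empty selection falls back to the intercept-only rule (training
majority class) so null data score at chance rather than erroring.

**DFH and norming.** d = (w·x + b)/‖w‖₂ in standardized-feature units,
invariant to rescaling of (w, b). The final TD_train-fit hyperplane (not
per-fold ones) scores everyone. The norm reference is the mean and sample
s.d. (ddof = 1) of the TD training reward distances; z = (d − μ)/σ. The
five bins partition the reals with boundary ties assigned inward (more
normative): z > 2; 1 < z ≤ 2; −1 ≤ z ≤ 1; −2 ≤ z < −1; z < −2. Punishment
rows report the negated distance so larger = stronger punishment-side
response; categories are assigned to reward rows only. Norm references
built from fewer than 10 subjects trigger an instability warning.

**Group statistics.** Pearson chi-square of homogeneity without continuity
correction on the 5-bin category table (groups: TD_test vs clinical,
TD_train vs TD_test, TD_test vs each diagnosis flag — a comorbid subject
appears in each diagnosis-specific comparison). Collapsed schemes: `low3`
(normative, −2..−1, <−2) and `high3` (normative, +1..+2, >+2), dropping
out-of-scheme subjects with the count reported. All-zero columns are
dropped with a warning and the df adjusted — deficient bins can be empty
in small TD samples — rather than erroring. Correlations are Pearson r of
reward (and separately punishment) DFH with phenotype variables, default
filter TD_test ∪ clinical, pairwise-complete, two-sided p with
0.05/0.01/0.005 tiers; fewer than 3 complete pairs marks the result
not-computable. Severity comparisons are Welch two-sample t between the
normative bin and the deficient group (< −2 s.d. by default; < −1
optionally); for two groups the one-way ANOVA F is t², so Welch is the
conservative common currency. Sensitivity analyses refit the comparison
as OLS outcome ~ group + age + IQ + sex on complete cases, reporting the
group coefficient beside the unadjusted test; collinear covariates skip
the adjusted model with a reason. No multiple-testing correction is
applied by default, matching starred-threshold reporting; a
Benjamini–Hochberg helper is available.

## The synthetic cohort generator

There is no shareable participant data, so the generator is a first-class
module that encodes the statistical structure the analysis assumes — it is
the package's test bench and defines the conditions under which every
calibration claim is made. Cell values are additive:

    x[s, c, r] = u_s + 1[c=reward]·g_s·δʳᵉʷ_r + 1[c=punishment]·δᵖᵘⁿ_r + ε

with subject effect u_s ~ N(0, 0.5), residual ε ~ N(0, 1), region
baselines 0, δʳᵉʷ = 1 on 20 reward-preferring regions, δᵖᵘⁿ = 1 on 14
disjoint punishment-preferring regions (the punishment response *exceeds*
the reward response there, matching the red/blue partition the selection
signs record). TD subjects have gain g = 1; each clinical subject draws a
primary diagnosis uniformly, adds comorbid flags at rate 0.3 each, and
gets g = min over carried diagnoses of {CD 0.4, ADHD 0.5, MDD 0.6,
GAD 0.8} — attenuation touches only the reward condition. Sample sizes
default to 65/39/195. Symptom scales are affine in the attenuation,
score = intercept + β·(1 − g) + noise truncated to the instrument range,
with positive β only on the scales meant to track reward integrity
(conduct problems, reactive aggression, callous-unemotional traits,
hyperactivity/ADHD, depression/emotional problems, neglect) and β = 0 for
anxiety, irritability, proactive aggression, abuse and substance-use
scales. Intercepts, slopes and noise s.d. were chosen once as plausible
values for adolescent self-report instruments; demographics are sampled
independently of features (configurable confounding switches exist for
testing the sensitivity analysis). This is deliberately the *simplest*
model under which the analysis's claims hold by construction, which makes
parameter recovery a meaningful check of the pipeline — and means passing
tests certify the machinery, not the realism of fMRI noise: no spatial
correlation between regions, no scanner drift or motion artifacts, no
heavy-tailed residuals, no measurement unreliability in the scales.

## Validation studies and problem sizes

The repeated-cohort studies (shared by the test suite and
`scripts/acceptance.py`) use 60-region cohorts that keep the full
discriminative structure (20 + 14 regions) and a compact penalty grid
(8 C values, 4 inner folds) per cohort; the single-cohort recovery study
keeps the full 412-region design and default grid. Chosen sizes: feature
recovery and selection null 20 seeds each; permutation null of the CV
accuracy 50 seeds at 40 subjects against the central 95% binomial band;
category-test power 100 cohorts; type-I calibration 1000 cohorts with all
gains at 1; symptom-coupling recovery 20 seeds. Determinism: one global
seed fans out to stage seeds via `SeedSequence` spawning (fixed order:
simulate, select, cv), reductions are computed on contiguous arrays so
results do not depend on DataFrame memory layout, and a rerun with the
same config and seed reproduces byte-identical outputs; the `stats` stage
consumes the written intermediates, so re-running it alone from disk
reproduces `stats.json` exactly.

## Known limitations

DFH categories inherit the noise of a 65-subject norm reference; the ±1/±2
boundaries are sharp, so near-boundary subjects are unstable across
refits. The SVM compresses its own training spread along w, so the
training s.d. slightly understates held-out spread and both test groups
drift outward in z symmetrically. Chi-square p values rely on asymptotic
expected counts that are small in the extreme bins for a 39-subject test
sample (the 1000-cohort calibration shows the realized type-I rate stays
near nominal). The generator's independence assumptions above mean
real-data performance claims require real data.
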