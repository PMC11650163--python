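# rewarddfh

Functional-classifier analysis of reward responsiveness for adolescent
psychiatry research: train a linear support-vector classifier that
separates parcel-level BOLD responses to **received reward** vs **received
punishment** in typically-developing (TD) adolescents, score any
individual by the signed **distance from the hyperplane (DFH)** of their
reward response, norm that distance against the TD training distribution
into five s.d. categories, and test whether clinical groups (conduct
disorder, ADHD, depression, generalized anxiety) are over-represented
among deficient reward responders and whether DFH tracks symptom severity.

The package is aimed at computational-psychiatry researchers who want a
leakage-safe, reproducible implementation of this normative-modelling
workflow. Because raw participant data of this kind cannot be shared, a
synthetic cohort generator with the assumed statistical structure is a
first-class module: every stage is testable, and every calibration claim
is made against cohorts the generator draws.

## The method

For standardized, selected feature vectors x the classifier is the
soft-margin linear SVM minimizing ½‖w‖² + C·Σᵢξᵢ; an individual's DFH is

    d = (w·x + b) / ‖w‖₂ ,

oriented so the reward side is positive. With μ, σ the mean and sample
s.d. of the TD training sample's reward distances, each subject's normed
score z = (d − μ)/σ falls into one of five bins
(>+2, +1..+2, −1..+1, −2..−1, <−2); z < −2 marks a **deficient** reward
response. Feature selection before the SVM is an L1-penalized (lasso)
conditional-logistic classification of condition on within-subject
difference vectors, with the penalty chosen by subject-grouped
cross-validated log-loss under the one-standard-error rule. Downstream:
Pearson chi-square tests on the category × group contingency tables,
pairwise-complete Pearson correlations of DFH with symptom scales, and
Welch t comparisons of symptom severity between normative and deficient
responders (with OLS covariate-adjusted sensitivity versions). See
`docs/methods.md` for the full account.

## Worked example

```python
from rewarddfh import SimulationConfig, analyze_cohort, simulate_cohort

cohort = simulate_cohort(SimulationConfig(seed=1))   # 65 TD train / 39 TD test / 195 clinical
bundle = analyze_cohort(cohort.features, cohort.phenotypes, seed=1)

cv = bundle.cv
print(f"accuracy {100*cv.accuracy:.2f}%, sensitivity {100*cv.sensitivity:.2f}%, "
      f"specificity {100*cv.specificity:.2f}%")
print(f"{bundle.selection.n_selected} regions selected")
full5 = bundle.tests["contingency"]["td_test_vs_clinical"]["full5"]
print(f"TD_test vs clinical 5-bin: chi2({full5['df']}, N={full5['n']}) "
      f"= {full5['statistic']:.2f}, p = {full5['p']:.2g}")
```

prints (seed 1):

```
accuracy 98.46%, sensitivity 100.00%, specificity 96.92%
23 regions selected
TD_test vs clinical 5-bin: chi2(3, N=234) = 41.30, p = 5.7e-09
```

Reading: the classifier separates the two conditions almost perfectly in
held-out TD subjects (the simulated effect sizes make the conditions
nearly separable); the 23 selected regions are drawn almost entirely from
the generator's 34 truly discriminative ones and carry the hyperplane;
and the clinical group's category distribution differs
sharply from the independent TD sample — clinical subjects pile up below
−1/−2 s.d., i.e. their reward responses sit abnormally close to (or past)
the hyperplane. One empty extreme bin was dropped from the chi-square
with the df adjusted, hence df 3. The `examples/` directory has one
narrative script per capability (simulation, selection + training,
norming, group statistics, the one-call pipeline).

There is also a thin command line:

```bash
rewarddfh simulate --out-dir data/ --seed 1
rewarddfh run --config run.yaml --out-dir results/
```

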