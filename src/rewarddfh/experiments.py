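"""Repeated-cohort calibration and recovery experiments.

These are the package's validation studies, shared by the test suite and
the acceptance script: feature recovery at high signal-to-noise, the
pure-noise selection null, the permutation null of the grouped CV
accuracy, statistical power and type-I calibration of the category
chi-square, and symptom-coupling recovery. Each experiment simulates many
cohorts, runs the relevant pipeline stages from scratch on each, and
summarizes.

The repeated runs use a reduced problem size chosen once for tractability
on a single CPU: 60-region cohorts (10 reward- and 7 punishment-preferring
regions) and a compact penalty grid (8 log-spaced C values, 4 inner CV
folds) for the per-cohort lasso; the single-cohort recovery experiment
keeps the full 412-region design and default 50-point grid. Seeds fan out
from one base seed through ``SeedSequence`` spawning.
"""
from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy import stats as sps

from . import features as feat
from . import stats
from .classifier import grouped_cv_evaluate
from .errors import DegenerateDataError
from .pipeline import analyze_cohort
from .synthetic import REWARD, SimulationConfig, simulate_cohort

__all__ = [
    "REDUCED_SELECTION",
    "reduced_config",
    "feature_recovery",
    "null_selection_sizes",
    "permutation_cv_null",
    "category_power",
    "category_type1",
    "symptom_coupling",
]

REDUCED_SELECTION = {"penalty_grid": np.logspace(-2, 1, 8).tolist(), "folds": 4}


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1, dtype=np.uint32)[0] % (2**31)) for c in ss.spawn(n)]


def reduced_config(seed: int, **overrides) -> SimulationConfig:
    """60-region cohort used by the repeated-cohort experiments.

    Only the total feature count is reduced; the discriminative structure
    (20 reward-preferring, 14 punishment-preferring regions, default
    effect sizes and attenuations) is the same as the full design.
    """
    kwargs = dict(
        n_regions=60,
        reward_regions=tuple(range(20)),
        punishment_regions=tuple(range(20, 34)),
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def _fit_selection(cohort, seed: int, selection_kwargs: dict):
    train = cohort.phenotypes.loc[
        cohort.phenotypes["group"] == "TD_train", "subject_id"
    ].tolist()
    std = feat.fit_standardizer(cohort.features, train)
    X, y, g = feat.training_matrix(std.transform(cohort.features), train)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return feat.select_features(X, y, g, seed=seed, **selection_kwargs)


def feature_recovery(
    n_seeds: int = 20,
    delta: float = 1.5,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> dict:
    """Lasso recovery at high SNR on the full 412-region design.

    For each seed: simulate a cohort with the stated effect size and noise,
    run standardization + selection on the 65 TD training subjects, and
    score the fraction of selected regions that are truly discriminative
    (the generator's 34 reward/punishment regions).
    """
    precisions, sizes = [], []
    for s in _child_seeds(seed, n_seeds):
        cohort = simulate_cohort(SimulationConfig(
            seed=s, delta_reward=delta, delta_punishment=delta,
            noise_sd=noise_sd, n_td_test=2, n_clinical=2,
        ))
        sel = _fit_selection(cohort, s, {})
        truth = set(cohort.truth["reward_regions"]) | set(
            cohort.truth["punishment_regions"]
        )
        sizes.append(sel.n_selected)
        precisions.append(
            float(np.mean([r in truth for r in sel.region_ids]))
            if sel.region_ids else np.nan
        )
    return {
        "mean_precision": float(np.nanmean(precisions)),
        "precisions": precisions,
        "mean_size": float(np.mean(sizes)),
        "n_seeds": n_seeds,
    }


def null_selection_sizes(n_seeds: int = 20, seed: int = 0) -> dict:
    """Selection sizes on pure-noise cohorts (all effect sizes zero)."""
    sizes = []
    for s in _child_seeds(seed, n_seeds):
        cohort = simulate_cohort(SimulationConfig(
            seed=s, delta_reward=0.0, delta_punishment=0.0,
            n_td_test=2, n_clinical=2,
        ))
        try:
            sel = _fit_selection(cohort, s, {})
            sizes.append(sel.n_selected)
        except DegenerateDataError:
            sizes.append(0)
    return {"sizes": sizes, "median_size": float(np.median(sizes)), "n_seeds": n_seeds}


def permutation_cv_null(
    n_seeds: int = 50,
    n_subjects: int = 40,
    folds: int = 10,
    seed: int = 0,
    selection_kwargs: dict | None = None,
) -> dict:
    """Grouped-CV accuracy under within-subject label permutation.

    Condition labels are swapped within each subject's pair with
    probability 1/2, destroying the condition signal while preserving the
    paired structure; accuracy should then fall inside the central 95%
    binomial band around 1/2 for the 2*n_subjects pooled predictions.
    """
    selection_kwargs = dict(REDUCED_SELECTION if selection_kwargs is None
                            else selection_kwargs)
    n_obs = 2 * n_subjects
    lo, hi = sps.binom.interval(0.95, n_obs, 0.5)
    accs, inside = [], 0
    for s in _child_seeds(seed, n_seeds):
        cohort = simulate_cohort(reduced_config(
            s, n_td_train=n_subjects, n_td_test=2, n_clinical=2,
        ))
        rng = np.random.default_rng(s + 1)
        features = cohort.features.copy()
        for subj, swap in zip(
            features["subject_id"].unique(), rng.random(n_subjects + 4) < 0.5
        ):
            if swap:
                mask = features["subject_id"] == subj
                features.loc[mask, "condition"] = (
                    features.loc[mask, "condition"].map(
                        {"reward": "punishment", "punishment": "reward"}
                    )
                )
        train = cohort.phenotypes.loc[
            cohort.phenotypes["group"] == "TD_train", "subject_id"
        ].tolist()
        cv = grouped_cv_evaluate(
            features, train, k=folds, seed=s, selection_kwargs=selection_kwargs
        )
        accs.append(cv.accuracy)
        if lo / n_obs <= cv.accuracy <= hi / n_obs:
            inside += 1
    return {
        "accuracies": accs,
        "fraction_in_band": inside / n_seeds,
        "band": [lo / n_obs, hi / n_obs],
        "n_seeds": n_seeds,
    }


def _cohort_chi_square(cohort, seed: int, scheme: str,
                       selection_kwargs: dict) -> tuple[float, dict]:
    """p value of the TD_test-vs-clinical category test on one cohort,
    plus the below -1 proportions per group."""
    bundle = analyze_cohort(
        cohort.features, cohort.phenotypes, seed=seed,
        selection_kwargs=selection_kwargs, run_cv=False, run_stats=False,
    )
    groups = stats.groups_from_phenotypes(
        cohort.phenotypes, ["TD_test", "clinical"]
    )
    table = stats.category_table(bundle.dfh, groups)
    low = {}
    for label, row in zip(table.row_labels, table.counts):
        low[label] = (row[0] + row[1]) / row.sum()  # below -1 s.d. mass
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        collapsed = stats.collapse_bins(table, scheme)
        res = stats.chi_square(collapsed, scheme=scheme)
    return res.p, low


def category_power(
    n_cohorts: int = 100, alpha: float = 0.05, seed: int = 0,
    selection_kwargs: dict | None = None,
) -> dict:
    """Power of the low-response collapsed chi-square under the default
    attenuations, and how often the clinical group carries more below -1
    mass than TD_test. Reduced 60-region cohorts."""
    selection_kwargs = dict(REDUCED_SELECTION if selection_kwargs is None
                            else selection_kwargs)
    rejections = 0
    clinical_lower = 0
    for s in _child_seeds(seed, n_cohorts):
        cohort = simulate_cohort(reduced_config(s))
        p, low = _cohort_chi_square(cohort, s, "low3", selection_kwargs)
        rejections += p < alpha
        clinical_lower += low["clinical"] > low["TD_test"]
    return {
        "power": rejections / n_cohorts,
        "fraction_clinical_more_deficient": clinical_lower / n_cohorts,
        "alpha": alpha,
        "n_cohorts": n_cohorts,
    }


def category_type1(
    n_cohorts: int = 1000, alpha: float = 0.05, seed: int = 0,
    selection_kwargs: dict | None = None,
) -> dict:
    """Type-I rate of the 5-bin chi-square with all attenuations at 1
    (clinical indistinguishable from TD). Reduced 60-region cohorts."""
    selection_kwargs = dict(REDUCED_SELECTION if selection_kwargs is None
                            else selection_kwargs)
    lam1 = {d: 1.0 for d in ("CD", "ADHD", "MDD", "GAD")}
    rejections = 0
    for s in _child_seeds(seed, n_cohorts):
        cohort = simulate_cohort(reduced_config(s, attenuation=lam1))
        p, _ = _cohort_chi_square(cohort, s, "full5", selection_kwargs)
        rejections += p < alpha
    return {
        "type1_rate": rejections / n_cohorts,
        "alpha": alpha,
        "n_cohorts": n_cohorts,
    }


def symptom_coupling(
    n_seeds: int = 20,
    scales: Sequence[str] = ("SDQ-CP", "CDI", "Conners-ADHD"),
    seed: int = 0,
    selection_kwargs: dict | None = None,
) -> dict:
    """Recovery of the generator's symptom coupling through the pipeline.

    For each seed: the reward-DFH correlation of each coupled scale should
    be negative (stronger symptoms with weaker reward response), and the
    deficient bin's scale mean should exceed the normative bin's.
    """
    selection_kwargs = dict(REDUCED_SELECTION if selection_kwargs is None
                            else selection_kwargs)
    neg_corr = {sc: 0 for sc in scales}
    elevated = {sc: 0 for sc in scales}
    usable = {sc: 0 for sc in scales}
    for s in _child_seeds(seed, n_seeds):
        cohort = simulate_cohort(reduced_config(s, missing_rate=0.0))
        bundle = analyze_cohort(
            cohort.features, cohort.phenotypes, seed=s,
            selection_kwargs=selection_kwargs, run_cv=False, run_stats=False,
        )
        results = stats.correlate_dfh(
            bundle.dfh, cohort.phenotypes, list(scales)
        )
        for r in results:
            if r.dfh_condition == REWARD and r.computable:
                neg_corr[r.variable] += r.r < 0
        for sc in scales:
            try:
                cmp = stats.compare_symptom_severity(bundle.dfh, cohort.phenotypes, sc)
                usable[sc] += 1
                elevated[sc] += cmp.means[1] > cmp.means[0]
            except DegenerateDataError:
                pass
    return {
        "fraction_negative_correlation": {
            sc: neg_corr[sc] / n_seeds for sc in scales
        },
        "fraction_deficient_elevated": {
            sc: (elevated[sc] / usable[sc]) if usable[sc] else float("nan")
            for sc in scales
        },
        "n_seeds": n_seeds,
    }
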