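"""Standardizer and lasso selection: leakage, shrinkage, recovery."""
import numpy as np
import pandas as pd
import pytest

from rewarddfh import (
    fit_standardizer,
    select_features,
    simulate_cohort,
    training_matrix,
)
from rewarddfh.errors import DegenerateDataError
from rewarddfh.features import FeatureSelection

from conftest import SMALL_SELECTION, small_config


def _train_xyg(cohort):
    train = cohort.phenotypes.loc[
        cohort.phenotypes["group"] == "TD_train", "subject_id"
    ].tolist()
    std = fit_standardizer(cohort.features, train)
    return std, *training_matrix(std.transform(cohort.features), train)


def test_standardizer_self_transform_is_zero_one(small_cohort):
    train = small_cohort.phenotypes.loc[
        small_cohort.phenotypes["group"] == "TD_train", "subject_id"
    ].tolist()
    std = fit_standardizer(small_cohort.features, train)
    assert std.n_obs == 2 * len(train)
    X, _, _ = training_matrix(std.transform(small_cohort.features), train)
    assert np.max(np.abs(X.mean(axis=0))) < 1e-10
    assert np.max(np.abs(X.std(axis=0, ddof=1) - 1)) < 1e-10


def test_standardizer_heldout_means_nonzero(small_cohort):
    """Applied to subjects it never saw, column means are generally != 0."""
    ph = small_cohort.phenotypes
    train = ph.loc[ph["group"] == "TD_train", "subject_id"].tolist()
    clin = ph.loc[ph["group"] == "clinical", "subject_id"].tolist()
    std = fit_standardizer(small_cohort.features, train)
    Xc, _, _ = training_matrix(std.transform(small_cohort.features), clin)
    assert np.max(np.abs(Xc.mean(axis=0))) > 0.05


def test_constant_column_rejected_by_name(small_cohort):
    feats = small_cohort.features.copy()
    feats["region_001"] = 3.14
    train = small_cohort.phenotypes.loc[
        small_cohort.phenotypes["group"] == "TD_train", "subject_id"
    ].tolist()
    with pytest.raises(DegenerateDataError, match="region_001"):
        fit_standardizer(feats, train)


def test_standardizer_uses_training_rows_only(small_cohort):
    """Permuting non-training rows never changes the fit (no leakage)."""
    ph = small_cohort.phenotypes
    train = ph.loc[ph["group"] == "TD_train", "subject_id"].tolist()
    std_a = fit_standardizer(small_cohort.features, train)
    scrambled = small_cohort.features.copy()
    other = ~scrambled["subject_id"].isin(train)
    regions = [c for c in scrambled.columns if c not in ("subject_id", "condition")]
    scrambled.loc[other, regions] = -999.0
    std_b = fit_standardizer(scrambled, train)
    pd.testing.assert_series_equal(std_a.means, std_b.means)
    pd.testing.assert_series_equal(std_a.sds, std_b.sds)


def test_strong_penalty_limit_gives_empty_flagged_selection(small_cohort):
    std, X, y, g = _train_xyg(small_cohort)
    with pytest.warns(UserWarning, match="empty"):
        sel = select_features(X, y, g, penalty_grid=[1e-6, 1e-5], folds=4, seed=0)
    assert sel.empty and sel.n_selected == 0


def test_selection_no_leakage_from_nontraining_rows(small_cohort):
    """Byte-identical selection when test/clinical rows are corrupted."""
    std, X, y, g = _train_xyg(small_cohort)
    sel_a = select_features(X, y, g, seed=3, **SMALL_SELECTION)
    scrambled = small_cohort.features.copy()
    train = small_cohort.phenotypes.loc[
        small_cohort.phenotypes["group"] == "TD_train", "subject_id"
    ].tolist()
    other = ~scrambled["subject_id"].isin(train)
    regions = [c for c in scrambled.columns if c not in ("subject_id", "condition")]
    scrambled.loc[other, regions] = 123.0
    std2 = fit_standardizer(scrambled, train)
    X2, y2, g2 = training_matrix(std2.transform(scrambled), train)
    sel_b = select_features(X2, y2, g2, seed=3, **SMALL_SELECTION)
    assert sel_a.to_dict() == sel_b.to_dict()


def test_grid_endpoints_monotone_in_cardinality(small_cohort):
    """The strongest penalty on the grid selects no more regions than the
    weakest (tested at the endpoints only; the path need not be monotone)."""
    from rewarddfh.features import _l1_fit, _paired_differences

    std, X, y, g = _train_xyg(small_cohort)
    D, _ = _paired_differences(
        np.asarray(X, float), np.asarray(y), np.asarray(g)
    )
    Xp = np.vstack([D, -D])
    yp = np.concatenate([np.ones(len(D)), -np.ones(len(D))])
    n_strong = np.count_nonzero(_l1_fit(Xp, yp, 1e-3, fit_intercept=False).coef_)
    n_weak = np.count_nonzero(_l1_fit(Xp, yp, 10.0, fit_intercept=False).coef_)
    assert n_strong <= n_weak


def test_selected_signs_match_region_roles(small_cohort):
    """Reward-preferring regions get positive coefficients, punishment-
    preferring ones negative (the red/blue partition)."""
    std, X, y, g = _train_xyg(small_cohort)
    sel = select_features(X, y, g, seed=1, **SMALL_SELECTION)
    rew = set(small_cohort.truth["reward_regions"])
    pun = set(small_cohort.truth["punishment_regions"])
    for region, sign in sel.signs.items():
        if region in rew:
            assert sign > 0, region
        elif region in pun:
            assert sign < 0, region


def test_selection_round_trip():
    sel = FeatureSelection(
        region_ids=["a", "b"], signs={"a": 1, "b": -1},
        coefficients={"a": 0.5, "b": -0.25}, penalty=0.1,
        penalty_grid=[0.01, 0.1, 1.0], folds=4, seed=9,
    )
    assert FeatureSelection.from_dict(sel.to_dict()).to_dict() == sel.to_dict()


def test_high_snr_recovery_small():
    """At high SNR the selected set is dominated by truly discriminative
    regions (compact 3-seed version of the recovery study)."""
    precs = []
    for seed in range(3):
        cohort = simulate_cohort(small_config(
            seed=100 + seed, delta_reward=1.5, delta_punishment=1.5, noise_sd=0.5,
        ))
        _, X, y, g = _train_xyg(cohort)
        sel = select_features(X, y, g, seed=seed, **SMALL_SELECTION)
        truth = set(cohort.truth["reward_regions"]) | set(
            cohort.truth["punishment_regions"]
        )
        assert sel.n_selected > 0
        precs.append(np.mean([r in truth for r in sel.region_ids]))
    assert np.mean(precs) >= 0.8
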