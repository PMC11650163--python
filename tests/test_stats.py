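"""Contingency, correlation, Welch and covariate-adjusted statistics."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rewarddfh import stats as gs
from rewarddfh.errors import DegenerateDataError, ValidationError
from rewarddfh.norming import CATEGORIES


def brute_force_chi2(counts):
    """Independent oracle: sum (O - E)^2 / E with E from the margins."""
    counts = np.asarray(counts, float)
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    expected = row @ col / counts.sum()
    return float(((counts - expected) ** 2 / expected).sum())


def _dfh_frame(records):
    """records: list of (subject_id, z) reward rows."""
    return pd.DataFrame({
        "subject_id": [s for s, _ in records],
        "condition": "reward",
        "d": [z for _, z in records],
        "z": [z for _, z in records],
        "category": [
            "below_minus2" if z < -2 else
            "minus2_to_minus1" if z < -1 else
            "normative" if z <= 1 else
            "plus1_to_plus2" if z <= 2 else "above_plus2"
            for _, z in records
        ],
    })


def test_category_table_direct_binning():
    """3 TD at z=0 vs 2 clinical at z=-3 -> [[0,0,3,0,0],[2,0,0,0,0]]."""
    dfh = _dfh_frame([("t1", 0), ("t2", 0), ("t3", 0), ("c1", -3), ("c2", -3)])
    table = gs.category_table(
        dfh, {"TD": ["t1", "t2", "t3"], "clinical": ["c1", "c2"]}
    )
    assert table.col_labels == list(CATEGORIES)
    assert table.counts.tolist() == [[0, 0, 3, 0, 0], [2, 0, 0, 0, 0]]


def test_category_table_rejects_unknown_diagnosis(fitted_bundle, small_cohort):
    with pytest.raises(ValidationError, match="unknown"):
        gs.groups_from_phenotypes(small_cohort.phenotypes, ["TD_test", "psychosis"])


def test_category_table_rejects_empty_and_overlap():
    dfh = _dfh_frame([("a", 0), ("b", 0)])
    with pytest.raises(ValidationError, match="empty"):
        gs.category_table(dfh, {"g1": ["a"], "g2": []})
    with pytest.raises(ValidationError, match="overlap"):
        gs.category_table(dfh, {"g1": ["a"], "g2": ["a", "b"]})


def test_collapse_full5_identity():
    t = gs.ContingencyTable(["a", "b"], list(CATEGORIES),
                            np.array([[1, 2, 3, 4, 5], [5, 4, 3, 2, 1]]))
    c = gs.collapse_bins(t, "full5")
    assert c.counts.tolist() == t.counts.tolist()
    assert c.dropped == 0


def test_collapse_low3_hand_bookkeeping():
    """Column order (below -2, -2..-1, normative, +1..+2, >+2); low3 keeps
    (normative, -2..-1, below -2) and drops the high-bin subjects."""
    t = gs.ContingencyTable(["td", "cl"], list(CATEGORIES),
                            np.array([[0, 1, 3, 1, 0], [2, 3, 5, 0, 0]]))
    c = gs.collapse_bins(t, "low3")
    assert c.col_labels == ["normative", "minus2_to_minus1", "below_minus2"]
    assert c.counts.tolist() == [[3, 1, 0], [5, 3, 2]]
    assert c.dropped == 1


def test_collapse_high3_degenerate_warns():
    t = gs.ContingencyTable(["td", "cl"], list(CATEGORIES),
                            np.array([[1, 2, 3, 0, 0], [2, 3, 5, 0, 0]]))
    with pytest.warns(UserWarning, match="high3"):
        c = gs.collapse_bins(t, "high3")
    with pytest.warns(UserWarning), pytest.raises(DegenerateDataError):
        gs.chi_square(c)


def test_collapse_unknown_scheme():
    t = gs.ContingencyTable(["a", "b"], list(CATEGORIES), np.ones((2, 5), int))
    with pytest.raises(ValidationError):
        gs.collapse_bins(t, "mid3")


@pytest.mark.parametrize(
    "counts, stat, df",
    [
        ([[10, 20], [20, 10]], 6.6667, 1),
        ([[1, 2, 3], [2, 4, 6]], 0.0, 2),
        ([[2, 5, 28, 3, 1], [10, 25, 120, 25, 15]], 2.5048, 4),
    ],
)
def test_chi_square_known_tables(counts, stat, df):
    labels = [f"c{i}" for i in range(len(counts[0]))]
    t = gs.ContingencyTable(["r1", "r2"], labels, np.array(counts))
    res = gs.chi_square(t)
    assert res.statistic == pytest.approx(stat, abs=1e-3)
    assert res.statistic == pytest.approx(brute_force_chi2(counts), abs=1e-10)
    assert res.df == df
    assert res.n == int(np.sum(counts))


def test_chi_square_matches_oracle_on_random_tables():
    """1000 random small tables: Pearson statistic matches the brute-force
    sum (O-E)^2/E oracle to 1e-8."""
    rng = np.random.default_rng(12345)
    for _ in range(1000):
        r = rng.integers(2, 4)
        c = rng.integers(2, 6)
        counts = rng.integers(1, 30, size=(r, c))
        t = gs.ContingencyTable(
            [f"r{i}" for i in range(r)], [f"c{j}" for j in range(c)], counts
        )
        res = gs.chi_square(t)
        assert res.statistic == pytest.approx(brute_force_chi2(counts), abs=1e-8)
        assert res.df == (r - 1) * (c - 1)
        assert 0 <= res.p <= 1


def test_chi_square_drops_zero_columns_with_df_adjustment():
    t = gs.ContingencyTable(["a", "b"], ["c1", "c2", "c3"],
                            np.array([[5, 0, 7], [3, 0, 9]]))
    with pytest.warns(UserWarning, match="c2"):
        res = gs.chi_square(t)
    assert res.df == 1
    assert res.dropped_columns == ["c2"]


def _pheno(subjects, **cols):
    base = {"subject_id": subjects,
            "group": ["TD_test"] * len(subjects)}
    base.update(cols)
    return pd.DataFrame(base)


def test_pearson_correlations_hand_examples():
    dfh = _dfh_frame([("s1", 1.0), ("s2", 2.0), ("s3", 3.0), ("s4", 4.0)])
    pheno = _pheno(["s1", "s2", "s3", "s4"],
                   perfect=[2.0, 4.0, 6.0, 8.0], partial=[1.0, 3.0, 2.0, 4.0])
    res = gs.correlate_dfh(dfh, pheno, ["perfect", "partial"],
                           subjects=["s1", "s2", "s3", "s4"])
    rew = {r.variable: r for r in res if r.dfh_condition == "reward"}
    assert rew["perfect"].r == pytest.approx(1.0)
    assert rew["partial"].r == pytest.approx(0.8)  # 4/5 by hand
    assert rew["partial"].n == 4


def test_correlation_pairwise_complete_and_tiers():
    dfh = _dfh_frame([(f"s{i}", float(i)) for i in range(30)])
    rng = np.random.default_rng(0)
    vals = np.arange(30) * -1.0 + rng.normal(0, 1, 30)
    vals[:3] = np.nan
    pheno = _pheno([f"s{i}" for i in range(30)], scale=vals)
    res = gs.correlate_dfh(dfh, pheno, ["scale"],
                           subjects=[f"s{i}" for i in range(30)])
    rew = next(r for r in res if r.dfh_condition == "reward")
    assert rew.n == 27
    assert rew.r < -0.9
    assert rew.tier == "0.005"


def test_correlation_not_computable_below_three_pairs():
    dfh = _dfh_frame([("s1", 1.0), ("s2", 2.0), ("s3", 3.0)])
    pheno = _pheno(["s1", "s2", "s3"], scale=[1.0, np.nan, np.nan])
    res = gs.correlate_dfh(dfh, pheno, ["scale"], subjects=["s1", "s2", "s3"])
    assert all(not r.computable for r in res)


def test_welch_hand_example():
    """typical {1,2,3} vs deficient {4,5,6}: t = -3.674 (hand Welch)."""
    dfh = _dfh_frame([("t1", 0), ("t2", 0), ("t3", 0),
                      ("d1", -3), ("d2", -3), ("d3", -3)])
    pheno = _pheno(["t1", "t2", "t3", "d1", "d2", "d3"],
                   scale=[1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    res = gs.compare_symptom_severity(dfh, pheno, "scale",
                                      subjects=pheno["subject_id"].tolist())
    assert res.t == pytest.approx(-3.674, abs=1e-3)
    assert res.means == [pytest.approx(2.0), pytest.approx(5.0)]
    assert res.ns == [3, 3]
    # Welch equals scipy's on the same data
    t_ref, p_ref = sps.ttest_ind([1, 2, 3], [4, 5, 6], equal_var=False)
    assert res.t == pytest.approx(float(t_ref))
    assert res.p == pytest.approx(float(p_ref))


def test_welch_identical_groups_t_zero():
    dfh = _dfh_frame([("t1", 0), ("t2", 0), ("d1", -3), ("d2", -3)])
    pheno = _pheno(["t1", "t2", "d1", "d2"], scale=[1.0, 2.0, 1.0, 2.0])
    res = gs.compare_symptom_severity(dfh, pheno, "scale",
                                      subjects=pheno["subject_id"].tolist())
    assert res.t == pytest.approx(0.0)


def test_deficient_definition_widens_group():
    dfh = _dfh_frame([("t1", 0), ("t2", 0), ("m1", -1.5), ("m2", -1.5),
                      ("d1", -3), ("d2", -3)])
    pheno = _pheno(["t1", "t2", "m1", "m2", "d1", "d2"],
                   scale=[1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    narrow = gs.compare_symptom_severity(dfh, pheno, "scale",
                                         subjects=pheno["subject_id"].tolist())
    wide = gs.compare_symptom_severity(dfh, pheno, "scale",
                                       deficient_def="below_minus1",
                                       subjects=pheno["subject_id"].tolist())
    assert narrow.ns == [2, 2]
    assert wide.ns == [2, 4]


def test_covariate_adjustment_absorbs_confounded_outcome():
    """Outcome exactly equal to a covariate: group coefficient ~ 0."""
    rng = np.random.default_rng(4)
    n = 60
    group = pd.Series(np.repeat([0, 1], n // 2), name="grp")
    age = pd.Series(rng.normal(15, 2, n) + group * 2, name="age")
    res = gs.covariate_adjusted_comparison(
        age.rename("outcome"), group, pd.DataFrame({"age": age})
    )
    assert res.adjusted_coef == pytest.approx(0.0, abs=1e-8)
    assert abs(res.t) > 2  # unadjusted comparison sees the confound


def test_covariate_adjustment_matches_unadjusted_when_independent():
    rng = np.random.default_rng(5)
    n = 400
    group = pd.Series(np.repeat([0, 1], n // 2))
    outcome = pd.Series(1.0 * group + rng.normal(0, 1, n), name="scale")
    cov = pd.DataFrame({"age": rng.normal(15, 2, n), "IQ": rng.normal(100, 12, n)})
    res = gs.covariate_adjusted_comparison(outcome, group, cov)
    unadjusted_diff = res.means[1] - res.means[0]
    assert res.adjusted_coef == pytest.approx(unadjusted_diff, abs=0.15)


def test_collinear_covariates_skip_adjustment():
    rng = np.random.default_rng(6)
    n = 40
    group = pd.Series(np.repeat([0, 1], n // 2))
    outcome = pd.Series(rng.normal(size=n), name="y")
    age = rng.normal(15, 2, n)
    cov = pd.DataFrame({"age": age, "age2": 2 * age})
    res = gs.covariate_adjusted_comparison(outcome, group, cov)
    assert res.adjusted_skipped == "collinear covariates"
    assert res.adjusted_coef is None


def test_benjamini_hochberg_monotone():
    adj = gs.benjamini_hochberg([0.001, 0.01, 0.04, 0.5])
    assert all(a >= p for a, p in zip(adj, [0.001, 0.01, 0.04, 0.5]))
    assert adj == sorted(adj)
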