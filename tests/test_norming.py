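"""DFH geometry, norm reference identities, and the five s.d. bins."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from rewarddfh import (
    build_norm_reference,
    categorize,
    score_cohort,
    signed_distance,
)
from rewarddfh.classifier import Hyperplane
from rewarddfh.errors import DegenerateDataError, ValidationError
from rewarddfh.norming import CATEGORIES, NormReference


def _plane(w, b):
    return Hyperplane(weights=np.asarray(w, float), intercept=float(b),
                      region_ids=[f"x{i}" for i in range(len(w))], C=1.0)


def test_on_plane_point_distance_zero():
    plane = _plane([1.0, -2.0], 3.0)
    x = np.array([1.0, 2.0])  # w.x + b = 1 - 4 + 3 = 0
    assert signed_distance(plane, x) == pytest.approx(0.0, abs=1e-12)


def test_distance_parallel_to_weights():
    assert signed_distance(_plane([3.0, 4.0], 0.0), [3.0, 4.0]) == pytest.approx(5.0)


def test_distance_matches_numeric_projection():
    """d = (w.x+b)/||w|| equals the minimal Euclidean distance to the plane
    found by numeric projection (independent geometric oracle)."""
    plane = _plane([1.0, 1.0], -1.0)
    x = np.array([2.0, 0.0])
    d = signed_distance(plane, x)
    assert d == pytest.approx(0.70711, abs=1e-5)

    def dist_on_plane(p):
        return np.linalg.norm(p - x)

    cons = {"type": "eq", "fun": lambda p: p @ plane.weights + plane.intercept}
    res = minimize(dist_on_plane, x0=np.zeros(2), constraints=[cons], tol=1e-12)
    assert abs(d) == pytest.approx(res.fun, abs=1e-6)


def test_distance_dimension_mismatch():
    with pytest.raises(ValidationError):
        signed_distance(_plane([1.0, 2.0], 0.0), [1.0, 2.0, 3.0])


def test_norm_reference_hand_example():
    ref = build_norm_reference([1.0, 2.0, 3.0])
    assert ref.mu == pytest.approx(2.0)
    assert ref.sigma == pytest.approx(1.0)  # ddof=1
    assert ref.n == 3


def test_norm_reference_degenerate_inputs():
    with pytest.raises(DegenerateDataError):
        build_norm_reference([5.0, 5.0, 5.0])
    with pytest.raises(DegenerateDataError):
        build_norm_reference([1.0])


def test_self_norming_identity():
    rng = np.random.default_rng(3)
    d = rng.normal(2.0, 1.7, size=65)
    ref = build_norm_reference(d)
    z = ref.z(d)
    assert abs(z.mean()) < 1e-10
    assert abs(z.std(ddof=1) - 1) < 1e-10


@pytest.mark.parametrize(
    "z, expected",
    [
        (0.0, "normative"),
        (-2.5, "below_minus2"),
        (1.0, "normative"),
        (-1.0, "normative"),
        (-2.0, "minus2_to_minus1"),
        (2.0, "plus1_to_plus2"),
        (2.0000001, "above_plus2"),
        (-1.0000001, "minus2_to_minus1"),
    ],
)
def test_category_boundaries_tie_inward(z, expected):
    assert categorize(z) == expected


def test_boundary_scan_epsilon():
    """Exhaustive scan of +-1, +-2 +- 1e-9: ties go to the inner bin."""
    eps = 1e-9
    assert categorize(1 - eps) == categorize(1) == "normative"
    assert categorize(1 + eps) == "plus1_to_plus2"
    assert categorize(-1 + eps) == categorize(-1) == "normative"
    assert categorize(-1 - eps) == "minus2_to_minus1"
    assert categorize(2 - eps) == categorize(2) == "plus1_to_plus2"
    assert categorize(2 + eps) == "above_plus2"
    assert categorize(-2 + eps) == categorize(-2) == "minus2_to_minus1"
    assert categorize(-2 - eps) == "below_minus2"


@settings(max_examples=300, derandomize=True)
@given(st.floats(min_value=-1e6, max_value=1e6, allow_nan=False))
def test_categories_partition_reals(z):
    """Exactly one of the five categories fires for any finite z."""
    cat = categorize(z)
    assert cat in CATEGORIES
    hits = sum(
        [
            z < -2 and cat == "below_minus2",
            -2 <= z < -1 and cat == "minus2_to_minus1",
            -1 <= z <= 1 and cat == "normative",
            1 < z <= 2 and cat == "plus1_to_plus2",
            z > 2 and cat == "above_plus2",
        ]
    )
    assert hits == 1


def test_categorize_rejects_non_finite():
    with pytest.raises(ValidationError):
        categorize(float("nan"))


def test_category_invariant_under_hyperplane_rescaling(fitted_bundle, small_cohort):
    """Rescaling (w, b) by c > 0 leaves distances, z and categories
    unchanged (both distance and reference rescale together)."""
    std = fitted_bundle.standardizer.transform(small_cohort.features)
    plane = fitted_bundle.hyperplane
    scaled = Hyperplane(
        weights=plane.weights * 4.2, intercept=plane.intercept * 4.2,
        region_ids=plane.region_ids, C=plane.C,
    )
    a = score_cohort(std, plane, fitted_bundle.norm_reference)
    b = score_cohort(std, scaled, fitted_bundle.norm_reference)
    assert np.allclose(a["d"], b["d"])
    assert (a["category"] == b["category"]).all()


def test_score_cohort_layout(fitted_bundle, small_cohort):
    dfh = fitted_bundle.dfh
    assert set(dfh.columns) == {"subject_id", "condition", "d", "z", "category"}
    rew = dfh[dfh["condition"] == "reward"]
    pun = dfh[dfh["condition"] == "punishment"]
    assert rew["category"].isin(CATEGORIES).all()
    assert (pun["category"] == "").all()
    assert pun["z"].isna().all()
    # training rewards self-norm to mean 0, sd 1
    train = small_cohort.phenotypes.loc[
        small_cohort.phenotypes["group"] == "TD_train", "subject_id"
    ]
    z_train = rew.set_index("subject_id").loc[train, "z"]
    assert abs(z_train.mean()) < 1e-10
    assert abs(z_train.std(ddof=1) - 1) < 1e-10


def test_punishment_dfh_sign_convention(fitted_bundle, small_cohort):
    """Punishment rows report the negated signed distance, so stronger
    punishment-side responses score higher."""
    std = fitted_bundle.standardizer.transform(small_cohort.features)
    pun_rows = std[std["condition"] == "punishment"]
    raw = signed_distance(
        fitted_bundle.hyperplane, pun_rows[fitted_bundle.hyperplane.region_ids]
    )
    reported = fitted_bundle.dfh[fitted_bundle.dfh["condition"] == "punishment"]["d"]
    assert np.allclose(reported.to_numpy(), -raw)
    assert reported.mean() > 0  # punishment rows sit on the punishment side


def test_clinical_mean_z_decreases_with_gain():
    """Clinical mean normed reward z is negative and monotone in the
    attenuation gain (averaged over seeds)."""
    from rewarddfh import analyze_cohort
    from rewarddfh.synthetic import DIAGNOSES, simulate_cohort
    from conftest import SMALL_SELECTION, small_config

    means = {lam: [] for lam in (1.0, 0.7, 0.4)}
    for seed in range(3):
        for lam in means:
            cohort = simulate_cohort(small_config(
                seed=200 + seed, attenuation={d: lam for d in DIAGNOSES},
            ))
            bundle = analyze_cohort(
                cohort.features, cohort.phenotypes, seed=seed,
                selection_kwargs=SMALL_SELECTION, run_cv=False, run_stats=False,
            )
            rew = bundle.dfh[bundle.dfh["condition"] == "reward"]
            clin = cohort.phenotypes.loc[
                cohort.phenotypes["group"] == "clinical", "subject_id"
            ]
            means[lam].append(
                rew.set_index("subject_id").loc[clin, "z"].mean()
            )
    m = {lam: np.mean(v) for lam, v in means.items()}
    assert m[1.0] > m[0.7] > m[0.4]
    assert m[0.4] < 0
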