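"""Downstream group statistics on DFH records.

Covers the analysis stages that follow normative scoring: contingency
tables of the five s.d. categories across groups with Pearson chi-square
tests (optionally collapsed to the low-response or high-response triplet),
Pearson correlations between DFH and phenotype variables (pairwise
complete, with the 0.05/0.01/0.005 significance tiers), Welch t
comparisons of symptom severity between typical and deficient reward
responders, and OLS covariate-adjusted sensitivity re-analyses.

No multiple-testing correction is applied by default, matching the
starred-threshold reporting style; a Benjamini-Hochberg helper is
available for callers who want it.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, ValidationError
from .norming import CATEGORIES
from .synthetic import DIAGNOSES, PUNISHMENT, REWARD

__all__ = [
    "ContingencyTable",
    "TestResult",
    "CorrelationResult",
    "GroupComparisonResult",
    "groups_from_phenotypes",
    "category_table",
    "collapse_bins",
    "chi_square",
    "correlate_dfh",
    "compare_symptom_severity",
    "covariate_adjusted_comparison",
    "benjamini_hochberg",
]

COLLAPSE_SCHEMES = ("full5", "low3", "high3")
_LOW3 = ("normative", "minus2_to_minus1", "below_minus2")
_HIGH3 = ("normative", "plus1_to_plus2", "above_plus2")


@dataclass
class ContingencyTable:
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray
    dropped: int = 0          # subjects outside a collapsed scheme's bins

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValidationError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValidationError("negative counts")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_dict(self) -> dict:
        return {
            "row_labels": self.row_labels,
            "col_labels": self.col_labels,
            "counts": self.counts.tolist(),
            "dropped": self.dropped,
        }


@dataclass
class TestResult:
    statistic: float
    df: int
    p: float
    n: int
    test: str
    scheme: str = "full5"
    dropped_columns: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic, "df": self.df, "p": self.p,
            "n": self.n, "test": self.test, "scheme": self.scheme,
            "dropped_columns": self.dropped_columns,
        }


def _tier(p: float) -> str:
    if p < 0.005:
        return "0.005"
    if p < 0.01:
        return "0.01"
    if p < 0.05:
        return "0.05"
    return "ns"


@dataclass
class CorrelationResult:
    variable: str
    dfh_condition: str
    r: float
    p: float
    n: int
    tier: str
    computable: bool = True

    def to_dict(self) -> dict:
        return {
            "variable": self.variable, "dfh_condition": self.dfh_condition,
            "r": self.r, "p": self.p, "n": self.n, "tier": self.tier,
            "computable": self.computable,
        }


@dataclass
class GroupComparisonResult:
    scale: str
    group_labels: list[str]
    means: list[float]
    sds: list[float]
    ns: list[int]
    t: float
    df: float
    p: float
    adjusted_coef: float | None = None
    adjusted_p: float | None = None
    adjusted_skipped: str | None = None

    def to_dict(self) -> dict:
        return {
            "scale": self.scale, "group_labels": self.group_labels,
            "means": self.means, "sds": self.sds, "ns": self.ns,
            "t": self.t, "df": self.df, "p": self.p,
            "adjusted_coef": self.adjusted_coef, "adjusted_p": self.adjusted_p,
            "adjusted_skipped": self.adjusted_skipped,
        }


def groups_from_phenotypes(
    phenotypes: pd.DataFrame, spec: Sequence[str]
) -> dict[str, list[str]]:
    """Resolve group names to subject-id lists.

    Names may be the cohort groups (TD_train, TD_test, clinical) or a
    diagnosis flag (CD, ADHD, MDD, GAD); a comorbid subject appears in
    each diagnosis-specific group it carries.
    """
    out: dict[str, list[str]] = {}
    for name in spec:
        if name in ("TD_train", "TD_test", "clinical"):
            ids = phenotypes.loc[phenotypes["group"] == name, "subject_id"]
        elif name in DIAGNOSES:
            if name not in phenotypes.columns:
                raise ValidationError(f"diagnosis column {name!r} not in phenotypes")
            ids = phenotypes.loc[phenotypes[name].astype(bool), "subject_id"]
        else:
            raise ValidationError(f"unknown group or diagnosis: {name!r}")
        out[name] = ids.tolist()
    return out


def _reward_categories(dfh: pd.DataFrame) -> pd.Series:
    rew = dfh[dfh["condition"] == REWARD]
    return pd.Series(rew["category"].to_numpy(), index=rew["subject_id"].to_numpy())


def category_table(
    dfh: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
) -> ContingencyTable:
    """Counts of subjects per five s.d. category for each named group.

    ``groups`` maps a row label to its subject ids (see
    :func:`groups_from_phenotypes`). Groups within one table must be
    disjoint; each group must be non-empty and scored.
    """
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    cats = _reward_categories(dfh)
    seen: set[str] = set()
    rows = []
    for label, ids in groups.items():
        ids = list(ids)
        if not ids:
            raise ValidationError(f"empty group: {label!r}")
        overlap = seen & set(ids)
        if overlap:
            raise ValidationError(
                f"groups overlap within one table: {sorted(overlap)[:5]}"
            )
        seen |= set(ids)
        missing = [s for s in ids if s not in cats.index]
        if missing:
            raise ValidationError(
                f"group {label!r}: subjects without reward DFH: {missing[:5]}"
            )
        sub = cats.loc[ids]
        rows.append([int((sub == c).sum()) for c in CATEGORIES])
    return ContingencyTable(
        row_labels=list(groups), col_labels=list(CATEGORIES),
        counts=np.array(rows),
    )


def collapse_bins(table: ContingencyTable, scheme: str) -> ContingencyTable:
    """Collapse a full 5-bin table to a low- or high-response triplet.

    low3 keeps (normative, minus2_to_minus1, below_minus2); high3 keeps
    (normative, plus1_to_plus2, above_plus2); subjects in the discarded
    bins are dropped and counted in ``dropped``.
    """
    if scheme not in COLLAPSE_SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}; use one of {COLLAPSE_SCHEMES}")
    if scheme == "full5":
        return ContingencyTable(
            row_labels=list(table.row_labels), col_labels=list(table.col_labels),
            counts=table.counts.copy(), dropped=0,
        )
    keep = _LOW3 if scheme == "low3" else _HIGH3
    idx = [table.col_labels.index(c) for c in keep]
    counts = table.counts[:, idx]
    dropped = int(table.counts.sum() - counts.sum())
    if (counts[:, 1:].sum(axis=0) == 0).all():
        warnings.warn(
            f"{scheme}: all non-normative bins empty in every group; "
            "chi-square test would be degenerate", stacklevel=2,
        )
    return ContingencyTable(
        row_labels=list(table.row_labels), col_labels=list(keep),
        counts=counts, dropped=dropped,
    )


def chi_square(table: ContingencyTable, scheme: str | None = None) -> TestResult:
    """Pearson chi-square of homogeneity, no continuity correction.

    All-zero columns (expected count zero) are dropped with a warning and
    the degrees of freedom adjusted; an all-zero row is an error (empty
    group). df = (r - 1)(c - 1) on the tested table.
    """
    counts = table.counts
    if counts.shape[0] < 2:
        raise ValidationError("need >= 2 rows")
    if (counts.sum(axis=1) == 0).any():
        raise DegenerateDataError("all-zero row (empty group)")
    col_ok = counts.sum(axis=0) > 0
    dropped_cols = [c for c, ok in zip(table.col_labels, col_ok) if not ok]
    if dropped_cols:
        warnings.warn(
            f"dropping all-zero column(s) {dropped_cols}; df adjusted",
            stacklevel=2,
        )
        counts = counts[:, col_ok]
    if counts.shape[1] < 2:
        raise DegenerateDataError("fewer than 2 non-degenerate columns")
    stat, p, df, _ = sps.chi2_contingency(counts, correction=False)
    return TestResult(
        statistic=float(stat), df=int(df), p=float(p), n=int(counts.sum()),
        test="pearson_chi_square",
        scheme=scheme or ("full5" if len(table.col_labels) == 5 else "custom"),
        dropped_columns=dropped_cols,
    )


def _subject_dfh(dfh: pd.DataFrame, condition: str) -> pd.Series:
    rows = dfh[dfh["condition"] == condition]
    return pd.Series(rows["d"].to_numpy(), index=rows["subject_id"].to_numpy())


def correlate_dfh(
    dfh: pd.DataFrame,
    phenotypes: pd.DataFrame,
    variables: Sequence[str],
    subjects: Sequence[str] | None = None,
) -> list[CorrelationResult]:
    """Pearson correlations of reward and punishment DFH with phenotypes.

    Default subject filter is the test samples (TD_test plus clinical);
    pairs with missing values are excluded per variable, and a variable
    with fewer than 3 complete pairs is flagged not-computable.
    """
    if subjects is None:
        subjects = phenotypes.loc[
            phenotypes["group"].isin(["TD_test", "clinical"]), "subject_id"
        ].tolist()
    pheno = phenotypes.set_index("subject_id").loc[list(subjects)]
    results = []
    for condition in (REWARD, PUNISHMENT):
        d = _subject_dfh(dfh, condition).reindex(subjects)
        for var in variables:
            if var not in pheno.columns:
                raise ValidationError(f"variable {var!r} not in phenotypes")
            v = pd.to_numeric(pheno[var], errors="coerce")
            mask = d.notna().to_numpy() & v.notna().to_numpy()
            n = int(mask.sum())
            if n < 3:
                results.append(CorrelationResult(
                    variable=var, dfh_condition=condition, r=float("nan"),
                    p=float("nan"), n=n, tier="ns", computable=False,
                ))
                continue
            r, p = sps.pearsonr(d.to_numpy()[mask], v.to_numpy()[mask])
            results.append(CorrelationResult(
                variable=var, dfh_condition=condition, r=float(r), p=float(p),
                n=n, tier=_tier(float(p)),
            ))
    return results


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    t, p = sps.ttest_ind(a, b, equal_var=False)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    na, nb = len(a), len(b)
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    return float(t), float(df), float(p)


def compare_symptom_severity(
    dfh: pd.DataFrame,
    phenotypes: pd.DataFrame,
    scale: str,
    deficient_def: str = "below_minus2",
    subjects: Sequence[str] | None = None,
) -> GroupComparisonResult:
    """Welch t test of a symptom scale: typical vs deficient responders.

    Typical = the normative bin; deficient = below -2 s.d. (default) or
    everything below -1 s.d. (``deficient_def="below_minus1"``). Subject
    filter defaults to TD_test plus clinical.
    """
    if deficient_def not in ("below_minus2", "below_minus1"):
        raise ValidationError(f"unknown deficient_def {deficient_def!r}")
    if scale not in phenotypes.columns:
        raise ValidationError(f"scale {scale!r} not in phenotypes")
    if subjects is None:
        subjects = phenotypes.loc[
            phenotypes["group"].isin(["TD_test", "clinical"]), "subject_id"
        ].tolist()
    cats = _reward_categories(dfh).reindex(subjects)
    scores = pd.to_numeric(
        phenotypes.set_index("subject_id").loc[list(subjects), scale],
        errors="coerce",
    )
    deficient_bins = (
        {"below_minus2"} if deficient_def == "below_minus2"
        else {"below_minus2", "minus2_to_minus1"}
    )
    typ = scores[(cats == "normative").to_numpy() & scores.notna().to_numpy()]
    def_ = scores[cats.isin(deficient_bins).to_numpy() & scores.notna().to_numpy()]
    if len(typ) < 2 or len(def_) < 2:
        raise DegenerateDataError(
            f"group too small for {scale}: typical n={len(typ)}, deficient n={len(def_)}"
        )
    t, df, p = _welch(typ.to_numpy(), def_.to_numpy())
    return GroupComparisonResult(
        scale=scale, group_labels=["typical", "deficient"],
        means=[float(typ.mean()), float(def_.mean())],
        sds=[float(typ.std(ddof=1)), float(def_.std(ddof=1))],
        ns=[int(len(typ)), int(len(def_))],
        t=t, df=df, p=p,
    )


def covariate_adjusted_comparison(
    outcome: pd.Series,
    group: pd.Series,
    covariates: pd.DataFrame,
) -> GroupComparisonResult:
    """OLS sensitivity analysis: outcome ~ group + covariates.

    Rows with any missing value are dropped (complete cases). Reports the
    group coefficient and its two-sided test alongside the unadjusted
    Welch comparison. Collinear covariates skip the adjusted model with a
    reason, keeping the unadjusted result.
    """
    import statsmodels.api as sm

    df_all = pd.concat(
        [outcome.rename("outcome"), group.rename("group_ind"), covariates], axis=1
    )
    # encode any non-numeric covariate (e.g. sex) as categorical dummies
    enc = pd.get_dummies(df_all, drop_first=True, dtype=float)
    enc = enc.apply(pd.to_numeric, errors="coerce").dropna()
    if enc["group_ind"].nunique() != 2:
        raise ValidationError("group must be a two-level indicator")
    g_vals = sorted(enc["group_ind"].unique())
    a = enc.loc[enc["group_ind"] == g_vals[0], "outcome"].to_numpy()
    b = enc.loc[enc["group_ind"] == g_vals[1], "outcome"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise DegenerateDataError("need >= 2 complete cases per group")
    t, dfree, p = _welch(a, b)
    base = GroupComparisonResult(
        scale=str(outcome.name or "outcome"),
        group_labels=[str(g_vals[0]), str(g_vals[1])],
        means=[float(a.mean()), float(b.mean())],
        sds=[float(np.std(a, ddof=1)), float(np.std(b, ddof=1))],
        ns=[len(a), len(b)], t=t, df=dfree, p=p,
    )
    X = enc.drop(columns=["outcome"])
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        base.adjusted_skipped = "collinear covariates"
        return base
    fit = sm.OLS(enc["outcome"], Xc).fit()
    base.adjusted_coef = float(fit.params["group_ind"])
    base.adjusted_p = float(fit.pvalues["group_ind"])
    return base


def benjamini_hochberg(pvalues: Sequence[float]) -> list[float]:
    """BH-adjusted p values (off by default everywhere; opt-in helper)."""
    from statsmodels.stats.multitest import multipletests

    return list(multipletests(list(pvalues), method="fdr_bh")[1])
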