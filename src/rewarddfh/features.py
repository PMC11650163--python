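"""Training-sample standardization and L1-penalized feature selection.

The classifier operates on z-scored region features. The standardizer is
fit on the TD training observations only (both conditions pooled, so the
reward/punishment contrast survives scaling) and then applied unchanged to
every other row — no statistics leak from test or clinical subjects.

Feature selection is the lasso stage: an L1-penalized logistic
classification of condition (reward vs punishment) over a log-spaced grid
of inverse penalties C, with the penalty chosen by subject-grouped
cross-validated log-loss under the one-standard-error rule. A subject's
two condition rows never straddle CV folds, so fold performance is an
honest out-of-subject estimate. Regions with nonzero coefficients at the
chosen penalty form the selected set; positive coefficients mark
reward-preferring regions, negative ones punishment-preferring.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss

from .errors import DegenerateDataError, ValidationError
from .synthetic import REWARD

__all__ = ["Standardizer", "FeatureSelection", "fit_standardizer", "select_features",
           "default_penalty_grid", "training_matrix"]


def default_penalty_grid(num: int = 50) -> np.ndarray:
    """Log-spaced inverse-penalty (C) grid, strongest penalty first."""
    return np.logspace(-3, 1, num)


@dataclass
class Standardizer:
    """Per-region mean/s.d. estimated from the training observations."""

    means: pd.Series
    sds: pd.Series
    n_obs: int

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        """Z-score the region columns of ``table`` (metadata columns kept)."""
        regions = list(self.means.index)
        missing = [r for r in regions if r not in table.columns]
        if missing:
            raise ValidationError(f"table lacks standardized regions: {missing[:10]}")
        out = table.copy()
        out[regions] = (table[regions] - self.means) / self.sds
        return out

    def to_dict(self) -> dict:
        return {
            "means": self.means.to_dict(),
            "sds": self.sds.to_dict(),
            "n_obs": self.n_obs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(means=pd.Series(d["means"]), sds=pd.Series(d["sds"]),
                   n_obs=int(d["n_obs"]))


def _region_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ("subject_id", "condition")]


def training_matrix(
    features: pd.DataFrame, training_ids
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Rows of the training subjects as (X frame, labels, subject groups).

    Labels are +1 for reward rows, -1 for punishment rows; groups are the
    subject ids, for grouped CV.
    """
    ids = set(training_ids)
    rows = features[features["subject_id"].isin(ids)]
    missing = ids - set(rows["subject_id"])
    if missing:
        raise ValidationError(f"training subjects absent from features: {sorted(missing)[:10]}")
    y = np.where(rows["condition"].to_numpy() == REWARD, 1, -1)
    groups = rows["subject_id"].to_numpy()
    return rows[_region_columns(rows)], y, groups


def fit_standardizer(features: pd.DataFrame, training_ids) -> Standardizer:
    """Estimate per-region mean/s.d. over the 2·n_train training rows only."""
    if len(set(training_ids)) < 2:
        raise DegenerateDataError("need at least 2 training subjects")
    X, _, _ = training_matrix(features, training_ids)
    # reductions on a materialized array: summation order (hence the exact
    # float result) must not depend on the frame's internal block layout
    vals = np.ascontiguousarray(X.to_numpy(dtype=float))
    means = pd.Series(vals.mean(axis=0), index=X.columns)
    sds = pd.Series(vals.std(axis=0, ddof=1), index=X.columns)
    constant = sds.index[sds <= 0].tolist()
    if constant:
        raise DegenerateDataError(
            f"constant training column(s): {constant[:10]}"
        )
    return Standardizer(means=means, sds=sds, n_obs=len(X))


@dataclass
class FeatureSelection:
    """Outcome of the lasso stage."""

    region_ids: list[str]
    signs: dict[str, int]          # +1 reward-preferring, -1 punishment-preferring
    coefficients: dict[str, float]
    penalty: float                 # chosen inverse penalty C
    penalty_grid: list[float]
    folds: int
    seed: int
    cv_log_loss: dict[str, list[float]] = field(default_factory=dict)
    empty: bool = False

    @property
    def n_selected(self) -> int:
        return len(self.region_ids)

    def to_dict(self) -> dict:
        return {
            "region_ids": self.region_ids,
            "signs": self.signs,
            "coefficients": self.coefficients,
            "penalty": self.penalty,
            "penalty_grid": list(self.penalty_grid),
            "folds": self.folds,
            "seed": self.seed,
            "empty": self.empty,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSelection":
        return cls(
            region_ids=list(d["region_ids"]),
            signs={k: int(v) for k, v in d["signs"].items()},
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            penalty=float(d["penalty"]),
            penalty_grid=[float(c) for c in d["penalty_grid"]],
            folds=int(d["folds"]),
            seed=int(d["seed"]),
            empty=bool(d.get("empty", False)),
        )


def _grouped_folds(groups: np.ndarray, k: int, rng: np.random.Generator):
    """Partition subjects (not rows) into k shuffled folds; yield row masks."""
    subjects = np.sort(pd.unique(groups))  # row-order independent
    if len(subjects) < k:
        raise DegenerateDataError(f"{len(subjects)} subjects < {k} folds")
    order = rng.permutation(len(subjects))
    fold_of = {}
    for pos, subj_i in enumerate(order):
        fold_of[subjects[subj_i]] = pos % k
    assignment = np.array([fold_of[g] for g in groups])
    for fold in range(k):
        yield assignment != fold, assignment == fold


def _l1_fit(
    X: np.ndarray, y: np.ndarray, C: float, fit_intercept: bool = True
) -> LogisticRegression:
    model = LogisticRegression(
        l1_ratio=1, C=C, solver="liblinear", tol=1e-6, max_iter=2000,
        fit_intercept=fit_intercept, random_state=0,
    )
    model.fit(X, y)
    return model


def _paired_differences(
    X: np.ndarray, y: np.ndarray, groups: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Within-subject reward-minus-punishment difference vectors.

    Returns (D, subjects) with one row per subject, sorted by subject id.
    The subject-level additive effect common to a subject's two condition
    rows cancels exactly in the difference.
    """
    subjects = np.sort(pd.unique(groups))
    rows = []
    for s in subjects:
        mask = groups == s
        if mask.sum() != 2 or set(y[mask]) != {-1, 1}:
            raise ValidationError(
                f"subject {s!r} must have exactly one reward and one "
                "punishment observation"
            )
        rows.append(X[mask & (y == 1)][0] - X[mask & (y == -1)][0])
    return np.asarray(rows), subjects


def select_features(
    standardized: pd.DataFrame,
    labels: np.ndarray,
    groups: np.ndarray,
    penalty_grid=None,
    folds: int = 10,
    seed: int = 0,
) -> FeatureSelection:
    """L1-penalized logistic selection with grouped CV and the 1-SE rule.

    The condition design is paired (each subject contributes one reward and
    one punishment row), so the logistic classification is fit
    conditionally on subject: on within-subject reward-minus-punishment
    difference vectors, symmetrized (each difference enters as +d with
    label +1 and -d with label -1) and without an intercept. This cancels
    the subject-level additive effect exactly, so a region enters the model
    only through its reward/punishment contrast — a region that merely
    tracks overall subject responsiveness cannot be selected. The penalty
    is chosen by subject-grouped cross-validated log-loss with the
    one-standard-error rule (most-penalized model within one s.e. of the
    best); a subject's two symmetrized rows always share a fold.

    Parameters
    ----------
    standardized
        Training observations (rows) over region columns, already z-scored.
    labels
        +1 (reward) / -1 (punishment) per row.
    groups
        Subject id per row; a subject's rows share a CV fold.
    penalty_grid
        Inverse-penalty values C; default 50 log-spaced in [1e-3, 10].
    """
    grid = np.sort(np.asarray(
        default_penalty_grid() if penalty_grid is None else penalty_grid, dtype=float))
    if grid.size == 0:
        raise ValidationError("penalty_grid is empty")
    X = np.asarray(standardized, dtype=float)
    y = np.asarray(labels)
    regions = list(standardized.columns)
    if set(np.unique(y)) != {-1, 1}:
        raise ValidationError("labels must contain both classes coded +1/-1")

    D, subjects = _paired_differences(X, y, np.asarray(groups))
    Xp = np.vstack([D, -D])
    yp = np.concatenate([np.ones(len(D)), -np.ones(len(D))])
    gp = np.concatenate([subjects, subjects])

    rng = np.random.default_rng(seed)
    fold_masks = list(_grouped_folds(gp, folds, rng))

    losses = np.full((grid.size, folds), np.nan)
    for ci, C in enumerate(grid):
        for fi, (tr, te) in enumerate(fold_masks):
            model = _l1_fit(Xp[tr], yp[tr], C, fit_intercept=False)
            prob = model.predict_proba(Xp[te])
            losses[ci, fi] = log_loss(yp[te], prob, labels=model.classes_)

    mean_loss = losses.mean(axis=1)
    se_loss = losses.std(axis=1, ddof=1) / np.sqrt(folds)
    best = int(np.argmin(mean_loss))
    # one-SE rule: the most-penalized grid point whose CV loss is within one
    # standard error of the best
    threshold = mean_loss[best] + se_loss[best]
    chosen = int(np.flatnonzero(mean_loss <= threshold)[0])
    C_chosen = float(grid[chosen])

    final = _l1_fit(Xp, yp, C_chosen, fit_intercept=False)
    coefs = final.coef_.ravel() * (1 if final.classes_[1] == 1 else -1)

    if np.all(np.abs(coefs) <= 0):
        # distinguish "shrunk to zero at this penalty" (legitimate null
        # outcome, flagged) from "no signal anywhere on a grid that probed
        # weak penalties" (error); a grid of only near-infinite penalties
        # (all C < 1) is expected to shrink everything and is not an error
        any_nonzero = any(
            np.any(_l1_fit(Xp, yp, C, fit_intercept=False).coef_ != 0)
            for C in grid[::-1]
        )
        if not any_nonzero and grid.max() >= 1.0:
            raise DegenerateDataError(
                "all-zero L1 solution at every grid point: no separable signal"
            )
        warnings.warn("selection empty at the chosen penalty", stacklevel=2)

    nz = np.flatnonzero(coefs != 0)
    selected = [regions[i] for i in nz]
    return FeatureSelection(
        region_ids=selected,
        signs={regions[i]: int(np.sign(coefs[i])) for i in nz},
        coefficients={regions[i]: float(coefs[i]) for i in nz},
        penalty=C_chosen,
        penalty_grid=grid.tolist(),
        folds=folds,
        seed=seed,
        cv_log_loss={"mean": mean_loss.tolist(), "se": se_loss.tolist()},
        empty=len(selected) == 0,
    )
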