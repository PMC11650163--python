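"""Distance-from-hyperplane (DFH) scoring and normative categorization.

The signed distance of a standardized, selected feature vector x from the
hyperplane {x : w.x + b = 0} is ``d = (w.x + b) / ||w||_2`` — Euclidean
distance in standardized-feature units, positive on the reward side by the
orientation convention. Because both numerator and denominator scale with
(w, b), the distance is invariant to rescaling of the hyperplane.

Reward-condition distances of the TD training sample define the normative
reference: their mean and sample s.d. (ddof=1) z-score every other
subject's reward distance. Five categories partition the z axis, with
boundary ties assigned to the inner (more normative) bin:

    z >  2          above_plus2       exaggerated reward response
    1 < z <= 2      plus1_to_plus2
    -1 <= z <= 1    normative
    -2 <= z < -1    minus2_to_minus1
    z < -2          below_minus2      deficient reward response

Punishment-condition DFH is reported as the negated signed distance so
that larger values mean a stronger punishment-side response; categories
are assigned to reward rows only.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import Hyperplane
from .errors import DegenerateDataError, ValidationError
from .synthetic import REWARD

__all__ = [
    "CATEGORIES",
    "NormReference",
    "signed_distance",
    "build_norm_reference",
    "categorize",
    "score_cohort",
]

# canonical ascending-z order, used by every contingency table
CATEGORIES = (
    "below_minus2",
    "minus2_to_minus1",
    "normative",
    "plus1_to_plus2",
    "above_plus2",
)


def signed_distance(hyperplane: Hyperplane, x) -> float | np.ndarray:
    """Signed Euclidean distance(s) of x (vector or rows) from the plane."""
    arr = np.asarray(x, dtype=float)
    scalar = arr.ndim == 1 and not isinstance(x, pd.DataFrame)
    d = hyperplane.decision_values(x) / hyperplane.norm
    return float(d[0]) if scalar else d


@dataclass
class NormReference:
    """Training-sample reward-DFH mean and s.d. used to norm everyone else."""

    mu: float
    sigma: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DegenerateDataError("norm reference needs >= 2 training values")
        if not self.sigma > 0:
            raise DegenerateDataError("norm reference s.d. must be > 0")

    def z(self, d) -> float | np.ndarray:
        return (np.asarray(d, dtype=float) - self.mu) / self.sigma

    def to_dict(self) -> dict:
        return {"mu": self.mu, "sigma": self.sigma, "n": self.n}

    @classmethod
    def from_dict(cls, d: dict) -> "NormReference":
        return cls(mu=float(d["mu"]), sigma=float(d["sigma"]), n=int(d["n"]))


def build_norm_reference(train_reward_distances) -> NormReference:
    """Mean and sample s.d. (ddof=1) of the TD training reward distances."""
    d = np.asarray(train_reward_distances, dtype=float)
    if d.size < 2:
        raise DegenerateDataError("need >= 2 training distances")
    sigma = float(np.std(d, ddof=1))
    if not sigma > 0:
        raise DegenerateDataError("training distances are all equal")
    return NormReference(mu=float(np.mean(d)), sigma=sigma, n=int(d.size))


def categorize(z: float) -> str:
    """Map a normed reward distance to its s.d. category (ties inward)."""
    if not math.isfinite(z):
        raise ValidationError(f"non-finite normed distance: {z}")
    if z > 2:
        return "above_plus2"
    if z > 1:
        return "plus1_to_plus2"
    if z >= -1:
        return "normative"
    if z >= -2:
        return "minus2_to_minus1"
    return "below_minus2"


def score_cohort(
    standardized: pd.DataFrame,
    hyperplane: Hyperplane,
    norm_ref: NormReference,
) -> pd.DataFrame:
    """Per-row DFH records for a standardized feature table.

    Returns a frame with columns subject_id, condition, d (signed distance,
    positive = reward side; punishment rows negated so larger = stronger
    punishment response), z (reward rows only), category (reward rows only).
    """
    for col in ("subject_id", "condition"):
        if col not in standardized.columns:
            raise ValidationError(f"standardized table missing {col!r}")
    raw = signed_distance(hyperplane, standardized[hyperplane.region_ids])
    is_reward = standardized["condition"].to_numpy() == REWARD
    d = np.where(is_reward, raw, -raw)
    z = np.where(is_reward, norm_ref.z(raw), np.nan)
    category = [
        categorize(zi) if rew else ""
        for zi, rew in zip(z, is_reward)
    ]
    return pd.DataFrame(
        {
            "subject_id": standardized["subject_id"].to_numpy(),
            "condition": standardized["condition"].to_numpy(),
            "d": d,
            "z": z,
            "category": category,
        }
    )
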