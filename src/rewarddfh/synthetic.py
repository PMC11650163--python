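"""Synthetic cohort generator.

Emulates the statistical structure the downstream pipeline assumes: each
subject contributes two condition-level feature rows (reward receipt,
punishment receipt) over a fixed set of brain regions (by default 400
Schaefer cortical parcels plus 12 bilateral subcortical structures); a
subset of regions responds more strongly to reward, a disjoint subset more
strongly to punishment; clinical subjects carry psychiatric diagnosis flags
whose attenuation gains shrink the reward-condition contrast; and symptom
scale scores are coupled to the degree of that attenuation.

The generative model for the cell value of subject ``s``, condition ``c``,
region ``r`` is additive::

    x[s, c, r] = mu_r + u_s + 1[c = reward] * g_s * delta_rew_r
                       + 1[c = punishment] * delta_pun_r + eps

with subject random effect ``u_s ~ N(0, subject_sd)``, i.i.d. residual
``eps ~ N(0, noise_sd)``, region baselines ``mu_r = 0``, and a per-subject
reward gain ``g_s`` equal to 1 for typically-developing (TD) subjects and
the minimum attenuation over a clinical subject's diagnoses. Attenuation
touches only the reward condition; punishment rows are distributionally
identical across groups.

Symptom scales are affine in the attenuation: ``score = intercept +
beta * (1 - g_s) + N(0, noise)``, truncated to the instrument range, so a
scale with positive ``beta`` is elevated exactly in subjects with a
weakened reward response.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "ScaleSpec",
    "SCALE_SPECS",
    "SimulationConfig",
    "Cohort",
    "simulate_cohort",
    "default_region_labels",
]

REWARD = "reward"
PUNISHMENT = "punishment"
CONDITIONS = (REWARD, PUNISHMENT)
DIAGNOSES = ("CD", "ADHD", "MDD", "GAD")

_SUBCORTICAL = ("thalamus", "caudate", "putamen", "accumbens", "hippocampus", "amygdala")


@dataclass(frozen=True)
class ScaleSpec:
    """Range and generative parameters of one symptom scale."""

    minimum: float
    maximum: float
    intercept: float
    beta: float       # slope on (1 - g_s); 0 = uncoupled
    noise_sd: float


# Instrument ranges are the published scoring ranges; intercepts sit near
# healthy-population means; betas are nonzero only for the scales the
# analysis expects to track reward-response integrity (conduct problems,
# aggression/callousness, hyperactivity, depression/emotional problems,
# neglect), and zero for anxiety, irritability, proactive aggression,
# abuse and substance-use scales.
SCALE_SPECS: Mapping[str, ScaleSpec] = {
    "SDQ-CP": ScaleSpec(0, 10, 1.5, 6.0, 1.5),
    "RPAQ-Reactive": ScaleSpec(0, 22, 5.0, 10.0, 3.5),
    "RPAQ-Proactive": ScaleSpec(0, 24, 2.0, 0.0, 2.5),
    "Conners-ADHD": ScaleSpec(0, 30, 6.0, 14.0, 4.5),
    "SDQ-Hyperactivity": ScaleSpec(0, 10, 3.0, 5.0, 1.8),
    "SDQ-Emotional": ScaleSpec(0, 10, 2.0, 4.5, 1.8),
    "CDI": ScaleSpec(0, 54, 8.0, 16.0, 5.0),
    "SCARED-Total": ScaleSpec(0, 82, 15.0, 0.0, 8.0),
    "SCARED-GAD": ScaleSpec(0, 18, 4.0, 0.0, 2.5),
    "CTQ-Abuse": ScaleSpec(15, 75, 18.0, 0.0, 4.0),
    "CTQ-Neglect": ScaleSpec(10, 50, 13.0, 8.0, 3.5),
    "AUDIT": ScaleSpec(0, 40, 1.0, 0.0, 1.5),
    "CUDIT": ScaleSpec(0, 40, 1.0, 0.0, 1.5),
    "ICU": ScaleSpec(0, 72, 18.0, 12.0, 6.0),
    "ARI": ScaleSpec(0, 12, 2.0, 0.0, 2.0),
}

SCALE_COLUMNS = tuple(SCALE_SPECS)


def default_region_labels(n_regions: int) -> list[str]:
    """Atlas-style region labels.

    For the default 412-region layout the first 400 are Schaefer-style
    cortical parcel names and the last 12 are bilateral subcortical
    ``structure_hemisphere`` labels; any other count gets generic labels.
    """
    if n_regions == 412:
        cortical = [f"Schaefer400_{i + 1:03d}" for i in range(400)]
        subcortical = [f"{s}_{h}" for s in _SUBCORTICAL for h in ("lh", "rh")]
        return cortical + subcortical
    return [f"region_{i + 1:03d}" for i in range(n_regions)]


def _default_attenuation() -> dict[str, float]:
    return {"CD": 0.4, "ADHD": 0.5, "MDD": 0.6, "GAD": 0.8}


def _default_comorbidity() -> dict[str, float]:
    return {d: 0.3 for d in DIAGNOSES}


def _default_symptom_beta() -> dict[str, float]:
    return {name: spec.beta for name, spec in SCALE_SPECS.items()}


def _default_symptom_noise() -> dict[str, float]:
    return {name: spec.noise_sd for name, spec in SCALE_SPECS.items()}


@dataclass
class SimulationConfig:
    """Cohort design and generative parameters.

    Defaults reproduce the study design the pipeline targets: a TD training
    sample of 65, an independent TD test sample of 39, and a clinical
    sample of 195 carrying CD/ADHD/MDD/GAD flags, over 412 regions of
    which 20 prefer reward and 14 prefer punishment.
    """

    n_td_train: int = 65
    n_td_test: int = 39
    n_clinical: int = 195
    n_regions: int = 412
    reward_regions: tuple[int, ...] = tuple(range(20))
    punishment_regions: tuple[int, ...] = tuple(range(20, 34))
    delta_reward: float = 1.0
    delta_punishment: float = 1.0
    subject_sd: float = 0.5
    noise_sd: float = 1.0
    attenuation: dict[str, float] = field(default_factory=_default_attenuation)
    comorbidity_rates: dict[str, float] = field(default_factory=_default_comorbidity)
    symptom_beta: dict[str, float] = field(default_factory=_default_symptom_beta)
    symptom_noise_sd: dict[str, float] = field(default_factory=_default_symptom_noise)
    missing_rate: float = 0.02
    # Optional confounding switches for sensitivity-analysis testing:
    # shift added to clinical ages, and a common age slope on every scale.
    confound_age_shift: float = 0.0
    confound_age_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.reward_regions = tuple(int(i) for i in self.reward_regions)
        self.punishment_regions = tuple(int(i) for i in self.punishment_regions)
        self.validate()

    def validate(self) -> None:
        for name in ("n_td_train", "n_td_test", "n_clinical", "n_regions"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        rew, pun = set(self.reward_regions), set(self.punishment_regions)
        if rew & pun:
            raise ConfigError(
                f"reward_regions and punishment_regions overlap: {sorted(rew & pun)}"
            )
        for idx in rew | pun:
            if not 0 <= idx < self.n_regions:
                raise ConfigError(f"region index {idx} outside [0, {self.n_regions})")
        for dx, lam in self.attenuation.items():
            if dx not in DIAGNOSES:
                raise ConfigError(f"unknown diagnosis in attenuation map: {dx!r}")
            if not 0.0 <= lam <= 1.0:
                raise ConfigError(f"attenuation gain for {dx} must be in [0, 1], got {lam}")
        for name in ("subject_sd", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")
        for scale in self.symptom_beta:
            if scale not in SCALE_SPECS:
                raise ConfigError(f"unknown symptom scale: {scale!r}")

    def with_updates(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class Cohort:
    """Simulated cohort: feature table, phenotype table, and the realized
    ground truth (per-subject gains, per-region effect sizes) that recovery
    tests and the JSON sidecar use."""

    features: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: dict

    def __iter__(self):
        # allow ``features, phenotypes = simulate_cohort(cfg)`` unpacking;
        # truth stays accessible as an attribute
        yield self.features
        yield self.phenotypes


def _simulate_phenotypes(
    config: SimulationConfig,
    subject_ids: list[str],
    groups: list[str],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Diagnosis flags, gains, demographics and symptom scores.

    Returns the phenotype frame and the per-subject reward gain g_s.
    """
    n = len(subject_ids)
    groups_arr = np.asarray(groups)
    clinical = groups_arr == "clinical"

    flags = {d: np.zeros(n, dtype=bool) for d in DIAGNOSES}
    idx_clin = np.flatnonzero(clinical)
    # every clinical subject gets one primary diagnosis, then additional
    # comorbid flags independently at the configured rates
    primaries = rng.integers(0, len(DIAGNOSES), size=idx_clin.size)
    for j, subj_i in enumerate(idx_clin):
        flags[DIAGNOSES[primaries[j]]][subj_i] = True
    for d in DIAGNOSES:
        rate = float(config.comorbidity_rates.get(d, 0.0))
        extra = rng.random(idx_clin.size) < rate
        flags[d][idx_clin[extra]] = True

    g = np.ones(n)
    for i in idx_clin:
        lams = [config.attenuation.get(d, 1.0) for d in DIAGNOSES if flags[d][i]]
        g[i] = min(lams) if lams else 1.0

    # demographics; female rates per group match the target cohort design
    female_rate = {"TD_train": 32 / 65, "TD_test": 14 / 39, "clinical": 71 / 195}
    sex = np.where(
        rng.random(n) < np.array([female_rate[gr] for gr in groups_arr]), "F", "M"
    )
    age = np.clip(rng.normal(15.07, 2.30, size=n), 10.0, 19.0)
    age[clinical] += config.confound_age_shift
    iq = np.clip(rng.normal(102.0, 12.0, size=n) - 7.0 * clinical, 60.0, 145.0)

    data: dict[str, object] = {
        "subject_id": subject_ids,
        "group": groups,
        "age": np.round(age, 2),
        "sex": sex,
        "IQ": np.round(iq, 1),
    }
    for d in DIAGNOSES:
        data[d] = flags[d]

    one_minus_g = 1.0 - g
    for scale, spec in SCALE_SPECS.items():
        beta = float(config.symptom_beta.get(scale, 0.0))
        noise = float(config.symptom_noise_sd.get(scale, spec.noise_sd))
        score = spec.intercept + beta * one_minus_g
        score = score + config.confound_age_slope * (age - 15.0)
        if noise > 0:
            score = score + rng.normal(0.0, noise, size=n)
        score = np.clip(score, spec.minimum, spec.maximum)
        if config.missing_rate > 0:
            score = np.where(rng.random(n) < config.missing_rate, np.nan, score)
        data[scale] = np.round(score, 2)

    return pd.DataFrame(data), g


def simulate_cohort(config: SimulationConfig | None = None) -> Cohort:
    """Draw a full cohort (features + phenotypes + ground truth).

    Deterministic in ``config.seed``: identical configs give bit-identical
    tables. The feature table has exactly two rows per subject (reward and
    punishment condition) over ``n_regions`` region columns.
    """
    config = config or SimulationConfig()
    config.validate()

    ss = np.random.SeedSequence(config.seed)
    rng_feat, rng_phen = (np.random.default_rng(s) for s in ss.spawn(2))

    ids = (
        [f"td_train_{i + 1:03d}" for i in range(config.n_td_train)]
        + [f"td_test_{i + 1:03d}" for i in range(config.n_td_test)]
        + [f"clin_{i + 1:03d}" for i in range(config.n_clinical)]
    )
    groups = (
        ["TD_train"] * config.n_td_train
        + ["TD_test"] * config.n_td_test
        + ["clinical"] * config.n_clinical
    )
    n = len(ids)
    p = config.n_regions
    regions = default_region_labels(p)

    phenotypes, g = _simulate_phenotypes(config, ids, groups, rng_phen)

    delta_rew = np.zeros(p)
    delta_rew[list(config.reward_regions)] = config.delta_reward
    delta_pun = np.zeros(p)
    delta_pun[list(config.punishment_regions)] = config.delta_punishment

    u = rng_feat.normal(0.0, config.subject_sd, size=n)
    x_rew = u[:, None] + g[:, None] * delta_rew[None, :] \
        + rng_feat.normal(0.0, config.noise_sd, size=(n, p))
    x_pun = u[:, None] + delta_pun[None, :] \
        + rng_feat.normal(0.0, config.noise_sd, size=(n, p))

    # interleave so each subject's two rows are adjacent: reward first
    values = np.empty((2 * n, p))
    values[0::2] = x_rew
    values[1::2] = x_pun
    features = pd.DataFrame(values, columns=regions)
    features.insert(0, "condition", np.tile(CONDITIONS, n))
    features.insert(0, "subject_id", np.repeat(ids, 2))

    truth = {
        "gain": dict(zip(ids, g.tolist())),
        "reward_regions": [regions[i] for i in config.reward_regions],
        "punishment_regions": [regions[i] for i in config.punishment_regions],
        "delta_reward": {
            regions[i]: config.delta_reward for i in config.reward_regions
        },
        "delta_punishment": {
            regions[i]: config.delta_punishment for i in config.punishment_regions
        },
        "seed": config.seed,
    }
    return Cohort(features=features, phenotypes=phenotypes, truth=truth)
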