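"""Shared fixtures: small simulated cohorts and fitted pipeline objects.

Session-scoped where the object is expensive (a fitted analysis bundle) so
the suite stays fast; everything is generated programmatically from fixed
seeds — no stored data files.
"""
import numpy as np
import pytest

from rewarddfh import analyze_cohort
from rewarddfh.synthetic import SimulationConfig, simulate_cohort

SMALL_SELECTION = {"penalty_grid": np.logspace(-2, 1, 8).tolist(), "folds": 4}


def small_config(seed=42, **overrides):
    """Compact cohort: 30 regions (8 reward / 5 punishment), 20/10/30 subjects."""
    kwargs = dict(
        n_td_train=20, n_td_test=10, n_clinical=30, n_regions=30,
        reward_regions=tuple(range(8)), punishment_regions=tuple(range(8, 13)),
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_config())


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size default cohort (65/39/195, 412 regions)."""
    return simulate_cohort(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def fitted_bundle(small_cohort):
    """Pipeline fit on the small cohort, no CV (kept for speed)."""
    return analyze_cohort(
        small_cohort.features, small_cohort.phenotypes,
        selection_kwargs=SMALL_SELECTION, seed=42, run_cv=False,
    )
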