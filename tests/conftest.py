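"""Shared fixtures: configs, small cohorts, and session-scoped model fits."""

import numpy as np
import pytest

import satplan as sp
from satplan.cohort import GroupSpec, older_spec, sample_cohort, younger_spec
from satplan.model import FitSettings, PlanningDepthModel


@pytest.fixture(scope="session")
def config() -> sp.TaskConfig:
    return sp.TaskConfig()


@pytest.fixture(scope="session")
def small_config() -> sp.TaskConfig:
    """Reduced design: 3 blocks per condition, for fast end-to-end runs."""
    return sp.TaskConfig(
        phase_design=(((2, "low"), 3), ((2, "high"), 3), ((3, "low"), 3), ((3, "high"), 3))
    )


@pytest.fixture(scope="session")
def tiny_cohort(small_config):
    """Four subjects, 12 blocks each, mixed groups."""
    behavior, truth = sample_cohort(
        small_config, [younger_spec(2), older_spec(2)], seed=7
    )
    return behavior, truth


@pytest.fixture(scope="session")
def recovery_fit(config):
    """Parameter-recovery study: 20 subjects drawn from the default group
    regimes, full 100-block experiments, hierarchical variational fit.

    Session-scoped because the fit takes on the order of a minute; reused by
    the recovery, calibration and correlation tests.
    """
    behavior, truth = sample_cohort(config, [younger_spec(10), older_spec(10)], seed=21)
    model = PlanningDepthModel(behavior, config)
    results = model.fit(
        FitSettings(steps=3000, learning_rate=0.03, n_mc=2, n_posterior_samples=100, seed=1)
    )
    return behavior, truth, results


@pytest.fixture(scope="session")
def depth_recovery_fit(config):
    """Depth-recovery study: idealised deep planners (high beta, alpha near
    zero, maximum feasible depth every block) on discriminating blocks."""
    spec = GroupSpec(
        label="deep",
        n_subjects=10,
        beta_loc=np.log(4.0), beta_scale=0.0,
        theta_loc=0.0, theta_scale=0.0,
        alpha_loc=-4.0, alpha_scale=0.0,
        depth_policy="max",
        fixed_params={"beta": 4.0, "theta": 0.0, "alpha": 0.02},
    )
    behavior, truth = sample_cohort(config, [spec], seed=11)
    model = PlanningDepthModel(behavior, config)
    results = model.fit(
        FitSettings(steps=1500, learning_rate=0.05, n_posterior_samples=100, seed=0)
    )
    return behavior, truth, results
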