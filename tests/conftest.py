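"""Shared fixtures: study-scale synthetic behaviour is expensive enough to
generate once per session and reuse across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import reachadapt as ra


@pytest.fixture(scope="session")
def full_design() -> ra.ExperimentDesign:
    """The study design: 8 subjects x 2 tasks x 180 trials."""
    return ra.make_design(8, seed=1)


@pytest.fixture(scope="session")
def full_behavior(full_design):
    """Default-parameter behaviour for the full design (incl. 2 injected outliers)."""
    return ra.simulate_behavior(full_design)


@pytest.fixture(scope="session")
def full_kinematics(full_behavior):
    trials, traj = full_behavior
    return ra.compute_trial_kinematics(trials, traj)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
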