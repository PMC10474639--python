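"""Shared fixtures: the committed hand-checked cohort and derived tables."""

from pathlib import Path

import pytest

from cloneweight import clone_and_censor, generate_cohort
from cloneweight.emulate import EmulationConfig
from cloneweight.io import read_cohort
from cloneweight.simulate import SimulationConfig

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def hand_cohort():
    """10 hand-constructed patients; one varying binary covariate (sex)."""
    return read_cohort(DATA_DIR / "hand_cohort.csv")


@pytest.fixture(scope="session")
def hand_clones(hand_cohort):
    """The 20 clones of the hand cohort (grace 5, admin 45)."""
    return clone_and_censor(hand_cohort, EmulationConfig(5, 45))


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort reused across read-only tests."""
    return generate_cohort(SimulationConfig(n_patients=400, seed=2024))
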