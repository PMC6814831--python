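import numpy as np
import pandas as pd
import pytest

from bioticres.simulate import generate_study_dataset

# Published study-scale inputs used across tests: per-group attack rates /
# handling times, and per-availability mean Manly preferences.
STUDY_PARAMS = pd.DataFrame(
    [
        ("M. albidus", "A. albopictus", 2.507, 0.200),
        ("M. albidus", "C. pipiens", 1.820, 0.214),
        ("M. fuscus", "A. albopictus", 3.726, 0.112),
        ("M. fuscus", "C. pipiens", 5.285, 0.166),
        ("M. viridis", "A. albopictus", 2.549, 0.122),
        ("M. viridis", "C. pipiens", 1.139, 0.204),
    ],
    columns=["predator", "prey", "a", "h"],
)

STUDY_PREFERENCE = pd.DataFrame(
    [
        ("M. albidus", 0.10, 0.756),
        ("M. albidus", 0.25, 0.475),
        ("M. albidus", 0.50, 0.735),
        ("M. albidus", 0.75, 0.565),
        ("M. albidus", 0.90, 1.000),
        ("M. fuscus", 0.10, 0.618),
        ("M. fuscus", 0.25, 0.466),
        ("M. fuscus", 0.50, 0.776),
        ("M. fuscus", 0.75, 0.876),
        ("M. fuscus", 0.90, 0.773),
        ("M. viridis", 0.10, 0.285),
        ("M. viridis", 0.25, 0.830),
        ("M. viridis", 0.50, 0.816),
        ("M. viridis", 0.75, 0.711),
        ("M. viridis", 0.90, 0.773),
    ],
    columns=["predator", "prop_invader", "mean_alpha"],
)

STUDY_FECUNDITY = {"M. albidus": 0.350, "M. fuscus": 0.200, "M. viridis": 0.370}


@pytest.fixture(scope="session")
def study_params():
    return STUDY_PARAMS.copy()


@pytest.fixture(scope="session")
def study_preference():
    return STUDY_PREFERENCE.copy()


@pytest.fixture(scope="session")
def study_fecundity():
    return dict(STUDY_FECUNDITY)


@pytest.fixture(scope="session")
def synthetic_study():
    """One full simulated study (FR + switching trials + ground truth)."""
    return generate_study_dataset(seed=20240917)
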