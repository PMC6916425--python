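import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import microgliaseq as mg

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def small_counts() -> mg.CountMatrix:
    """3 genes x 4 samples with unequal depths."""
    return mg.CountMatrix(
        pd.DataFrame(
            {
                "s1": [10, 100, 4],
                "s2": [20, 200, 8],
                "s3": [12, 110, 5],
                "s4": [24, 220, 10],
            },
            index=["apoeb", "p2ry12", "hexb"],
        )
    )


@pytest.fixture
def small_design() -> mg.SampleDesign:
    return mg.SampleDesign(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3", "s4"],
                "group": ["3dpf", "3dpf", "5dpf", "5dpf"],
                "replicate": [1, 2, 1, 2],
                "species": ["zebrafish"] * 4,
            }
        )
    )


@pytest.fixture
def null_experiment():
    """Seeded two-group NB experiment with no planted effects."""
    cfg = mg.SimConfig(
        n_genes=500,
        groups={"A": 3, "B": 3},
        dispersion_a0=0.1,
        dispersion_a1=0.0,
        de_fraction=0.0,
        seed=7,
    )
    counts, design, truth = mg.simulate_experiment(cfg)
    return counts, design, truth


def pattern_signs() -> dict[str, tuple[int, int, int]]:
    """Canonical sign triples produced by each planted temporal pattern."""
    return {
        "G1": (1, 1, 0),
        "G2": (0, 1, 1),
        "G3": (-1, 0, 1),
        "G4": (-1, -1, 0),
        "G5": (0, -1, -1),
        "G6": (1, 0, -1),
    }
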