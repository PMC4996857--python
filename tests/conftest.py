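"""Shared fixtures: small seeded synthetic datasets and toy matrices."""

import numpy as np
import pandas as pd
import pytest

from cardiomat import (ExpressionMatrix, SampleTable, SimulationConfig,
                       simulate_human, simulate_mouse_pair)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast, fully-featured generator config for module-level tests."""
    return SimulationConfig(
        n_genes=400,
        frac_maturation=0.1,
        samples_per_stage_a=(8, 10, 8, 8, 20),
        samples_per_stage_b=(6, 4, 4, 4, 20),
        seed=11,
    )


@pytest.fixture(scope="session")
def mouse_pair(small_config):
    """(matrix_a, annotation_a, matrix_b, samples_a, samples_b, truth)."""
    return simulate_mouse_pair(small_config)


@pytest.fixture(scope="session")
def human_data(small_config, mouse_pair):
    truth = mouse_pair[5]
    return simulate_human(small_config, truth)


@pytest.fixture()
def toy_matrix() -> ExpressionMatrix:
    """3 features x 4 samples, plain numbers."""
    rng = np.random.default_rng(5)
    vals = pd.DataFrame(
        rng.uniform(1, 100, size=(3, 4)),
        index=["f1", "f2", "f3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(vals, feature_kind="probe", platform="toy")


@pytest.fixture()
def staged_samples() -> SampleTable:
    """8 samples over 4 stages, 2 per stage."""
    rows = []
    for i in range(8):
        rows.append({"sample_id": f"s{i}", "stage": i // 2 + 1,
                     "species": "mouse-like", "batch": f"b{i % 2}"})
    return SampleTable(pd.DataFrame(rows))
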