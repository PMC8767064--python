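import numpy as np
import pandas as pd
import pytest

import embryoeffect as ee


@pytest.fixture(scope="session")
def default_config():
    return ee.GeneratorConfig()


@pytest.fixture(scope="session")
def default_sim(default_config):
    """The full default study, simulated once per session."""
    catalog = ee.generate_catalog(default_config)
    matrix, truth, records = ee.simulate_metabolome(default_config, catalog)
    return catalog, matrix, truth, records


@pytest.fixture(scope="session")
def default_scaled(default_sim):
    _, matrix, _, _ = default_sim
    return ee.median_scale(matrix)


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down catalog for fast unit tests."""
    return ee.GeneratorConfig.with_counts(60, 12, 8, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_config):
    catalog = ee.generate_catalog(small_config)
    matrix, truth, records = ee.simulate_metabolome(small_config, catalog)
    return catalog, matrix, truth, records


def make_cell_matrix(cell_means: dict, n_reps: int = 3, feature_id: str = "F1"):
    """Build a single-feature endosperm matrix with exact replicate values.

    ``cell_means`` maps (genotype, tissue, stage) -> value; replicates are
    identical (noise-free construction).
    """
    records, cols = [], {}
    for (g, t, s), v in cell_means.items():
        for r in range(1, n_reps + 1):
            sid = f"{g}_{t}_{s}_r{r}"
            records.append(ee.SampleRecord(sid, g, t, s, r))
            cols[sid] = v
    values = pd.DataFrame([cols], index=[feature_id], dtype=float)
    values = values[[r.sample_id for r in records]]
    return ee.FeatureMatrix(values, "metabolome", records)


@pytest.fixture
def cell_matrix_factory():
    return make_cell_matrix
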