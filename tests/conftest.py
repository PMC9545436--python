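"""Shared fixtures: small synthetic landscapes and hand-built containers."""

import numpy as np
import pandas as pd
import pytest

from gfzones import (CLIMATE_VARIABLES, ClimateTable, GenotypeMatrix,
                     SimulationConfig, fit_gradient_forest, simulate_dataset)


def make_climate_table(X: np.ndarray, sample_ids=None) -> ClimateTable:
    """Wrap an (n, 20) matrix as a ClimateTable."""
    n = len(X)
    if sample_ids is None:
        sample_ids = [f"s{i:04d}" for i in range(n)]
    return ClimateTable(pd.DataFrame(
        X, columns=list(CLIMATE_VARIABLES),
        index=pd.Index(sample_ids, name="sample_id")))


def random_climate(n: int, seed: int = 0) -> ClimateTable:
    rng = np.random.default_rng(seed)
    return make_climate_table(rng.normal(size=(n, 20)))


@pytest.fixture(scope="session")
def small_landscape():
    """A 40x40 landscape with 15 populations and a few SNPs of each class."""
    cfg = SimulationConfig(grid_shape=(40, 40), n_populations=15,
                           samples_per_population=8, n_adaptive=8,
                           n_neutral=12, correlation_length=6, seed=11)
    grid, locations, table, genotypes, truth = simulate_dataset(cfg)
    return {"cfg": cfg, "grid": grid, "locations": locations,
            "climate": table, "genotypes": genotypes, "truth": truth}


@pytest.fixture(scope="session")
def small_model(small_landscape):
    """Gradient-forest model fitted on the small landscape (50 trees)."""
    return fit_gradient_forest(small_landscape["genotypes"],
                               small_landscape["climate"],
                               n_trees=50, seed=5)


@pytest.fixture
def tiny_genotypes():
    """3 samples x 2 SNPs, fully called."""
    return GenotypeMatrix(
        ["a", "b", "c"], ["p1", "p1", "p2"], ["snp1", "snp2"],
        np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]]))
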