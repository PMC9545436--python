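"""Synthetic landscape generator with known adaptive architecture.

Emulates the study design the pipeline targets: populations sampled on a
climatically heterogeneous landscape, "adaptive" SNPs whose allele
frequencies follow logistic clines in one climate variable, and "neutral"
SNPs drawn under Balding-Nichols hierarchical population structure with a
differentiation parameter F (the expected FST).  Climate variables are
smooth Gaussian random fields linearly mixed to a configured inter-variable
correlation and affinely rescaled into plausible ranges for each of the 20
predictors.

Every random draw comes from one seeded generator in a fixed call order, so
identical configurations reproduce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grids import ClimateGrid
from .io import CLIMATE_VARIABLES, ClimateTable, GenotypeMatrix

#: Plausible value ranges used to rescale standardized fields, per variable.
#: MAT and MAP follow the reported span of the BC/AB study area; the rest
#: are realistic western-Canada magnitudes for each unit.
VARIABLE_RANGES: dict[str, tuple[float, float]] = {
    "MAT": (-7.3, 10.3), "MWMT": (5.0, 20.0), "MCMT": (-25.0, 3.0),
    "TD": (8.0, 30.0), "MAP": (225.0, 8769.0), "MSP": (100.0, 1500.0),
    "AHM": (0.5, 60.0), "SHM": (10.0, 150.0), "DD_0": (0.0, 3500.0),
    "DD5": (150.0, 2500.0), "NFFD": (50.0, 300.0), "FFP": (20.0, 220.0),
    "bFFP": (100.0, 200.0), "eFFP": (200.0, 300.0), "PAS": (20.0, 2000.0),
    "EMT": (-55.0, -5.0), "EXT": (20.0, 42.0), "Eref": (300.0, 900.0),
    "CMD": (0.0, 750.0), "RH": (50.0, 85.0),
}


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic landscape.

    Defaults are the desk-scale screening design: a 100 x 100 grid of
    800 m cells, 50 populations of 20 individuals, 200 adaptive SNPs with
    cline slopes |b| in [1.5, 3] on standardized drivers, and 2000 neutral
    SNPs at Balding-Nichols F = 0.1.
    """

    grid_shape: tuple[int, int] = (100, 100)
    cell_size: float = 800.0
    n_populations: int = 50
    samples_per_population: int = 20
    total_samples: int | None = None   # uneven designs; overrides per-pop count
    n_adaptive: int = 200
    n_neutral: int = 2000
    slope_range: tuple[float, float] = (1.5, 3.0)
    intercept_range: tuple[float, float] = (-0.5, 0.5)
    driver_variables: list[str] | None = None   # None = any of the 20
    fst: float = 0.1
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    correlation_length: float = 15.0            # in cells
    inter_variable_corr: np.ndarray | float = 0.5
    adaptive_structure: bool = False  # add BN deviation to adaptive SNPs too
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.fst < 1.0:
            raise SimulationError(f"F must be in (0,1), got {self.fst}")
        lo, hi = self.slope_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
            raise SimulationError("slope_range must be finite and ordered")
        if self.correlation_length <= 0:
            raise SimulationError("correlation_length must be positive")
        if self.driver_variables:
            unknown = set(self.driver_variables) - set(CLIMATE_VARIABLES)
            if unknown:
                raise SimulationError(f"unknown driver variables: {unknown}")

    def correlation_matrix(self) -> np.ndarray:
        p = len(CLIMATE_VARIABLES)
        c = self.inter_variable_corr
        if np.isscalar(c):
            m = np.full((p, p), float(c))
            np.fill_diagonal(m, 1.0)
        else:
            m = np.asarray(c, dtype=float)
            if m.shape != (p, p):
                raise SimulationError(f"correlation matrix must be {p}x{p}")
        try:
            np.linalg.cholesky(m)
        except np.linalg.LinAlgError:
            raise SimulationError(
                "inter-variable correlation matrix is not positive definite"
            ) from None
        return m


def simulate_climate_grid(cfg: SimulationConfig) -> ClimateGrid:
    """Smooth, cross-correlated climate fields rescaled to plausible ranges."""
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    rows, cols = cfg.grid_shape
    p = len(CLIMATE_VARIABLES)
    fields = np.empty((p, rows, cols))
    for j in range(p):
        white = rng.standard_normal((rows, cols))
        smooth = gaussian_filter(white, cfg.correlation_length, mode="reflect")
        sd = smooth.std()
        if sd == 0:
            raise SimulationError("degenerate climate field (zero variance)")
        fields[j] = (smooth - smooth.mean()) / sd
    L = np.linalg.cholesky(cfg.correlation_matrix())
    mixed = np.einsum("ab,bij->aij", L, fields)
    data = np.empty_like(mixed)
    for j, name in enumerate(CLIMATE_VARIABLES):
        lo, hi = VARIABLE_RANGES[name]
        f = mixed[j]
        fmin, fmax = f.min(), f.max()
        data[j] = lo + (f - fmin) * (hi - lo) / (fmax - fmin)
    return ClimateGrid(data, list(CLIMATE_VARIABLES), cfg.cell_size)


def place_samples(cfg: SimulationConfig, grid: ClimateGrid
                  ) -> tuple[pd.DataFrame, ClimateTable]:
    """Draw population centres from valid cells; samples inherit cell climate.

    Returns (locations, climate): *locations* has one row per sample with
    sample_id, population_id and the population's (row, col) cell.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    valid = np.flatnonzero(grid.mask.ravel())
    if valid.size == 0:
        raise SimulationError("climate grid is fully masked")
    if cfg.n_populations > valid.size:
        raise SimulationError(
            f"{cfg.n_populations} populations requested but only "
            f"{valid.size} valid cells")
    cells = rng.choice(valid, size=cfg.n_populations, replace=False)
    rows, cols = np.unravel_index(cells, grid.shape)
    pop_ids = [f"P{k + 1:03d}" for k in range(cfg.n_populations)]
    if cfg.total_samples is not None:
        # distribute as evenly as possible: first (total % npop) pops get
        # one extra sample
        base, extra = divmod(cfg.total_samples, cfg.n_populations)
        if base < 1:
            raise SimulationError("total_samples gives empty populations")
        per_pop = [base + 1 if k < extra else base
                   for k in range(cfg.n_populations)]
    else:
        per_pop = [cfg.samples_per_population] * cfg.n_populations
    recs = []
    for k, pop in enumerate(pop_ids):
        for i in range(per_pop[k]):
            recs.append({
                "sample_id": f"{pop}_{i + 1:03d}", "population_id": pop,
                "row": int(rows[k]), "col": int(cols[k]),
            })
    locations = pd.DataFrame(recs)
    climate_rows = grid.data[:, locations["row"], locations["col"]].T
    table = ClimateTable(pd.DataFrame(
        climate_rows, columns=list(CLIMATE_VARIABLES),
        index=pd.Index(locations["sample_id"], name="sample_id")))
    return locations, table


def simulate_genotypes(cfg: SimulationConfig, climate: ClimateTable,
                       population_ids: list[str] | None = None
                       ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate adaptive-cline and Balding-Nichols neutral genotypes.

    Adaptive SNP j: dosage_i ~ Binomial(2, logistic(a_j + b_j z_ij)) with z
    the standardized driver variable.  Neutral SNP: ancestral frequency
    pi ~ U(0.1, 0.9); population frequency ~ Beta(pi(1-F)/F, (1-pi)(1-F)/F);
    dosages ~ Binomial(2, population frequency).

    Returns (genotypes, truth) where *truth* records each SNP's class,
    driver, intercept/slope and ancestral frequency.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    sample_ids = climate.sample_ids
    n = len(sample_ids)
    if population_ids is None:
        population_ids = [s.rsplit("_", 1)[0] for s in sample_ids]
    if len(population_ids) != n:
        raise SimulationError("population ids misaligned with climate rows")
    pops, pop_index = np.unique(population_ids, return_inverse=True)
    n_pops = len(pops)

    X = climate.matrix()
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    var_names = climate.variables
    drivers_pool = (cfg.driver_variables if cfg.driver_variables
                    else list(var_names))

    cols: list[np.ndarray] = []
    truth_rows: list[dict] = []
    # adaptive SNPs
    for j in range(cfg.n_adaptive):
        driver = drivers_pool[int(rng.integers(len(drivers_pool)))]
        b = float(rng.uniform(*cfg.slope_range) * rng.choice((-1.0, 1.0)))
        a = float(rng.uniform(*cfg.intercept_range))
        z = Z[:, var_names.index(driver)]
        p_ind = _logistic(a + b * z)
        if cfg.adaptive_structure:
            alpha = p_ind * (1 - cfg.fst) / cfg.fst
            beta = (1 - p_ind) * (1 - cfg.fst) / cfg.fst
            # population-level Balding-Nichols deviation around the cline
            pop_p = rng.beta(np.maximum(alpha, 1e-9), np.maximum(beta, 1e-9))
            p_ind = pop_p
        cols.append(rng.binomial(2, p_ind).astype(float))
        truth_rows.append({"snp_id": f"adaptive_{j + 1:05d}",
                           "class": "adaptive", "driver": driver,
                           "intercept": a, "slope": b,
                           "ancestral_freq": np.nan})
    # neutral SNPs
    for j in range(cfg.n_neutral):
        pi = float(rng.uniform(*cfg.ancestral_freq_range))
        alpha = pi * (1 - cfg.fst) / cfg.fst
        beta = (1 - pi) * (1 - cfg.fst) / cfg.fst
        pop_freq = rng.beta(alpha, beta, size=n_pops)
        cols.append(rng.binomial(2, pop_freq[pop_index]).astype(float))
        truth_rows.append({"snp_id": f"neutral_{j + 1:05d}",
                           "class": "neutral", "driver": "",
                           "intercept": np.nan, "slope": np.nan,
                           "ancestral_freq": pi})
    truth = pd.DataFrame(truth_rows)
    dosages = (np.stack(cols, axis=1) if cols
               else np.empty((n, 0)))
    genotypes = GenotypeMatrix(sample_ids, list(population_ids),
                               list(truth["snp_id"]), dosages, "custom")
    return genotypes, truth


def simulate_dataset(cfg: SimulationConfig
                     ) -> tuple[ClimateGrid, pd.DataFrame, ClimateTable,
                                GenotypeMatrix, pd.DataFrame]:
    """Full landscape: climate grid, sample placement, genotypes, truth."""
    grid = simulate_climate_grid(cfg)
    locations, table = place_samples(cfg, grid)
    genotypes, truth = simulate_genotypes(cfg, table,
                                          list(locations["population_id"]))
    return grid, locations, table, genotypes, truth


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))
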