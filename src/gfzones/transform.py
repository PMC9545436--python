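"""Climate-to-genomic-composition transformation, PCA summary and RGB map.

Each climate raster cell is pushed through the model's aggregate turnover
functions, giving a 20-band grid in cumulative-importance units whose
between-cell distances approximate expected allelic-composition turnover.
A PCA over the masked-in cells (centred, unscaled - the bands already share
the importance scale) summarizes the composition; the top three components
drive the RGB rendering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gradient_forest import GFModel
from .grids import ClimateGrid, GridError


class TransformError(ValueError):
    pass


@dataclass
class GenomicGrid:
    """Raster of transformed genomic composition plus its PCA summary."""

    bands: np.ndarray        # (n_predictors, rows, cols), cumulative-importance units
    band_names: list[str]
    mask: np.ndarray
    cell_size: float
    x_origin: float = 0.0
    y_origin: float = 0.0
    crs: str = "local-equal-area"
    scores: np.ndarray | None = None          # (n_components, rows, cols)
    variance_fractions: np.ndarray | None = None
    loadings: np.ndarray | None = None        # (n_components, n_predictors)

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands.shape[1:]

    def valid_matrix(self) -> np.ndarray:
        """Masked-in cells as (n_valid, n_bands), row-major cell order."""
        return self.bands[:, self.mask].T.copy()

    def valid_scores(self) -> np.ndarray:
        if self.scores is None:
            raise TransformError("PCA scores not computed yet")
        return self.scores[:, self.mask].T.copy()


def transform_grid(model: GFModel, grid: ClimateGrid,
                   kind: str = "linear") -> GenomicGrid:
    """Evaluate every aggregate turnover function over the climate grid.

    *kind* selects linear interpolation between turnover breakpoints
    (default) or right-continuous staircase evaluation.
    """
    missing = [p for p in model.predictor_names if p not in grid.band_names]
    if missing:
        raise TransformError(f"predictor(s) missing from grid: "
                             f"{', '.join(missing)}")
    rows, cols = grid.shape
    out = np.zeros((len(model.predictor_names), rows, cols))
    for i, p in enumerate(model.predictor_names):
        tf = model.turnover[p]
        band = grid.band(p)
        vals = tf(band[grid.mask], kind=kind)
        out[i][grid.mask] = vals
    return GenomicGrid(out, list(model.predictor_names), grid.mask.copy(),
                       grid.cell_size, grid.x_origin, grid.y_origin, grid.crs)


def transform_table(model: GFModel, X: np.ndarray,
                    kind: str = "linear") -> np.ndarray:
    """Turnover evaluation of a plain (n, n_predictors) climate matrix."""
    X = np.asarray(X, dtype=float)
    out = np.empty_like(X)
    for i, p in enumerate(model.predictor_names):
        out[:, i] = model.turnover[p](X[:, i], kind=kind)
    return out


def toy_grid_from_matrix(M: np.ndarray, band_names=None,
                         cell_size: float = 800.0) -> GenomicGrid:
    """Lay an (n, p) composition matrix out as a fully-valid 1 x n raster.

    Convenience for PCA on tabular compositions (oracle tests, site-level
    sensitivity checks).
    """
    M = np.asarray(M, dtype=float)
    n, p = M.shape
    if band_names is None:
        band_names = [f"b{j}" for j in range(p)]
    return GenomicGrid(M.T[:, None, :], list(band_names),
                       np.ones((1, n), dtype=bool), cell_size)


def pca_scores(gg: GenomicGrid, n_components: int = 3) -> GenomicGrid:
    """PCA of the transformed bands over masked-in cells (centred, unscaled).

    Sign convention: the largest-magnitude loading of each component is made
    positive, so maps are reproducible across runs and platforms.  Returns
    the same grid with scores, variance fractions and loadings attached;
    variance fractions cover *all* non-degenerate components (summing to 1),
    scores and loadings only the requested leading ones.
    """
    M = gg.valid_matrix()
    n_cells, n_bands = M.shape
    if n_cells < n_components:
        raise TransformError("fewer valid cells than requested components")
    centred = M - M.mean(axis=0)
    if not np.any(centred):
        raise TransformError("all bands constant; PCA undefined")
    # SVD of the centred matrix: right singular vectors are the loadings
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    var = svals**2
    fractions = var / var.sum()
    if n_components > n_bands:
        raise TransformError(f"requested {n_components} components for "
                             f"{n_bands} bands")
    load = vt[:n_components]
    # deterministic sign: largest-|loading| entry of each component positive
    for c in range(load.shape[0]):
        j = int(np.argmax(np.abs(load[c])))
        if load[c, j] < 0:
            load[c] = -load[c]
    sc = centred @ load.T                     # (n_valid, n_components)
    scores = np.zeros((n_components,) + gg.shape)
    scores[:, gg.mask] = sc.T
    gg.scores = scores
    gg.variance_fractions = fractions
    gg.loadings = load
    return gg


def rgb_map(gg: GenomicGrid, stretch: str = "percentile",
            percentiles: tuple[float, float] = (2.0, 98.0)
            ) -> tuple[np.ndarray, dict]:
    """Render the top-3 PC scores as an RGB image.

    Each component is linearly rescaled to [0, 255] by the chosen stretch
    ('percentile', default 2nd-98th, or 'minmax'); masked cells get alpha 0.
    Returns (image, params): image is (rows, cols, 4) uint8 RGBA and
    *params* records the per-channel stretch bounds for reproducibility.
    """
    if gg.scores is None or gg.scores.shape[0] < 3:
        raise TransformError("rgb_map needs 3 computed score bands")
    rows, cols = gg.shape
    img = np.zeros((rows, cols, 4), dtype=np.uint8)
    bounds = {}
    for c in range(3):
        vals = gg.scores[c][gg.mask]
        if stretch == "minmax":
            lo, hi = float(vals.min()), float(vals.max())
        elif stretch == "percentile":
            lo, hi = (float(np.percentile(vals, percentiles[0])),
                      float(np.percentile(vals, percentiles[1])))
        else:
            raise ValueError(f"unknown stretch {stretch!r}")
        if hi <= lo:  # constant score band: mid-gray
            import warnings

            warnings.warn(f"PC{c + 1} scores constant; mapped to 128")
            chan = np.full(vals.shape, 128, dtype=np.uint8)
            lo, hi = float(vals.min()), float(vals.min())
        else:
            chan = np.clip((vals - lo) / (hi - lo), 0.0, 1.0)
            chan = np.round(chan * 255).astype(np.uint8)
        img[..., c][gg.mask] = chan
        bounds[f"PC{c + 1}"] = (lo, hi)
    img[..., 3][gg.mask] = 255
    return img, {"stretch": stretch, "percentiles": percentiles,
                 "bounds": bounds}
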