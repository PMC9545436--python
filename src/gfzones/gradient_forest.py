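"""Gradient-forest core: per-SNP forests aggregated into turnover functions.

One regression forest is fitted per SNP (dosage 0/1/2 response, 20 climate
predictors, 200 trees).  SNPs with positive out-of-bag R-squared are
"predictive" and retained.  For each retained SNP the forest's split
impurity reductions on a predictor are scaled so they sum to that SNP's
R-squared share for the predictor (share = R2 x raw importance fraction),
which gives the conservation law

    sum over predictors of a SNP's shares  =  its OOB R2.

Aggregation across SNPs is a plain sum divided by the number of retained
SNPs, so the overall importance of a predictor is the mean partitioned R2
share, and each aggregate turnover curve ends exactly at its predictor's
overall importance.

Along each predictor's observed range the model also reports, on a shared
equal-width binning: the raw importance density I(x), the data density
d(x) (normalized to integrate to 1), and the standardized importance
f(x) = I(x) / d(x) with a density floor that prevents blow-ups where the
sampled climate is sparse.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .forest import BinnedPredictors, bin_predictors, fit_regression_forest
from .io import ClimateTable, GenotypeMatrix

log = logging.getLogger(__name__)

DEFAULT_N_TREES = 200
DEFAULT_N_BINS = 101
DEFAULT_DENSITY_FLOOR = 0.01
MIN_COMPLETE_CASES = 30
MIN_OOB_FRACTION = 0.5
_REL_TOL = 1e-9


class GradientForestError(ValueError):
    pass


@dataclass
class SNPModelFit:
    """Fit record of one SNP's regression forest."""

    snp_id: str
    oob_r2: float
    n_complete: int
    oob_fraction: float
    flagged: bool                 # True when too few samples had OOB predictions
    split_predictor: np.ndarray   # predictor index per split
    split_value: np.ndarray       # split threshold in predictor units
    split_importance: np.ndarray  # impurity reduction per split, >= 0
    predictor_names: list[str]

    @property
    def retained(self) -> bool:
        return self.oob_r2 > 0.0 and not self.flagged

    def raw_importance(self) -> np.ndarray:
        """Per-predictor sum of split impurity reductions."""
        out = np.zeros(len(self.predictor_names))
        np.add.at(out, self.split_predictor, self.split_importance)
        return out

    def r2_shares(self) -> np.ndarray:
        """OOB R2 partitioned across predictors by raw-importance fraction."""
        raw = self.raw_importance()
        total = raw.sum()
        if total <= 0.0:
            return np.zeros_like(raw)
        return self.oob_r2 * raw / total


@dataclass
class TurnoverFunction:
    """Monotone cumulative-importance curve of one predictor.

    ``breakpoints`` ascend over [observed min, observed max]; ``values``
    start at 0 and are non-decreasing.  Evaluation clamps to 0 below the
    range and to ``total`` above it.
    """

    predictor: str
    breakpoints: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.breakpoints.shape != self.values.shape:
            raise GradientForestError("breakpoints/values length mismatch")
        if np.any(np.diff(self.breakpoints) < 0):
            raise GradientForestError("breakpoints must be ascending")
        if self.values.size and (self.values[0] != 0.0 or
                                 np.any(np.diff(self.values) < -1e-12)):
            raise GradientForestError("turnover values must start at 0 and be "
                                      "non-decreasing")

    @property
    def total(self) -> float:
        return float(self.values[-1]) if self.values.size else 0.0

    def __call__(self, x, kind: str = "linear") -> np.ndarray:
        """Evaluate at x; ``kind`` is 'linear' or 'step' (right-continuous)."""
        x = np.asarray(x, dtype=float)
        if self.values.size == 0:
            return np.zeros_like(x)
        if kind == "linear":
            return np.interp(x, self.breakpoints, self.values)
        if kind == "step":
            idx = np.searchsorted(self.breakpoints, x, side="right") - 1
            idx = np.clip(idx, 0, len(self.values) - 1)
            out = self.values[idx]
            return np.where(x < self.breakpoints[0], 0.0, out)
        raise ValueError(f"unknown evaluation kind {kind!r}")


@dataclass
class GFModel:
    """Aggregated gradient-forest model over all retained SNPs."""

    predictor_names: list[str]
    fits: list[SNPModelFit]            # retained fits only
    n_input_snps: int
    bin_edges: dict[str, np.ndarray]   # per predictor, len n_bins+1
    raw_density: dict[str, np.ndarray]       # I(x) per bin
    data_density: dict[str, np.ndarray]      # d(x) per bin, integrates to 1
    standardized: dict[str, np.ndarray]      # f(x) = I/d (floored)
    floor_flags: dict[str, np.ndarray]       # bins where the floor applied
    turnover: dict[str, TurnoverFunction]
    overall_importance: "pd.Series"
    n_trees: int
    seed: int
    density_floor: float

    @property
    def n_retained(self) -> int:
        return len(self.fits)

    @property
    def retained_snp_ids(self) -> list[str]:
        return [f.snp_id for f in self.fits]

    def r2_summary(self) -> dict[str, float]:
        r2 = np.array([f.oob_r2 for f in self.fits])
        if r2.size == 0:
            return {"mean": float("nan"), "min": float("nan"),
                    "max": float("nan")}
        return {"mean": float(r2.mean()), "min": float(r2.min()),
                "max": float(r2.max())}

    def retained_table(self) -> pd.DataFrame:
        rows = []
        for f in self.fits:
            row = {"snp_id": f.snp_id, "oob_r2": f.oob_r2,
                   "n_complete": f.n_complete}
            for name, share in zip(self.predictor_names, f.r2_shares()):
                row[f"share_{name}"] = share
            rows.append(row)
        return pd.DataFrame(rows)

    # -- persistence --------------------------------------------------------

    def to_json(self, path: str | Path) -> Path:
        """Serialize curves, densities and metadata (not raw split lists)."""
        payload = {
            "predictor_names": self.predictor_names,
            "n_input_snps": self.n_input_snps,
            "n_retained": self.n_retained,
            "n_trees": self.n_trees,
            "seed": self.seed,
            "density_floor": self.density_floor,
            "r2_summary": self.r2_summary(),
            "overall_importance": {k: float(v)
                                   for k, v in self.overall_importance.items()},
            "retained": [
                {"snp_id": f.snp_id, "oob_r2": f.oob_r2,
                 "shares": [float(s) for s in f.r2_shares()]}
                for f in self.fits
            ],
            "per_predictor": {
                p: {
                    "bin_edges": self.bin_edges[p].tolist(),
                    "raw_density": self.raw_density[p].tolist(),
                    "data_density": self.data_density[p].tolist(),
                    "standardized": self.standardized[p].tolist(),
                    "floor_flags": self.floor_flags[p].astype(int).tolist(),
                    "turnover_x": self.turnover[p].breakpoints.tolist(),
                    "turnover_y": self.turnover[p].values.tolist(),
                }
                for p in self.predictor_names
            },
        }
        path = Path(path)
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GFModel":
        payload = json.loads(Path(path).read_text())
        names = payload["predictor_names"]
        fits = []
        for rec in payload["retained"]:
            shares = np.asarray(rec["shares"], dtype=float)
            r2 = rec["oob_r2"]
            # reconstruct a minimal fit whose shares reproduce the stored ones
            keep = shares > 0
            fits.append(SNPModelFit(
                snp_id=rec["snp_id"], oob_r2=r2, n_complete=-1,
                oob_fraction=1.0, flagged=False,
                split_predictor=np.flatnonzero(keep),
                split_value=np.full(int(keep.sum()), np.nan),
                split_importance=shares[keep],
                predictor_names=names,
            ))
        per = payload["per_predictor"]
        model = cls(
            predictor_names=names,
            fits=fits,
            n_input_snps=payload["n_input_snps"],
            bin_edges={p: np.asarray(per[p]["bin_edges"]) for p in names},
            raw_density={p: np.asarray(per[p]["raw_density"]) for p in names},
            data_density={p: np.asarray(per[p]["data_density"]) for p in names},
            standardized={p: np.asarray(per[p]["standardized"]) for p in names},
            floor_flags={p: np.asarray(per[p]["floor_flags"], bool)
                         for p in names},
            turnover={p: TurnoverFunction(p, np.asarray(per[p]["turnover_x"]),
                                          np.asarray(per[p]["turnover_y"]))
                      for p in names},
            overall_importance=pd.Series(payload["overall_importance"]),
            n_trees=payload["n_trees"],
            seed=payload["seed"],
            density_floor=payload["density_floor"],
        )
        return model

    def turnover_frame(self) -> pd.DataFrame:
        """Long-format table of all aggregate turnover curves (for CSV export)."""
        parts = []
        for p in self.predictor_names:
            tf = self.turnover[p]
            parts.append(pd.DataFrame({
                "predictor": p, "x": tf.breakpoints, "cumulative": tf.values,
            }))
        return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# Fitting


def fit_snp_forest(dosages: np.ndarray, climate: ClimateTable,
                   n_trees: int = DEFAULT_N_TREES, seed: int = 0,
                   snp_id: str = "snp", mtry: int | None = None,
                   binned: BinnedPredictors | None = None) -> SNPModelFit:
    """Fit one SNP's regression forest on its complete cases.

    Missing dosages (NaN) drop that sample for this SNP only; no imputation
    is performed.  Errors on constant responses or < 30 complete cases.
    """
    dosages = np.asarray(dosages, dtype=float)
    if binned is None:
        binned = bin_predictors(climate.matrix(), climate.variables)
    if len(dosages) != binned.n_samples:
        raise GradientForestError("dosage vector does not match climate rows")
    complete = ~np.isnan(dosages)
    n_complete = int(complete.sum())
    if n_complete < MIN_COMPLETE_CASES:
        raise GradientForestError(
            f"{snp_id}: only {n_complete} complete cases "
            f"(need >= {MIN_COMPLETE_CASES})")
    y = dosages[complete]
    if np.var(y) == 0.0:
        raise GradientForestError(f"{snp_id}: constant dosages, R2 undefined")
    sub = binned if complete.all() else binned.subset(np.flatnonzero(complete))
    fit = fit_regression_forest(sub, y, n_trees=n_trees, mtry=mtry, seed=seed)
    flagged = fit.oob_fraction < MIN_OOB_FRACTION
    r2 = 0.0 if flagged else fit.oob_r2(y)
    return SNPModelFit(
        snp_id=snp_id, oob_r2=r2, n_complete=n_complete,
        oob_fraction=fit.oob_fraction, flagged=flagged,
        split_predictor=fit.split_predictor, split_value=fit.split_value,
        split_importance=fit.split_importance,
        predictor_names=list(binned.names),
    )


def fit_gradient_forest(g: GenotypeMatrix, climate: ClimateTable,
                        n_trees: int = DEFAULT_N_TREES, seed: int = 0,
                        mtry: int | None = None,
                        n_bins: int = DEFAULT_N_BINS,
                        density_floor: float = DEFAULT_DENSITY_FLOOR,
                        progress: bool = False) -> GFModel:
    """Fit forests for every SNP and aggregate the retained ones.

    SNPs that cannot be fitted (constant, too few complete cases) are
    skipped with a log entry and count as not retained.  A model with zero
    retained SNPs is returned as an explicit empty model, not an error.
    """
    climate = climate.aligned_to(g.sample_ids)
    X = climate.matrix()
    binned = bin_predictors(X, climate.variables)
    fits: list[SNPModelFit] = []
    n_skipped = 0
    seeds = _snp_seeds(seed, g.n_snps)
    iterator = range(g.n_snps)
    if progress:
        from tqdm import tqdm
        iterator = tqdm(iterator, desc="fitting per-SNP forests")
    for j in iterator:
        try:
            fit = fit_snp_forest(g.dosages[:, j], climate, n_trees=n_trees,
                                 seed=int(seeds[j]), snp_id=g.snp_ids[j],
                                 mtry=mtry, binned=binned)
        except GradientForestError as exc:
            log.debug("skipping %s: %s", g.snp_ids[j], exc)
            n_skipped += 1
            continue
        if fit.retained:
            fits.append(fit)
    if n_skipped:
        log.info("skipped %d unfittable SNPs", n_skipped)
    log.info("retained %d of %d SNPs (positive OOB R2)", len(fits), g.n_snps)
    return aggregate_model(fits, X, binned.names, n_input_snps=g.n_snps,
                           n_bins=n_bins, density_floor=density_floor,
                           n_trees=n_trees, seed=seed)


def _snp_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-SNP forest seeds derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return ss.generate_state(max(n, 1), dtype=np.uint32)[:n].astype(np.int64)


# ---------------------------------------------------------------------------
# Densities and turnover


def _normalized_split_weights(fit: SNPModelFit) -> np.ndarray:
    """Split importances rescaled so each predictor's sum equals the SNP's
    partitioned R2 share for that predictor."""
    raw = fit.raw_importance()
    shares = fit.r2_shares()
    scale = np.zeros_like(raw)
    nz = raw > 0
    scale[nz] = shares[nz] / raw[nz]
    return fit.split_importance * scale[fit.split_predictor]


def raw_importance_density(fits: list[SNPModelFit], predictor: str,
                           bin_edges: np.ndarray,
                           normalize_per_snp: bool = True) -> np.ndarray:
    """Binned raw importance density I(x) for one predictor.

    Split impurity reductions of all retained fits on *predictor* are
    accumulated into the bins; with *normalize_per_snp* each SNP's splits
    are first rescaled to its partitioned R2 share (the aggregation used by
    the model), and the sum is divided by the number of fits.
    """
    if not fits:
        raise GradientForestError("no retained fits")
    bin_edges = np.asarray(bin_edges, dtype=float)
    out = np.zeros(len(bin_edges) - 1)
    for fit in fits:
        pi = fit.predictor_names.index(predictor)
        sel = fit.split_predictor == pi
        if not sel.any():
            continue
        w = (_normalized_split_weights(fit)[sel] if normalize_per_snp
             else fit.split_importance[sel])
        idx = np.clip(np.searchsorted(bin_edges, fit.split_value[sel],
                                      side="right") - 1, 0, len(out) - 1)
        np.add.at(out, idx, w)
    if normalize_per_snp:
        out /= len(fits)
    return out


def data_density(x: np.ndarray, bin_edges: np.ndarray) -> np.ndarray:
    """Histogram density of observed predictor values (integrates to 1)."""
    hist, _ = np.histogram(x, bins=bin_edges)
    width = np.diff(bin_edges)
    total = hist.sum()
    if total == 0:
        raise GradientForestError("no observations in binning range")
    return hist / (total * width)


def standardized_importance(I: np.ndarray, d: np.ndarray,
                            floor: float = DEFAULT_DENSITY_FLOOR
                            ) -> tuple[np.ndarray, np.ndarray]:
    """f(x) = I(x) / max(d(x), floor * max d); returns (f, floored_flags)."""
    I = np.asarray(I, dtype=float)
    d = np.asarray(d, dtype=float)
    if I.shape != d.shape:
        raise GradientForestError("I(x) and d(x) binnings differ")
    if np.any(I < 0) or np.any(d < 0):
        raise GradientForestError("densities must be non-negative")
    dmax = d.max() if d.size else 0.0
    floor_val = floor * dmax
    flags = d < floor_val
    denom = np.maximum(d, floor_val)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(denom > 0, I / denom, 0.0)
    return f, flags


def cumulative_importance(predictor: str, *,
                          f: np.ndarray | None = None,
                          bin_edges: np.ndarray | None = None,
                          total: float | None = None,
                          fit: SNPModelFit | None = None) -> TurnoverFunction:
    """Build a TurnoverFunction for one predictor.

    Aggregate scope: pass the binned standardized importance *f* with its
    *bin_edges* and the right-endpoint *total* (the predictor's overall
    importance); the cumulative sum over bins is rescaled to end at
    *total*.  Per-SNP scope: pass a single *fit*; the curve is the
    staircase of that SNP's normalized split weights on the predictor.
    """
    if fit is not None:
        pi = fit.predictor_names.index(predictor)
        sel = fit.split_predictor == pi
        if fit.oob_r2 <= 0.0:
            # per-SNP curves are defined for retained (positive-R2) fits
            return TurnoverFunction(predictor, np.array([0.0]),
                                    np.array([0.0]))
        w = _normalized_split_weights(fit)[sel]
        xs = fit.split_value[sel]
        order = np.argsort(xs, kind="stable")
        xs, w = xs[order], w[order]
        # collapse duplicate split values
        ux, inv = np.unique(xs, return_inverse=True)
        if len(ux) == 0:
            return TurnoverFunction(predictor, np.array([0.0]), np.array([0.0]))
        cw = np.zeros(len(ux))
        np.add.at(cw, inv, w)
        bx = np.concatenate(([ux[0]], ux))
        by = np.concatenate(([0.0], np.cumsum(cw)))
        return TurnoverFunction(predictor, bx, by)
    if f is None or bin_edges is None:
        raise GradientForestError("need either f + bin_edges or a fit")
    f = np.asarray(f, dtype=float)
    cum = np.cumsum(f)
    if cum[-1] > 0 and total is not None:
        cum = cum * (total / cum[-1])
    elif total is None:
        pass  # unscaled cumulative of f
    breakpoints = np.asarray(bin_edges, dtype=float)
    values = np.concatenate(([0.0], cum))
    return TurnoverFunction(predictor, breakpoints, values)


def overall_importance(fits: list[SNPModelFit],
                       predictor_names: list[str]) -> pd.Series:
    """Mean partitioned R2 share per predictor over retained SNPs.

    Sorted descending, ties broken alphabetically by variable name.
    """
    if not fits:
        return pd.Series(dtype=float)
    shares = np.zeros(len(predictor_names))
    for fit in fits:
        shares += fit.r2_shares()
    shares /= len(fits)
    s = pd.Series(shares, index=predictor_names)
    return s.iloc[np.lexsort((s.index, -s.to_numpy()))]


def aggregate_model(fits: list[SNPModelFit], X: np.ndarray,
                    predictor_names: list[str], n_input_snps: int,
                    n_bins: int = DEFAULT_N_BINS,
                    density_floor: float = DEFAULT_DENSITY_FLOOR,
                    n_trees: int = DEFAULT_N_TREES, seed: int = 0) -> GFModel:
    """Assemble a GFModel from retained fits and the training predictors."""
    overall = overall_importance(fits, predictor_names)
    bin_edges, raw_d, dat_d, std_f, flags, turns = {}, {}, {}, {}, {}, {}
    for j, p in enumerate(predictor_names):
        col = X[:, j]
        lo, hi = float(col.min()), float(col.max())
        if hi <= lo:
            hi = lo + 1.0
        edges = np.linspace(lo, hi, n_bins + 1)
        bin_edges[p] = edges
        dat_d[p] = data_density(col, edges)
        if fits:
            raw_d[p] = raw_importance_density(fits, p, edges)
            f, fl = standardized_importance(raw_d[p], dat_d[p], density_floor)
        else:
            raw_d[p] = np.zeros(n_bins)
            f, fl = np.zeros(n_bins), np.zeros(n_bins, bool)
        std_f[p] = f
        flags[p] = fl
        total = float(overall.get(p, 0.0)) if len(overall) else 0.0
        turns[p] = cumulative_importance(p, f=f, bin_edges=edges, total=total)
    return GFModel(
        predictor_names=list(predictor_names), fits=fits,
        n_input_snps=n_input_snps, bin_edges=bin_edges, raw_density=raw_d,
        data_density=dat_d, standardized=std_f, floor_flags=flags,
        turnover=turns, overall_importance=overall, n_trees=n_trees,
        seed=seed, density_floor=density_floor,
    )
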