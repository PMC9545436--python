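"""Config-driven orchestration of the full workflow with manifests.

Stages: simulate -> fit -> transform -> map -> zone -> compare (or "all").
Each stage reads its upstream artifacts from the output directory, writes
its own outputs plus a JSON manifest (config snapshot, input hashes, seed,
package version), and is bit-reproducible for a fixed config and master
seed.  Stage seeds are derived from the master seed through named
substreams so no stage's randomness depends on another's.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import backward_delineate, overlap_report, zone_areas
from .gradient_forest import GFModel, fit_gradient_forest
from .grids import (ClimateGrid, ZoneMap, read_climate_grid, read_zone_map,
                    write_climate_grid, write_zone_map)
from .io import (ClimateTable, filter_maf, filter_missingness, read_climate_table,
                 read_genotypes, write_climate_table, write_genotypes)
from .simulate import SimulationConfig, simulate_dataset
from .transform import GenomicGrid, pca_scores, rgb_map, transform_grid
from .zonation import (DEFAULT_K_RANGE, DEFAULT_RESTARTS, DEFAULT_SUBSAMPLE,
                       DEFAULT_THETA, cluster_scan, delineate, select_k)

log = logging.getLogger(__name__)

STAGES = ("simulate", "fit", "transform", "map", "zone", "compare")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Validated run configuration; every defaulted value is logged."""

    out_dir: str = "runs/default"
    seed: int = 0
    # inputs (empty = produced by the simulate stage)
    genotypes_path: str = ""
    climate_table_path: str = ""
    climate_grid_dir: str = ""
    reference_zones_path: str = ""
    # SNP-set handling
    set_label: str = "custom"
    maf_threshold: float = 0.05
    max_missing: float = 0.2
    # forest settings
    n_trees: int = 200
    mtry: int = 6
    n_bins: int = 101
    density_floor: float = 0.01
    # transform / zonation
    n_components: int = 3
    k_min: int = 2
    k_max: int = 16
    theta: float = DEFAULT_THETA
    subsample: int = DEFAULT_SUBSAMPLE
    n_restarts: int = DEFAULT_RESTARTS
    # comparison
    denominator: str = "reference"
    weighting: str = "area"
    correspondence: list = field(default_factory=list)
    backward_k: list = field(default_factory=list)
    # simulation (used only by the simulate stage)
    simulation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                log.info("config default: %s = %r", f.name,
                         getattr(cfg, f.name))
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage substream of the master seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)

    def simulation_config(self) -> SimulationConfig:
        sim = dict(self.simulation)
        sim.setdefault("seed", self.stage_seed("simulate"))
        if "grid_shape" in sim:
            sim["grid_shape"] = tuple(sim["grid_shape"])
        return SimulationConfig(**sim)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out: Path, stage: str, cfg: RunConfig,
                    inputs: list[Path], outputs: list[Path]) -> Path:
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": cfg.seed,
        "stage_seed": cfg.stage_seed(stage),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": cfg.to_dict(),
        "inputs": {str(p): _hash_file(p) for p in inputs if p.exists()},
        "outputs": {str(p): _hash_file(p) for p in outputs if p.exists()},
    }
    path = out / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"missing upstream artifact {path.name!r}: run the "
            f"{producer!r} stage first")
    return path


def run_stage(stage: str, cfg: RunConfig) -> dict:
    """Run one pipeline stage (or 'all'); returns a dict of artifact paths."""
    if stage == "all":
        arts: dict = {}
        for s in STAGES:
            if s == "compare" and not (cfg.reference_zones_path
                                       or cfg.backward_k):
                continue
            arts.update(run_stage(s, cfg))
        return arts
    if stage not in STAGES:
        raise PipelineError(f"unknown stage {stage!r}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return {
        "simulate": _stage_simulate, "fit": _stage_fit,
        "transform": _stage_transform, "map": _stage_map,
        "zone": _stage_zone, "compare": _stage_compare,
    }[stage](cfg, out)


def _stage_simulate(cfg: RunConfig, out: Path) -> dict:
    sim = cfg.simulation_config()
    grid, locations, table, genotypes, truth = simulate_dataset(sim)
    grid_dir = out / "climate_grid"
    paths = write_climate_grid(grid, grid_dir)
    p_table = write_climate_table(table, out / "climate.csv")
    p_geno = write_genotypes(genotypes, out / "genotypes.tsv")
    p_truth = out / "truth.csv"
    truth.to_csv(p_truth, index=False)
    p_loc = out / "locations.csv"
    locations.to_csv(p_loc, index=False)
    outputs = [p_table, p_geno, p_truth, p_loc, *paths]
    _write_manifest(out, "simulate", cfg, [], outputs)
    return {"climate_grid": grid_dir, "climate_table": p_table,
            "genotypes": p_geno, "truth": p_truth, "locations": p_loc}


def _inputs_for_fit(cfg: RunConfig, out: Path) -> tuple[Path, Path]:
    geno = (Path(cfg.genotypes_path) if cfg.genotypes_path
            else out / "genotypes.tsv")
    clim = (Path(cfg.climate_table_path) if cfg.climate_table_path
            else out / "climate.csv")
    return _require(geno, "simulate"), _require(clim, "simulate")


def _stage_fit(cfg: RunConfig, out: Path) -> dict:
    p_geno, p_clim = _inputs_for_fit(cfg, out)
    genotypes = read_genotypes(p_geno, set_label=cfg.set_label)
    genotypes = filter_missingness(genotypes, cfg.max_missing)
    genotypes = filter_maf(genotypes, cfg.maf_threshold)
    climate = read_climate_table(p_clim)
    model = fit_gradient_forest(
        genotypes, climate, n_trees=cfg.n_trees,
        seed=cfg.stage_seed("fit"), mtry=cfg.mtry, n_bins=cfg.n_bins,
        density_floor=cfg.density_floor)
    p_model = model.to_json(out / "gf_model.json")
    p_ret = out / "retained_snps.csv"
    model.retained_table().to_csv(p_ret, index=False)
    p_turn = out / "turnover.csv"
    model.turnover_frame().to_csv(p_turn, index=False)
    p_imp = out / "overall_importance.csv"
    model.overall_importance.rename("importance").rename_axis(
        "predictor").to_csv(p_imp)
    _write_manifest(out, "fit", cfg, [p_geno, p_clim],
                    [p_model, p_ret, p_turn, p_imp])
    return {"model": p_model, "retained": p_ret, "turnover": p_turn,
            "importance": p_imp}


def _stage_transform(cfg: RunConfig, out: Path) -> dict:
    p_model = _require(out / "gf_model.json", "fit")
    grid_dir = (Path(cfg.climate_grid_dir) if cfg.climate_grid_dir
                else out / "climate_grid")
    _require(grid_dir, "simulate")
    model = GFModel.from_json(p_model)
    grid = read_climate_grid(grid_dir, band_names=model.predictor_names)
    gg = transform_grid(model, grid)
    gg = pca_scores(gg, n_components=cfg.n_components)
    score_dir = out / "pca_scores"
    score_dir.mkdir(exist_ok=True)
    from .grids import write_asc

    score_paths = []
    assert gg.scores is not None and gg.variance_fractions is not None
    for c in range(gg.scores.shape[0]):
        score_paths.append(write_asc(score_dir / f"PC{c + 1}.asc",
                                     gg.scores[c], gg.cell_size,
                                     gg.x_origin, gg.y_origin, gg.mask))
    p_var = out / "pca_variance.csv"
    pd.DataFrame({
        "component": np.arange(1, len(gg.variance_fractions) + 1),
        "variance_fraction": gg.variance_fractions,
    }).to_csv(p_var, index=False)
    p_load = out / "pca_loadings.csv"
    pd.DataFrame(gg.loadings, columns=gg.band_names,
                 index=[f"PC{c + 1}" for c in range(len(gg.loadings))]
                 ).to_csv(p_load)
    _write_manifest(out, "transform", cfg, [p_model],
                    [*score_paths, p_var, p_load])
    return {"scores": score_dir, "variance": p_var, "loadings": p_load}


def _load_scores(cfg: RunConfig, out: Path):
    score_dir = _require(out / "pca_scores", "transform")
    names = [f"PC{c + 1}" for c in range(cfg.n_components)]
    return read_climate_grid(score_dir, band_names=names)


def _stage_map(cfg: RunConfig, out: Path) -> dict:
    scores = _load_scores(cfg, out)
    gg = GenomicGrid(scores.data, scores.band_names, scores.mask,
                     scores.cell_size, scores.x_origin, scores.y_origin)
    gg.scores = scores.data
    img, params = rgb_map(gg)
    p_png = out / "genomic_rgb.png"
    import matplotlib.image

    matplotlib.image.imsave(p_png, img)
    p_par = out / "genomic_rgb_params.json"
    p_par.write_text(json.dumps(params))
    _write_manifest(out, "map", cfg, [], [p_png, p_par])
    return {"rgb": p_png, "rgb_params": p_par}


def _stage_zone(cfg: RunConfig, out: Path) -> dict:
    scores = _load_scores(cfg, out)
    pts = scores.valid_table()
    seed = cfg.stage_seed("zone")
    sub = pts
    if len(pts) > cfg.subsample:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
        sub = pts[np.sort(rng.choice(len(pts), cfg.subsample, replace=False))]
    scan = cluster_scan(sub, range(cfg.k_min, cfg.k_max + 1), seed=seed,
                        n_restarts=cfg.n_restarts)
    sel = select_k(scan, cfg.theta)
    p_scan = out / "cluster_scan.csv"
    scan.frame().to_csv(p_scan, index=False)
    p_sel = out / "k_selection.json"
    p_sel.write_text(json.dumps({
        "chosen_k": sel.k, "theta": sel.theta, "no_elbow": sel.no_elbow,
        "trace": sel.trace}))
    zmap = delineate(pts, scores.mask, scores.cell_size, k=sel.k, seed=seed,
                     subsample=cfg.subsample, n_restarts=cfg.n_restarts,
                     x_origin=scores.x_origin, y_origin=scores.y_origin)
    p_zone = write_zone_map(zmap, out / "zones.asc")
    p_area = out / "zone_areas.csv"
    zone_areas(zmap).rename("area_km2").to_csv(p_area)
    _write_manifest(out, "zone", cfg, [], [p_scan, p_sel, p_zone, p_area])
    return {"scan": p_scan, "selection": p_sel, "zones": p_zone,
            "areas": p_area}


def _stage_compare(cfg: RunConfig, out: Path) -> dict:
    p_zone = _require(out / "zones.asc", "zone")
    gf_map = read_zone_map(p_zone, provenance="gradient-forest PAM")
    arts: dict = {}
    seed = cfg.stage_seed("zone")
    scores = _load_scores(cfg, out)
    if cfg.reference_zones_path:
        ref = read_zone_map(Path(cfg.reference_zones_path),
                            provenance="reference")
        corr = (cfg.correspondence
                or [([z], [z]) for z in gf_map.zone_ids
                    if z in set(ref.zone_ids)])
        rep = overlap_report(gf_map, ref, corr, cfg.denominator,
                             cfg.weighting)
        p_rep = out / "overlap_report.csv"
        rep.to_frame().to_csv(p_rep, index=False)
        p_sum = out / "overlap_summary.json"
        p_sum.write_text(json.dumps({
            "average_rate_pct": rep.average_rate,
            "denominator": rep.denominator, "weighting": rep.weighting,
            "total_area_gf_km2": rep.total_area_gf,
            "total_area_reference_km2": rep.total_area_reference}))
        arts.update({"overlap": p_rep, "overlap_summary": p_sum})
    for k in cfg.backward_k:
        zmap = backward_delineate(scores.valid_table(), scores.mask,
                                  scores.cell_size, k=int(k), seed=seed,
                                  subsample=cfg.subsample,
                                  n_restarts=cfg.n_restarts,
                                  x_origin=scores.x_origin,
                                  y_origin=scores.y_origin)
        p_back = write_zone_map(zmap, out / f"zones_k{k}.asc")
        arts[f"zones_k{k}"] = p_back
    _write_manifest(out, "compare", cfg, [p_zone],
                    [p for p in arts.values()])
    return arts
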