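"""Genotype and climate-table containers, SNP-set filters, and readers.

The canonical genotype exchange format is a TSV with columns
``sample_id``, ``population_id`` followed by one column per SNP holding
diploid dosages 0/1/2 (empty or ``NA`` = missing call).  A VCF reader
(diploid GT field only) is provided as a convenience; multiallelic records
are dropped with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: The 20 annual climate variables used as forest predictors, with units.
CLIMATE_VARIABLES: dict[str, str] = {
    "MAT": "degC",      # mean annual temperature
    "MWMT": "degC",     # mean warmest month temperature
    "MCMT": "degC",     # mean coldest month temperature
    "TD": "degC",       # continentality (MWMT - MCMT)
    "MAP": "mm",        # mean annual precipitation
    "MSP": "mm",        # May-September precipitation
    "AHM": "index",     # annual heat-moisture index
    "SHM": "index",     # summer heat-moisture index
    "DD_0": "degree-days",   # degree-days below 0 C
    "DD5": "degree-days",    # degree-days above 5 C
    "NFFD": "days",     # number of frost-free days
    "FFP": "days",      # frost-free period
    "bFFP": "day-of-year",   # day FFP begins
    "eFFP": "day-of-year",   # day FFP ends
    "PAS": "mm",        # precipitation as snow
    "EMT": "degC",      # 30-yr extreme minimum temperature
    "EXT": "degC",      # 30-yr extreme maximum temperature
    "Eref": "mm",       # Hargreaves reference evaporation
    "CMD": "mm",        # Hargreaves climatic moisture deficit
    "RH": "%",          # mean annual relative humidity
}

#: Case-insensitive header aliases accepted on ingestion.
_ALIASES = {
    "dd<0": "DD_0", "dd_0": "DD_0", "ddsub0": "DD_0", "dd0": "DD_0",
    "dd>5": "DD5", "dd_5": "DD5", "dd5": "DD5",
}


class GenotypeError(ValueError):
    """Raised for malformed or inconsistent genotype inputs."""


class ClimateError(ValueError):
    """Raised for malformed or incomplete climate tables."""


def canonical_variable(name: str) -> str | None:
    """Map a header to its canonical climate-variable name, or None."""
    squeezed = name.strip()
    for canon in CLIMATE_VARIABLES:
        if squeezed.lower() == canon.lower():
            return canon
    return _ALIASES.get(squeezed.lower().replace(" ", ""))


# ---------------------------------------------------------------------------
# Genotypes


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs diploid dosage matrix with sample metadata.

    ``dosages`` is float (individuals, SNPs) with values in {0, 1, 2} or NaN
    for missing calls.  ``set_label`` records which SNP set the matrix
    represents (full / neutral / candidate / custom).
    """

    sample_ids: list[str]
    population_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray
    set_label: str = "custom"

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise GenotypeError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.population_ids) != n:
            raise GenotypeError("population_ids length mismatch")
        if len(self.snp_ids) != m:
            raise GenotypeError(f"{len(self.snp_ids)} snp ids for {m} columns")
        if len(set(self.sample_ids)) != n:
            raise GenotypeError("duplicate sample ids")
        if len(set(self.snp_ids)) != m:
            raise GenotypeError("duplicate snp ids")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = np.unique(vals[~np.isin(vals, (0.0, 1.0, 2.0))])[:5]
            raise GenotypeError(f"dosages outside {{0,1,2}}: {bad}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosages.shape

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset_snps(self, keep: np.ndarray | Sequence[str],
                    set_label: str | None = None) -> "GenotypeMatrix":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {s: i for i, s in enumerate(self.snp_ids)}
            try:
                idx = np.array([pos[s] for s in keep], dtype=int)
            except KeyError as exc:
                raise GenotypeError(f"unknown snp id {exc.args[0]!r}") from None
        return GenotypeMatrix(
            self.sample_ids, self.population_ids,
            [self.snp_ids[i] for i in idx], self.dosages[:, idx],
            set_label if set_label is not None else self.set_label,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.dosages, columns=self.snp_ids)
        df.insert(0, "population_id", self.population_ids)
        df.insert(0, "sample_id", self.sample_ids)
        return df


def write_genotypes(g: GenotypeMatrix, path: str | Path) -> Path:
    path = Path(path)
    df = g.to_frame()
    # integral dosages; missing as empty field
    df.to_csv(path, sep="\t", index=False, float_format="%.0f", na_rep="NA")
    return path


def read_genotypes(path: str | Path, fmt: str = "matrix-012",
                   set_label: str = "custom") -> GenotypeMatrix:
    """Read a genotype matrix from ``matrix-012`` TSV or diploid ``vcf``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "matrix-012":
        return _read_matrix_012(path, set_label)
    if fmt == "vcf":
        return _read_vcf(path, set_label)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_matrix_012(path: Path, set_label: str) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str},
                         na_values=["NA", "na", ".", ""])
    except pd.errors.ParserError as exc:
        raise GenotypeError(f"{path.name}: cannot parse 012 TSV ({exc})") from exc
    if df.shape[1] < 3 or list(df.columns[:2]) != ["sample_id", "population_id"]:
        raise GenotypeError(
            f"{path.name}: first two columns must be sample_id, population_id"
        )
    snp_ids = list(df.columns[2:])
    dosages = df.iloc[:, 2:].to_numpy(dtype=float)
    bad = ~(np.isnan(dosages) | np.isin(dosages, (0.0, 1.0, 2.0)))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise GenotypeError(
            f"{path.name}: non-diploid dosage {dosages[r, c]!r} at data line "
            f"{r + 2}, column {snp_ids[c]!r}"
        )
    return GenotypeMatrix(list(df["sample_id"]), list(df["population_id"]),
                          snp_ids, dosages, set_label)


def _read_vcf(path: Path, set_label: str) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF support requires cyvcf2") from exc
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    snp_ids, cols = [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        if rec.ploidy != 2:
            raise GenotypeError(
                f"{path.name}: non-diploid call at {rec.CHROM}:{rec.POS}"
            )
        gt = np.asarray(rec.gt_types, dtype=float)  # 0/1/2 dosage, 3 = missing
        gt[gt == 3] = np.nan
        snp_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        cols.append(gt)
    if n_multi:
        log.info("dropped %d multiallelic VCF records", n_multi)
    if not cols:
        raise GenotypeError(f"{path.name}: no biallelic records")
    dosages = np.stack(cols, axis=1)
    return GenotypeMatrix(samples, ["NA"] * len(samples), snp_ids, dosages,
                          set_label)


# ---------------------------------------------------------------------------
# SNP-set filters and assembly


def minor_allele_frequency(g: GenotypeMatrix) -> np.ndarray:
    """Per-SNP minor allele frequency over all individuals pooled.

    MAF = min(p, 1-p) with p = (sum of dosages) / (2 x non-missing calls).
    """
    called = ~np.isnan(g.dosages)
    n_called = called.sum(axis=0)
    empty = np.flatnonzero(n_called == 0)
    if empty.size:
        names = ", ".join(g.snp_ids[i] for i in empty[:10])
        raise GenotypeError(f"SNPs with all calls missing: {names}")
    # count minor alleles directly: allele counts are exact integers, so
    # frequencies at the filter threshold are computed without cancellation
    alt = np.nansum(g.dosages, axis=0)
    total = 2.0 * n_called
    return np.minimum(alt, total - alt) / total


def filter_maf(g: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Retain SNPs with MAF strictly greater than *threshold* (idempotent)."""
    if not 0.0 <= threshold < 0.5:
        raise ValueError(f"MAF threshold must be in [0, 0.5), got {threshold}")
    keep = minor_allele_frequency(g) > threshold
    log.info("MAF > %.3g filter: %d of %d SNPs retained",
             threshold, int(keep.sum()), g.n_snps)
    return g.subset_snps(keep)


def filter_missingness(g: GenotypeMatrix, max_missing: float = 0.2) -> GenotypeMatrix:
    """Drop SNPs whose per-SNP missing-call fraction exceeds *max_missing*."""
    frac = np.isnan(g.dosages).mean(axis=0)
    keep = frac <= max_missing
    dropped = int((~keep).sum())
    if dropped:
        log.info("missingness > %.0f%% filter: dropped %d of %d SNPs",
                 100 * max_missing, dropped, g.n_snps)
    return g.subset_snps(keep)


def assemble_candidate_set(gea_ids: Iterable[str], gpa_ids: Iterable[str]) -> set[str]:
    """Union of GEA- and GPA-nominated SNP ids (overlap counted once)."""
    gea, gpa = list(gea_ids), list(gpa_ids)
    for name, ids in (("GEA", gea), ("GPA", gpa)):
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate ids within the {name} set")
    union = set(gea) | set(gpa)
    log.info("candidate set: |GEA|=%d, |GPA|=%d, overlap=%d, union=%d",
             len(gea), len(gpa), len(gea) + len(gpa) - len(union), len(union))
    return union


# ---------------------------------------------------------------------------
# Climate tables


@dataclass
class ClimateTable:
    """Per-sample table of the 20 climate predictors.

    ``values`` is indexed by sample_id with exactly the canonical columns of
    :data:`CLIMATE_VARIABLES`, all finite.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [v for v in CLIMATE_VARIABLES if v not in self.values.columns]
        if missing:
            raise ClimateError(f"climate variable(s) absent: {', '.join(missing)}")
        self.values = self.values[list(CLIMATE_VARIABLES)].astype(float)
        if self.values.index.has_duplicates:
            raise ClimateError("duplicate sample ids in climate table")
        if not np.isfinite(self.values.to_numpy()).all():
            bad = self.values.index[~np.isfinite(self.values).all(axis=1)][:5]
            raise ClimateError(f"non-finite climate values for samples: {list(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.index]

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def aligned_to(self, sample_ids: Sequence[str]) -> "ClimateTable":
        missing = [s for s in sample_ids if s not in self.values.index]
        if missing:
            raise ClimateError(f"climate rows absent for samples: {missing[:5]}")
        return ClimateTable(self.values.loc[list(sample_ids)])


def read_climate_table(path: str | Path, id_column: str = "sample_id") -> ClimateTable:
    path = Path(path)
    df = pd.read_csv(path)
    rename = {}
    for col in df.columns:
        canon = canonical_variable(str(col))
        if canon:
            rename[col] = canon
    df = df.rename(columns=rename)
    if id_column not in df.columns:
        raise ClimateError(f"{path.name}: id column {id_column!r} absent")
    missing = [v for v in CLIMATE_VARIABLES if v not in df.columns]
    if missing:
        raise ClimateError(f"{path.name}: {missing[0]} absent")
    return ClimateTable(df.set_index(id_column))


def write_climate_table(table: ClimateTable, path: str | Path) -> Path:
    path = Path(path)
    table.values.rename_axis("sample_id").to_csv(path)
    return path
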