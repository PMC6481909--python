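"""Genotype matrices and sample metadata: reading, validation, writing.

The internal genotype encoding is the per-sample count of ``allele_b``
copies (0, 1, 2; ``-1`` for missing).  Tetraploid plants are diploid-coded,
matching what GBS genotype callers emit; ploidy is carried only as a
population-level label used for inclusion/exclusion.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("rangexp")

MISSING = -1

LOCUS_SETS = ("assembled", "unassembled")
PLOIDIES = ("diploid", "tetraploid")
ROLES = ("ingroup", "outgroup")

SITE_COLUMNS = ["locus_id", "snp_index", "locus_set", "allele_a", "allele_b"]


class ValidationError(ValueError):
    """Raised when input data violates the data-model invariants."""


@dataclass(frozen=True)
class SampleInfo:
    """Per-sample metadata record."""

    sample_id: str
    population_id: str
    latitude: float
    longitude: float
    ploidy: str
    role: str
    outgroup_taxon: str = ""
    group: str = ""

    def __post_init__(self):
        if self.ploidy not in PLOIDIES:
            raise ValidationError(f"unknown ploidy {self.ploidy!r} for sample {self.sample_id}")
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r} for sample {self.sample_id}")
        if math.isfinite(self.latitude) and not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(f"latitude {self.latitude} out of range for {self.sample_id}")
        if self.role == "ingroup":
            if not (math.isfinite(self.latitude) and math.isfinite(self.longitude)):
                raise ValidationError(f"ingroup sample {self.sample_id} lacks coordinates")
        # normalize longitude to [-180, 180]
        if math.isfinite(self.longitude):
            lon = ((self.longitude + 180.0) % 360.0) - 180.0
            object.__setattr__(self, "longitude", lon)


@dataclass
class SnpGenotypeTable:
    """Biallelic SNP genotypes: one row per site, one column per sample.

    ``sites`` holds locus_id, snp_index, locus_set, allele_a, allele_b;
    ``genotypes`` is an ``int8`` array of allele_b copy counts with ``-1``
    marking missing calls.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    samples: list[str]

    def __post_init__(self):
        self.sites = self.sites.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sites), len(self.samples)):
            raise ValidationError(
                f"genotype shape {self.genotypes.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample id in genotype table")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample_id: str) -> int:
        return self.samples.index(sample_id)

    def subset_sites(self, mask_or_idx) -> "SnpGenotypeTable":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SnpGenotypeTable(
            sites=self.sites.iloc[idx],
            genotypes=self.genotypes[idx],
            samples=list(self.samples),
        )

    def subset_samples(self, sample_ids) -> "SnpGenotypeTable":
        cols = [self.samples.index(s) for s in sample_ids]
        return SnpGenotypeTable(
            sites=self.sites.copy(),
            genotypes=self.genotypes[:, cols],
            samples=list(sample_ids),
        )

    def non_missing_counts(self) -> np.ndarray:
        """Number of non-missing calls per site."""
        return (self.genotypes >= 0).sum(axis=1)

    def equals(self, other: "SnpGenotypeTable") -> bool:
        return (
            self.samples == other.samples
            and self.sites.reset_index(drop=True).equals(other.sites.reset_index(drop=True))
            and np.array_equal(self.genotypes, other.genotypes)
        )


def _validate_table(sites: pd.DataFrame, genotypes: np.ndarray, samples: list[str],
                    source: str) -> SnpGenotypeTable:
    """Drop degenerate sites (monomorphic / empty) and enforce invariants."""
    geno = np.asarray(genotypes, dtype=np.int8)
    keep = []
    n_dropped = 0
    for i in range(len(sites)):
        row = geno[i]
        obs = row[row >= 0]
        # polymorphic: both alleles observed among non-missing calls
        if obs.size and obs.min() < 2 and obs.max() > 0:
            keep.append(i)
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("%s: dropped %d monomorphic/empty sites", source, n_dropped)
    if not keep:
        raise ValidationError(f"{source}: empty table (no biallelic polymorphic sites)")
    key = sites[["locus_id", "snp_index"]].astype(str).agg("\x00".join, axis=1)
    if key.duplicated().any():
        raise ValidationError(f"{source}: duplicate (locus_id, snp_index) pair")
    bad = ~sites["locus_set"].isin(LOCUS_SETS)
    if bad.any():
        raise ValidationError(f"{source}: unknown locus_set {sites.loc[bad, 'locus_set'].iloc[0]!r}")
    return SnpGenotypeTable(sites.iloc[keep], geno[keep], samples)


def _parse_call(call: str, allele_a: str, allele_b: str) -> int:
    alleles = call.replace("|", "/").split("/")
    if len(alleles) != 2:
        raise ValidationError(f"malformed genotype call {call!r}")
    if "." in alleles:
        return MISSING
    count = 0
    for al in alleles:
        if al == allele_b:
            count += 1
        elif al != allele_a:
            return -2  # foreign allele: site is not biallelic on {a, b}
    return count


def read_genotype_table(path: str, format: str = "tsv") -> SnpGenotypeTable:
    """Read a genotype table from a TSV SNP table or a VCF.

    Sites with more than two observed alleles are dropped (count logged);
    monomorphic or all-missing sites are dropped.
    """
    if format == "tsv":
        return _read_tsv(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown format {format!r}")


def _read_tsv(path: str) -> SnpGenotypeTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(set(header)) != len(header):
        dup = sorted({c for c in header if header.count(c) > 1})
        raise ValidationError(f"{path}: duplicate sample columns {dup}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"{path}: missing columns {missing_cols}")
    samples = [c for c in df.columns if c not in SITE_COLUMNS]
    if not samples:
        raise ValidationError(f"{path}: no sample columns")
    sites = df[SITE_COLUMNS].copy()
    sites["snp_index"] = sites["snp_index"].astype(int)
    calls = df[samples].to_numpy(dtype=object)
    geno = np.empty((len(df), len(samples)), dtype=np.int8)
    bad_sites = np.zeros(len(df), dtype=bool)
    for i in range(len(df)):
        a, b = sites.at[i, "allele_a"], sites.at[i, "allele_b"]
        if a == b:
            bad_sites[i] = True
            continue
        for j in range(len(samples)):
            c = _parse_call(str(calls[i, j]), a, b)
            if c == -2:
                bad_sites[i] = True
                break
            geno[i, j] = c
    if bad_sites.any():
        logger.info("%s: dropped %d sites with >2 alleles", path, int(bad_sites.sum()))
    keep = ~bad_sites
    return _validate_table(sites[keep], geno[keep], samples, path)


def _read_vcf(path: str) -> SnpGenotypeTable:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("cyvcf2 is required for VCF input") from exc
    vcf = VCF(path)
    samples = list(vcf.samples)
    rows, geno_rows = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_multi += 1
            continue
        locus_set = "assembled"
        try:
            ls = var.INFO.get("LOCSET")
            if ls in LOCUS_SETS:
                locus_set = ls
        except Exception:
            pass
        rows.append((var.CHROM, var.POS, locus_set, var.REF, var.ALT[0]))
        gts = var.genotype.array()[:, :2]
        calls = np.where((gts < 0).any(axis=1), MISSING, gts.clip(min=0).sum(axis=1))
        geno_rows.append(calls.astype(np.int8))
    if n_multi:
        logger.info("%s: dropped %d non-biallelic-SNP records", path, n_multi)
    if not rows:
        raise ValidationError(f"{path}: empty table (no biallelic SNP records)")
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    return _validate_table(sites, np.vstack(geno_rows), samples, path)


def write_genotype_table(table: SnpGenotypeTable, path: str) -> None:
    """Write the TSV SNP-table dialect read by :func:`read_genotype_table`."""
    out = table.sites.copy()
    a = table.sites["allele_a"].to_numpy()
    b = table.sites["allele_b"].to_numpy()
    for j, s in enumerate(table.samples):
        col = np.empty(table.n_sites, dtype=object)
        g = table.genotypes[:, j]
        col[g == 0] = [f"{x}/{x}" for x in a[g == 0]]
        col[g == 1] = [f"{x}/{y}" for x, y in zip(a[g == 1], b[g == 1])]
        col[g == 2] = [f"{y}/{y}" for y in b[g == 2]]
        col[g < 0] = "./."
        out[s] = col
    out.to_csv(path, sep="\t", index=False)


def read_sample_info(path: str) -> list[SampleInfo]:
    """Read and validate the sample metadata TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "population_id", "latitude", "longitude", "ploidy", "role"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        lat = float(row["latitude"]) if row["latitude"] not in (None, "", "NA") and not pd.isna(row["latitude"]) else float("nan")
        lon = float(row["longitude"]) if row["longitude"] not in (None, "", "NA") and not pd.isna(row["longitude"]) else float("nan")
        records.append(SampleInfo(
            sample_id=str(row["sample_id"]),
            population_id=str(row["population_id"]),
            latitude=lat,
            longitude=lon,
            ploidy=str(row["ploidy"]),
            role=str(row["role"]),
            outgroup_taxon="" if "outgroup_taxon" not in df.columns or pd.isna(row.get("outgroup_taxon")) else str(row["outgroup_taxon"]),
            group="" if "group" not in df.columns or pd.isna(row.get("group")) else str(row["group"]),
        ))
    validate_sample_info(records)
    return records


def validate_sample_info(records: list[SampleInfo]) -> None:
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate sample ids: {dup}")
    by_pop: dict[str, list[SampleInfo]] = {}
    for r in records:
        if r.role == "ingroup":
            by_pop.setdefault(r.population_id, []).append(r)
    for pop, members in by_pop.items():
        coords = {(m.latitude, m.longitude) for m in members}
        if len(coords) > 1:
            raise ValidationError(f"population {pop!r} has mixed coordinates: {sorted(coords)}")
        ploidies = {m.ploidy for m in members}
        if len(ploidies) > 1:
            raise ValidationError(f"population {pop!r} has mixed ploidy labels")


def write_sample_info(records: list[SampleInfo], path: str) -> None:
    rows = [
        {
            "sample_id": r.sample_id, "population_id": r.population_id,
            "latitude": r.latitude, "longitude": r.longitude,
            "ploidy": r.ploidy, "role": r.role,
            "outgroup_taxon": r.outgroup_taxon, "group": r.group,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def ingroup_populations(records: list[SampleInfo]) -> dict[str, list[SampleInfo]]:
    """Map population id -> ingroup sample records, insertion-ordered."""
    pops: dict[str, list[SampleInfo]] = {}
    for r in records:
        if r.role == "ingroup":
            pops.setdefault(r.population_id, []).append(r)
    return pops


def population_coordinates(records: list[SampleInfo]) -> dict[str, tuple[float, float]]:
    return {pop: (members[0].latitude, members[0].longitude)
            for pop, members in ingroup_populations(records).items()}


def write_outputs(psi, surface, embedding, out_dir: str) -> list[str]:
    """Write the standard result files; return the manifest of paths created.

    ``psi`` is a PsiMatrix, ``surface`` an OriginSurface, ``embedding`` a
    PcoaResult; any may be ``None`` to skip its files.
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest: list[str] = []

    def _save(df: pd.DataFrame, name: str, index=False):
        p = os.path.join(out_dir, name)
        df.to_csv(p, sep="\t", index=index, float_format="%.12g")
        manifest.append(p)

    summary: dict = {}
    if psi is not None:
        if len(psi.populations) < 2:
            raise ValidationError("need >=2 populations to write a psi matrix")
        pops = psi.populations
        _save(pd.DataFrame(psi.psi, index=pops, columns=pops), "psi.tsv", index=True)
        _save(pd.DataFrame(psi.se, index=pops, columns=pops), "psi_se.tsv", index=True)
        _save(pd.DataFrame(psi.n_informative, index=pops, columns=pops),
              "psi_n_snps.tsv", index=True)
        summary["psi_settings"] = {"m": psi.m, "bootstrap": psi.n_bootstrap, "seed": psi.seed}
    if surface is not None:
        _save(surface.to_frame(), "origin_surface.tsv")
        summary["origin"] = surface.summary()
    if embedding is not None:
        _save(embedding.to_frame(), "pcoa_coordinates.tsv")
        _save(pd.DataFrame({
            "axis": np.arange(1, len(embedding.eigenvalues) + 1),
            "eigenvalue": embedding.eigenvalues,
            "percent_variance": embedding.percent_variance,
        }), "pcoa_eigenvalues.tsv")
    p = os.path.join(out_dir, "run_summary.json")
    with open(p, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    manifest.append(p)
    return manifest
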