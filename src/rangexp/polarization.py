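"""Ancestral/derived polarization from an outgroup and per-population counts.

Ancestral states are accepted only under a strict unanimity rule: every
non-missing outgroup call at the site must be homozygous for the same one of
the site's two alleles.  Deterministic downsampling uses the hypergeometric
projection of (k derived out of n chromosomes) to m chromosomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .genotypes import SampleInfo, SnpGenotypeTable, ingroup_populations
from .selection import ConfigurationError

logger = logging.getLogger("rangexp")


@dataclass
class PolarizedCounts:
    """Per-site, per-population derived allele counts.

    ``k[s, p]`` derived copies out of ``n[s, p]`` sampled chromosomes among
    non-missing diploid calls; ``sites`` carries locus ids and the resolved
    derived/ancestral alleles.
    """

    populations: list[str]
    sites: pd.DataFrame  # locus_id, snp_index, derived_allele, ancestral_allele
    k: np.ndarray  # (n_sites, n_pops) int
    n: np.ndarray  # (n_sites, n_pops) int

    def __post_init__(self):
        self.k = np.asarray(self.k, dtype=np.int64)
        self.n = np.asarray(self.n, dtype=np.int64)
        if np.any(self.k < 0) or np.any(self.k > self.n):
            raise ValueError("invalid polarized counts: need 0 <= k <= n")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def pop_index(self, pop: str) -> int:
        try:
            return self.populations.index(pop)
        except ValueError:
            raise KeyError(f"unknown population {pop!r}") from None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p, pop in enumerate(self.populations):
            df = self.sites[["locus_id", "snp_index", "derived_allele",
                             "ancestral_allele"]].copy()
            df["population"] = pop
            df["k"] = self.k[:, p]
            df["n"] = self.n[:, p]
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def infer_ancestral_allele(allele_a: str, allele_b: str, outgroup_calls) -> str | None:
    """Return the ancestral allele, or None on failure.

    ``outgroup_calls`` are allele_b copy counts (-1 missing).  Succeeds iff
    all non-missing calls are homozygous for the same allele of the site.
    """
    calls = np.asarray(outgroup_calls)
    obs = calls[calls >= 0]
    if obs.size == 0:
        raise ValueError("all outgroup calls missing; site should have been filtered")
    if np.all(obs == 0):
        return allele_a
    if np.all(obs == 2):
        return allele_b
    return None  # heterozygous or conflicting outgroup


def infer_ancestral_from_calls(allele_a: str, allele_b: str, calls) -> str | None:
    """As :func:`infer_ancestral_allele` but on raw call strings like "A/A".

    A homozygous call for an allele outside {allele_a, allele_b} fails
    polarization (returns None), as does any heterozygous call.
    """
    seen = set()
    for call in calls:
        pair = call.replace("|", "/").split("/")
        if "." in pair:
            continue
        if pair[0] != pair[1]:
            return None
        seen.add(pair[0])
    if not seen:
        raise ValueError("all outgroup calls missing; site should have been filtered")
    if len(seen) > 1:
        return None
    allele = seen.pop()
    return allele if allele in (allele_a, allele_b) else None


def polarize_table(table: SnpGenotypeTable, info: list[SampleInfo],
                   outgroup_taxon: str | None = None) -> PolarizedCounts:
    """Polarize every site and tally derived copies per ingroup population.

    Sites failing the unanimity rule, and sites monomorphic across the
    ingroup after polarization, are dropped with logged counts.
    """
    out_recs = [r for r in info if r.role == "outgroup" and r.sample_id in table.samples]
    if outgroup_taxon is not None:
        out_recs = [r for r in out_recs if r.outgroup_taxon == outgroup_taxon]
    if not out_recs:
        raise ConfigurationError("no outgroup samples for polarization")
    out_cols = np.array([table.sample_index(r.sample_id) for r in out_recs])

    pops = ingroup_populations(info)
    pops = {p: [m for m in ms if m.sample_id in table.samples] for p, ms in pops.items()}
    pops = {p: ms for p, ms in pops.items() if ms}
    pop_names = list(pops)
    pop_cols = [np.array([table.sample_index(m.sample_id) for m in ms])
                for ms in pops.values()]

    g = table.genotypes
    og = g[:, out_cols]
    og_nonmiss = og >= 0
    covered = og_nonmiss.any(axis=1)
    anc_is_a = covered & np.all((og <= 0), axis=1)            # all calls in {missing, 0}
    anc_is_b = covered & np.all((og == 2) | (og < 0), axis=1)  # all calls in {missing, 2}
    polarized = anc_is_a | anc_is_b
    n_fail = int((covered & ~polarized).sum())
    if n_fail:
        logger.info("polarize_table: %d sites failed unanimity and were dropped", n_fail)
    n_uncov = int((~covered).sum())
    if n_uncov:
        logger.info("polarize_table: %d sites without outgroup coverage dropped", n_uncov)

    # derived copies: allele_b copies when ancestral is allele_a, else flipped
    k_cols, n_cols = [], []
    for cols in pop_cols:
        sub = g[:, cols]
        nonmiss = sub >= 0
        b_copies = np.where(nonmiss, sub, 0).sum(axis=1)
        n_chrom = 2 * nonmiss.sum(axis=1)
        k = np.where(anc_is_a, b_copies, n_chrom - b_copies)
        k_cols.append(k)
        n_cols.append(n_chrom)
    K = np.stack(k_cols, axis=1)
    N = np.stack(n_cols, axis=1)

    k_tot = K.sum(axis=1)
    n_tot = N.sum(axis=1)
    poly = polarized & (k_tot > 0) & (k_tot < n_tot)
    n_mono = int((polarized & ~poly).sum())
    if n_mono:
        logger.info("polarize_table: %d sites monomorphic after polarization dropped", n_mono)

    idx = np.flatnonzero(poly)
    sites = table.sites.iloc[idx][["locus_id", "snp_index"]].copy()
    a = table.sites["allele_a"].to_numpy()[idx]
    b = table.sites["allele_b"].to_numpy()[idx]
    anc_a = anc_is_a[idx]
    sites["derived_allele"] = np.where(anc_a, b, a)
    sites["ancestral_allele"] = np.where(anc_a, a, b)
    return PolarizedCounts(pop_names, sites.reset_index(drop=True), K[idx], N[idx])


def project_counts(k: int, n: int, m: int) -> np.ndarray:
    """Hypergeometric projection: P(j derived in m of n chromosomes), j=0..m."""
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 1 <= m:
        raise ValueError(f"need m >= 1, got m={m}")
    if m > n:
        raise ValueError(f"projection unavailable: m={m} > n={n}")
    return hypergeom.pmf(np.arange(m + 1), n, k, m)
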