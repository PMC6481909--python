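"""Forward-time lattice simulators producing GBS-like SNP tables.

Two generators share a stepping-stone engine of unlinked biallelic SNPs
(binomial Wright-Fisher drift per deme, nearest-neighbour migration):

* :func:`simulate_expansion` — a colonization wave from a single origin
  deme; each newly occupied deme is founded by F diploid founders drawn
  from a random occupied neighbour, producing allele surfing and derived
  frequency clines away from the origin.
* :func:`simulate_ibd` — all demes occupied from generation 0 with a long
  burn-in, giving a migration-drift equilibrium (isolation by distance,
  no expansion signal).

Both emit a genotype table, sample metadata with lattice demes mapped onto
geographic coordinates, and (for expansions) a truth record with the origin
and colonization order.  :func:`plant_linear_psi` builds an exactly linear
psi matrix for TDOA oracle tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .directionality import PsiMatrix
from .genotypes import MISSING, SampleInfo, SnpGenotypeTable
from .origin import geodesic_distance

logger = logging.getLogger("rangexp")

BASES = np.array(list("ACGT"))

# lattice -> geography anchor (arid central Australia) and scale
DEFAULT_ANCHOR = (-24.0, 127.0)
DEFAULT_KM_PER_STEP = 50.0
KM_PER_DEG_LAT = 111.32


@dataclass
class ExpansionSimConfig:
    lattice: tuple[int, int] = (8, 8)
    origin_deme: tuple[int, int] = (0, 0)
    deme_size: int = 100              # diploid individuals per deme (K)
    founder_size: int = 10            # diploid founders per colonization (F)
    migration_rate: float = 0.05
    generations_per_colonization: int = 2
    total_snps: int = 2000
    outgroup_mispolarization_rate: float = 0.0
    missingness_rate: float = 0.1
    sampled_demes: list[tuple[int, int]] | None = None
    samples_per_deme: int = 2
    n_outgroup_samples: int = 2
    tetraploid_demes: list[tuple[int, int]] = field(default_factory=list)
    anchor: tuple[float, float] = DEFAULT_ANCHOR
    km_per_step: float = DEFAULT_KM_PER_STEP
    seed: int = 0

    def __post_init__(self):
        if self.founder_size > self.deme_size:
            raise ValueError("founder_size must be <= deme_size")
        r, c = self.origin_deme
        if not (0 <= r < self.lattice[0] and 0 <= c < self.lattice[1]):
            raise ValueError("origin_deme outside lattice")
        for p in (self.migration_rate, self.missingness_rate,
                  self.outgroup_mispolarization_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.sampled_demes is not None:
            for d in self.sampled_demes:
                if not (0 <= d[0] < self.lattice[0] and 0 <= d[1] < self.lattice[1]):
                    raise ValueError(f"sampled deme {d} outside lattice")


@dataclass
class IbdSimConfig:
    lattice: tuple[int, int] = (6, 6)
    deme_size: int = 50
    migration_rate: float = 0.05
    burn_in_generations: int = 500
    total_snps: int = 1000
    outgroup_mispolarization_rate: float = 0.0
    missingness_rate: float = 0.1
    sampled_demes: list[tuple[int, int]] | None = None
    samples_per_deme: int = 2
    n_outgroup_samples: int = 2
    tetraploid_demes: list[tuple[int, int]] = field(default_factory=list)
    anchor: tuple[float, float] = DEFAULT_ANCHOR
    km_per_step: float = DEFAULT_KM_PER_STEP
    seed: int = 0


@dataclass
class ExpansionTruth:
    """Ground truth sufficient to score origin recovery."""

    origin_deme: tuple[int, int]
    origin_lat: float
    origin_lon: float
    colonization_order: dict[str, int]   # population id -> colonization step
    derived_allele: list[str]            # per emitted site
    km_per_step: float

    def to_dict(self) -> dict:
        return asdict(self)


def deme_id(r: int, c: int) -> str:
    return f"d{r}_{c}"


def deme_latlon(r: int, c: int, anchor=DEFAULT_ANCHOR,
                km_per_step=DEFAULT_KM_PER_STEP) -> tuple[float, float]:
    """Map lattice coordinates onto geography (rows go south, cols go east)."""
    lat0, lon0 = anchor
    lat = lat0 - r * km_per_step / KM_PER_DEG_LAT
    lon = lon0 + c * km_per_step / (KM_PER_DEG_LAT * math.cos(math.radians(lat0)))
    return lat, lon


def _neighbors(r, c, rows, cols):
    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        rr, cc = r + dr, c + dc
        if 0 <= rr < rows and 0 <= cc < cols:
            yield rr, cc


def _sfs_initial_counts(rng, n_snps: int, two_n: int) -> np.ndarray:
    """Standing-variation derived counts from a discretized 1/f law on 1..2N-1."""
    counts = np.arange(1, two_n)
    w = 1.0 / counts
    return rng.choice(counts, size=n_snps, p=w / w.sum())


def _migration_weights(neighbor_lists, occupied: np.ndarray, m: float) -> np.ndarray:
    """Row-stochastic mixing matrix: (1-m) self + m * mean of occupied neighbours."""
    n = len(neighbor_lists)
    W = np.zeros((n, n))
    for d in np.flatnonzero(occupied):
        nb = [x for x in neighbor_lists[d] if occupied[x]]
        if nb and m > 0:
            W[d, d] = 1.0 - m
            W[d, nb] = m / len(nb)
        else:
            W[d, d] = 1.0
    return W


def _wf_generation(rng, counts: np.ndarray, occupied: np.ndarray,
                   W: np.ndarray, two_k: int) -> np.ndarray:
    """One generation: migrant mixing of allele frequencies, then drift."""
    p_next = np.clip(W @ (counts / two_k), 0.0, 1.0)
    counts = counts.copy()
    occ = np.flatnonzero(occupied)
    counts[occ] = rng.binomial(two_k, p_next[occ])
    return counts


def _sample_genotypes(rng, freqs: np.ndarray, n_ind: int) -> np.ndarray:
    """Diploid genotypes (derived copies 0/1/2) for n_ind individuals."""
    return rng.binomial(2, freqs[None, :].repeat(n_ind, axis=0)).astype(np.int8)


def _emit_table(rng, geno_rows: dict[str, np.ndarray], n_snps: int,
                missingness: float, outgroup_geno: np.ndarray,
                outgroup_ids: list[str]):
    """Assemble the SNP table: allele labels, allele_a/b shuffling, missingness.

    Returns (sites, genotype matrix of allele_b copies, sample ids,
    derived_is_b mask, keep mask of polymorphic sites).
    """
    sample_ids = list(geno_rows) + outgroup_ids
    derived = np.vstack(list(geno_rows.values()) + [outgroup_geno]).T  # sites x samples
    # per-site ancestral/derived bases, and random assignment to columns a/b
    anc_idx = rng.integers(0, 4, size=n_snps)
    offset = rng.integers(1, 4, size=n_snps)
    der_idx = (anc_idx + offset) % 4
    derived_is_b = rng.random(n_snps) < 0.5
    geno_b = np.where(derived_is_b[:, None], derived, 2 - derived).astype(np.int8)
    if missingness > 0:
        miss = rng.random(geno_b.shape) < missingness
        geno_b[miss] = MISSING
    allele_a = np.where(derived_is_b, BASES[anc_idx], BASES[der_idx])
    allele_b = np.where(derived_is_b, BASES[der_idx], BASES[anc_idx])
    obs_max = np.where(geno_b >= 0, geno_b, -1).max(axis=1)
    obs_min = np.where(geno_b >= 0, geno_b, 3).min(axis=1)
    keep = (obs_min < 2) & (obs_max > 0)  # both alleles observed
    sites = pd.DataFrame({
        "locus_id": [f"L{i:06d}" for i in range(n_snps)],
        "snp_index": np.zeros(n_snps, dtype=int),
        "locus_set": rng.choice(["assembled", "unassembled"], size=n_snps),
        "allele_a": allele_a,
        "allele_b": allele_b,
    })
    return sites, geno_b, sample_ids, derived_is_b, keep


def _make_outgroup(rng, n_snps: int, n_out: int, mispolarization: float) -> np.ndarray:
    """Outgroup diploids: homozygous ancestral except a flipped fraction."""
    geno = np.zeros((n_out, n_snps), dtype=np.int8)
    flipped = rng.random(n_snps) < mispolarization
    geno[:, flipped] = 2
    return geno


def _metadata(sampled, samples_per_deme, tetraploid, anchor, km_per_step,
              outgroup_ids) -> list[SampleInfo]:
    info = []
    tetra = {tuple(d) for d in tetraploid}
    for (r, c) in sampled:
        lat, lon = deme_latlon(r, c, anchor, km_per_step)
        for i in range(samples_per_deme):
            info.append(SampleInfo(
                sample_id=f"{deme_id(r, c)}_s{i}", population_id=deme_id(r, c),
                latitude=lat, longitude=lon,
                ploidy="tetraploid" if (r, c) in tetra else "diploid",
                role="ingroup"))
    for oid in outgroup_ids:
        info.append(SampleInfo(sample_id=oid, population_id="outgroup",
                               latitude=float("nan"), longitude=float("nan"),
                               ploidy="diploid", role="outgroup",
                               outgroup_taxon="sim_outgroup"))
    return info


def _default_sampled(lattice, rng, k=15):
    rows, cols = lattice
    all_demes = [(r, c) for r in range(rows) for c in range(cols)]
    idx = rng.choice(len(all_demes), size=min(k, len(all_demes)), replace=False)
    return [all_demes[i] for i in sorted(idx)]


def simulate_expansion(cfg: ExpansionSimConfig):
    """Serial-founder range expansion; returns (table, info, truth)."""
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.lattice
    n_demes = rows * cols
    S = cfg.total_snps
    two_k = 2 * cfg.deme_size
    flat = lambda r, c: r * cols + c
    neighbor_lists = [[flat(rr, cc) for rr, cc in _neighbors(d // cols, d % cols, rows, cols)]
                      for d in range(n_demes)]

    counts = np.zeros((n_demes, S), dtype=np.int64)
    occupied = np.zeros(n_demes, dtype=bool)
    colonized_step = np.full(n_demes, -1, dtype=int)
    o = flat(*cfg.origin_deme)
    counts[o] = _sfs_initial_counts(rng, S, two_k)
    occupied[o] = True
    colonized_step[o] = 0

    step = 0
    while not occupied.all():
        step += 1
        frontier = [d for d in range(n_demes)
                    if not occupied[d] and any(occupied[x] for x in neighbor_lists[d])]
        founders = {}
        for d in frontier:
            src = rng.choice([x for x in neighbor_lists[d] if occupied[x]])
            fc = rng.binomial(2 * cfg.founder_size, counts[src] / two_k)
            # founder group grows to carrying capacity in one generation
            founders[d] = rng.binomial(two_k, fc / (2 * cfg.founder_size))
        for d, c in founders.items():
            counts[d] = c
            occupied[d] = True
            colonized_step[d] = step
        W = _migration_weights(neighbor_lists, occupied, cfg.migration_rate)
        for _ in range(cfg.generations_per_colonization):
            counts = _wf_generation(rng, counts, occupied, W, two_k)

    sampled = cfg.sampled_demes or _default_sampled(cfg.lattice, rng)
    geno_rows: dict[str, np.ndarray] = {}
    for (r, c) in sampled:
        freqs = counts[flat(r, c)] / two_k
        g = _sample_genotypes(rng, freqs, cfg.samples_per_deme)
        for i in range(cfg.samples_per_deme):
            geno_rows[f"{deme_id(r, c)}_s{i}"] = g[i]

    out_ids = [f"og_s{i}" for i in range(cfg.n_outgroup_samples)]
    out_geno = _make_outgroup(rng, S, cfg.n_outgroup_samples,
                              cfg.outgroup_mispolarization_rate)
    sites, geno_b, sample_ids, derived_is_b, keep = _emit_table(
        rng, geno_rows, S, cfg.missingness_rate, out_geno, out_ids)
    table = SnpGenotypeTable(sites[keep], geno_b[keep], sample_ids)
    info = _metadata(sampled, cfg.samples_per_deme, cfg.tetraploid_demes,
                     cfg.anchor, cfg.km_per_step, out_ids)

    olat, olon = deme_latlon(*cfg.origin_deme, cfg.anchor, cfg.km_per_step)
    derived_base = np.where(derived_is_b, sites["allele_b"], sites["allele_a"])
    truth = ExpansionTruth(
        origin_deme=tuple(cfg.origin_deme), origin_lat=olat, origin_lon=olon,
        colonization_order={deme_id(r, c): int(colonized_step[flat(r, c)])
                            for (r, c) in sampled},
        derived_allele=list(derived_base[keep]),
        km_per_step=cfg.km_per_step,
    )
    logger.info("simulate_expansion: %d/%d sites polymorphic, %d steps to full "
                "colonization", table.n_sites, S, step)
    return table, info, truth


def simulate_ibd(cfg: IbdSimConfig):
    """Equilibrium stepping-stone (no expansion); returns (table, info)."""
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.lattice
    n_demes = rows * cols
    S = cfg.total_snps
    two_k = 2 * cfg.deme_size
    if cfg.burn_in_generations < 10 * cfg.deme_size:
        logger.warning("simulate_ibd: burn_in %d < 10*K = %d; equilibrium may "
                       "not be reached", cfg.burn_in_generations, 10 * cfg.deme_size)
    flat = lambda r, c: r * cols + c
    neighbor_lists = [[flat(rr, cc) for rr, cc in _neighbors(d // cols, d % cols, rows, cols)]
                      for d in range(n_demes)]
    occupied = np.ones(n_demes, dtype=bool)
    init = _sfs_initial_counts(rng, S, two_k)
    counts = np.tile(init, (n_demes, 1))
    W = _migration_weights(neighbor_lists, occupied, cfg.migration_rate)
    for _ in range(cfg.burn_in_generations):
        counts = _wf_generation(rng, counts, occupied, W, two_k)

    sampled = cfg.sampled_demes or _default_sampled(cfg.lattice, rng,
                                                    k=min(15, n_demes))
    geno_rows: dict[str, np.ndarray] = {}
    for (r, c) in sampled:
        freqs = counts[flat(r, c)] / two_k
        g = _sample_genotypes(rng, freqs, cfg.samples_per_deme)
        for i in range(cfg.samples_per_deme):
            geno_rows[f"{deme_id(r, c)}_s{i}"] = g[i]
    out_ids = [f"og_s{i}" for i in range(cfg.n_outgroup_samples)]
    out_geno = _make_outgroup(rng, S, cfg.n_outgroup_samples,
                              cfg.outgroup_mispolarization_rate)
    sites, geno_b, sample_ids, _, keep = _emit_table(
        rng, geno_rows, S, cfg.missingness_rate, out_geno, out_ids)
    table = SnpGenotypeTable(sites[keep], geno_b[keep], sample_ids)
    info = _metadata(sampled, cfg.samples_per_deme, cfg.tetraploid_demes,
                     cfg.anchor, cfg.km_per_step, out_ids)
    return table, info


def plant_linear_psi(populations: dict[str, tuple[float, float]], origin,
                     slope: float, noise_sd: float = 0.0, seed: int = 0,
                     n_informative: int = 100) -> PsiMatrix:
    """psi that is exactly linear in distance difference from ``origin``.

    psi(i, j) = slope * (d(origin, j) - d(origin, i)) + noise, with noise
    drawn once per unordered pair so antisymmetry is exact.
    """
    if not math.isfinite(slope):
        raise ValueError("slope must be finite")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    pops = list(populations)
    P = len(pops)
    d = np.array([geodesic_distance(origin, populations[p]) for p in pops])
    psi = slope * (d[None, :] - d[:, None])
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=(P, P))
        noise = np.triu(noise, 1)
        psi = psi + noise - noise.T
    if np.any(np.abs(psi) > 1.0):
        logger.warning("plant_linear_psi: clipping psi values outside [-1, 1]")
        psi = np.clip(psi, -1.0, 1.0)
        psi = (psi - psi.T) / 2.0  # re-antisymmetrize after clipping
    np.fill_diagonal(psi, 0.0)
    n_inf = np.full((P, P), n_informative, dtype=np.int64)
    np.fill_diagonal(n_inf, 0)
    return PsiMatrix(pops, psi, np.zeros((P, P)), n_inf, m=2, seed=seed)
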