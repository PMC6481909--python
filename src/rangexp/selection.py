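"""SNP retention filters, one-SNP-per-locus choice and population subsetting.

"Present in a sample" means a non-missing genotype call of any kind,
including homozygous for the common allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genotypes import SampleInfo, SnpGenotypeTable, ValidationError, ingroup_populations

logger = logging.getLogger("rangexp")


class ConfigurationError(ValueError):
    pass


@dataclass
class SelectionConfig:
    """All knobs of the site/sample selection stage, serialized with each run."""

    min_samples_per_snp: int = 4
    require_outgroup_presence: bool = True
    snp_choice_mode: str = "random"  # or "rare_allele_bias"
    per_population_scheme: str = "downsample_to_common"  # or "one_individual"
    include_tetraploids: bool = True
    group_filter: list[str] | None = None
    locus_sets: list[str] = field(default_factory=lambda: ["assembled", "unassembled"])
    seed: int = 0

    def __post_init__(self):
        if self.min_samples_per_snp < 1:
            raise ConfigurationError("min_samples_per_snp must be >= 1")
        if self.snp_choice_mode not in ("random", "rare_allele_bias"):
            raise ConfigurationError(f"unknown snp_choice_mode {self.snp_choice_mode!r}")
        if self.per_population_scheme not in ("one_individual", "downsample_to_common"):
            raise ConfigurationError(
                f"unknown per_population_scheme {self.per_population_scheme!r}")


def filter_min_samples(table: SnpGenotypeTable, min_samples: int) -> SnpGenotypeTable:
    """Keep sites with at least ``min_samples`` non-missing calls."""
    if min_samples < 1:
        raise ConfigurationError("min_samples must be >= 1")
    mask = table.non_missing_counts() >= min_samples
    n_drop = int((~mask).sum())
    if n_drop:
        logger.info("filter_min_samples(%d): dropped %d of %d sites",
                    min_samples, n_drop, table.n_sites)
    if not mask.any():
        logger.warning("filter_min_samples: no sites retained")
    return table.subset_sites(mask)


def filter_outgroup_presence(table: SnpGenotypeTable,
                             info: list[SampleInfo]) -> SnpGenotypeTable:
    """Keep sites with a non-missing call in at least one outgroup sample."""
    out_ids = [r.sample_id for r in info if r.role == "outgroup" and r.sample_id in table.samples]
    if not out_ids:
        raise ConfigurationError("no outgroup samples available for outgroup-presence filter")
    cols = [table.sample_index(s) for s in out_ids]
    mask = (table.genotypes[:, cols] >= 0).any(axis=1)
    n_drop = int((~mask).sum())
    if n_drop:
        logger.info("filter_outgroup_presence: dropped %d of %d sites", n_drop, table.n_sites)
    return table.subset_sites(mask)


def filter_locus_sets(table: SnpGenotypeTable, locus_sets) -> SnpGenotypeTable:
    mask = table.sites["locus_set"].isin(list(locus_sets)).to_numpy()
    return table.subset_sites(mask)


def minor_allele_copy_counts(table: SnpGenotypeTable) -> np.ndarray:
    """Per-site copy count of the rarer allele over all non-missing calls."""
    g = table.genotypes
    nonmiss = g >= 0
    b_copies = np.where(nonmiss, g, 0).sum(axis=1)
    total = 2 * nonmiss.sum(axis=1)
    return np.minimum(b_copies, total - b_copies)


def select_one_snp_per_locus(table: SnpGenotypeTable, mode: str = "random",
                             seed: int = 0) -> SnpGenotypeTable:
    """Pick one SNP per locus.

    mode="random": uniform over the locus's SNPs.  mode="rare_allele_bias":
    uniform over the locus's SNPs whose minor-allele copy count is >= 2,
    falling back to all SNPs of the locus when none qualify.
    """
    if mode not in ("random", "rare_allele_bias"):
        raise ConfigurationError(f"unknown snp choice mode {mode!r}")
    rng = np.random.default_rng(seed)
    minor = minor_allele_copy_counts(table) if mode == "rare_allele_bias" else None
    chosen = []
    for _, idx in table.sites.groupby("locus_id", sort=False).indices.items():
        cand = np.asarray(idx)
        if mode == "rare_allele_bias":
            qualified = cand[minor[cand] >= 2]
            if qualified.size:
                cand = qualified
        chosen.append(rng.choice(cand))
    chosen = np.sort(np.asarray(chosen))
    return table.subset_sites(chosen)


def apply_population_scheme(table: SnpGenotypeTable, info: list[SampleInfo],
                            cfg: SelectionConfig) -> tuple[SnpGenotypeTable, list[SampleInfo]]:
    """Subset samples by scheme / ploidy / group; outgroup samples always kept."""
    rng = np.random.default_rng(cfg.seed)
    pops = ingroup_populations(info)

    kept_pops = {}
    for pop, members in pops.items():
        if not cfg.include_tetraploids and members[0].ploidy == "tetraploid":
            continue
        if cfg.group_filter is not None and members[0].group not in cfg.group_filter:
            continue
        kept_pops[pop] = [m for m in members if m.sample_id in table.samples]
    kept_pops = {p: ms for p, ms in kept_pops.items() if ms}
    if not kept_pops:
        raise ConfigurationError("population scheme removed all populations")

    kept: list[SampleInfo] = []
    if cfg.per_population_scheme == "one_individual":
        for pop, members in kept_pops.items():
            kept.append(members[rng.integers(len(members))])
    else:  # downsample_to_common
        n_common = min(len(ms) for ms in kept_pops.values())
        for pop, members in kept_pops.items():
            idx = rng.choice(len(members), size=n_common, replace=False)
            kept.extend(members[i] for i in sorted(idx))

    kept.extend(r for r in info if r.role == "outgroup" and r.sample_id in table.samples)
    kept_ids = [r.sample_id for r in kept]
    return table.subset_samples(kept_ids), kept


def apply_selection(table: SnpGenotypeTable, info: list[SampleInfo],
                    cfg: SelectionConfig) -> tuple[SnpGenotypeTable, list[SampleInfo]]:
    """Run the full selection stage in the standard order."""
    table = filter_locus_sets(table, cfg.locus_sets)
    if table.n_sites == 0:
        raise ConfigurationError("locus_sets filter removed all sites")
    table = filter_min_samples(table, cfg.min_samples_per_snp)
    if cfg.require_outgroup_presence:
        table = filter_outgroup_presence(table, info)
    table = select_one_snp_per_locus(table, cfg.snp_choice_mode, cfg.seed)
    table, info = apply_population_scheme(table, info, cfg)
    return table, info
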