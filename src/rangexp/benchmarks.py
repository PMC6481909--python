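"""Reference benchmark experiments used for validation.

Each function runs a self-contained, seeded experiment and returns summary
numbers.  They are shared by the test suite and the standalone acceptance
report so both measure exactly the same quantities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .directionality import bootstrap_psi, compute_psi_matrix, compute_psi_pair
from .origin import geodesic_distance, make_grid, origin_scan, test_expansion_vs_ibd
from .polarization import PolarizedCounts, polarize_table
from .simulate import ExpansionSimConfig, IbdSimConfig, simulate_expansion, simulate_ibd

# 15 demes spread over the 8x8 lattice, corners included
SPREAD_DEMES_8X8 = [(0, 0), (0, 3), (0, 7), (1, 6), (2, 1), (2, 5), (3, 3),
                    (3, 7), (4, 0), (5, 2), (5, 5), (6, 5), (7, 0), (7, 3),
                    (7, 7)]


def expansion_recovery(n_replicates: int = 20, seed: int = 0,
                       spacing_deg: float = 0.25,
                       padding_fraction: float = 0.1) -> dict:
    """Origin recovery and psi-cline direction on serial-founder runs.

    8x8 lattice, origin at a corner, K=100, F=10, m=0.05, 15 sampled demes
    x 2 diploids, 2000 SNPs, 10% missingness.  Returns the fraction of
    replicates whose inferred origin lies within 2 lattice spacings of the
    truth, whether all hits had a positive fitted slope, and the fraction of
    replicates with Spearman(psi, colonization-order difference) > 0.5.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates)
    hits, pos_slope_in_hits, cline_ok, dists = 0, 0, 0, []
    for s in seeds:
        cfg = ExpansionSimConfig(
            lattice=(8, 8), origin_deme=(0, 0), deme_size=100, founder_size=10,
            migration_rate=0.05, generations_per_colonization=2,
            total_snps=2000, missingness_rate=0.1,
            sampled_demes=SPREAD_DEMES_8X8, samples_per_deme=2, seed=int(s))
        table, info, truth = simulate_expansion(cfg)
        counts = polarize_table(table, info)
        psi = compute_psi_matrix(counts, m=2)
        grid = make_grid(info, spacing_deg, padding_fraction)
        surf = origin_scan(psi, info, grid)
        d = geodesic_distance(surf.best_cell, (truth.origin_lat, truth.origin_lon))
        dists.append(d / truth.km_per_step)
        if d <= 2 * truth.km_per_step:
            hits += 1
            pos_slope_in_hits += surf.slope > 0
        order = np.array([truth.colonization_order[p] for p in psi.populations])
        iu, ju = np.triu_indices(len(psi.populations), 1)
        rho, _ = spearmanr(psi.psi[iu, ju], order[ju] - order[iu])
        cline_ok += rho > 0.5
    return {
        "n_replicates": n_replicates,
        "recovery_rate": hits / n_replicates,
        "all_hits_positive_slope": bool(hits == pos_slope_in_hits),
        "cline_rate": cline_ok / n_replicates,
        "mean_distance_spacings": float(np.mean(dists)),
    }


def ibd_type_one_error(n_replicates: int = 100, n_perm: int = 199,
                       seed: int = 0, alpha: float = 0.01) -> dict:
    """Rejection rate of the expansion-vs-IBD test on equilibrium
    stepping-stone nulls (6x6 demes, K=50, m=0.2, 500 SNPs, burn-in 500)."""
    seeds = np.random.SeedSequence(seed + 1).generate_state(n_replicates)
    pvals = []
    for s in seeds:
        cfg = IbdSimConfig(lattice=(6, 6), deme_size=50, migration_rate=0.2,
                           burn_in_generations=500, total_snps=500,
                           missingness_rate=0.1, seed=int(s))
        table, info = simulate_ibd(cfg)
        counts = polarize_table(table, info)
        psi = compute_psi_matrix(counts, m=2)
        grid = make_grid(info, 0.25, 0.5)
        pvals.append(test_expansion_vs_ibd(psi, info, grid, n_perm=n_perm,
                                           seed=int(s)))
    pvals = np.asarray(pvals)
    return {
        "n_replicates": n_replicates,
        "rejection_rate": float((pvals <= alpha).mean()),
        "median_pvalue": float(np.median(pvals)),
    }


def panmictic_split_counts(seed: int, n_snps: int = 400,
                           two_n: int = 200) -> PolarizedCounts:
    """Split one panmictic sample of 8 diploids into two pseudo-populations."""
    rng = np.random.default_rng(seed)
    cvals = np.arange(1, two_n)
    w = 1.0 / cvals
    f = rng.choice(cvals, size=n_snps, p=w / w.sum()) / two_n
    g = rng.binomial(2, np.tile(f, (8, 1)))
    K = np.column_stack([g[:4].sum(axis=0), g[4:].sum(axis=0)])
    N = np.full_like(K, 8)
    sites = pd.DataFrame({"locus_id": [f"L{i}" for i in range(n_snps)],
                          "snp_index": 0, "derived_allele": "G",
                          "ancestral_allele": "A"})
    return PolarizedCounts(["p1", "p2"], sites, K, N)


def exchangeability_null(n_replicates: int = 100, seed: int = 0) -> dict:
    """Fraction of panmictic splits with |psi|/se exceeding 2.58."""
    seeds = np.random.SeedSequence(seed + 2).generate_state(n_replicates)
    n_sig = 0
    for s in seeds:
        c = panmictic_split_counts(int(s))
        est = compute_psi_pair(c, "p1", "p2", 2)
        se, _ = bootstrap_psi(c, ("p1", "p2"), 2, B=200, seed=int(s))
        if np.isfinite(est.psi) and np.isfinite(se) and se > 0 \
                and abs(est.psi) / se > 2.58:
            n_sig += 1
    return {"n_replicates": n_replicates, "significant_rate": n_sig / n_replicates}
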