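"""Pairwise directionality index on shared derived SNPs.

psi(i, j) is the mean, over informative sites, of the derived-allele
frequency difference f_j - f_i.  A site is informative for a pair when both
populations have at least m sampled chromosomes, the derived allele is seen
in both, and it is not fixed in both.  Positive psi(i, j) means population j
carries higher derived frequencies, i.e. lies farther from the expansion
origin.  Because the hypergeometric projection preserves expected frequency,
the projected estimate equals the plain k/n difference on informative sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .polarization import PolarizedCounts
from .selection import ConfigurationError

logger = logging.getLogger("rangexp")


@dataclass
class PsiEstimate:
    pop_i: str
    pop_j: str
    psi: float          # nan when undefined
    se: float           # nan when not computed / undefined
    n_informative: int
    m: int

    @property
    def defined(self) -> bool:
        return self.n_informative > 0


@dataclass
class PsiMatrix:
    populations: list[str]
    psi: np.ndarray           # antisymmetric, nan where undefined
    se: np.ndarray
    n_informative: np.ndarray
    m: int
    n_bootstrap: int = 0
    seed: int | None = None

    def pair(self, pop_i: str, pop_j: str) -> PsiEstimate:
        i = self.populations.index(pop_i)
        j = self.populations.index(pop_j)
        return PsiEstimate(pop_i, pop_j, float(self.psi[i, j]), float(self.se[i, j]),
                           int(self.n_informative[i, j]), self.m)


def _informative_mask(counts: PolarizedCounts, i: int, j: int, m: int) -> np.ndarray:
    ki, ni = counts.k[:, i], counts.n[:, i]
    kj, nj = counts.k[:, j], counts.n[:, j]
    return (
        (ni >= m) & (nj >= m)
        & (ki > 0) & (kj > 0)
        & ~((ki == ni) & (kj == nj))
    )


def psi_site_differences(counts: PolarizedCounts, pop_i: str, pop_j: str,
                         m: int) -> np.ndarray:
    """Per-informative-site derived frequency differences f_j - f_i."""
    i, j = counts.pop_index(pop_i), counts.pop_index(pop_j)
    mask = _informative_mask(counts, i, j, m)
    fi = counts.k[mask, i] / counts.n[mask, i]
    fj = counts.k[mask, j] / counts.n[mask, j]
    return fj - fi


def compute_psi_pair(counts: PolarizedCounts, pop_i: str, pop_j: str,
                     m: int = 2) -> PsiEstimate:
    """psi for one ordered pair; undefined (nan, n_informative=0) when no
    informative sites exist."""
    if m < 1:
        raise ConfigurationError("projection size m must be >= 1")
    diffs = psi_site_differences(counts, pop_i, pop_j, m)
    if diffs.size == 0:
        return PsiEstimate(pop_i, pop_j, float("nan"), float("nan"), 0, m)
    return PsiEstimate(pop_i, pop_j, float(diffs.mean()), float("nan"), diffs.size, m)


def bootstrap_psi(counts: PolarizedCounts, pair: tuple[str, str], m: int,
                  B: int = 1000, seed: int = 0):
    """Bootstrap over informative sites: returns (se, (lo, hi) 95% interval).

    Undefined (nan, (nan, nan)) when fewer than 2 informative sites.
    """
    if B < 100:
        raise ConfigurationError("bootstrap count B must be >= 100")
    diffs = psi_site_differences(counts, pair[0], pair[1], m)
    if diffs.size < 2:
        return float("nan"), (float("nan"), float("nan"))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, diffs.size, size=(B, diffs.size))
    reps = diffs[idx].mean(axis=1)
    se = float(reps.std(ddof=1))
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return se, (float(lo), float(hi))


def compute_psi_matrix(counts: PolarizedCounts, m: int = 2, B: int = 0,
                       seed: int = 0) -> PsiMatrix:
    """All unordered pairs once; antisymmetry by construction.

    B > 0 additionally fills the bootstrap-SE matrix (one sub-seed per pair,
    derived from ``seed``).
    """
    pops = counts.populations
    P = len(pops)
    if P < 2:
        raise ConfigurationError("need >= 2 populations for a psi matrix")
    psi = np.zeros((P, P))
    se = np.full((P, P), np.nan)
    n_inf = np.zeros((P, P), dtype=np.int64)
    np.fill_diagonal(se, 0.0)
    ss = np.random.SeedSequence(seed).spawn(P * P)
    for i in range(P):
        for j in range(i + 1, P):
            est = compute_psi_pair(counts, pops[i], pops[j], m)
            psi[i, j], psi[j, i] = est.psi, -est.psi
            n_inf[i, j] = n_inf[j, i] = est.n_informative
            if B > 0 and est.n_informative >= 2:
                sub = int(ss[i * P + j].generate_state(1)[0])
                se_ij, _ = bootstrap_psi(counts, (pops[i], pops[j]), m, B, sub)
                se[i, j] = se[j, i] = se_ij
    n_undef = int(np.isnan(psi[np.triu_indices(P, 1)]).sum())
    if n_undef:
        logger.warning("compute_psi_matrix: %d pairs undefined (no informative sites)",
                       n_undef)
    return PsiMatrix(list(pops), psi, se, n_inf, m, B, seed)
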