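"""Classical principal coordinates analysis of genotype Euclidean distances,
with pairwise-deletion scaling for missing data, plus observed heterozygosity."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import SampleInfo, SnpGenotypeTable, ingroup_populations


@dataclass
class PcoaResult:
    sample_ids: list[str]
    coordinates: np.ndarray       # (n_samples, n_axes)
    eigenvalues: np.ndarray       # all eigenvalues, non-increasing
    percent_variance: np.ndarray  # over positive eigenvalues (0 elsewhere)
    groups: list[str] | None = None

    @property
    def n_positive(self) -> int:
        return int((self.eigenvalues > 1e-10 * max(1.0, abs(self.eigenvalues[0]))).sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coordinates,
            columns=[f"axis{i+1}" for i in range(self.coordinates.shape[1])],
        )
        df.insert(0, "sample_id", self.sample_ids)
        if self.groups is not None:
            df["group"] = self.groups
        return df


def euclidean_distance_matrix(table: SnpGenotypeTable) -> np.ndarray:
    """Pairwise Euclidean distances on 0/1/2 genotypes.

    Missing data handled by pairwise deletion with the classical scaling
    d = sqrt((P / M) * sum of squared differences over the M mutually
    non-missing sites), P being the total number of sites.
    """
    if table.n_samples < 2:
        raise ValueError("need >= 2 samples for a distance matrix")
    G = table.genotypes.astype(float)
    P = table.n_sites
    obs = G >= 0
    Gz = np.where(obs, G, 0.0)
    # sum over shared sites of (g_a - g_b)^2, computed from cross products
    sq = Gz ** 2
    shared = obs.T.astype(float) @ obs.astype(float)       # M per pair
    cross = Gz.T @ Gz
    ssq_a = sq.T @ obs.astype(float)                       # sum g_a^2 over shared
    sumsq = ssq_a + ssq_a.T - 2.0 * cross
    if np.any(shared == 0):
        a, b = np.argwhere(shared == 0)[0]
        raise ValueError(
            f"no mutually non-missing sites for pair "
            f"({table.samples[a]!r}, {table.samples[b]!r})")
    d = np.sqrt((P / shared) * np.clip(sumsq, 0.0, None))
    np.fill_diagonal(d, 0.0)
    return d


def pcoa_embed(d: np.ndarray, axes: int = 2) -> PcoaResult | tuple:
    """Classical MDS: double-center -D^2/2, eigendecompose, scale eigenvectors.

    ``axes`` is capped at the number of positive eigenvalues; negative
    eigenvalues are reported in ``eigenvalues``.
    """
    if axes < 1:
        raise ValueError("axes must be >= 1")
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8) or not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d ** 2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-10 * max(1.0, abs(evals[0]))
    n_pos = int((evals > tol).sum())
    k = min(axes, n_pos) if n_pos else 1
    coords = evecs[:, :k] * np.sqrt(np.clip(evals[:k], 0.0, None))
    pos_sum = evals[evals > tol].sum()
    pct = np.where(evals > tol, 100.0 * np.clip(evals, 0.0, None) / pos_sum if pos_sum > 0 else 0.0, 0.0)
    return PcoaResult(sample_ids=[str(i) for i in range(n)], coordinates=coords,
                      eigenvalues=evals, percent_variance=pct)


def pcoa_from_table(table: SnpGenotypeTable, axes: int = 2,
                    groups: dict[str, str] | None = None) -> PcoaResult:
    d = euclidean_distance_matrix(table)
    res = pcoa_embed(d, axes)
    res.sample_ids = list(table.samples)
    if groups is not None:
        res.groups = [groups.get(s, "") for s in table.samples]
    return res


def kmeans_groups(result: PcoaResult, k: int, n_axes: int = 2, seed: int = 0) -> list[int]:
    """Convenience k-means on the leading axes (group labels are normally
    user-supplied; this helper automates them when asked)."""
    from scipy.cluster.vq import kmeans2

    X = result.coordinates[:, :n_axes]
    _, labels = kmeans2(X, k, seed=seed, minit="++")
    return labels.tolist()


def sample_heterozygosity(table: SnpGenotypeTable) -> dict[str, float]:
    """Per sample: fraction of non-missing sites with a heterozygous call."""
    g = table.genotypes
    nonmiss = (g >= 0).sum(axis=0)
    het = (g == 1).sum(axis=0)
    out = {}
    for j, s in enumerate(table.samples):
        if nonmiss[j] == 0:
            continue  # excluded; caller may warn
        out[s] = het[j] / nonmiss[j]
    return out


def population_heterozygosity(table: SnpGenotypeTable,
                              info: list[SampleInfo]) -> dict[str, float]:
    """Mean observed heterozygosity over each population's samples."""
    per_sample = sample_heterozygosity(table)
    result = {}
    for pop, members in ingroup_populations(info).items():
        vals = [per_sample[m.sample_id] for m in members if m.sample_id in per_sample]
        if vals:
            result[pop] = float(np.mean(vals))
    return result
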