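import numpy as np
import pandas as pd
import pytest

from rangexp.genotypes import SampleInfo, SnpGenotypeTable

# 15 demes spread over the 8x8 lattice, corners included
SPREAD_DEMES = [(0, 0), (0, 3), (0, 7), (1, 6), (2, 1), (2, 5), (3, 3), (3, 7),
                (4, 0), (5, 2), (5, 5), (6, 5), (7, 0), (7, 3), (7, 7)]


def make_table(genotypes, samples=None, locus_ids=None, locus_set="assembled",
               allele_a="A", allele_b="G", snp_index=None):
    """Build a SnpGenotypeTable from a (sites x samples) array of
    allele_b copy counts (-1 missing)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    if samples is None:
        samples = [f"s{j}" for j in range(n_samples)]
    if locus_ids is None:
        locus_ids = [f"L{i}" for i in range(n_sites)]
    sites = pd.DataFrame({
        "locus_id": locus_ids,
        "snp_index": snp_index if snp_index is not None else [0] * n_sites,
        "locus_set": [locus_set] * n_sites if isinstance(locus_set, str) else locus_set,
        "allele_a": [allele_a] * n_sites if isinstance(allele_a, str) else allele_a,
        "allele_b": [allele_b] * n_sites if isinstance(allele_b, str) else allele_b,
    })
    return SnpGenotypeTable(sites, g, list(samples))


def make_info(n_pops, samples_per_pop=2, n_outgroup=2, tetraploid_pops=(),
              lat0=-24.0, lon0=127.0):
    info = []
    for p in range(n_pops):
        for i in range(samples_per_pop):
            info.append(SampleInfo(
                sample_id=f"p{p}_s{i}", population_id=f"p{p}",
                latitude=lat0 - 0.4 * (p % 4), longitude=lon0 + 0.5 * (p // 4),
                ploidy="tetraploid" if f"p{p}" in tetraploid_pops else "diploid",
                role="ingroup"))
    for i in range(n_outgroup):
        info.append(SampleInfo(
            sample_id=f"og_s{i}", population_id="outgroup",
            latitude=float("nan"), longitude=float("nan"),
            ploidy="diploid", role="outgroup", outgroup_taxon="taxonA"))
    return info


@pytest.fixture(scope="session")
def expansion_sim():
    """One deterministic serial-founder run shared across tests."""
    from rangexp.simulate import ExpansionSimConfig, simulate_expansion
    cfg = ExpansionSimConfig(seed=3, sampled_demes=SPREAD_DEMES)
    return simulate_expansion(cfg)
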