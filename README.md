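# rangexp

Inference of range expansions from population SNP data.

Given biallelic SNP genotypes for ingroup populations plus an outgroup,
`rangexp`:

1. applies GBS-style retention filters (minimum sample coverage, outgroup
   presence, one SNP per locus — random or biased towards SNPs with multiple
   copies of the rare allele) and population sampling schemes (one
   individual per population, downsampling to a common size, tetraploid
   exclusion, group subsets);
2. polarizes SNPs into ancestral/derived states from the outgroup (strict
   unanimity rule) and tallies per-population derived-allele counts, with
   deterministic hypergeometric projection for downsampling;
3. computes the pairwise directionality index ψ — the mean difference in
   derived-allele frequencies over shared derived SNPs; ψ(i, j) > 0 means
   population j lies farther from the expansion origin — with bootstrap
   standard errors;
4. localizes the most likely expansion origin by a time-difference-of-arrival
   (TDOA) grid search: at each candidate origin, ψ(i, j) is regressed
   through zero on the distance difference d(o, j) − d(o, i), and the cell
   minimizing the residual sum of squares wins;
5. tests the expansion signal against an isolation-by-distance null by
   permuting the population→coordinate assignment;
6. embeds samples by classical PCoA of genotype Euclidean distances
   (pairwise-deletion missing-data scaling) and reports per-population
   observed heterozygosity.

A forward-time simulator generates matched synthetic data: serial-founder
expansions with allele surfing on a deme lattice, equilibrium
stepping-stone (IBD) nulls, GBS-style missingness, an outgroup with
configurable mispolarization, and a planted-linear-ψ generator for exact
TDOA oracles.

## Test

```bash
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which runs the full
property-based acceptance criteria (origin recovery on 20 simulated
expansions, type-I error on 100 IBD nulls, exact oracles); it takes a few
minutes.

## CLI

```bash
# simulate an expansion data set (TSV SNP table + metadata + truth record)
rangexp simulate --kind expansion --seed 1 --out-prefix scratch/demo

# full pipeline: filter -> polarize -> psi -> origin scan -> IBD test -> PCoA
rangexp run --genotypes scratch/demo.snps.tsv --samples scratch/demo.samples.tsv \
    --seed 1 --out-dir scratch/demo_out

# individual stages
rangexp filter   --genotypes ... --samples ... --min-samples 4 --out ...
rangexp polarize --genotypes ... --samples ... --out ...
rangexp psi      --genotypes ... --samples ... --out-prefix ...
rangexp origin   --genotypes ... --samples ... --out ... [--heatmap map.png]
rangexp pcoa     --genotypes ... --samples ... --out-prefix ...

# analysis matrix over setting combinations
rangexp matrix --genotypes ... --samples ... \
    --axis selection.snp_choice_mode=random,rare_allele_bias \
    --axis m=2,4 --out matrix.tsv
```

`rangexp run` also accepts a YAML/JSON config (`--config`); flags override
config values, and every run writes its resolved config next to its
outputs.

## Input formats

- **Genotype TSV**: columns `locus_id`, `snp_index`, `locus_set`
  (`assembled`/`unassembled`), `allele_a`, `allele_b`, then one column per
  sample with calls like `A/G` or `./.`.
- **VCF** (v4.x, GT field): biallelic SNP records; `LOCSET` INFO tag is
  read as the locus set when present.
- **Sample metadata TSV**: `sample_id`, `population_id`, `latitude`,
  `longitude`, `ploidy` (`diploid`/`tetraploid`), `role`
  (`ingroup`/`outgroup`), optional `outgroup_taxon` and `group`.

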