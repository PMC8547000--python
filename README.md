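# rarebiome

Analysis pipeline for rare vs. abundant soil bacteria along environmental
(salinity) gradients: abundance-class partitioning, taxonomic and
phylogenetic diversity with null models, community-assembly inference
(betaNTI + Raup–Crick), phylogenetic signal of environmental preferences
(Blomberg's K, Fritz–Purvis D), threshold indicator taxon analysis (TITAN),
and the ecosystem-multifunctionality (EMF) / functional-redundancy linkage.
A synthetic-data module generates gradient-structured metacommunities with
known assembly regimes so every stage is testable without sequencing data.

## Modules

| module | what it does |
|---|---|
| `io_config` | TSV/newick readers and writers, core containers, run config, pipeline driver |
| `synthetic_data` | Yule trees, Brownian traits, lognormal SAD communities under selection / dispersal / neutral / mixed regimes, function annotations |
| `abundance_partition` | <20-read filter, rare (<0.01%) / abundant (>0.1%) / intermediate classification, occupancy, abundance–occupancy regressions |
| `diversity` | Shannon, cophenetic distances, MNTD, SES.MNTD, betaMNTD, Bray–Curtis |
| `assembly` | betaNTI and RC_bray null models, five-process classification, fractions, Mantel vs. environment, salinity-bin analysis |
| `phylosignal` | Spearman preference traits, Blomberg's K, Fritz–Purvis D and the 1−D transform |
| `titan` | per-taxon IndVal change points, permutation z, bootstrap purity/reliability, community sum(z) thresholds and breadth |
| `emf_function` | Z-score EMF index, functional redundancy index, function census/log-ratios, FRI↔EMF and diversity↔EMF regressions |
| `stats_core` | seedable Pearson/Spearman, OLS, Mantel, single-factor PERMANOVA, Wilcoxon, Kruskal–Wallis |

## CLI

```sh
rarebiome simulate --regime selection --n-samples 90 --n-otus 800 --seed 1 --outdir syn
rarebiome classify  --community syn/community.tsv --out classification.tsv
rarebiome diversity --community syn/community.tsv --tree syn/tree.nwk --outdir results
rarebiome assembly  --community syn/community.tsv --tree syn/tree.nwk --n-nulls 999 --seed 1 --outdir results
rarebiome signal    --community syn/community.tsv --tree syn/tree.nwk --metadata syn/metadata.tsv --out signals.tsv
rarebiome titan     --community syn/community.tsv --metadata syn/metadata.tsv --out titan.tsv
rarebiome emf       --metadata syn/metadata.tsv --out emf.tsv
rarebiome all       --config config.yaml --seed 1 --outdir results
```

Input conventions: community tables are TSV with OTUs as rows and samples as
columns (use `samples_as_rows=True` in the reader for the transposed
layout); trees are newick with branch lengths; metadata is TSV with samples
as rows, environmental variables (pH, EC, TC, TN, IP, OP, TP, AP, TK, AK,
NH4, NO3) and the 17 ecosystem-function measurements as columns.  All
randomized statistics accept a seed and reproduce exactly under it.

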