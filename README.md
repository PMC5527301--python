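# skinmatch

Couple-matching analysis toolkit for skin-microbiome OTU tables.

The package starts at the OTU-table level (no sequence processing) and
re-implements, as a tested and reusable pipeline, the statistics used to
ask whether cohabiting partners can be identified from skin microbial
communities:

- **core_tables** (`skinmatch.tables`) — classic tab-separated OTU table
  and mapping-file I/O, depth filtering, rarefaction (subsampling
  without replacement), relative abundance, taxonomy collapsing.
- **synthetic_data** (`skinmatch.simulate`) — a household-structured
  community simulator (site ≫ individual > couple > sex log-additive
  effects, softmax → multinomial sampling, log-normal depths with a
  floor). The default design is 10 couples × 2 participants × 17 swabs
  (7 bilateral + 3 single body locations) = 340 samples.
- **diversity_stats** (`skinmatch.alpha`) — Shannon index (base 2 by
  default), observed OTUs, multiple-rarefaction sweeps, permutation
  two-sample t tests with Bonferroni correction across metadata
  categories.
- **distances_ordination** (`skinmatch.beta`) — Bray-Curtis distance
  matrices and principal-coordinates analysis (classical scaling;
  negative eigenvalues reported, not corrected).
- **closest_match** (`skinmatch.matching`) — nearest-neighbor
  self/partner/other matching under three candidate scopes (all,
  nonself, nonself-opposite-sex), per-location summaries, analytic
  chance baselines, and the same-sex non-partner match test.
- **permanova** (`skinmatch.permanova`) — one-factor distance-based
  PERMANOVA (pseudo-F, R², permutation p with the +1 smoothed
  estimator) and per-category / per-location significance sweeps.
- **pairing_null** (`skinmatch.pairing`) — the shuffled-couple-pairing
  permutation null: derangement enumeration/uniform sampling, couple
  relabeling, and null distributions of both the PERMANOVA pseudo-F and
  the cross-validated random-forest couple-classification error.
- **indicator_core** (`skinmatch.indicators`) — Dufrene-Legendre
  indicator values (specificity × fidelity, label-permutation p),
  threshold filtering (indval ≥ 0.7, mean ≥ 10 reads, p < 0.05),
  core-OTU detection, and the sex-enrichment table.
- **cli_pipeline** (`skinmatch.cli`, `skinmatch.pipeline`) — subcommands
  and an end-to-end run that chains every stage on synthetic or user
  data and writes a TSV/JSON report bundle with a manifest.

## CLI

```sh
# simulate the full study layout (340 samples, 17 swabs/participant)
skinmatch simulate --preset paper-design --seed 1 \
    --out-table otu.tsv --out-metadata map.tsv \
    --seed-low-depth 10 --low-depth-cutoff 5293

# filter + rarefy to 5,293 reads/sample
skinmatch rarefy --table otu.tsv --depth 5293 --seed 1 --out rare.tsv

# Bray-Curtis + PCoA
skinmatch beta --table rare.tsv --out-dm dm.tsv --out-pcoa pcoa.tsv

# nearest-neighbor matching (nonself scope, per body location)
skinmatch match --dm dm.tsv --metadata map.tsv --scope nonself \
    --within-location --out match.tsv

# per-category PERMANOVA sweep
skinmatch permanova --dm dm.tsv --metadata map.tsv --per-location \
    --n-perms 1000 --out permanova.tsv

# shuffled-pairing null for the PERMANOVA F statistic
skinmatch pairing-null --statistic permanova --dm dm.tsv \
    --metadata map.tsv --n-pairings 1000 --out null.json

# full pipeline on synthetic data (fast settings)
skinmatch report --outdir out/ --seed 1 --scaled-down
```

Every source of randomness takes an explicit `--seed`; reruns with the
same seed produce byte-identical statistical outputs.

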