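# metaqtl

Meta-QTL analysis for multi-study QTL compilations: consensus genetic-map
construction, confidence-interval re-estimation and QTL projection,
meta-QTL detection by Gaussian-mixture clustering with multi-criterion
model selection (plus a contiguous-cluster model-reduction method for
sparse chromosomes), physical anchoring with gene-interval extraction,
and marker-based validation on extreme-phenotype panels. A synthetic-data
generator produces complete, statistically realistic end-to-end fixtures
so every stage is testable offline.

## Method summary

- **Consensus map** (`metaqtl.consensus`): study maps are expressed in
  reference coordinates via markers shared with a saturated reference map.
  Order conflicts are resolved by a longest order-consistent anchor
  subsequence; positions transfer by piecewise-linear interpolation with
  terminal-slope extrapolation.
- **Projection** (`metaqtl.projection`): each QTL's 95% CI is taken from
  the source study or recomputed as `530 / (N · R²)` (population size N,
  variance explained R²), rescaled by the local map-expansion ratio, and
  converted to a Gaussian sd via `CI = 3.92 σ`.
- **Meta-analysis** (`metaqtl.meta`): chromosomes with more than nine QTL
  are fitted with a known-variance Gaussian mixture by multi-start EM for
  K = 1..K_max; K is chosen by a vote of AIC, AICc, AIC3, BIC and AWE,
  requiring agreement of at least three. Chromosomes with nine or fewer
  QTL are partitioned into contiguous blocks by exact dynamic
  programming, choosing among {1, 2, 3, 4, n} blocks with a BIC-like
  penalty. Each component is summarized as a meta-QTL: inverse-variance
  position, combined sd, 95% CI, weight, peak and flanking markers.
- **Annotation** (`metaqtl.annotation`): flanking markers anchor each
  meta-QTL to a physical interval; genes overlapping the closed interval
  are extracted from a GFF3 annotation; aligned FASTA sequences can be
  scanned for variants that perfectly separate low/high phenotype classes.
- **Validation** (`metaqtl.validation`): marker alleles vs extreme
  phenotype classes, two-sided Fisher exact test by full hypergeometric
  enumeration plus an allele/class concordance measure.
- **Simulation** (`metaqtl.simulate`): multi-study compilations drawn
  around configurable true meta-loci, with per-QTL spread implied by the
  `530/(N·R²)` rule, calibrated R² and LOD marginals, jittered study maps,
  toy gene annotations, and a validation panel.

## CLI

```sh
metaqtl simulate  --out bundle/ [--config cfg.yaml] [--seed 1]
metaqtl consensus --map bundle/maps.tsv --ref-map bundle/ref_map.tsv --out consensus.tsv
metaqtl project   --qtl bundle/qtl.tsv --map bundle/maps.tsv \
                  --ref-map bundle/ref_map.tsv --out projected.tsv
metaqtl meta      --projected projected.tsv --consensus bundle/ref_map.tsv \
                  --seed 1 --out mqtl.tsv --decision-log decisions.json
metaqtl annotate  --mqtl mqtl.tsv --markers-bp bundle/markers_bp.tsv \
                  --gff bundle/genes.gff3 --out genes.tsv
metaqtl variants  --aln aligned.fasta --classes classes.tsv
metaqtl validate  --panel bundle/panel.tsv --out validation.json
```

File formats are plain TSV (QTL tables, genetic maps in long format,
marker physical positions, validation panels), GFF3 for annotations and
aligned FASTA for sequence comparison; see the docstrings in
`metaqtl.qtl_io` for the expected columns.

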