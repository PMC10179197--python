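# Methods

## Problem and model

Absolute transcript abundance of translation machinery components varies
enormously across human tissues simply because tissues differ in overall
protein-synthesis demand. To ask whether the *composition* of a complex
differs between tissues, `complexshare` works with relative abundance: for a
defined group of genes G (a complex or functional set) and a sample *s*, the
share of member *g* is

    share(g, s) = x(g, s) / Σ_{h ∈ G} x(h, s)

with *x* the linear-scale abundance (TPM for transcriptomic sources,
intensity for proteomic ones). Shares are never computed on log-transformed
values — a fraction of a total is only meaningful on the linear scale.
Within a sample the shares of a group sum to 1, are invariant to any
per-sample scale factor (library size, normalization), and monotone in the
member's own abundance, which makes them a direct readout of presumptive
complex stoichiometry at the transcript level.

Before shares are formed, samples in which the group as a whole is barely
expressed are removed: sample *s* is excluded when its group total is
strictly below half the mean group total over all samples. The threshold is
computed once, in a single pass, not iteratively — re-applying the filter to
its own output with the original threshold changes nothing.

## Tissue enrichment statistic

Whether a gene's share is systematically high (or low) in one tissue is
tested with the set-enrichment running-sum statistic of the GSEA family,
with the roles swapped: the ranked list contains *samples* ordered by the
gene's share (descending, ties broken by ascending sample identifier), and
the sets are tissue groups of samples. Walking down the ranking, a hit
(sample in the tissue) adds `|share_i|^p / Σ_hits |share|^p` and a miss
subtracts `1/(N − n_set)`; the enrichment score ES is the running-sum value
of maximal absolute deviation from zero, signed. The walk ends exactly at
zero and ES ∈ [−1, 1]. When the positive and negative extrema tie in
magnitude (common with tied statistics), the positive one is taken, with a
1e-12 tolerance absorbing floating-point rounding of exact ties.

The weight exponent defaults to p = 1 (hits weighted by share magnitude,
the default of the standard gene-set implementations); p = 0 recovers the
classic unweighted two-sample Kolmogorov–Smirnov statistic. If every hit
statistic is zero, hits fall back to equal weights so the walk remains
defined.

### Permutation null, NES, p-values

The null holds the ranked statistic fixed and draws uniformly random
same-size sample subsets — the analogue of gene-set permutation, where
permutations are shared across same-size sets. The default is 10,000
permutations. When the subset space is small (`C(N, k) ≤ permutations`) the
null is enumerated exhaustively instead of sampled ("auto" mode).

NES = ES divided by the mean |ES| of null values with the same sign as ES.
The p-value is the +1-corrected same-sign tail estimator,
`p = (1 + #{same-sign null, |null| ≥ |ES|}) / (1 + #same-sign null)`,
so p = 0 is impossible; a null score equal to |ES| up to 1e-12 counts as at
least as extreme. ES = 0 maps to (NES 0, p 1); if no null value shares the
sign of ES, NES is flagged undefined (NaN) and p is `1/(1 + n_permutations)`.

p-values are Benjamini–Hochberg-adjusted within each gene across the tissue
labels tested for it (the family is the number of sample groups; a global
adjustment over all genes × tissues is available but off by default), and
the significance flag marks q < 0.01. Tissues with fewer than
`min_set_size = 3` retained samples are skipped with a warning.

Randomness: a single root seed expands through keyed `SeedSequence`
substreams per (gene, set size), so the null for a ranking is computed once
per set size, shared across same-size tissue sets, and identical regardless
of iteration order.

## Weighted totals and correlation

To compare the overall expression of a gene set with a reference set
(typically ribosomal protein genes, a bundled editable RPL*/RPS* list),
each gene is first normalized to its own mean across all samples of the
matrix; the weighted total of a set in a sample is the sum of the
normalized values over members, and the per-tissue value is the mean over
that tissue's samples. Two identities pin the construction down: the
per-sample totals average exactly to the member count, and the totals are
invariant to global rescaling of the matrix. Pearson r between two sets'
per-tissue vectors is computed over shared tissues (at least 3 required,
zero variance is an error).

## Input dialects

* **GCT 1.2 / gene TSV** — gene-level TPM; the gene symbol is the GCT
  Description entry when it looks like a symbol, else Name (GTEx GCT stores
  Ensembl ids in Name). Duplicate gene rows are summed.
* **Transcript TSV + normalization factors** (CAGE-style) — samples with a
  normalization factor strictly below 0.7 or strictly above 1.4 are
  excluded (boundary values kept); transcript TPM is summed per gene;
  unmapped transcripts are excluded with a warning.
* **Probe TSV** (microarray) — probe values are averaged per gene; each
  probe maps to exactly one gene.
* Proteomic intensity tables ride the gene-TSV path; missing values should
  be encoded as 0 (they then contribute nothing to totals) and are
  exercised by the generator's dropout mechanism.

The bundled group catalog collapses duplicated members within a group
(the source table prints one eIF3 subunit twice) with a warning, and a
bundled alias table bridges gene-symbol generations (VARS/VARS1 etc.) in
both directions during member resolution; unmatched members are reported,
never silently dropped. Chromosome annotation is limited to the sex-linked
genes the analyses need (EIF1AX/EIF1AY, DDX3X/DDX3Y, EIF2S3, PABPC5);
everything else defaults to "autosome".

## Synthetic data: what it emulates and what it does not

The generator draws `x(g, s) = exp(Normal(log_mean_g, log_sd_g))`, applies
planted multiplicative fold-changes per (gene, tissue set), optional hard
tissue restriction (exact zeros outside a tissue set), and finally dropout
zeroing — in that fixed order, from a single seeded generator, so a seed
fully determines the matrix. Log-normal noise is the standard
heavy-right-tail model for TPM; it is a declared modeling choice.

Presets (the package's study conditions):

* `gtex_like` — 12 tissues × 30 samples; 40 genes: the bundled groups
  eIF2B (5), eIF3 (13), PABPC paralogs (8) and ELONGATION (10) plus 4
  background genes outside any group; log-sd 0.5 for every gene; baseline
  TPM 100 for ordinary members, TPM 2 for the six "minor paralog" genes
  carrying planted effects, TPM 200 for background genes. Six planted
  single-tissue effects with folds 3–10 (EEF1A2/muscle 10, PABPC3/testis 8,
  EIF5A2/testis 6, PABPC1L/ovary 5, EIF3J/brain 4, EIF2B4/testis 3).
  Planting effects on *minor* members is deliberate: it reproduces the
  biological archetype of a lowly-expressed paralog switched on in one
  organ, moves the planted gene's own share strongly, and leaves
  co-members' shares essentially untouched (the denominator shifts by
  ~1–2%), so unplanted (gene, tissue) pairs remain a clean false-positive
  family.
* `null` — the same geometry with no effects; used for type-I calibration.
* `proteome_like` — 20 tissues × 1 sample, dropout 0.3, intensity units;
  emulates sparse per-tissue proteomics.

What the generator does **not** emulate: tissue-level covariance in overall
expression (each gene × sample is independent given its tissue effects),
GTEx's real tissue count (30) and sample count (11,688), CAGE peak
structure, batch effects, or correlated noise between co-regulated genes.
Passing the synthetic checks therefore demonstrates correctness of the
statistics under the declared model, not robustness to every property of
real data.

## Study sizes for the statistical checks

The packaged acceptance checks use 200 null replicates at 1,000
permutations for type-I calibration (the p < 0.05 fraction must fall in the
99% binomial band around 0.05 over all gene × tissue tests) and 50
`gtex_like` replicates at the default 10,000 permutations for recovery
(every planted pair at q < 0.01 in ≥ 95% of replicates, unplanted flagged
fraction within the nominal 0.01). Share invariants are checked on 1,000
random matrices; the enrichment p-value is checked against an independent
brute-force enumeration oracle for every set size of rankings with N ≤ 7,
where the package path itself enumerates the subset space exactly.

## Numerical choices and degenerate inputs

* Share column sums are validated to 1 within 1e-9.
* ES tie-break: positive extremum wins at |max| = |min|, tolerance 1e-12;
  ES is clipped into [−1, 1] against accumulated rounding.
* A retained sample with non-positive group total (possible only if the
  caller bypasses the filter) is an error, as is a group with no member
  present in the matrix.
* Gene means of zero are excluded from weighted totals with a warning; a
  set with no nonzero-mean member is an error.
* `n_permutations ≥ 100` is enforced for p-value reporting.
* Tissue summaries default to the median (robust to outlier samples); the
  mean is exposed since the appropriate central tendency for display is a
  judgment call.

## Known limitations

* The sampled permutation p-value has resolution `1/(#same-sign + 1)`;
  detecting q < 0.01 after BH over ~30 tissue groups needs several thousand
  permutations (the default 10,000 suffices; very small permutation counts
  silently cap attainable significance).
* No multilevel/adaptive refinement for extreme p-values and no
  leading-edge reporting (meaningless for sample sets).
* No batch correction or covariate adjustment anywhere in the pipeline.
* Correlations of weighted totals are validated by identities and a direct
  formula oracle only; there is no external numeric reference for them.
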