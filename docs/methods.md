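# Methods

## Scope

`insituanno` scores claimed marker genes for single-cell RNA-seq cell-type
annotation against cell-type-pure bulk reference transcriptomes (e.g. laser
capture microdissection, LCM). It covers: data containers and file formats,
normalization and gene-space alignment, the two-round correlation
procedure with between-type testing and marker calls, expressed-gene
overlap between datasets, a synthetic-data generator with planted ground
truth, and a declarative pipeline with a CLI. It does not re-process raw
sequencing reads, cluster or embed cells, or discover markers de novo.

## Data model

All expression data live in a genes × samples table with an explicit
*layer* tag: `raw` (integer counts), `linear` (continuous non-negative
values on a linear scale, the natural layer for bulk LCM profiles), `cpm`
(columns scaled to 1e6) and `logcpm` (`log2(cpm + 1)`). Correlation stages
refuse to mix layers. Gene ids are matched by exact, case-sensitive string
equality: the intended use is within a single gene-model namespace, and
silent fuzzy matching across namespaces would be dangerous. Supported
formats are the 10x-style MatrixMarket triplet (1-based coordinate
indices, integer field) and dense TSV (header = sample ids, first column =
gene ids, genes in rows; a transpose flag declares flipped input).

## Normalization

The default working layer for both correlation rounds is logCPM: column
scaling removes the large library-size difference between single cells
and bulk profiles, and the log transform keeps a handful of abundant
transcripts from dominating Pearson-type statistics. CPM and raw layers
are selectable. Zero-total columns are dropped with a logged warning.

## First round: cell-to-reference similarity

Every cell is correlated against every reference sample over the aligned
gene set (intersection, lexicographic row order; at least 50 shared genes
by default). Spearman — Pearson on mid-ranks, average ranks for ties — is
the default coefficient: it is invariant to monotone transforms and
robust to the mean–variance mismatch between bulk and single-cell data.
Pearson is available. References are kept **per replicate**, never
averaged, so that the second round can form replicate-level groups for
its tests. Cells whose aligned vector is constant get flagged missing
values (NaN), never zeros, with a logged count. An optional gene subset
or top-N-variable-gene restriction is supported; the default uses all
aligned genes.

## Second round: marker concordance, tests, calls

For marker $g$ and reference sample $s$, $r_{g,s}$ is the correlation
across cells between $g$'s expression and the cells' first-round
similarity to $s$. Catalog genes absent from the cell matrix are reported
and skipped (not fatal); markers constant across cells are excluded from
testing as undefined.

The replicate-level values for type $T$ (three per type in the default
design) form groups for a two-sample t-test. The default variant is the
pooled-variance Student's t-test, with Welch's unequal-variance variant
behind a flag. The degenerate case of two identical constant groups is
defined as $t = 0, p = 1$. Stars follow the strict convention
`p < 0.001 → ***`, `< 0.01 → **`, `< 0.05 → *`, else `ns`. No multiple-
testing adjustment is applied by default (the stars describe raw
per-comparison thresholds); Benjamini–Hochberg adjusted p-values can be
reported alongside, and are never used for the calls.

**Call rule.** Let $T^\*$ be the type with maximal mean $r$. If that mean
is ≤ 0 the marker annotates nothing (`none`). Otherwise the call set
contains $T^\*$, every type exactly tied with it (ties always produce
ambiguity, never an order-dependent pick), and every type whose
replicate values are not significantly below $T^\*$'s (two-sided
$p \ge \alpha$, default $\alpha = 0.05$, pairwise by default with a
pooled-others option). A singleton call set is a unique call; a marker is
*consistent* only when its unique call equals its claimed type. The rule
deliberately allows multi-type and no-type outcomes, because claimed
markers in practice do annotate the wrong type, several types, or none.

Two under-determined choices are exposed as options rather than baked in:
the second round can correlate against type-averaged similarity columns
instead of per-replicate columns (`replicate_mode="averaged"`; no
replicate groups then exist, so calls reduce to the positive-maximum rule
without significance testing), and the between-type comparison can pool
all non-top types into one group (`comparison="pooled"`).

## Expressed-gene overlap

Two metrics over the detected gene sets (value ≥ `min_count` in ≥
`min_samples` cells, defaults 1 and 1): the min-denominator rate
$|G_1 \cap G_2| / \min(|G_1|, |G_2|)$ (default, the conventional "overlap
rate of the smaller set") and the Jaccard index
$|G_1 \cap G_2| / |G_1 \cup G_2|$, always reported together with all set
sizes so the computation is auditable. Overlap is computed over gene
sets, not cell barcodes: two independent studies share a transcriptome
space, not cells. Jaccard never exceeds the min-denominator rate; both
are symmetric.

## Synthetic-data generator

The generator emulates the validation study's design: `n_types = 3` cell
types (fiber / vessel / ray), `n_replicates = 3` LCM profiles per type,
and a single-cell matrix over the same genes.

* Baseline gene means: lognormal, `meanlog 0`, `sdlog = base_mean_log_sd`
  (default 1.0 — roughly the spread of mean expression seen across genes
  in log-normalised expression atlases).
* Markers: `markers_per_type` genes per type (disjoint sets), multiplied
  by `2**log2_fold_change` in their own type's mean profile. Planting is
  multiplicative on the linear mean so the parameter is exactly the
  expected log2 expression difference. Default fold 3 (8×), a strong but
  realistic marker effect.
* LCM replicates: gene-wise lognormal noise, `sdlog = replicate_noise_sd`
  (default 0.2, i.e. ~20% coefficient of variation, typical of bulk
  RNA-seq replicates).
* Cells: negative-binomial counts with mean
  `mean_depth × profile / profile.sum()` and dispersion `a`
  (variance `μ + aμ²`); defaults `mean_depth = 5000` and `a = 0.5` are
  conventions for shallow droplet scRNA-seq, not measured values. Per-cell
  depth is fixed at `mean_depth` to keep effect-recovery tests sharp;
  library-size variation is deliberately not modelled.

Not emulated: doublets, ambient RNA, batch effects, UMI chemistry, zero
inflation beyond NB sampling, and correlated gene programs. Passing tests
on this generator therefore demonstrate that the *procedure* recovers
planted signal under clean overdispersed sampling — not that any real
marker catalog is right or wrong.

Determinism: every operation takes an integer seed; the one-call wrapper
derives per-stage sub-seeds from a single seed in a fixed order (truth,
references, cells). Identical seeds give bit-identical output.

## Numerical choices

* Cross-correlations are computed vectorized from the product-moment
  formula on centered matrices; results are clipped to [-1, 1] to remove
  floating-point overshoot. Zero-variance columns yield NaN (an explicit
  "undefined" signal), never 0.
* Spearman uses `scipy.stats.rankdata` mid-ranks (average ranks on ties).
* t-distribution tail probabilities come from `scipy.stats.t.sf`.
* Normalization requires non-degenerate columns; all-zero columns are
  dropped, not imputed.
* Config-driven runs write every resolved option and seed to
  `run_log.json` and contain no timestamps, so reruns are byte-identical.

## Problem sizes

Unit and property tests run on down-scaled instances (hundreds of genes,
tens of cells per type). The recovery, calibration and monotonicity
checks and the acceptance script use the full default design — 2000
genes, 60 planted markers, 900 cells, five seeds — which completes in
seconds on one CPU; these sizes were chosen as the smallest at which the
study design is represented faithfully.

## Known limitations

* The call rule with three replicates per group has limited power; it is
  calibrated (≤ a few % false unique calls at zero planted effect) but a
  real study with noisier references may need more replicates.
* Exact-tie handling in the call rule is measure-zero under continuous
  noise and matters only for degenerate inputs.
* The overlap metrics describe detected gene sets only; they say nothing
  about expression-level agreement.
* Gene identifiers must share a namespace; no ortholog mapping is
  attempted.
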