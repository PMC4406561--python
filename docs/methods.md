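# Methods

## Scope and data model

`seqmine` implements the computational core of a multi-level RNA-seq
mining protocol. It deliberately does not run aligners or re-implement
the dispersion models of dedicated DE packages: alignments arrive as SAM,
and per-method DE results arrive as TSV tables. What the package owns is
the glue that turns those inputs into knowledge — unique-mapper
filtering, counting and normalization, consensus calling, enrichment
ranking, and regulatory module-network learning — together with seeded
generators for every input so each stage is testable against planted
ground truth.

Coordinates are 0-based half-open internally; SAM and GTF keep their
native 1-based conventions at the file boundary, the single conversion
point. Genes, counts and expression live in pandas objects; exon interval
lookup uses an interval tree; GTF parsing goes through `gffutils`. SAM
parsing is a validated text reader because the contract requires
headerless input and format errors that name line numbers; it is
cross-checked against `pysam` in the test suite.

## Read classification and counting

A read is *filtered* when any of its records carries the QC-fail flag or
its best mapping quality is below the configurable threshold (default 0:
no quality filtering on the primary path, since the protocol's own
counter applies none); *failed* when unmapped; *multi-mapped* when it has
more than one reported placement (NH tag preferred, line multiplicity as
fallback — the choice is order-independent); otherwise *unique*. The four
tallies always sum to the total, and the mapped percentage is rounded
half-up to two decimals to match published tables. Only unique reads are
counted.

Read↔exon compatibility is ≥1 bp overlap with an exon interval; spliced
junction modeling belongs to the aligner and is out of scope. A read
touching exons of more than one gene is discarded and tallied as
ambiguous (union-mode spirit); a read inside one gene always increments
that gene, so gene-level counts are identical under all three isoform
rules. At the transcript level a read compatible with *n* isoforms adds 1
to each (`total_to_each_isoform`, the package default), is dropped when
*n* > 1 (`discard_ambiguous`), or adds 1/*n* to each (`proportional`).
RPKM uses the union of exon intervals across isoforms as the gene length;
per-isoform values use the isoform's own exonic length. Depth-normalized
values are count / uniquely-mapped-library-size, averaged over a sample's
replicates.

## Differential expression and consensus

Selection is inclusive (value ≤ threshold, default 0.05), matching the
conventions of the standard R packages. BH adjustment is the vectorized
step-up with a cumulative minimum; it is verified against a literal
O(n²) implementation of the definition and against statsmodels.
The consensus vote includes a gene iff it appears in at least
`min_support` method lists (default 3, configurable because the rule is
a convention, not a theorem); with `min_support` equal to the number of
lists it degenerates to intersection, with 1 to union, and support counts
are monotone in both the threshold and `min_support`.

The suitability check for normalization methods that assume most genes
are similarly expressed computes per-gene |log2| ratios of
depth-normalized condition means with a pseudo-count of 1 on raw counts
(a pseudo-count on the normalized scale would swamp the signal); it fails
when ≥50% of genes exceed |log2FC| > 2. Both cut-offs are config keys;
the statistic is a pragmatic operationalization, not an inference.

The built-in DE test is plumbing so the pipeline runs without external
tables: counts and library sizes are pooled within condition and each
gene gets a two-sided exact binomial test of x₁ successes in x₁+x₂ trials
with success probability N₁/(N₁+N₂). This is exact under Poisson sampling
and dependency-free, but it does not model biological overdispersion: its
type-I error inflates roughly with φ·μ (dispersion × mean). The null
fixtures used for calibration therefore use near-Poisson dispersion
(φ = 0.001), and passing those tests says nothing about error control on
strongly overdispersed biological replicates — use a dedicated DE package
for that and feed its table in.

## Enrichment

Terms are tested per ontology category with Fisher's exact test
(two-sided by default, mirroring the default of the standard R function;
one-sided "greater" is available since enrichment is directional) on
a = DE∩term, b = DE∖term, c = bg∩term, d = bg∖term, where the background
is the measured universe minus the DE set. No multiple-testing correction
is applied to enrichment p-values; ranking is by ascending p with ties on
term id. The CMH pre-check uses the three GO categories as strata
(tables of annotated-in-category × DE status) and is advisory: its
p-value is logged and stored, never used to drop terms, because the
interpretation of the stratified test in this role is ambiguous. The
implementation follows the unclamped continuity-corrected closed form
(agreeing with statsmodels); it differs from R's `mantelhaen.test` only
in the corner |Σ(a−E)| < 0.5, where R clamps the statistic to 0.

## Module networks

The learner models a module's expression as condition-wise Gaussians
selected by a binary decision tree over TF expression. Design choices
where the procedure is genuinely open:

- **Leaf model**: pooled over member genes — a leaf holds the ML mean and
  variance of all member-gene values in its conditions (variance floored
  at 1e-6). Pooled leaves make tree refitting exactly maximize the summed
  member likelihood, which is what gives the loop its monotone trace.
  A per-gene variance variant is a possible extension.
- **Splits**: greedy top-down, candidates are midpoints between
  consecutive distinct TF values on the node's conditions, on the raw
  (not discretized) TF scale; growth stops at `max_depth` (default 3),
  at pure/degenerate nodes, or when no candidate has positive likelihood
  gain. The TFs "selected" for a module are whichever the splits use.
- **Loop**: K-means (scikit-learn, fixed seed, n_init=10) on gene-wise
  z-scored profiles seeds the clusters; undersized seed clusters are
  dissolved before the first trace entry. Each iteration refits trees
  (keeping the previous tree when the greedy refit would lower the
  current members' likelihood — the keep-best safeguard that makes the
  refit step provably non-decreasing) and reassigns genes to the
  highest-likelihood tree, ties toward the lowest module id. Convergence
  at relative improvement < 1e-6 or 100 iterations. Modules falling below
  `min_module_size` (default 2) during reassignment are dissolved,
  smallest first, members going to their next-best module; dissolution is
  the one event that could interrupt trace monotonicity, which is why
  seed clusters are pruned up front.
- **Scale**: the pipeline feeds log2(RPKM+1) per replicate; z-scoring is
  internal to K-means only, and leaves model the log scale.
- **Scoring and export**: a module's correlation score is the mean
  pairwise Pearson correlation of member profiles (pairs with a
  zero-variance profile contribute 0 and are flagged; single-member
  modules score 1.0 and are flagged). The exported network has one edge
  per (tree TF) × (member gene) for the top modules by score, self-edges
  dropped. K defaults to max(2, n/20) capped at 10 when unset.

## Synthetic data

The generators are pure functions of a `FixtureSpec` (same seed →
identical bytes) and return ground truth with the data. Classification
tallies are exact partitions of the read total, not samples, so
classification tests are exact. Counts are negative-binomial with
variance μ + φμ²; gene means are log-normal around 30 reads. The
regulatory generator drives each planted module with a depth ≤ 2
threshold tree over standard-normal TF profiles, median splits, adjacent
leaf means `leaf_separation` apart (default 3, i.e. 3σ at the default
noise), and redraws a TF whose median split duplicates an earlier
module's condition partition — without that, two modules can become
indistinguishable after z-scoring.

What the fixtures do **not** emulate: spliced reads, sequence content and
quality scores, positional bias, realistic library-size variation,
biological overdispersion beyond the NB parameter, GO-graph structure
(terms are flat labels), and TF profiles correlated with their targets'
chromatin context. Passing tests demonstrates algorithmic correctness on
the stated models, not performance on real libraries.

## Problem sizes and determinism

Default validation sizes are chosen so the whole suite runs in seconds:
studies of 30–60 genes with thousands of reads, 2,000-gene null
calibrations, and 10–20 seeded repetitions for recovery and monotonicity
checks. Every stochastic step takes an explicit seed, and pipeline TSV
outputs are byte-identical across re-runs with the same config; the run
report additionally carries timestamps and is the one non-reproducible
artifact.

## Known limitations

- The SAM reader handles the 11 mandatory columns plus NH; CIGAR is used
  only for the reference span (no spliced placement of reads).
- The built-in DE test is anti-conservative under overdispersion (see
  above) and is not a substitute for count-model DE inference.
- Enrichment treats GO terms as flat labels; no ancestor propagation.
- The module learner's greedy trees carry no significance guarantees on
  edges; the exported network is a hypothesis-generation device.
- The printed module correlation of external studies cannot be reproduced
  here (their expression data is not distributable); the score's
  definition (mean pairwise Pearson) is validated on constructed cases
  instead.
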