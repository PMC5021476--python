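# Methods

## The screening model

`mirlink` treats a direct miRNA→mRNA regulation as a hypothesis with two
independent lines of evidence. Across the samples of one histological
group, repression shows up as a negative monotone association between the
miRNA's and the gene's expression; at the sequence level it requires a
binding site complementary to the miRNA seed in the transcript. Neither
line alone is convincing — strong inverse correlations arise in bulk
cohorts from co-regulation and cell-type composition, and seed matches
occur by chance roughly once per 4⁶–4⁸ nucleotides — so the pipeline only
calls a regulation when an inverse-correlation screen and two independent
sequence predictors agree, and reports the attrition at every stage.

Correlations are Spearman rank correlations: monotone repression need not
be linear, expression units (RPM vs normalized counts) differ between the
two matrices, and rank statistics are insensitive to the heavy right tails
of expression data. Each group is screened separately because group sizes
differ by an order of magnitude and pooling groups would let the largest
group dominate or induce spurious correlation from between-group shifts.

## Preprocessing

Order: prevalence filter → quantile normalization → log2(x+1) → per-batch
mean centering.

* **Prevalence** — a feature is "detected" when its value is strictly
  positive; features detected in fewer than ⌈n/2⌉ samples are dropped.
  This removes low-abundance isoforms whose rank vectors are mostly ties
  between zeros.
* **Quantile normalization** — every sample's sorted values are replaced
  by the across-sample mean of sorted values; ties receive the mean of
  their destination quantiles, so ties stay tied and within-sample order
  is preserved.
* **log2 pseudocount** — +1 on linear RPM/counts keeps zeros at zero. The
  offset is configurable.
* **Batch centering** — for each feature, each batch's mean is subtracted
  from that batch's samples. The model is a purely additive per-(feature,
  batch) offset on the log scale; the operation is idempotent and leaves
  every (feature, batch) mean at 0. No model-based correction (ComBat,
  limma) is attempted — the additive model is the method's assumption.

Some sequencing pipelines log-transform before normalizing; the
`order="log-then-normalize"` switch covers that convention. The default
normalizes on the linear scale first. PCA QC (feature-centered SVD, no
variance scaling, sign fixed by the largest-magnitude loading) is provided
to visualize batch structure before and after centering.

## Differential expression

MBFC is the ratio of group medians — a single aberrant sample cannot move
a group median, which is the point of using it over a mean fold change.
On log2 input the back-transform is plain 2^x; because the exponential is
monotone, median(2^x) = 2^median(x) and MBFC equals 2 to the difference of
group medians on the log scale. This stays meaningful on batch-centered
data, where medians sit near zero on the log scale; re-subtracting the
pseudocount there would clip medians to zero and destroy the ratio
semantics of the 1.25/0.8 significance bounds. A small pseudocount
(1e-9) guards zero medians on raw linear input.

The test is Welch's unequal-variance *t* (group variances differ between
histotypes; a pooled-variance switch exists). P-values are BH-adjusted
across the features that survive a first-quartile variance filter
(per-feature sample variances, Q1 by linear interpolation, strict >; if
all variances are equal everything is kept, since a strict cut would empty
the matrix). The multiple-testing family defaults to the variance-filtered
feature set; `m_total` can override it with a larger family for a stricter
convention. Significance = FDR < 0.05 AND MBFC outside [0.8, 1.25]; the
top-k marker panel (default k = 8) takes the lowest-FDR significant
features, ties broken by |log2 MBFC|.

## Correlation screen at scale

Ranks (average method for ties) are computed once per feature and
standardized to unit norm; the Spearman coefficient of any pair is then a
dot product, and a chunk of miRNAs against all genes is one matrix
product. Peak additional memory is O(chunk_size × n_genes) and results are
streamed in a fixed traversal order, so output is deterministic and equal
(to 1e-9) to per-pair computation. P-values use the *t* approximation
t = r√((n−2)/(1−r²)) with n−2 df — exact permutation p-values are not
computable for ~7 × 10⁷ pairs, and at the screen's |r| range the
approximation is conservative enough. |r| = 1 maps to p = 0. Constant
features yield NaN records which are logged and excluded from the FDR
family.

BH-FDR is applied per group over the full emitted pair family, then the
screen keeps r strictly below −0.6. Final calling uses stricter per-group
cuts — −0.65 (cPTC), −0.70 (fvPTC), −0.80 (tcPTC) — smaller groups demand
stronger correlation because the sampling variance of ρ grows as n
shrinks. All thresholds are strict `<` and configurable.

## Target prediction

The three stages capture the decision logic of the canonical tool
classes in a self-contained, desk-testable form; tables produced by the
original external tools can be imported via `load_external_predictions`
to replace any stage for fidelity runs.

* **Seed classes** — seed = miRNA positions 2–8 (position 1 = 5′
  terminus). On the mRNA, 6mer = reverse complement of positions 2–7;
  7mer-m8 adds the base pairing position 8 at the 5′ end; 7mer-A1 adds an
  A 3′ of the 6mer; 8mer has both. Each 6mer core occurrence is reported
  once under its most specific class. All three regions (5′UTR, CDS,
  3′UTR) are scanned and the region recorded per site.
* **Duplex alignment** — Smith–Waterman/Gotoh local alignment of the
  miRNA against the reversed site window (antiparallel pairing):
  Watson–Crick +5, G:U wobble +1, mismatch −3, gap open −8, gap extend
  −2, substitution contributions at seed positions doubled. A pair is
  "predicted" at score ≥ 140; a 21-nt perfect duplex scores 5·21+35 =
  140, so the default demands near-full-length complementarity. Windows
  extend mainly 5′ of the seed match (where the miRNA 3′ end pairs), and
  the local maximum is invariant to non-pairing flank extension. The
  scorer deliberately omits thermodynamics (free energy), conservation
  and non-canonical site models.
* **Seed-weighted ranking** — per gene, the score sums 3′UTR site-class
  weights (8mer 1.0, 7mer-m8 0.75, 7mer-A1 0.5, 6mer 0.25); genes are
  ranked per miRNA (ties by gene id), and a gene is confirmed when
  rank ≤ 100 and score ≥ 0.25, serialized as `YES (rank, score)`.
  Weights and cutoffs are configuration; no attempt is made to reproduce
  any external tool's numeric ranks.

T and U are interchangeable on input and normalized to U.

## Integration

Stage counts per group: (a) pairs past the −0.6 screen, (b) of those,
pairs with ≥ 1 predictor, (c) pairs with both predictors, then the strict
cut, then ranking confirmation. Candidates are named `{GROUP}_{k}` by r
ascending (ties by miRNA id then gene id). The ranking stage is evaluated
lazily — only for strict both-predictor candidates — mirroring the staged
design. When an isoform→mature-name map is supplied, funnel counts are
also reported with isoforms collapsed to mature names, since several
isoforms of one mature miRNA hitting the same gene are arguably one
regulation. The final table asserts that every record's r is below its
group's strict cut.

## Synthetic cohorts

The generator emulates what the screen actually consumes:

* **Expression** — features are log-normal on the log2 scale (baseline
  means uniform in [3, 9] log2 units, per-sample spread `feature_sd` = 1).
  Implanted regulations are bivariate-normal couplings with Pearson
  ρ = 2·sin(π·s/6), the value whose population Spearman is exactly the
  target strength s (default 0.85). Only rank structure matters to a
  Spearman screen, so no negative-binomial count realism is attempted.
* **Batches** — additive per-(feature, batch) offsets, N(0, batch_sd),
  batch_sd = 0.5 over 16 batches by default. Offsets are constant within a
  batch, so per-batch mean centering removes them exactly (up to the
  centering of the underlying signal itself).
* **Non-detection** — each feature is left-censored at the
  `dropout_rate` quantile of its own values (default 0.05): in bulk
  sequencing a zero means the abundance fell below the detection limit,
  so zeros must land on the low tail, not uniformly at random — uniform
  zeroing would create rank outliers that real RPM data does not contain.
  A `rare_fraction` (default 0.2) of features is additionally detected in
  only ~30% of samples, giving the prevalence filter real work.
* **Differential features** — a `de_fraction` of prevalent features gets a
  ±`de_effect` log2 shift (default 2.0) in the second group.
* **Sequences** — mature miRNAs are 21–23 nt random-composition RNA
  starting with U (the prevalent 5′ base of real mature miRNAs). Each
  regulated gene's 3′UTR receives the full reverse complement of its
  miRNA — a genuine 8mer (the base opposite position 1 is A because the
  miRNA starts with U) with perfect flanking pairing, so both sequence
  predictors can fire on true pairs. Unregulated genes carry only chance
  sites at the background k-mer rate.
* Group sizes default to 100/31/11 (cPTC/fvPTC/tcPTC), the 321/99/35
  proportions of the motivating cohort scaled to desk size; a single RNG
  stream seeded from the config drives everything, so outputs are
  bit-reproducible.

What the generator does *not* emulate: count overdispersion, correlated
co-expression modules, cell-type composition effects, library-size
variation, or non-canonical binding. Passing the recovery benchmark
therefore shows that the pipeline's stages compose correctly and recover
known monotone couplings under batch effects and censoring — not that the
thresholds are optimal for any real cohort.

## Benchmark panels and problem sizes

The recovery benchmark (`integration.synthetic_benchmark`) uses the
generator defaults — 200 miRNAs × 1000 genes, 142 samples in three
groups, 16 batches, 20 implanted regulations at strength 0.85 — screens
the 100-sample classical-variant group at the default thresholds, and
scores final calls against the implanted pairs; the test suite averages
10 fixed seeds. The differential-expression panel plants 50 shifted genes
(log2 shift 2.0) among 625 over two groups of 40. The batch-QC panel
plants 4 batches at batch_sd 1.0: a before/after PCA scatter can only
show batch clustering that two components can hold, and with 16 batches
the clusters overlap in 2-D even before correction (silhouette ≈ −0.2);
with few strong batches the silhouette falls from ≈ +0.7 to ≈ −0.07 on
centering. These sizes keep a full run of every panel within a few
seconds to a couple of minutes on one CPU.

## Numerical conventions and degenerate inputs

* Quantile of variances: linear-interpolation convention (configurable).
* All-equal variances: variance filter keeps everything.
* Zero variance in both *t*-test groups: equal means → (t=0, p=1);
  unequal → (±inf, 0), flagged in the log.
* Constant vectors in correlation: NaN record, excluded from FDR.
* BH adjustment: step-up with cumulative minimum from the largest p,
  capped at 1; stable sort makes output order-independent of ties.
* Overlap ties in isoform→mature mapping: lexicographically smallest
  mature name; strand must match, 1-based inclusive coordinates.
* Matrix TSVs round-trip bit-exactly (`%.17g` on write, round-trip float
  parsing on read).

## Known limitations

* The duplex scorer and ranking stage are simplified scorers, not
  re-implementations of the published tools; absolute scores and ranks
  are not comparable to theirs (import external tables where that
  matters).
* The per-batch mean-centering model cannot remove batch effects that
  interact with expression level or group composition.
* P-values from the *t* approximation are anti-conservative for very
  small groups with heavy ties; the smallest-group strict threshold
  (−0.80) is the main guard there.
* Isoform-level screening multiplies the pair family; the FDR family is
  the full grid, which is conservative for isoforms of the same mature
  miRNA that are nearly collinear.
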