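# mirlink

Integrative discovery of direct miRNA–mRNA regulations from grouped bulk
expression cohorts.

A miRNA that represses a transcript leaves two independent fingerprints: the
pair's expression is inversely correlated across samples, and the
transcript carries sequence-level binding sites for the miRNA's seed.
`mirlink` implements a staged screen that demands both — a genome-wide
inverse-correlation scan confirmed by sequence-based target prediction —
for cohorts partitioned into histological groups (the motivating setting is
papillary thyroid carcinoma with its classical, follicular-variant and
tall-cell-variant subtypes). It is aimed at computational biologists who
have isoform-level miRNA quantifications (reads per million miRNA mapped),
gene-level counts, and per-sample group/batch annotations, and who want
final regulation calls with a transparent audit trail of every filtering
stage.

## Method

For each histotype group *g* with samples *S_g*, and every (miRNA *i*,
gene *j*) pair:

1. **Preprocessing** — features detected (value > 0) in at least half the
   samples are kept; quantile normalization equalizes sample distributions;
   values are log2(x+1) transformed; batch effects are removed by
   subtracting each batch's per-feature mean.
2. **Differential expression** (between any two groups) — median-based fold
   change MBFC = median₁/median₂ on the linear scale, Welch's two-sample
   *t*-test on log2 values, Benjamini–Hochberg FDR; significant when
   FDR < 0.05 and MBFC > 1.25 or < 0.8. A first-quartile variance filter
   runs first.
3. **Correlation screen** — Spearman's ρ with average ranks for every
   pair over *S_g* (ranks computed once per feature, correlations by chunked
   matrix products, so tens of millions of pairs stream under bounded
   memory), BH-FDR over the full per-group pair family, and a screen at
   ρ < −0.6.
4. **Target prediction** — three predictor stages over 5′UTR/CDS/3′UTR
   sequences: canonical seed-site classes (8mer > 7mer-m8 > 7mer-A1 > 6mer,
   seed = miRNA positions 2–8), a local antiparallel duplex alignment score
   (Watson–Crick +5, G:U +1, mismatch −3, affine gaps −8/−2, seed positions
   doubled; fires at ≥ 140), and a seed-weighted per-gene ranking over
   3′UTR sites (8mer = 1.0 … 6mer = 0.25; confirmed when rank ≤ 100 and
   score ≥ 0.25). Tables from external prediction tools can be imported in
   place of any stage.
5. **Integration funnel** — screened pairs → ≥ 1 predictor → both
   predictors → per-group strict thresholds (ρ < −0.65 cPTC, < −0.70
   fvPTC, < −0.80 tcPTC) → ranking confirmation. Every stage count is
   reported; final calls carry `"YES (rank, score)"` verdicts.

A synthetic-data module generates cohorts with implanted negative couplings
whose target genes carry genuine planted seed sites, so the whole pipeline
is verifiable against known ground truth without any cohort download.

## Worked example

```bash
python examples/simulate_and_recover.py
```

```
implanted regulations : 20
screen (r < -0.6)     : 20 pairs
>=1 predictor         : 20
both predictors       : 20
strict cut + both     : 20
final (rank-confirmed): 20
sensitivity           : 1.00
false-discovery prop. : 0.00
```

Twenty miRNA→gene couplings at Spearman strength 0.85 were implanted into a
200 × 1000-feature cohort (100 classical-variant samples, 16 batches); the
funnel narrows monotonically, all 20 implanted pairs survive every stage,
and no spurious pair passes both sequence predictors. The other scripts in
`examples/` demonstrate differential-marker selection, the three predictor
stages on a let-7-like miRNA, and batch-effect QC via PCA silhouettes.

The same pipeline runs from the shell: `mirlink simulate`, `mirlink
ingest`, `mirlink preprocess`, `mirlink diffexpr`, `mirlink screen`,
`mirlink predict`, and `mirlink run --config config.yaml` for the whole
chain (per-stage TSVs, QC scatters, funnel counts and a run log).

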