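"""Canonical seed sites, duplex alignment scoring, and seed-weighted ranking.

Uses a let-7-like miRNA against hand-built 3'UTRs to show the three
predictor stages: site classes, the miRanda-style alignment score, and the
per-gene ranking with its YES/NO confirmation verdict.
"""

from mirlink.target_prediction import (
    MirnaSequence,
    TranscriptRegions,
    find_seed_sites,
    format_targetrank,
    miranda_like_score,
    predict_pair,
    revcomp,
    targetrank_confirmed,
    targetrank_like,
)

mir = MirnaSequence("let-7-like", "UGAGGUAGUAGGUUGUAUAGUU")
print(f"miRNA {mir.mature_name}: {mir.seq} (seed {mir.seed})")

utr = "GGGCUACCUCAGGG"  # contains the 8mer CUACCUCA
sites = find_seed_sites(mir, TranscriptRegions("DEMO", utr3=utr))
for s in sites:
    print(f"seed site in {s.region} at {s.start}: {s.site_type}")

perfect = revcomp(mir.seq)
print(f"alignment vs full complement : {miranda_like_score(mir, perfect):.0f} (>=140 fires)")

# a gene with a planted perfect site vs genes with none
genes = [
    TranscriptRegions("TARGET", utr3="ACGU" * 10 + perfect + "ACGU" * 10),
    TranscriptRegions("DECOY1", utr3="ACGU" * 30),
    TranscriptRegions("DECOY2", utr3="AAGG" * 30),
]
ts, miranda, _ = predict_pair(mir, genes[0])
print(f"TARGET: seed-class predictor={ts}, alignment predictor={miranda}")

for rec in targetrank_like(mir, genes):
    verdict = format_targetrank(rec, targetrank_confirmed(rec))
    print(f"  {rec.gene_id}: score={rec.targetrank_score:.2f} -> {verdict}")
# The ranking sums 3'UTR site-class weights (8mer=1.0 ... 6mer=0.25); a
# confirmed gene reports its rank and score as "YES (rank, score)".
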