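"""Seed-site detection, duplex alignment scoring, ranking, and external tables."""

import numpy as np
import pytest

from mirlink.target_prediction import (
    GAP_EXTEND,
    GAP_OPEN,
    MirnaSequence,
    PredictionRecord,
    TranscriptRegions,
    duplex_align_score,
    find_seed_sites,
    format_targetrank,
    load_external_predictions,
    miranda_like_score,
    predict_pair,
    revcomp,
    targetrank_confirmed,
    targetrank_like,
    _pair_score,
)

LET7 = MirnaSequence("let-7-like", "UGAGGUAGUAGGUUGUAUAGUU")


def brute_force_seed_scan(mir: MirnaSequence, regions: TranscriptRegions):
    """Oracle: test every window of every region against the literal site
    definitions, most specific class first."""
    core6 = revcomp(mir.seq[1:7])
    site7m8 = revcomp(mir.seq[1:8])
    patterns = [  # (type, pattern, 1-based start offset of the reported site)
        ("8mer", site7m8 + "A", 0),
        ("7mer-m8", site7m8, 0),
        ("7mer-A1", core6 + "A", 0),
        ("6mer", core6, 0),
    ]
    found = []
    for region in ("utr5", "cds", "utr3"):
        seq = regions.region_seq(region)
        claimed_cores = set()  # position of the 6mer core already reported
        for site_type, pattern, _ in patterns:
            core_offset = 1 if site_type in ("8mer", "7mer-m8") else 0
            for start0 in range(len(seq) - len(pattern) + 1):
                if seq[start0 : start0 + len(pattern)] != pattern:
                    continue
                core_pos = start0 + core_offset
                if core_pos in claimed_cores:
                    continue
                claimed_cores.add(core_pos)
                found.append((regions.gene_id, region, start0 + 1, site_type))
    return sorted(found)


def brute_force_align(m: str, t: str) -> float:
    """Oracle: enumerate every local alignment path explicitly (tiny sizes)."""
    t = t[::-1]
    best = 0.0

    def sub(i, j):
        w = 2 if 2 <= i + 1 <= 8 else 1
        return w * _pair_score(m[i], t[j])

    def extend(i, j, state, score):
        nonlocal best
        best = max(best, score)
        if i < len(m) and j < len(t):
            extend(i + 1, j + 1, "M", score + sub(i, j))
        if j < len(t):
            extend(i, j + 1, "E", score + (GAP_EXTEND if state == "E" else GAP_OPEN))
        if i < len(m):
            extend(i + 1, j, "F", score + (GAP_EXTEND if state == "F" else GAP_OPEN))

    for i in range(len(m)):
        for j in range(len(t)):
            extend(i + 1, j + 1, "M", sub(i, j))
    return best


class TestFindSeedSites:
    def test_planted_8mer_hand_example(self):
        regions = TranscriptRegions("G1", utr3="GGGCUACCUCAGGG")
        sites = find_seed_sites(LET7, regions)
        assert len(sites) == 1
        s = sites[0]
        assert (s.region, s.start, s.site_type) == ("utr3", 4, "8mer")

    def test_no_complementary_window_no_sites(self):
        regions = TranscriptRegions("G1", utr3="A" * 50)
        assert find_seed_sites(LET7, regions) == []

    def test_exact_7mer_m8_without_trailing_a(self):
        regions = TranscriptRegions("G1", utr3=revcomp(LET7.seq[1:8]))
        sites = find_seed_sites(LET7, regions)
        assert [s.site_type for s in sites] == ["7mer-m8"]
        assert sites[0].start == 1

    def test_7mer_a1_and_6mer_classes(self):
        core = revcomp(LET7.seq[1:7])
        sites = find_seed_sites(LET7, TranscriptRegions("G1", utr3="GG" + core + "AGG"))
        assert [s.site_type for s in sites] == ["7mer-A1"]
        sites = find_seed_sites(LET7, TranscriptRegions("G1", utr3="GG" + core + "GGG"))
        assert [s.site_type for s in sites] == ["6mer"]

    def test_most_specific_class_only_never_double_reported(self):
        # an 8mer context also satisfies every weaker rule; exactly one site comes back
        regions = TranscriptRegions("G1", utr3="GG" + revcomp(LET7.seq[1:8]) + "A" + "GG")
        sites = find_seed_sites(LET7, regions)
        assert len(sites) == 1 and sites[0].site_type == "8mer"

    def test_sites_found_in_all_three_regions(self):
        site = revcomp(LET7.seq[1:8]) + "A"
        regions = TranscriptRegions("G1", utr5="AA" + site, cds=site + "CC", utr3=site)
        found = {s.region for s in find_seed_sites(LET7, regions)}
        assert found == {"utr5", "cds", "utr3"}

    def test_matches_brute_force_scan_on_random_cases(self):
        rng = np.random.default_rng(17)
        bases = np.array(list("ACGU"))
        for case in range(200):
            mir = MirnaSequence(f"m{case}", "".join(bases[rng.integers(0, 4, size=21)]))
            utr3 = "".join(bases[rng.integers(0, 4, size=120)])
            # implant the core in half the cases so matches are not vanishingly rare
            if case % 2:
                pos = int(rng.integers(0, 110))
                utr3 = utr3[:pos] + revcomp(mir.seq[1:7]) + utr3[pos + 6:]
            regions = TranscriptRegions(f"g{case}", utr3=utr3)
            got = sorted(
                (s.gene_id, s.region, s.start, s.site_type) for s in find_seed_sites(mir, regions)
            )
            assert got == brute_force_seed_scan(mir, regions)

    def test_empty_mirna_rejected(self):
        with pytest.raises(ValueError):
            MirnaSequence("x", "")


class TestDuplexAlignment:
    def test_perfect_duplex_score(self):
        # 22 WC pairs at +5 with the 7 seed positions doubled: 22*5 + 7*5 = 145
        assert miranda_like_score(LET7, revcomp(LET7.seq)) == 145

    def test_no_positive_alignment_scores_zero(self):
        mir = MirnaSequence("polyA", "A" * 22)
        assert miranda_like_score(mir, "A" * 30) == 0.0

    def test_wobble_pairs_score_low_positive(self):
        # G:U wobbles only: +1 per pair, doubled in the seed
        mir = MirnaSequence("polyG", "G" * 20)
        assert duplex_align_score(mir.seq, "U" * 20) == 20 * 1 + 7 * 1

    def test_invariant_under_non_pairing_flank_extension(self):
        window = revcomp(LET7.seq)
        base = miranda_like_score(LET7, window)
        extended = miranda_like_score(LET7, "A" * 15 + window + "A" * 15)
        assert extended == base

    def test_window_shorter_than_mirna_rejected(self):
        with pytest.raises(ValueError):
            miranda_like_score(LET7, "ACGU")

    def test_non_rna_characters_rejected(self):
        with pytest.raises(ValueError):
            miranda_like_score(LET7, "ACGX" * 8)

    def test_matches_exhaustive_enumeration_at_toy_sizes(self):
        rng = np.random.default_rng(23)
        bases = np.array(list("ACGU"))
        for _ in range(12):
            m = "".join(bases[rng.integers(0, 4, size=5)])
            t = "".join(bases[rng.integers(0, 4, size=7)])
            assert duplex_align_score(m, t) == brute_force_align(m, t)


class TestPredictPair:
    def test_planted_site_with_perfect_pairing_fires_both(self):
        utr3 = "ACGU" * 10 + revcomp(LET7.seq) + "ACGU" * 10
        ts, miranda, sites = predict_pair(LET7, TranscriptRegions("G1", utr3=utr3))
        assert ts and miranda
        assert any(s.site_type == "8mer" for s in sites)

    def test_lone_6mer_with_poor_flanks_fires_neither(self):
        core = revcomp(LET7.seq[1:7])
        utr3 = "A" * 30 + core + "G" + "A" * 30  # G blocks the A1; poly-A flanks pair nothing
        ts, miranda, sites = predict_pair(LET7, TranscriptRegions("G1", utr3=utr3))
        assert [s.site_type for s in sites] == ["6mer"]
        assert not ts and not miranda
        assert sites[0].alignment_score < 140

    def test_no_sites_anywhere_fires_neither(self):
        ts, miranda, sites = predict_pair(LET7, TranscriptRegions("G1", utr3="A" * 60))
        assert not ts and not miranda and sites == []


class TestTargetrankLike:
    @staticmethod
    def _gene_with(utr3, gid):
        return TranscriptRegions(gid, utr3=utr3)

    def test_single_8mer_ranks_first(self):
        genes = [
            self._gene_with("GG" + revcomp(LET7.seq[1:8]) + "A" + "GG", "HIT"),
            self._gene_with("A" * 40, "MISS1"),
            self._gene_with("C" * 40, "MISS2"),
        ]
        records = {r.gene_id: r for r in targetrank_like(LET7, genes)}
        assert records["HIT"].targetrank_score == pytest.approx(1.0)
        assert records["HIT"].targetrank_rank == 1
        assert records["MISS1"].targetrank_rank is None

    def test_two_7mer_m8_outrank_one_8mer(self):
        m8site = revcomp(LET7.seq[1:8])
        genes = [
            self._gene_with("GG" + m8site + "G" + m8site + "G", "DOUBLE"),  # 2 x 0.75
            self._gene_with("GG" + m8site + "A" + "GG", "SINGLE"),  # 1.0
        ]
        records = sorted(targetrank_like(LET7, genes), key=lambda r: r.targetrank_rank)
        assert [r.gene_id for r in records] == ["DOUBLE", "SINGLE"]
        assert records[0].targetrank_score == pytest.approx(1.5)

    def test_utr3_only_counts(self):
        site = revcomp(LET7.seq[1:8]) + "A"
        genes = [TranscriptRegions("CDSONLY", cds="GG" + site + "GG"),
                 TranscriptRegions("EMPTY", utr3="A" * 20)]
        records = {r.gene_id: r for r in targetrank_like(LET7, genes)}
        assert records["CDSONLY"].targetrank_score == 0.0

    def test_confirmation_serialization(self):
        rec = PredictionRecord("m", "g", targetrank_score=0.48, targetrank_rank=19)
        assert format_targetrank(rec, targetrank_confirmed(rec)) == "YES (19, 0.48)"
        miss = PredictionRecord("m", "g", targetrank_score=0.0)
        assert format_targetrank(miss, targetrank_confirmed(miss)) == "NO"

    def test_empty_transcript_list_rejected(self):
        with pytest.raises(ValueError):
            targetrank_like(LET7, [])


class TestLoadExternalPredictions:
    def test_miranda_tag_sets_flag(self, tmp_path):
        p = tmp_path / "ext.tsv"
        p.write_text("mirna_id\tgene_id\nm1\tg1\nm1\tg2\nm2\tg3\n")
        records = load_external_predictions(p, "miranda")
        assert len(records) == 3
        assert all(r.predicted_miranda and not r.predicted_targetscan for r in records)

    def test_duplicates_deduplicated(self, tmp_path):
        p = tmp_path / "ext.tsv"
        p.write_text("mirna_id\tgene_id\nm1\tg1\nm1\tg1\n")
        assert len(load_external_predictions(p, "targetscan")) == 1

    def test_empty_table_warns_and_returns_nothing(self, tmp_path):
        p = tmp_path / "ext.tsv"
        p.write_text("mirna_id\tgene_id\n")
        assert load_external_predictions(p, "miranda") == []

    def test_unknown_tool_rejected(self, tmp_path):
        p = tmp_path / "ext.tsv"
        p.write_text("mirna_id\tgene_id\nm1\tg1\n")
        with pytest.raises(ValueError):
            load_external_predictions(p, "pita")
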