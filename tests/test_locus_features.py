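"""GC content, intron comparison, TE-TIR flank scan and pair orientation."""

import random

import pytest

from synorth.locus_features import (GeneStructure, RepeatInterval, gc_content,
                                    intron_metrics, pair_orientation,
                                    te_flank_scan)

from conftest import build_table


# ---------------------------------------------------------------------------
# GC content
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seq,expect", [
    ("GGCC", 100.0), ("ATAT", 0.0), ("ACGTN", 50.0), ("NNNN", None),
    ("", None), ("acgt", 50.0),
])
def test_gc_content_examples(seq, expect):
    assert gc_content(seq) == expect


def test_gc_content_rejects_non_nucleotides():
    with pytest.raises(ValueError):
        gc_content("ACGU")


def test_gc_plus_at_is_total_for_nfree_sequences():
    rng = random.Random(11)
    for _ in range(25):
        seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 200)))
        at = 100.0 * (seq.count("A") + seq.count("T")) / len(seq)
        assert gc_content(seq) + at == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# introns
# ---------------------------------------------------------------------------

def test_intron_lengths_from_exon_gaps():
    g = GeneStructure("g", exons=[(0, 10), (20, 30), (40, 50)])
    assert g.introns == [(10, 20), (30, 40)]
    other = GeneStructure("h", exons=[(0, 5), (15, 25), (35, 45)])
    res = intron_metrics(g, other)
    assert [r["length_a"] for r in res["per_rank"]] == [10, 10]
    assert res["count_mismatch"] is False


def test_shorter_gene_reported_per_rank():
    a = GeneStructure("a", exons=[(0, 10), (110, 120), (200, 210)])   # introns 100, 80
    b = GeneStructure("b", exons=[(0, 10), (310, 320), (520, 530)])   # introns 300, 200
    res = intron_metrics(a, b)
    assert all(r["shorter"] == "a" for r in res["per_rank"])


def test_first_intron_contraction_ratio():
    # duplicated copy with a contracted first intron: 1,158 vs 3,226 bases
    copy = GeneStructure("copy", exons=[(0, 100), (1258, 1400)])
    parent = GeneStructure("parent", exons=[(0, 100), (3326, 3500), (4000, 4100)])
    res = intron_metrics(copy, parent)
    r0 = res["per_rank"][0]
    assert (r0["length_a"], r0["length_b"]) == (1158, 3226)
    assert r0["ratio_a_over_b"] == pytest.approx(0.3590, abs=1e-4)
    assert res["count_mismatch"] is True and res["n_compared"] == 1


def test_intron_gc_uses_sequence_slices():
    seq = "A" * 4 + "GGCC" + "T" * 4      # exon(0,4) intron(4,8) exon(8,12)
    g = GeneStructure("g", exons=[(0, 4), (8, 12)], sequence=seq)
    res = intron_metrics(g, g)
    assert res["per_rank"][0]["gc_a"] == 100.0


def test_metrics_require_introns():
    single = GeneStructure("s", exons=[(0, 10)])
    with pytest.raises(ValueError):
        intron_metrics(single, single)


# ---------------------------------------------------------------------------
# TE-TIR flanks
# ---------------------------------------------------------------------------

def test_tir_repeat_upstream_reported_with_side_and_distance():
    table = build_table("sp", {"c": ["g0", "focus", "g1"]}, coords=True,
                        spacing=10_000, width=2_000)
    focus = table.get("focus")  # [10000, 12000)
    reps = [RepeatInterval("c", focus.start - 300, focus.start - 200, "DNA/hAT", True),
            RepeatInterval("c", focus.end + 50, focus.end + 150, "LINE/L1", False)]
    out = te_flank_scan(table, "focus", reps, window_bp=1000)
    assert len(out) == 1
    assert out[0]["side"] == "5'" and out[0]["distance"] == 200


def test_non_tir_repeats_are_ignored():
    table = build_table("sp", {"c": ["focus"]}, coords=True)
    reps = [RepeatInterval("c", 100, 300, "LTR/ERV", False)]
    assert te_flank_scan(table, "focus", reps, window_bp=5000) == []


def test_flank_distances_bounded_by_window():
    table = build_table("sp", {"c": ["g0", "focus"]}, coords=True,
                        spacing=100_000, width=1_000)
    reps = [RepeatInterval("c", s, s + 50, "DNA/TcMar", True)
            for s in range(0, 200_000, 7_000)]
    for hit in te_flank_scan(table, "focus", reps, window_bp=3_000):
        assert hit["distance"] <= 3_000


def test_repeat_bed_classification():
    tir = RepeatInterval.from_bed_line("chr1\t10\t60\tDNA/TcMar-Tigger")
    line = RepeatInterval.from_bed_line("chr1\t80\t120\tLINE/L2")
    assert tir.has_TIR and not line.has_TIR


def test_marker_sits_at_the_copy_not_the_parent(h1_dataset):
    table = h1_dataset.genomes["frogs"]
    reps = h1_dataset.repeats["frogs"]
    assert te_flank_scan(table, "OT", reps, window_bp=1_000)
    assert te_flank_scan(table, "VT_a", reps, window_bp=1_000) == []


# ---------------------------------------------------------------------------
# pair orientation
# ---------------------------------------------------------------------------

def test_same_strand_pair_is_tail_to_head():
    table = build_table("sp", {"c": [("A", "+"), ("B", "+"), ("n1", "+")]})
    res = pair_orientation(table, "A", "B")
    assert res["orientation"] == "tail_to_head" and res["inverted"] is None


def test_inverted_member_found_by_neighbourhood_majority():
    specs = [(f"u{i}", "+") for i in range(5)] + [("A", "-"), ("B", "+")] + \
            [(f"d{i}", "+") for i in range(5)]
    table = build_table("sp", {"c": specs})
    res = pair_orientation(table, "A", "B")
    assert res["orientation"] == "head_to_head"  # 5' ends face each other
    assert res["inverted"] == "A" and not res["ambiguous"]


def test_placental_like_pair_calls_the_copy_inverted(h1_dataset):
    res = pair_orientation(h1_dataset.genomes["mammals"], "OT", "VT_a")
    assert res["orientation"] == "tail_to_tail"
    assert res["inverted"] == "OT"
    res2 = pair_orientation(h1_dataset.genomes["birds"], "OT", "VT_a")
    assert res2["orientation"] == "tail_to_head"


def test_orientation_invariant_under_chromosome_flip():
    rng = random.Random(5)
    for trial in range(15):
        strands = [rng.choice("+-") for _ in range(12)]
        strands[5], strands[6] = "+", "-"
        specs = [(f"g{i}", s) for i, s in enumerate(strands)]
        fwd = build_table("sp", {"c": specs})
        flipped = build_table("sp", {"c": [(g, "+" if s == "-" else "-")
                                           for g, s in reversed(specs)]})
        a = pair_orientation(fwd, "g5", "g6")
        b = pair_orientation(flipped, "g5", "g6")
        assert a["orientation"] == b["orientation"]
        assert a["inverted"] == b["inverted"]


def test_pair_on_different_chromosomes_rejected():
    table = build_table("sp", {"c": [("A", "+")], "d": [("B", "+")]})
    with pytest.raises(ValueError):
        pair_orientation(table, "A", "B")
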