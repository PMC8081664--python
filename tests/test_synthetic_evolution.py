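"""Event semantics, replay determinism, bookkeeping and ground truth of
the gene-order evolution simulator."""

import pytest

from synorth import fixtures
from synorth.locus_features import pair_orientation
from synorth.synthetic_evolution import (Event, EventError, apply_event,
                                         replay, simulate, truth_orthogroups)
from synorth.species_tree import SpeciesTree

from conftest import build_table


def test_wgd_doubles_everything():
    t = build_table("sp", {"c1": [f"a{i}" for i in range(7)],
                           "c2": [f"b{i}" for i in range(4)]})
    out = apply_event(t, Event("WGD", None, {}))
    assert sorted(out.chromosomes) == ["c1_a", "c1_b", "c2_a", "c2_b"]
    assert out.n_genes == 22
    assert out.get("a0_a").family == out.get("a0_b").family == "a0"


def test_inversion_reverses_order_and_flips_strands():
    t = build_table("sp", {"c": [f"g{i}" for i in range(7)]})
    out = apply_event(t, Event("INVERSION", None, {"chrom": "c", "start": 2, "end": 5}))
    assert [r.gene_id for r in out.chromosomes["c"]] == \
        ["g0", "g1", "g4", "g3", "g2", "g5", "g6"]
    strands = {r.gene_id: r.strand for r in out.chromosomes["c"]}
    assert strands["g2"] == strands["g3"] == strands["g4"] == "-"
    assert strands["g0"] == strands["g5"] == "+"
    assert [r.order_index for r in out.chromosomes["c"]] == list(range(7))


def test_tandem_dup_then_inversion_gives_tail_to_tail_pair():
    # the monotreme/placental configuration: the copy, not the parent, flips
    t = build_table("sp", {"c": [(f"n{i}", "-") for i in range(5)]
                           + [("VT", "-")] + [(f"m{i}", "-") for i in range(5)]})
    t = apply_event(t, Event("TANDEM_DUP", None,
                             {"gene": "VT", "side": "before", "copy_id": "OT"}))
    assert pair_orientation(t, "OT", "VT")["orientation"] == "tail_to_head"
    idx = t.get("OT").order_index
    t = apply_event(t, Event("INVERSION", None,
                             {"chrom": "c", "start": idx, "end": idx + 1}))
    res = pair_orientation(t, "OT", "VT")
    assert res["orientation"] == "tail_to_tail"
    assert res["inverted"] == "OT"


def test_segment_events_bookkeeping():
    t = build_table("sp", {"c": [f"g{i}" for i in range(10)], "d": ["h0", "h1"]})
    n = t.n_genes
    dup = apply_event(t, Event("SEG_DUP", None,
                               {"chrom": "c", "start": 2, "end": 5,
                                "dest_chrom": "d", "dest_index": 1}))
    assert dup.n_genes == n + 3
    assert [r.gene_id for r in dup.chromosomes["d"]] == ["h0", "g2_s", "g3_s", "g4_s", "h1"]
    lost = apply_event(dup, Event("SEGMENT_LOSS", None,
                                  {"chrom": "c", "start": 0, "end": 4}))
    assert lost.n_genes == n + 3 - 4
    moved = apply_event(t, Event("TRANSLOCATION", None,
                                 {"chrom": "c", "start": 0, "end": 2,
                                  "dest_chrom": "d", "dest_index": 2}))
    assert moved.n_genes == n
    assert [r.gene_id for r in moved.chromosomes["d"]] == ["h0", "h1", "g0", "g1"]
    split = apply_event(t, Event("FISSION", None, {"chrom": "c", "at": 4}))
    assert split.n_genes == n
    assert len(split.chromosomes["c"]) == 4 and len(split.chromosomes["c_f"]) == 6


def test_event_errors_name_the_event():
    t = build_table("sp", {"c": ["g0", "g1"]})
    with pytest.raises(EventError, match="SEGMENT_LOSS"):
        apply_event(t, Event("SEGMENT_LOSS", "somebranch",
                             {"chrom": "c", "start": 0, "end": 9}))
    with pytest.raises(EventError, match="unknown event kind"):
        Event("POLYPLOIDY", None, {})


TINY_TREE = "((x,y)xy,z)root;"


def tiny_config(events=None, rates=None):
    return {"species_tree": TINY_TREE,
            "ancestor": {"c1": [f"g{i}" for i in range(12)]},
            "events": events or {}, "rates": rates or {}}


def test_zero_events_gives_identical_genomes():
    ds = simulate(tiny_config(), seed=5)
    tables = list(ds.genomes.values())
    assert all(t.n_genes == 12 for t in tables)
    ids = [[r.gene_id for r in t.chromosomes["c1"]] for t in tables]
    assert ids[0] == ids[1] == ids[2]
    assert ds.event_log == []


def test_same_seed_reproduces_dataset_bytes():
    cfg = tiny_config(rates={"*": {"TANDEM_DUP": 0.8, "GENE_LOSS": 0.8,
                                   "INVERSION": 0.5}})
    a = simulate(cfg, seed=42)
    b = simulate(cfg, seed=42)
    assert [e.to_dict() for e in a.event_log] == [e.to_dict() for e in b.event_log]
    for sp in a.genomes:
        assert a.genomes[sp].to_tsv() == b.genomes[sp].to_tsv()


def test_replay_of_event_log_reproduces_emitted_genomes():
    cfg = tiny_config(rates={"*": {"TANDEM_DUP": 1.0, "GENE_LOSS": 1.0}})
    ds = simulate(cfg, seed=3)
    by_branch = {}
    for ev in ds.event_log:
        by_branch.setdefault(ev.branch, []).append(ev)
    tree = SpeciesTree.from_newick(TINY_TREE)
    from synorth.synthetic_evolution import _ancestor_from_config, assign_coordinates
    genomes = replay(tree, _ancestor_from_config(cfg), by_branch)
    for leaf in tree.leaves:
        again = genomes[leaf]
        assign_coordinates(again)
        assert again.to_tsv() == ds.genomes[leaf].to_tsv()


def test_negative_rates_rejected():
    with pytest.raises(ValueError, match="rates"):
        simulate(tiny_config(rates={"*": {"GENE_LOSS": -1.0}}), seed=0)


def test_truth_status_lost_vs_territory_absent():
    # one leaf loses just the focus gene, the other loses the whole block
    events = {"x": [{"kind": "GENE_LOSS", "gene": "g6"}],
              "y": [{"kind": "SEGMENT_LOSS", "chrom": "c1", "start": 1, "end": 12}]}
    cfg = tiny_config(events=events)
    cfg["naming"] = {"g6": "FOCUS"}
    ds = simulate(cfg, seed=0)
    truth = truth_orthogroups(ds, {"g6"})
    assert truth.status("FOCUS", "x") == "gene_lost_territory_present"
    assert truth.status("FOCUS", "y") == "territory_absent"
    assert truth.status("FOCUS", "z") == "present"


def test_panel_truth_matches_encoded_presence_matrix(h1_dataset):
    truth = truth_orthogroups(h1_dataset, {"VTR", "VT"})
    got = truth.presence_matrix()
    expected = fixtures.fig_presence_matrix()
    for og in expected.index:
        for sp in expected.columns:
            cell = got.loc[og, sp] if og in got.index and sp in got.columns else "."
            assert cell == expected.loc[og, sp], (og, sp)


def test_te_mark_survives_at_the_tandem_copy(h1_dataset):
    reps = h1_dataset.repeats["birds"]
    assert len(reps) == 1 and reps[0].has_TIR
    ot = h1_dataset.genomes["birds"].get("OT")
    assert reps[0].chrom == ot.chrom
    # no repeats in species that predate the duplication
    assert h1_dataset.repeats["lampreys"] == []
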