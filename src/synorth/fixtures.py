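"""Packaged fixtures: the vertebrate lineage tree, the printed
presence/absence matrix of the oxytocin–vasotocin ligand and receptor
genes, the synthetic-genome configuration whose replay reproduces that
matrix, and the two competing duplication scenarios (one round of WGD
plus segmental duplications, versus two rounds of WGD).

The synthetic world is a *stated* one: gene content, co-locations,
territory fates and separations encode what comparative annotation of the
real genomes shows (six receptors in jawed vertebrates, four in lampreys,
two in hagfishes; OTR with VTR2B and VTR1A with VTR2A on shared
chromosomes; VTR1B and VTR2C alone on theirs; a mammalian fission at the
deleted VTR2A locus; the tandem OT/VT pair with a TE-TIR flank on OT and
a placental OT inversion).  Neighbour-gene blocks are sized so that
five-gene windows behave the way the real ones do: orthologous windows
share ten families, paralogous windows share at most two.
"""

from __future__ import annotations

import pandas as pd

from .genome_model import GenomeTable, GeneRecord
from .scenario_parsimony import RepertoireObservation
from .synthetic_evolution import Event

RECEPTOR_UNIVERSE = {"OTR", "VTR1A", "VTR1B", "VTR2A", "VTR2B", "VTR2C"}
UNIVERSAL_NAMES = {"OT", "VT"} | RECEPTOR_UNIVERSE

LINEAGES = ["mammals", "birds", "turtles_crocodiles", "frogs", "coelacanth",
            "holostei", "teleostei", "sharks", "lampreys", "hagfishes"]

GNATHOSTOMES = ["mammals", "birds", "turtles_crocodiles", "frogs",
                "coelacanth", "holostei", "teleostei", "sharks"]


def species_tree_newick() -> str:
    """Lineage-level vertebrate tree (hagfishes placed outside the
    lamprey+gnathostome clade, i.e. cyclostome paraphyly)."""
    return ("(hagfishes,(lampreys,(sharks,((holostei,teleostei)neopterygii,"
            "(coelacanth,(frogs,((turtles_crocodiles,birds)archosauria,"
            "mammals)amniota)tetrapoda)sarcopterygii)osteichthyes)"
            "gnathostomata)vertebrata_core)vertebrata;")


def fig_presence_matrix() -> pd.DataFrame:
    """Encoded phylogenetic distribution of the ligand and receptor genes.

    Glyphs: ``1`` the gene is present, ``0`` the gene was lost (its
    syntenic territory remains), ``.`` the gene never evolved in that
    lineage (or no trace of gene nor territory).
    """
    rows = {
        #            mam  bir  tur  fro  coe  hol  tel  sha  lam  hag
        "OT":      ["1", "1", "1", "1", "1", "1", "1", "1", ".", "."],
        "VT":      ["1", "1", "1", "1", "1", "1", "1", "1", "1", "1"],
        "OTR":     ["1", "1", "1", "1", "1", "1", "1", "1", "1", "."],
        "VTR1A":   ["1", "1", "1", "1", "1", "1", "1", "1", "1", "."],
        "VTR1B":   ["1", "1", "1", "1", "1", "0", "0", "1", ".", "."],
        "VTR2A":   ["0", "1", "1", "1", "1", "1", "0", "1", "1", "."],
        "VTR2B":   ["0", "0", "0", "0", "1", "1", "1", "1", "1", "."],
        "VTR2C":   ["1", "0", "1", "1", "1", "1", "1", ".", ".", "."],
        "VTR1":    [".", ".", ".", ".", ".", ".", ".", ".", ".", "1"],
        "VTR2":    [".", ".", ".", ".", ".", ".", ".", ".", ".", "1"],
    }
    return pd.DataFrame(rows, index=LINEAGES).T


# ---------------------------------------------------------------------------
# full synthetic-genome configuration
# ---------------------------------------------------------------------------

# orthogroup labels for every focus-gene id that appears during replay
SIM_NAMING = {
    "VTR": "VTR1", "VTR_2": "VTR2",               # hagfish (pre-WGD) receptors
    "VTR_a": "VTR1A", "VTR_2_a": "VTR2A",
    "VTR_b": "OTR", "VTR_b_t": "OTR",             # incl. the teleost tandem copy
    "VTR_2_b": "VTR2B",
    "VTR_a_s": "VTR1B", "VTR_2_b_s": "VTR2C",
    "VT": "VT", "VT_a": "VT", "OT": "OT",
}


def _rng(prefix: str, n: int, start: int = 1) -> list[str]:
    return [f"{prefix}{i}" for i in range(start, start + n)]


def sim_config() -> dict:
    """Simulation settings whose replay yields extant genomes matching the
    encoded presence matrix, co-locations and territory statements.

    Ancestral chromosome c1 carries the single receptor precursor flanked
    by proximal blocks (A/M/B, which undergo complementary post-WGD loss
    so the two chromosome copies become distinguishable at window scale)
    and distal blocks (D/E, retained on both copies so chromosome-scale
    paralogy stays detectable).  c2/c3 are the host chromosomes that later
    receive the translocated segmental duplicates; c4 carries the ligand.
    """
    ancestor = {
        "c1": _rng("D", 12) + _rng("A", 10) + ["VTR"] + _rng("M", 24)
              + _rng("B", 10) + _rng("E", 12),
        "c2": _rng("F", 20),
        "c3": _rng("G", 20),
        "c4": [{"id": k, "strand": "-"} for k in _rng("K", 8)]
              + [{"id": "VT", "strand": "-"}]
              + [{"id": k, "strand": "-"} for k in _rng("K", 8, start=9)],
    }

    odds = [1, 3, 5, 7, 9]
    evens = [2, 4, 6, 8, 10]
    c1_a_losses = [{"kind": "GENE_LOSS", "gene": f"A{i}_a"} for i in evens] + \
                  [{"kind": "GENE_LOSS", "gene": f"M{i}_a"} for i in range(2, 25, 2)] + \
                  [{"kind": "GENE_LOSS", "gene": f"B{i}_a"} for i in evens]
    c1_b_losses = [{"kind": "GENE_LOSS", "gene": f"A{i}_b"} for i in odds] + \
                  [{"kind": "GENE_LOSS", "gene": f"M{i}_b"} for i in range(1, 24, 2)] + \
                  [{"kind": "GENE_LOSS", "gene": f"B{i}_b"} for i in odds]

    events = {
        # the ligand/receptor precursor duplications shared by every vertebrate
        "vertebrata": [
            # tandem segmental duplication of the single ancestral receptor,
            # copy landing downstream on the same chromosome (VTR1 + VTR2)
            {"kind": "SEG_DUP", "chrom": "c1", "start": 22, "end": 23,
             "dest_chrom": "c1", "dest_index": 47, "copy_suffix": "_2"},
        ],
        # fragmented hagfish assembly: the two receptors end up on two scaffolds
        "hagfishes": [
            {"kind": "FISSION", "chrom": "c1", "at": 35, "new_chrom": "c1_scaf2"},
        ],
        "vertebrata_core": [
            {"kind": "WGD"},
            # rediploidisation: one copy of the non-receptor chromosomes is lost
            {"kind": "SEGMENT_LOSS", "chrom": "c2_b", "start": 0, "end": 20},
            {"kind": "SEGMENT_LOSS", "chrom": "c3_b", "start": 0, "end": 20},
            {"kind": "SEGMENT_LOSS", "chrom": "c4_b", "start": 0, "end": 17},
            # complementary loss differentiates the two receptor chromosomes
            *c1_a_losses, *c1_b_losses,
        ],
        "gnathostomata": [
            # translocated segmental duplication: VTR1A region -> VTR1B on c2_a
            {"kind": "SEG_DUP", "chrom": "c1_a", "start": 16, "end": 19,
             "dest_chrom": "c2_a", "dest_index": 6, "copy_suffix": "_s"},
            # tandem duplication of VT gives OT, TE-TIR flank at the copy
            {"kind": "TANDEM_DUP", "gene": "VT_a", "side": "before",
             "copy_id": "OT", "mark_te_flank": True},
        ],
        "osteichthyes": [
            # translocated segmental duplication: VTR2B region -> VTR2C on c3_a
            {"kind": "SEG_DUP", "chrom": "c1_b", "start": 29, "end": 32,
             "dest_chrom": "c3_a", "dest_index": 6, "copy_suffix": "_s"},
        ],
        "lampreys": [
            # lineage-specific divergence wipes the (future) insertion-site
            # context, so the VTR1B/VTR2C territories are untraceable here
            {"kind": "SEGMENT_LOSS", "chrom": "c2_a", "start": 2, "end": 10},
            {"kind": "SEGMENT_LOSS", "chrom": "c3_a", "start": 2, "end": 10},
        ],
        "neopterygii": [
            {"kind": "GENE_LOSS", "gene": "VTR_a_s"},          # VTR1B
        ],
        "teleostei": [
            {"kind": "GENE_LOSS", "gene": "VTR_2_a"},          # VTR2A
            {"kind": "TANDEM_DUP", "gene": "VTR_b", "copy_id": "VTR_b_t"},  # OTRb
            {"kind": "INVERSION", "chrom": "c2_a", "start": 12, "end": 16},
            # OT moved a few genes away from VT, still one chromosome
            {"kind": "TRANSLOCATION", "chrom": "c4_a", "start": 8, "end": 9,
             "dest_chrom": "c4_a", "dest_index": 14},
        ],
        "tetrapoda": [
            {"kind": "GENE_LOSS", "gene": "VTR_2_b"},          # VTR2B
        ],
        "mammals": [
            {"kind": "GENE_LOSS", "gene": "VTR_2_a"},          # VTR2A ...
            {"kind": "FISSION", "chrom": "c1_a", "at": 30,     # ... plus fission
             "new_chrom": "c1_a_fis"},                         #     at the locus
            {"kind": "INVERSION", "chrom": "c4_a", "start": 8, "end": 9},  # OT flips
        ],
        "birds": [
            # the block around VTR2C is deleted, not just the gene
            {"kind": "SEGMENT_LOSS", "chrom": "c3_a", "start": 5, "end": 9},
        ],
    }
    return {"species_tree": species_tree_newick(), "ancestor": ancestor,
            "events": events, "naming": dict(SIM_NAMING)}


# ---------------------------------------------------------------------------
# duplication scenarios (origin of the six receptors)
# ---------------------------------------------------------------------------

H1_NAMING = {"VTR": "VTR1", "VTR_2": "VTR2",
             "VTR_a": "VTR1A", "VTR_2_a": "VTR2A",
             "VTR_b": "OTR", "VTR_2_b": "VTR2B",
             "VTR_a_s": "VTR1B", "VTR_2_b_s": "VTR2C"}

H2_NAMING = {"VTR": "VTR1", "VTR_2": "VTR2",
             "VTR_a_a": "VTR1A", "VTR_2_a_a": "VTR2A",
             "VTR_b_a": "OTR", "VTR_2_b_a": "VTR2B",
             "VTR_a_b": "VTR1B", "VTR_2_a_b": "VTR2C",
             "VTR_b_b": "VTR1C", "VTR_2_b_b": "VTR2D"}


def scenario_ancestor() -> GenomeTable:
    """Minimal ancestral genome for scenario replay: one chromosome, one
    receptor precursor."""
    t = GenomeTable("ancestor")
    t.add(GeneRecord(gene_id="VTR", species="ancestor", chrom="anc1",
                     order_index=0, strand="+", family="VTR"))
    return t


def h1_origin_scenario() -> list[Event]:
    """One-round-WGD hypothesis: tandem segmental duplication (VTR1+VTR2),
    one whole-genome duplication, then two lineage-anchored translocated
    segmental duplications (VTR1B, VTR2C).  Unit-cost steps: 1+1+2+2."""
    return [
        Event("SEG_DUP", "vertebrata",
              {"chrom": "anc1", "start": 0, "end": 1,
               "dest_chrom": "anc1", "dest_index": 1, "copy_suffix": "_2"}),
        Event("WGD", "vertebrata_core", {}),
        Event("SEG_DUP", "gnathostomata",
              {"chrom": "anc1_a", "start": 0, "end": 1,
               "dest_chrom": "sd1", "copy_suffix": "_s"}),
        Event("SEG_DUP", "osteichthyes",
              {"chrom": "anc1_b", "start": 1, "end": 2,
               "dest_chrom": "sd2", "copy_suffix": "_s"}),
    ]


def h2_origin_scenario() -> list[Event]:
    """Two-round-WGD hypothesis: tandem segmental duplication then two
    whole-genome duplications before the cyclostome divergence, plus the
    events the observations force — loss of the never-observed
    (VTR1C, VTR2D) chromosome in the stem ancestor, a fission separating
    VTR1B from VTR2C (observed on different chromosomes), segment losses
    in both cyclostome lineages, and the shark-lineage VTR2C loss."""
    return [
        Event("SEG_DUP", "vertebrata",
              {"chrom": "anc1", "start": 0, "end": 1,
               "dest_chrom": "anc1", "dest_index": 1, "copy_suffix": "_2"}),
        Event("WGD", "vertebrata", {}),
        Event("WGD", "vertebrata", {}),
        Event("SEGMENT_LOSS", "vertebrata", {"chrom": "anc1_b_b", "start": 0, "end": 2}),
        Event("FISSION", "gnathostomata", {"chrom": "anc1_a_b", "at": 1}),
        Event("SEGMENT_LOSS", "hagfishes", {"chrom": "anc1_b_a", "start": 0, "end": 2}),
        Event("SEGMENT_LOSS", "hagfishes", {"chrom": "anc1_a_b", "start": 0, "end": 2}),
        Event("SEGMENT_LOSS", "lampreys", {"chrom": "anc1_a_b", "start": 0, "end": 2}),
        Event("GENE_LOSS", "sharks", {"gene": "VTR_2_a_b"}),
    ]


def shared_loss_events(hypothesis: str) -> list[Event]:
    """The five lineage-specific receptor losses both hypotheses agree on
    (VTR2B in tetrapods, VTR2A in mammals and in teleosts, VTR1B in
    holostei+teleostei, VTR2C in birds); excluded from both step counts."""
    ids = {"h1": {"VTR2B": "VTR_2_b", "VTR2A": "VTR_2_a",
                  "VTR1B": "VTR_a_s", "VTR2C": "VTR_2_b_s"},
           "h2": {"VTR2B": "VTR_2_b_a", "VTR2A": "VTR_2_a_a",
                  "VTR1B": "VTR_a_b", "VTR2C": "VTR_2_a_b"}}[hypothesis]
    return [
        Event("GENE_LOSS", "tetrapoda", {"gene": ids["VTR2B"]}),
        Event("GENE_LOSS", "mammals", {"gene": ids["VTR2A"]}),
        Event("GENE_LOSS", "teleostei", {"gene": ids["VTR2A"]}),
        Event("GENE_LOSS", "neopterygii", {"gene": ids["VTR1B"]}),
        Event("GENE_LOSS", "birds", {"gene": ids["VTR2C"]}),
    ]


def observed_repertoires() -> RepertoireObservation:
    """The receptor observations the scenarios must reproduce: per-lineage
    presence (from the encoded matrix), the chromosome co-locations and
    separations reported across species, and the hagfish two-receptor
    count."""
    matrix = fig_presence_matrix()
    presence = {}
    for lineage in LINEAGES:
        if lineage == "hagfishes":
            continue  # fragmentary; constrained via the count instead
        presence[lineage] = {og for og in RECEPTOR_UNIVERSE
                             if matrix.loc[og, lineage] == "1"}
    colocated = {}
    for lineage in ["coelacanth", "holostei", "teleostei", "sharks", "lampreys"]:
        colocated.setdefault(lineage, set()).add(frozenset({"OTR", "VTR2B"}))
    for lineage in ["birds", "turtles_crocodiles", "frogs", "coelacanth",
                    "holostei", "sharks", "lampreys"]:
        colocated.setdefault(lineage, set()).add(frozenset({"VTR1A", "VTR2A"}))
    separated = {lineage: {frozenset({"VTR1B", "VTR2C"})}
                 for lineage in ["mammals", "turtles_crocodiles", "frogs",
                                 "coelacanth"]}
    return RepertoireObservation(universe=set(RECEPTOR_UNIVERSE),
                                 presence=presence, colocated=colocated,
                                 separated=separated,
                                 counts={"hagfishes": 2})
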