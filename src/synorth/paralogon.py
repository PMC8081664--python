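"""Intraspecies territory analysis: windows around present and deleted
receptor loci, the pairwise gene-family overlap matrix, and anchoring of
deleted loci via a donor species that retains the gene.

A *territory* is the gene-family content of a fixed-size neighbourhood
(10 Mb of sequence, or the 40 nearest genes when bp coordinates are
missing) around an anchor.  Overlap between territories is counted on
family identity, not gene identity: two chromosomal regions descended
from one ancestral region via duplication (a paralogon) betray themselves
by the paralogous families they still share.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_model import GenomeTable, HomologyFamilies, neighbors

__all__ = ["Territory", "territory", "deleted_locus_anchor", "territory_overlap"]


@dataclass
class Territory:
    species: str
    anchor: str | tuple[str, ...]
    chrom: str
    window_spec: str           # e.g. "bp:10000000" or "genes:40"
    members: list[str]
    families: set[str]
    label: str = ""

    def __post_init__(self):
        if not self.label:
            self.label = f"{self.species}:{self.anchor}"


def _family_of(rec, families: HomologyFamilies | None) -> str | None:
    if families is not None:
        fam = families.family_of(rec.gene_id)
        if fam is not None:
            return fam
    return rec.family


def territory(table: GenomeTable, anchor: str,
              families: HomologyFamilies | None = None,
              window_bp: int = 10_000_000, window_genes: int = 40,
              mode: str | None = None, label: str = "") -> Territory:
    """Neighbourhood of one anchor gene.

    bp mode (used whenever coordinates exist, unless overridden) collects
    genes whose midpoint lies within +/- window_bp/2 of the anchor
    midpoint; gene mode collects the ``window_genes`` nearest genes by
    order distance (ties resolved upstream first).  The anchor itself is
    a member.  The mode actually used is recorded in ``window_spec``.
    """
    rec = table.get(anchor)
    if not table.placed.get(rec.chrom, True):
        raise ValueError(f"anchor {anchor!r} sits on an unplaced scaffold")
    recs = table.chromosomes[rec.chrom]
    if mode is None:
        mode = "bp" if rec.start is not None else "genes"
    if mode == "bp":
        if rec.start is None:
            raise ValueError(f"anchor {anchor!r} has no bp coordinates")
        mid = rec.midpoint
        members = [r for r in recs
                   if r.start is not None and abs(r.midpoint - mid) <= window_bp / 2]
        spec = f"bp:{window_bp}"
    elif mode == "genes":
        i = rec.order_index
        ranked = sorted(recs, key=lambda r: (abs(r.order_index - i),
                                             r.order_index - i))
        members = sorted(ranked[:window_genes + 1], key=lambda r: r.order_index)
        spec = f"genes:{window_genes}"
    else:
        raise ValueError(f"unknown territory mode {mode!r}")
    fams = {f for r in members if (f := _family_of(r, families)) is not None}
    return Territory(species=table.species, anchor=anchor, chrom=rec.chrom,
                     window_spec=spec, members=[r.gene_id for r in members],
                     families=fams, label=label or anchor)


def deleted_locus_anchor(donor_table: GenomeTable, target_table: GenomeTable,
                         families: HomologyFamilies | None, donor_gene: str,
                         k: int = 5) -> dict:
    """Locate the territory of a gene deleted in the target species by
    projecting the donor's 10-gene flanking families onto the target.

    Returns the matched target genes grouped by chromosome, an anchor
    midpoint per chromosome, and a ``split`` flag when the flanks resolve
    to two or more chromosomes (each holding at least two matched
    families) — the signature of a fission at the deleted locus.
    Raises when fewer than two flanking families can be found (territory
    untraceable).
    """
    up, down = neighbors(donor_table, donor_gene, k)
    flank_fams = []
    for r in up[::-1] + down:
        fam = _family_of(r, families)
        if fam is not None and fam not in flank_fams:
            flank_fams.append(fam)
    matches: dict[str, list] = {}
    matched_fams: dict[str, set[str]] = {}
    for rec in target_table.genes():
        fam = _family_of(rec, families)
        if fam in flank_fams:
            matches.setdefault(rec.chrom, []).append(rec)
            matched_fams.setdefault(rec.chrom, set()).add(fam)
    total_fams = set().union(*matched_fams.values()) if matched_fams else set()
    if len(total_fams) < 2:
        raise ValueError(
            f"territory of {donor_gene!r} untraceable in {target_table.species}: "
            f"only {len(total_fams)} flanking families found")
    anchors = {}
    for chrom, recs in matches.items():
        recs.sort(key=lambda r: r.order_index)
        if all(r.start is not None for r in recs):
            mid = (recs[0].start + recs[-1].end) / 2
        else:
            mid = (recs[0].order_index + recs[-1].order_index) / 2
        anchors[chrom] = {"genes": [r.gene_id for r in recs],
                          "families": sorted(matched_fams[chrom]),
                          "anchor_midpoint": mid}
    informative = [c for c, f in matched_fams.items() if len(f) >= 2]
    return {"donor_gene": donor_gene, "flank_families": flank_fams,
            "anchors": anchors, "split": len(informative) >= 2,
            "chromosomes": sorted(anchors)}


def territory_overlap(territories: list[Territory]) -> tuple[pd.DataFrame, dict]:
    """Symmetric matrix of shared-family counts between territories.

    The diagonal holds each territory's own family count; the companion
    dict maps (label_i, label_j) to the sorted shared-family list.
    """
    if len(territories) < 2:
        raise ValueError("need at least two territories")
    labels = [t.label for t in territories]
    if len(set(labels)) != len(labels):
        raise ValueError("territory labels must be unique")
    n = len(territories)
    mat = np.zeros((n, n), dtype=int)
    shared: dict[tuple[str, str], list[str]] = {}
    for i, a in enumerate(territories):
        mat[i, i] = len(a.families)
        for j in range(i + 1, n):
            b = territories[j]
            common = sorted(a.families & b.families)
            mat[i, j] = mat[j, i] = len(common)
            shared[(a.label, b.label)] = common
    return pd.DataFrame(mat, index=labels, columns=labels), shared
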