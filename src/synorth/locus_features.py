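"""Locus-level descriptors of the OT/VT tandem pair: GC content, intron
length comparison, TE-TIR flank detection and gene-pair orientation with
inversion attribution.

Orientation classes follow transcriptional geometry: *tail-to-head* means
consecutive genes on the same strand; for opposite-strand pairs the class
is named by which gene ends face each other (3'-3' = tail-to-tail,
5'-5' = head-to-head).  The inverted member of a non-tail-to-head pair is
the one whose strand disagrees with the majority strand of its own
five-gene neighbourhood — duplicated copies invert, territories do not.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_model import GenomeTable, neighbors

__all__ = [
    "RepeatInterval", "GeneStructure",
    "gc_content", "intron_metrics", "te_flank_scan", "pair_orientation",
]

NUCLEOTIDES = set("ACGTN")


@dataclass(frozen=True)
class RepeatInterval:
    chrom: str
    start: int
    end: int
    repeat_class: str
    has_TIR: bool = False

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"repeat end ({self.end}) must exceed start ({self.start})")

    @classmethod
    def from_bed_line(cls, line: str) -> "RepeatInterval":
        f = line.rstrip("\n").split("\t")
        rc = f[3] if len(f) > 3 else "unknown"
        # TIR-bearing cut-and-paste superfamilies (RepeatMasker class names)
        tir = any(tok in rc for tok in ("TIR", "TcMar", "hAT", "PIF", "Merlin",
                                        "MULE", "CACTA", "PiggyBac"))
        return cls(chrom=f[0], start=int(f[1]), end=int(f[2]),
                   repeat_class=rc, has_TIR=tir)


def gc_content(sequence: str) -> float | None:
    """Percent G+C over A/C/G/T; N is excluded from the denominator.

    Returns None (flagged undefined) when the effective length is zero.
    Raises on any non-nucleotide character.
    """
    seq = sequence.upper()
    bad = set(seq) - NUCLEOTIDES
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    n = sum(1 for c in seq if c != "N")
    if n == 0:
        return None
    gc = seq.count("G") + seq.count("C")
    return 100.0 * gc / n


@dataclass
class GeneStructure:
    """Exon layout of one gene; introns are the gaps between exons."""

    gene_id: str
    exons: list[tuple[int, int]]
    sequence: str | None = None  # genomic sequence spanning exons[0][0]..exons[-1][1]

    def __post_init__(self):
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        self.exons = ex

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    def intron_sequence(self, rank: int) -> str | None:
        if self.sequence is None:
            return None
        offset = self.exons[0][0]
        s, e = self.introns[rank]
        return self.sequence[s - offset:e - offset]


def intron_metrics(a: GeneStructure, b: GeneStructure) -> dict:
    """Rank-aligned intron length comparison between two genes.

    Reports per-rank lengths, length ratio (a/b), which gene is shorter,
    and intron GC when sequence is available.  Mismatched intron counts
    are compared up to the shorter list and flagged.
    """
    ia, ib = a.introns, b.introns
    if not ia or not ib:
        raise ValueError("both genes need at least one intron")
    n = min(len(ia), len(ib))
    rows = []
    for r in range(n):
        la = ia[r][1] - ia[r][0]
        lb = ib[r][1] - ib[r][0]
        row = {
            "rank": r, "length_a": la, "length_b": lb,
            "ratio_a_over_b": la / lb if lb else float("inf"),
            "shorter": a.gene_id if la < lb else (b.gene_id if lb < la else "tie"),
        }
        sa, sb = a.intron_sequence(r), b.intron_sequence(r)
        if sa is not None:
            row["gc_a"] = gc_content(sa)
        if sb is not None:
            row["gc_b"] = gc_content(sb)
        rows.append(row)
    return {"per_rank": rows,
            "count_mismatch": len(ia) != len(ib),
            "n_compared": n}


def te_flank_scan(table: GenomeTable, gene_id: str, repeats,
                  window_bp: int = 1000) -> list[dict]:
    """TIR-bearing repeats overlapping [start - window, end + window) of the
    gene; reports flank side (5'/3' relative to the chromosome) and
    distance (0 when overlapping the gene body)."""
    rec = table.get(gene_id)
    if rec.start is None or rec.end is None:
        raise ValueError(f"{gene_id} has no bp coordinates")
    out = []
    for rep in repeats:
        if not rep.has_TIR or rep.chrom != rec.chrom:
            continue
        if rep.end <= rec.start - window_bp or rep.start >= rec.end + window_bp:
            continue
        if rep.end <= rec.start:
            side, dist = "5'", rec.start - rep.end
        elif rep.start >= rec.end:
            side, dist = "3'", rep.start - rec.end
        else:
            side, dist = "overlap", 0
        out.append({"repeat": rep, "side": side, "distance": dist})
    return sorted(out, key=lambda d: (d["distance"], d["repeat"].start))


def _majority_strand(table: GenomeTable, gene_id: str, exclude: set[str],
                     k: int = 5) -> str | None:
    up, down = neighbors(table, gene_id, k)
    votes = [r.strand for r in up + down
             if r.gene_id not in exclude and r.strand in ("+", "-")]
    plus = votes.count("+")
    minus = votes.count("-")
    if plus == minus:
        return None
    return "+" if plus > minus else "-"


def pair_orientation(table: GenomeTable, gene_a: str, gene_b: str) -> dict:
    """Orientation class of two genes on one chromosome, plus which member
    (if any) is inverted relative to its territory."""
    ra, rb = table.get(gene_a), table.get(gene_b)
    if ra.chrom != rb.chrom:
        raise ValueError(f"{gene_a} and {gene_b} are on different chromosomes")
    if ra.strand is None or rb.strand is None:
        raise ValueError("both genes need a strand for orientation calls")
    first, second = (ra, rb) if ra.order_index < rb.order_index else (rb, ra)
    if first.strand == second.strand:
        cls = "tail_to_head"
    elif (first.strand, second.strand) == ("+", "-"):
        cls = "tail_to_tail"   # 3' ends face each other
    else:
        cls = "head_to_head"   # 5' ends face each other

    inverted, flagged = None, False
    if cls != "tail_to_head":
        exclude = {ra.gene_id, rb.gene_id}
        offenders = []
        for rec in (ra, rb):
            maj = _majority_strand(table, rec.gene_id, exclude)
            if maj is None:
                flagged = True
            elif rec.strand != maj:
                offenders.append(rec.gene_id)
        if len(offenders) == 1:
            inverted = offenders[0]
        else:
            flagged = True
    return {"orientation": cls, "inverted": inverted, "ambiguous": flagged,
            "order": (first.gene_id, second.gene_id),
            "strands": (first.strand, second.strand)}
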