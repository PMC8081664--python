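"""Core data model: per-species gene orders, homology hits and families.

Gene *order* (rank along a chromosome) is the primary coordinate axis:
comparative windows are counted in genes, mirroring how microsynteny is
scored by eye in annotation browsers.  Base-pair coordinates are optional
and only used by bp-window operations (territories, repeat-flank scans).
All coordinates are 0-based half-open internally; GFF3's 1-based closed
intervals are converted on load.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import networkx as nx

__all__ = [
    "GeneRecord",
    "GenomeTable",
    "HomologyHit",
    "HomologyFamilies",
    "ParseError",
    "load_gene_orders",
    "read_homology_tsv",
    "filter_homology_hits",
    "build_families",
    "neighbors",
]

BIOTYPES = {"protein_coding", "miRNA", "lncRNA", "other"}


class ParseError(ValueError):
    """Malformed annotation or table input (carries the offending line no.)."""


@dataclass
class GeneRecord:
    gene_id: str
    species: str
    chrom: str
    order_index: int
    start: int | None = None
    end: int | None = None
    strand: str | None = None
    family: str | None = None
    biotype: str = "protein_coding"
    aliases: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.start is not None and self.end is not None and self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end ({self.end}) must exceed start ({self.start})")
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.biotype not in BIOTYPES:
            self.biotype = "other"

    @property
    def midpoint(self) -> float:
        if self.start is None or self.end is None:
            raise ValueError(f"{self.gene_id} has no bp coordinates")
        return (self.start + self.end) / 2.0


class GenomeTable:
    """Ordered gene records of one species, grouped by chromosome.

    Unplaced scaffolds are retained and flagged (``placed[chrom] = False``)
    rather than dropped: fragmented assemblies (hagfish, amphioxus) are
    exactly the cases where the flag matters downstream.
    """

    def __init__(self, species: str):
        self.species = species
        self.chromosomes: dict[str, list[GeneRecord]] = {}
        self.placed: dict[str, bool] = {}
        self._index: dict[str, GeneRecord] = {}

    # -- construction -------------------------------------------------
    def add(self, record: GeneRecord, placed: bool = True) -> None:
        if record.gene_id in self._index:
            raise ValueError(f"duplicate gene_id {record.gene_id!r} in {self.species}")
        if record.species != self.species:
            raise ValueError(f"{record.gene_id}: species {record.species!r} != {self.species!r}")
        self.chromosomes.setdefault(record.chrom, []).append(record)
        self.placed.setdefault(record.chrom, placed)
        self._index[record.gene_id] = record

    def reindex(self) -> None:
        """Restore the 0..n-1 order_index invariant on every chromosome.

        Records with coordinates are ordered by (start, end, gene_id); those
        without keep their current list order.
        """
        for chrom, recs in self.chromosomes.items():
            if all(r.start is not None for r in recs):
                recs.sort(key=lambda r: (r.start, r.end, r.gene_id))
            for i, r in enumerate(recs):
                r.order_index = i

    # -- access -------------------------------------------------------
    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def get(self, gene_id: str) -> GeneRecord:
        try:
            return self._index[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not found in {self.species}") from None

    def genes(self):
        for chrom in self.chromosomes:
            yield from self.chromosomes[chrom]

    @property
    def n_genes(self) -> int:
        return len(self._index)

    def copy(self) -> "GenomeTable":
        out = GenomeTable(self.species)
        for chrom, recs in self.chromosomes.items():
            for r in recs:
                out.add(replace(r, aliases=set(r.aliases)), placed=self.placed[chrom])
        return out

    # -- package TSV dialect ------------------------------------------
    TSV_HEADER = "gene_id\tspecies\tchrom\torder_index\tstart\tend\tstrand\tfamily\tbiotype\taliases\tplaced"

    def to_tsv(self) -> str:
        lines = [self.TSV_HEADER]
        for chrom in self.chromosomes:
            for r in self.chromosomes[chrom]:
                lines.append("\t".join([
                    r.gene_id, r.species, r.chrom, str(r.order_index),
                    "." if r.start is None else str(r.start),
                    "." if r.end is None else str(r.end),
                    r.strand or ".",
                    r.family or ".",
                    r.biotype,
                    ",".join(sorted(r.aliases)) or ".",
                    "1" if self.placed[chrom] else "0",
                ]))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "GenomeTable":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines or lines[0] != cls.TSV_HEADER:
            raise ParseError("missing or unrecognised GenomeTable TSV header")
        table: GenomeTable | None = None
        for lineno, ln in enumerate(lines[1:], start=2):
            f = ln.split("\t")
            if len(f) != 11:
                raise ParseError(f"line {lineno}: expected 11 fields, got {len(f)}")
            if table is None:
                table = cls(f[1])
            rec = GeneRecord(
                gene_id=f[0], species=f[1], chrom=f[2], order_index=int(f[3]),
                start=None if f[4] == "." else int(f[4]),
                end=None if f[5] == "." else int(f[5]),
                strand=None if f[6] == "." else f[6],
                family=None if f[7] == "." else f[7],
                biotype=f[8],
                aliases=set() if f[9] == "." else set(f[9].split(",")),
            )
            table.add(rec, placed=f[10] == "1")
        return table if table is not None else cls("empty")


# ---------------------------------------------------------------------------
# annotation loading
# ---------------------------------------------------------------------------

def _load_bed(lines: list[str], species: str) -> GenomeTable:
    table = GenomeTable(species)
    for lineno, ln in lines:
        f = ln.split("\t")
        if len(f) < 4:
            raise ParseError(f"line {lineno}: BED needs >= 4 columns")
        try:
            start, end = int(f[1]), int(f[2])
        except ValueError:
            raise ParseError(f"line {lineno}: non-integer BED coordinates") from None
        strand = f[5] if len(f) >= 6 and f[5] in "+-" else None
        table.add(GeneRecord(gene_id=f[3], species=species, chrom=f[0],
                             order_index=0, start=start, end=end, strand=strand))
    table.reindex()
    return table


def _load_gff3(text: str, species: str) -> GenomeTable:
    import gffutils

    try:
        db = gffutils.create_db(text, dbfn=":memory:", from_string=True,
                                merge_strategy="error", keep_order=True)
    except Exception as exc:  # gffutils wraps sqlite + parse errors variously
        raise ParseError(f"GFF3 parse failed: {exc}") from exc
    table = GenomeTable(species)
    gene_types = {"gene", "ncRNA_gene", "pseudogene"}
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype not in gene_types:
            continue
        gid = (feat.attributes.get("ID") or feat.attributes.get("Name") or [feat.id])[0]
        biotype = (feat.attributes.get("gene_biotype") or feat.attributes.get("biotype")
                   or ["protein_coding"])[0]
        aliases = set(feat.attributes.get("Name", [])) | set(feat.attributes.get("Alias", []))
        table.add(GeneRecord(
            gene_id=gid, species=species, chrom=feat.seqid, order_index=0,
            start=feat.start - 1, end=feat.end,  # 1-based closed -> 0-based half-open
            strand=feat.strand if feat.strand in "+-" else None,
            biotype=biotype if biotype in BIOTYPES else "other",
            aliases=aliases - {gid},
        ))
    table.reindex()
    return table


def load_gene_orders(annotation_stream, species: str) -> GenomeTable:
    """Build a :class:`GenomeTable` from GFF3 gene features or BED content.

    order_index is assigned per chromosome by ascending start, ties broken
    by ascending end then gene_id.
    """
    if isinstance(annotation_stream, io.IOBase):
        text = annotation_stream.read()
    else:
        text = str(annotation_stream)
    body = [(i, ln) for i, ln in enumerate(text.splitlines(), start=1)
            if ln.strip() and not ln.startswith("#")]
    if not body:
        return GenomeTable(species)
    looks_gff = any(len(ln.split("\t")) == 9 for _, ln in body)
    if looks_gff:
        return _load_gff3(text, species)
    return _load_bed(body, species)


# ---------------------------------------------------------------------------
# homology hits and families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HomologyHit:
    """One row of an outfmt-6-like similarity table (query vs subject gene)."""

    query_gene: str
    subject_gene: str
    pct_identity: float
    aln_length: int
    evalue: float
    bit_score: float

    def __post_init__(self):
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity {self.pct_identity} outside [0, 100]")
        if self.evalue < 0:
            raise ValueError(f"negative E-value {self.evalue}")
        if not (self.bit_score == self.bit_score and abs(self.bit_score) != float("inf")):
            raise ValueError("bit_score must be finite")


def read_homology_tsv(text: str) -> list[HomologyHit]:
    """Parse BLAST outfmt-6 columns (qseqid sseqid pident length mismatch
    gapopen qstart qend sstart send evalue bitscore)."""
    hits = []
    for lineno, ln in enumerate(text.splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        f = ln.split("\t")
        if len(f) < 12:
            raise ParseError(f"line {lineno}: outfmt-6 needs 12 columns, got {len(f)}")
        hits.append(HomologyHit(query_gene=f[0], subject_gene=f[1],
                                pct_identity=float(f[2]), aln_length=int(f[3]),
                                evalue=float(f[10]), bit_score=float(f[11])))
    return hits


def filter_homology_hits(hits, min_bit: float = 40.0, max_evalue: float = 1e-4):
    """Keep hits with bit score strictly above ``min_bit`` AND E-value
    strictly below ``max_evalue``; input order preserved.

    Both inequalities are strict: a hit at exactly bit 40 or E 1e-4 is
    excluded.  Idempotent by construction.
    """
    out = []
    for h in hits:
        if h.evalue < 0:
            raise ValueError(f"negative E-value on {h.query_gene}-{h.subject_gene}")
        if h.bit_score > min_bit and h.evalue < max_evalue:
            out.append(h)
    return out


class HomologyFamilies:
    """Cross-species partition of genes into named homology families."""

    def __init__(self, members: dict[str, set[str]], provenance: str = "supplied"):
        seen: dict[str, str] = {}
        for fam, genes in members.items():
            for g in genes:
                if g in seen:
                    raise ValueError(f"gene {g!r} in families {seen[g]!r} and {fam!r}")
                seen[g] = fam
        self.members = {f: set(g) for f, g in members.items()}
        self.provenance = provenance
        self._of_gene = seen

    def family_of(self, gene_id: str) -> str | None:
        return self._of_gene.get(gene_id)

    def genes_of(self, family: str) -> set[str]:
        return self.members.get(family, set())

    def __len__(self):
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    @classmethod
    def from_table(cls, table: GenomeTable, *more_tables: GenomeTable) -> "HomologyFamilies":
        """Collect family labels already present on gene records."""
        members: dict[str, set[str]] = {}
        for t in (table, *more_tables):
            for r in t.genes():
                if r.family is not None:
                    members.setdefault(r.family, set()).add(r.gene_id)
        return cls(members, provenance="supplied")


def build_families(filtered_hits, genes=()) -> HomologyFamilies:
    """Single-linkage connected components over the hit graph.

    Family labels are the lexicographically smallest member id, so the
    result is invariant under permutation of the hit list.  Gene ids in
    ``genes`` that take part in no hit become singleton families.
    """
    g = nx.Graph()
    g.add_nodes_from(genes)
    for h in filtered_hits:
        g.add_edge(h.query_gene, h.subject_gene)
    members = {}
    for comp in nx.connected_components(g):
        members[min(comp)] = set(comp)
    return HomologyFamilies(members, provenance="clustered")


# ---------------------------------------------------------------------------
# gene neighbourhoods
# ---------------------------------------------------------------------------

def neighbors(table: GenomeTable, gene_id: str, k: int,
              include_noncoding: bool = False):
    """Up to ``k`` genes on each side of the focus, nearest first.

    Non-protein-coding records are skipped by default, following the
    convention of counting "5 protein-coding genes before and after" a
    focus locus; pass ``include_noncoding=True`` to count every record.
    Truncates silently at chromosome ends.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    focus = table.get(gene_id)
    recs = table.chromosomes[focus.chrom]
    i = focus.order_index

    def take(indices):
        out = []
        for j in indices:
            r = recs[j]
            if not include_noncoding and r.biotype != "protein_coding":
                continue
            out.append(r)
            if len(out) == k:
                break
        return out

    upstream = take(range(i - 1, -1, -1))
    downstream = take(range(i + 1, len(recs)))
    return upstream, downstream
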