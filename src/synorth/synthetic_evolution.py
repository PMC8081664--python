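"""Gene-order evolution simulator.

Replays an explicit, branch-anchored log of elementary events (tandem and
segmental duplication, whole-genome duplication, gene/segment loss,
inversion, fission, translocation) down a rooted species tree, emitting
per-species gene orders with ground-truth homology families, orthogroup
labels and locus statuses.  It stands in for a panel of sequenced genomes:
every downstream stage (microsynteny orthology, chromosome-scale chaining,
paralogon overlap, Dollo and step-count parsimony) can be exercised against
a known event history.

Conventions
-----------
* Events are explicit and replayable; a Poisson rate mode exists for
  property tests.  Replay is deterministic for a fixed (config, seed).
* WGD renames chromosome ``c`` to ``c_a``/``c_b`` and gene ``g`` to
  ``g_a``/``g_b``; duplication copies get ``_t`` (tandem) / ``_s``
  (segmental) suffixes.
* Family labels propagate through every copy, so seeding each ancestral
  gene's family with its own id makes "same family" mean "descends from
  the same ancestral gene".
* Gene order is the only coordinate during replay; synthetic bp
  coordinates (10 kb spacing, 5 kb gene width) are assigned at emission.
* A tandem duplication may leave a TE-TIR marker on the copy (emulating
  cut-and-paste transposition at the donor site); markers materialise as
  repeat intervals at emission.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome_model import GeneRecord, GenomeTable, HomologyFamilies
from .species_tree import SpeciesTree

__all__ = [
    "Event", "EventError", "SyntheticDataset",
    "apply_event", "assign_coordinates", "replay", "simulate",
    "truth_orthogroups",
]

EVENT_KINDS = {"TANDEM_DUP", "SEG_DUP", "TRANSLOCATION", "WGD",
               "GENE_LOSS", "SEGMENT_LOSS", "INVERSION", "FISSION"}

TE_MARK = "te_tir_flank"

GENE_SPACING = 10_000
GENE_WIDTH = 5_000


class EventError(ValueError):
    """An event's payload cannot be resolved against the current genome."""


@dataclass(frozen=True)
class Event:
    kind: str
    branch: str | None = None
    payload: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise EventError(f"unknown event kind {self.kind!r}")

    @classmethod
    def from_dict(cls, d: dict, branch: str | None = None) -> "Event":
        d = dict(d)
        kind = d.pop("kind")
        branch = d.pop("branch", branch)
        return cls(kind=kind, branch=branch, payload=d)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "branch": self.branch, **self.payload}


def _renumber(table: GenomeTable) -> None:
    for recs in table.chromosomes.values():
        for i, r in enumerate(recs):
            r.order_index = i
            r.start = r.end = None  # bp coordinates are stale after any move


def _describe(event: Event) -> str:
    return f"{event.kind} on branch {event.branch!r} with payload {event.payload}"


def apply_event(table: GenomeTable, event: Event) -> GenomeTable:
    """Apply one elementary event, returning a new :class:`GenomeTable`.

    order_index values are renumbered to restore the 0..n-1 invariant;
    bp coordinates (if any) are dropped because they are stale after any
    structural change (re-assign with :func:`assign_coordinates`).
    """
    t = table.copy()
    p = event.payload
    try:
        if event.kind == "TANDEM_DUP":
            src = t.get(p["gene"])
            recs = t.chromosomes[src.chrom]
            copy_id = p.get("copy_id", src.gene_id + p.get("copy_suffix", "_t"))
            if copy_id in t:
                raise EventError(f"copy id {copy_id!r} already exists")
            copy = replace(src, gene_id=copy_id, aliases=set(src.aliases))
            if p.get("mark_te_flank", False):
                copy.aliases.add(TE_MARK)
            offset = 0 if p.get("side", "after") == "before" else 1
            recs.insert(src.order_index + offset, copy)
            t._index[copy_id] = copy

        elif event.kind == "SEG_DUP":
            recs = t.chromosomes[p["chrom"]]
            start, end = p["start"], p["end"]
            if not (0 <= start < end <= len(recs)):
                raise EventError("segment out of range")
            suffix = p.get("copy_suffix", "_s")
            copies = []
            for r in recs[start:end]:
                cid = r.gene_id + suffix
                if cid in t:
                    raise EventError(f"copy id {cid!r} already exists")
                copies.append(replace(r, gene_id=cid, aliases=set(r.aliases)))
            dest = p.get("dest_chrom", p["chrom"])
            if dest not in t.chromosomes:
                t.chromosomes[dest] = []
                t.placed[dest] = bool(p.get("placed", True))
            dest_recs = t.chromosomes[dest]
            di = p.get("dest_index", len(dest_recs))
            if not 0 <= di <= len(dest_recs):
                raise EventError("dest_index out of range")
            for c in copies:
                c.chrom = dest
            dest_recs[di:di] = copies
            for c in copies:
                t._index[c.gene_id] = c

        elif event.kind == "TRANSLOCATION":
            recs = t.chromosomes[p["chrom"]]
            start, end = p["start"], p["end"]
            if not (0 <= start < end <= len(recs)):
                raise EventError("segment out of range")
            seg = recs[start:end]
            del recs[start:end]
            dest = p.get("dest_chrom", p["chrom"])
            if dest not in t.chromosomes:
                t.chromosomes[dest] = []
                t.placed[dest] = bool(p.get("placed", True))
            dest_recs = t.chromosomes[dest]
            di = p.get("dest_index", len(dest_recs))
            if not 0 <= di <= len(dest_recs):
                raise EventError("dest_index out of range")
            for r in seg:
                r.chrom = dest
            dest_recs[di:di] = seg

        elif event.kind == "WGD":
            new_chroms: dict[str, list[GeneRecord]] = {}
            new_placed: dict[str, bool] = {}
            new_index: dict[str, GeneRecord] = {}
            for chrom, recs in t.chromosomes.items():
                for suf in ("_a", "_b"):
                    copies = [replace(r, gene_id=r.gene_id + suf, chrom=chrom + suf,
                                      aliases=set(r.aliases)) for r in recs]
                    new_chroms[chrom + suf] = copies
                    new_placed[chrom + suf] = t.placed[chrom]
                    for c in copies:
                        new_index[c.gene_id] = c
            t.chromosomes, t.placed, t._index = new_chroms, new_placed, new_index

        elif event.kind == "GENE_LOSS":
            gone = t.get(p["gene"])
            t.chromosomes[gone.chrom].remove(gone)
            del t._index[gone.gene_id]

        elif event.kind == "SEGMENT_LOSS":
            recs = t.chromosomes[p["chrom"]]
            start, end = p["start"], p["end"]
            if not (0 <= start < end <= len(recs)):
                raise EventError("segment out of range")
            for r in recs[start:end]:
                del t._index[r.gene_id]
            del recs[start:end]

        elif event.kind == "INVERSION":
            recs = t.chromosomes[p["chrom"]]
            start, end = p["start"], p["end"]
            if not (0 <= start < end <= len(recs)):
                raise EventError("range out of range")
            seg = recs[start:end][::-1]
            for r in seg:
                if r.strand is not None:
                    r.strand = "+" if r.strand == "-" else "-"
            recs[start:end] = seg

        elif event.kind == "FISSION":
            recs = t.chromosomes[p["chrom"]]
            at = p["at"]
            if not 0 < at < len(recs):
                raise EventError("fission index must split the chromosome")
            new_name = p.get("new_chrom", p["chrom"] + "_f")
            if new_name in t.chromosomes:
                raise EventError(f"chromosome {new_name!r} already exists")
            tail = recs[at:]
            del recs[at:]
            for r in tail:
                r.chrom = new_name
            t.chromosomes[new_name] = tail
            t.placed[new_name] = t.placed[p["chrom"]]
    except KeyError as exc:
        raise EventError(f"unresolvable payload in {_describe(event)}: {exc}") from exc
    except EventError as exc:
        raise EventError(f"{exc} ({_describe(event)})") from None

    _renumber(t)
    return t


def assign_coordinates(table: GenomeTable, spacing: int = GENE_SPACING,
                       width: int = GENE_WIDTH) -> None:
    """Give every gene synthetic bp coordinates from its order rank."""
    for recs in table.chromosomes.values():
        for r in recs:
            r.start = r.order_index * spacing
            r.end = r.start + width


# ---------------------------------------------------------------------------
# replay along a tree
# ---------------------------------------------------------------------------

def _with_species(table: GenomeTable, species: str) -> GenomeTable:
    out = GenomeTable(species)
    for chrom, recs in table.chromosomes.items():
        for r in recs:
            out.add(replace(r, species=species, aliases=set(r.aliases)),
                    placed=table.placed[chrom])
    return out


def replay(tree: SpeciesTree, ancestor: GenomeTable,
           events_by_branch: dict[str, list[Event]]) -> dict[str, GenomeTable]:
    """Fold events over every branch in preorder; returns the genome at the
    *bottom* of each branch (leaves included), keyed by branch id."""
    genomes: dict[str, GenomeTable] = {}
    for branch in tree.branches_preorder():
        parent = tree.parent(branch)
        g = ancestor.copy() if parent is None else genomes[parent].copy()
        g = _with_species(g, branch)
        for ev in events_by_branch.get(branch, []):
            g = apply_event(g, ev)
        genomes[branch] = g
    return genomes


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    tree: SpeciesTree
    genomes: dict[str, GenomeTable]          # per extant species, with bp coords
    branch_genomes: dict[str, GenomeTable]   # snapshot at the bottom of every branch
    families: HomologyFamilies               # truth: descent from one ancestral gene
    naming: dict[str, str]                   # gene id -> orthogroup label (focus genes)
    event_log: list[Event]                   # applied order
    repeats: dict[str, list]                 # species -> [RepeatInterval] (TE-TIR marks)
    seed: int | None

    def receptor_candidates(self, focus_family: str) -> dict[str, list[str]]:
        """Extant members of one focus family, per species."""
        out: dict[str, list[str]] = {}
        for sp, table in self.genomes.items():
            ids = [r.gene_id for r in table.genes() if r.family == focus_family]
            if ids:
                out[sp] = sorted(ids)
        return out


def _ancestor_from_config(config: dict) -> GenomeTable:
    table = GenomeTable("ancestor")
    for chrom, genes in config["ancestor"].items():
        for i, g in enumerate(genes):
            if isinstance(g, str):
                g = {"id": g}
            table.add(GeneRecord(
                gene_id=g["id"], species="ancestor", chrom=chrom, order_index=i,
                strand=g.get("strand", "+"),
                family=g.get("family", g["id"]),
                biotype=g.get("biotype", "protein_coding"),
            ), placed=True)
    return table


_RATE_KINDS = ("TANDEM_DUP", "GENE_LOSS", "INVERSION", "SEGMENT_LOSS",
               "TRANSLOCATION", "SEG_DUP", "FISSION", "WGD")


def _sample_event(kind: str, genome: GenomeTable, rng: np.random.Generator,
                  branch: str, counter: list[int]) -> Event | None:
    chroms = [c for c in sorted(genome.chromosomes) if genome.chromosomes[c]]
    if not chroms:
        return None
    chrom = chroms[rng.integers(len(chroms))]
    recs = genome.chromosomes[chrom]
    n = len(recs)
    counter[0] += 1
    uniq = f"_r{counter[0]}"
    if kind == "TANDEM_DUP":
        g = recs[rng.integers(n)]
        return Event(kind, branch, {"gene": g.gene_id, "copy_id": g.gene_id + uniq})
    if kind == "GENE_LOSS":
        return Event(kind, branch, {"gene": recs[rng.integers(n)].gene_id})
    if kind in ("INVERSION", "SEGMENT_LOSS", "TRANSLOCATION", "SEG_DUP"):
        if n < 2:
            return None
        start = int(rng.integers(n - 1))
        end = int(min(n, start + 1 + rng.integers(1, 6)))
        p = {"chrom": chrom, "start": start, "end": end}
        if kind == "TRANSLOCATION":
            dest = chroms[rng.integers(len(chroms))]
            p["dest_chrom"] = dest
            p["dest_index"] = 0 if dest != chrom else None
            if p["dest_index"] is None:
                return None  # skip degenerate same-chromosome move
        if kind == "SEG_DUP":
            p["dest_chrom"] = f"novel{uniq}"
            p["copy_suffix"] = uniq
        return Event(kind, branch, p)
    if kind == "FISSION":
        if n < 2:
            return None
        return Event(kind, branch, {"chrom": chrom, "at": int(rng.integers(1, n)),
                                    "new_chrom": chrom + uniq})
    if kind == "WGD":
        return Event(kind, branch, {})
    return None


def simulate(config: dict, seed: int | None = None) -> SyntheticDataset:
    """Run the generator.

    ``config`` keys:

    * ``species_tree`` — Newick with labelled internal nodes.
    * ``ancestor`` — mapping chromosome -> ordered gene list (ids or dicts
      with ``id``/``strand``/``family``/``biotype``).
    * ``events`` — mapping branch id -> list of event dicts, applied in
      list order (branches in preorder).
    * ``rates`` — optional mapping branch id (or ``"*"``) ->
      {event kind: Poisson mean}; sampled events run after explicit ones.
    * ``naming`` — optional gene id -> orthogroup label map for focus loci.
    """
    tree = SpeciesTree.from_newick(config["species_tree"])
    ancestor = _ancestor_from_config(config)
    rng = np.random.default_rng(seed)
    counter = [0]

    rates = config.get("rates", {})
    for v in rates.values():
        if any(r < 0 for r in v.values()):
            raise ValueError("event rates must be non-negative")

    explicit = {b: [Event.from_dict(d, branch=b) for d in evs]
                for b, evs in config.get("events", {}).items()}

    genomes: dict[str, GenomeTable] = {}
    log: list[Event] = []
    for branch in tree.branches_preorder():
        parent = tree.parent(branch)
        g = ancestor.copy() if parent is None else genomes[parent].copy()
        g = _with_species(g, branch)
        for ev in explicit.get(branch, []):
            g = apply_event(g, ev)
            log.append(ev)
        branch_rates = rates.get(branch, rates.get("*", {}))
        for kind in _RATE_KINDS:
            lam = branch_rates.get(kind, 0.0)
            if lam > 0:
                for _ in range(rng.poisson(lam)):
                    ev = _sample_event(kind, g, rng, branch, counter)
                    if ev is not None:
                        g = apply_event(g, ev)
                        log.append(ev)
        genomes[branch] = g

    from .locus_features import RepeatInterval  # deferred: avoid import cycle

    extant: dict[str, GenomeTable] = {}
    repeats: dict[str, list] = {}
    for leaf in tree.leaves:
        table = genomes[leaf].copy()
        assign_coordinates(table)
        extant[leaf] = table
        marks = []
        for r in table.genes():
            if TE_MARK in r.aliases:
                marks.append(RepeatInterval(chrom=r.chrom, start=max(0, r.start - 300),
                                            end=max(1, r.start - 100),
                                            repeat_class="DNA/TcMar", has_TIR=True))
        repeats[leaf] = marks

    families = HomologyFamilies.from_table(*extant.values()) if extant else \
        HomologyFamilies({})
    return SyntheticDataset(tree=tree, genomes=extant, branch_genomes=genomes,
                            families=families, naming=dict(config.get("naming", {})),
                            event_log=log, repeats=repeats, seed=seed)


# ---------------------------------------------------------------------------
# ground-truth orthology statuses
# ---------------------------------------------------------------------------

def truth_orthogroups(dataset: SyntheticDataset, focus_families: set[str]):
    """Ground-truth locus status matrix for the named focus families.

    A locus is ``present`` where the gene survives; where it was lost on
    the lineage path it is ``gene_lost_territory_present`` if at least
    half of its ancestral 10-gene territory (5 protein-coding neighbour
    families each side, taken at the last branch where the gene existed)
    still has members in the extant genome, else ``territory_absent``.
    Lineages on whose path the gene never existed get no call (the gene
    never evolved there).
    """
    from .microsynteny import OrthologyCallMatrix
    from .genome_model import neighbors as _neighbors

    naming = dataset.naming
    tree = dataset.tree
    matrix = OrthologyCallMatrix()
    for species in tree.leaves:
        leaf_table = dataset.genomes[species]
        extant_families = {r.family for r in leaf_table.genes()}
        path = tree.path_from_root(species)
        for gene_id, og in naming.items():
            root_family = None
            if gene_id in leaf_table:
                rec = leaf_table.get(gene_id)
                if rec.family in focus_families:
                    matrix.set(og, species, "present", genes=[gene_id])
                continue
            # find the deepest branch on the path where the gene existed
            last_branch = None
            last_idx = -1
            for i, b in enumerate(path):
                if gene_id in dataset.branch_genomes[b]:
                    last_branch, last_idx = b, i
                    root_family = dataset.branch_genomes[b].get(gene_id).family
            if last_branch is None or root_family not in focus_families:
                continue  # never evolved on this lineage
            if last_idx + 1 < len(path) and \
                    gene_id + "_a" in dataset.branch_genomes[path[last_idx + 1]]:
                continue  # id retired by WGD renaming, not a loss
            if matrix.status(og, species) == "present":
                continue  # another copy of this orthogroup survives here
            snap = dataset.branch_genomes[last_branch]
            up, down = _neighbors(snap, gene_id, k=5)
            territory = {r.family for r in up + down if r.family is not None}
            survived = territory & extant_families
            if territory and len(survived) >= 0.5 * len(territory):
                matrix.set(og, species, "gene_lost_territory_present",
                           evidence={"territory_families": len(territory),
                                     "surviving": len(survived)})
            else:
                matrix.set(og, species, "territory_absent",
                           evidence={"territory_families": len(territory),
                                     "surviving": len(survived)})
    return matrix
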