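"""Evolutionary inference over gene repertoires: Dollo gain/loss
reconstruction, replay of duplication scenarios against a species tree,
consistency checking against observed repertoires and chromosome
co-locations, and mutational step counting for hypothesis comparison.

The event model is deliberately minimal: every elementary event —
duplication, whole-genome duplication, translocation, gene loss, segment
loss, inversion, fission — costs one step, and a *translocated segmental
duplication* decomposes into duplication + translocation (two steps).
Under Dollo parsimony a gene is gained exactly once and can only be lost
below its gain branch; no regain is allowed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .genome_model import GenomeTable
from .species_tree import SpeciesTree
from .synthetic_evolution import Event, apply_event, replay

__all__ = [
    "RepertoireObservation", "EventModel",
    "dollo_reconstruct", "apply_scenario", "scenario_consistent",
    "step_count", "min_steps_search", "SearchGrammar",
]


# ---------------------------------------------------------------------------
# observations and event costs
# ---------------------------------------------------------------------------

@dataclass
class RepertoireObservation:
    """What the genomes show, at lineage granularity.

    ``presence`` maps a lineage to the set of orthogroups observed there;
    lineages absent from the mapping are unchecked for named orthogroups
    (fragmentary assemblies).  ``colocated`` / ``separated`` hold pairs of
    orthogroups observed on the same / on different chromosomes in a
    lineage.  ``counts`` optionally pins the total number of focus genes
    in a lineage (the hagfish "two receptors" style of statement).
    """

    universe: set[str]
    presence: dict[str, set[str]] = field(default_factory=dict)
    colocated: dict[str, set[frozenset]] = field(default_factory=dict)
    separated: dict[str, set[frozenset]] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for lineage, pairs in {**self.colocated}.items():
            present = self.presence.get(lineage, set())
            for pair in pairs:
                if not pair <= present:
                    raise ValueError(
                        f"co-location {sorted(pair)} in {lineage} references "
                        f"an orthogroup not observed there")


class EventModel:
    """Step costs per elementary event kind (all default to 1); a
    segmental duplication whose copy lands on a different chromosome is a
    translocated segmental duplication and decomposes into duplication +
    translocation."""

    DEFAULT_COSTS = {"TANDEM_DUP": 1, "SEG_DUP": 1, "TRANSLOCATION": 1,
                     "WGD": 1, "GENE_LOSS": 1, "SEGMENT_LOSS": 1,
                     "INVERSION": 1, "FISSION": 1}

    def __init__(self, costs: dict[str, int] | None = None):
        self.costs = dict(self.DEFAULT_COSTS)
        if costs:
            self.costs.update(costs)
        if any(not (isinstance(c, int) and c > 0) for c in self.costs.values()):
            raise ValueError("event costs must be positive integers")

    def cost(self, event: Event) -> int:
        if event.kind not in self.costs:
            raise ValueError(f"unknown event kind {event.kind!r}")
        base = self.costs[event.kind]
        if event.kind == "SEG_DUP":
            dest = event.payload.get("dest_chrom", event.payload.get("chrom"))
            if dest != event.payload.get("chrom"):
                base = self.costs["SEG_DUP"] + self.costs["TRANSLOCATION"]
        return base


def step_count(scenario: list[Event], model: EventModel | None = None) -> int:
    """Total mutational steps of a scenario; additive over concatenation."""
    model = model or EventModel()
    return sum(model.cost(ev) for ev in scenario)


# ---------------------------------------------------------------------------
# Dollo reconstruction
# ---------------------------------------------------------------------------

def dollo_reconstruct(tree: SpeciesTree, presence: dict[str, bool]):
    """Single-gain placement with a minimal loss set.

    The gain sits on the branch above the most recent common ancestor of
    all present leaves; losses sit on the maximal subtrees below the gain
    that contain no present leaf.  Leaves missing from ``presence`` are
    treated as absent.
    """
    present = {leaf for leaf in tree.leaves if presence.get(leaf, False)}
    if not present:
        raise ValueError("Dollo reconstruction needs at least one present leaf")
    gain = tree.mrca(present)
    losses = []

    def walk(branch: str):
        under = tree.leaves_under(branch)
        if not under & present:
            losses.append(branch)
            return
        for child in tree.children(branch):
            walk(child)

    for child in tree.children(gain):
        walk(child)
    return gain, sorted(losses)


# ---------------------------------------------------------------------------
# scenario replay and consistency
# ---------------------------------------------------------------------------

def _repertoire(table: GenomeTable, naming: dict[str, str]):
    """(labels present, co-located label pairs, focus gene count)."""
    labels: set[str] = set()
    by_chrom: dict[str, set[str]] = {}
    count = 0
    for rec in table.genes():
        if rec.gene_id in naming:
            lab = naming[rec.gene_id]
            labels.add(lab)
            by_chrom.setdefault(rec.chrom, set()).add(lab)
            count += 1
    pairs = set()
    for labs in by_chrom.values():
        pairs.update(frozenset(p) for p in itertools.combinations(sorted(labs), 2))
    return labels, pairs, count


def apply_scenario(ancestor: GenomeTable, scenario: list[Event],
                   tree: SpeciesTree, naming: dict[str, str]) -> dict[str, dict]:
    """Deterministic replay of a branch-anchored scenario; returns per-leaf
    presence sets, same-chromosome pairs and focus gene counts (gene ids
    are mapped to orthogroup labels through ``naming``)."""
    events_by_branch: dict[str, list[Event]] = {}
    for ev in scenario:
        if ev.branch is None:
            raise ValueError(f"scenario event {ev.kind} has no branch anchor")
        events_by_branch.setdefault(ev.branch, []).append(ev)
    unknown = set(events_by_branch) - set(tree.branches_preorder())
    if unknown:
        raise ValueError(f"scenario references unknown branches: {sorted(unknown)}")
    genomes = replay(tree, ancestor, events_by_branch)
    out = {}
    for leaf in tree.leaves:
        labels, pairs, count = _repertoire(genomes[leaf], naming)
        out[leaf] = {"presence": labels, "colocated": pairs, "count": count}
    return out


def scenario_consistent(predicted: dict[str, dict],
                        observed: RepertoireObservation):
    """True iff every observed presence, absence, co-location, separation
    and count is matched by the prediction; violations itemised."""
    violations = []
    for lineage, expected in observed.presence.items():
        if lineage not in predicted:
            violations.append(f"{lineage}: no prediction for observed lineage")
            continue
        got = predicted[lineage]["presence"] & observed.universe
        for og in sorted(expected - got):
            violations.append(f"{lineage}: missing {og}")
        for og in sorted(got - expected):
            violations.append(f"{lineage}: unexpected {og}")
    for lineage, pairs in observed.colocated.items():
        got = predicted.get(lineage, {}).get("colocated", set())
        for pair in sorted(pairs, key=sorted):
            if pair not in got:
                violations.append(
                    f"{lineage}: {' and '.join(sorted(pair))} not on one chromosome")
    for lineage, pairs in observed.separated.items():
        got = predicted.get(lineage, {}).get("colocated", set())
        for pair in sorted(pairs, key=sorted):
            if pair in got:
                violations.append(
                    f"{lineage}: {' and '.join(sorted(pair))} unexpectedly co-located")
    for lineage, n in observed.counts.items():
        got = predicted.get(lineage, {}).get("count")
        if got != n:
            violations.append(f"{lineage}: expected {n} focus genes, predicted {got}")
    return not violations, violations


# ---------------------------------------------------------------------------
# minimal-scenario search
# ---------------------------------------------------------------------------

@dataclass
class SearchGrammar:
    """What the search may propose: an ancestral genome, the species tree,
    the event kinds allowed on each branch (``"*"`` = every branch) and a
    gene-id -> orthogroup naming map (genes not in the map are labelled by
    their own id)."""

    tree: SpeciesTree
    ancestor: GenomeTable
    allowed: dict[str, list[str]]
    naming: dict[str, str] = field(default_factory=dict)

    def kinds_for(self, branch: str) -> list[str]:
        return self.allowed.get(branch, self.allowed.get("*", []))

    def label(self, gene_id: str) -> str:
        return self.naming.get(gene_id, gene_id)


def _candidate_events(grammar: SearchGrammar, branch: str,
                      genome: GenomeTable) -> list[Event]:
    out = []
    for kind in grammar.kinds_for(branch):
        if kind == "GENE_LOSS":
            for gid in sorted(g.gene_id for g in genome.genes()):
                out.append(Event("GENE_LOSS", branch, {"gene": gid}))
        elif kind == "TANDEM_DUP":
            for gid in sorted(g.gene_id for g in genome.genes()):
                out.append(Event("TANDEM_DUP", branch, {"gene": gid}))
        elif kind == "WGD":
            out.append(Event("WGD", branch, {}))
        elif kind == "SEGMENT_LOSS":
            for chrom in sorted(genome.chromosomes):
                n = len(genome.chromosomes[chrom])
                for s, e in itertools.combinations(range(n + 1), 2):
                    out.append(Event("SEGMENT_LOSS", branch,
                                     {"chrom": chrom, "start": s, "end": e}))
        elif kind == "FISSION":
            for chrom in sorted(genome.chromosomes):
                for at in range(1, len(genome.chromosomes[chrom])):
                    out.append(Event("FISSION", branch, {"chrom": chrom, "at": at}))
        elif kind == "SEG_DUP":
            for chrom in sorted(genome.chromosomes):
                n = len(genome.chromosomes[chrom])
                for s, e in itertools.combinations(range(n + 1), 2):
                    out.append(Event("SEG_DUP", branch,
                                     {"chrom": chrom, "start": s, "end": e,
                                      "dest_chrom": f"{chrom}_sd{s}_{e}"}))
    return out


def _leaf_consistent(genome: GenomeTable, leaf: str, grammar: SearchGrammar,
                     observed: RepertoireObservation) -> bool:
    naming = {g.gene_id: grammar.label(g.gene_id) for g in genome.genes()}
    labels, pairs, count = _repertoire(genome, naming)
    if leaf in observed.presence:
        if (labels & observed.universe) != observed.presence[leaf]:
            return False
    if leaf in observed.counts and count != observed.counts[leaf]:
        return False
    if not observed.colocated.get(leaf, set()) <= pairs:
        return False
    if observed.separated.get(leaf, set()) & pairs:
        return False
    return True


def min_steps_search(observed: RepertoireObservation, grammar: SearchGrammar,
                     bound: int = 12, model: EventModel | None = None):
    """Smallest-cost scenario consistent with the observation, or
    ``(None, None)`` when nothing within ``bound`` steps fits.

    Iterative deepening over the total step budget with deterministic
    event enumeration: branches are processed in preorder and within each
    branch candidate events are tried in a fixed order, so the first
    minimal scenario found is reproducible.  Exhaustive — keep the
    ancestral genome and bound at desk scale.
    """
    model = model or EventModel()
    branches = grammar.tree.branches_preorder()

    def search(bi: int, genomes: dict, remaining: int, chosen: list):
        if bi == len(branches):
            return list(chosen)
        branch = branches[bi]
        parent = grammar.tree.parent(branch)
        base = grammar.ancestor if parent is None else genomes[parent]

        def extend(genome, remaining):
            # option 1: no further events on this branch
            if not grammar.tree.is_leaf(branch) or \
                    _leaf_consistent(genome, branch, grammar, observed):
                res = search(bi + 1, {**genomes, branch: genome}, remaining, chosen)
                if res is not None:
                    return res
            # option 2: one more event, then recurse on this branch
            for ev in _candidate_events(grammar, branch, genome):
                c = model.cost(ev)
                if c > remaining:
                    continue
                try:
                    nxt = apply_event(genome, ev)
                except Exception:
                    continue
                chosen.append(ev)
                res = extend(nxt, remaining - c)
                if res is not None:
                    return res
                chosen.pop()
            return None

        return extend(base, remaining)

    for budget in range(bound + 1):
        result = search(0, {}, budget, [])
        if result is not None:
            return result, step_count(result, model)
    return None, None
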