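"""Tree-vs-synteny concordance, subfamily-diagnostic alignment sites,
universal nomenclature renaming, and pipeline orchestration.

Gene trees are *inputs* (Newick with optional bootstrap supports on
internal nodes), never inferred here; monophyly of a synteny-defined
orthogroup is tested on the rooted topology, and disagreements are
reported — not adjudicated, since contradiction may reflect either
sequence convergence or a radiation too rapid to resolve.
"""

from __future__ import annotations

import importlib.resources
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy

__all__ = [
    "GeneTree", "AliasTable",
    "orthogroup_monophyly", "diagnostic_sites", "rename", "load_alias_table",
    "run_pipeline",
]

LOW_SUPPORT = 50.0  # bootstrap percentages below this are "less informative"


@dataclass
class GeneTree:
    """Rooted gene-family tree with a leaf -> (species, orthogroup) map."""

    tree: dendropy.Tree
    leaf_map: dict[str, tuple[str, str]]

    @classmethod
    def from_newick(cls, newick: str, leaf_map: dict[str, tuple[str, str]],
                    outgroup: str | list[str] | None = None) -> "GeneTree":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        tree.is_rooted = True
        labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
        missing = set(leaf_map) - labels
        if missing:
            raise ValueError(f"mapped leaves not in tree: {sorted(missing)}")
        if outgroup is not None:
            og = [outgroup] if isinstance(outgroup, str) else list(outgroup)
            mrca = tree.mrca(taxon_labels=og) if len(og) > 1 else \
                tree.find_node_with_taxon_label(og[0])
            tree.reroot_at_edge(mrca.edge, update_bipartitions=True)
        return cls(tree=tree, leaf_map=dict(leaf_map))

    def leaves_of_group(self, orthogroup: str) -> set[str]:
        return {leaf for leaf, (_, og) in self.leaf_map.items() if og == orthogroup}


def _is_monophyletic(tree: dendropy.Tree, leaves: set[str],
                     ignore: set[str]) -> tuple[bool, float | None]:
    """Monophyly of `leaves` among the non-ignored leaves; returns the
    clade's bootstrap support when monophyletic."""
    mrca = tree.mrca(taxon_labels=list(leaves)) if len(leaves) > 1 else \
        tree.find_node_with_taxon_label(next(iter(leaves)))
    under = {lf.taxon.label for lf in mrca.leaf_iter()} - ignore
    if under == leaves:
        support = None
        if mrca.label is not None:
            try:
                support = float(mrca.label)
            except ValueError:
                pass
        return True, support
    return False, None


def orthogroup_monophyly(gene_tree: GeneTree, max_exact: int = 3) -> dict[str, dict]:
    """Per-orthogroup monophyly report.

    For a non-monophyletic group, the violating leaves are the smallest
    leaf set whose removal restores monophyly — found exactly for up to
    ``max_exact`` violators, greedily beyond (flagged ``approximate``).
    Tree leaves without a mapping are excluded with a warning entry.
    """
    tree = gene_tree.tree
    mapped = set(gene_tree.leaf_map)
    all_leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    unmapped = sorted(all_leaves - mapped)
    groups = sorted({og for _, og in gene_tree.leaf_map.values()})
    report: dict[str, dict] = {}
    if unmapped:
        report["_unmapped_leaves"] = {"leaves": unmapped}
    for og in groups:
        members = gene_tree.leaves_of_group(og)
        if len(members) < 2:
            report[og] = {"monophyletic": None, "note": "fewer than 2 leaves"}
            continue
        ignore = set(unmapped)
        ok, support = _is_monophyletic(tree, members, ignore)
        entry = {"monophyletic": ok, "violating_leaves": [], "support": support,
                 "low_support": support is not None and support < LOW_SUPPORT}
        if not ok:
            candidates = sorted(members | {
                lf for lf in mapped - members
                if lf in _leafset_under_mrca(tree, members)})
            found = None
            for size in range(1, min(max_exact, len(candidates)) + 1):
                for combo in itertools.combinations(candidates, size):
                    remaining = members - set(combo)
                    if not remaining:
                        continue
                    ok2, _ = _is_monophyletic(tree, remaining,
                                              ignore | set(combo))
                    if ok2:
                        found = list(combo)
                        break
                if found:
                    break
            if found is not None:
                entry["violating_leaves"] = found
                entry["approximate"] = False
            else:
                entry["violating_leaves"] = _greedy_violators(
                    tree, members, ignore)
                entry["approximate"] = True
        report[og] = entry
    return report


def _leafset_under_mrca(tree, leaves: set[str]) -> set[str]:
    mrca = tree.mrca(taxon_labels=list(leaves))
    return {lf.taxon.label for lf in mrca.leaf_iter()}


def _greedy_violators(tree, members: set[str], ignore: set[str]) -> list[str]:
    removed: list[str] = []
    current = set(members)
    while current and len(removed) < len(members) + 10:
        ok, _ = _is_monophyletic(tree, current, ignore | set(removed))
        if ok:
            break
        intruders = _leafset_under_mrca(tree, current) - current - ignore - set(removed)
        pool = sorted(intruders | current)
        best, best_leaf = None, None
        for leaf in pool:
            rem = current - {leaf}
            if not rem:
                continue
            under = _leafset_under_mrca(tree, rem) - ignore - set(removed) - {leaf}
            excess = len(under - rem)
            if best is None or excess < best:
                best, best_leaf = excess, leaf
        removed.append(best_leaf)
        current.discard(best_leaf)
    return removed


# ---------------------------------------------------------------------------
# diagnostic alignment sites
# ---------------------------------------------------------------------------

def diagnostic_sites(alignment: dict[str, str], group_a: list[str],
                     group_b: list[str], include_gaps: bool = False) -> list[int]:
    """0-based columns fixed for one residue state within each group and
    different between the groups (columns containing gaps are skipped
    unless ``include_gaps``)."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    lengths = {len(alignment[name]) for name in (*group_a, *group_b)}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: rows differ in length")
    (ncol,) = lengths
    out = []
    for col in range(ncol):
        states_a = {alignment[n][col] for n in group_a}
        states_b = {alignment[n][col] for n in group_b}
        if not include_gaps and "-" in (states_a | states_b):
            continue
        if len(states_a) == 1 and len(states_b) == 1 and states_a != states_b:
            out.append(col)
    return out


# ---------------------------------------------------------------------------
# universal nomenclature
# ---------------------------------------------------------------------------

from .fixtures import UNIVERSAL_NAMES  # noqa: E402  (single source of truth)


@dataclass
class AliasTable:
    """(lineage, alias) -> universal gene name, with one canonical alias
    per (lineage, universal) for the reverse direction."""

    forward: dict[tuple[str, str], str] = field(default_factory=dict)
    canonical: dict[tuple[str, str], str] = field(default_factory=dict)

    def add(self, lineage: str, alias: str, universal: str,
            is_canonical: bool = False) -> None:
        if universal not in UNIVERSAL_NAMES:
            raise ValueError(f"{universal!r} is not a universal gene name")
        key = (lineage, alias)
        if key in self.forward and self.forward[key] != universal:
            raise ValueError(f"alias conflict: {key} -> {self.forward[key]} "
                             f"and {universal}")
        self.forward[key] = universal
        if is_canonical:
            self.canonical[(lineage, universal)] = alias

    def to_universal(self, lineage: str, name: str) -> str | None:
        if name in UNIVERSAL_NAMES:
            return name
        return self.forward.get((lineage, name))

    def to_alias(self, lineage: str, universal: str) -> str | None:
        return self.canonical.get((lineage, universal))


def load_alias_table(path: str | Path | None = None) -> AliasTable:
    """Load the packaged lineage-alias fixture (or a user TSV with columns
    lineage, alias, universal, canonical)."""
    if path is None:
        ref = importlib.resources.files("synorth.data").joinpath("aliases.tsv")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    table = AliasTable()
    lines = text.strip().splitlines()
    header = lines[0].split("\t")
    if header[:3] != ["lineage", "alias", "universal"]:
        raise ValueError("alias table needs columns lineage, alias, universal")
    for ln in lines[1:]:
        f = ln.split("\t")
        table.add(f[0], f[1], f[2], is_canonical=len(f) > 3 and f[3] == "1")
    return table


def rename(records: list[tuple[str, str]], aliases: AliasTable) -> dict:
    """Map (lineage, name) records onto the universal nomenclature.

    Matched aliases are replaced; names that are already universal pass
    through unchanged (idempotence); anything unmatched passes through
    and is listed in the report.
    """
    renamed, unmatched, out = [], [], []
    for lineage, name in records:
        uni = aliases.to_universal(lineage, name)
        if uni is None:
            out.append((lineage, name))
            unmatched.append((lineage, name))
        else:
            out.append((lineage, uni))
            if uni != name:
                renamed.append((lineage, name, uni))
    return {"records": out, "renamed": renamed, "unmatched": unmatched}


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------

STAGES = ("simulate", "families", "microsynteny", "macrosynteny", "paralogon",
          "scenario", "concordance", "rename")


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the configured analysis stages in order, writing per-stage
    TSVs plus a machine-readable ``summary.json`` (seeds and parameters
    included).  The configuration is validated before any stage runs.
    """
    stages = config.get("stages", [])
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown pipeline stage(s): {unknown}")
    needs_sim = {"families", "microsynteny", "macrosynteny", "paralogon"}
    if needs_sim & set(stages) and "simulate" not in stages:
        raise ValueError("data-dependent stages require the simulate stage")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": list(stages), "seed": config.get("seed")}

    dataset = None
    if "simulate" in stages:
        from . import fixtures
        from .synthetic_evolution import simulate
        sim_cfg = config.get("sim_config") or fixtures.sim_config()
        dataset = simulate(sim_cfg, seed=config.get("seed"))
        for sp, table in dataset.genomes.items():
            (out_dir / f"genome_{sp}.tsv").write_text(table.to_tsv())
        (out_dir / "event_log.json").write_text(
            json.dumps([ev.to_dict() for ev in dataset.event_log], indent=1))
        summary["simulate"] = {"species": sorted(dataset.genomes),
                               "genes": {sp: t.n_genes
                                         for sp, t in dataset.genomes.items()}}

    if "families" in stages:
        summary["families"] = {"n_families": len(dataset.families),
                               "provenance": dataset.families.provenance}

    if "microsynteny" in stages:
        from . import fixtures
        from .microsynteny import assign_orthogroups
        candidates = dataset.receptor_candidates("VTR")
        candidates.pop("hagfishes", None)  # scored separately (fragmentary)
        calls = assign_orthogroups(candidates, dataset.genomes,
                                   dataset.families)
        (out_dir / "orthogroups.tsv").write_text(calls.to_tsv())
        summary["microsynteny"] = {
            "n_orthogroups": len(calls.orthogroups),
            "hagfish_receptors": len(
                dataset.receptor_candidates("VTR").get("hagfishes", []))}

    if "macrosynteny" in stages:
        from .macrosynteny import chromosome_hit_counts, top2_test
        ref_cfg = config.get("macrosynteny", {})
        ref_sp = ref_cfg.get("reference", "lampreys")
        ref_chrom = ref_cfg.get("ref_chrom", "c1_b")
        query_sp = ref_cfg.get("query", "mammals")
        ref = dataset.genomes[ref_sp].chromosomes[ref_chrom]
        counts = chromosome_hit_counts(ref, dataset.genomes[query_sp],
                                       dataset.families)
        result = top2_test(counts, n_ref_genes=len(ref))
        summary["macrosynteny"] = {
            "reference": f"{ref_sp}:{ref_chrom}", "query": query_sp,
            "counts": counts, "top2": list(result.top_labels),
            "chi2": result.chi2, "p_value": result.p_value}

    if "paralogon" in stages:
        from .paralogon import territory, territory_overlap
        foci = {og: gid for gid, og in dataset.naming.items()
                if og in {"OTR", "VTR1A", "VTR2A", "VTR2B", "VTR1B", "VTR2C"}}
        sp = config.get("paralogon", {}).get("species", "coelacanth")
        table = dataset.genomes[sp]
        terrs = [territory(table, gid, dataset.families, label=og)
                 for og, gid in sorted(foci.items()) if gid in table]
        overlap, _ = territory_overlap(terrs)
        overlap.to_csv(out_dir / "territory_overlap.tsv", sep="\t")
        summary["paralogon"] = {"species": sp,
                                "territories": [t.label for t in terrs]}

    if "scenario" in stages:
        from . import fixtures
        from .scenario_parsimony import (EventModel, apply_scenario,
                                         dollo_reconstruct, scenario_consistent,
                                         step_count)
        from .species_tree import SpeciesTree
        tree = SpeciesTree.from_newick(fixtures.species_tree_newick())
        matrix = fixtures.fig_presence_matrix()
        dollo = {}
        for og in matrix.index:
            presence = {sp: matrix.loc[og, sp] == "1" for sp in matrix.columns}
            gain, losses = dollo_reconstruct(tree, presence)
            dollo[og] = {"gain": gain, "losses": losses}
        model = EventModel()
        obs = fixtures.observed_repertoires()
        anc = fixtures.scenario_ancestor()
        steps = {}
        for hyp, scen, naming in (
                ("h1", fixtures.h1_origin_scenario(), fixtures.H1_NAMING),
                ("h2", fixtures.h2_origin_scenario(), fixtures.H2_NAMING)):
            full = scen + fixtures.shared_loss_events(hyp)
            predicted = apply_scenario(anc, full, tree, naming)
            ok, violations = scenario_consistent(predicted, obs)
            steps[hyp] = {"steps": step_count(scen, model), "consistent": ok,
                          "violations": violations}
        summary["scenario"] = {"dollo": dollo, "hypotheses": steps}

    if "rename" in stages:
        aliases = load_alias_table(config.get("alias_table"))
        records = config.get("rename_records", [])
        summary["rename"] = rename([tuple(r) for r in records], aliases)

    if "concordance" in stages:
        cc = config.get("concordance", {})
        gt = GeneTree.from_newick(cc["newick"], cc["leaf_map"],
                                  outgroup=cc.get("outgroup"))
        summary["concordance"] = orthogroup_monophyly(gt)

    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1,
                                                     default=str))
    return summary
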