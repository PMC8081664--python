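"""Ten-gene-window microsynteny: profiles, scoring, orthogroup assignment
and locus status classification.

The unit of evidence is the *window profile*: the homology families of the
five protein-coding genes on each side of a focus locus.  Two loci in
different species are held orthologous when their windows share enough
families; duplicates within one species are ranked against the group
consensus and suffixed ``a``, ``b``, ... in decreasing order of shared
synteny.  Matching is order-free by default — local rearrangements within
a window are tolerated — with an order-aware longest-common-run variant
available for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome_model import GenomeTable, HomologyFamilies, neighbors

__all__ = [
    "WindowProfile", "OrthologyCallMatrix",
    "window_profile", "shared_synteny_score",
    "assign_orthogroups", "classify_locus",
]

STATUSES = ("present", "gene_lost_territory_present", "territory_absent", "unresolved")


@dataclass
class WindowProfile:
    focus: str
    species: str
    upstream: list[str]     # family labels, nearest first
    downstream: list[str]   # family labels, nearest first
    strands: list[str]
    k: int

    @property
    def families(self) -> set[str]:
        return set(self.upstream) | set(self.downstream)

    @property
    def size(self) -> int:
        return len(self.upstream) + len(self.downstream)


def window_profile(table: GenomeTable, families: HomologyFamilies | None,
                   gene_id: str, k: int = 5,
                   include_noncoding: bool = False) -> WindowProfile:
    """Families of the k nearest protein-coding neighbours on each side.

    Family labels come from the gene records themselves, overridden by the
    ``families`` partition when it covers a gene; unlabelled neighbours are
    recorded as anonymous singletons (``anon:<gene_id>``), which can never
    match across species.
    """
    up, down = neighbors(table, gene_id, k, include_noncoding=include_noncoding)

    def label(rec):
        if families is not None:
            fam = families.family_of(rec.gene_id)
            if fam is not None:
                return fam
        return rec.family if rec.family is not None else f"anon:{rec.gene_id}"

    return WindowProfile(
        focus=gene_id, species=table.species,
        upstream=[label(r) for r in up],
        downstream=[label(r) for r in down],
        strands=[r.strand or "." for r in up[::-1]] + [r.strand or "." for r in down],
        k=k,
    )


def _longest_common_run(a: list[str], b: list[str]) -> int:
    # longest common ordered sublist (classic LCS, small inputs)
    m, n = len(a), len(b)
    dp = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m):
        for j in range(n):
            dp[i + 1][j + 1] = dp[i][j] + 1 if a[i] == b[j] else \
                max(dp[i][j + 1], dp[i + 1][j])
    return dp[m][n]


def shared_synteny_score(a: WindowProfile, b: WindowProfile,
                         order_aware: bool = False):
    """Number of distinct families present in both windows (symmetric,
    bounded by 2k).  With ``order_aware`` also reports the longest common
    ordered family run over the full (upstream-reversed + downstream)
    window sequence."""
    matched = a.families & b.families
    if not order_aware:
        return len(matched), matched
    seq_a = a.upstream[::-1] + a.downstream
    seq_b = b.upstream[::-1] + b.downstream
    return len(matched), matched, _longest_common_run(seq_a, seq_b)


class OrthologyCallMatrix:
    """orthogroup x species locus-status matrix with per-call evidence."""

    def __init__(self):
        self._calls: dict[tuple[str, str], dict] = {}

    def set(self, orthogroup: str, species: str, status: str,
            genes: list[str] | None = None, suffixes: list[str] | None = None,
            evidence: dict | None = None) -> None:
        if status not in STATUSES:
            raise ValueError(f"unknown status {status!r}")
        key = (orthogroup, species)
        prev = self._calls.get(key)
        if prev is not None and prev["status"] == "present":
            if status != "present":
                return  # a surviving copy outranks any loss call
            prev["genes"] = sorted(set(prev["genes"]) | set(genes or []))
            return
        self._calls[key] = {"status": status, "genes": sorted(genes or []),
                            "suffixes": suffixes or [], "evidence": evidence or {}}

    def status(self, orthogroup: str, species: str) -> str | None:
        call = self._calls.get((orthogroup, species))
        return None if call is None else call["status"]

    def genes(self, orthogroup: str, species: str) -> list[str]:
        call = self._calls.get((orthogroup, species))
        return [] if call is None else list(call["genes"])

    def evidence(self, orthogroup: str, species: str) -> dict:
        call = self._calls.get((orthogroup, species))
        return {} if call is None else dict(call["evidence"])

    @property
    def orthogroups(self) -> list[str]:
        return sorted({og for og, _ in self._calls})

    @property
    def species(self) -> list[str]:
        return sorted({sp for _, sp in self._calls})

    def to_frame(self) -> pd.DataFrame:
        rows = [{"orthogroup": og, "species": sp, **{k: v for k, v in call.items()
                                                     if k != "evidence"},
                 "evidence": repr(call["evidence"])}
                for (og, sp), call in sorted(self._calls.items())]
        return pd.DataFrame(rows)

    def to_tsv(self) -> str:
        df = self.to_frame().copy()
        if not df.empty:
            df["genes"] = df["genes"].map(",".join)
            df["suffixes"] = df["suffixes"].map(",".join)
        return df.to_csv(sep="\t", index=False)

    def presence_matrix(self) -> pd.DataFrame:
        """Glyph matrix: 1 = present, 0 = gene lost but territory present,
        '.' = territory absent / never evolved (no call)."""
        glyph = {"present": "1", "gene_lost_territory_present": "0",
                 "territory_absent": ".", "unresolved": "?"}
        df = pd.DataFrame(".", index=self.orthogroups, columns=self.species)
        for (og, sp), call in self._calls.items():
            df.loc[og, sp] = glyph[call["status"]]
        return df


@dataclass
class _Group:
    label: str
    members: list[WindowProfile] = field(default_factory=list)

    def consensus(self) -> set[str]:
        """Families seen in >= 2 member species (all of them while the
        group has a single species)."""
        per_species: dict[str, set[str]] = {}
        for p in self.members:
            per_species.setdefault(p.species, set()).update(p.families)
        need = min(2, len(per_species))
        counts: dict[str, int] = {}
        for fams in per_species.values():
            for f in fams:
                counts[f] = counts.get(f, 0) + 1
        return {f for f, c in counts.items() if c >= need}


def assign_orthogroups(candidates: dict[str, list[str]],
                       tables: dict[str, GenomeTable],
                       families: HomologyFamilies | None = None,
                       k: int = 5, min_shared: int = 3) -> OrthologyCallMatrix:
    """Group candidate loci across species by shared window synteny.

    Candidates are seeded from the locus with the most annotated window
    and greedily absorbed into the group whose consensus profile they
    share >= ``min_shared`` families with; within a species, members of a
    group are suffixed ``a`` (highest score), ``b``, ... with ties broken
    by (chromosome, order_index).  Deterministic and independent of the
    input dict ordering.
    """
    if not candidates or not any(candidates.values()):
        raise ValueError("empty candidate set")
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")

    profiles: list[WindowProfile] = []
    for species in sorted(candidates):
        for gid in sorted(candidates[species]):
            profiles.append(window_profile(tables[species], families, gid, k=k))
    # largest annotated window first; then stable content-based order
    profiles.sort(key=lambda p: (-p.size, p.species, p.focus))

    groups: list[_Group] = []
    for prof in profiles:
        best, best_score = None, 0
        for grp in groups:
            score, _ = shared_synteny_score(prof, _consensus_profile(grp))
            if score > best_score:
                best, best_score = grp, score
        if best is not None and best_score >= min_shared:
            best.members.append(prof)
        else:
            groups.append(_Group(label=f"OG_{prof.species}_{prof.focus}",
                                 members=[prof]))

    matrix = OrthologyCallMatrix()
    for grp in groups:
        cons = _consensus_profile(grp)
        by_species: dict[str, list[WindowProfile]] = {}
        for p in grp.members:
            by_species.setdefault(p.species, []).append(p)
        for species, members in by_species.items():
            scored = []
            for p in members:
                score, _ = shared_synteny_score(p, cons)
                rec = tables[species].get(p.focus)
                scored.append((-score, rec.chrom, rec.order_index, p))
            scored.sort(key=lambda t: t[:3])
            suffixes = [_suffix(i) for i in range(len(scored))] if len(scored) > 1 else [""]
            matrix.set(grp.label, species, "present",
                       genes=[t[3].focus for t in scored],
                       suffixes=suffixes,
                       evidence={"best_score": -scored[0][0],
                                 "group_size": len(grp.members)})
    return matrix


def _suffix(i: int) -> str:
    return chr(ord("a") + i) if i < 26 else f"x{i}"


def _consensus_profile(grp: _Group) -> WindowProfile:
    cons = grp.consensus()
    return WindowProfile(focus=f"<consensus:{grp.label}>", species="<consensus>",
                         upstream=sorted(cons), downstream=[], strands=[],
                         k=max((p.k for p in grp.members), default=5))


def classify_locus(table: GenomeTable, families: HomologyFamilies | None,
                   consensus: set[str], candidate_genes: set[str] | None = None,
                   min_territory: int = 3, span: int = 10) -> tuple[str, dict]:
    """Status of one orthogroup's locus in one species.

    ``present`` if a candidate gene exists; else the genome is scanned for
    a run of ``span`` consecutive protein-coding genes carrying >=
    ``min_territory`` consensus families (``gene_lost_territory_present``).
    When the best-scoring stretch sits on a scaffold too short to hold a
    full span (an assembly-gap caveat) the call is ``unresolved``;
    otherwise ``territory_absent``.
    """
    if not consensus:
        raise ValueError("empty consensus profile")
    candidate_genes = candidate_genes or set()
    for gid in candidate_genes:
        if gid in table:
            return "present", {"genes": sorted(g for g in candidate_genes if g in table)}

    best = 0
    best_chrom = None
    best_chrom_len = 0
    for chrom, recs in table.chromosomes.items():
        coding = [r for r in recs if r.biotype == "protein_coding"]
        if not coding:
            continue
        n = len(coding)
        windows = range(max(1, n - span + 1))
        for i in windows:
            fams = set()
            for r in coding[i:i + span]:
                fam = None
                if families is not None:
                    fam = families.family_of(r.gene_id)
                if fam is None:
                    fam = r.family
                if fam is not None:
                    fams.add(fam)
            hit = len(fams & consensus)
            if hit > best or (hit == best and best_chrom is None):
                best, best_chrom, best_chrom_len = hit, chrom, n
    evidence = {"best_span_hits": best, "chrom": best_chrom}
    if best >= min_territory:
        return "gene_lost_territory_present", evidence
    if best >= 1 and best_chrom is not None and best_chrom_len < span:
        return "unresolved", evidence
    return "territory_absent", evidence
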