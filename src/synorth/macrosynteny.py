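"""Chromosome-scale synteny: 100-gene cumulative profiles, gene-level
collinear chaining, per-chromosome syntenic-hit counts and the top-2
chi-square test with gene-density normalisation.

Chains are anchored on homology families rather than DNA alignment: a
chain is a run of homologous gene pairs whose positions are strictly
monotone on both chromosomes (co-linear or anti-diagonal — inversions are
pervasive) with at most ``max_gap`` genes between consecutive anchors on
either axis, and at least ``min_pairs`` anchors in total.  This is the
implementable gene-order equivalent of dot-plot chaining with a "minimum
number of aligned pairs" of 3 within a 20-gene distance; it is stated as
such, not claimed bit-identical to any alignment-anchored tool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genome_model import GenomeTable, HomologyFamilies

__all__ = [
    "CumulativeCurve", "CollinearChain", "Top2TestResult",
    "cumulative_profile", "collinear_chains", "chromosome_hit_counts",
    "top2_test", "density_normalize",
]


# ---------------------------------------------------------------------------
# cumulative 100-gene profiles
# ---------------------------------------------------------------------------

@dataclass
class CumulativeCurve:
    focus: str
    query_species: str
    offsets: list[int]            # -W .. +W gene positions relative to focus
    cumulative: list[int]         # hit count accumulated outward from 0
    hits: list[bool]              # per-offset hit indicator

    def value_at(self, offset: int) -> int:
        return self.cumulative[self.offsets.index(offset)]


def _record_family(rec, families: HomologyFamilies | None) -> str | None:
    if families is not None:
        fam = families.family_of(rec.gene_id)
        if fam is not None:
            return fam
    return rec.family


def cumulative_profile(ref_table: GenomeTable, query_table: GenomeTable,
                       families: HomologyFamilies | None, focus: str,
                       half_window: int = 50) -> CumulativeCurve:
    """Cumulative syntenic-hit curve in a (2*half_window+1)-gene window
    centred on the focus gene.

    At each offset the curve increments iff the reference gene there has
    at least one family member annotated in the query species; totals
    accumulate outward (5' and 3') from the focus, so conserved stretches
    appear as climbing ramps and divergence as plateaus.
    """
    rec = ref_table.get(focus)
    if not ref_table.placed.get(rec.chrom, True):
        raise ValueError(f"focus {focus!r} sits on an unplaced scaffold")
    recs = ref_table.chromosomes[rec.chrom]
    centre = rec.order_index

    def hit(idx: int) -> bool:
        if not 0 <= idx < len(recs):
            return False
        fam = _record_family(recs[idx], families)
        if fam is None:
            return False
        if families is not None:
            return any(g in query_table for g in families.genes_of(fam))
        return any(r2.family == fam for r2 in query_table.genes())

    offsets = list(range(-half_window, half_window + 1))
    hits = [hit(centre + o) for o in offsets]
    base = int(hits[half_window])
    cumulative = []
    for o in offsets:
        if o == 0:
            cumulative.append(base)
        elif o > 0:
            cumulative.append(base + sum(hits[half_window + 1:half_window + 1 + o]))
        else:
            cumulative.append(base + sum(hits[half_window + o:half_window]))
    return CumulativeCurve(focus=focus, query_species=query_table.species,
                           offsets=offsets, cumulative=cumulative, hits=hits)


# ---------------------------------------------------------------------------
# collinear chaining
# ---------------------------------------------------------------------------

@dataclass
class CollinearChain:
    pairs: list[tuple[int, int]]   # (ref position, query position), ref ascending
    ref_chrom: str
    query_chrom: str
    orientation: str               # "colinear" | "anti"
    ref_genes: list[str]
    query_genes: list[str]

    def __len__(self):
        return len(self.pairs)


def _homologous_pairs(ref_genes, query_genes, families):
    """Anchor list: (ref position, query position, ref id, query id)."""
    by_family: dict[str, list[int]] = {}
    for j, q in enumerate(query_genes):
        fam = _record_family(q, families)
        if fam is not None:
            by_family.setdefault(fam, []).append(j)
    pairs = []
    for i, r in enumerate(ref_genes):
        fam = _record_family(r, families)
        for j in by_family.get(fam, ()):
            pairs.append((i, j, r.gene_id, query_genes[j].gene_id))
    return pairs


def _edges(pairs, sign: int, max_gap: int):
    """q follows p when both coordinates advance (query by `sign`) within
    max_gap on each axis."""
    succ = {k: [] for k in range(len(pairs))}
    pred = {k: [] for k in range(len(pairs))}
    for a, (i1, j1, *_) in enumerate(pairs):
        for b, (i2, j2, *_) in enumerate(pairs):
            if i2 > i1 and 0 < sign * (j2 - j1) and \
                    i2 - i1 <= max_gap and abs(j2 - j1) <= max_gap:
                succ[a].append(b)
                pred[b].append(a)
    return succ, pred


def _tight(pairs, a: int, b: int, sign: int) -> bool:
    """No anchor strictly between a and b on both axes (any such anchor
    could be inserted, so a path using this step would not be maximal)."""
    i1, j1, *_ = pairs[a]
    i2, j2, *_ = pairs[b]
    for i, j, *_ in pairs:
        if i1 < i < i2 and (j1 < j < j2 if sign > 0 else j2 < j < j1):
            return False
    return True


def collinear_chains(ref_genes, query_genes, families: HomologyFamilies | None,
                     min_pairs: int = 3, max_gap: int = 20) -> list[CollinearChain]:
    """All maximal collinear (and anti-diagonal) chains between two
    ordered gene lists.

    A chain is maximal when no homologous pair can be added to it without
    violating monotonicity or the gap bound.  Enumeration walks only
    "tight" steps (no insertable anchor between consecutive members) from
    anchors with no valid predecessor to anchors with no valid successor,
    which yields exactly the maximal chains.  Ties in reporting order are
    broken by (length desc, starting ref position asc).
    """
    if min_pairs < 1 or max_gap < 1:
        raise ValueError("min_pairs and max_gap must be >= 1")
    ref_genes = list(ref_genes)
    query_genes = list(query_genes)
    pairs = _homologous_pairs(ref_genes, query_genes, families)
    ref_chrom = ref_genes[0].chrom if ref_genes else ""
    query_chrom = query_genes[0].chrom if query_genes else ""

    chains: list[CollinearChain] = []
    seen: set[tuple] = set()
    for sign, orientation in ((1, "colinear"), (-1, "anti")):
        succ, pred = _edges(pairs, sign, max_gap)
        tight_succ = {a: [b for b in succ[a] if _tight(pairs, a, b, sign)]
                      for a in succ}
        sources = [a for a in range(len(pairs)) if not pred[a]]

        def extend(path):
            last = path[-1]
            if not tight_succ[last]:
                if len(path) >= min_pairs:
                    key = tuple(path)
                    if key not in seen:
                        seen.add(key)
                        chains.append(CollinearChain(
                            pairs=[(pairs[k][0], pairs[k][1]) for k in path],
                            ref_chrom=ref_chrom, query_chrom=query_chrom,
                            orientation=orientation,
                            ref_genes=[pairs[k][2] for k in path],
                            query_genes=[pairs[k][3] for k in path]))
                return
            for nxt in tight_succ[last]:
                extend(path + [nxt])

        for s in sources:
            extend([s])

    chains.sort(key=lambda c: (-len(c), c.pairs[0][0], c.pairs[0][1], c.orientation))
    return chains


def _pairs_in_valid_chains(pairs, sign: int, min_pairs: int, max_gap: int):
    """Indices of anchors that sit on at least one chain of >= min_pairs,
    via longest-chain-through-anchor dynamic programming (no enumeration)."""
    succ, pred = _edges(pairs, sign, max_gap)
    order = sorted(range(len(pairs)), key=lambda k: (pairs[k][0], sign * pairs[k][1]))
    fwd = {k: 1 for k in range(len(pairs))}
    for k in order:
        for p in pred[k]:
            fwd[k] = max(fwd[k], fwd[p] + 1)
    bwd = {k: 1 for k in range(len(pairs))}
    for k in reversed(order):
        for s in succ[k]:
            bwd[k] = max(bwd[k], bwd[s] + 1)
    return {k for k in range(len(pairs)) if fwd[k] + bwd[k] - 1 >= min_pairs}


def chromosome_hit_counts(ref_genes, query_table: GenomeTable,
                          families: HomologyFamilies | None,
                          min_pairs: int = 3, max_gap: int = 20) -> dict[str, int]:
    """Per query chromosome: number of distinct reference genes taking part
    in at least one collinear chain to that chromosome.

    Reference genes are deduplicated (a gene hit by several chains to one
    chromosome counts once) because downstream proportion tests use the
    reference chromosome's gene count as the sample size.
    """
    counts: dict[str, int] = {}
    ref_genes = list(ref_genes)
    for chrom in sorted(query_table.chromosomes):
        qgenes = query_table.chromosomes[chrom]
        pairs = _homologous_pairs(ref_genes, qgenes, families)
        hit_refs: set[str] = set()
        for sign in (1, -1):
            for k in _pairs_in_valid_chains(pairs, sign, min_pairs, max_gap):
                hit_refs.add(pairs[k][2])
        if hit_refs:
            counts[chrom] = len(hit_refs)
    return counts


# ---------------------------------------------------------------------------
# top-2 chi-square test and density normalisation
# ---------------------------------------------------------------------------

@dataclass
class Top2TestResult:
    counts: dict[str, int]
    top_labels: tuple[str, str]
    table: list[list[int]]
    chi2: float
    df: int
    p_value: float
    proportion_diff: float
    ci95: tuple[float, float]
    n: int


def top2_test(counts: dict[str, int], n_ref_genes: int) -> Top2TestResult:
    """Chi-square comparison of the two best-hit query chromosomes.

    Builds the 2x2 table [hits1, n-hits1; hits2, n-hits2] with n the
    reference chromosome's gene count, computes the uncorrected
    sum((O-E)^2/E) statistic on df=1 with a two-sided p, and a 95% Wald
    interval for the difference of proportions.  Label order is
    deterministic (count desc, then label asc) and the statistic is
    symmetric under swapping the two labels.
    """
    nonzero = [(c, lab) for lab, c in counts.items() if c > 0]
    if len(nonzero) < 2:
        raise ValueError("need at least two chromosomes with nonzero counts")
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    (lab1, h1), (lab2, h2) = ordered[0], ordered[1]
    if n_ref_genes < max(h1, h2):
        raise ValueError("sample size n is smaller than a hit count")
    n = n_ref_genes
    table = [[h1, n - h1], [h2, n - h2]]
    obs = np.asarray(table, dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    p1, p2 = h1 / n, h2 / n
    se = float(np.sqrt(p1 * (1 - p1) / n + p2 * (1 - p2) / n))
    z = stats.norm.ppf(0.975)
    diff = p1 - p2
    return Top2TestResult(counts=dict(counts), top_labels=(lab1, lab2),
                          table=table, chi2=chi2, df=1, p_value=p,
                          proportion_diff=diff,
                          ci95=(diff - z * se, diff + z * se), n=n)


def density_normalize(counts: dict[str, int],
                      chrom_gene_totals: dict[str, int]) -> dict:
    """Hits per gene for each query chromosome, plus the rank correlation
    of raw counts against chromosome gene totals.

    Rules out the confound that the best-hit chromosome simply carries the
    most genes; flags when the top chromosome by rate differs from the top
    by raw count.
    """
    labels = sorted(counts)
    for lab in labels:
        if chrom_gene_totals.get(lab, 0) <= 0:
            raise ValueError(f"chromosome {lab!r} has non-positive gene total")
    rates = {lab: counts[lab] / chrom_gene_totals[lab] for lab in labels}
    raw = [counts[lab] for lab in labels]
    totals = [chrom_gene_totals[lab] for lab in labels]
    if len(labels) >= 2 and len(set(raw)) > 1 and len(set(totals)) > 1:
        rho, p = stats.spearmanr(raw, totals)
        rho, p = float(rho), float(p)
    else:
        rho, p = float("nan"), float("nan")
    top_by_count = min(labels, key=lambda l: (-counts[l], l))
    top_by_rate = min(labels, key=lambda l: (-rates[l], l))
    return {"rates": rates, "spearman_rho": rho, "spearman_p": p,
            "top_by_count": top_by_count, "top_by_rate": top_by_rate,
            "top_rank_changed": top_by_count != top_by_rate}
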