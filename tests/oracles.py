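"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's own algorithms: chains are found by
exhaustive subset enumeration, Dollo losses by enumerating loss-branch
subsets and simulating presence down the tree.
"""

import itertools

from synorth.genome_model import GeneRecord


def brute_force_maximal_chains(pairs, min_pairs, max_gap):
    """All maximal valid chains over (ref, query) anchor positions, as
    frozensets of pair indices, by enumerating every subset."""
    n = len(pairs)
    valid = set()
    for r in range(1, n + 1):
        for combo in itertools.combinations(range(n), r):
            chain = sorted((pairs[k] for k in combo))
            iis = [p[0] for p in chain]
            jjs = [p[1] for p in chain]
            if len(set(iis)) < len(iis):
                continue
            for sign in (1, -1):
                sj = [sign * j for j in jjs]
                if all(b > a for a, b in zip(sj, sj[1:])) and \
                        all(b - a <= max_gap for a, b in zip(iis, iis[1:])) and \
                        all(abs(b - a) <= max_gap for a, b in zip(jjs, jjs[1:])):
                    valid.add((frozenset(combo), sign))
    out = set()
    for s, sign in valid:
        if len(s) < min_pairs:
            continue
        if any(s < s2 and sign == g2 for s2, g2 in valid):
            continue
        out.add(s)
    return out


def chains_from_pair_list(pairs, min_pairs, max_gap):
    """Run the package's chainer on an explicit anchor list by encoding
    each pair through a family label; returns chains as frozensets of pair
    indices, or None when the pair list cannot be encoded (a query
    position matched to two reference genes)."""
    from synorth.macrosynteny import collinear_chains

    ref = [GeneRecord(gene_id=f"r{k}", species="s1", chrom="c", order_index=k)
           for k in range(max(p[0] for p in pairs) + 1)]
    query = [GeneRecord(gene_id=f"q{k}", species="s2", chrom="d", order_index=k)
             for k in range(max(p[1] for p in pairs) + 1)]
    for r in ref:
        r.family = None
    for q in query:
        q.family = None
    for i, j in pairs:
        ref[i].family = f"F{i}"
    for i, j in pairs:
        if query[j].family is not None:
            return None
        query[j].family = f"F{i}"
    found = collinear_chains(ref, query, None, min_pairs=min_pairs, max_gap=max_gap)
    index = {tuple(p): k for k, p in enumerate(pairs)}
    return {frozenset(index[p] for p in c.pairs) for c in found}


def random_pair_instance(rng, max_pairs, grid=13):
    """Random anchor set with unique query positions (so the family
    encoding above is exact)."""
    raw = {(rng.randint(0, grid - 1), rng.randint(0, grid - 1))
           for _ in range(rng.randint(3, max_pairs))}
    seen_j, pairs = set(), []
    for i, j in sorted(raw):
        if j not in seen_j:
            seen_j.add(j)
            pairs.append((i, j))
    return pairs


def dollo_oracle(tree, presence):
    """Minimum-loss single-gain labelling by exhaustive search.

    For every candidate gain branch whose subtree covers the present
    leaves, losses can only help on branches rooted at nodes without
    present descendants; all subsets of those candidates are simulated.
    Returns (min_losses, set of optimal gain branches).
    """
    present = {leaf for leaf in tree.leaves if presence.get(leaf, False)}
    best = None
    best_gains = set()
    for gain in tree.branches_preorder():
        if not present <= tree.leaves_under(gain):
            continue
        candidates = [b for b in tree.branches_preorder()
                      if b != gain and tree.is_descendant(b, gain)
                      and not (tree.leaves_under(b) & present)]
        for r in range(len(candidates) + 1):
            done = False
            for losses in itertools.combinations(candidates, r):
                covered = set()
                for b in losses:
                    covered |= tree.leaves_under(b)
                simulated = tree.leaves_under(gain) - covered
                if simulated == present:
                    if best is None or r < best:
                        best, best_gains = r, {gain}
                    elif r == best:
                        best_gains.add(gain)
                    done = True
                    break
            if done:
                break
    return best, best_gains
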