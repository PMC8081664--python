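"""Rooted species tree with stable branch identifiers.

A branch is named by the node at its child end, so the edge above internal
node ``gnathostomata`` is branch ``"gnathostomata"`` and the edge above a
leaf is the species name.  Unlabelled internal nodes get deterministic
``nodeN`` labels in preorder.
"""

from __future__ import annotations

import dendropy


class SpeciesTree:
    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        counter = 0
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                node._branch_id = node.taxon.label
            elif node.label:
                node._branch_id = node.label
            else:
                node._branch_id = f"node{counter}"
            counter += 1
        ids = [n._branch_id for n in tree.preorder_node_iter()]
        if len(ids) != len(set(ids)):
            raise ValueError("branch ids (node labels / species names) must be unique")
        self._by_id = {n._branch_id: n for n in tree.preorder_node_iter()}

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 suppress_internal_node_taxa=True,
                                 preserve_underscores=True)
        tree.is_rooted = True
        return cls(tree)

    # -- topology queries ---------------------------------------------
    @property
    def root_branch(self) -> str:
        return self._tree.seed_node._branch_id

    @property
    def leaves(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    def branches_preorder(self) -> list[str]:
        return [n._branch_id for n in self._tree.preorder_node_iter()]

    def children(self, branch: str) -> list[str]:
        return [c._branch_id for c in self._by_id[branch].child_nodes()]

    def parent(self, branch: str) -> str | None:
        p = self._by_id[branch].parent_node
        return None if p is None else p._branch_id

    def is_leaf(self, branch: str) -> bool:
        return self._by_id[branch].is_leaf()

    def leaves_under(self, branch: str) -> set[str]:
        return {lf.taxon.label for lf in self._by_id[branch].leaf_iter()}

    def mrca(self, leaf_names) -> str:
        leaf_names = set(leaf_names)
        if not leaf_names:
            raise ValueError("mrca of empty leaf set")
        if not leaf_names <= set(self.leaves):
            raise ValueError(f"unknown leaves: {leaf_names - set(self.leaves)}")
        if len(leaf_names) == 1:
            return next(iter(leaf_names))
        node = self._tree.mrca(taxon_labels=list(leaf_names))
        return node._branch_id

    def path_from_root(self, branch: str) -> list[str]:
        """Branch ids from the root edge down to ``branch`` inclusive."""
        node = self._by_id[branch]
        path = []
        while node is not None:
            path.append(node._branch_id)
            node = node.parent_node
        return path[::-1]

    def is_descendant(self, branch: str, ancestor: str) -> bool:
        """True if ``ancestor`` lies on the root path of ``branch`` (inclusive)."""
        return ancestor in self.path_from_root(branch)

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()
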