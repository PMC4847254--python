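"""Strain trees: simulation, Newick IO and tree comparison.

A :class:`StrainTree` is a thin wrapper around a :class:`dendropy.Tree` that
pins down the conventions the rest of the package relies on: leaf labels are
strain tags, every non-root edge carries a positive branch length, and the
Newick serialisation of a given tree object is byte-stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = ["StrainTree", "simulate_tree", "rf_distance"]


@dataclass
class StrainTree:
    """A rooted or unrooted phylogeny over a set of strains."""

    tree: dendropy.Tree

    @classmethod
    def from_newick(cls, newick: str) -> "StrainTree":
        t = dendropy.Tree.get(data=newick, schema="newick",
                              preserve_underscores=True)
        return cls(t)

    @classmethod
    def read(cls, path) -> "StrainTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(lf.taxon.label for lf in self.tree.leaf_node_iter())

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True,
            unquoted_underscores=True).strip() + "\n"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick())

    def n_edges(self) -> int:
        """Number of edges (root edge excluded)."""
        return sum(1 for e in self.tree.preorder_edge_iter()
                   if e.tail_node is not None)

    def edges(self) -> list[tuple[frozenset, float]]:
        """Non-root edges as ``(descendant leaf set, branch length)``.

        Deterministically ordered by (clade size, sorted labels).
        """
        out = []
        for edge in self.tree.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            clade = frozenset(lf.taxon.label
                              for lf in edge.head_node.leaf_iter())
            out.append((clade, float(edge.length or 0.0)))
        out.sort(key=lambda cl: (len(cl[0]), tuple(sorted(cl[0]))))
        return out

    def branch_iter(self):
        """Yield ``(parent_id, child_id, length, leaf_label_or_None)`` in
        preorder; node ids are stable integers with the root first."""
        ids: dict[int, int] = {}
        for i, node in enumerate(self.tree.preorder_node_iter()):
            ids[id(node)] = i
            if node.parent_node is None:
                continue
            label = node.taxon.label if node.is_leaf() else None
            yield ids[id(node.parent_node)], i, float(node.edge.length or 0.0), label

    def leaf_distance_matrix(self) -> tuple[list[str], np.ndarray]:
        """Patristic (path-length) distances between leaves."""
        labels = self.leaf_labels
        idx = {lab: i for i, lab in enumerate(labels)}
        pdm = self.tree.phylogenetic_distance_matrix()
        n = len(labels)
        d = np.zeros((n, n))
        taxa = {t.label: t for t in self.tree.taxon_namespace}
        for a in labels:
            for b in labels:
                if a < b:
                    v = pdm.patristic_distance(taxa[a], taxa[b])
                    d[idx[a], idx[b]] = d[idx[b], idx[a]] = v
        return labels, d


def simulate_tree(n_strains: int, seed: int) -> StrainTree:
    """Simulate a random rooted binary tree over ``n_strains`` strains.

    Topology is built by uniform random joins of active lineages (a simple
    coalescent-style process) with strictly positive branch lengths; leaves
    are labelled ``strain_001`` ... ``strain_NNN``.  Deterministic for a
    fixed ``seed``.
    """
    if n_strains < 3:
        raise ValueError("n_strains must be >= 3, got %d" % n_strains)
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    active: list[tuple[dendropy.Node, float]] = []
    for i in range(1, n_strains + 1):
        label = f"strain_{i:03d}"
        taxon = taxa.new_taxon(label)
        node = dendropy.Node(taxon=taxon)
        active.append((node, 0.0))
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        (ni, hi), (nj, hj) = active[i], active[j]
        height = max(hi, hj) + 0.02 + float(rng.exponential(0.08))
        parent = dendropy.Node()
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = height - hi
        nj.edge.length = height - hj
        del active[j], active[i]
        active.append((parent, height))
    root = active[0][0]
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = True
    return StrainTree(tree)


def rf_distance(a: StrainTree, b: StrainTree) -> int:
    """Unrooted Robinson-Foulds (symmetric bipartition) distance."""
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=a.newick(), schema="newick",
                           taxon_namespace=tns, preserve_underscores=True)
    tb = dendropy.Tree.get(data=b.newick(), schema="newick",
                           taxon_namespace=tns, preserve_underscores=True)
    ta.is_rooted = False
    tb.is_rooted = False
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(ta, tb))
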