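"""SNP pseudo-genomes, pairwise SNP distances and neighbour-joining.

Per-strain variant calls against a reference strain are substituted into
the reference sequence to form equal-length *pseudo-genomes*; pairwise
Hamming distances over these aligned sequences feed a classic
Saitou-Nei neighbour-joining reconstruction.  All non-variant positions
are treated as reference-equal (no coverage masking).  NJ here is exact
on additive distance matrices — path lengths on the output tree reproduce
the input matrix — which is the testable contract the rest of the package
relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .trees import StrainTree

__all__ = [
    "VariantSet", "DistanceMatrix", "apply_snps", "snp_distance_matrix",
    "neighbor_joining", "group_strains", "variant_set_from_diff",
]


@dataclass
class VariantSet:
    """Biallelic SNPs of one strain vs. a reference (1-based positions)."""

    strain_tag: str
    variants: list[tuple[int, str, str]]     # (pos, ref allele, alt allele)

    def validate(self, reference: str) -> None:
        seen = set()
        for pos, ref, alt in self.variants:
            if not (1 <= pos <= len(reference)):
                raise ValueError(f"{self.strain_tag}: variant position {pos} "
                                 f"outside reference (length {len(reference)})")
            if pos in seen:
                raise ValueError(f"{self.strain_tag}: duplicate variant "
                                 f"position {pos}")
            seen.add(pos)
            if reference[pos - 1] != ref:
                raise ValueError(
                    f"{self.strain_tag}: ref-allele mismatch at position "
                    f"{pos}: expected {reference[pos - 1]!r}, VCF says "
                    f"{ref!r} (check coordinate conventions)")


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def validate(self) -> None:
        m = self.matrix
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.labels):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix is not symmetric")
        if (m < 0).any():
            raise ValueError("distance matrix has negative entries")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("distance matrix diagonal is not zero")

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.matrix):
                fh.write(lab + "  " + "  ".join(f"{v:.6f}" for v in row)
                         + "\n")


def apply_snps(reference: str, vs: VariantSet) -> str:
    """Substitute a strain's SNPs into the reference sequence.

    The output has the reference's length and differs from it at exactly
    the variant positions.
    """
    vs.validate(reference)
    seq = bytearray(reference.encode())
    for pos, _ref, alt in vs.variants:
        seq[pos - 1] = ord(alt)
    return seq.decode()


def variant_set_from_diff(reference: str, pseudo: str,
                          strain_tag: str) -> VariantSet:
    """Re-diff a pseudo-genome against the reference (round-trip check)."""
    if len(reference) != len(pseudo):
        raise ValueError("sequence length mismatch")
    a = np.frombuffer(reference.encode(), dtype=np.uint8)
    b = np.frombuffer(pseudo.encode(), dtype=np.uint8)
    variants = [(int(p) + 1, chr(a[p]), chr(b[p]))
                for p in np.nonzero(a != b)[0]]
    return VariantSet(strain_tag=strain_tag, variants=variants)


def snp_distance_matrix(pseudo_genomes: dict[str, str],
                        normalized: bool = False) -> DistanceMatrix:
    """Pairwise Hamming distances between equal-length pseudo-genomes."""
    labels = sorted(pseudo_genomes)
    lengths = {len(pseudo_genomes[lab]) for lab in labels}
    if len(lengths) > 1:
        raise ValueError(f"pseudo-genomes have differing lengths: "
                         f"{sorted(lengths)}")
    L = lengths.pop()
    arrs = np.stack([np.frombuffer(pseudo_genomes[lab].encode(),
                                   dtype=np.uint8) for lab in labels])
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            h = int((arrs[i] != arrs[j]).sum())
            d[i, j] = d[j, i] = h / L if normalized else h
    return DistanceMatrix(labels=labels, matrix=d)


# ------------------------------------------------------------------- NJ

def neighbor_joining(dm: DistanceMatrix) -> StrainTree:
    """Classic Saitou-Nei neighbour-joining.

    Deterministic: ties in the Q criterion break on the lexicographically
    smallest (label_i, label_j) pair, where a merged node is labelled by
    the smallest leaf beneath it.  Negative branch lengths are clamped to
    zero with the deficit moved to the sibling edge (standard practice).
    For an additive input matrix, path lengths on the output reproduce
    the matrix exactly.
    """
    dm.validate()
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    taxa = dendropy.TaxonNamespace()
    nodes: dict[str, dendropy.Node] = {}
    for lab in dm.labels:
        nodes[lab] = dendropy.Node(taxon=taxa.new_taxon(lab))
    labels = list(dm.labels)
    D = {a: {b: float(dm.matrix[i, j]) for j, b in enumerate(labels)}
         for i, a in enumerate(labels)}
    active = sorted(labels)
    n_clamped = 0

    def attach(parent, child_label, length):
        child = nodes[child_label]
        parent.add_child(child)
        child.edge.length = length

    while len(active) > 3:
        m = len(active)
        r = {a: sum(D[a][b] for b in active if b != a) for a in active}
        best = None
        for ai in range(m):
            for bi in range(ai + 1, m):
                a, b = active[ai], active[bi]
                q = (m - 2) * D[a][b] - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        la = 0.5 * D[a][b] + (r[a] - r[b]) / (2 * (m - 2))
        lb = D[a][b] - la
        if la < 0 or lb < 0:
            n_clamped += 1
        la, lb = _clamp_pair(la, lb)
        new_label = min(a, b)
        parent = dendropy.Node()
        # merged node keeps the smaller label; store under a key that
        # cannot collide with remaining actives
        attach(parent, a, la)
        attach(parent, b, lb)
        newD = {}
        for c in active:
            if c in (a, b):
                continue
            newD[c] = 0.5 * (D[a][c] + D[b][c] - D[a][b])
        active = sorted(c for c in active if c not in (a, b))
        nodes[new_label] = parent
        D[new_label] = {}
        for c in active:
            D[new_label][c] = newD[c]
            D[c][new_label] = newD[c]
        active = sorted(active + [new_label])

    a, b, c = active
    # three-point formulas
    la = 0.5 * (D[a][b] + D[a][c] - D[b][c])
    lb = 0.5 * (D[a][b] + D[b][c] - D[a][c])
    lc = 0.5 * (D[a][c] + D[b][c] - D[a][b])
    root = dendropy.Node()
    if min(la, lb, lc) < 0:
        n_clamped += 1
    for lab, ln in ((a, la), (b, lb), (c, lc)):
        attach(root, lab, max(ln, 0.0))
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    out = StrainTree(tree)
    out.clamped_branches = n_clamped   # flagged for downstream reporting
    return out


def _clamp_pair(la: float, lb: float) -> tuple[float, float]:
    if la < 0:
        lb += la
        la = 0.0
    if lb < 0:
        la += lb
        lb = 0.0
    return max(la, 0.0), max(lb, 0.0)


# ------------------------------------------------------------- grouping

def group_strains(tree: StrainTree, k: int) -> dict[str, str]:
    """Partition leaves into k groups by removing the k-1 longest
    internal edges (ties break on the clade's smallest leaf label)."""
    leaves = tree.leaf_labels
    n = len(leaves)
    if not (2 <= k <= n):
        raise ValueError(f"k must be in [2, {n}], got {k}")
    if k == n:
        return {lab: f"group_{i + 1}" for i, lab in enumerate(sorted(leaves))}
    internal = [(clade, length) for clade, length in tree.edges()
                if 1 < len(clade) < n]
    internal.sort(key=lambda cl: (-cl[1], min(cl[0]), tuple(sorted(cl[0]))))
    cuts = [clade for clade, _ in internal[:k - 1]]
    if len(cuts) < k - 1:
        raise ValueError(f"tree has only {len(internal)} internal edges; "
                         f"cannot cut into {k} groups")
    assignment = {lab: 0 for lab in leaves}
    # larger clades first so nested (deeper) cuts override
    for gid, clade in enumerate(
            sorted(cuts, key=lambda c: (-len(c), min(c))), start=1):
        for lab in clade:
            assignment[lab] = gid
    # relabel deterministically by each group's smallest leaf
    groups: dict[int, list[str]] = {}
    for lab, gid in assignment.items():
        groups.setdefault(gid, []).append(lab)
    order = sorted(groups, key=lambda g: min(groups[g]))
    rename = {gid: f"group_{i + 1}" for i, gid in enumerate(order)}
    return {lab: rename[gid] for lab, gid in assignment.items()}
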