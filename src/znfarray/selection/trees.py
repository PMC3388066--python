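"""Phylogenetic tree structure, newick IO and the neighbor-joining fallback.

The likelihood code treats trees as unrooted; internally they are stored
rooted at an arbitrary (basal, usually trifurcating) node.  Branch lengths
are expected substitutions per codon and are clamped to be non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0  # branch to parent; ignored at the root
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """A rooted-representation tree with named leaves and branch lengths."""

    def __init__(self, root: TreeNode):
        self.root = root

    def postorder(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def visit(node: TreeNode):
            for c in node.children:
                visit(c)
            out.append(node)

        visit(self.root)
        return out

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    @property
    def n_branches(self) -> int:
        return len(self.postorder()) - 1

    def branch_lengths(self) -> np.ndarray:
        return np.array([n.length for n in self.postorder()[:-1]])

    def set_branch_lengths(self, lengths: Sequence[float]) -> None:
        nodes = self.postorder()[:-1]
        if len(lengths) != len(nodes):
            raise ValueError(f"expected {len(nodes)} branch lengths, got {len(lengths)}")
        for n, t in zip(nodes, lengths):
            n.length = max(0.0, float(t))

    def copy(self) -> "PhyloTree":
        def clone(node: TreeNode) -> TreeNode:
            return TreeNode(node.name, node.length, [clone(c) for c in node.children])

        return PhyloTree(clone(self.root))

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}):{node.length:.10g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dt = dendropy.Tree.get(data=newick, schema="newick")

        def convert(dnode) -> TreeNode:
            name = dnode.taxon.label if dnode.taxon is not None else None
            length = dnode.edge.length if dnode.edge.length is not None else 0.0
            return TreeNode(name, max(0.0, float(length)), [convert(c) for c in dnode.child_nodes()])

        return cls(convert(dt.seed_node))


def nucleotide_p_distance(seqs: Sequence[str]) -> np.ndarray:
    """Pairwise proportion of differing positions between equal-length strings."""
    n = len(seqs)
    length = len(seqs[0])
    arrs = [np.frombuffer(s.encode("ascii"), dtype=np.uint8) for s in seqs]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if len(seqs[j]) != length:
                raise ValueError("sequences of unequal length")
            D[i, j] = D[j, i] = np.mean(arrs[i] != arrs[j])
    return D


def neighbor_joining(names: Sequence[str], dist: np.ndarray) -> PhyloTree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by smallest (i, j) index pair, so the
    topology depends only on the input order of taxa.  Negative branch
    lengths are clamped to zero.
    """
    n = len(names)
    if n < 3:
        raise ValueError(f"neighbor joining requires at least 3 taxa, got {n}")
    D = np.array(dist, dtype=float)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")
    nodes: list[TreeNode] = [TreeNode(name) for name in names]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # deterministic argmin: first (i, j) in row-major order
        flat = int(np.argmin(Q))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        nodes[i].length = max(0.0, li)
        nodes[j].length = max(0.0, lj)
        new = TreeNode(children=[nodes[i], nodes[j]])
        # distances from the new node to every other active node
        newdist = np.zeros(D.shape[0] + 1)
        for ak in active:
            if ak in (i, j):
                continue
            newdist[ak] = 0.5 * (D[i, ak] + D[j, ak] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(newdist) - 1] = newdist[:-1]
        D[: len(newdist) - 1, -1] = newdist[:-1]
        nodes.append(new)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    # resolve the final three lineages on a central node
    li = max(0.0, 0.5 * (D[i, j] + D[i, k] - D[j, k]))
    lj = max(0.0, 0.5 * (D[i, j] + D[j, k] - D[i, k]))
    lk = max(0.0, 0.5 * (D[i, k] + D[j, k] - D[i, j]))
    nodes[i].length, nodes[j].length, nodes[k].length = li, lj, lk
    return PhyloTree(TreeNode(children=[nodes[i], nodes[j], nodes[k]]))


def neighbor_joining_tree(aln) -> PhyloTree:
    """NJ tree from nucleotide p-distances of a codon alignment."""
    seqs = [aln.nt_sequence(i) for i in range(aln.n_taxa)]
    return neighbor_joining(aln.taxa, nucleotide_p_distance(seqs))
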