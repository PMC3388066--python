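"""Felsenstein-pruning likelihood for mixture-of-omega codon site models.

The generator is time-reversible, so transition matrices come from a
symmetric eigendecomposition (exact up to floating point, no Padé
truncation).  Site patterns are compressed and per-node partials rescaled,
so alignments of hundreds of codon sites on tens of taxa evaluate in
milliseconds.

Branch lengths are expected substitutions per codon site *averaged over the
site-class mixture*: each class generator is divided by the common factor
``c = sum_k p_k r_k`` where ``r_k`` is the stationary rate of class k.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import eigh
from scipy.special import logsumexp

from .alignment import CodonAlignment
from .codon import GOLDMAN_WHELAN, CodonFrequencies, empirical_frequencies, rate_matrix
from .trees import PhyloTree


class TreeIndex:
    """Flattened postorder view of a tree, tied to alignment rows."""

    def __init__(self, tree: PhyloTree, taxa: Sequence[str]):
        nodes = tree.postorder()
        self.n_nodes = len(nodes)
        self.root = self.n_nodes - 1
        pos = {id(n): i for i, n in enumerate(nodes)}
        self.children: list[list[int]] = [[pos[id(c)] for c in n.children] for n in nodes]
        self.branch_lengths = np.array([n.length for n in nodes[:-1]], dtype=float)
        row_of = {name: r for r, name in enumerate(taxa)}
        self.leaf_row: dict[int, int] = {}
        leaf_names = []
        for i, n in enumerate(nodes):
            if n.is_leaf:
                if n.name not in row_of:
                    raise ValueError(f"tree leaf {n.name!r} absent from alignment taxa")
                self.leaf_row[i] = row_of[n.name]
                leaf_names.append(n.name)
        if set(leaf_names) != set(taxa):
            missing = set(taxa) - set(leaf_names)
            raise ValueError(f"alignment taxa missing from tree: {sorted(missing)}")

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1


def transition_matrices(Q: np.ndarray, pi: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """exp(Q t) for every branch, via the reversible symmetrization."""
    sp = np.sqrt(pi)
    S = sp[:, None] * Q / sp[None, :]
    lam, U = eigh((S + S.T) / 2)
    left = U / sp[:, None]
    right = U.T * sp[None, :]
    E = np.exp(np.clip(lam[None, :] * np.asarray(lengths)[:, None], -700, 700))
    P = np.einsum("ik,bk,kj->bij", left, E, right)
    np.clip(P, 0.0, None, out=P)
    return P


def prune_log_likelihoods(
    P: np.ndarray,
    index: TreeIndex,
    patterns: np.ndarray,
    pi: np.ndarray,
) -> np.ndarray:
    """Per-pattern log likelihood by postorder pruning with rescaling."""
    npat = patterns.shape[1]
    conds: list[np.ndarray | None] = [None] * index.n_nodes
    logscale = np.zeros(npat)
    for i in range(index.n_nodes):
        kids = index.children[i]
        if not kids:
            conds[i] = P[i][:, patterns[index.leaf_row[i]]]
            continue
        inner = conds[kids[0]].copy()
        for c in kids[1:]:
            inner *= conds[c]
        for c in kids:
            conds[c] = None
        m = inner.max(axis=0)
        m = np.where(m > 0, m, 1.0)
        inner /= m
        logscale += np.log(m)
        if i == index.root:
            f = pi @ inner
            return np.log(np.maximum(f, 1e-300)) + logscale
        conds[i] = P[i] @ inner
    raise AssertionError("root not reached in postorder traversal")


@dataclass
class MixtureEvaluation:
    lnL: float
    log_f: np.ndarray  # (n_classes, n_patterns) per-class log site likelihoods
    scale: float  # mixture rate normalizer c


class MixtureLikelihood:
    """Likelihood engine for one alignment + tree + frequency model."""

    def __init__(
        self,
        aln: CodonAlignment,
        tree: PhyloTree,
        codon_freq_model: str = "F3x4",
        style: str = GOLDMAN_WHELAN,
        freqs: CodonFrequencies | None = None,
    ):
        self.aln = aln
        self.freqs = freqs if freqs is not None else empirical_frequencies(aln.codon_idx, codon_freq_model)
        self.style = style
        self.tree = tree.copy()
        self.index = TreeIndex(self.tree, aln.taxa)
        patterns, inverse, counts = np.unique(
            aln.codon_idx, axis=1, return_inverse=True, return_counts=True
        )
        self.patterns = patterns
        self.pattern_inverse = np.asarray(inverse).ravel()
        self.weights = counts.astype(float)

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[1]

    def expand(self, per_pattern: np.ndarray) -> np.ndarray:
        """Map per-pattern values back to per-site order (last axis)."""
        return np.take(per_pattern, self.pattern_inverse, axis=-1)

    def class_log_f(
        self,
        kappa: float,
        omega: float,
        branch_lengths: np.ndarray,
        scale: float = 1.0,
        pattern_cols: np.ndarray | None = None,
    ) -> np.ndarray:
        """Per-pattern log likelihood under a single omega class."""
        Q, pi, _ = rate_matrix(kappa, omega, self.freqs, self.style)
        P = transition_matrices(Q, pi, np.asarray(branch_lengths) / scale)
        pats = self.patterns if pattern_cols is None else self.patterns[:, pattern_cols]
        return prune_log_likelihoods(P, self.index, pats, pi)

    def evaluate(
        self,
        kappa: float,
        omegas: Sequence[float],
        proportions: Sequence[float],
        branch_lengths: np.ndarray | None = None,
    ) -> MixtureEvaluation:
        """Mixture log likelihood with codeml-style rate normalization."""
        props = np.asarray(proportions, dtype=float)
        if branch_lengths is None:
            branch_lengths = self.index.branch_lengths
        comps = [rate_matrix(kappa, w, self.freqs, self.style) for w in omegas]
        scale = float(sum(p * r for p, (_, _, r) in zip(props, comps)))
        if scale <= 0:
            return MixtureEvaluation(-np.inf, np.full((len(omegas), self.n_patterns), -np.inf), scale)
        lengths = np.asarray(branch_lengths, dtype=float) / scale
        log_f = np.empty((len(omegas), self.n_patterns))
        for k, (Q, pi, _) in enumerate(comps):
            P = transition_matrices(Q, pi, lengths)
            log_f[k] = prune_log_likelihoods(P, self.index, self.patterns, pi)
        site_log = logsumexp(log_f + np.log(np.maximum(props, 1e-300))[:, None], axis=0)
        return MixtureEvaluation(float(site_log @ self.weights), log_f, scale)

    def lnL(self, kappa, omegas, proportions, branch_lengths=None) -> float:
        return self.evaluate(kappa, omegas, proportions, branch_lengths).lnL


def dense_log_likelihood(
    aln: CodonAlignment,
    tree: PhyloTree,
    kappa: float,
    omega: float,
    freqs: CodonFrequencies,
    style: str = GOLDMAN_WHELAN,
    scale: float | None = None,
) -> float:
    """Brute-force single-class log likelihood via dense matrix exponential.

    Independent of the pruning path: sums over all internal-node state
    assignments using scipy's expm.  Only usable on tiny instances.
    """
    from itertools import product as iproduct

    from scipy.linalg import expm

    Q, pi, rate = rate_matrix(kappa, omega, freqs, style)
    if scale is None:
        scale = rate
    nodes = tree.postorder()
    pos = {id(n): i for i, n in enumerate(nodes)}
    parent = {}
    for i, n in enumerate(nodes):
        for c in n.children:
            parent[pos[id(c)]] = i
    P = {i: expm(Q * (n.length / scale)) for i, n in enumerate(nodes[:-1])}
    row_of = {name: r for r, name in enumerate(aln.taxa)}
    internal = [i for i, n in enumerate(nodes) if not n.is_leaf]
    root = len(nodes) - 1
    total = 0.0
    for site in range(aln.n_sites):
        leaf_assign = {
            i: int(aln.codon_idx[row_of[n.name], site])
            for i, n in enumerate(nodes)
            if n.is_leaf
        }
        site_sum = 0.0
        for states in iproduct(range(len(pi)), repeat=len(internal)):
            assign = dict(zip(internal, states))
            assign.update(leaf_assign)
            prob = pi[assign[root]]
            for i in range(root):
                prob *= P[i][assign[parent[i]], assign[i]]
            site_sum += prob
        total += np.log(site_sum)
    return float(total)
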