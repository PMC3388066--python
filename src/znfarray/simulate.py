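"""Synthetic-data generators with recorded ground truth.

Everything the pipeline consumes can be generated here: repeat libraries
with variation concentrated at DNA-contact residues, diploid populations of
phased array alleles with incomplete allele recovery, grouped allele
spectra, two-block arrays, and codon alignments evolved under the same
mixture-of-omega site models the fitters implement (so recovery tests are
well-posed).  Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .diversity import GroupedAlleleSpectrum
from .parser import (
    ZnfArrayAllele,
    ZnfRepeat,
    parse_allele,
    translate_repeats,
)
from .selection.alignment import CodonAlignment
from .selection.codon import (
    CODON_INDEX,
    CODONS,
    GENETIC_CODE,
    CodonFrequencies,
    rate_matrix,
    uniform_frequencies,
)
from .selection.likelihood import TreeIndex, transition_matrices
from .selection.trees import PhyloTree, TreeNode

# 28-residue template repeat: cysteines at offsets 7/10, histidines at
# 23/27, so the first histidine anchors contact offsets -1/2/3/6 at
# 16/18/19/22.  Position 2 carries the fixed serine.
TEMPLATE_AA = "TGEKPYECKECGKAFSQSSSLIKHQRTH"
_PREFERRED_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGA",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCA", "Q": "CAA", "R": "AGA", "S": "AGT", "T": "ACA", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
TEMPLATE_NT = "".join(_PREFERRED_CODON[a] for a in TEMPLATE_AA)

#: aa offsets of the variable contact residues (-1, 3, 6); position 2 (18)
#: is held fixed at serine.
CONTACT_VARIABLE_OFFSETS = (16, 19, 22)
FIXED_SERINE_OFFSET = 18
SCAFFOLD_OFFSETS = (7, 10, 23, 27)

#: residues safe to substitute in (no extra C/H that could confuse the
#: scaffold pattern, no stop-prone codons)
_SAFE_RESIDUES = "ADEFGIKLMNQRSTVWY"


@dataclass
class GroundTruth:
    """Recorded generator state, consumed by closure tests."""

    variable_columns: list[int] | None = None
    contact_columns: list[int] | None = None
    variant_masks: list[int] | None = None
    synonymous_pairs: list[tuple[int, int]] | None = None
    spectrum: dict[str, dict[str, int]] | None = None
    allele_sequences: dict[str, str] | None = None
    shared_alleles: list[str] | None = None
    dropped_records: list[str] | None = None
    block_gap: float | None = None
    block_split: int | None = None
    site_classes: np.ndarray | None = None
    params: dict | None = None


@dataclass
class SimulationConfig:
    """Knobs for every generator; unused fields are ignored per generator."""

    seed: int = 0
    # repeat library
    repeat_length: int = 84
    n_repeat_variants: int = 6
    n_variable_columns: int = 6
    contact_fraction: float = 0.5
    contact_rate_multiplier: float = 1.0
    n_synonymous_variants: int = 1
    # population
    min_repeats: int = 7
    max_repeats: int = 17
    groups: tuple[str, ...] = ("grpA", "grpB")
    allele_counts: Mapping[str, Sequence[int]] | None = None
    n_alleles_per_group: int = 5
    sequences_per_group: int = 10
    n_shared_alleles: int = 0
    dropout: float = 0.0
    # two-block arrays
    block_repeats_per_half: int = 5
    block_gap: float = 0.25
    # codon simulation
    site_model: str = "M2a"
    kappa: float = 2.0
    omegas: tuple[float, ...] = (0.1, 1.0, 8.0)
    proportions: tuple[float, ...] = (0.75, 0.125, 0.125)
    n_codon_sites: int = 300
    n_taxa: int = 16
    branch_length_range: tuple[float, float] = (0.05, 0.3)

    def __post_init__(self):
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be in [0, 1]")
        if not 0.0 <= self.contact_fraction <= 1.0:
            raise ValueError("contact_fraction must be in [0, 1]")
        if self.min_repeats < 1 or self.max_repeats < self.min_repeats:
            raise ValueError("need 1 <= min_repeats <= max_repeats")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("site-class proportions must sum to 1")


@dataclass
class RepeatLibrary:
    repeats_nt: list[str]
    repeats_aa: list[str]
    truth: GroundTruth


def _mutate_codon(aa_seq: str, nt_seq: str, column: int, new_aa: str) -> str:
    codon = _PREFERRED_CODON[new_aa]
    return nt_seq[: 3 * column] + codon + nt_seq[3 * column + 3 :]


def simulate_repeat_library(config: SimulationConfig, rng: np.random.Generator | None = None) -> RepeatLibrary:
    """Mutate the template repeat at planted columns.

    A configurable fraction of the variable columns falls at the contact
    offsets (-1, 3, 6); with ``contact_rate_multiplier == 0`` no contact
    column is touched.  Every planted column is guaranteed polymorphic in
    the emitted library, and distinct variant bitmasks guarantee distinct
    repeats.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    aa_len = len(TEMPLATE_AA)
    k = config.n_variable_columns
    if k > aa_len:
        raise ValueError(f"{k} variable columns exceed repeat length {aa_len}")
    n_contact = 0 if config.contact_rate_multiplier == 0 else round(k * config.contact_fraction)
    if n_contact > len(CONTACT_VARIABLE_OFFSETS):
        raise ValueError(
            f"requested {n_contact} contact columns but only "
            f"{len(CONTACT_VARIABLE_OFFSETS)} variable contact offsets exist"
        )
    contact_cols = sorted(
        rng.choice(CONTACT_VARIABLE_OFFSETS, size=n_contact, replace=False).tolist()
    )
    forbidden = set(SCAFFOLD_OFFSETS) | set(CONTACT_VARIABLE_OFFSETS) | {FIXED_SERINE_OFFSET}
    safe_cols = [c for c in range(aa_len) if c not in forbidden]
    noncontact_cols = sorted(
        rng.choice(safe_cols, size=k - n_contact, replace=False).tolist()
    )
    columns = sorted(contact_cols + noncontact_cols)

    alt_residue = {}
    for c in columns:
        choices = [r for r in _SAFE_RESIDUES if r != TEMPLATE_AA[c]]
        alt_residue[c] = str(rng.choice(choices))

    n_variants = config.n_repeat_variants - 1
    if n_variants < 1:
        raise ValueError("n_repeat_variants must be >= 2")
    all_masks = np.arange(1, 2**k)
    masks = rng.choice(all_masks, size=min(n_variants, len(all_masks)), replace=False).tolist()
    # guarantee every planted column varies somewhere in the library
    covered = set()
    for m in masks:
        covered |= {i for i in range(k) if m >> i & 1}
    for i in set(range(k)) - covered:
        j = int(rng.integers(len(masks)))
        masks[j] |= 1 << i
    masks = sorted(set(int(m) for m in masks))

    repeats_aa = [TEMPLATE_AA]
    repeats_nt = [TEMPLATE_NT]
    for m in masks:
        aa = list(TEMPLATE_AA)
        nt = TEMPLATE_NT
        for i, c in enumerate(columns):
            if m >> i & 1:
                aa[c] = alt_residue[c]
                nt = _mutate_codon("".join(aa), nt, c, alt_residue[c])
        repeats_aa.append("".join(aa))
        repeats_nt.append(nt)

    synonymous_pairs = []
    for s in range(config.n_synonymous_variants):
        src = s % len(repeats_nt)
        nt = repeats_nt[src]
        # swap one codon for a synonymous alternative
        for col in range(aa_len - 1, -1, -1):
            codon = nt[3 * col : 3 * col + 3]
            syn = [c for c in CODONS if GENETIC_CODE[c] == GENETIC_CODE[codon] and c != codon]
            if syn:
                new_nt = nt[: 3 * col] + syn[0] + nt[3 * col + 3 :]
                if new_nt not in repeats_nt:
                    repeats_nt.append(new_nt)
                    repeats_aa.append(repeats_aa[src])
                    synonymous_pairs.append((src, len(repeats_nt) - 1))
                    break

    truth = GroundTruth(
        variable_columns=columns,
        contact_columns=contact_cols,
        variant_masks=masks,
        synonymous_pairs=synonymous_pairs,
    )
    return RepeatLibrary(repeats_nt=repeats_nt, repeats_aa=repeats_aa, truth=truth)


@dataclass
class PopulationSample:
    """FASTA-ready records plus the sample->group map and ground truth."""

    records: list[tuple[str, str, str, str]]  # (record_id, sample_id, group, nt_seq)
    group_map: dict[str, str]
    truth: GroundTruth


def _default_counts(n_alleles: int, n_sequences: int) -> list[int]:
    """One common allele plus a tail of singletons/doubletons."""
    if n_alleles > n_sequences:
        raise ValueError("more alleles than sequences in a group")
    counts = [1] * n_alleles
    counts[0] += n_sequences - n_alleles
    return counts


def _assemble_allele(library: RepeatLibrary, length: int, rng: np.random.Generator) -> str:
    idx = rng.integers(0, len(library.repeats_nt), size=length)
    return "".join(library.repeats_nt[i] for i in idx)


def simulate_znf_population(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    library: RepeatLibrary | None = None,
) -> PopulationSample:
    """Emit a diploid population of phased array alleles.

    Per group, allele counts follow ``config.allele_counts`` (or the default
    one-common-plus-singletons shape); sequences are paired into diploid
    individuals and the second record of a heterozygous pair is dropped
    with probability ``config.dropout``.  The first ``n_shared_alleles``
    alleles are planted in *both* of the first two groups.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    library = library or simulate_repeat_library(config, rng)
    counts: dict[str, list[int]] = {}
    for g in config.groups:
        if config.allele_counts and g in config.allele_counts:
            counts[g] = list(config.allele_counts[g])
        else:
            counts[g] = _default_counts(config.n_alleles_per_group, config.sequences_per_group)

    if config.n_shared_alleles and len(config.groups) < 2:
        raise ValueError("shared alleles require at least two groups")

    seen: set[str] = set()

    def new_allele() -> str:
        for _ in range(1000):
            length = int(rng.integers(config.min_repeats, config.max_repeats + 1))
            seq = _assemble_allele(library, length, rng)
            if seq not in seen:
                seen.add(seq)
                return seq
        raise RuntimeError("could not assemble a distinct allele; enlarge the repeat library")

    shared = [new_allele() for _ in range(config.n_shared_alleles)]
    shared_labels = [f"S{i + 1}" for i in range(len(shared))]
    allele_seq: dict[str, str] = dict(zip(shared_labels, shared))
    spectrum: dict[str, dict[str, int]] = {}
    for gi, g in enumerate(config.groups):
        table: dict[str, int] = {}
        group_labels = []
        n_shared_here = len(shared_labels) if gi < 2 else 0
        for ai, c in enumerate(counts[g]):
            if ai < n_shared_here:
                lab = shared_labels[ai]
            else:
                lab = f"{g}.a{ai + 1}"
                if lab not in allele_seq:
                    allele_seq[lab] = new_allele()
            table[lab] = table.get(lab, 0) + c
            group_labels.append(lab)
        spectrum[g] = table

    records: list[tuple[str, str, str, str]] = []
    group_map: dict[str, str] = {}
    dropped: list[str] = []
    for g in config.groups:
        expanded = [lab for lab, c in spectrum[g].items() for _ in range(c)]
        if len(expanded) % 2 != 0:
            raise ValueError(f"group {g!r} needs an even sequence count to form diploids")
        order = rng.permutation(len(expanded))
        for ind, (i, j) in enumerate(zip(order[0::2], order[1::2])):
            sample = f"{g}_ind{ind + 1}"
            group_map[sample] = g
            a, b = expanded[i], expanded[j]
            records.append((f"{sample}.1", sample, g, allele_seq[a]))
            rec2 = (f"{sample}.2", sample, g, allele_seq[b])
            if rng.random() < config.dropout:
                dropped.append(rec2[0])
            else:
                records.append(rec2)

    truth = dataclasses.replace(
        library.truth,
        spectrum=spectrum,
        allele_sequences=allele_seq,
        shared_alleles=shared_labels,
        dropped_records=dropped,
    )
    return PopulationSample(records=records, group_map=group_map, truth=truth)


def simulate_grouped_spectrum(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    counts: Mapping[str, Mapping[str, int]] | None = None,
) -> tuple[GroupedAlleleSpectrum, GroundTruth]:
    """Sample a grouped allele spectrum without realizing sequences.

    With ``counts`` given (e.g. a literal transcription of a published
    table) the spectrum replicates it exactly.
    """
    if counts is not None:
        nested = {g: dict(t) for g, t in counts.items()}
        return GroupedAlleleSpectrum.from_counts(nested), GroundTruth(spectrum=nested)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    nested = {}
    for g in config.groups:
        cts = _default_counts(config.n_alleles_per_group, config.sequences_per_group)
        nested[g] = {f"{g}.a{i + 1}": c for i, c in enumerate(cts)}
    return GroupedAlleleSpectrum.from_counts(nested), GroundTruth(spectrum=nested)


def make_two_block_array(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ZnfArrayAllele, GroundTruth]:
    """Array of two internally identical, mutually divergent repeat halves.

    The planted aa-identity gap is ``round(gap * 28) / 28``; the two-block
    score of the result equals it exactly.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    nhalf = config.block_repeats_per_half
    if nhalf < 2:
        raise ValueError("need at least 2 repeats per half")
    aa_len = len(TEMPLATE_AA)
    m = round(config.block_gap * aa_len)
    forbidden = set(SCAFFOLD_OFFSETS) | {FIXED_SERINE_OFFSET}
    safe_cols = [c for c in range(aa_len) if c not in forbidden]
    if m > len(safe_cols):
        raise ValueError(f"gap {config.block_gap} needs {m} substitutions; only {len(safe_cols)} safe columns")
    cols = sorted(rng.choice(safe_cols, size=m, replace=False).tolist())
    aa = list(TEMPLATE_AA)
    nt = TEMPLATE_NT
    for c in cols:
        choices = [r for r in _SAFE_RESIDUES if r != TEMPLATE_AA[c]]
        res = str(rng.choice(choices))
        aa[c] = res
        nt = _mutate_codon("".join(aa), nt, c, res)
    family_b = nt
    seq = TEMPLATE_NT * nhalf + family_b * nhalf
    allele = parse_allele("twoblock", seq, sample_id="sim", group="sim")
    truth = GroundTruth(block_gap=m / aa_len, block_split=nhalf)
    return allele, truth


def random_tree(
    n_taxa: int,
    rng: np.random.Generator,
    branch_length_range: tuple[float, float] = (0.05, 0.3),
    prefix: str = "t",
) -> PhyloTree:
    """Random bifurcating topology by sequential joining."""
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    lo, hi = branch_length_range

    def blen() -> float:
        return float(rng.uniform(lo, hi)) if hi > lo else float(lo)

    nodes = [TreeNode(f"{prefix}{i + 1}", blen()) for i in range(n_taxa)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False).tolist())
        merged = TreeNode(None, blen(), [nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    root = TreeNode(None, 0.0, nodes)
    return PhyloTree(root)


def simulate_codon_alignment(
    config: SimulationConfig,
    tree: PhyloTree | None = None,
    rng: np.random.Generator | None = None,
    freqs: CodonFrequencies | None = None,
) -> tuple[CodonAlignment, PhyloTree, GroundTruth]:
    """Evolve codons along a tree under a mixture-of-omega site model.

    Site classes are drawn from the configured mixture; each class evolves
    under the one-ratio codon process normalized by the mixture rate, so
    branch lengths mean expected substitutions per codon averaged over
    classes (matching the fitters).  Stop codons are excluded from the
    state space by construction.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if tree is None:
        tree = random_tree(config.n_taxa, rng, config.branch_length_range)
    freqs = freqs if freqs is not None else uniform_frequencies()
    props = np.asarray(config.proportions, dtype=float)
    omegas = np.asarray(config.omegas, dtype=float)
    if props.shape != omegas.shape:
        raise ValueError("proportions and omegas must align")

    comps = [rate_matrix(config.kappa, w, freqs, "goldmanwhelan") for w in omegas]
    scale = float(sum(p * r for p, (_, _, r) in zip(props, comps)))
    nsites = config.n_codon_sites
    site_class = rng.choice(len(omegas), size=nsites, p=props)

    taxa = sorted({leaf for leaf in tree.leaf_names})
    index = TreeIndex(tree, taxa)
    lengths = index.branch_lengths / scale
    # per-class cumulative transition matrices per branch
    cum = []
    for Q, pi, _ in comps:
        P = transition_matrices(Q, pi, lengths)
        P = P / P.sum(axis=2, keepdims=True)
        cum.append(np.cumsum(P, axis=2))

    pi = comps[0][1]
    states = np.empty((index.n_nodes, nsites), dtype=np.int64)
    root_states = rng.choice(len(pi), size=nsites, p=pi / pi.sum())
    states[index.root] = root_states
    # preorder: parents before children
    parent = np.full(index.n_nodes, -1)
    for i, kids in enumerate(index.children):
        for c in kids:
            parent[c] = i
    for node in range(index.n_nodes - 2, -1, -1):
        ps = states[parent[node]]
        u = rng.random(nsites)
        for k in range(len(omegas)):
            mask = site_class == k
            if not mask.any():
                continue
            rows = cum[k][node][ps[mask]]
            states[node, mask] = (u[mask][:, None] > rows).sum(axis=1)

    rows = np.vstack([states[i] for i in sorted(index.leaf_row, key=lambda n: index.leaf_row[n])])
    aln = CodonAlignment(taxa=taxa, codon_idx=rows)
    truth = GroundTruth(
        site_classes=site_class,
        params={
            "model": config.site_model,
            "kappa": config.kappa,
            "omegas": tuple(float(w) for w in omegas),
            "proportions": tuple(float(p) for p in props),
        },
    )
    return aln, tree, truth
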