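"""Universal-code codon machinery: state space, frequencies, rate matrices.

The state space is the 61 sense codons of the standard genetic code (stop
codons carry zero frequency and are excluded from the generator).  The rate
matrix is the one-ratio-per-class codon model: single-nucleotide changes
only, a transition/transversion ratio kappa, and a nonsynonymous factor
omega.  Two ways of bringing codon frequencies into the matrix are
supported:

* ``goldmanwhelan`` — the rate to codon j is proportional to the target
  codon's equilibrium frequency pi_j;
* ``musegaut`` — the rate is proportional to the frequency of the target
  *nucleotide* at the changed codon position; the stationary distribution
  is then the product-form codon frequency (F1x4/F3x4), so this style
  requires a product-form frequency model.

Both parameterizations are time-reversible with respect to their stationary
distributions, which the likelihood code exploits via a symmetric
eigendecomposition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

BASES = "TCAG"
NT_INDEX = {b: i for i, b in enumerate(BASES)}
STOP_CODONS = frozenset(_TABLE.stop_codons)

CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a, b, c in itertools.product(BASES, repeat=3)
    if a + b + c not in STOP_CODONS
)
N_CODONS = len(CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
GENETIC_CODE = dict(_TABLE.forward_table)
CODON_AA = np.array([GENETIC_CODE[c] for c in CODONS])

#: (61, 3) array of nucleotide indices per codon position.
CODON_NT_IDX = np.array([[NT_INDEX[b] for b in c] for c in CODONS], dtype=np.int64)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _build_pairs():
    I, J, POS, NTI, NTJ, TS, SYN = [], [], [], [], [], [], []
    for i in range(N_CODONS):
        for j in range(i + 1, N_CODONS):
            diffs = [p for p in range(3) if CODONS[i][p] != CODONS[j][p]]
            if len(diffs) != 1:
                continue
            p = diffs[0]
            I.append(i)
            J.append(j)
            POS.append(p)
            NTI.append(NT_INDEX[CODONS[i][p]])
            NTJ.append(NT_INDEX[CODONS[j][p]])
            TS.append((CODONS[i][p], CODONS[j][p]) in _TRANSITIONS)
            SYN.append(CODON_AA[i] == CODON_AA[j])
    return (
        np.array(I),
        np.array(J),
        np.array(POS),
        np.array(NTI),
        np.array(NTJ),
        np.array(TS),
        np.array(SYN),
    )


PAIR_I, PAIR_J, PAIR_POS, PAIR_NTI, PAIR_NTJ, PAIR_TS, PAIR_SYN = _build_pairs()

GOLDMAN_WHELAN = "goldmanwhelan"
MUSE_GAUT = "musegaut"
_STYLES = (GOLDMAN_WHELAN, MUSE_GAUT)

FREQ_MODELS = ("F1x4", "F3x4", "F61")
_FREQ_ALIASES = {"F60": "F61", "F61/F60": "F61"}


@dataclass(frozen=True)
class CodonFrequencies:
    """Equilibrium codon frequencies plus per-position nucleotide frequencies.

    ``pi`` sums to 1 over the 61 sense codons.  ``pos_nt`` is a (3, 4)
    matrix of nucleotide frequencies per codon position (rows identical for
    F1x4), used by the Muse–Gaut matrix parameterization.
    """

    model: str
    pi: np.ndarray
    pos_nt: np.ndarray

    def __post_init__(self):
        if not np.isclose(self.pi.sum(), 1.0):
            raise ValueError("codon frequencies must sum to 1 over sense codons")


def empirical_frequencies(codon_idx: np.ndarray, model: str = "F3x4", floor: float = 1e-8) -> CodonFrequencies:
    """Estimate codon frequencies from an alignment of codon indices.

    F1x4 pools nucleotide counts over all codon positions; F3x4 keeps them
    per position; F61 (alias F60) uses empirical sense-codon frequencies
    with a small floor so every codon keeps positive mass.
    """
    model = _FREQ_ALIASES.get(model, model)
    if model not in FREQ_MODELS:
        raise ValueError(f"unknown codon frequency model {model!r}")
    counts = np.bincount(np.asarray(codon_idx).ravel(), minlength=N_CODONS).astype(float)
    pos_counts = np.zeros((3, 4))
    for p in range(3):
        np.add.at(pos_counts[p], CODON_NT_IDX[:, p], counts)
    if model == "F1x4":
        tot = pos_counts.sum(axis=0)
        pos_nt = np.tile(tot / tot.sum(), (3, 1))
    else:
        pos_nt = pos_counts / pos_counts.sum(axis=1, keepdims=True)
    pos_nt = np.maximum(pos_nt, floor)
    pos_nt = pos_nt / pos_nt.sum(axis=1, keepdims=True)
    if model == "F61":
        pi = counts + floor * counts.sum() + 1e-300
        pi = pi / pi.sum()
    else:
        pi = product_form_pi(pos_nt)
    return CodonFrequencies(model=model, pi=pi, pos_nt=pos_nt)


def product_form_pi(pos_nt: np.ndarray) -> np.ndarray:
    """Sense-codon frequencies as normalized products of position frequencies."""
    pi = (
        pos_nt[0, CODON_NT_IDX[:, 0]]
        * pos_nt[1, CODON_NT_IDX[:, 1]]
        * pos_nt[2, CODON_NT_IDX[:, 2]]
    )
    return pi / pi.sum()


def uniform_frequencies() -> CodonFrequencies:
    """Uniform frequencies over the 61 sense codons (used by simulators)."""
    return CodonFrequencies(
        model="F61", pi=np.full(N_CODONS, 1.0 / N_CODONS), pos_nt=np.full((3, 4), 0.25)
    )


def stationary_pi(freqs: CodonFrequencies, style: str = GOLDMAN_WHELAN) -> np.ndarray:
    """Stationary distribution of the rate matrix for the chosen style."""
    if style == GOLDMAN_WHELAN:
        return freqs.pi
    if style == MUSE_GAUT:
        if freqs.model == "F61":
            raise ValueError("musegaut style requires a product-form frequency model (F1x4/F3x4)")
        return product_form_pi(freqs.pos_nt)
    raise ValueError(f"unknown style {style!r}; expected one of {_STYLES}")


def rate_matrix(
    kappa: float,
    omega: float,
    freqs: CodonFrequencies,
    style: str = GOLDMAN_WHELAN,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Build the (unscaled) 61x61 generator for one omega class.

    Returns ``(Q, pi, rate)`` where ``pi`` is the stationary distribution
    and ``rate`` the expected number of substitutions per unit time at
    stationarity (used for mixture-wide normalization).
    """
    pi = stationary_pi(freqs, style)
    fac = np.where(PAIR_TS, kappa, 1.0) * np.where(PAIR_SYN, 1.0, omega)
    if style == GOLDMAN_WHELAN:
        tgt_fwd = freqs.pi[PAIR_J]
        tgt_rev = freqs.pi[PAIR_I]
    else:
        tgt_fwd = freqs.pos_nt[PAIR_POS, PAIR_NTJ]
        tgt_rev = freqs.pos_nt[PAIR_POS, PAIR_NTI]
    Q = np.zeros((N_CODONS, N_CODONS))
    Q[PAIR_I, PAIR_J] = fac * tgt_fwd
    Q[PAIR_J, PAIR_I] = fac * tgt_rev
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = float(-(pi * np.diag(Q)).sum())
    return Q, pi, rate
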