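"""Self-comparison dot plots with windowed mismatch tolerance.

The tested artifact is the boolean matrix; PNG rendering is a thin optional
layer (requires matplotlib).  Windows are compared on the given strand only
(no reverse complement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .parser import ZnfArrayAllele, translate_repeats

START_ANCHORED = "start-anchored"
CENTERED = "centered"


@dataclass(frozen=True)
class DotplotParams:
    window: int = 83
    mismatch_limit: int = 5
    placement: str = START_ANCHORED

    def __post_init__(self):
        if self.placement not in (START_ANCHORED, CENTERED):
            raise ValueError(f"unknown placement {self.placement!r}")
        if not 0 <= self.mismatch_limit < self.window:
            raise ValueError(
                f"need 0 <= mismatch_limit < window, got limit {self.mismatch_limit}, window {self.window}"
            )


@dataclass
class DotplotMatrix:
    """Square boolean matrix over valid window positions.

    ``coordinate_offset`` maps matrix index i to sequence coordinate
    (i + offset): 0 for start-anchored placement, window // 2 for centered.
    """

    matrix: np.ndarray
    window: int
    mismatch_limit: int
    coordinate_offset: int

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def self_dotplot(seq: str, params: DotplotParams | None = None) -> DotplotMatrix:
    """Compare every window of ``seq`` against every other.

    Cell (i, j) is true iff the windows starting at i and j differ at no
    more than ``mismatch_limit`` positions.
    """
    params = params or DotplotParams()
    w = params.window
    if len(seq) < w:
        raise ValueError(f"sequence of length {len(seq)} shorter than window {w}")
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    n = len(arr) - w + 1
    neq = (arr[:, None] != arr[None, :]).astype(np.int32)
    mism = np.zeros((n, n), dtype=np.int32)
    for k in range(w):
        mism += neq[k : k + n, k : k + n]
    offset = w // 2 if params.placement == CENTERED else 0
    return DotplotMatrix(
        matrix=mism <= params.mismatch_limit,
        window=w,
        mismatch_limit=params.mismatch_limit,
        coordinate_offset=offset,
    )


def _aa_identity(a: str, b: str) -> float:
    if len(a) != len(b):
        raise ValueError("repeat translations of unequal length")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def _mean_pairwise(seqs: Sequence[str], other: Sequence[str] | None = None) -> float:
    if other is None:
        pairs = [(i, j) for i in range(len(seqs)) for j in range(i + 1, len(seqs))]
        return sum(_aa_identity(seqs[i], seqs[j]) for i, j in pairs) / len(pairs)
    return sum(_aa_identity(a, b) for a in seqs for b in other) / (len(seqs) * len(other))


def two_block_score(allele: ZnfArrayAllele | Sequence[str]) -> float:
    """Quantify two-block structure of an array at the repeat level.

    Score = mean within-half amino-acid repeat identity (averaged over the
    two halves) minus mean between-half identity.  Positive values indicate
    that repeats resemble their half-mates more than the other half; an odd
    middle repeat is assigned to the first half.  Requires >= 4 full repeats.
    """
    if isinstance(allele, ZnfArrayAllele):
        reps = allele.full_repeats
        if any(r.aa_seq is None for r in reps):
            reps = translate_repeats(reps)
        seqs = [r.aa_seq for r in reps]
    else:
        seqs = list(allele)
    k = len(seqs)
    if k < 4:
        raise ValueError(f"two_block_score undefined for fewer than 4 full repeats (got {k})")
    cut = math.ceil(k / 2)
    first, second = seqs[:cut], seqs[cut:]
    within = (_mean_pairwise(first) + _mean_pairwise(second)) / 2
    between = _mean_pairwise(first, second)
    return within - between


def render_dotplot(dp: DotplotMatrix, path: str, title: str = "") -> None:
    """Write a PNG of the matrix (optional layer; needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(dp.matrix, cmap="Greys", origin="lower", interpolation="nearest")
    ax.set_xlabel("window position")
    ax.set_ylabel("window position")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
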