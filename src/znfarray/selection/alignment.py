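"""In-frame codon alignments of repeat units."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ..parser import ZnfArrayAllele, ZnfRepeat
from .codon import CODON_INDEX, CODONS, STOP_CODONS


@dataclass
class CodonAlignment:
    """Matrix of in-frame codons: rows = taxa, columns = codon sites."""

    taxa: list[str]
    codon_idx: np.ndarray  # (n_taxa, n_sites) int indices into CODONS
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.codon_idx = np.asarray(self.codon_idx, dtype=np.int64)
        if self.codon_idx.ndim != 2 or self.codon_idx.shape[0] != len(self.taxa):
            raise ValueError("codon matrix shape does not match taxa")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.codon_idx.shape[1]

    def nt_sequence(self, row: int) -> str:
        return "".join(CODONS[i] for i in self.codon_idx[row])

    def nt_sequences(self) -> dict[str, str]:
        return {t: self.nt_sequence(i) for i, t in enumerate(self.taxa)}

    @classmethod
    def from_nt(cls, labels: Sequence[str], seqs: Sequence[str], excluded: Iterable[str] = ()) -> "CodonAlignment":
        """Build from equal-length, in-frame, stop-free nucleotide strings."""
        if len(labels) != len(seqs):
            raise ValueError("labels and sequences differ in number")
        if not seqs:
            raise ValueError("empty alignment")
        length = len(seqs[0])
        if length == 0 or length % 3 != 0:
            raise ValueError(f"alignment length {length} is not a positive codon multiple")
        rows = []
        for lab, s in zip(labels, seqs):
            s = s.upper()
            if len(s) != length:
                raise ValueError(f"ragged alignment: {lab} has length {len(s)}, expected {length}")
            codons = [s[i : i + 3] for i in range(0, length, 3)]
            for k, c in enumerate(codons):
                if c in STOP_CODONS:
                    raise ValueError(f"stop codon {c} at codon site {k} of {lab}")
                if c not in CODON_INDEX:
                    raise ValueError(f"unrecognized codon {c!r} at site {k} of {lab}")
            rows.append([CODON_INDEX[c] for c in codons])
        return cls(taxa=list(labels), codon_idx=np.array(rows), excluded=list(excluded))


def build_codon_alignment(
    source: Iterable[ZnfArrayAllele] | Iterable[ZnfRepeat],
    deduplicate: bool = True,
    label_prefix: str = "r",
) -> CodonAlignment:
    """Collect full repeats into a codon alignment, one row per repeat.

    Truncated leading repeats are excluded (and recorded under
    ``excluded``).  With ``deduplicate`` (default) one row is kept per
    distinct repeat nucleotide sequence, in first-encounter order.
    """
    repeats: list[ZnfRepeat] = []
    for item in source:
        if isinstance(item, ZnfArrayAllele):
            repeats.extend(item.repeats)
        else:
            repeats.append(item)
    excluded = [f"truncated@{r.index_in_array}" for r in repeats if r.is_truncated]
    full = [r for r in repeats if not r.is_truncated]
    if not full:
        raise ValueError("no full repeats to align")
    seqs: list[str] = []
    seen: set[str] = set()
    for r in full:
        s = r.nt_seq.upper()
        if deduplicate:
            if s in seen:
                continue
            seen.add(s)
        seqs.append(s)
    labels = [f"{label_prefix}{i + 1}" for i in range(len(seqs))]
    return CodonAlignment.from_nt(labels, seqs, excluded=excluded)
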