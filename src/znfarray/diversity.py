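"""Permutation tests of allelic diversity between and among groups.

Two statistics are implemented:

* two-group: the number of unique allele labels in the smaller group
  (fewer sequences; ties broken by first-listed group);
* multi-group: the sum of squared deviations from the mean of the per-group
  ratio (unique alleles / total sequences).

The permuted unit is the individual sequence's allele label.  One-tailed
p-values are the proportion of permutations with a statistic at least as
large as the observed one; the observed statistic is *not* added to the
numerator or denominator, so p = 0 is attainable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

TWO_GROUP = "two_group"
MULTI_GROUP = "multi_group"
_STATISTIC_KINDS = (TWO_GROUP, MULTI_GROUP)


@dataclass
class GroupedAlleleSpectrum:
    """Per-group lists of allele labels, one label per observed sequence.

    Labels are shared across groups iff the underlying allele is shared.
    """

    labels: dict[str, list[str]]

    def __post_init__(self):
        if not self.labels:
            raise ValueError("spectrum must contain at least one group")
        for g, labs in self.labels.items():
            if not labs:
                raise ValueError(f"group {g!r} is empty")

    @classmethod
    def from_counts(cls, counts: Mapping[str, Mapping[str, int]]) -> "GroupedAlleleSpectrum":
        """Build from nested ``{group: {allele_label: count}}`` mappings."""
        labels = {}
        for group, table in counts.items():
            expanded: list[str] = []
            for lab, c in table.items():
                if c < 1 or c != int(c):
                    raise ValueError(f"count for ({group!r}, {lab!r}) must be a positive integer, got {c}")
                expanded.extend([lab] * int(c))
            labels[group] = expanded
        return cls(labels=labels)

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.labels)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(v) for v in self.labels.values())

    @property
    def total(self) -> int:
        return sum(self.sizes)

    @property
    def unique_counts(self) -> tuple[int, ...]:
        return tuple(len(set(v)) for v in self.labels.values())

    def pooled(self, name: str, groups: Sequence[str]) -> "GroupedAlleleSpectrum":
        """Merge ``groups`` into a single group called ``name``."""
        merged: list[str] = []
        labels: dict[str, list[str]] = {}
        for g, labs in self.labels.items():
            if g in groups:
                merged.extend(labs)
            else:
                labels[g] = list(labs)
        out = {name: merged}
        out.update(labels)
        return GroupedAlleleSpectrum(labels=out)


@dataclass(frozen=True)
class PermutationResult:
    observed_statistic: float
    p_value: float
    n_permutations: int
    seed: int
    statistic_kind: str
    smaller_group: str | None = None


def _smaller_group_index(sizes: Sequence[int]) -> int:
    # tie -> first-listed group
    return int(np.argmin(sizes))


def unique_count_statistic_two_group(spectrum: GroupedAlleleSpectrum) -> int:
    """Number of unique allele labels in the smaller (by sequences) group."""
    if len(spectrum.groups) != 2:
        raise ValueError(f"two-group statistic requires exactly 2 groups, got {len(spectrum.groups)}")
    idx = _smaller_group_index(spectrum.sizes)
    return len(set(spectrum.labels[spectrum.groups[idx]]))


def dispersion_statistic_multi_group(spectrum: GroupedAlleleSpectrum) -> float:
    """Sum of squared deviations of per-group u/n ratios from their mean."""
    if len(spectrum.groups) < 2:
        raise ValueError("multi-group statistic requires at least 2 groups")
    ratios = np.array(spectrum.unique_counts, dtype=float) / np.array(spectrum.sizes, dtype=float)
    return float(np.sum((ratios - ratios.mean()) ** 2))


def _statistic(spectrum: GroupedAlleleSpectrum, kind: str) -> float:
    if kind == TWO_GROUP:
        return float(unique_count_statistic_two_group(spectrum))
    if kind == MULTI_GROUP:
        return dispersion_statistic_multi_group(spectrum)
    raise ValueError(f"unknown statistic kind {kind!r}; expected one of {_STATISTIC_KINDS}")


def _encode(spectrum: GroupedAlleleSpectrum) -> tuple[np.ndarray, np.ndarray]:
    pool = [lab for labs in spectrum.labels.values() for lab in labs]
    codes, _ = pd_factorize(pool)
    return codes, np.array(spectrum.sizes)


def pd_factorize(labels: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Map labels to small ints (stable first-encounter order)."""
    index: dict[str, int] = {}
    codes = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        codes[i] = index.setdefault(lab, len(index))
    return codes, list(index)


def _unique_counts_per_row(block: np.ndarray) -> np.ndarray:
    """Unique value count per row of a 2-D int array."""
    s = np.sort(block, axis=1)
    return (np.diff(s, axis=1) != 0).sum(axis=1) + 1


def permutation_test(
    spectrum: GroupedAlleleSpectrum,
    statistic_kind: str,
    n_permutations: int = 10_000,
    seed: int = 0,
    batch_size: int = 2_000,
) -> PermutationResult:
    """One-tailed Monte-Carlo permutation test of the requested statistic.

    Allele labels of individual sequences are shuffled across groups,
    preserving group sizes; the result is bit-identical for a fixed seed.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    observed = _statistic(spectrum, statistic_kind)
    codes, sizes = _encode(spectrum)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    rng = np.random.default_rng(seed)
    small = _smaller_group_index(sizes)

    n_tail = 0
    done = 0
    while done < n_permutations:
        b = min(batch_size, n_permutations - done)
        perms = rng.permuted(np.tile(codes, (b, 1)), axis=1)
        if statistic_kind == TWO_GROUP:
            block = perms[:, bounds[small] : bounds[small + 1]]
            stats = _unique_counts_per_row(block).astype(float)
        else:
            ratios = np.empty((b, len(sizes)))
            for gi in range(len(sizes)):
                block = perms[:, bounds[gi] : bounds[gi + 1]]
                ratios[:, gi] = _unique_counts_per_row(block) / sizes[gi]
            stats = ((ratios - ratios.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        n_tail += int(np.sum(stats >= observed - 1e-12))
        done += b

    return PermutationResult(
        observed_statistic=observed,
        p_value=n_tail / n_permutations,
        n_permutations=n_permutations,
        seed=seed,
        statistic_kind=statistic_kind,
        smaller_group=spectrum.groups[small] if statistic_kind == TWO_GROUP else None,
    )


def exhaustive_permutation_oracle(
    spectrum: GroupedAlleleSpectrum,
    statistic_kind: str,
    max_arrangements: int = 1_000_000,
) -> float:
    """Exact one-tailed p by complete enumeration of label permutations.

    Enumerates all ``total!`` orderings of the pooled labels (duplicates
    included, so every distinct group assignment is weighted correctly).
    Intended as a test oracle for small spectra.
    """
    total = spectrum.total
    n_arr = math.factorial(total)
    if n_arr > max_arrangements:
        raise ValueError(
            f"{n_arr} arrangements exceed bound {max_arrangements}; use permutation_test instead"
        )
    observed = _statistic(spectrum, statistic_kind)
    codes, sizes = _encode(spectrum)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    small = _smaller_group_index(sizes)

    n_tail = 0
    for perm in itertools.permutations(codes.tolist()):
        if statistic_kind == TWO_GROUP:
            stat = len(set(perm[bounds[small] : bounds[small + 1]]))
        else:
            ratios = [
                len(set(perm[bounds[gi] : bounds[gi + 1]])) / sizes[gi]
                for gi in range(len(sizes))
            ]
            mean = sum(ratios) / len(ratios)
            stat = sum((r - mean) ** 2 for r in ratios)
        if stat >= observed - 1e-12:
            n_tail += 1
    return n_tail / n_arr
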