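"""Collapse array sequences into unique alleles and report sharing.

Allele identity is exact full-length string equality (length variants are
distinct alleles); there is no alignment-based clustering.  Nucleotide
alleles whose translations coincide merge into one amino-acid allele.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field
from typing import Collection, Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .parser import InvalidRepeatError, ZnfArrayAllele


@dataclass(frozen=True)
class NtAlleleRow:
    allele_id: str
    sequence: str
    count: int
    groups: frozenset[str]
    samples: tuple[str, ...]


@dataclass
class NtAlleleTable:
    """Unique nucleotide alleles, ordered by descending count then sequence."""

    rows: list[NtAlleleRow]
    n_sequences: int

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def by_sequence(self) -> dict[str, NtAlleleRow]:
        return {r.sequence: r for r in self.rows}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "allele_id": [r.allele_id for r in self.rows],
                "count": [r.count for r in self.rows],
                "groups": [",".join(sorted(r.groups)) for r in self.rows],
                "samples": [",".join(r.samples) for r in self.rows],
                "sequence": [r.sequence for r in self.rows],
            }
        )


@dataclass(frozen=True)
class AaAlleleRow:
    allele_id: str
    sequence: str
    count: int
    nt_allele_ids: frozenset[str]
    groups: frozenset[str]


@dataclass
class AaAlleleTable:
    rows: list[AaAlleleRow]
    n_sequences: int

    def __len__(self) -> int:
        return len(self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "allele_id": [r.allele_id for r in self.rows],
                "count": [r.count for r in self.rows],
                "nt_alleles": [",".join(sorted(r.nt_allele_ids)) for r in self.rows],
                "groups": [",".join(sorted(r.groups)) for r in self.rows],
                "sequence": [r.sequence for r in self.rows],
            }
        )


def collapse_to_nt_alleles(
    sequences: Iterable,
    labels: Mapping[str, str] | None = None,
    id_prefix: str = "p",
) -> NtAlleleTable:
    """Collapse labeled sequences into unique nucleotide alleles.

    ``sequences`` is an iterable of objects with ``sequence``, ``sample_id``
    and ``group`` attributes (e.g. :class:`znfarray.io.LabeledSequence`).
    Output order is deterministic: descending count, then lexicographic
    sequence.  ``labels`` optionally maps default allele ids (``p1`` ...)
    to user-supplied published names.
    """
    buckets: dict[str, list] = {}
    n = 0
    for rec in sequences:
        n += 1
        buckets.setdefault(rec.sequence.upper(), []).append(rec)
    ordered = sorted(buckets.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    rows = []
    for i, (seq, members) in enumerate(ordered, start=1):
        default_id = f"{id_prefix}{i}"
        rows.append(
            NtAlleleRow(
                allele_id=(labels or {}).get(default_id, default_id),
                sequence=seq,
                count=len(members),
                groups=frozenset(m.group for m in members),
                samples=tuple(sorted(m.sample_id for m in members)),
            )
        )
    return NtAlleleTable(rows=rows, n_sequences=n)


def _translate_full(nt: str) -> str:
    aa = str(Seq(nt).translate())
    if "*" in aa:
        raise InvalidRepeatError(f"in-frame stop codon at residue {aa.index('*')}")
    return aa


def collapse_to_aa_alleles(nt_table: NtAlleleTable, id_prefix: str = "P") -> AaAlleleTable:
    """Merge nucleotide alleles with identical translations.

    Counts are summed over the merged nucleotide alleles; translation
    failures propagate as :class:`~znfarray.parser.InvalidRepeatError`.
    """
    buckets: dict[str, list[NtAlleleRow]] = {}
    for row in nt_table.rows:
        buckets.setdefault(_translate_full(row.sequence), []).append(row)
    ordered = sorted(
        buckets.items(), key=lambda kv: (-sum(r.count for r in kv[1]), kv[0])
    )
    rows = []
    for i, (aa, members) in enumerate(ordered, start=1):
        rows.append(
            AaAlleleRow(
                allele_id=f"{id_prefix}{i}",
                sequence=aa,
                count=sum(r.count for r in members),
                nt_allele_ids=frozenset(r.allele_id for r in members),
                groups=frozenset(g for r in members for g in r.groups),
            )
        )
    return AaAlleleTable(rows=rows, n_sequences=nt_table.n_sequences)


@dataclass
class RepeatLetterEncoding:
    """Letter codes for repeats: same base letter iff identical aa sequence.

    A trailing ``*`` (doubled for further variants) marks a synonymous
    nucleotide variant of the same letter.
    """

    symbols: dict[str, list[str]]
    letter_to_aa: dict[str, str]
    symbol_to_nt: dict[str, str]

    def encoded(self, allele_id: str) -> str:
        return "".join(self.symbols[allele_id])


def _letter_stream():
    for letter in string.ascii_uppercase:
        yield letter
    for a, b in itertools.product(string.ascii_uppercase, repeat=2):
        yield a + b


def assign_repeat_letters(alleles: Sequence[ZnfArrayAllele]) -> RepeatLetterEncoding:
    """Assign letter codes to repeats in first-encounter order.

    Alleles are visited in sorted ``allele_id`` order so the encoding is
    reproducible run-to-run; truncated leading repeats carry no symbol.
    """
    letters = _letter_stream()
    aa_to_letter: dict[str, str] = {}
    nt_variants: dict[str, dict[str, str]] = {}
    symbols: dict[str, list[str]] = {}
    for allele in sorted(alleles, key=lambda a: a.allele_id):
        out: list[str] = []
        for rep in allele.full_repeats:
            if rep.aa_seq is None:
                raise ValueError(f"repeat {rep.index_in_array} of {allele.allele_id} not translated")
            letter = aa_to_letter.get(rep.aa_seq)
            if letter is None:
                letter = next(letters)
                aa_to_letter[rep.aa_seq] = letter
                nt_variants[letter] = {}
            variants = nt_variants[letter]
            if rep.nt_seq not in variants:
                variants[rep.nt_seq] = letter + "*" * len(variants)
            out.append(variants[rep.nt_seq])
        symbols[allele.allele_id] = out
    return RepeatLetterEncoding(
        symbols=symbols,
        letter_to_aa={v: k for k, v in aa_to_letter.items()},
        symbol_to_nt={sym: nt for variants in nt_variants.values() for nt, sym in variants.items()},
    )


@dataclass
class PolymorphicSiteReport:
    columns: list[int]
    contact_columns: list[int]
    contact_fraction: float | None

    @property
    def n_sites(self) -> int:
        return len(self.columns)


def find_polymorphic_sites(
    aligned: Sequence[str],
    contact_offsets: Collection[int] | None = None,
) -> PolymorphicSiteReport:
    """List columns with more than one state in an ungapped alignment.

    ``aligned`` is a list of equal-length strings (nt or aa); truncated
    leading repeats must be excluded by the caller.  If ``contact_offsets``
    is given, the fraction of polymorphic columns falling at those offsets
    is reported.
    """
    if not aligned:
        return PolymorphicSiteReport([], [], None)
    length = len(aligned[0])
    for s in aligned:
        if len(s) != length:
            raise ValueError(f"ragged alignment: lengths {length} vs {len(s)}")
    columns = [i for i in range(length) if len({s[i] for s in aligned}) > 1]
    if contact_offsets is None:
        return PolymorphicSiteReport(columns, [], None)
    contact = sorted(set(contact_offsets))
    hits = [c for c in columns if c in contact]
    fraction = len(hits) / len(columns) if columns else None
    return PolymorphicSiteReport(columns, hits, fraction)


@dataclass
class SharingReport:
    """Alleles present in more than one group, with their group sets."""

    nt_shared: dict[str, tuple[str, ...]]
    aa_shared: dict[str, tuple[str, ...]]

    @property
    def any_shared(self) -> bool:
        return bool(self.nt_shared or self.aa_shared)


def cross_group_sharing(nt_table: NtAlleleTable, aa_table: AaAlleleTable | None = None) -> SharingReport:
    """Report nt and aa alleles observed in more than one group."""
    nt_shared = {
        r.allele_id: tuple(sorted(r.groups)) for r in nt_table.rows if len(r.groups) > 1
    }
    aa_shared = {}
    if aa_table is not None:
        aa_shared = {
            r.allele_id: tuple(sorted(r.groups)) for r in aa_table.rows if len(r.groups) > 1
        }
    return SharingReport(nt_shared=nt_shared, aa_shared=aa_shared)


def shared_labels(labels_by_group: Mapping[str, Iterable[str]]) -> dict[str, tuple[str, ...]]:
    """Sharing report for pre-tabulated spectra: label -> sorted group tuple.

    Labels are shared across groups iff the underlying allele is shared, so
    this operates directly on a grouped allele spectrum.
    """
    where: dict[str, set[str]] = {}
    for group, labels in labels_by_group.items():
        for lab in labels:
            where.setdefault(lab, set()).add(group)
    return {lab: tuple(sorted(gs)) for lab, gs in sorted(where.items()) if len(gs) > 1}
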