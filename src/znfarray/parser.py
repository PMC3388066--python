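"""Decomposition and validation of tandem C2H2 zinc-finger array sequences.

A zinc-finger (ZnF) array allele is a single phased nucleotide sequence made
of tandem repeat units (84 nt / 28 aa by default).  The array may carry a
truncated leading repeat that lacks the first zinc-coordinating cysteine; it
is flagged and excluded from the "full repeat" count used downstream.

The DNA-contact residues of each finger (helix positions -1, 2, 3 and 6) are
located relative to the first zinc-coordinating histidine of the C2H2
scaffold.  All coordinates in this module are 0-based; the -1/2/3/6 labels
are presentation-layer names only.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

DEFAULT_REPEAT_LENGTH = 84

#: Residues that may legally appear in a nucleotide array sequence.
VALID_BASES = frozenset("ACGT")

#: IUPAC ambiguity codes; arrays containing these are rejected for
#: cataloguing because allele identity is exact string equality.
IUPAC_AMBIGUITY = frozenset("RYSWKMBDHVN")

#: C2H2 scaffold of a full repeat: two zinc-coordinating cysteines followed
#: by two histidines.  Group starts give the residue offsets.
DEFAULT_SCAFFOLD_PATTERN = r"(C).{2,4}(C).{10,14}(H).{2,5}(H)"

#: Scaffold of a truncated leading repeat, which lacks the first cysteine.
TRUNCATED_SCAFFOLD_PATTERN = r"(C).{10,14}(H).{2,5}(H)"

#: Helix-position offsets of the DNA-contact residues, relative to the first
#: zinc-coordinating histidine (helix position +7 convention).
DEFAULT_HELIX_OFFSETS: Mapping[str, int] = {
    "pos_minus1": -7,
    "pos2": -5,
    "pos3": -4,
    "pos6": -1,
}


class MalformedArrayError(ValueError):
    """Array length is not decomposable into repeat units.

    ``remainder`` carries the leftover length (mod repeat length).
    """

    def __init__(self, message: str, remainder: int | None = None):
        super().__init__(message)
        self.remainder = remainder


class InvalidRepeatError(ValueError):
    """A repeat unit violates a hard precondition (frame, stop codon)."""

    def __init__(self, message: str, repeat_index: int | None = None):
        super().__init__(message)
        self.repeat_index = repeat_index


class ScaffoldNotFoundError(ValueError):
    """The C2H2 pattern could not be located in a repeat translation."""


class ContactOffsetError(ValueError):
    """A computed contact-residue offset falls outside the repeat."""


@dataclass
class ZnfRepeat:
    """One repeat unit of a ZnF array.

    Full repeats are exactly ``repeat_length`` nt (84 by default) and
    translate to 28 residues; the truncated leading repeat is shorter.
    """

    index_in_array: int
    nt_seq: str
    aa_seq: str | None = None
    is_truncated: bool = False

    def __len__(self) -> int:
        return len(self.nt_seq)


@dataclass
class ZnfArrayAllele:
    """An ordered array of repeats forming one phased allele."""

    allele_id: str
    sample_id: str
    group: str
    repeats: list[ZnfRepeat]
    leading_truncated_present: bool = False

    @property
    def full_repeats(self) -> list[ZnfRepeat]:
        return [r for r in self.repeats if not r.is_truncated]

    @property
    def sequence(self) -> str:
        """Concatenation of repeat sequences; round-trips to the input."""
        return "".join(r.nt_seq for r in self.repeats)

    @property
    def n_full_repeats(self) -> int:
        return len(self.full_repeats)


@dataclass(frozen=True)
class ScaffoldPositions:
    """0-based offsets of the zinc-coordinating residues within a repeat.

    ``cys1`` is ``None`` for the truncated leading repeat.
    """

    cys1: int | None
    cys2: int
    his1: int
    his2: int

    def __post_init__(self):
        offsets = [o for o in (self.cys1, self.cys2, self.his1, self.his2) if o is not None]
        if sorted(offsets) != offsets or len(set(offsets)) != len(offsets):
            raise ValueError(f"scaffold offsets not strictly increasing: {self}")


@dataclass(frozen=True)
class ContactResidues:
    """Residues at helix positions -1, 2, 3 and 6 of one finger."""

    pos_minus1: str
    pos2: str
    pos3: str
    pos6: str

    @property
    def triplet(self) -> tuple[str, str, str]:
        """The (-1, 3, 6) combination used for colour coding."""
        return (self.pos_minus1, self.pos3, self.pos6)


@dataclass(frozen=True)
class ValidationIssue:
    repeat_index: int | None
    kind: str
    detail: str


@dataclass
class ValidationReport:
    allele_id: str
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    @property
    def usable_for_catalog(self) -> bool:
        """Alleles with ambiguity codes or hard defects are excluded."""
        return self.ok


def split_into_repeats(
    array_nt: str,
    repeat_length: int = DEFAULT_REPEAT_LENGTH,
    leading_truncated: bool = False,
) -> list[ZnfRepeat]:
    """Split an array sequence into ordered repeat units.

    If ``leading_truncated`` is set, the remainder of the sequence length
    modulo ``repeat_length`` is taken from the 5' end as the truncated
    leading repeat; otherwise the length must be an exact positive multiple
    of ``repeat_length``.

    Raises
    ------
    MalformedArrayError
        If the (post-leading-segment) length is not a positive multiple of
        ``repeat_length``; the remainder length is attached to the error.
    """
    if repeat_length <= 0:
        raise ValueError("repeat_length must be positive")
    seq = array_nt.upper()
    remainder = len(seq) % repeat_length
    lead: str | None = None
    if leading_truncated:
        if remainder == 0:
            raise MalformedArrayError(
                "leading_truncated declared but sequence length is an exact "
                f"multiple of {repeat_length}; truncated segment is ambiguous",
                remainder=0,
            )
        lead, seq = seq[:remainder], seq[remainder:]
    elif remainder != 0:
        raise MalformedArrayError(
            f"array length {len(seq)} is not a multiple of {repeat_length} "
            f"(remainder {remainder})",
            remainder=remainder,
        )
    if not seq:
        raise MalformedArrayError("array contains no full repeats", remainder=remainder)

    repeats: list[ZnfRepeat] = []
    if lead is not None:
        repeats.append(ZnfRepeat(0, lead, is_truncated=True))
    base = len(repeats)
    for k in range(len(seq) // repeat_length):
        repeats.append(ZnfRepeat(base + k, seq[k * repeat_length : (k + 1) * repeat_length]))
    return repeats


def translate_repeats(repeats: Iterable[ZnfRepeat]) -> list[ZnfRepeat]:
    """Fill ``aa_seq`` on each repeat using the standard genetic code.

    Raises
    ------
    InvalidRepeatError
        For out-of-frame repeats or in-frame stop codons; the error names
        the offending repeat index.
    """
    out: list[ZnfRepeat] = []
    for rep in repeats:
        if len(rep.nt_seq) % 3 != 0:
            raise InvalidRepeatError(
                f"repeat {rep.index_in_array}: length {len(rep.nt_seq)} not a codon multiple",
                repeat_index=rep.index_in_array,
            )
        aa = str(Seq(rep.nt_seq).translate())
        if "*" in aa:
            raise InvalidRepeatError(
                f"repeat {rep.index_in_array}: in-frame stop codon at residue {aa.index('*')}",
                repeat_index=rep.index_in_array,
            )
        out.append(dataclasses.replace(rep, aa_seq=aa))
    return out


def locate_scaffold(
    repeat_aa: str,
    pattern: str | None = None,
    truncated: bool = False,
) -> ScaffoldPositions:
    """Locate the two cysteines and two histidines of the C2H2 scaffold.

    For truncated repeats (first cysteine absent) the truncated pattern is
    used and ``cys1`` is reported as ``None``.
    """
    if not repeat_aa:
        raise ScaffoldNotFoundError("empty repeat translation")
    if pattern is None:
        pattern = TRUNCATED_SCAFFOLD_PATTERN if truncated else DEFAULT_SCAFFOLD_PATTERN
    m = re.search(pattern, repeat_aa)
    if m is None:
        raise ScaffoldNotFoundError(
            f"C2H2 scaffold pattern {pattern!r} not found in {repeat_aa!r}"
        )
    starts = [m.start(g) for g in range(1, (m.re.groups or 0) + 1)]
    if len(starts) == 4:
        return ScaffoldPositions(*starts)
    if len(starts) == 3:
        return ScaffoldPositions(None, *starts)
    raise ScaffoldNotFoundError(f"pattern {pattern!r} must capture 3 or 4 residues")


def extract_contact_residues(
    repeat_aa: str,
    scaffold: ScaffoldPositions,
    helix_offsets: Mapping[str, int] | None = None,
) -> ContactResidues:
    """Extract the DNA-contact residues at helix positions -1, 2, 3, 6.

    Offsets are computed from the first zinc-coordinating histidine using
    ``helix_offsets`` (defaults to :data:`DEFAULT_HELIX_OFFSETS`).
    """
    offsets = dict(DEFAULT_HELIX_OFFSETS if helix_offsets is None else helix_offsets)
    residues: dict[str, str] = {}
    for name, off in offsets.items():
        p = scaffold.his1 + off
        if not 0 <= p < len(repeat_aa):
            raise ContactOffsetError(
                f"contact offset {name} = his1{off:+d} = {p} outside repeat of length {len(repeat_aa)}"
            )
        residues[name] = repeat_aa[p]
    return ContactResidues(**residues)


def contact_offsets(scaffold: ScaffoldPositions, helix_offsets: Mapping[str, int] | None = None) -> dict[str, int]:
    """Absolute 0-based offsets of the contact residues within a repeat."""
    offsets = dict(DEFAULT_HELIX_OFFSETS if helix_offsets is None else helix_offsets)
    return {name: scaffold.his1 + off for name, off in offsets.items()}


def validate_array(
    allele: ZnfArrayAllele,
    repeat_length: int = DEFAULT_REPEAT_LENGTH,
    scaffold_pattern: str | None = None,
) -> ValidationReport:
    """Report per-repeat scaffold, stop-codon, length and ambiguity issues.

    Never raises: every problem becomes a :class:`ValidationIssue`.  Alleles
    with a non-empty issue list are rejected for downstream cataloguing
    (heterozygotes were clone-resolved upstream, so ambiguity codes signal
    an unresolved sequence).
    """
    report = ValidationReport(allele_id=allele.allele_id)
    seen = set(allele.sequence)
    bad = seen - VALID_BASES
    if bad:
        kinds = sorted(bad & IUPAC_AMBIGUITY)
        other = sorted(bad - IUPAC_AMBIGUITY)
        if kinds:
            report.issues.append(
                ValidationIssue(None, "ambiguity", f"IUPAC ambiguity codes present: {','.join(kinds)}")
            )
        if other:
            report.issues.append(
                ValidationIssue(None, "invalid_character", f"non-nucleotide characters: {','.join(other)}")
            )
        return report

    for rep in allele.repeats:
        if not rep.is_truncated and len(rep.nt_seq) != repeat_length:
            report.issues.append(
                ValidationIssue(rep.index_in_array, "length", f"full repeat of {len(rep.nt_seq)} nt, expected {repeat_length}")
            )
            continue
        try:
            (translated,) = translate_repeats([rep])
        except InvalidRepeatError as exc:
            report.issues.append(ValidationIssue(rep.index_in_array, "stop_codon", str(exc)))
            continue
        try:
            locate_scaffold(translated.aa_seq, pattern=scaffold_pattern, truncated=rep.is_truncated)
        except ScaffoldNotFoundError as exc:
            report.issues.append(ValidationIssue(rep.index_in_array, "scaffold", str(exc)))
    return report


def parse_allele(
    allele_id: str,
    array_nt: str,
    sample_id: str = "",
    group: str = "",
    repeat_length: int = DEFAULT_REPEAT_LENGTH,
    leading_truncated: bool = False,
    translate: bool = True,
) -> ZnfArrayAllele:
    """Split, (optionally) translate and wrap one array sequence."""
    repeats = split_into_repeats(array_nt, repeat_length, leading_truncated)
    if translate:
        repeats = translate_repeats(repeats)
    return ZnfArrayAllele(
        allele_id=allele_id,
        sample_id=sample_id,
        group=group,
        repeats=repeats,
        leading_truncated_present=leading_truncated,
    )


def repeat_table_rows(allele: ZnfArrayAllele, helix_offsets: Mapping[str, int] | None = None) -> list[dict]:
    """Flatten an allele into per-repeat records for TSV output."""
    rows = []
    for rep in allele.repeats:
        contacts = ("", "", "", "")
        if rep.aa_seq and not rep.is_truncated:
            try:
                scaffold = locate_scaffold(rep.aa_seq)
                cr = extract_contact_residues(rep.aa_seq, scaffold, helix_offsets)
                contacts = (cr.pos_minus1, cr.pos2, cr.pos3, cr.pos6)
            except (ScaffoldNotFoundError, ContactOffsetError):
                pass
        rows.append(
            {
                "allele_id": allele.allele_id,
                "repeat_index": rep.index_in_array,
                "is_truncated": int(rep.is_truncated),
                "nt_seq": rep.nt_seq,
                "aa_seq": rep.aa_seq or "",
                "pos_minus1": contacts[0],
                "pos2": contacts[1],
                "pos3": contacts[2],
                "pos6": contacts[3],
            }
        )
    return rows
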