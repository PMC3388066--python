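"""Readers and writers for the pipeline's standard formats.

TSV (tab-delimited, UTF-8, header row) is the canonical tabular format;
JSON is used for ground truth and run logs.  Sequences are uppercased and
U is normalized to T on input.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .diversity import GroupedAlleleSpectrum


class InputFormatError(ValueError):
    """Malformed or inconsistent input file."""


class MissingGroupError(InputFormatError):
    """A FASTA record has no row in the group-mapping table."""


class DuplicateRecordError(InputFormatError):
    pass


class EmptyInputError(InputFormatError):
    pass


@dataclass(frozen=True)
class LabeledSequence:
    """One phased allele sequence with its sample and group labels."""

    seq_id: str
    sample_id: str
    group: str
    sequence: str


def read_group_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV ``sample_id<TAB>group`` (optional header)."""
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t")):
            if not row or (i == 0 and row[0].lower() in ("sample", "sample_id")):
                continue
            if len(row) < 2:
                raise InputFormatError(f"group map line {i + 1}: expected 2 columns, got {len(row)}")
            if row[0] in out and out[row[0]] != row[1]:
                raise InputFormatError(f"conflicting group rows for sample {row[0]!r}")
            out[row[0]] = row[1]
    if not out:
        raise EmptyInputError(f"group map {path} is empty")
    return out


def read_grouped_fasta(
    fasta_path: str | Path,
    groups_path: str | Path,
    id_delimiter: str = ".",
) -> list[LabeledSequence]:
    """Read phased allele FASTA plus the sample->group mapping.

    Record IDs carry sample and allele labels as ``sampleID<delim>index``;
    every sample must have a group row.  Sequences are uppercased and U is
    normalized to T.
    """
    group_of = read_group_map(groups_path)
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise EmptyInputError(f"FASTA {fasta_path} contains no records")
    seen: set[str] = set()
    out: list[LabeledSequence] = []
    for rec in records:
        if rec.id in seen:
            raise DuplicateRecordError(f"duplicate record ID {rec.id!r}")
        seen.add(rec.id)
        sample = rec.id.rsplit(id_delimiter, 1)[0] if id_delimiter in rec.id else rec.id
        if sample not in group_of:
            raise MissingGroupError(f"record {rec.id!r}: sample {sample!r} has no group mapping")
        seq = str(rec.seq).upper().replace("U", "T")
        out.append(LabeledSequence(rec.id, sample, group_of[sample], seq))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as FASTA."""
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_spectrum_table(path: str | Path) -> GroupedAlleleSpectrum:
    """Three-column TSV ``group<TAB>allele<TAB>count`` into a spectrum.

    Counts must be positive integers; duplicate (group, allele) rows and
    empty files are errors.  Per-sequence labels are expanded so the result
    feeds the permutation tests directly.
    """
    counts: dict[str, dict[str, int]] = {}
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r]
    if not rows:
        raise EmptyInputError(f"spectrum table {path} is empty")
    if rows and rows[0][0].lower() == "group":
        rows = rows[1:]
    if not rows:
        raise EmptyInputError(f"spectrum table {path} has a header but no data")
    for i, row in enumerate(rows):
        if len(row) != 3:
            raise InputFormatError(f"spectrum line {i + 1}: expected 3 columns, got {len(row)}")
        group, allele, count_s = row
        try:
            count = int(count_s)
        except ValueError as exc:
            raise InputFormatError(f"spectrum line {i + 1}: count {count_s!r} is not an integer") from exc
        if count < 1:
            raise InputFormatError(f"spectrum line {i + 1}: count must be >= 1, got {count}")
        table = counts.setdefault(group, {})
        if allele in table:
            raise InputFormatError(f"duplicate spectrum row for ({group!r}, {allele!r})")
        table[allele] = count
    return GroupedAlleleSpectrum.from_counts(counts)


def write_spectrum_table(spectrum: GroupedAlleleSpectrum, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["group", "allele", "count"])
        for group, labels in spectrum.labels.items():
            seen: dict[str, int] = {}
            for lab in labels:
                seen[lab] = seen.get(lab, 0) + 1
            for lab, c in seen.items():
                w.writerow([group, lab, c])


def write_tsv(rows: Sequence[Mapping], path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write a list of dict rows as a TSV with a header."""
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(columns)
        for row in rows:
            w.writerow([row.get(c, "") for c in columns])


def write_matrix_tsv(matrix: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(matrix, dtype=int), fmt="%d", delimiter="\t")


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, frozenset, tuple)):
            return sorted(o) if isinstance(o, (set, frozenset)) else list(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
        fh.write("\n")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (see ``run_pipeline``)."""

    fasta: str | None = None
    groups: str | None = None
    spectrum: str | None = None
    outdir: str = "znf_out"
    stages: tuple[str, ...] = ("parse", "catalog", "divtest", "dotplot")
    id_delimiter: str = "."
    repeat_length: int = 84
    leading_truncated: bool = False
    window: int = 83
    mismatch_limit: int = 5
    n_permutations: int = 10_000
    seed: int = 0
    models: tuple[str, ...] = ("M0", "M1a", "M2a", "M3", "M7", "M8")
    codon_freq_model: str = "F3x4"
    freq_incorporation: str = "musegaut"
    n_restarts: int = 3
    correction: str = "holm"

    def __post_init__(self):
        known = {"parse", "catalog", "divtest", "dotplot", "selection"}
        bad = set(self.stages) - known
        if bad:
            raise ValueError(f"unknown pipeline stages: {sorted(bad)}")
        if self.repeat_length <= 0 or self.window <= 0:
            raise ValueError("repeat_length and window must be positive")
        if not 0 <= self.mismatch_limit < self.window:
            raise ValueError("need 0 <= mismatch_limit < window")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("stages", "models"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)
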