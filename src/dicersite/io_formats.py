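"""Readers and writers for the on-disk artifacts of the pipeline.

Formats handled: FASTA hairpin sequences (via Biopython), Vienna-style
dot-bracket structure files (two-line-per-record, or a two-column TSV),
mature-arm annotation TSVs (1-based inclusive coordinates, the miRBase
convention) and the flat CSV schema used for labeled pattern datasets.
DNA input is silently normalized to the RNA alphabet (T -> U, uppercase):
miRBase distributes some files in DNA alphabet.

The package consumes secondary structures; it never predicts them.  Use
RNAfold (or any pseudoknot-free predictor) to produce structures for real
hairpins.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "StructureRecord",
    "MatureAnnotation",
    "ValidationError",
    "read_fasta",
    "write_fasta",
    "read_structures",
    "write_structures",
    "read_mature_annotation",
    "write_mature_annotation",
    "read_pattern_dataset",
    "write_pattern_dataset",
]

RNA_ALPHABET = frozenset("ACGU")
STRUCT_ALPHABET = frozenset("().")

#: Column schema of the pattern-dataset CSV, in order.
DATASET_COLUMNS = [
    "pattern_id",
    "premirna_id",
    "window_start",
    "pattern_seq",
    "pattern_struct",
    "premirna_seq",
    "premirna_struct",
    "label",
    "fold",
]


class ValidationError(ValueError):
    """Raised when an input file violates a format invariant."""


@dataclasses.dataclass(frozen=True)
class SequenceRecord:
    """A hairpin sequence over the RNA alphabet {A, C, G, U}."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValidationError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValidationError(
                f"record {self.id!r}: characters outside RNA alphabet: {sorted(bad)}"
            )


@dataclasses.dataclass(frozen=True)
class StructureRecord:
    """A pseudoknot-free dot-bracket secondary structure."""

    id: str
    structure: str

    def __post_init__(self):
        bad = set(self.structure) - STRUCT_ALPHABET
        if bad:
            raise ValidationError(
                f"structure {self.id!r}: invalid characters {sorted(bad)}"
            )
        depth = 0
        for ch in self.structure:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
            if depth < 0:
                raise ValidationError(f"structure {self.id!r}: unbalanced brackets")
        if depth != 0:
            raise ValidationError(f"structure {self.id!r}: unbalanced brackets")


@dataclasses.dataclass(frozen=True)
class MatureAnnotation:
    """One mature-miRNA arm on a hairpin, 1-based inclusive coordinates."""

    premirna_id: str
    arm: str  # "5p" or "3p"
    start: int
    end: int

    def __post_init__(self):
        if self.arm not in ("5p", "3p"):
            raise ValidationError(
                f"annotation {self.premirna_id!r}: arm must be 5p or 3p, got {self.arm!r}"
            )
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"annotation {self.premirna_id!r}/{self.arm}: "
                f"require 1 <= start <= end, got ({self.start}, {self.end})"
            )


def _normalize_sequence(seq: str) -> str:
    return seq.upper().replace("T", "U")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read hairpin sequences, normalizing to uppercase RNA (T -> U)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(rec.id, _normalize_sequence(str(rec.seq))))
    if not records:
        # SeqIO silently yields nothing for files without a valid header
        with open(path) as fh:
            first = fh.readline()
        if not first.startswith(">"):
            raise ValidationError(f"{path}: not a FASTA file (first line {first!r})")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_structures(path: str | Path,
                    sequences: list[SequenceRecord] | None = None
                    ) -> list[StructureRecord]:
    """Read dot-bracket structures.

    Accepts the Vienna two-/three-line layout (">id", optional sequence
    line, structure line) or a headerless two-column TSV (id, structure).
    If ``sequences`` is given, each structure's length is validated against
    the same-id sequence.
    """
    path = Path(path)
    text = path.read_text()
    records: list[StructureRecord] = []
    if text.lstrip().startswith(">"):
        lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
        i = 0
        while i < len(lines):
            if not lines[i].startswith(">"):
                raise ValidationError(f"{path}: expected '>' header at line {i + 1}")
            rid = lines[i][1:].split()[0]
            body = []
            i += 1
            while i < len(lines) and not lines[i].startswith(">"):
                body.append(lines[i].split()[0])  # RNAfold appends energies
                i += 1
            struct_lines = [b for b in body if set(b) <= STRUCT_ALPHABET]
            if not struct_lines:
                raise ValidationError(f"{path}: record {rid!r} has no structure line")
            records.append(StructureRecord(rid, struct_lines[-1]))
    else:
        for ln_no, ln in enumerate(text.splitlines(), 1):
            if not ln.strip():
                continue
            parts = ln.split("\t")
            if len(parts) != 2:
                raise ValidationError(f"{path}:{ln_no}: expected two tab-separated columns")
            records.append(StructureRecord(parts[0], parts[1]))
    if sequences is not None:
        seq_len = {r.id: len(r.sequence) for r in sequences}
        for rec in records:
            if rec.id in seq_len and seq_len[rec.id] != len(rec.structure):
                raise ValidationError(
                    f"structure {rec.id!r}: length {len(rec.structure)} does not "
                    f"match sequence length {seq_len[rec.id]}"
                )
    return records


def write_structures(records: Iterable[StructureRecord], path: str | Path,
                     sequences: dict[str, str] | None = None) -> None:
    """Write Vienna-style structure records (sequence line if available)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            if sequences and rec.id in sequences:
                fh.write(sequences[rec.id] + "\n")
            fh.write(rec.structure + "\n")


def read_mature_annotation(path: str | Path,
                           hairpin_ids: Iterable[str] | None = None
                           ) -> list[MatureAnnotation]:
    """Read the mature-arm TSV (columns premirna_id, arm, start, end).

    Every hairpin id present must carry exactly one 5p and one 3p row.
    If ``hairpin_ids`` is given, those ids must all be annotated.
    """
    df = pd.read_csv(path, sep="\t", dtype={"premirna_id": str, "arm": str})
    required = {"premirna_id", "arm", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    annotations = [
        MatureAnnotation(row.premirna_id, row.arm, int(row.start), int(row.end))
        for row in df.itertuples(index=False)
    ]
    by_id: dict[str, set[str]] = {}
    for ann in annotations:
        arms = by_id.setdefault(ann.premirna_id, set())
        if ann.arm in arms:
            raise ValidationError(f"duplicate {ann.arm} annotation for {ann.premirna_id!r}")
        arms.add(ann.arm)
    incomplete = sorted(i for i, arms in by_id.items() if arms != {"5p", "3p"})
    if hairpin_ids is not None:
        incomplete = sorted(set(incomplete) | (set(hairpin_ids) - set(by_id)))
    if incomplete:
        raise ValidationError("incomplete annotation: " + ", ".join(incomplete))
    return annotations


def write_mature_annotation(annotations: Iterable[MatureAnnotation],
                            path: str | Path) -> None:
    df = pd.DataFrame(
        [(a.premirna_id, a.arm, a.start, a.end) for a in annotations],
        columns=["premirna_id", "arm", "start", "end"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_pattern_dataset(dataset, path: str | Path) -> None:
    """Write a :class:`~dicersite.pattern_engine.PatternDataset` as CSV."""
    dataset.to_frame().to_csv(path, index=False)


def read_pattern_dataset(path: str | Path):
    """Read a pattern-dataset CSV back into a ``PatternDataset``.

    The ``fold`` column may be absent (folds unset).  Labels must lie in
    {0..s-1} for the pattern size s implied by the pattern strings.
    """
    from .pattern_engine import PatternDataset  # avoid import cycle

    df = pd.read_csv(path, dtype={"pattern_id": str, "premirna_id": str})
    known = set(DATASET_COLUMNS)
    unknown = set(df.columns) - known
    if unknown:
        raise ValidationError(f"{path}: unknown columns {sorted(unknown)}")
    required = known - {"fold"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return PatternDataset.from_frame(df)
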