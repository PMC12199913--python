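"""Reading, validation and windowing of RNA sequences.

2'-O-methylation (Nm/2OM) predictors in this encoder family operate on
fixed 41-nt windows with the candidate modified nucleotide at 1-based
position 21.  This module is the single entry point for sequence data:
it normalizes DNA input to the RNA alphabet (T -> U, case-folded),
rejects anything outside {A, C, G, U}, and slides fully-contained 41-nt
windows over longer sequences.

Coordinates are 1-based and inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

ALPHABET = "ACGU"
WINDOW_LENGTH = 41
#: 1-based position of the candidate 2OM site within a window.
CENTER_POSITION = 21


class ValidationError(ValueError):
    """Input violates a sequence/window contract."""


def _normalize(raw: str, record_id: str) -> str:
    """Uppercase, convert T to U, and reject non-ACGU residues."""
    folded = raw.upper().replace("T", "U")
    for pos, ch in enumerate(folded, start=1):
        if ch not in ALPHABET:
            raise ValidationError(
                f"record {record_id!r}: invalid residue {ch!r} at position {pos} "
                f"(alphabet is A/C/G/U, T accepted as U)"
            )
    return folded


@dataclass(frozen=True)
class SequenceRecord:
    """A validated RNA sequence.

    ``source_offset`` is the 1-based position of residue 1 within a parent
    sequence, for windows cut out of longer records.
    """

    id: str
    residues: str
    source_offset: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        object.__setattr__(self, "residues", _normalize(self.residues, self.id))

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SequenceWindow:
    """A 41-nt window whose center (position 21, 1-based) is the candidate site.

    ``label`` is 1 for an experimentally supported 2OM site, 0 for a
    non-site, None when unknown (prediction input).  ``parent_id`` and
    ``center_coord`` locate the window in the sequence it was cut from.
    """

    residues: str
    label: Optional[int] = None
    parent_id: Optional[str] = None
    center_coord: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.residues) != WINDOW_LENGTH:
            raise ValidationError(
                f"window must be exactly {WINDOW_LENGTH} nt, got {len(self.residues)}"
            )
        object.__setattr__(
            self, "residues", _normalize(self.residues, self.parent_id or "<window>")
        )
        if self.label is not None and self.label not in (0, 1):
            raise ValidationError(f"label must be 0 or 1, got {self.label!r}")

    @property
    def center_base(self) -> str:
        return self.residues[CENTER_POSITION - 1]

    def reversed(self) -> "SequenceWindow":
        """The same window read 3'->5' (used by the reverse encodings)."""
        return SequenceWindow(
            self.residues[::-1],
            label=self.label,
            parent_id=self.parent_id,
            center_coord=self.center_coord,
        )


def read_sequences(path: str | Path, format: str = "fasta") -> list[SequenceRecord]:
    """Read a FASTA file or a plain one-sequence-per-line text file.

    T/t is normalized to U and lowercase is uppercased; any other
    non-ACGU character raises :class:`ValidationError` naming the record
    and offending position.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    records: list[SequenceRecord] = []
    if format == "fasta":
        for entry in SeqIO.parse(str(path), "fasta"):
            records.append(SequenceRecord(id=entry.id, residues=str(entry.seq)))
    elif format == "plain":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                seq = line.strip()
                if seq:
                    records.append(SequenceRecord(id=f"line{lineno}", residues=seq))
    else:
        raise ValueError(f"unknown format {format!r} (expected 'fasta' or 'plain')")
    return records


def write_sequences(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as unwrapped FASTA."""
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta-2line")


def make_window(record: SequenceRecord, label: Optional[int] = None) -> SequenceWindow:
    """Turn a 41-nt record into a window; any other length is an error."""
    if len(record) != WINDOW_LENGTH:
        raise ValidationError(
            f"record {record.id!r} has length {len(record)}, "
            f"expected exactly {WINDOW_LENGTH}"
        )
    return SequenceWindow(
        record.residues,
        label=label,
        parent_id=record.id,
        center_coord=(record.source_offset or 1) + CENTER_POSITION - 1,
    )


def extract_windows(record: SequenceRecord) -> list[SequenceWindow]:
    """Slide a 41-nt window over a longer record (fully-contained only).

    A record of length L yields L - 40 windows; the window starting at
    1-based position s has its center at parent coordinate s + 20.
    """
    L = len(record)
    if L < WINDOW_LENGTH:
        raise ValidationError(
            f"record {record.id!r} has length {L} < {WINDOW_LENGTH}; cannot scan"
        )
    offset = record.source_offset or 1
    windows = []
    for start in range(L - WINDOW_LENGTH + 1):  # 0-based starts
        windows.append(
            SequenceWindow(
                record.residues[start : start + WINDOW_LENGTH],
                parent_id=record.id,
                center_coord=offset + start + CENTER_POSITION - 1,
            )
        )
    return windows


def filter_by_center(
    windows: Iterable[SequenceWindow], base: str
) -> list[SequenceWindow]:
    """Windows whose central residue equals ``base``, order preserved."""
    if base not in ALPHABET:
        raise ValidationError(f"center base must be one of {ALPHABET}, got {base!r}")
    return [w for w in windows if w.center_base == base]


def write_windows(windows: Iterable[SequenceWindow], path: str | Path) -> None:
    """Export windows as FASTA with ``parentID|center=<pos>|base=<b>`` headers."""
    bio = []
    for i, w in enumerate(windows):
        header = (
            f"{w.parent_id or f'window{i}'}"
            f"|center={w.center_coord if w.center_coord is not None else CENTER_POSITION}"
            f"|base={w.center_base}"
        )
        bio.append(_BioRecord(Seq(w.residues), id=header, description=""))
    SeqIO.write(bio, str(path), "fasta-2line")
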