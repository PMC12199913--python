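"""Synthetic labeled 2OM-style datasets.

Real Nm/2OM benchmark collections come as four nucleotide-specific
binary sets (A/C/G/U centers) of 41-nt windows in which the positive
class shows guanine enrichment in the downstream half of the window
(sequence-logo signal), while U-centered positives are near uniform.
The generator emulates exactly that structure with a class-conditional
per-position product model: positives draw the enrichment base with
probability ``p_enriched`` at positions 22-41 (and fall back to the
three other bases uniformly otherwise); every other position — and all
of the negative class — is drawn from the background distribution.
Position 21 is pinned to the configured center base in both classes.

Defaults are the conditions used throughout the test-suite: 200
positives + 200 negatives per set, G enrichment at probability 0.9
against a uniform 0.25 background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .sequence_io import (
    ALPHABET,
    CENTER_POSITION,
    WINDOW_LENGTH,
    SequenceRecord,
    SequenceWindow,
    ValidationError,
    read_sequences,
    write_sequences,
)


@dataclass(frozen=True)
class SyntheticConfig:
    center_base: str = "A"
    n_pos: int = 200
    n_neg: int = 200
    enrichment_base: str = "G"
    #: 1-based inclusive window positions carrying the positive-class signal.
    enrichment_region: tuple[int, int] = (22, 41)
    p_enriched: float = 0.9
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.center_base not in ALPHABET:
            raise ValidationError(f"center_base must be one of {ALPHABET}")
        if self.enrichment_base not in ALPHABET:
            raise ValidationError(f"enrichment_base must be one of {ALPHABET}")
        if not 0.0 <= self.p_enriched <= 1.0:
            raise ValidationError("p_enriched must be in [0, 1]")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or np.any(bg < 0) or not np.isclose(bg.sum(), 1.0):
            raise ValidationError("background must be 4 probabilities summing to 1")
        lo, hi = self.enrichment_region
        if not (1 <= lo <= hi <= WINDOW_LENGTH):
            raise ValidationError("enrichment_region out of window bounds")


def generate(config: SyntheticConfig) -> list[SequenceWindow]:
    """n_pos windows labeled 1 followed by n_neg labeled 0, seeded."""
    rng = np.random.default_rng(config.seed)
    bases = np.array(list(ALPHABET))
    background = np.asarray(config.background, dtype=float)
    enr_idx = ALPHABET.index(config.enrichment_base)
    others = [i for i in range(4) if i != enr_idx]
    lo, hi = config.enrichment_region

    windows: list[SequenceWindow] = []
    for label, count in ((1, config.n_pos), (0, config.n_neg)):
        for i in range(count):
            draws = rng.choice(4, size=WINDOW_LENGTH, p=background)
            if label == 1:
                for pos in range(lo, hi + 1):
                    if pos == CENTER_POSITION:
                        continue
                    if rng.random() < config.p_enriched:
                        draws[pos - 1] = enr_idx
                    else:
                        draws[pos - 1] = others[rng.integers(3)]
            draws[CENTER_POSITION - 1] = ALPHABET.index(config.center_base)
            windows.append(
                SequenceWindow(
                    "".join(bases[draws]),
                    label=label,
                    parent_id=f"{'pos' if label else 'neg'}{i}",
                )
            )
    return windows


def write_dataset(
    windows: Sequence[SequenceWindow], directory: str | Path, prefix: str = "synthetic"
) -> tuple[Path, Path]:
    """Write positive/negative FASTA pair; round-trips through sequence_io."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pos_path = directory / f"{prefix}_pos.fasta"
    neg_path = directory / f"{prefix}_neg.fasta"
    for path, wanted in ((pos_path, 1), (neg_path, 0)):
        records = [
            SequenceRecord(id=f"{w.parent_id or i}|label={wanted}", residues=w.residues)
            for i, w in enumerate(windows)
            if w.label == wanted
        ]
        write_sequences(records, path)
    return pos_path, neg_path


def read_dataset(pos_path: str | Path, neg_path: str | Path) -> list[SequenceWindow]:
    """Read a positive/negative FASTA pair back into labeled windows."""
    windows = []
    for path, label in ((pos_path, 1), (neg_path, 0)):
        for rec in read_sequences(path, format="fasta"):
            windows.append(
                SequenceWindow(rec.residues, label=label, parent_id=rec.id.split("|")[0])
            )
    return windows
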