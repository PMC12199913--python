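"""Assembly of the canonical 522-dimensional feature vector.

Block layout (fixed; 1-based feature positions):

=========  =========  =====================================================
positions  size       content
=========  =========  =====================================================
1-90       90         PRIM moments, k = 1, 2, 3 x [raw|central|Hahn] x 10
91-180     90         RPRIM moments, same sub-layout
181-264    84         frequency vector [mono 4 | di 16 | tri 64]
265-348    84         AAPIV position sums, same sub-layout
349-432    84         RAAPIV position sums, same sub-layout
433-522    90         2-D grid moments, k = 1, 2, 3 x [raw|central|Hahn]
=========  =========  =====================================================

Identical windows always produce bitwise-identical vectors.  Dataset
standardization (z-scoring with the population standard deviation,
zero-variance columns mapped to 0) is fitted on training data only and
carried around as an explicit :class:`ScalerState`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import kmer_encoding as ke
from .moments import MOMENT_FAMILIES, MOMENT_ORDERS, moment_block
from .sequence_io import SequenceWindow, ValidationError

N_FEATURES = 522
BLOCK_BOUNDS = {
    "prim": (0, 90),
    "rprim": (90, 180),
    "frequency": (180, 264),
    "aapiv": (264, 348),
    "raapiv": (348, 432),
    "grid": (432, 522),
}


def _moment_names(prefix: str) -> list[str]:
    names = []
    for k in ke.K_ORDERS:
        for family in MOMENT_FAMILIES:
            for u, v in MOMENT_ORDERS:
                names.append(f"{prefix}.k{k}.{family}.m{u}{v}")
    return names


def _kmer_names(prefix: str) -> list[str]:
    return [f"{prefix}.{kmer}" for k in ke.K_ORDERS for kmer in ke.all_kmers(k)]


def feature_names() -> list[str]:
    """The 522 column names, in block order (stable across runs)."""
    return (
        _moment_names("prim")
        + _moment_names("rprim")
        + _kmer_names("freq")
        + _kmer_names("aapiv")
        + _kmer_names("raapiv")
        + _moment_names("grid")
    )


FEATURE_NAMES = feature_names()


def assemble(window: SequenceWindow) -> np.ndarray:
    """Encode one 41-nt window into its 522-value feature vector."""
    with warnings.catch_warnings():
        # absent k-mers give zero-mass PRIM rows only in degenerate toy
        # inputs; real 41-mers always carry mass, so silence is safe here
        warnings.simplefilter("ignore", RuntimeWarning)
        prim_block = np.concatenate(
            [moment_block(ke.prim(window, k)) for k in ke.K_ORDERS]
        )
        rprim_block = np.concatenate(
            [moment_block(ke.rprim(window, k)) for k in ke.K_ORDERS]
        )
        grid_block = np.concatenate(
            [moment_block(ke.encode_matrix_2d(window, k)) for k in ke.K_ORDERS]
        )
    vector = np.concatenate(
        [
            prim_block,
            rprim_block,
            ke.frequency_vector(window).astype(float),
            ke.aapiv(window).astype(float),
            ke.raapiv(window).astype(float),
            grid_block,
        ]
    )
    assert vector.shape == (N_FEATURES,)
    return vector


def assemble_dataset(
    windows: Sequence[SequenceWindow], require_labels: bool = True
) -> tuple[pd.DataFrame, pd.Series]:
    """Feature table (rows = windows, 522 named columns) plus labels.

    Row order follows input order.  With ``require_labels`` (the
    training path) every window must carry a 0/1 label; for prediction
    input pass ``require_labels=False`` and ignore the label column.
    """
    rows = []
    labels = []
    for i, w in enumerate(windows):
        if require_labels and w.label is None:
            raise ValidationError(f"window {i} has no label")
        rows.append(assemble(w))
        labels.append(w.label)
    table = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, N_FEATURES)),
        columns=FEATURE_NAMES,
    )
    return table, pd.Series(labels, name="label", dtype="Int64")


@dataclass(frozen=True)
class ScalerState:
    """Per-column mean and population standard deviation of a training table."""

    mean: np.ndarray
    std: np.ndarray
    fitted_on: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "mean": self.mean.tolist(),
                    "std": self.std.tolist(),
                    "fitted_on": self.fitted_on,
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalerState":
        doc = json.loads(Path(path).read_text())
        return cls(
            mean=np.asarray(doc["mean"], dtype=float),
            std=np.asarray(doc["std"], dtype=float),
            fitted_on=int(doc["fitted_on"]),
        )


def fit_scaler(table: pd.DataFrame) -> ScalerState:
    """Column means and population standard deviations of a training table."""
    if len(table) < 2:
        raise ValidationError("need at least 2 rows to fit a scaler")
    values = table.to_numpy(dtype=float)
    return ScalerState(
        mean=values.mean(axis=0), std=values.std(axis=0, ddof=0), fitted_on=len(table)
    )


def apply_scaler(table: pd.DataFrame, state: ScalerState) -> pd.DataFrame:
    """z = (x - mean) / std per column; zero-variance columns map to 0."""
    if table.shape[1] != state.mean.shape[0]:
        raise ValidationError(
            f"table has {table.shape[1]} columns, scaler expects {state.mean.shape[0]}"
        )
    safe_std = np.where(state.std == 0.0, 1.0, state.std)
    z = (table.to_numpy(dtype=float) - state.mean) / safe_std
    z[:, state.std == 0.0] = 0.0
    return pd.DataFrame(z, columns=table.columns, index=table.index)
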