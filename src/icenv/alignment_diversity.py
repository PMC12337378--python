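"""Alignment gap filtering, Shannon diversity and conservation detection.

Shannon diversity is computed per alignment column in nats over the 20
amino acids, with gaps excluded from the proportions; a uniform column
therefore reaches ln(20) ~= 2.996 and a single-residue column scores 0.
Conserved regions are called on a centred rolling mean (window 3): a position
is conserved when its rolling diversity falls below 1.50 *and* the next
position does not drop more than 0.1 below it — the second condition guards
against single-position artefacts inside the rolling window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqs import AMINO_ACIDS, GAP, SequenceSet
from .synthetic_data import FaceMap

DEFAULT_H_THRESHOLD = 1.50
DEFAULT_DROP_TOLERANCE = 0.1
DEFAULT_MAX_COL_GAP_FRAC = 0.5
DEFAULT_MAX_SEQ_GAP_FRAC = 0.3


@dataclass
class DiversityProfile:
    """Per-position Shannon diversity of an alignment (nats)."""

    positions: np.ndarray  # 1-based original column indices
    H: np.ndarray
    H_rolling: np.ndarray
    conserved: np.ndarray | None = None
    environment: str | None = None  # None = pooled over all environments

    def to_frame(self) -> pd.DataFrame:
        data = {
            "position": self.positions,
            "H": self.H,
            "H_rolling": self.H_rolling,
        }
        if self.conserved is not None:
            data["conserved"] = self.conserved
        df = pd.DataFrame(data)
        if self.environment is not None:
            df["environment"] = self.environment
        return df


@dataclass
class ColumnSummary:
    """Pooled residue statistics of one named vertical column."""

    column: str
    face: str
    shannon: float
    modal_proportion: float
    modal_residue: str
    environment: str | None = None


def filter_alignment_gaps(
    aln: SequenceSet,
    max_col_gap_frac: float = DEFAULT_MAX_COL_GAP_FRAC,
    max_seq_gap_frac: float = DEFAULT_MAX_SEQ_GAP_FRAC,
) -> SequenceSet:
    """Two-stage gap filter: gappy columns first, then gappy sequences.

    Stage 1 removes columns whose gap fraction exceeds ``max_col_gap_frac``;
    stage 2 removes sequences whose gap fraction — measured on the
    column-filtered alignment — exceeds ``max_seq_gap_frac``. The order
    matters: a sequence gappy only inside removed columns survives.
    """
    if len(aln) == 0:
        raise ValueError("empty alignment")
    matrix = aln.to_matrix()
    is_gap = matrix == GAP

    keep_cols = is_gap.mean(axis=0) <= max_col_gap_frac
    if not keep_cols.any():
        raise ValueError("gap filtering removed every column")
    filtered = matrix[:, keep_cols]

    keep_rows = (filtered == GAP).mean(axis=1) <= max_seq_gap_frac
    from .seqs import SequenceRecord

    records = [
        SequenceRecord(
            id=r.id,
            residues="".join(filtered[i]),
            environment=r.environment,
            phylum=r.phylum,
        )
        for i, r in enumerate(aln)
        if keep_rows[i]
    ]
    if not records:
        raise ValueError("gap filtering removed every sequence")
    return SequenceSet(records)


def _column_entropy(column: np.ndarray) -> float:
    residues = column[column != GAP]
    if residues.size == 0:
        return 0.0
    _, counts = np.unique(residues, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def rolling_average(H: np.ndarray, window: int = 3) -> np.ndarray:
    """Centred rolling mean with edge truncation.

    Edge positions average only the values available inside the window, so
    the output has the same length as the input.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    H = np.asarray(H, dtype=float)
    half = window // 2
    out = np.empty_like(H)
    for i in range(len(H)):
        lo = max(0, i - half)
        hi = min(len(H), i + half + 1)
        out[i] = H[lo:hi].mean()
    return out


def shannon_profile(
    aln: SequenceSet,
    environment: str | None = None,
    window: int = 3,
) -> DiversityProfile:
    """Per-position Shannon diversity (nats), optionally for one environment."""
    subset = aln.by_environment(environment) if environment else aln
    matrix = subset.to_matrix()
    H = np.array([_column_entropy(matrix[:, j]) for j in range(matrix.shape[1])])
    return DiversityProfile(
        positions=np.arange(1, matrix.shape[1] + 1),
        H=H,
        H_rolling=rolling_average(H, window=window),
        environment=environment,
    )


def detect_conserved_regions(
    profile: DiversityProfile,
    H_threshold: float = DEFAULT_H_THRESHOLD,
    drop_tolerance: float = DEFAULT_DROP_TOLERANCE,
    compare_rolling: bool = True,
) -> np.ndarray:
    """Flag conserved positions on the rolling diversity profile.

    Position ``i`` is flagged iff (a) ``H_rolling[i] < H_threshold`` and (b)
    the next position's diversity is not more than ``drop_tolerance`` below
    ``H_rolling[i]``. Condition (b) uses the rolling value at ``i+1`` by
    default (``compare_rolling=False`` switches to the raw value); the final
    position applies condition (a) only.
    """
    H_rolling = np.asarray(profile.H_rolling, dtype=float)
    if H_rolling.size == 0:
        raise ValueError("empty profile")
    nxt = H_rolling if compare_rolling else np.asarray(profile.H, dtype=float)
    flags = H_rolling < H_threshold
    if H_rolling.size > 1:
        flags[:-1] &= nxt[1:] >= H_rolling[:-1] - drop_tolerance
    profile.conserved = flags
    return flags


def column_summary(
    aln: SequenceSet,
    face_map: FaceMap,
    column_name: str,
    per_environment: bool = False,
) -> ColumnSummary | list[ColumnSummary]:
    """Pooled Shannon diversity and modal-residue proportion of a column.

    Residues at the column's positions are pooled across sequences with gaps
    excluded. With ``per_environment`` one summary per environment label is
    returned.
    """
    positions = face_map.column_positions(column_name)
    faces = {face_map.face_of(p) for p in positions} - {"unassigned"}
    face = faces.pop() if len(faces) == 1 else "mixed"

    def summarise(subset: SequenceSet, env: str | None) -> ColumnSummary:
        matrix = subset.to_matrix()
        pooled = matrix[:, [p - 1 for p in positions]].ravel()
        pooled = pooled[pooled != GAP]
        if pooled.size == 0:
            raise ValueError(
                f"column {column_name!r} is all gaps"
                + (f" in environment {env!r}" if env else "")
            )
        symbols, counts = np.unique(pooled, return_counts=True)
        p = counts / counts.sum()
        modal = int(np.argmax(counts))
        return ColumnSummary(
            column=column_name,
            face=face,
            shannon=float(-(p * np.log(p)).sum()),
            modal_proportion=float(p[modal]),
            modal_residue=str(symbols[modal]),
            environment=env,
        )

    if not per_environment:
        return summarise(aln, None)
    envs = sorted(set(aln.environments))
    return [summarise(aln.by_environment(env), env) for env in envs]


def summaries_to_frame(summaries: list[ColumnSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "column": [s.column for s in summaries],
            "face": [s.face for s in summaries],
            "environment": [s.environment for s in summaries],
            "shannon": [s.shannon for s in summaries],
            "modal_residue": [s.modal_residue for s in summaries],
            "modal_proportion": [s.modal_proportion for s in summaries],
        }
    )
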