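"""Feature attribution and physicochemical interpretation.

Feature importance comes from a Monte-Carlo permutation-sampling Shapley
estimator (out-of-coalition features are taken from a paired background row,
so per-instance attributions telescope to f(x) - f(background) and the
efficiency property holds up to Monte-Carlo error over background draws),
cross-checked by permutation importance. Selected embedding features are then
regressed on sequence-averaged physicochemical residue scales — whole
sequence or restricted to one protein face — reporting simple-regression R².

A small fixture of published residue scales ships with the package
(hydropathy, residue volume as a side-chain-size scale, positive and
negative charge); arbitrary scales load from delimited text.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.inspection import permutation_importance as _sk_permutation_importance

from .seqs import AMINO_ACIDS, GAP
from .synthetic_data import FaceMap

# ---------------------------------------------------------------------------
# bundled residue scales
# ---------------------------------------------------------------------------

#: Kyte-Doolittle hydropathy index
HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Zamyatnin residue volume (A^3) — a side-chain-size scale
RESIDUE_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

#: positive charge at physiological pH (R/K = 1, H = 0.5)
POSITIVE_CHARGE = {aa: 0.0 for aa in AMINO_ACIDS} | {"R": 1.0, "K": 1.0, "H": 0.5}

#: negative charge at physiological pH
NEGATIVE_CHARGE = {aa: 0.0 for aa in AMINO_ACIDS} | {"D": 1.0, "E": 1.0}

DEFAULT_PROPERTIES: dict[str, dict[str, float]] = {
    "hydropathy": HYDROPATHY,
    "residue_volume": RESIDUE_VOLUME,
    "positive_charge": POSITIVE_CHARGE,
    "negative_charge": NEGATIVE_CHARGE,
}


@dataclass(frozen=True)
class PropertyTable:
    """One residue scale: property name plus residue -> value."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.values)
        if missing:
            raise ValueError(
                f"property {self.name!r} missing residues {sorted(missing)}"
            )


def default_property_tables() -> list[PropertyTable]:
    return [PropertyTable(name, vals) for name, vals in DEFAULT_PROPERTIES.items()]


def read_property_tables(path, sep: str = "\t") -> list[PropertyTable]:
    """Delimited text: residue column then one numeric column per property."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    return [
        PropertyTable(str(col), {str(r): float(v) for r, v in df[col].items()})
        for col in df.columns
    ]


# ---------------------------------------------------------------------------
# attribution
# ---------------------------------------------------------------------------

@dataclass
class ImportanceReport:
    """Mean |attribution| per feature, sorted descending."""

    method: str
    importance: np.ndarray  # per-feature mean |value|, original feature order
    attributions: np.ndarray | None = None  # per-instance (shapley only)

    @property
    def ranking(self) -> np.ndarray:
        return np.argsort(-self.importance)

    def top_features(self, k: int = 3) -> np.ndarray:
        return self.ranking[:k]


def shapley_importance(
    model_fn: Callable[[np.ndarray], np.ndarray],
    X: np.ndarray,
    background: np.ndarray,
    n_samples: int = 200,
    seed: int = 0,
) -> ImportanceReport:
    """Monte-Carlo permutation-sampling Shapley attribution.

    For each instance, ``n_samples`` feature orderings are drawn, each paired
    with one background row; walking along the ordering, each feature's
    marginal contribution is the change in ``model_fn`` when that feature
    flips from the background value to the instance value. Summed over
    features the contributions telescope to f(x) - f(z) per sample, so the
    per-instance attributions satisfy the efficiency property relative to
    the mean background prediction up to Monte-Carlo error.

    ``model_fn`` maps an (m, d) matrix to m scalars (e.g. the predicted
    probability of one class).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.shape[0] == 0:
        raise ValueError("background must be non-empty")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if X.shape[1] != background.shape[1]:
        raise ValueError("X and background dimensionality differ")
    n, d = X.shape
    rng = np.random.default_rng(seed)
    attributions = np.zeros((n, d))
    for i in range(n):
        x = X[i]
        for _ in range(n_samples):
            z = background[int(rng.integers(background.shape[0]))]
            order = rng.permutation(d)
            # build the chain of hybrids in one batch evaluation
            hybrids = np.empty((d + 1, d))
            hybrids[0] = z
            current = z.copy()
            for step, j in enumerate(order, start=1):
                current[j] = x[j]
                hybrids[step] = current
            values = model_fn(hybrids)
            attributions[i, order] += np.diff(values) / n_samples
    return ImportanceReport(
        method="shapley",
        importance=np.abs(attributions).mean(axis=0),
        attributions=attributions,
    )


def permutation_importance(
    model,
    X: np.ndarray,
    y: Sequence,
    scoring: str | None = None,
    n_repeats: int = 5,
    seed: int = 0,
) -> ImportanceReport:
    """Mean score drop per feature over repeated column shuffles."""
    result = _sk_permutation_importance(
        model, np.asarray(X, dtype=float), np.asarray(y),
        scoring=scoring, n_repeats=n_repeats, random_state=seed,
    )
    return ImportanceReport(
        method="permutation",
        importance=np.maximum(result.importances_mean, 0.0),
    )


# ---------------------------------------------------------------------------
# physicochemical regression
# ---------------------------------------------------------------------------

def sequence_property_average(
    seq: str,
    prop: PropertyTable,
    face_map: FaceMap | None = None,
    face: str | None = None,
) -> float:
    """Mean property value over the sequence's residues (gaps skipped).

    With a face map and face label, only residues at alignment positions on
    that face contribute (the sequence must then be aligned).
    """
    if face is not None:
        if face_map is None:
            raise ValueError("face restriction requires a face map")
        positions = [p for p in range(1, len(seq) + 1) if face_map.face_of(p) == face]
        residues = [seq[p - 1] for p in positions if seq[p - 1] != GAP]
    else:
        residues = [c for c in seq if c != GAP]
    if not residues:
        raise ValueError("no residues to average over")
    return float(np.mean([prop.values[c] for c in residues]))


def property_feature_regression(
    features: np.ndarray,
    feature_names: Sequence,
    sequences: Sequence[str],
    properties: Sequence[PropertyTable],
    face_map: FaceMap | None = None,
    faces: Sequence[str] = (),
) -> pd.DataFrame:
    """Simple least-squares R² per (feature, property, scope).

    ``features`` holds one column per selected embedding feature aligned
    with ``sequences``. Scope 'whole' averages over all residues; each
    entry of ``faces`` adds a face-restricted scope.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[0] != len(sequences):
        raise ValueError("feature rows must match sequences")
    scopes: list[tuple[str, str | None]] = [("whole", None)]
    scopes += [(f"face_{f}", f) for f in faces]
    rows = []
    for scope_name, face in scopes:
        for prop in properties:
            avgs = np.array(
                [
                    sequence_property_average(s, prop, face_map=face_map, face=face)
                    for s in sequences
                ]
            )
            for fi, fname in enumerate(feature_names):
                x = features[:, fi]
                if np.ptp(x) == 0 or np.ptp(avgs) == 0:
                    r2 = 0.0
                else:
                    r2 = float(stats.linregress(avgs, x).rvalue ** 2)
                rows.append(
                    {
                        "feature": fname,
                        "property": prop.name,
                        "scope": scope_name,
                        "r_squared": r2,
                    }
                )
    return pd.DataFrame(rows)
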