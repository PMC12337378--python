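"""Fixed-length sequence encodings feeding the classifiers.

Three encoders satisfy the embedding contract (n sequences x d features):

* :class:`SurrogateEncoder` — a deterministic mean-pooled random-projection
  encoder. Each residue symbol owns a fixed d-vector drawn once from a seeded
  standard normal and a sequence embeds as the mean of its residues' vectors.
  It preserves the two properties the downstream stages rely on — determinism
  and sensitivity to residue substitutions — and makes no attempt to mimic
  the semantics of a protein language model. By convention d = 1280, the
  width of the mean-pooled penultimate-layer representation of the large
  protein language model used for transfer learning in this problem setting.
* :func:`read_embeddings` — ingest of externally computed per-sequence
  embedding tables (e.g. real language-model layer averages) as delimited
  text, first column id, d numeric columns.
* :class:`OneHotPositionalEncoder` — per-position one-hot encoding of a
  rectangular alignment over the 21-symbol dictionary (20 residues + gap),
  n x (21 * L) features; the positional-identity benchmark input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .seqs import ALPHABET, AMINO_ACIDS, GAP, SequenceSet

DEFAULT_DIM = 1280


@dataclass
class EmbeddingMatrix:
    """Ordered per-sequence embeddings: ids aligned with rows of features."""

    ids: list[str]
    features: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if len(self.ids) != self.features.shape[0]:
            raise ValueError("row count does not match id count")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids in embedding matrix")
        if not np.isfinite(self.features).all():
            raise ValueError("embedding matrix contains non-finite values")

    @property
    def d(self) -> int:
        return self.features.shape[1]

    def __len__(self) -> int:
        return len(self.ids)

    def write(self, path: str | Path, sep: str = "\t") -> None:
        df = pd.DataFrame(self.features, index=self.ids)
        df.to_csv(path, sep=sep, header=False, float_format="%.10g")


def read_embeddings(source: str | Path | IO[str], sep: str = "\t") -> EmbeddingMatrix:
    """Read a delimited embedding table: id column then d numeric columns."""
    df = pd.read_csv(source, sep=sep, header=None, index_col=0)
    ids = [str(i) for i in df.index]
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sequence id {dup[0]!r} in embedding table")
    features = df.to_numpy(dtype=float)
    if np.isnan(features).any():
        raise ValueError("embedding table contains missing or non-numeric cells")
    return EmbeddingMatrix(ids=ids, features=features)


class SurrogateEncoder(BaseEstimator, TransformerMixin):
    """Deterministic mean-pooled residue-vector encoder.

    Parameters
    ----------
    d : int
        Embedding dimensionality (default 1280).
    seed : int
        Seed of the per-residue base vectors; the encoder is a pure function
        of (sequence, d, seed).
    """

    def __init__(self, d: int = DEFAULT_DIM, seed: int = 0):
        self.d = d
        self.seed = seed

    def _base_vectors(self) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        return rng.standard_normal((len(AMINO_ACIDS), self.d))

    def fit(self, X=None, y=None) -> "SurrogateEncoder":
        self.base_vectors_ = self._base_vectors()
        self.residue_index_ = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
        return self

    def transform(self, X: SequenceSet | Sequence[str]) -> np.ndarray:
        if not hasattr(self, "base_vectors_"):
            self.fit()
        seqs = X.sequences if isinstance(X, SequenceSet) else list(X)
        out = np.empty((len(seqs), self.d))
        for i, seq in enumerate(seqs):
            seq = seq.replace(GAP, "")
            if not seq:
                raise ValueError(f"sequence at row {i} is empty after degapping")
            idx = [self.residue_index_[aa] for aa in seq]
            out[i] = self.base_vectors_[idx].mean(axis=0)
        return out

    def encode(self, seqs: SequenceSet) -> EmbeddingMatrix:
        return EmbeddingMatrix(ids=list(seqs.ids), features=self.transform(seqs))


def surrogate_encode(
    seqs: SequenceSet, d: int = DEFAULT_DIM, seed: int = 0
) -> EmbeddingMatrix:
    """Functional form of :class:`SurrogateEncoder`."""
    return SurrogateEncoder(d=d, seed=seed).fit().encode(seqs)


class OneHotPositionalEncoder(BaseEstimator, TransformerMixin):
    """One-hot positional encoding of a rectangular alignment.

    Each of the L alignment positions expands to a 21-wide block (20 amino
    acids + gap); a 185-column alignment therefore yields 3885 features.
    """

    #: dictionary of the 21 possible symbols at an aligned position
    symbols = ALPHABET

    def fit(self, X: SequenceSet | Sequence[str], y=None) -> "OneHotPositionalEncoder":
        seqs = X.sequences if isinstance(X, SequenceSet) else list(X)
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("input is not a rectangular alignment")
        self.alignment_length_ = lengths.pop()
        self.n_features_out_ = len(self.symbols) * self.alignment_length_
        return self

    def transform(self, X: SequenceSet | Sequence[str]) -> np.ndarray:
        seqs = X.sequences if isinstance(X, SequenceSet) else list(X)
        L = self.alignment_length_
        k = len(self.symbols)
        index = {s: i for i, s in enumerate(self.symbols)}
        out = np.zeros((len(seqs), k * L), dtype=np.uint8)
        for i, seq in enumerate(seqs):
            if len(seq) != L:
                raise ValueError(f"sequence row {i} length {len(seq)} != {L}")
            for j, symbol in enumerate(seq):
                if symbol not in index:
                    raise ValueError(
                        f"symbol {symbol!r} outside the 21-symbol dictionary"
                    )
                out[i, j * k + index[symbol]] = 1
        return out

    def inverse_transform(self, X: np.ndarray) -> list[str]:
        L, k = self.alignment_length_, len(self.symbols)
        out = []
        for row in np.asarray(X).reshape(len(X), L, k):
            out.append("".join(self.symbols[int(np.argmax(block))] for block in row))
        return out


def onehot_positional(aln: SequenceSet) -> np.ndarray:
    """Functional form of :class:`OneHotPositionalEncoder` (fit+transform)."""
    return OneHotPositionalEncoder().fit(aln).transform(aln)
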