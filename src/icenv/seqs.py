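"""Sequence containers shared across the pipeline.

Amino-acid sequences are kept as plain strings over the 20 standard one-letter
codes, plus ``-`` for alignment gaps. A :class:`SequenceSet` carries the
per-sequence environment label (and optionally a phylum) alongside the
residues, because every downstream stage — diversity profiles, classifier
training, rule mining, mutagenesis — is label-aware.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = AMINO_ACIDS + GAP
#: one-hot dictionary order: the 20 amino acids followed by the gap symbol
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}


@dataclass(frozen=True)
class SequenceRecord:
    """One labelled amino-acid sequence (aligned or unaligned)."""

    id: str
    residues: str
    environment: str
    phylum: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid symbols {sorted(bad)!r}"
            )

    def ungapped(self) -> "SequenceRecord":
        return replace(self, residues=self.residues.replace(GAP, ""))


@dataclass
class SequenceSet:
    """An ordered collection of :class:`SequenceRecord` with unique ids."""

    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate sequence id {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def environments(self) -> list[str]:
        return [r.environment for r in self.records]

    @property
    def sequences(self) -> list[str]:
        return [r.residues for r in self.records]

    def is_aligned(self) -> bool:
        lengths = {len(r.residues) for r in self.records}
        return len(lengths) <= 1

    @property
    def alignment_length(self) -> int:
        if not self.records:
            raise ValueError("empty sequence set has no alignment length")
        if not self.is_aligned():
            raise ValueError("sequence set is not a rectangular alignment")
        return len(self.records[0].residues)

    def to_matrix(self) -> np.ndarray:
        """Residue matrix (n_sequences x n_columns) of single characters."""
        if not self.records:
            raise ValueError("empty sequence set")
        if not self.is_aligned():
            raise ValueError("sequence set is not a rectangular alignment")
        return np.array([list(r.residues) for r in self.records], dtype="<U1")

    def ungapped(self) -> "SequenceSet":
        return SequenceSet([r.ungapped() for r in self.records])

    def subset(self, ids: Iterable[str]) -> "SequenceSet":
        wanted = set(ids)
        return SequenceSet([r for r in self.records if r.id in wanted])

    def by_environment(self, environment: str) -> "SequenceSet":
        sub = [r for r in self.records if r.environment == environment]
        if not sub:
            raise ValueError(f"no sequences with environment {environment!r}")
        return SequenceSet(sub)

    def environment_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.environment] = counts.get(r.environment, 0) + 1
        return counts

    # ---- I/O ------------------------------------------------------------

    def write_fasta(self, path: str | Path, ungap: bool = False) -> None:
        records = self.ungapped() if ungap else self
        bio = [
            SeqRecord(Seq(r.residues), id=r.id, description="")
            for r in records
        ]
        SeqIO.write(bio, str(path), "fasta")

    def write_labels(self, path: str | Path, sep: str = "\t") -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(f"{r.id}{sep}{r.environment}\n")

    @classmethod
    def read_fasta(
        cls,
        path: str | Path,
        labels: Mapping[str, str] | None = None,
        default_environment: str = "unknown",
    ) -> "SequenceSet":
        labels = dict(labels or {})
        recs = [
            SequenceRecord(
                id=rec.id,
                residues=str(rec.seq).upper(),
                environment=labels.get(rec.id, default_environment),
            )
            for rec in SeqIO.parse(str(path), "fasta")
        ]
        return cls(recs)


def read_label_table(path: str | Path, sep: str = "\t") -> dict[str, str]:
    """Read a two-column (id, environment) delimited table."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            seq_id, env = line.split(sep)[:2]
            out[seq_id] = env
    return out


def from_arrays(
    ids: Sequence[str],
    residues: Sequence[str],
    environments: Sequence[str],
) -> SequenceSet:
    return SequenceSet(
        [
            SequenceRecord(id=i, residues=s, environment=e)
            for i, s, e in zip(ids, residues, environments, strict=True)
        ]
    )
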