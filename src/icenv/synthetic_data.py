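"""Synthetic environment-labelled alignment generator.

Generates rectangular amino-acid alignments over a set of environment labels
with *planted* column motifs: at chosen alignment positions each environment
draws its residue from its own distribution, while every other position draws
from a shared background. This plants a known, tunable classification signal
so that the curation, diversity, classification, rule-mining and mutagenesis
stages can all be tested against ground truth without any external download.

The default class ratios mirror the heavy imbalance of the five-environment
study design (polar marine dominating, subsurface rarest), and the default
face map reproduces the published mapping of alignment positions onto the
faces of the DUF3494 beta-solenoid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .seqs import AMINO_ACIDS, GAP, SequenceRecord, SequenceSet

#: the five environment labels of the most specific model grouping
DEFAULT_ENVIRONMENTS = (
    "frozen_sediment",
    "rock",
    "subsurface",
    "polar_marine",
    "glacier_ice",
)

#: per-environment sample counts of the five-label grouping, as published
MODEL3_COUNTS = {
    "polar_marine": 32649,
    "frozen_sediment": 7563,
    "rock": 7849,
    "glacier_ice": 4987,
    "subsurface": 453,
}

FACES = ("a", "b", "c", "between", "helix", "unassigned")

# face assignments of alignment positions, by beta-sheet row (1-based,
# inclusive ranges); rows spanning two faces are labelled 'between'
_FACE_ROWS: list[tuple[int, int, str]] = [
    (5, 10, "b"),
    (17, 20, "a"),
    (26, 30, "b"),
    (71, 73, "b"),
    (76, 78, "c"),
    (80, 83, "a"),
    (94, 98, "c"),
    (105, 109, "a"),
    (124, 127, "between"),
    (132, 135, "a"),
    (142, 145, "b"),
    (151, 154, "between"),
    (169, 173, "between"),
    (176, 180, "b"),
]

# bottom residues of the two b-face columns of interest
_B_COLUMN_BOTTOMS = {"b_col2": 87, "b_col4": 89}

# Default membership of the named 7-residue vertical columns. Only the column
# SIZE (7) and the bottom residues (87 and 89) are published; the remaining
# members are synthetic placeholders taking one position per face row from the
# top of the solenoid down, and are fully configurable.
DEFAULT_COLUMNS = {
    "b_col2": (6, 27, 72, 143, 177, 86, 87),
    "b_col4": (8, 29, 73, 144, 179, 88, 89),
    "a_col0": (17, 18, 80, 81, 105, 106, 133),
}


@dataclass(frozen=True)
class FaceMap:
    """Maps alignment positions (1-based) to protein faces and named columns."""

    faces: Mapping[int, str]
    columns: Mapping[str, tuple[int, ...]]
    n_columns: int

    def __post_init__(self) -> None:
        for pos, face in self.faces.items():
            if not 1 <= pos <= self.n_columns:
                raise ValueError(f"face position {pos} outside alignment")
            if face not in FACES:
                raise ValueError(f"unknown face label {face!r}")
        for name, positions in self.columns.items():
            if len(set(positions)) != len(positions):
                raise ValueError(f"column {name!r} repeats positions")
            for pos in positions:
                if not 1 <= pos <= self.n_columns:
                    raise ValueError(
                        f"column {name!r} position {pos} outside alignment"
                    )

    def face_of(self, position: int) -> str:
        return self.faces.get(position, "unassigned")

    def positions_on_face(self, face: str) -> tuple[int, ...]:
        return tuple(sorted(p for p, f in self.faces.items() if f == face))

    def column_positions(self, name: str) -> tuple[int, ...]:
        if name not in self.columns:
            raise KeyError(f"unknown column {name!r}")
        return tuple(self.columns[name])

    def write(self, path: str | Path, sep: str = "\t") -> None:
        pos_to_cols: dict[int, list[str]] = {}
        for name, positions in self.columns.items():
            for p in positions:
                pos_to_cols.setdefault(p, []).append(name)
        with open(path, "w") as fh:
            fh.write(f"position{sep}face{sep}column_name\n")
            for pos in range(1, self.n_columns + 1):
                cols = ",".join(sorted(pos_to_cols.get(pos, [])))
                fh.write(f"{pos}{sep}{self.face_of(pos)}{sep}{cols}\n")

    @classmethod
    def read(cls, path: str | Path, sep: str = "\t") -> "FaceMap":
        faces: dict[int, str] = {}
        columns: dict[str, list[int]] = {}
        n_columns = 0
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("position"):
                raise ValueError("face map table must start with a header row")
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                pos_s, face, cols = (line.split(sep) + [""])[:3]
                pos = int(pos_s)
                n_columns = max(n_columns, pos)
                if face != "unassigned":
                    faces[pos] = face
                for name in filter(None, cols.split(",")):
                    columns.setdefault(name, []).append(pos)
        return cls(
            faces=faces,
            columns={k: tuple(v) for k, v in columns.items()},
            n_columns=n_columns,
        )


def make_default_face_map(n_columns: int = 185) -> FaceMap:
    """The default face/column fixture for a >=185-column alignment.

    Reproduces the published position->face row assignments; the named
    7-residue columns end at the published bottom residues 87 (b_col2) and
    89 (b_col4), with remaining membership a documented placeholder.
    """
    if n_columns < 185:
        raise ValueError(
            f"default face map needs >= 185 alignment columns, got {n_columns}"
        )
    faces: dict[int, str] = {}
    for start, end, face in _FACE_ROWS:
        for pos in range(start, end + 1):
            faces[pos] = face
    for bottom in _B_COLUMN_BOTTOMS.values():
        faces[bottom] = "b"
    return FaceMap(faces=faces, columns=dict(DEFAULT_COLUMNS), n_columns=n_columns)


Distribution = Mapping[str, float]


@dataclass(frozen=True)
class PlantedMotif:
    """A set of alignment positions with per-environment residue distributions.

    ``per_environment`` maps environment -> residue distribution; environments
    missing from the mapping fall back to the background at these positions.
    A distribution may be a degenerate single-residue mapping like
    ``{"A": 1.0}``.
    """

    positions: tuple[int, ...]
    per_environment: Mapping[str, Distribution]

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("motif has no positions")
        for env, dist in self.per_environment.items():
            _validate_distribution(dist, f"motif distribution for {env!r}")


def _validate_distribution(dist: Distribution, what: str) -> None:
    if not dist:
        raise ValueError(f"{what} is empty")
    for symbol in dist:
        if symbol not in AMINO_ACIDS:
            raise ValueError(f"{what} contains non-residue symbol {symbol!r}")
    total = float(sum(dist.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{what} sums to {total}, not 1")
    if any(p < 0 for p in dist.values()):
        raise ValueError(f"{what} has negative probabilities")


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of one synthetic dataset draw."""

    n_per_environment: Mapping[str, int]
    n_columns: int = 185
    planted_motifs: tuple[PlantedMotif, ...] = ()
    background: Distribution | None = None  # None = uniform over 20 residues
    gap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_per_environment:
            raise ValueError("environment list is empty")
        for env, n in self.n_per_environment.items():
            if n < 0:
                raise ValueError(f"negative count for environment {env!r}")
        if self.n_columns < 1:
            raise ValueError("alignment must have at least one column")
        if not 0.0 <= self.gap_rate < 1.0:
            raise ValueError("gap_rate must be in [0, 1)")
        if self.background is not None:
            _validate_distribution(self.background, "background distribution")
        for motif in self.planted_motifs:
            for pos in motif.positions:
                if not 1 <= pos <= self.n_columns:
                    raise ValueError(
                        f"planted position {pos} outside [1, {self.n_columns}]"
                    )

    @property
    def environments(self) -> tuple[str, ...]:
        return tuple(self.n_per_environment)


def model3_class_counts(total: int) -> dict[str, int]:
    """Scale the published five-label class counts to ``total`` sequences.

    Largest-remainder rounding; every environment keeps at least 2 sequences
    so stratified splitting stays well defined.
    """
    if total < 2 * len(MODEL3_COUNTS):
        raise ValueError("total too small to give every environment >= 2")
    grand = sum(MODEL3_COUNTS.values())
    raw = {env: total * n / grand for env, n in MODEL3_COUNTS.items()}
    counts = {env: max(2, int(x)) for env, x in raw.items()}
    remainders = sorted(
        MODEL3_COUNTS, key=lambda e: raw[e] - int(raw[e]), reverse=True
    )
    i = 0
    while sum(counts.values()) < total:
        counts[remainders[i % len(remainders)]] += 1
        i += 1
    while sum(counts.values()) > total:
        env = max(counts, key=counts.get)  # type: ignore[arg-type]
        counts[env] -= 1
    return counts


def _dist_arrays(dist: Distribution | None) -> tuple[np.ndarray, np.ndarray]:
    if dist is None:
        symbols = np.array(list(AMINO_ACIDS), dtype="<U1")
        probs = np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
        return symbols, probs
    symbols = np.array(list(dist.keys()), dtype="<U1")
    probs = np.array([float(p) for p in dist.values()])
    return symbols, probs / probs.sum()


def generate_dataset(config: GeneratorConfig) -> tuple[SequenceSet, FaceMap]:
    """Draw a labelled aligned dataset plus its face map.

    Deterministic for a fixed config (including seed). Per-environment counts
    are exact; residues at planted positions follow the motif's
    per-environment distribution, all other cells follow the background, and
    gaps are injected independently per cell at ``gap_rate``.
    """
    rng = np.random.default_rng(config.seed)
    bg_symbols, bg_probs = _dist_arrays(config.background)

    # planted lookup: (environment, position) -> distribution arrays
    planted: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]] = {}
    for motif in config.planted_motifs:
        for env, dist in motif.per_environment.items():
            arrays = _dist_arrays(dist)
            for pos in motif.positions:
                planted[(env, pos)] = arrays

    records: list[SequenceRecord] = []
    counter = 0
    for env in config.environments:
        n = config.n_per_environment[env]
        if n == 0:
            continue
        # background draw for the whole block, then overwrite planted columns
        block = bg_symbols[
            rng.choice(len(bg_symbols), size=(n, config.n_columns), p=bg_probs)
        ]
        for pos in range(1, config.n_columns + 1):
            key = (env, pos)
            if key in planted:
                symbols, probs = planted[key]
                block[:, pos - 1] = symbols[
                    rng.choice(len(symbols), size=n, p=probs)
                ]
        if config.gap_rate > 0:
            gaps = rng.random(size=block.shape) < config.gap_rate
            block[gaps] = GAP
        for row in block:
            counter += 1
            records.append(
                SequenceRecord(
                    id=f"seq{counter:06d}", residues="".join(row), environment=env
                )
            )

    if config.n_columns >= 185:
        face_map = make_default_face_map(config.n_columns)
    else:
        face_map = FaceMap(faces={}, columns={}, n_columns=config.n_columns)
    return SequenceSet(records), face_map


def planted_signal_dataset(
    n_per_environment: Mapping[str, int],
    signal_positions: Sequence[int],
    n_columns: int = 185,
    gap_rate: float = 0.0,
    seed: int = 0,
    environments: Sequence[str] | None = None,
) -> tuple[SequenceSet, FaceMap, PlantedMotif]:
    """Convenience: a dataset where each environment owns a distinct residue.

    Every environment deterministically carries its own residue at every
    signal position, giving a perfectly discriminating planted signal.
    """
    envs = list(environments or n_per_environment)
    if len(envs) > len(AMINO_ACIDS):
        raise ValueError("more environments than available residues")
    motif = PlantedMotif(
        positions=tuple(signal_positions),
        per_environment={env: {AMINO_ACIDS[i]: 1.0} for i, env in enumerate(envs)},
    )
    config = GeneratorConfig(
        n_per_environment=dict(n_per_environment),
        n_columns=n_columns,
        planted_motifs=(motif,),
        gap_rate=gap_rate,
        seed=seed,
    )
    seqs, face_map = generate_dataset(config)
    return seqs, face_map, motif
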