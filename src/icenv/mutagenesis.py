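"""In silico mutagenesis of alignment positions in full sequences.

Chosen alignment positions (GA rule positions, or the named b-face columns)
are randomised in each test sequence, the mutants are re-encoded with the
same encoder as training, and the classifier is re-run. Comparing per-
environment accuracy before and after tells how much of the model's
predictive ability lives in those positions: randomising the true signal
columns collapses accuracy to chance, randomising inert columns leaves it
unchanged.

Mutation operates on the aligned (curated-envelope) sequences: each non-gap
cell at a plan position is replaced by a residue drawn uniformly from the 19
amino acids differing from the original (a flag allows all-20 draws); gaps
are untouched, so sequence length and coordinates are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .classification import EvaluationReport, evaluate
from .seqs import AMINO_ACIDS, GAP, SequenceRecord, SequenceSet
from .synthetic_data import FaceMap


@dataclass(frozen=True)
class MutagenesisPlan:
    """A named set of alignment positions (1-based) to randomise."""

    name: str
    positions: tuple[int, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.positions)) != len(self.positions):
            raise ValueError(f"plan {self.name!r} repeats positions")
        if any(p < 1 for p in self.positions):
            raise ValueError("positions are 1-based")


@dataclass
class MutagenesisResult:
    """Accuracy before/after randomising one plan's positions."""

    plan: str
    n_residues_mutated: int
    baseline_accuracy: float
    mutated_accuracy: float
    baseline_report: EvaluationReport
    mutated_report: EvaluationReport

    @property
    def accuracy_drop(self) -> float:
        return self.baseline_accuracy - self.mutated_accuracy


def plan_from_column(face_map: FaceMap, column_name: str, seed: int = 0) -> MutagenesisPlan:
    return MutagenesisPlan(
        name=column_name, positions=face_map.column_positions(column_name), seed=seed
    )


def read_plans(path, sep: str = "\t") -> list[MutagenesisPlan]:
    """Plans as delimited text: name, comma-separated 1-based positions."""
    plans = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            name, positions = line.split(sep)[:2]
            plans.append(
                MutagenesisPlan(
                    name=name,
                    positions=tuple(int(p) for p in positions.split(",")),
                )
            )
    return plans


def map_alignment_to_sequence(aln: SequenceSet, sequence_id: str) -> dict[int, int]:
    """Map alignment positions to unaligned residue indices (both 1-based).

    Gap cells are absent from the mapping; the mapping is strictly
    increasing in both coordinates, so composing it with gap-stripping
    reconstructs the unaligned sequence.
    """
    try:
        record = next(r for r in aln if r.id == sequence_id)
    except StopIteration:
        raise KeyError(f"unknown sequence id {sequence_id!r}") from None
    mapping: dict[int, int] = {}
    residue_index = 0
    for aln_pos, symbol in enumerate(record.residues, start=1):
        if symbol != GAP:
            residue_index += 1
            mapping[aln_pos] = residue_index
    return mapping


def mutate_positions(
    seqs: SequenceSet,
    plan: MutagenesisPlan,
    allow_original: bool = False,
) -> SequenceSet:
    """Randomise the plan's positions in every sequence (aligned coordinates).

    Non-gap cells at plan positions are replaced by a uniform draw over the
    19 alternative residues (all 20 with ``allow_original``); everything
    else, including gap cells, is untouched. Deterministic per plan seed.
    """
    if len(seqs) == 0:
        return seqs
    L = seqs.alignment_length
    for p in plan.positions:
        if p > L:
            raise ValueError(f"plan position {p} outside alignment of {L}")
    rng = np.random.default_rng(plan.seed)
    out: list[SequenceRecord] = []
    for record in seqs:
        residues = list(record.residues)
        for pos in plan.positions:
            original = residues[pos - 1]
            if original == GAP:
                continue
            if allow_original:
                choices = AMINO_ACIDS
            else:
                choices = AMINO_ACIDS.replace(original, "")
            residues[pos - 1] = choices[int(rng.integers(len(choices)))]
        out.append(
            SequenceRecord(
                id=record.id,
                residues="".join(residues),
                environment=record.environment,
                phylum=record.phylum,
            )
        )
    return SequenceSet(out)


def stratified_subsample(seqs: SequenceSet, n: int, seed: int = 0) -> SequenceSet:
    """Subsample ~n sequences with equal per-environment proportions."""
    envs = sorted(set(seqs.environments))
    per_env = max(1, n // len(envs))
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    for env in envs:
        ids = seqs.by_environment(env).ids
        take = min(per_env, len(ids))
        chosen.extend(
            np.array(ids)[rng.choice(len(ids), size=take, replace=False)]
        )
    return seqs.subset(chosen)


def run_mutagenesis_experiment(
    model,
    encoder,
    test_seqs: SequenceSet,
    plans: Sequence[MutagenesisPlan],
    subsample: int | None = None,
    seed: int = 0,
) -> list[MutagenesisResult]:
    """Baseline vs per-plan mutated accuracy on the (sub)sampled test set.

    ``encoder`` must expose ``transform`` on sequences and match the
    dimensionality the model was trained on; mutants are gap-stripped before
    encoding, as the encoder operates on unaligned sequences.
    """
    if subsample is not None:
        test_seqs = stratified_subsample(test_seqs, subsample, seed=seed)
    y_true = np.asarray(test_seqs.environments)

    X_base = encoder.transform(test_seqs.ungapped())
    baseline_pred = model.predict(X_base)
    baseline_report = evaluate(y_true, baseline_pred)

    results: list[MutagenesisResult] = []
    for plan in plans:
        mutated = mutate_positions(test_seqs, plan)
        n_mutated = sum(
            1
            for orig, mut in zip(test_seqs, mutated)
            for a, b in zip(orig.residues, mut.residues)
            if a != b
        )
        X_mut = encoder.transform(mutated.ungapped())
        mutated_report = evaluate(y_true, model.predict(X_mut))
        results.append(
            MutagenesisResult(
                plan=plan.name,
                n_residues_mutated=n_mutated,
                baseline_accuracy=baseline_report.overall_accuracy,
                mutated_accuracy=mutated_report.overall_accuracy,
                baseline_report=baseline_report,
                mutated_report=mutated_report,
            )
        )
    return results
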