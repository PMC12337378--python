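"""Genetic-algorithm rule discovery over aligned positions.

A generalised discriminant-function analysis: candidate classifiers are flat
logical expressions over alignment positions, e.g.::

    (position 50 = A) AND (position 73 <> T) OR (position 102 = I)

Atoms test one position for the presence (``=``) or absence (``<>``) of one
symbol (20 amino acids or the gap); connectives are applied strictly left to
right with no precedence, mirroring the flat rule strings of the original
formulation. Each expression is scored one-vs-rest against a target
environment with a *penalised phi coefficient*: the 2x2 association phi minus
a linear complexity penalty per extra atom. Evolution keeps the top-scoring
fraction as breeders, refills by mutation, single-point recombination and
fresh random immigrants, and tracks the best-ever rule elitistically, so best
penalised phi is non-decreasing across generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .seqs import ALPHABET, SequenceSet

EQUALS = "="
NOT_EQUALS = "<>"
OPERATORS = (EQUALS, NOT_EQUALS)
CONNECTIVES = ("AND", "OR")


@dataclass(frozen=True)
class RuleAtom:
    """One test: does the residue at ``position`` equal ``residue``?"""

    position: int  # 1-based alignment column
    operator: str
    residue: str

    def __post_init__(self) -> None:
        if self.operator not in OPERATORS:
            raise ValueError(f"unknown operator {self.operator!r}")
        if self.residue not in ALPHABET:
            raise ValueError(f"unknown residue symbol {self.residue!r}")
        if self.position < 1:
            raise ValueError("positions are 1-based")

    def __str__(self) -> str:
        return f"(position {self.position} {self.operator} {self.residue})"


@dataclass(frozen=True)
class RuleExpression:
    """A flat chain of atoms joined by AND/OR, evaluated left to right."""

    atoms: tuple[RuleAtom, ...]
    connectives: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("expression needs at least one atom")
        if len(self.connectives) != len(self.atoms) - 1:
            raise ValueError("need exactly len(atoms) - 1 connectives")
        for c in self.connectives:
            if c not in CONNECTIVES:
                raise ValueError(f"unknown connective {c!r}")

    @property
    def parameter_count(self) -> int:
        return len(self.atoms)

    def __str__(self) -> str:
        parts = [str(self.atoms[0])]
        for conn, atom in zip(self.connectives, self.atoms[1:]):
            parts.append(conn)
            parts.append(str(atom))
        return " ".join(parts)

    def sort_key(self) -> tuple:
        """Deterministic tie-break order: fewer atoms, then lexicographic."""
        return (
            self.parameter_count,
            tuple((a.position, a.operator, a.residue) for a in self.atoms),
            self.connectives,
        )


@dataclass(frozen=True)
class RuleFitness:
    """Contingency of rule truth vs class membership, with phi scores."""

    tp: int
    fp: int
    fn: int
    tn: int
    phi: float
    penalised_phi: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n


@dataclass(frozen=True)
class GaConfig:
    """One genetic-algorithm run (one-vs-rest against ``target_class``)."""

    target_class: str
    generations: int = 2500
    population_size: int = 500
    breeding_fraction: float = 0.5
    immigrant_fraction: float = 0.1
    max_params: int = 20
    phi_penalty_rate: float = 0.005
    crossover_probability: float = 0.3
    seed: int = 0
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.population_size < 2:
            raise ValueError("population must hold at least 2 expressions")
        if not 0 < self.breeding_fraction < 1:
            raise ValueError("breeding_fraction must be in (0, 1)")
        if not 0 < self.immigrant_fraction < 1:
            raise ValueError("immigrant_fraction must be in (0, 1)")
        if self.max_params < 1:
            raise ValueError("max_params must be >= 1")


@dataclass
class EvolvedRule:
    """Best rule of one replicate, with its fitness and trajectory."""

    expression: RuleExpression
    fitness: RuleFitness
    best_phi_trajectory: list[float] = field(default_factory=list)
    seed: int = 0


# --------------------------------------------------------------------------
# evaluation and fitness
# --------------------------------------------------------------------------

def _as_matrix(aln) -> np.ndarray:
    if isinstance(aln, SequenceSet):
        return aln.to_matrix()
    return np.asarray(aln, dtype="<U1")


def evaluate_expression(expr: RuleExpression, aln) -> np.ndarray:
    """Boolean truth of the expression for every sequence (left-to-right)."""
    matrix = _as_matrix(aln)
    n_cols = matrix.shape[1]
    for atom in expr.atoms:
        if atom.position > n_cols:
            raise ValueError(
                f"atom position {atom.position} outside alignment of {n_cols}"
            )

    def atom_truth(atom: RuleAtom) -> np.ndarray:
        col = matrix[:, atom.position - 1]
        hit = col == atom.residue
        return hit if atom.operator == EQUALS else ~hit

    value = atom_truth(expr.atoms[0])
    for conn, atom in zip(expr.connectives, expr.atoms[1:]):
        rhs = atom_truth(atom)
        value = (value & rhs) if conn == "AND" else (value | rhs)
    return value


def contingency(rule_truth: np.ndarray, is_target: np.ndarray) -> tuple[int, int, int, int]:
    rule_truth = np.asarray(rule_truth, dtype=bool)
    is_target = np.asarray(is_target, dtype=bool)
    tp = int(np.sum(rule_truth & is_target))
    fp = int(np.sum(rule_truth & ~is_target))
    fn = int(np.sum(~rule_truth & is_target))
    tn = int(np.sum(~rule_truth & ~is_target))
    return tp, fp, fn, tn


def phi_coefficient(tp: int, fp: int, fn: int, tn: int) -> float:
    """Phi association of a 2x2 table; any zero marginal gives 0."""
    if tp + fp + fn + tn < 1:
        raise ValueError("empty contingency table")
    denom = float(tp + fp) * (fn + tn) * (tp + fn) * (fp + tn)
    if denom == 0:
        return 0.0
    return (float(tp) * tn - float(fp) * fn) / np.sqrt(denom)


def penalised_phi(phi: float, parameter_count: int, rate: float) -> float:
    """Phi minus a linear complexity penalty; single atoms are unpenalised."""
    return phi - rate * (parameter_count - 1)


def score_expression(
    expr: RuleExpression, aln, is_target: np.ndarray, rate: float
) -> RuleFitness:
    truth = evaluate_expression(expr, aln)
    tp, fp, fn, tn = contingency(truth, is_target)
    phi = phi_coefficient(tp, fp, fn, tn)
    return RuleFitness(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        phi=phi,
        penalised_phi=penalised_phi(phi, expr.parameter_count, rate),
    )


# --------------------------------------------------------------------------
# evolution
# --------------------------------------------------------------------------

def observed_symbols(matrix: np.ndarray) -> list[str]:
    """Per-position symbols present in the data, in a fixed order.

    Random atoms draw their residue from the symbols observed at the chosen
    position — expressions are built from the predictor variables' actual
    values, keeping the search space data-driven.
    """
    return ["".join(sorted(set(matrix[:, j]))) for j in range(matrix.shape[1])]


def _random_atom(symbols: Sequence[str], rng: np.random.Generator) -> RuleAtom:
    position = int(rng.integers(1, len(symbols) + 1))
    pool = symbols[position - 1]
    return RuleAtom(
        position=position,
        operator=OPERATORS[int(rng.integers(2))],
        residue=pool[int(rng.integers(len(pool)))],
    )


def _random_expression(
    symbols: Sequence[str], max_params: int, rng: np.random.Generator
) -> RuleExpression:
    n_atoms = int(rng.integers(1, min(max_params, 3) + 1))
    atoms = tuple(_random_atom(symbols, rng) for _ in range(n_atoms))
    conns = tuple(CONNECTIVES[int(rng.integers(2))] for _ in range(n_atoms - 1))
    return RuleExpression(atoms=atoms, connectives=conns)


def _mutate(
    expr: RuleExpression, symbols: Sequence[str], max_params: int, rng: np.random.Generator
) -> RuleExpression:
    atoms = list(expr.atoms)
    conns = list(expr.connectives)
    moves = ["position", "residue", "operator"]
    if conns:
        moves.append("connective")
    if len(atoms) < max_params:
        moves.append("add")
    if len(atoms) > 1:
        moves.append("remove")
    move = moves[int(rng.integers(len(moves)))]
    i = int(rng.integers(len(atoms)))
    if move == "position":
        new_pos = int(rng.integers(1, len(symbols) + 1))
        pool = symbols[new_pos - 1]
        residue = atoms[i].residue
        if residue not in pool:
            residue = pool[int(rng.integers(len(pool)))]
        atoms[i] = replace(atoms[i], position=new_pos, residue=residue)
    elif move == "residue":
        pool = symbols[atoms[i].position - 1]
        atoms[i] = replace(atoms[i], residue=pool[int(rng.integers(len(pool)))])
    elif move == "operator":
        atoms[i] = replace(
            atoms[i],
            operator=NOT_EQUALS if atoms[i].operator == EQUALS else EQUALS,
        )
    elif move == "connective":
        j = int(rng.integers(len(conns)))
        conns[j] = "OR" if conns[j] == "AND" else "AND"
    elif move == "add":
        atoms.append(_random_atom(symbols, rng))
        conns.append(CONNECTIVES[int(rng.integers(2))])
    elif move == "remove":
        del atoms[i]
        del conns[min(i, len(conns) - 1)]
    return RuleExpression(atoms=tuple(atoms), connectives=tuple(conns))


def _recombine(
    a: RuleExpression,
    b: RuleExpression,
    max_params: int,
    rng: np.random.Generator,
) -> RuleExpression:
    """Single-point recombination on the two atom lists."""
    cut_a = int(rng.integers(1, len(a.atoms) + 1))
    cut_b = int(rng.integers(0, len(b.atoms)))
    atoms = (a.atoms[:cut_a] + b.atoms[cut_b:])[:max_params]
    conns_pool = a.connectives + b.connectives
    conns = list(conns_pool[: len(atoms) - 1])
    while len(conns) < len(atoms) - 1:
        conns.append(CONNECTIVES[int(rng.integers(2))])
    return RuleExpression(atoms=tuple(atoms), connectives=tuple(conns))


def evolve(
    config: GaConfig,
    aln,
    labels: Sequence[str],
) -> list[EvolvedRule]:
    """Run the GA; one :class:`EvolvedRule` per replicate.

    Deterministic per seed. Within each generation the population is scored
    (penalised phi, one-vs-rest against the target class), the top
    ``breeding_fraction`` survives, and the remainder is refilled with
    mutants, recombinants and ``immigrant_fraction`` fresh random
    expressions.
    """
    matrix = _as_matrix(aln)
    labels = np.asarray(labels)
    if len(labels) != matrix.shape[0]:
        raise ValueError("label count does not match alignment rows")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes")
    is_target = labels == config.target_class
    if not is_target.any():
        raise ValueError(f"target class {config.target_class!r} is empty")
    symbols = observed_symbols(matrix)

    results: list[EvolvedRule] = []
    for rep in range(config.n_replicates):
        seed = (config.seed + 7919 * rep) % (2**31)
        rng = np.random.default_rng(seed)
        population = [
            _random_expression(symbols, config.max_params, rng)
            for _ in range(config.population_size)
        ]
        best_expr: RuleExpression | None = None
        best_fit: RuleFitness | None = None
        trajectory: list[float] = []

        n_breed = max(2, int(round(config.breeding_fraction * config.population_size)))
        n_immigrants = max(1, int(round(config.immigrant_fraction * config.population_size)))

        for _ in range(config.generations):
            scored = [
                (score_expression(e, matrix, is_target, config.phi_penalty_rate), e)
                for e in population
            ]
            scored.sort(key=lambda fe: (-fe[0].penalised_phi, fe[1].sort_key()))
            top_fit, top_expr = scored[0]
            if best_fit is None or top_fit.penalised_phi > best_fit.penalised_phi:
                best_fit, best_expr = top_fit, top_expr
            trajectory.append(best_fit.penalised_phi)

            breeders = [e for _, e in scored[:n_breed]]
            nxt: list[RuleExpression] = list(breeders)
            for _ in range(n_immigrants):
                nxt.append(_random_expression(symbols, config.max_params, rng))
            while len(nxt) < config.population_size:
                if (
                    len(breeders) >= 2
                    and rng.random() < config.crossover_probability
                ):
                    i, j = rng.choice(len(breeders), size=2, replace=False)
                    child = _recombine(
                        breeders[i], breeders[j], config.max_params, rng
                    )
                else:
                    parent = breeders[int(rng.integers(len(breeders)))]
                    child = _mutate(parent, symbols, config.max_params, rng)
                nxt.append(child)
            population = nxt[: config.population_size]

        assert best_expr is not None and best_fit is not None
        results.append(
            EvolvedRule(
                expression=best_expr,
                fitness=best_fit,
                best_phi_trajectory=trajectory,
                seed=seed,
            )
        )
    return results


class GeneticRuleMiner:
    """Estimator facade over :func:`evolve`.

    ``fit(aln, labels)`` evolves one-vs-rest rules for ``target_class``;
    ``predict(aln)`` applies the best rule as a boolean one-vs-rest
    classifier.
    """

    def __init__(self, **config_kwargs):
        self.config_kwargs = config_kwargs

    def get_params(self, deep: bool = True) -> dict:
        return dict(self.config_kwargs)

    def set_params(self, **params) -> "GeneticRuleMiner":
        self.config_kwargs.update(params)
        return self

    def fit(self, X, y) -> "GeneticRuleMiner":
        self.config_ = GaConfig(**self.config_kwargs)
        self.replicates_ = evolve(self.config_, X, y)
        self.best_rule_ = max(
            self.replicates_, key=lambda r: r.fitness.penalised_phi
        )
        return self

    def predict(self, X) -> np.ndarray:
        return evaluate_expression(self.best_rule_.expression, X)


def ruleset_accuracy(
    rules_by_class: dict[str, list[EvolvedRule]],
    aln,
    labels: Sequence[str],
) -> dict[str, tuple[float, float]]:
    """Per class: mean +/- sample SD of best-rule one-vs-rest accuracy.

    Accuracy of one replicate's best rule is (TP+TN)/N against the class's
    one-vs-rest membership; the spread is across replicates.
    """
    matrix = _as_matrix(aln)
    labels = np.asarray(labels)
    out: dict[str, tuple[float, float]] = {}
    for cls, rules in rules_by_class.items():
        is_target = labels == cls
        accs = []
        for rule in rules:
            truth = evaluate_expression(rule.expression, matrix)
            tp, fp, fn, tn = contingency(truth, is_target)
            accs.append((tp + tn) / (tp + fp + fn + tn))
        arr = np.asarray(accs)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        out[cls] = (float(arr.mean()), sd)
    return out


def rules_report(rules: Sequence[EvolvedRule]) -> str:
    """One rule per line in the textual syntax, with its scores."""
    lines = ["rule\tphi\tpenalised_phi\ttp\tfp\tfn\ttn\taccuracy"]
    for r in rules:
        f = r.fitness
        lines.append(
            f"{r.expression}\t{f.phi:.4f}\t{f.penalised_phi:.4f}"
            f"\t{f.tp}\t{f.fp}\t{f.fn}\t{f.tn}\t{f.accuracy:.4f}"
        )
    return "\n".join(lines) + "\n"
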