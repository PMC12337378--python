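"""Rule evaluation oracles, phi fitness, and evolutionary search."""

import itertools

import numpy as np
import pytest

from icenv.ga_rules import (
    GaConfig,
    GeneticRuleMiner,
    RuleAtom,
    RuleExpression,
    contingency,
    evaluate_expression,
    evolve,
    penalised_phi,
    phi_coefficient,
    ruleset_accuracy,
    score_expression,
)
from icenv.seqs import from_arrays
from icenv.synthetic_data import planted_signal_dataset


def _expr(*atoms, connectives=()):
    return RuleExpression(
        atoms=tuple(RuleAtom(*a) for a in atoms), connectives=tuple(connectives)
    )


def _matrix(rows):
    return np.array([list(r) for r in rows], dtype="<U1")


class TestEvaluateExpression:
    def test_single_atom(self):
        truth = evaluate_expression(
            _expr((2, "=", "A")), _matrix(["GA-", "GS-", "CA-"])
        )
        assert list(truth) == [True, False, True]

    def test_and_with_not_equals(self):
        expr = _expr((1, "=", "G"), (2, "<>", "A"), connectives=("AND",))
        assert evaluate_expression(expr, _matrix(["GS-"]))[0]
        assert not evaluate_expression(expr, _matrix(["GA-"]))[0]

    def test_gap_participates_as_a_symbol(self):
        truth = evaluate_expression(_expr((3, "=", "-")), _matrix(["GA-", "GAT"]))
        assert list(truth) == [True, False]

    def test_left_to_right_matches_bruteforce_interpreter(self):
        """Exhaustive check over all truth combinations of a 3-atom rule."""
        expr = _expr(
            (1, "=", "G"), (2, "=", "A"), (3, "=", "I"),
            connectives=("AND", "OR"),
        )

        def brute(a, b, c):  # ((a AND b) OR c), strict left-to-right
            return (a and b) or c

        for bits in itertools.product([0, 1], repeat=3):
            row = (
                ("G" if bits[0] else "C")
                + ("A" if bits[1] else "S")
                + ("I" if bits[2] else "L")
            )
            got = evaluate_expression(expr, _matrix([row]))[0]
            assert got == brute(*map(bool, bits))

    def test_random_expressions_match_bruteforce_over_all_rows(self):
        rng = np.random.default_rng(0)
        symbols = "AST-"
        rows = ["".join(r) for r in itertools.product(symbols, repeat=3)]
        matrix = _matrix(rows)
        for _ in range(30):
            n_atoms = int(rng.integers(1, 4))
            atoms = [
                (int(rng.integers(1, 4)),
                 "=" if rng.random() < 0.5 else "<>",
                 symbols[int(rng.integers(4))])
                for _ in range(n_atoms)
            ]
            conns = tuple(
                "AND" if rng.random() < 0.5 else "OR" for _ in range(n_atoms - 1)
            )
            expr = _expr(*atoms, connectives=conns)
            got = evaluate_expression(expr, matrix)
            for i, row in enumerate(rows):
                value = (
                    (row[atoms[0][0] - 1] == atoms[0][2])
                    if atoms[0][1] == "="
                    else (row[atoms[0][0] - 1] != atoms[0][2])
                )
                for conn, (p, op, res) in zip(conns, atoms[1:]):
                    rhs = (row[p - 1] == res) if op == "=" else (row[p - 1] != res)
                    value = (value and rhs) if conn == "AND" else (value or rhs)
                assert got[i] == value

    def test_position_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            evaluate_expression(_expr((9, "=", "A")), _matrix(["GA"]))


class TestPhi:
    def test_perfect_association(self):
        assert phi_coefficient(50, 0, 0, 50) == pytest.approx(1.0)

    def test_hand_evaluated_table(self):
        assert phi_coefficient(30, 20, 20, 30) == pytest.approx(0.2)

    def test_independent_rule_is_zero(self):
        # truth split 50/50 independently of a 50/50 class -> phi 0
        assert phi_coefficient(25, 25, 25, 25) == pytest.approx(0.0)

    def test_zero_marginal_gives_zero(self):
        assert phi_coefficient(0, 0, 50, 50) == 0.0
        assert phi_coefficient(50, 50, 0, 0) == 0.0

    def test_symmetric_under_joint_polarity_swap(self):
        # swapping rule truth AND class membership leaves phi unchanged
        assert phi_coefficient(40, 10, 20, 30) == pytest.approx(
            phi_coefficient(30, 20, 10, 40)
        )

    def test_matches_bruteforce_pearson_correlation(self):
        rng = np.random.default_rng(1)
        truth = rng.random(200) < 0.4
        target = rng.random(200) < 0.5
        tp, fp, fn, tn = contingency(truth, target)
        expected = np.corrcoef(truth.astype(float), target.astype(float))[0, 1]
        assert phi_coefficient(tp, fp, fn, tn) == pytest.approx(expected)


class TestPenalisedPhi:
    def test_single_atom_unpenalised(self):
        assert penalised_phi(0.8, 1, 0.01) == pytest.approx(0.8)

    def test_linear_penalty(self):
        assert penalised_phi(0.8, 3, 0.01) == pytest.approx(0.78)

    def test_large_rate_always_favours_simpler_equal_phi_rules(self):
        rate = 0.5
        for phi in np.linspace(-1, 1, 9):
            scores = [penalised_phi(phi, k, rate) for k in range(1, 6)]
            assert all(a > b for a, b in zip(scores, scores[1:]))


class TestEvolve:
    def _dataset(self, seed=11, n=100):
        envs = {
            "frozen_sediment": n, "rock": n, "subsurface": n,
            "polar_marine": n, "glacier_ice": n,
        }
        seqs, _, _ = planted_signal_dataset(envs, [10], n_columns=40, seed=seed)
        return seqs

    def test_recovers_planted_rule(self):
        seqs = self._dataset()
        config = GaConfig(
            target_class="frozen_sediment", generations=100,
            population_size=200, max_params=2, n_replicates=3, seed=1,
        )
        rules = evolve(config, seqs, seqs.environments)
        for r in rules:
            assert r.fitness.phi == pytest.approx(1.0)
            assert any(a.position == 10 for a in r.expression.atoms)

    def test_best_phi_trajectory_is_monotone(self):
        seqs = self._dataset()
        config = GaConfig(
            target_class="rock", generations=40, population_size=100,
            max_params=2, seed=3,
        )
        [rule] = evolve(config, seqs, seqs.environments)
        traj = rule.best_phi_trajectory
        assert all(a <= b + 1e-12 for a, b in zip(traj, traj[1:]))

    def test_max_params_one_yields_single_atom_rules(self):
        seqs = self._dataset(n=40)
        config = GaConfig(
            target_class="rock", generations=20, population_size=60,
            max_params=1, n_replicates=2, seed=4,
        )
        for r in evolve(config, seqs, seqs.environments):
            assert r.expression.parameter_count == 1

    def test_deterministic_per_seed(self):
        seqs = self._dataset(n=30)
        config = GaConfig(
            target_class="rock", generations=15, population_size=50, seed=9
        )
        a = evolve(config, seqs, seqs.environments)
        b = evolve(config, seqs, seqs.environments)
        assert str(a[0].expression) == str(b[0].expression)
        assert a[0].fitness == b[0].fitness

    def test_shuffled_labels_match_permutation_null(self):
        """With labels shuffled, the best evolved phi falls inside the null
        distribution of best single-atom phi under label permutation."""
        seqs = self._dataset(n=30)
        rng = np.random.default_rng(5)
        labels = np.array(seqs.environments)
        shuffled = rng.permutation(labels)
        config = GaConfig(
            target_class="rock", generations=30, population_size=100,
            max_params=2, seed=6,
        )
        [rule] = evolve(config, seqs, shuffled)

        # permutation null: best phi over an atom grid for random labelings
        matrix = seqs.to_matrix()
        is_target_pool = [
            rng.permutation(labels) == "rock" for _ in range(30)
        ]
        null_best = []
        for is_target in is_target_pool:
            best = 0.0
            for pos in range(1, matrix.shape[1] + 1):
                col = matrix[:, pos - 1]
                for res in np.unique(col):
                    for truth in (col == res, col != res):
                        tp, fp, fn, tn = contingency(truth, is_target)
                        best = max(best, phi_coefficient(tp, fp, fn, tn))
            null_best.append(best)
        # evolved best on shuffled labels should not exceed the null range
        assert rule.fitness.phi <= max(null_best) + 0.05

    def test_tiny_matrix_matches_exhaustive_single_atom_enumeration(self):
        rows = ["AST", "ASA", "TST", "TTA", "ASA", "TCA"]
        labels = ["x", "x", "y", "y", "x", "y"]
        matrix = _matrix(rows)
        config = GaConfig(
            target_class="x", generations=50, population_size=40,
            max_params=1, seed=2,
        )
        [rule] = evolve(config, matrix, labels)

        best = -2.0
        is_target = np.array(labels) == "x"
        for pos in range(1, 4):
            col = matrix[:, pos - 1]
            for res in np.unique(col):
                for truth in (col == res, col != res):
                    tp, fp, fn, tn = contingency(truth, is_target)
                    best = max(best, phi_coefficient(tp, fp, fn, tn))
        assert rule.fitness.phi == pytest.approx(best)

    def test_empty_target_class_rejected(self):
        seqs = self._dataset(n=10)
        config = GaConfig(target_class="absent", generations=2, population_size=10)
        with pytest.raises(ValueError, match="empty"):
            evolve(config, seqs, seqs.environments)


class TestRulesetAccuracy:
    def test_perfect_rule_scores_one(self):
        seqs, _, _ = planted_signal_dataset(
            {"x": 20, "y": 20}, [5], n_columns=10, seed=3
        )
        config = GaConfig(
            target_class="x", generations=30, population_size=60,
            max_params=1, n_replicates=2, seed=7,
        )
        rules = evolve(config, seqs, seqs.environments)
        accs = ruleset_accuracy({"x": rules}, seqs, seqs.environments)
        assert accs["x"][0] == pytest.approx(1.0)

    def test_always_false_rule_equals_negative_rate(self):
        rows = ["AA"] * 3 + ["SS"] * 7
        labels = ["x"] * 3 + ["y"] * 7
        matrix = _matrix(rows)
        rule_expr = _expr((1, "=", "W"))  # never true
        from icenv.ga_rules import EvolvedRule

        fitness = score_expression(
            rule_expr, matrix, np.array(labels) == "x", rate=0.0
        )
        fake = EvolvedRule(expression=rule_expr, fitness=fitness)
        accs = ruleset_accuracy({"x": [fake]}, matrix, labels)
        assert accs["x"][0] == pytest.approx(0.7)

    def test_agrees_with_independent_confusion_recount(self):
        seqs, _, _ = planted_signal_dataset(
            {"x": 15, "y": 25}, [2], n_columns=8, seed=9
        )
        expr = _expr((2, "=", "A"))
        fitness = score_expression(
            expr, seqs.to_matrix(), np.array(seqs.environments) == "x", rate=0.0
        )
        # independent recount
        truth = np.array([r.residues[1] == "A" for r in seqs])
        is_x = np.array([r.environment == "x" for r in seqs])
        manual_acc = np.mean(truth == is_x)
        assert fitness.accuracy == pytest.approx(manual_acc)


def test_estimator_facade_fits_and_predicts():
    seqs, _, _ = planted_signal_dataset({"x": 30, "y": 30}, [4], n_columns=12, seed=1)
    miner = GeneticRuleMiner(
        target_class="x", generations=30, population_size=60, max_params=2, seed=0
    )
    miner.fit(seqs, seqs.environments)
    pred = miner.predict(seqs)
    assert (pred == (np.array(seqs.environments) == "x")).mean() == 1.0
    assert miner.get_params()["target_class"] == "x"
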