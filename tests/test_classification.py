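"""Splits, class weights, the feedforward network, benchmarks and metrics."""

import numpy as np
import pytest

from icenv.classification import (
    FeedForwardClassifier,
    ProfileClassifier,
    compute_class_weights,
    evaluate,
    f1_score_from,
    mcfadden_r2,
    multinomial_loglik,
    null_loglik,
    stratified_split,
    train_multinomial_lr,
    train_profile_classifier,
)
from icenv.encoding import SurrogateEncoder
from icenv.seqs import from_arrays


class TestStratifiedSplit:
    def test_proportional_counts(self):
        labels = ["A"] * 80 + ["B"] * 20
        train, test = stratified_split(labels, test_fraction=0.2, seed=1)
        test_labels = np.asarray(labels)[test]
        assert np.sum(test_labels == "A") == 16
        assert np.sum(test_labels == "B") == 4

    def test_disjoint_and_exhaustive(self):
        labels = ["A"] * 33 + ["B"] * 17 + ["C"] * 50
        train, test = stratified_split(labels, seed=5)
        assert set(train) & set(test) == set()
        assert sorted(np.concatenate([train, test])) == list(range(100))

    def test_deterministic_per_seed(self):
        labels = ["A"] * 30 + ["B"] * 30
        assert np.array_equal(
            stratified_split(labels, seed=7)[1], stratified_split(labels, seed=7)[1]
        )
        assert not np.array_equal(
            stratified_split(labels, seed=7)[1], stratified_split(labels, seed=8)[1]
        )

    def test_mean_test_fraction_across_seeds(self):
        labels = ["A"] * 37 + ["B"] * 23 + ["C"] * 40
        labels_arr = np.asarray(labels)
        fractions = []
        for seed in range(200):
            _, test = stratified_split(labels, test_fraction=0.2, seed=seed)
            test_labels = labels_arr[test]
            fractions.append(
                np.mean(
                    [np.sum(test_labels == c) / np.sum(labels_arr == c)
                     for c in "ABC"]
                )
            )
        assert abs(np.mean(fractions) - 0.2) < 0.005

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(["A", "A", "B"], seed=0)


class TestClassWeights:
    def test_balanced_formula(self):
        labels = ["A"] * 100 + ["B"] * 50 + ["C"] * 10
        w = compute_class_weights(labels)
        assert w["A"] == pytest.approx(160 / (3 * 100))
        assert w["B"] == pytest.approx(160 / (3 * 50))
        assert w["C"] == pytest.approx(160 / (3 * 10))

    def test_balanced_classes_give_unit_weights(self):
        w = compute_class_weights(["A"] * 5 + ["B"] * 5)
        assert all(v == pytest.approx(1.0) for v in w.values())

    def test_weighted_count_identity(self):
        labels = ["A"] * 71 + ["B"] * 13 + ["C"] * 16
        w = compute_class_weights(labels)
        total = sum(w[c] * labels.count(c) for c in "ABC")
        assert total == pytest.approx(len(labels))


class TestFeedForwardClassifier:
    def test_high_accuracy_on_strongly_planted_embeddings(self, signal_study):
        report = signal_study.test_report()
        assert report.overall_accuracy >= 0.95

    def test_chance_accuracy_without_planted_signal(self, nosignal_study):
        acc = nosignal_study.test_report().overall_accuracy
        n = len(nosignal_study.test_idx)
        chance = 1.0 / 5
        sigma = np.sqrt(chance * (1 - chance) / n)
        assert abs(acc - chance) < 3 * sigma

    def test_softmax_rows_sum_to_one(self, signal_study):
        proba = signal_study.model.predict_proba(signal_study.X[:50])
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(proba >= 0)

    def test_equal_class_weights_match_no_weighting(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 8))
        y = np.array(["a", "b", "c"] * 20)
        kwargs = dict(
            hidden_layers=(8,), dropout=0.0, learning_rate=1e-2,
            batch_size=16, epochs=5, random_state=1,
        )
        unweighted = FeedForwardClassifier(class_weight=None, **kwargs).fit(X, y)
        ones = FeedForwardClassifier(
            class_weight={"a": 1.0, "b": 1.0, "c": 1.0}, **kwargs
        ).fit(X, y)
        assert unweighted.loss_curve_ == pytest.approx(ones.loss_curve_)

    def test_reproducible_loss_trajectory(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 6))
        y = np.array(["a", "b"] * 20)
        kwargs = dict(hidden_layers=(8,), epochs=4, batch_size=8,
                      learning_rate=1e-3, random_state=9)
        a = FeedForwardClassifier(**kwargs).fit(X, y)
        b = FeedForwardClassifier(**kwargs).fit(X, y)
        assert a.loss_curve_ == pytest.approx(b.loss_curve_)

    def test_validation_curve_recorded_per_epoch(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 6))
        y = np.array(["a", "b"] * 20)
        model = FeedForwardClassifier(
            hidden_layers=(8,), epochs=6, batch_size=8, random_state=0
        ).fit(X[:30], y[:30], validation_data=(X[30:], y[30:]))
        assert len(model.loss_curve_) == 6
        assert len(model.validation_loss_curve_) == 6

    def test_dimension_mismatch_rejected_at_prediction(self, signal_study):
        with pytest.raises(ValueError, match="features"):
            signal_study.model.predict(np.zeros((2, 7)))


class TestMultinomialLR:
    def test_separable_1d_toy_is_perfect(self):
        X = np.array([[-2.0], [-1.5], [-1.0], [1.0], [1.5], [2.0]])
        y = np.array(["neg"] * 3 + ["pos"] * 3)
        model = train_multinomial_lr(X, y, max_iter=2000)
        assert (model.predict(X) == y).all()

    def test_stronger_l2_shrinks_coefficients(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((80, 5))
        y = np.where(X[:, 0] + 0.3 * rng.standard_normal(80) > 0, "a", "b")
        norms = [
            np.linalg.norm(train_multinomial_lr(X, y, l2_strength=s).coef_)
            for s in (0.1, 1.0, 10.0, 100.0)
        ]
        assert all(n1 >= n2 - 1e-9 for n1, n2 in zip(norms, norms[1:]))

    def test_gradient_of_penalised_weighted_objective_vanishes_at_optimum(self):
        """sklearn's optimum solves our weighted ridge multinomial likelihood."""
        rng = np.random.default_rng(5)
        X = rng.standard_normal((90, 4))
        logits = X @ rng.standard_normal((4, 3))
        y_idx = np.argmax(logits + rng.gumbel(size=(90, 3)), axis=1)
        y = np.array(list("abc"))[y_idx]
        l2 = 2.0
        model = train_multinomial_lr(X, y, l2_strength=l2, max_iter=20000)
        # objective: sum_i w_i * CE_i + (l2/2) * ||coef||^2 ; gradient wrt coef
        w = compute_class_weights(y)
        sample_w = np.array([w[c] for c in y])
        proba = model.predict_proba(X)
        onehot = np.eye(3)[y_idx]
        grad_coef = ((proba - onehot) * sample_w[:, None]).T @ X + l2 * model.coef_
        grad_intercept = ((proba - onehot) * sample_w[:, None]).sum(axis=0)
        assert np.abs(grad_coef).max() < 1e-2
        assert np.abs(grad_intercept).max() < 1e-2


class TestProfileClassifier:
    def _planted(self, n=40, L=12):
        rng = np.random.default_rng(6)
        residues = {"envA": "A", "envB": "S", "envC": "T"}
        rows, envs = [], []
        from icenv.seqs import AMINO_ACIDS

        for env, res in residues.items():
            for _ in range(n):
                seq = list(rng.choice(list(AMINO_ACIDS), size=L))
                for pos in range(10):
                    seq[pos] = res
                rows.append("".join(seq))
                envs.append(env)
        return from_arrays([f"s{i}" for i in range(len(rows))], rows, envs)

    def test_disjoint_planted_residues_classified_perfectly(self):
        aln = self._planted()
        train, test = stratified_split(aln.environments, seed=0)
        model = train_profile_classifier(
            aln.subset(np.array(aln.ids)[train])
        )
        test_set = aln.subset(np.array(aln.ids)[test])
        pred = model.predict(test_set)
        assert (pred == np.asarray(test_set.environments)).all()

    def test_uniform_profiles_tie_break_with_warning(self):
        aln = from_arrays(
            ["a", "b", "c", "d"], ["AC", "AC", "AC", "AC"], ["x", "x", "y", "y"]
        )
        model = train_profile_classifier(aln)
        with pytest.warns(UserWarning, match="tied"):
            pred = model.predict(["AC"])
        assert pred[0] == "x"  # earliest environment in sorted order

    def test_pseudocount_keeps_unseen_residues_finite(self):
        aln = from_arrays(["a", "b"], ["AA", "AA"], ["x", "x"])
        model = train_profile_classifier(aln)
        scores = model.decision_function(["WW"])
        assert np.isfinite(scores).all()

    def test_discriminative_model_beats_profile_on_compositional_signal(self):
        """Signal carried by joint composition, invisible to the per-position
        independence assumption of the profile scorer, is learned from the
        mean embedding: the network exceeds chance by >= 4 sigma and beats
        the profile classifier."""
        rng = np.random.default_rng(7)
        from icenv.seqs import AMINO_ACIDS

        L, k, n = 60, 30, 200
        rows, envs = [], []
        for _ in range(n):  # coherent: one residue repeated over signal sites
            seq = list(rng.choice(list(AMINO_ACIDS), size=L))
            res = "A" if rng.random() < 0.5 else "S"
            for pos in range(k):
                seq[pos] = res
            rows.append("".join(seq))
            envs.append("coherent")
        for _ in range(n):  # scrambled: signal sites independently A or S
            seq = list(rng.choice(list(AMINO_ACIDS), size=L))
            for pos in range(k):
                seq[pos] = "A" if rng.random() < 0.5 else "S"
            rows.append("".join(seq))
            envs.append("scrambled")
        aln = from_arrays([f"s{i}" for i in range(2 * n)], rows, envs)

        train, test = stratified_split(aln.environments, seed=1)
        ids = np.array(aln.ids)
        train_set, test_set = aln.subset(ids[train]), aln.subset(ids[test])
        y_test = np.asarray(test_set.environments)

        profile_pred = train_profile_classifier(train_set).predict(test_set)
        profile_acc = (profile_pred == y_test).mean()

        encoder = SurrogateEncoder(d=32, seed=8).fit()
        ann = FeedForwardClassifier(
            hidden_layers=(32, 16), dropout=0.2, learning_rate=1e-2,
            batch_size=32, epochs=80, random_state=2,
        ).fit(encoder.transform(train_set), train_set.environments)
        ann_acc = (ann.predict(encoder.transform(test_set)) == y_test).mean()

        sigma = np.sqrt(0.5 * 0.5 / len(y_test))
        assert ann_acc > 0.5 + 4 * sigma
        assert ann_acc > profile_acc


class TestEvaluate:
    def test_perfect_predictions(self):
        y = ["a", "b", "c", "a"]
        report = evaluate(y, y)
        assert report.overall_accuracy == 1.0
        assert np.all(np.diag(report.confusion.to_numpy()) >= 1)
        assert all(v == 1.0 for v in report.f1.values())

    def test_confusion_rows_sum_to_class_counts(self):
        y_true = ["a"] * 6 + ["b"] * 4
        y_pred = ["a", "a", "b", "a", "b", "a", "b", "b", "a", "b"]
        report = evaluate(y_true, y_pred)
        assert report.confusion.loc["a"].sum() == 6
        assert report.confusion.loc["b"].sum() == 4
        trace = np.trace(report.confusion.to_numpy())
        assert report.overall_accuracy == pytest.approx(trace / 10)

    def test_f1_is_harmonic_mean(self):
        assert f1_score_from(0.80, 0.75) == pytest.approx(0.7742, abs=1e-4)
        assert f1_score_from(0.0, 0.0) == 0.0

    def test_row_normalised_confusion_percentages(self):
        report = evaluate(["a", "a", "b"], ["a", "b", "b"])
        pct = report.confusion_percent
        assert pct.loc["a", "a"] == pytest.approx(50.0)
        assert pct.loc["b", "b"] == pytest.approx(100.0)


class TestMcFadden:
    def test_halved_likelihood(self):
        assert mcfadden_r2(-50.0, -100.0) == pytest.approx(0.5)

    def test_model_equal_to_null_is_zero(self):
        assert mcfadden_r2(-80.0, -80.0) == 0.0

    def test_saturated_model_approaches_one(self):
        assert mcfadden_r2(-1e-6, -100.0) == pytest.approx(1.0, abs=1e-6)

    def test_positive_null_rejected(self):
        with pytest.raises(ValueError):
            mcfadden_r2(-1.0, 0.0)

    def test_from_predicted_probabilities(self):
        y_idx = np.array([0, 0, 1, 1])
        proba = np.array([[0.9, 0.1], [0.8, 0.2], [0.2, 0.8], [0.3, 0.7]])
        r2 = mcfadden_r2(multinomial_loglik(proba, y_idx), null_loglik(y_idx))
        assert 0 < r2 < 1
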