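"""Normalization, SVM training, LOOCV, and wrapper metric selection."""

import numpy as np
import pandas as pd
import pytest

from voa import learning
from voa.errors import (
    CohortError,
    DegenerateMetricError,
    InputError,
    SchemaError,
    TrainingError,
)
from voa.learning import (
    CVResult,
    NormalizationParams,
    SVMConfig,
    SelectionConfig,
    fit_normalizer,
    hinge_objective,
    load_model,
    load_reference_model,
    loocv,
    normalize,
    pegasos,
    save_model,
    select_metrics,
    train_svm,
)


def two_group_table(rng, n_per_group=15, gap=4.0, k=2):
    """Raw-value table with a known group gap (novices higher)."""
    X = rng.normal(0.0, 1.0, size=(2 * n_per_group, k))
    X[n_per_group:] += gap
    labels = ["skilled"] * n_per_group + ["novice"] * n_per_group
    df = pd.DataFrame(X, columns=[f"m{i}" for i in range(k)])
    df.insert(0, "group", labels)
    df.insert(0, "trial_id", [f"t{i}" for i in range(2 * n_per_group)])
    return df


class TestNormalizer:
    def test_hand_computed_mean_and_sample_sd(self):
        p = fit_normalizer(np.array([[2.0], [4.0], [6.0]]), ["m"])
        assert p.means[0] == pytest.approx(4.0)
        assert p.sds[0] == pytest.approx(2.0)  # n-1 denominator

    def test_training_column_z_scores_to_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5.0, 3.0, size=(40, 2))
        p = fit_normalizer(X)
        Z = (X - p.means) / p.sds
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_constant_column_is_a_degenerate_metric(self):
        with pytest.raises(DegenerateMetricError, match="m0"):
            fit_normalizer(np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]), ["m0", "m1"])

    def test_single_row_rejected(self):
        with pytest.raises(InputError):
            fit_normalizer(np.array([[1.0, 2.0]]))

    def test_normalize_hand_value_and_round_trip(self):
        p = NormalizationParams(("m",), np.array([10.0]), np.array([2.0]))
        z = normalize([14.0], p)
        assert z[0] == pytest.approx(2.0)
        assert z[0] * p.sds[0] + p.means[0] == pytest.approx(14.0, abs=1e-12)

    def test_normalize_rejects_unknown_names(self):
        p = NormalizationParams(("m",), np.array([0.0]), np.array([1.0]))
        with pytest.raises(SchemaError):
            normalize({"other": 1.0}, p)


class TestTrainSVM:
    def make_separable_1d(self, seed=0):
        rng = np.random.default_rng(seed)
        z = np.concatenate(
            [rng.normal(-1.0, 0.01, 20), rng.normal(1.0, 0.01, 20)]
        )[:, None]
        y = np.array([1] * 20 + [-1] * 20)
        return z, y

    def test_separable_1d_trains_to_perfect_accuracy_with_negative_weight(self):
        z, y = self.make_separable_1d()
        model = train_svm(z, y)
        assert model.weights[0] < 0
        pred = np.sign(z @ model.weights + model.bias)
        assert np.all(pred == y)

    def test_label_flip_negates_weights_and_bias_exactly(self):
        z, y = self.make_separable_1d()
        m1 = train_svm(z, y)
        m2 = train_svm(z, -y)
        assert np.array_equal(m2.weights, -m1.weights)
        assert m2.bias == -m1.bias

    def test_training_is_deterministic(self):
        z, y = self.make_separable_1d()
        m1 = train_svm(z, y, SVMConfig(seed=7))
        m2 = train_svm(z, y, SVMConfig(seed=7))
        assert np.array_equal(m1.weights, m2.weights) and m1.bias == m2.bias

    def test_single_class_rejected(self):
        z = np.zeros((4, 1))
        with pytest.raises(TrainingError):
            train_svm(z, np.ones(4, dtype=int))

    def test_objective_decreases_from_start_to_finish(self):
        z, y = self.make_separable_1d()
        _, _, obj = pegasos(z, y, C=1.0, iterations=500)
        assert obj[-1] < obj[0]
        # after burn-in, excursions above the running minimum stay small
        run_min = np.minimum.accumulate(obj)
        assert np.all(obj[50:] - run_min[50:] <= 0.05 * obj[0])

    def test_agrees_with_independent_svm_on_separable_data(self):
        """Cross-check against scikit-learn's LinearSVC decision direction."""
        from sklearn.svm import LinearSVC

        rng = np.random.default_rng(3)
        Z = np.vstack(
            [rng.normal(-2.0, 0.5, size=(30, 2)), rng.normal(2.0, 0.5, size=(30, 2))]
        )
        y = np.array([1] * 30 + [-1] * 30)
        ours = train_svm(Z, y)
        ref = LinearSVC(C=1.0, loss="hinge", max_iter=20000).fit(Z, y)
        ours_pred = np.sign(Z @ ours.weights + ours.bias)
        assert np.all(ours_pred == ref.predict(Z))
        cos = np.dot(ours.weights, ref.coef_[0]) / (
            np.linalg.norm(ours.weights) * np.linalg.norm(ref.coef_[0])
        )
        assert cos > 0.95

    def test_parameter_recovery_of_generative_direction(self):
        """Hyperplane direction aligns with the generative weights (gap >= 3 sd)."""
        w_true = np.array([2.0, -1.0, 0.5])
        w_unit = w_true / np.linalg.norm(w_true)
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 200
            y = np.repeat([1, -1], n // 2)
            Z = rng.normal(size=(n, 3)) + 1.5 * y[:, None] * w_unit[None, :]
            model = train_svm(Z, y, SVMConfig(iterations=2000))
            cos = np.dot(model.weights, w_unit) / np.linalg.norm(model.weights)
            assert cos >= 0.95


class TestLOOCV:
    def test_confusion_arithmetic_matches_brute_force_counting(self):
        rng = np.random.default_rng(1)
        table = two_group_table(rng, n_per_group=8, gap=1.0)
        result = loocv(table, config=SVMConfig(iterations=200))
        c = result.confusion
        assert c["skilled->skilled"] + c["skilled->novice"] == 8
        assert c["novice->novice"] + c["novice->skilled"] == 8
        total_correct = c["skilled->skilled"] + c["novice->novice"]
        assert result.accuracy_pct == pytest.approx(100.0 * total_correct / 16)
        assert result.sensitivity_pct == pytest.approx(
            100.0 * c["skilled->skilled"] / 8
        )
        assert result.specificity_pct == pytest.approx(100.0 * c["novice->novice"] / 8)

    def test_separable_table_is_perfectly_classified(self):
        rng = np.random.default_rng(2)
        table = two_group_table(rng, n_per_group=10, gap=8.0)
        assert loocv(table, config=SVMConfig(iterations=300)).accuracy_pct == 100.0

    def test_held_out_member_does_not_influence_its_fold(self):
        """Fold-wise recomputation: corrupting the held-out row must not change
        the fold's normalization or weights, hence not its prediction."""
        rng = np.random.default_rng(4)
        table = two_group_table(rng, n_per_group=6, gap=3.0)
        X, y, _ = learning.table_to_arrays(table)
        config = SVMConfig(iterations=200)

        def fold_fit(X, i):
            mask = np.ones(len(X), dtype=bool)
            mask[i] = False
            means = X[mask].mean(axis=0)
            sds = X[mask].std(axis=0, ddof=1)
            Z = (X[mask] - means) / sds
            w, b, _ = pegasos(Z, y[mask], config.C, config.iterations)
            return means, sds, w, b

        i = 3
        base = fold_fit(X, i)
        X_corrupt = X.copy()
        X_corrupt[i] += 1e6  # held-out member moved far away
        corrupted = fold_fit(X_corrupt, i)
        for a, b_ in zip(base, corrupted):
            np.testing.assert_array_equal(a, b_)

    def test_needs_three_members_and_both_classes(self):
        with pytest.raises(CohortError):
            loocv(np.zeros((2, 1)), np.array([1, -1]))
        with pytest.raises(CohortError):
            loocv(np.random.default_rng(0).normal(size=(5, 1)), np.ones(5, dtype=int))

    def test_singleton_class_reports_fold_error(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(5, 1))
        y = np.array([1, -1, -1, -1, -1])
        result = loocv(X, y, SVMConfig(iterations=50))
        assert len(result.fold_errors) == 1
        assert "single class" in result.fold_errors[0]


class TestCVResultArithmetic:
    def test_published_confusion_counts_reproduce_reported_rates(self):
        r = CVResult.from_counts(
            skilled_correct=28, skilled_total=28, novice_correct=18, novice_total=22
        )
        assert r.accuracy_pct == pytest.approx(92.0)
        assert r.sensitivity_pct == pytest.approx(100.0)
        assert round(r.specificity_pct, 1) == 81.8
        assert round(r.specificity_pct) == 82

    def test_counts_must_be_consistent(self):
        with pytest.raises(InputError):
            CVResult.from_counts(29, 28, 0, 22)


class TestSelection:
    def test_single_candidate_is_selected_with_unit_trace(self):
        rng = np.random.default_rng(6)
        table = two_group_table(rng, n_per_group=8, gap=4.0, k=1)
        trace = select_metrics(table, config=SelectionConfig(SVMConfig(iterations=100)))
        assert trace.selected == ("m0",)
        assert len(trace.entries) == 1
        assert trace.entries[0]["phase"] == "forward"

    def test_final_accuracy_equals_max_over_trace(self):
        from voa.experiments import informative_noise_table

        table = informative_noise_table(0, n_per_group=12)
        trace = select_metrics(table, config=SelectionConfig(SVMConfig(iterations=150)))
        assert trace.selected_accuracy_pct == max(
            e["accuracy_pct"] for e in trace.entries
        )

    def test_forward_adds_a_metric_that_completes_the_separation(self):
        """Neither diagonal coordinate separates the groups alone, but their
        difference does: the forward phase must add the second metric."""
        n = 8
        skilled = np.column_stack([np.arange(n), np.arange(n)]).astype(float)
        novice = np.column_stack([np.arange(n) + 2.0, np.arange(n).astype(float)])
        X = np.vstack([skilled, novice])
        noise = np.tile([1.0, -1.0], n)[:, None]  # label-independent wiggle
        table = pd.DataFrame(
            np.hstack([X, noise]), columns=["diag_a", "diag_b", "wiggle"]
        )
        table.insert(0, "group", ["skilled"] * n + ["novice"] * n)
        trace = select_metrics(table, config=SelectionConfig(SVMConfig(iterations=300)))
        assert {"diag_a", "diag_b"} <= set(trace.selected)
        assert trace.selected_accuracy_pct == 100.0

    def test_empty_candidate_set_rejected(self):
        from voa.errors import SelectionError

        with pytest.raises(SelectionError):
            select_metrics(np.zeros((4, 0)), np.array([1, 1, -1, -1]), columns=[])


class TestModelIO:
    def make_model(self):
        rng = np.random.default_rng(8)
        norm = NormalizationParams(
            ("a", "b"), rng.normal(size=2), np.abs(rng.normal(size=2)) + 0.5
        )
        return learning.LinearModel(
            metric_names=("a", "b"),
            categories=("safety", "movement"),
            weights=rng.normal(size=2),
            bias=float(rng.normal()),
            normalization=norm,
            training_meta={"C": 1.0},
        )

    def test_save_load_round_trip_compares_equal(self, tmp_path):
        model = self.make_model()
        path = tmp_path / "model.json"
        save_model(model, path)
        assert load_model(path) == model

    def test_missing_weight_is_a_schema_error(self, tmp_path):
        import json

        model = self.make_model()
        path = tmp_path / "model.json"
        save_model(model, path)
        doc = json.loads(path.read_text())
        doc["weights"] = doc["weights"][:-1]
        path.write_text(json.dumps(doc))
        with pytest.raises(SchemaError):
            load_model(path)

    def test_schema_version_mismatch_rejected(self, tmp_path):
        import json

        model = self.make_model()
        path = tmp_path / "model.json"
        save_model(model, path)
        doc = json.loads(path.read_text())
        doc["schema_version"] = "voa-model/99"
        path.write_text(json.dumps(doc))
        with pytest.raises(SchemaError):
            load_model(path)

    def test_reference_model_carries_the_published_weights(self):
        model = load_reference_model()
        np.testing.assert_allclose(
            model.weights, [-0.6002, -0.5106, -1.4902, -0.2710], atol=0
        )
        assert model.metric_names[0] == "Max Force w/ Bipolar"
        assert model.categories == ("safety", "safety", "movement", "movement")
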