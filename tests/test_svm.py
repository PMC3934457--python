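"""Kernel SVM: dual feasibility, closed-form and QP oracles, multiclass voting."""

import numpy as np
import pytest
from scipy.optimize import minimize

from pulsewave.core import PulseLabel
from pulsewave.kernels import KernelParams
from pulsewave.metrics import ElasticParams
from pulsewave.svm import (
    SVMModel,
    decision_value,
    dual_objective,
    load_model,
    model_alphas,
    nn_classify,
    nn_predict_from_matrix,
    predict,
    predict_from_rows,
    save_model,
    train_binary_svm,
    train_multiclass,
    train_multiclass_from_gram,
)


def qp_oracle(K, y, C):
    """Independent dual solve (SLSQP) for small problems."""
    n = len(y)
    Q = (np.outer(y, y)) * K

    def neg_obj(a):
        return -(a.sum() - 0.5 * a @ Q @ a)

    res = minimize(
        neg_obj,
        x0=np.full(n, min(C, 1.0) / 2),
        jac=lambda a: -(np.ones(n) - Q @ a),
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    return -res.fun


def random_psd_gram(rng, n):
    X = rng.normal(0, 1, (n, 4))
    D2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    K = np.exp(-D2 / (2 * np.median(D2)))
    np.fill_diagonal(K, 1.0)
    return K


class TestBinarySvm:
    def test_two_point_closed_form(self):
        """K12=0.5, large C: alpha = 1/(1-K12) = 2 for both points, b = 0."""
        K = np.array([[1.0, 0.5], [0.5, 1.0]])
        y = np.array([1, -1])
        model = train_binary_svm(K, y, C=1e5)
        alphas = model_alphas(model, 2)
        np.testing.assert_allclose(alphas, [2.0, 2.0], atol=1e-3)
        assert model.bias == pytest.approx(0.0, abs=1e-3)
        # f(x1) = 2*1 - 2*0.5 + 0 = 1
        row = K[model.support, 0]
        assert decision_value(model, row) == pytest.approx(1.0, abs=1e-3)

    def test_inseparable_duplicate_hits_box_bound(self):
        """Identical points with opposite labels: both multipliers at C."""
        K = np.ones((2, 2))
        y = np.array([1, -1])
        model = train_binary_svm(K, y, C=0.5)
        np.testing.assert_allclose(np.abs(model.coef), [0.5, 0.5], atol=1e-6)

    def test_dual_feasibility_on_random_problems(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 10))
            K = random_psd_gram(rng, n)
            y = np.where(rng.random(n) < 0.5, 1, -1)
            if len(set(y)) < 2:
                y[0] = -y[1]
            C = float(rng.choice([0.1, 1.0, 10.0, 100.0]))
            model = train_binary_svm(K, y, C)
            alphas = model_alphas(model, n)
            assert (alphas >= -1e-8).all() and (alphas <= C + 1e-8).all()
            assert abs(alphas @ y) <= 1e-6 * max(1.0, C)

    def test_dual_objective_matches_qp_oracle(self, rng):
        """Solver's achieved dual objective vs an independent SLSQP solve."""
        for _ in range(30):
            n = int(rng.integers(4, 7))
            K = random_psd_gram(rng, n)
            y = np.where(rng.random(n) < 0.5, 1, -1)
            if len(set(y)) < 2:
                y[0] = -y[1]
            C = float(rng.choice([1.0, 10.0]))
            model = train_binary_svm(K, y, C, tol=1e-6)
            achieved = dual_objective(model_alphas(model, n), y, K)
            target = qp_oracle(K, y, C)
            assert achieved == pytest.approx(target, abs=1e-5 * max(1.0, abs(target)))

    def test_free_support_vector_has_unit_margin(self, rng):
        K = random_psd_gram(rng, 12)
        y = np.array([1] * 6 + [-1] * 6)
        model = train_binary_svm(K, y, C=10.0, tol=1e-6)
        alphas = model_alphas(model, 12)
        free = [i for i in model.support if 1e-6 < alphas[i] < 10.0 - 1e-6]
        for i in free:
            val = decision_value(model, K[model.support, i])
            assert np.sign(val) == y[i]
            assert abs(val) >= 1 - 1e-3

    def test_single_class_rejected(self):
        with pytest.raises(Exception, match="both classes"):
            train_binary_svm(np.eye(3), [1, 1, 1], C=1.0)

    def test_empty_expansion_decision_is_bias(self):
        model = SVMModel(coef=np.array([]), bias=0.7, support=np.array([]), C=1.0)
        assert decision_value(model, []) == 0.7

    def test_row_length_mismatch(self, rng):
        K = random_psd_gram(rng, 4)
        model = train_binary_svm(K, [1, 1, -1, -1], C=1.0)
        with pytest.raises(Exception, match="support"):
            decision_value(model, np.zeros(len(model.support) + 1))

    def test_separable_case_zero_training_error(self, rng):
        # two well-separated blobs under an RBF-style Gram
        X = np.concatenate([rng.normal(-5, 0.3, (10, 3)), rng.normal(5, 0.3, (10, 3))])
        D2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
        K = np.exp(-D2 / (2 * np.median(D2)))
        y = np.array([1] * 10 + [-1] * 10)
        model = train_binary_svm(K, y, C=1e5)
        preds = [np.sign(decision_value(model, K[model.support, i])) for i in range(20)]
        np.testing.assert_array_equal(preds, y)


class TestMulticlass:
    def test_training_set_accuracy_on_easy_data(self, small_dataset):
        kp = KernelParams(sigma=10.0, elastic=ElasticParams(lam=1e-2, nu=0.25))
        model = train_multiclass(small_dataset, kp, C=100.0)
        correct = 0
        for i, period in enumerate(small_dataset.periods):
            if predict(model, period).category == small_dataset.labels[i].category:
                correct += 1
        assert correct / len(small_dataset) >= 0.95

    def test_two_class_reduces_to_binary(self, rng):
        K = random_psd_gram(rng, 12)
        labels = ["moderate"] * 6 + ["taut"] * 6
        mc = train_multiclass_from_gram(K, labels, C=10.0)
        assert len(mc.machines) == 1
        binary = mc.machines[("moderate", "taut")]
        rows = K[:, binary.support]
        dec = rows @ binary.coef + binary.bias
        expected = np.where(dec >= 0, "moderate", "taut")
        assert predict_from_rows(mc, K) == expected.tolist()

    def test_pair_count_matches_class_count(self, small_dataset):
        kp = KernelParams(sigma=10.0)
        model = train_multiclass(small_dataset, kp, C=10.0)
        assert len(model.machines) == 5 * 4 // 2

    def test_deterministic_training(self, small_dataset):
        kp = KernelParams(sigma=10.0)
        m1 = train_multiclass(small_dataset, kp, C=10.0)
        m2 = train_multiclass(small_dataset, kp, C=10.0)
        p1 = [predict(m1, p).category for p in small_dataset.periods[:10]]
        p2 = [predict(m2, p).category for p in small_dataset.periods[:10]]
        assert p1 == p2

    def test_serialization_roundtrip_preserves_predictions(self, tmp_path, small_dataset):
        kp = KernelParams(sigma=10.0, elastic=ElasticParams(lam=1e-2, nu=0.25))
        model = train_multiclass(small_dataset, kp, C=100.0)
        from pulsewave.kernels import kernel_from_distance
        from pulsewave.metrics import cross_distance_matrix

        xs = [p.to_timeseries() for p in small_dataset.periods]
        rows = kernel_from_distance(
            cross_distance_matrix(xs[:8], xs, "twed", params=kp.elastic), kp.sigma
        )
        before = predict_from_rows(model, rows)
        save_model(model, tmp_path / "m.json")
        loaded = load_model(tmp_path / "m.json")
        assert predict_from_rows(loaded, rows) == before
        # a second save must be byte-identical
        save_model(model, tmp_path / "m2.json")
        assert (tmp_path / "m.json").read_bytes() == (tmp_path / "m2.json").read_bytes()


class TestNearestNeighbor:
    def test_training_sample_maps_to_own_label(self, small_dataset):
        z = small_dataset.periods[23]
        assert nn_classify(small_dataset, z, metric="ed") == small_dataset.labels[23]

    def test_tie_broken_by_lowest_index(self):
        import numpy as np

        from pulsewave.core import LabeledDataset, PulsePeriod

        a = PulsePeriod(values=np.zeros(150), label=PulseLabel("taut"))
        b = PulsePeriod(values=np.full(150, 2.0), label=PulseLabel("hollow"))
        ds = LabeledDataset(periods=[a, b], labels=[a.label, b.label])
        z = PulsePeriod(values=np.ones(150))
        assert nn_classify(ds, z, metric="ed") == PulseLabel("taut")

    def test_predictions_match_full_matrix_argmin(self, small_dataset):
        from pulsewave.metrics import cross_distance_matrix

        xs = [p.to_timeseries() for p in small_dataset.periods]
        params = ElasticParams(lam=1e-2, nu=0.25)
        D = cross_distance_matrix(xs[:10], xs, "twed", params=params)
        batch = nn_predict_from_matrix(D, small_dataset.label_strings)
        single = [
            nn_classify(small_dataset, p, metric="twed", params=params).category
            for p in small_dataset.periods[:10]
        ]
        assert batch == single

    def test_identity_accuracy_under_every_metric(self, small_dataset):
        from pulsewave.metrics import pairwise_distance_matrix

        xs = [p.to_timeseries() for p in small_dataset.periods]
        y = small_dataset.label_strings
        for metric in ("twed", "erp", "ed"):
            D = pairwise_distance_matrix(
                xs, metric, params=ElasticParams(1e-2, 0.25)
            )
            assert nn_predict_from_matrix(D, y) == y
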