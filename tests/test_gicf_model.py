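"""The group-instance cost function: scoring, cost terms, gradient, training."""

import numpy as np
import pytest
import scipy.sparse as sp

from regionfp.feature_space import FeatureSpace, SimilarityKernel
from regionfp.gicf_model import (
    GICFModel,
    LabelSet,
    OptimizerConfig,
    add_intercept,
    aggregate_protein,
    cost,
    fit,
    gradient,
    load_model,
    predict,
    save_model,
    score_region,
    score_regions,
    seed_theta,
    stable_sigmoid,
)

from conftest import make_toy_model


def make_kernel(values):
    return SimilarityKernel(FeatureSpace.KEY, 0.0, sp.csr_matrix(values))


def random_instance(rng, n_proteins=3, n_regions=7, dim=5):
    """A dense random small instance for gradient checks."""
    X = add_intercept(sp.csr_matrix(rng.normal(size=(n_regions, dim))))
    theta = rng.normal(scale=0.5, size=dim + 1)
    raw = rng.random((n_regions, n_regions))
    K = (raw + raw.T) / 2
    K[K < 0.4] = 0.0
    np.fill_diagonal(K, 1.0)
    splits = np.sort(rng.choice(np.arange(1, n_regions), size=n_proteins - 1,
                                replace=False))
    groups = np.split(np.arange(n_regions), splits)
    labels = LabelSet(
        protein_labels={f"P{i}": int(rng.integers(2)) for i in range(n_proteins)},
        protein_regions={f"P{i}": list(map(int, g)) for i, g in enumerate(groups)},
        positive_regions=frozenset(
            int(i) for i in range(n_regions) if rng.random() < 0.3
        ),
    )
    model = GICFModel("GO:0003677", FeatureSpace.KEY, theta,
                      w1=rng.uniform(0.2, 2), w2=rng.uniform(0.2, 2),
                      lam=rng.uniform(0.0, 1.0))
    return model, X, make_kernel(K), labels


def numerical_gradient(model, X, kernel, labels, h=1e-6):
    theta = model.theta
    grad = np.zeros_like(theta)
    for i in range(theta.size):
        for sign in (+1, -1):
            shifted = theta.copy()
            shifted[i] += sign * h
            m = GICFModel(model.go_id, model.space, shifted,
                          model.w1, model.w2, model.lam)
            grad[i] += sign * cost(m, X, kernel, labels)
    return grad / (2 * h)


class TestScoring:
    def test_sigmoid_closed_forms(self):
        x = np.array([1.0, 0.0])
        assert score_region(np.zeros(2), x) == 0.5
        assert score_region(np.array([np.log(3), 0.0]), x) == pytest.approx(0.75)
        assert score_region(np.array([-np.log(3), 0.0]), x) == pytest.approx(0.25)

    def test_sigmoid_stable_at_extremes(self):
        assert stable_sigmoid(1e3) == pytest.approx(1.0)
        assert stable_sigmoid(-1e3) == pytest.approx(0.0)
        assert np.isfinite(stable_sigmoid(np.array([-1e4, 1e4]))).all()

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            score_region(np.zeros(3), np.zeros(2))

    @pytest.mark.parametrize("scores, expected",
                             [([0.2, 0.8], 0.8), ([0.5], 0.5), ([0.3, 0.3], 0.3)])
    def test_max_aggregation(self, scores, expected):
        assert aggregate_protein(scores) == expected

    def test_empty_aggregation_raises(self):
        with pytest.raises(ValueError):
            aggregate_protein([])


class TestCost:
    def test_single_region_theta_zero(self):
        # yhat = 0.5, Y = 1, no kernel pairs, no anchors, no ridge
        X = add_intercept(sp.csr_matrix(np.array([[1.0]])))
        labels = LabelSet({"P1": 1}, {"P1": [0]})
        model = make_toy_model(np.zeros(2))
        assert cost(model, X, None, labels) == pytest.approx(0.25, abs=1e-12)

    def test_two_region_hand_computed(self, two_region_instance):
        X, theta, kv, labels = two_region_instance
        model = make_toy_model(theta, w1=1.0)
        kernel = make_kernel(kv.toarray())
        # (0.8-1)^2 + (1/4) * 2 * (0.8-0.2)^2 = 0.04 + 0.18
        assert cost(model, X, kernel, labels) == pytest.approx(0.22, abs=1e-12)

    def test_perfect_hard_predictions_zero_cost(self):
        X = add_intercept(sp.csr_matrix(np.array([[1.0], [-1.0]])))
        theta = np.array([1e3, 0.0])
        labels = LabelSet({"P1": 1, "P2": 0}, {"P1": [0], "P2": [1]})
        model = make_toy_model(theta, w1=1.0)
        kernel = make_kernel(np.eye(2))
        assert cost(model, X, kernel, labels) == pytest.approx(0.0, abs=1e-12)

    def test_cost_nonnegative_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            model, X, kernel, labels = random_instance(rng)
            assert cost(model, X, kernel, labels) >= 0.0

    def test_kernel_diagonal_contributes_nothing(self):
        rng = np.random.default_rng(1)
        model, X, kernel, labels = random_instance(rng)
        no_diag = kernel.values.toarray().copy()
        np.fill_diagonal(no_diag, 0.0)
        assert cost(model, X, kernel, labels) == pytest.approx(
            cost(model, X, make_kernel(no_diag), labels), rel=1e-12
        )

    def test_empty_anchor_set_drops_term_three(self, two_region_instance):
        X, theta, kv, labels = two_region_instance
        a = cost(make_toy_model(theta, w2=5.0), X, None, labels)
        b = cost(make_toy_model(theta, w2=0.0), X, None, labels)
        assert a == b


class TestGradient:
    def test_matches_central_differences(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            model, X, kernel, labels = random_instance(rng)
            g = gradient(model, X, kernel, labels)
            g_num = numerical_gradient(model, X, kernel, labels)
            denom = max(np.linalg.norm(g_num), 1e-8)
            assert np.linalg.norm(g - g_num) / denom < 1e-5

    def test_uniform_scores_zero_smoothness_gradient(self):
        # theta = 0 makes every yhat equal, so term 2 vanishes exactly
        rng = np.random.default_rng(2)
        _, X, kernel, labels = random_instance(rng)
        base = GICFModel("GO:1", FeatureSpace.KEY,
                         np.zeros(X.shape[1]), w1=3.0, w2=0.0, lam=0.0)
        only_t2 = gradient(base, X, kernel,
                           LabelSet(dict.fromkeys(labels.protein_labels, 0),
                                    labels.protein_regions))
        # remove the (nonzero) term-1 part by subtracting the w1=0 gradient
        no_t2 = GICFModel("GO:1", FeatureSpace.KEY,
                          np.zeros(X.shape[1]), w1=0.0, w2=0.0, lam=0.0)
        t2_part = only_t2 - gradient(no_t2, X, kernel,
                                     LabelSet(dict.fromkeys(labels.protein_labels, 0),
                                              labels.protein_regions))
        assert np.allclose(t2_part, 0.0, atol=1e-12)

    def test_ridge_only_closed_form(self):
        rng = np.random.default_rng(3)
        model, X, kernel, labels = random_instance(rng)
        lam_model = GICFModel(model.go_id, model.space, model.theta,
                              w1=0.0, w2=0.0, lam=0.7)
        g = gradient(lam_model, X, None,
                     LabelSet(labels.protein_labels, labels.protein_regions))
        expected = 2 * 0.7 * lam_model.theta / labels.n_proteins
        expected[-1] = 0.0  # intercept excluded from the penalty
        # subtract the protein-fit part computed with lam = 0
        zero = GICFModel(model.go_id, model.space, model.theta,
                         w1=0.0, w2=0.0, lam=0.0)
        g0 = gradient(zero, X, None,
                      LabelSet(labels.protein_labels, labels.protein_regions))
        assert np.allclose(g - g0, expected, atol=1e-12)


class TestSeedTheta:
    def _matrix(self, X, ids):
        from regionfp.feature_space import FeatureMatrix

        return FeatureMatrix(FeatureSpace.KEY, ids,
                             [f"f{j}" for j in range(X.shape[1])],
                             sp.csr_matrix(X))

    def test_separable_data_perfect_training_aupr(self):
        X = np.array([[1.0, 0], [1, 0], [0, 1], [0, 1.0]])
        labels = {"A": 1, "B": 1, "C": 0, "D": 0}
        theta, lam = seed_theta(self._matrix(X, list(labels)), labels)
        scores = score_regions(theta, add_intercept(sp.csr_matrix(X)))
        assert scores[0] > scores[2] and scores[1] > scores[3]
        assert lam in (0.1, 1.0, 10.0, 100.0)

    def test_single_class_raises(self):
        X = np.eye(3)
        with pytest.raises(ValueError):
            seed_theta(self._matrix(X, ["A", "B", "C"]),
                       {"A": 1, "B": 1, "C": 1})

    def test_lam_grid_honored(self):
        X = np.array([[1.0, 0], [1, 0], [0, 1], [0, 1.0]])
        labels = {"A": 1, "B": 1, "C": 0, "D": 0}
        _, lam = seed_theta(self._matrix(X, list(labels)), labels,
                            lam_grid=(0.5,))
        assert lam == 0.5


class TestFit:
    def test_zero_learning_rate_leaves_theta(self):
        rng = np.random.default_rng(5)
        model, X, kernel, labels = random_instance(rng)
        cfg = OptimizerConfig(learning_rate=1e-12, max_epochs=3, seed=0)
        res = fit(model, X, kernel, labels, cfg)
        assert np.allclose(res.model.theta, model.theta, atol=1e-9)

    def test_training_reduces_cost_on_small_instance(self):
        rng = np.random.default_rng(6)
        model, X, kernel, labels = random_instance(rng, n_proteins=4,
                                                   n_regions=10)
        before = cost(model, X, kernel, labels)
        cfg = OptimizerConfig(learning_rate=0.5, max_epochs=60,
                              early_stop_patience=60, seed=0)
        res = fit(model, X, kernel, labels, cfg)
        assert min(res.loss_trace) < before

    def test_fit_is_seeded_and_reproducible(self):
        rng = np.random.default_rng(7)
        model, X, kernel, labels = random_instance(rng)
        cfg = OptimizerConfig(max_epochs=5, seed=11)
        a = fit(model, X, kernel, labels, cfg).model.theta
        b = fit(model, X, kernel, labels, cfg).model.theta
        assert np.array_equal(a, b)


class TestPredict:
    def test_protein_score_is_max_of_regions(self):
        rng = np.random.default_rng(8)
        model, X, kernel, labels = random_instance(rng)
        yhat = predict(model, X)
        agg = predict(model, X, labels, aggregate=True)
        for acc, idxs in labels.protein_regions.items():
            assert agg[acc] == yhat[idxs].max()

    def test_raising_region_score_never_lowers_protein_score(self):
        theta = np.array([1.0, 0.0])
        X1 = add_intercept(sp.csr_matrix(np.array([[0.0], [1.0]])))
        X2 = add_intercept(sp.csr_matrix(np.array([[0.0], [2.0]])))
        g = {"P": [0, 1]}
        m = make_toy_model(theta)
        assert predict(m, X2, g, aggregate=True)["P"] >= \
            predict(m, X1, g, aggregate=True)["P"]


def test_model_archive_round_trip(tmp_path):
    model = GICFModel("GO:0003677", FeatureSpace.KEY,
                      np.array([0.5, -1.0, 2.0]), w1=1.5, w2=0.5, lam=2.0,
                      vocabulary_hash="abc123", loss_trace=[0.3, 0.2])
    cfg = OptimizerConfig(seed=9)
    save_model(model, cfg, tmp_path / "m.json")
    loaded, loaded_cfg = load_model(tmp_path / "m.json")
    assert np.array_equal(loaded.theta, model.theta)
    assert (loaded.go_id, loaded.space, loaded.w1, loaded.lam) == \
        ("GO:0003677", FeatureSpace.KEY, 1.5, 2.0)
    assert loaded_cfg == cfg
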