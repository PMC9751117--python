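"""Attribution scores, cosine-distance matrices, and k-means score curves."""

import numpy as np
import pytest

from seq2exp.attribution import (
    AttributionVector,
    DistanceMatrix,
    attribute,
    attribute_set,
    attribution_distance_matrix,
    compare_models,
    hierarchical_order,
    kmeans_score_curve,
)
from seq2exp.encoders import encode_onehot_binary
from seq2exp.errors import CapabilityError, ValidationError
from seq2exp.experiment import stratified_sample
from seq2exp.models import CnnArchitecture, ModelSpec, fit


@pytest.fixture(scope="module")
def trained_models(small_partitions):
    split = small_partitions.splits[1]
    train = stratified_sample(split.train_pool, 300, 10, 17)
    X = encode_onehot_binary(list(train["sequence"]))
    y = train["fluorescence"].to_numpy()
    arch = CnnArchitecture((16, 16), (5, 3), (2, 1), (32,), 0.1)
    return {
        "cnn": fit(ModelSpec("cnn", {"architecture": arch}), X, y, 17),
        "mlp": fit(ModelSpec("mlp", {"hidden_layer_sizes": (32, 32)}), X, y, 17),
        "ridge": fit(ModelSpec("ridge", {"alpha": 1e-6}), X, y, 17),
        "rf": fit(ModelSpec("random_forest", {"n_estimators": 5}), X, y, 17),
        "test": split.test,
    }


class TestAttribute:
    def test_linear_model_scores_are_exact_contributions(self, trained_models):
        handle = trained_models["ridge"]
        seq = trained_models["test"]["sequence"].iloc[0]
        av = attribute(handle, seq)
        x = encode_onehot_binary([seq]).values[0]
        w = handle.backend.coef_.reshape(-1)
        manual = (w * x).reshape(-1, 4).sum(axis=1)
        assert np.allclose(av.scores, manual)

    def test_network_scores_have_sequence_length(self, trained_models):
        seq = trained_models["test"]["sequence"].iloc[0]
        for name in ("cnn", "mlp"):
            av = attribute(trained_models[name], seq)
            assert av.scores.shape == (len(seq),)
            assert np.all(np.isfinite(av.scores))

    def test_mlp_completeness_vs_blank_reference(self, trained_models):
        from seq2exp.models import predict

        handle = trained_models["mlp"]
        seqs = trained_models["test"]["sequence"].iloc[:20]
        X = encode_onehot_binary(list(seqs))
        f = predict(handle, X)
        f0 = handle.backend.predict(np.zeros((1, X.n_cols)))[0]
        for i, seq in enumerate(seqs):
            av = attribute(handle, seq)
            assert abs(av.scores.sum() - (f[i] - f0)) < 1e-3

    def test_tree_model_has_no_gradient_surface(self, trained_models):
        with pytest.raises(CapabilityError):
            attribute(trained_models["rf"], trained_models["test"]["sequence"].iloc[0])


class TestDistanceMatrix:
    def _vec(self, name, values):
        return AttributionVector(name, np.asarray(values, dtype=float))

    def test_identical_orthogonal_antiparallel(self):
        vs = [
            self._vec("a", [1, 0, 1, 0]),
            self._vec("b", [1, 0, 1, 0]),
            self._vec("c", [0, 1, 0, 1]),
            self._vec("d", [-1, 0, -1, 0]),
        ]
        dm = attribution_distance_matrix(vs)
        assert dm.D[0, 1] == pytest.approx(0.0)
        assert dm.D[0, 2] == pytest.approx(1.0)
        assert dm.D[0, 3] == pytest.approx(2.0)

    def test_zero_vector_rejected_by_name(self):
        vs = [self._vec("ok", [1, 0]), self._vec("blank", [0, 0])]
        with pytest.raises(ValidationError, match="blank"):
            attribution_distance_matrix(vs)

    def test_symmetry_zero_diagonal_range(self, trained_models):
        vectors = attribute_set(trained_models["cnn"], trained_models["test"].iloc[:15])
        dm = attribution_distance_matrix(vectors)
        assert np.allclose(dm.D, dm.D.T)
        assert np.allclose(np.diag(dm.D), 0.0)
        assert dm.D.min() >= 0.0 and dm.D.max() <= 2.0

    def test_matrix_must_be_symmetric(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [0.5, 0.0]]))


def _two_blob_matrix(n_per=6, gap=5.0, seed=0):
    rng = np.random.default_rng(seed)
    pts = np.vstack([
        rng.normal(0.0, 0.1, size=(n_per, 2)),
        rng.normal(gap, 0.1, size=(n_per, 2)),
    ])
    D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    ids = [f"x{i}" for i in range(2 * n_per)]
    return DistanceMatrix(ids, D)


class TestHierarchicalOrder:
    def test_two_items_deterministic(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert hierarchical_order(dm) == hierarchical_order(dm)

    def test_blobs_are_contiguous_in_leaf_order(self):
        dm = _two_blob_matrix()
        order = hierarchical_order(dm)
        labels = [int(i[1:]) < 6 for i in order]
        assert labels == sorted(labels) or labels == sorted(labels, reverse=True)

    def test_order_is_a_bijection(self, trained_models):
        vectors = attribute_set(trained_models["cnn"], trained_models["test"].iloc[:12])
        dm = attribution_distance_matrix(vectors)
        assert sorted(hierarchical_order(dm)) == sorted(dm.ids)


class TestKmeansCurve:
    def test_k_equals_n_scores_zero(self):
        dm = _two_blob_matrix(n_per=4)
        curve = kmeans_score_curve(dm, [8], n_inits=3, rng_seed=0)
        assert curve["mean_score"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_best_scores_non_increasing_in_k(self):
        dm = _two_blob_matrix(n_per=8, seed=2)
        curve = kmeans_score_curve(dm, range(2, 9), n_inits=20, rng_seed=0)
        best = curve["min_score"].to_numpy()
        assert np.all(np.diff(best) <= 1e-9 + 0.1 * best[:-1])

    def test_two_blobs_collapse_at_k2(self):
        dm = _two_blob_matrix(n_per=8, seed=3)
        curve = kmeans_score_curve(dm, [1, 2], n_inits=10, rng_seed=1)
        assert curve["mean_score"].iloc[1] < 0.2 * curve["mean_score"].iloc[0]

    def test_curve_deterministic_given_seed(self):
        dm = _two_blob_matrix(n_per=5, seed=4)
        a = kmeans_score_curve(dm, [2, 3], n_inits=5, rng_seed=9)
        b = kmeans_score_curve(dm, [2, 3], n_inits=5, rng_seed=9)
        assert a.equals(b)

    def test_k_above_n_rejected(self):
        dm = _two_blob_matrix(n_per=2)
        with pytest.raises(ValidationError):
            kmeans_score_curve(dm, [5], n_inits=2)


class TestCompareModels:
    def test_identical_models_identical_curves(self, trained_models):
        result = compare_models(
            trained_models["cnn"], trained_models["cnn"],
            trained_models["test"].iloc[:12], k_values=range(2, 6), n_inits=5,
        )
        assert result.curve_a.equals(result.curve_b)

    def test_smoke_run_populates_verdict(self, trained_models):
        result = compare_models(
            trained_models["cnn"], trained_models["mlp"],
            trained_models["test"].iloc[:15], k_values=range(2, 8), n_inits=5,
        )
        assert result.verdict in ("model_a_lower", "model_b_lower", "mixed")
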