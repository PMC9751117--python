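"""Model families, selection protocols, and parameter counting."""

import numpy as np
import pytest

from seq2exp import nn
from seq2exp.encoders import EncodedMatrix, encode_onehot_binary
from seq2exp.errors import ConfigurationError, ValidationError
from seq2exp.experiment import r_squared
from seq2exp.models import (
    CnnArchitecture,
    ModelSpec,
    consensus_grid_search,
    conv1d_param_count,
    dense_param_count,
    fit,
    parameter_count,
    predict,
    tpe_search_cnn,
)


def _toy_regression(n=60, d=8, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.random((n, d))
    w = rng.normal(size=d)
    y = X @ w * 0.1 + 0.4 + noise * rng.normal(size=n)
    return X, y


class TestFitPredict:
    def test_unknown_family_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelSpec("gradient_boost")

    def test_unknown_hyperparameter_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelSpec("ridge", {"alpha": 1.0, "kernel": "rbf"})

    def test_ridge_training_r2_nonnegative(self):
        X, y = _toy_regression(10)
        handle = fit(ModelSpec("ridge", {"alpha": 0.1}), X, y)
        assert r_squared(y, predict(handle, X)) >= 0.0

    def test_ridge_matches_closed_form_on_toy_problem(self):
        # 3 points, 1 feature: ridge solution w = Sxy / (Sxx + alpha)
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array([0.0, 1.0, 2.0])
        alpha = 1.0
        handle = fit(ModelSpec("ridge", {"alpha": alpha}), X, y)
        xc = X[:, 0] - X[:, 0].mean()
        yc = y - y.mean()
        w = (xc @ yc) / (xc @ xc + alpha)
        b = y.mean() - w * X[:, 0].mean()
        assert predict(handle, X) == pytest.approx(w * X[:, 0] + b)

    @pytest.mark.parametrize("family", ["ridge", "svr_rbf", "random_forest", "mlp"])
    def test_prediction_length_and_determinism(self, family):
        X, y = _toy_regression(50, seed=3)
        hp = {"n_estimators": 10} if family == "random_forest" else {}
        handle = fit(ModelSpec(family, hp), X, y, rng_seed=5)
        f1, f2 = predict(handle, X), predict(handle, X)
        assert len(f1) == 50 and np.array_equal(f1, f2)

    def test_dimension_mismatch_rejected(self):
        X, y = _toy_regression(20)
        handle = fit(ModelSpec("ridge"), X, y)
        with pytest.raises(ValidationError):
            predict(handle, np.zeros((3, 5)))

    def test_refit_with_same_seed_is_reproducible(self):
        X, y = _toy_regression(80, seed=9)
        a = fit(ModelSpec("mlp", {"hidden_layer_sizes": (8,)}), X, y, rng_seed=2)
        b = fit(ModelSpec("mlp", {"hidden_layer_sizes": (8,)}), X, y, rng_seed=2)
        assert np.array_equal(predict(a, X), predict(b, X))

    def test_cnn_converges_on_constant_target(self):
        rng = np.random.default_rng(1)
        seqs = ["".join(rng.choice(list("ACGT"), size=24)) for _ in range(150)]
        X = encode_onehot_binary(seqs)
        y = np.full(150, 0.42)
        arch = CnnArchitecture((8,), (5,), (2,), (8,), 0.0)
        handle = fit(ModelSpec("cnn", {"architecture": arch}), X, y, rng_seed=1)
        assert np.all(np.abs(predict(handle, X) - 0.42) < 0.01)

    def test_network_training_halts_within_100_epochs(self):
        X, y = _toy_regression(200, seed=4, noise=0.05)
        handle = fit(ModelSpec("mlp", {"hidden_layer_sizes": (8,)}), X, y)
        assert len(handle.backend.history["val_loss"]) <= 100


class TestParameterCount:
    def test_dense_layer(self):
        assert dense_param_count(10, 1) == 11

    def test_conv_layer(self):
        # 4 channels x width 3 x 8 filters + 8 biases
        assert conv1d_param_count(4, 8, 3) == 104

    def test_mlp_stack(self):
        # (384*64+64) + (64*64+64) + (64*64+64) + (64*1+1)
        assert parameter_count([384, 64, 64, 64, 1]) == 33_025

    def test_counts_agree_with_built_network(self):
        rng = np.random.default_rng(0)
        net = nn.build_mlp(384, hidden=(64, 64, 64), rng=rng)
        assert net.parameter_count() == parameter_count([384, 64, 64, 64, 1])
        arch = CnnArchitecture((8, 8), (5, 3), (2, 2), (16,), 0.0)
        cnn = nn.build_cnn(48, arch.conv_filters, arch.kernel_widths,
                           arch.pool_sizes, arch.dense_widths, 0.0, rng=rng)
        assert cnn.parameter_count() == parameter_count(arch, L=48)

    def test_underspecified_rejected(self):
        with pytest.raises(ValidationError):
            parameter_count([10])
        with pytest.raises(ValidationError):
            parameter_count(CnnArchitecture((4,), (9,), (1,), (4,)), L=6)


def _encoded(name, X):
    return EncodedMatrix("kmer_counts", X, L=X.shape[1], k=0) if False else X


class TestCnnVersusMlp:
    def test_cnn_mean_r2_at_least_mlp_on_switch_ground_truth(self):
        """Across five bimodal (switch-term) series at matched training data,
        the convolutional net's mean accuracy is not worse than the
        three-hidden-layer perceptron's (margin 0.02)."""
        from seq2exp.experiment import (
            PartitionSpec, make_partitions, mean_r2, monte_carlo_cv,
        )
        from seq2exp.synthetic import LibraryConfig, build_library

        cfg = LibraryConfig(
            n_series=5, variants_per_series=800, length=30, master_seed=31,
            shapes=("bimodal",),
        )
        lib = build_library(config=cfg)
        parts = make_partitions(
            lib, PartitionSpec(train_pool_size=None, validation_per_series=80, seed=31)
        )
        # conv stages sized to the 30-nt region (the L=96 default does not fit)
        arch = CnnArchitecture((64, 64), (5, 3), (1, 1), (64, 32), 0.0)
        cnn_scores, mlp_scores = [], []
        for sid in parts.series_ids:
            cnn_scores.append(mean_r2(monte_carlo_cv(
                ModelSpec("cnn", {"architecture": arch}), "onehot_binary",
                sid, 500, parts, n_repeats=1, rng_seed=31)))
            mlp_scores.append(mean_r2(monte_carlo_cv(
                ModelSpec("mlp"), "onehot_binary", sid, 500, parts,
                n_repeats=1, rng_seed=31)))
        assert np.mean(cnn_scores) >= np.mean(mlp_scores) - 0.02


class TestConsensusGridSearch:
    def _validation(self, seed=0, informative=True, n=60, d=6):
        rng = np.random.default_rng(seed)
        X = rng.random((n, d))
        w = rng.normal(size=d)
        y = X @ w * 0.2 + 0.4
        if not informative:
            X = rng.random((n, d))  # decouple X from y
        return X, y

    def test_single_point_grid(self):
        X, y = self._validation()
        enc = {"a": _FakeEnc(X)}
        cfg = consensus_grid_search("ridge", enc, y, {"alpha": [0.5]}, n_folds=3)
        assert cfg == {"alpha": 0.5}

    def test_unanimous_winner(self):
        X, y = self._validation()
        enc = {f"e{i}": _FakeEnc(X) for i in range(6)}
        cfg = consensus_grid_search(
            "ridge", enc, y, {"alpha": [1e-6, 1e3]}, n_folds=3
        )
        assert cfg == {"alpha": 1e-6}

    def test_tie_broken_by_held_out_mse(self):
        Xi, y = self._validation(seed=1, informative=True)
        Xn, _ = self._validation(seed=2, informative=False)
        enc = {"info": _FakeEnc(Xi), "noise": _FakeEnc(Xn)}
        cfg, details = consensus_grid_search(
            "ridge", enc, y, {"alpha": [1e-6, 1e4]}, n_folds=3, return_details=True
        )
        if details["tie"]:
            best = min(details["tie_mse"], key=details["tie_mse"].get)
            assert details["tie_mse"][best] == min(details["tie_mse"].values())
        assert set(cfg) == {"alpha"}

    def test_empty_grid_rejected(self):
        X, y = self._validation()
        with pytest.raises(ConfigurationError):
            consensus_grid_search("ridge", {"a": _FakeEnc(X)}, y, {})


class _FakeEnc:
    """Minimal stand-in exposing .values like an EncodedMatrix."""

    def __init__(self, values):
        self.values = values


class TestTpeSearch:
    def _onehot_task(self, seed=0, n=160, L=24):
        rng = np.random.default_rng(seed)
        seqs = ["".join(rng.choice(list("ACGT"), size=L)) for _ in range(n)]
        X = encode_onehot_binary(seqs)
        # target depends on base composition in a window: learnable by a CNN
        y = np.array([(s[4:16].count("G") + s.count("A") / 4) / 16 for s in seqs])
        return X, y

    space_single = {
        "conv_filters": [(4,)],
        "kernel_widths": [(3,)],
        "pool_sizes": [(2,)],
        "dense_widths": [(8,)],
        "dropout_rate": [0.0],
    }

    def test_single_trial_returns_the_sampled_architecture(self):
        X, y = self._onehot_task()
        arch = tpe_search_cnn(
            X, y, self.space_single, n_trials=1, n_iterations=1,
            fit_kwargs={"max_epochs": 3},
        )
        assert arch == CnnArchitecture((4,), (3,), (2,), (8,), 0.0)

    def test_returned_candidate_minimizes_held_out_mse(self):
        X, y = self._onehot_task(seed=1)
        space = dict(self.space_single, dense_widths=[(4,), (8,)])
        best, candidates = tpe_search_cnn(
            X, y, space, n_trials=2, n_iterations=2,
            fit_kwargs={"max_epochs": 5}, return_candidates=True,
        )
        assert len(candidates) == 2
        assert best == min(candidates, key=lambda c: c[1])[0]

    def test_prefers_capacity_when_it_clearly_helps(self):
        # 24-filter first layer fits the composition task far better than 1 filter
        space = {
            "conv_filters": [(1,), (24,)],
            "kernel_widths": [(5,)],
            "pool_sizes": [(2,)],
            "dense_widths": [(16,)],
            "dropout_rate": [0.0],
        }
        wins = 0
        for seed in range(6):
            X, y = self._onehot_task(seed=seed, n=120)
            arch = tpe_search_cnn(
                X, y, space, n_trials=6, n_iterations=1, rng_seed=seed,
                n_startup=4, fit_kwargs={"max_epochs": 12},
            )
            wins += arch.conv_filters == (24,)
        assert wins > 3  # better than the uniform-sampling expectation
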