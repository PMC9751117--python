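"""Regressor families and hyperparameter-selection protocols.

Five families are exposed behind one fit/predict surface:

* ``ridge`` — L2-penalized linear regression (scikit-learn).
* ``svr_rbf`` — support vector regression with an RBF kernel (scikit-learn).
* ``random_forest`` — random forest regressor (scikit-learn).
* ``mlp`` — shallow multilayer perceptron (three hidden layers by default),
  trained in-package with Adam.
* ``cnn`` — convolutional network on binary one-hot input, trained
  in-package with MSE loss, batch size 64, step size 1e-3, Adam with no
  learning-rate schedule, at most 100 epochs and early stopping after 15
  epochs without validation-loss improvement.

Two selection protocols are provided.  ``consensus_grid_search`` picks, per
encoding, the grid point minimizing 10-fold cross-validated MSE on 90% of a
validation set, then settles on the most frequent configuration across the
six encodings (ties broken by MSE on the remaining 10%).
``tpe_search_cnn`` runs several independent Tree-of-Parzen-Estimators
searches over a categorical architecture space and returns the candidate
with the best MSE on the held-out 10% slice.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, asdict
from itertools import product
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from ._rand import STAGE_MODEL, STAGE_SEARCH, derive_int_seed, derive_rng
from .encoders import EncodedMatrix
from .errors import ConfigurationError, ValidationError
from . import nn

FAMILIES = ("ridge", "svr_rbf", "random_forest", "mlp", "cnn")

_SCHEMA: dict[str, set[str]] = {
    "ridge": {"alpha"},
    "svr_rbf": {"C", "gamma", "epsilon"},
    "random_forest": {"n_estimators", "max_depth", "min_samples_leaf", "max_features"},
    "mlp": {"hidden_layer_sizes", "dropout", "batch_size", "lr", "max_epochs", "patience"},
    "cnn": {
        "architecture", "batch_size", "lr", "max_epochs", "patience",
    },
}


@dataclass
class ModelSpec:
    family: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown model family {self.family!r}")
        extra = set(self.hyperparameters) - _SCHEMA[self.family]
        if extra:
            raise ConfigurationError(f"{self.family}: unknown hyperparameters {sorted(extra)}")


@dataclass
class CnnArchitecture:
    """Convolutional architecture: per-stage filters/kernels/pools, then dense widths."""

    conv_filters: tuple[int, ...] = (64, 128, 64)
    kernel_widths: tuple[int, ...] = (5, 5, 3)
    pool_sizes: tuple[int, ...] = (2, 2, 2)
    dense_widths: tuple[int, ...] = (128, 64, 32)
    dropout_rate: float = 0.2

    @property
    def n_conv_stages(self) -> int:
        return len(self.conv_filters)

    @property
    def n_dense_layers(self) -> int:
        return len(self.dense_widths) + 1  # + linear output layer

    def __post_init__(self) -> None:
        if not (len(self.conv_filters) == len(self.kernel_widths) == len(self.pool_sizes)):
            raise ConfigurationError("conv stage tuples must have equal length")


DEFAULT_CNN = CnnArchitecture()


@dataclass
class FittedModel:
    spec: ModelSpec
    backend: object
    encoding_name: str | None
    n_features: int
    L: int | None
    seed: int

    def describe(self) -> dict:
        return {
            "family": self.spec.family,
            "hyperparameters": {
                k: (asdict(v) if isinstance(v, CnnArchitecture) else v)
                for k, v in self.spec.hyperparameters.items()
            },
            "encoding": self.encoding_name,
            "n_features": self.n_features,
            "seed": self.seed,
        }


def _as_array(X) -> tuple[np.ndarray, str | None, int | None]:
    if isinstance(X, EncodedMatrix):
        return X.values, X.encoding_name, X.L
    return np.asarray(X, dtype=float), None, None


def fit(spec: ModelSpec, X, y, rng_seed: int = 0) -> FittedModel:
    """Fit one model; deterministic given ``rng_seed`` (within backend limits)."""
    values, enc_name, L = _as_array(X)
    y = np.asarray(y, dtype=float).reshape(-1)
    if values.shape[0] != len(y):
        raise ValidationError("rows(X) must equal len(y)")
    hp = dict(spec.hyperparameters)
    seed = derive_int_seed(rng_seed, STAGE_MODEL)
    if spec.family == "ridge":
        backend = Ridge(alpha=hp.get("alpha", 1.0)).fit(values, y)
    elif spec.family == "svr_rbf":
        backend = SVR(
            kernel="rbf",
            C=hp.get("C", 1.0),
            gamma=hp.get("gamma", "scale"),
            epsilon=hp.get("epsilon", 0.1),
        ).fit(values, y)
    elif spec.family == "random_forest":
        backend = RandomForestRegressor(
            n_estimators=hp.get("n_estimators", 100),
            max_depth=hp.get("max_depth", None),
            min_samples_leaf=hp.get("min_samples_leaf", 1),
            max_features=hp.get("max_features", 1.0),
            random_state=seed,
            n_jobs=1,
        ).fit(values, y)
    elif spec.family == "mlp":
        rng = derive_rng(rng_seed, STAGE_MODEL, 1)
        net = nn.build_mlp(
            values.shape[1],
            hidden=tuple(hp.get("hidden_layer_sizes", (64, 64, 64))),
            dropout=hp.get("dropout", 0.0),
            rng=rng,
        )
        net.fit(
            values, y, rng,
            batch_size=hp.get("batch_size", 64),
            lr=hp.get("lr", 1e-3),
            max_epochs=hp.get("max_epochs", 100),
            patience=hp.get("patience", 15),
        )
        backend = net
    elif spec.family == "cnn":
        if L is None:
            if values.shape[1] % 4 != 0:
                raise ValidationError("cnn requires binary one-hot input (4·L columns)")
            L = values.shape[1] // 4
        arch: CnnArchitecture = hp.get("architecture", DEFAULT_CNN)
        rng = derive_rng(rng_seed, STAGE_MODEL, 2)
        net = nn.build_cnn(
            L,
            conv_filters=arch.conv_filters,
            kernel_widths=arch.kernel_widths,
            pool_sizes=arch.pool_sizes,
            dense_widths=arch.dense_widths,
            dropout=arch.dropout_rate,
            rng=rng,
        )
        net.fit(
            values.reshape(len(y), L, 4), y, rng,
            batch_size=hp.get("batch_size", 64),
            lr=hp.get("lr", 1e-3),
            max_epochs=hp.get("max_epochs", 100),
            patience=hp.get("patience", 15),
        )
        backend = net
    else:  # pragma: no cover - guarded by ModelSpec
        raise ConfigurationError(spec.family)
    return FittedModel(spec, backend, enc_name, values.shape[1], L, seed)


def predict(handle: FittedModel, X) -> np.ndarray:
    """Finite predictions, one per row; inference is deterministic."""
    values, _, _ = _as_array(X)
    if values.shape[1] != handle.n_features:
        raise ValidationError(
            f"expected {handle.n_features} features, got {values.shape[1]}"
        )
    if handle.spec.family == "cnn":
        out = handle.backend.predict(values.reshape(len(values), handle.L, 4))
    elif handle.spec.family == "mlp":
        out = handle.backend.predict(values)
    else:
        out = handle.backend.predict(values)
    out = np.asarray(out, dtype=float).reshape(-1)
    if not np.all(np.isfinite(out)):
        raise ValidationError("non-finite predictions")
    return out


# ---------------------------------------------------------------------------
# hyperparameter selection


def _grid_points(grid: Mapping[str, Sequence]) -> list[dict]:
    if not grid:
        raise ConfigurationError("empty hyperparameter grid")
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in product(*(grid[k] for k in keys))]


def _cv_mse(spec: ModelSpec, X: np.ndarray, y: np.ndarray, n_folds: int, seed: int) -> float:
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    errs = []
    for tr, te in kf.split(X):
        handle = fit(spec, X[tr], y[tr], rng_seed=seed)
        f = predict(handle, X[te])
        errs.append(float(np.mean((y[te] - f) ** 2)))
    return float(np.mean(errs))


def consensus_grid_search(
    family: str,
    encoded_validation: Mapping[str, EncodedMatrix],
    y: np.ndarray,
    grid: Mapping[str, Sequence],
    n_folds: int = 10,
    rng_seed: int = 0,
    return_details: bool = False,
):
    """Consensus hyperparameter selection across encodings.

    ``encoded_validation`` maps encoding name → EncodedMatrix of the whole
    validation set.  Per encoding, the rows are split 90/10; each grid point
    is scored by ``n_folds``-fold cross-validated MSE on the 90% slice and
    the best point wins.  The final configuration is the mode over the
    per-encoding winners; a tie goes to the tied configuration with the
    lowest MSE on the held-out 10% slice (fit on the 90%).
    """
    points = _grid_points(grid)
    y = np.asarray(y, dtype=float).reshape(-1)
    rng = derive_rng(rng_seed, STAGE_SEARCH)
    n = len(y)
    perm = rng.permutation(n)
    cut = int(round(0.9 * n))
    idx90, idx10 = perm[:cut], perm[cut:]
    winners: list[int] = []
    for name in sorted(encoded_validation):
        X = encoded_validation[name].values
        scores = [
            _cv_mse(ModelSpec(family, p), X[idx90], y[idx90], n_folds,
                    derive_int_seed(rng_seed, STAGE_SEARCH, i))
            for i, p in enumerate(points)
        ]
        winners.append(int(np.argmin(scores)))
    counts = Counter(winners)
    top = counts.most_common()
    tied = [cfg for cfg, c in top if c == top[0][1]]
    details = {"winners": [points[w] for w in winners], "tie": len(tied) > 1, "tie_mse": {}}
    if len(tied) == 1:
        chosen = points[tied[0]]
        return (chosen, details) if return_details else chosen
    # tie-break: MSE on the remaining 10%, averaged over encodings
    best_cfg, best_mse = None, np.inf
    for cfg in tied:
        mses = []
        for name in sorted(encoded_validation):
            X = encoded_validation[name].values
            handle = fit(ModelSpec(family, points[cfg]), X[idx90], y[idx90], rng_seed)
            f = predict(handle, X[idx10])
            mses.append(float(np.mean((y[idx10] - f) ** 2)))
        mse = float(np.mean(mses))
        details["tie_mse"][cfg] = mse
        if mse < best_mse:
            best_cfg, best_mse = cfg, mse
    chosen = points[best_cfg]
    return (chosen, details) if return_details else chosen


# -- TPE architecture search ------------------------------------------------

DEFAULT_CNN_SPACE: dict[str, list] = {
    "conv_filters": [(32, 64, 32), (64, 128, 64), (32, 32, 32)],
    "kernel_widths": [(3, 3, 3), (5, 5, 3), (7, 5, 3)],
    "pool_sizes": [(1, 1, 1), (2, 2, 2)],
    "dense_widths": [(64, 32), (128, 64, 32), (64, 64, 64)],
    "dropout_rate": [0.0, 0.2, 0.4],
}


def _tpe_propose(
    space: Mapping[str, list],
    trials: list[tuple[dict, float]],
    rng: np.random.Generator,
    gamma: float = 0.25,
    n_candidates: int = 24,
) -> dict:
    """Categorical TPE: sample candidates from the 'good' density l(x) and
    rank by l(x)/g(x), with Laplace-smoothed per-dimension histograms."""
    losses = np.array([t[1] for t in trials])
    n_good = max(1, int(np.ceil(gamma * len(trials))))
    order = np.argsort(losses, kind="stable")
    good = [trials[i][0] for i in order[:n_good]]
    bad = [trials[i][0] for i in order[n_good:]] or good
    def densities(configs, key):
        opts = space[key]
        counts = np.ones(len(opts))  # Laplace smoothing
        for c in configs:
            counts[opts.index(c[key])] += 1
        return counts / counts.sum()
    best_cand, best_score = None, -np.inf
    for _ in range(n_candidates):
        cand, score = {}, 0.0
        for key, opts in space.items():
            lg = densities(good, key)
            bg = densities(bad, key)
            j = rng.choice(len(opts), p=lg)
            cand[key] = opts[j]
            score += np.log(lg[j]) - np.log(bg[j])
        if score > best_score:
            best_cand, best_score = cand, score
    return best_cand


def tpe_search_cnn(
    X_validation: EncodedMatrix | np.ndarray,
    y: np.ndarray,
    search_space: Mapping[str, list] | None = None,
    n_trials: int = 50,
    n_iterations: int = 5,
    rng_seed: int = 0,
    n_startup: int = 10,
    fit_kwargs: Mapping | None = None,
    return_candidates: bool = False,
):
    """Architecture search with independent TPE iterations.

    Each iteration runs ``n_trials`` trials on a 90% slice of the validation
    data (each trial trains a CNN and records its early-stopping validation
    MSE), yielding one candidate architecture; the candidate with the lowest
    MSE on the held-out 10% slice wins.  Budgets are scalable for desk-scale
    runs.
    """
    space = dict(search_space or DEFAULT_CNN_SPACE)
    if not space:
        raise ConfigurationError("empty search space")
    values, _, L = _as_array(X_validation)
    y = np.asarray(y, dtype=float).reshape(-1)
    rng = derive_rng(rng_seed, STAGE_SEARCH, 1)
    perm = rng.permutation(len(y))
    cut = int(round(0.9 * len(y)))
    idx90, idx10 = perm[:cut], perm[cut:]
    fit_kwargs = dict(fit_kwargs or {})

    def objective(cfg: dict, seed: int) -> float:
        arch = CnnArchitecture(**cfg)
        spec = ModelSpec("cnn", {"architecture": arch, **fit_kwargs})
        handle = fit(spec, values[idx90], y[idx90], rng_seed=seed)
        # trial objective: best validation loss reached during early stopping
        history = handle.backend.history.get("val_loss", [])
        if history:
            return float(min(history))
        return float(np.mean((y[idx90] - predict(handle, values[idx90])) ** 2))

    candidates: list[tuple[CnnArchitecture, float]] = []
    for it in range(n_iterations):
        it_rng = derive_rng(rng_seed, STAGE_SEARCH, 2, it)
        trials: list[tuple[dict, float]] = []
        for t in range(n_trials):
            if len(trials) < min(n_startup, n_trials):
                cfg = {k: opts[it_rng.choice(len(opts))] for k, opts in space.items()}
            else:
                cfg = _tpe_propose(space, trials, it_rng)
            loss = objective(cfg, derive_int_seed(rng_seed, STAGE_SEARCH, it, t))
            trials.append((cfg, loss))
        best_cfg = min(trials, key=lambda t: t[1])[0]
        arch = CnnArchitecture(**best_cfg)
        spec = ModelSpec("cnn", {"architecture": arch, **fit_kwargs})
        handle = fit(spec, values[idx90], y[idx90],
                     rng_seed=derive_int_seed(rng_seed, STAGE_SEARCH, it, n_trials))
        mse10 = float(np.mean((y[idx10] - predict(handle, values[idx10])) ** 2))
        candidates.append((arch, mse10))
    if not candidates:
        raise ConfigurationError("no candidates produced")
    best = min(candidates, key=lambda c: c[1])[0]
    return (best, candidates) if return_candidates else best


# ---------------------------------------------------------------------------
# parameter counting


def dense_param_count(n_in: int, n_out: int, bias: bool = True) -> int:
    return n_in * n_out + (n_out if bias else 0)


def conv1d_param_count(in_channels: int, filters: int, width: int, bias: bool = True) -> int:
    return in_channels * width * filters + (filters if bias else 0)


def parameter_count(spec, L: int = 96, in_channels: int = 4) -> int:
    """Exact trainable-parameter count.

    ``spec`` is either a sequence of layer widths (e.g. [384, 64, 64, 64, 1]
    for an MLP, biases included) or a :class:`CnnArchitecture`, in which case
    ``L`` fixes the flattened dimension entering the dense stack.
    """
    if isinstance(spec, CnnArchitecture):
        total, c, p = 0, in_channels, L
        for f, w, s in zip(spec.conv_filters, spec.kernel_widths, spec.pool_sizes):
            if p < w:
                raise ValidationError(f"architecture does not fit length {L}")
            total += conv1d_param_count(c, f, w)
            p = p - w + 1
            if s > 1:
                p //= s
            c = f
        if p < 1:
            raise ValidationError(f"architecture does not fit length {L}")
        dim = p * c
        for h in spec.dense_widths:
            total += dense_param_count(dim, h)
            dim = h
        total += dense_param_count(dim, 1)
        return total
    widths = list(spec)
    if len(widths) < 2:
        raise ValidationError("need at least input and output widths")
    return sum(dense_param_count(a, b) for a, b in zip(widths[:-1], widths[1:]))
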