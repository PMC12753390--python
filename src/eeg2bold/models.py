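"""Uniform train/predict adapters for the classical and neural model suites.

Classical families (logistic/linear, KNN, decision tree, random forest,
RBF-kernel SVM, gradient-boosted trees) wrap scikit-learn and XGBoost
estimators. Neural families (MLP, 1-D CNN on raw EEG windows, GRU,
transformer encoder) run on the in-repo numpy stack with Adam, ReLU hidden
activations, binary cross-entropy (classification) or mean squared error
(regression), and early stopping on the provided validation set.

All adapters share one contract: ``fit(spec, train, val)`` →
:class:`FittedModel`; ``predict(model, X)`` → ``increase``/``decrease``
labels or real values; deterministic given the spec seed and inputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from . import _nn
from .features import LABEL_DECREASE, LABEL_INCREASE, SupervisedSet

__all__ = ["ModelSpec", "FittedModel", "fit", "tune", "predict",
           "CLASSICAL_FAMILIES", "NEURAL_FAMILIES"]

CLASSIFICATION_FAMILIES = {"logistic", "knn", "dtree", "rforest", "svm",
                           "gboost", "mlp", "cnn1d", "gru", "transformer"}
REGRESSION_FAMILIES = {"linear", "knn", "dtree", "rforest", "svm", "gboost",
                       "mlp", "cnn1d", "gru", "transformer"}
NEURAL_FAMILIES = {"mlp", "cnn1d", "gru", "transformer"}
CLASSICAL_FAMILIES = (CLASSIFICATION_FAMILIES | REGRESSION_FAMILIES) - NEURAL_FAMILIES

# complexity-ordering keys for tie-breaking in tune(); lower = simpler
_COMPLEXITY_KEYS = ("n_neighbors", "max_depth", "n_estimators", "hidden_sizes")


@dataclass(frozen=True)
class ModelSpec:
    family: str
    task: str  # classification | regression
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")
        valid = (CLASSIFICATION_FAMILIES if self.task == "classification"
                 else REGRESSION_FAMILIES)
        if self.family not in valid:
            raise ValueError(f"family {self.family!r} is not valid for task "
                             f"{self.task!r}")


@dataclass
class FittedModel:
    spec: ModelSpec
    state: Any  # opaque fitted backend
    n_features: int
    training_summary: dict = field(default_factory=dict)

    @property
    def loss_curves(self) -> dict | None:
        return self.training_summary.get("curves")


def _encode_labels(y: np.ndarray) -> np.ndarray:
    return (np.asarray(y) == LABEL_INCREASE).astype(int)


def _decode_labels(y: np.ndarray) -> np.ndarray:
    return np.where(np.asarray(y).astype(int) == 1, LABEL_INCREASE, LABEL_DECREASE)


def _classical_estimator(spec: ModelSpec):
    hp = dict(spec.hyperparameters)
    cls = spec.task == "classification"
    if spec.family == "logistic":
        from sklearn.linear_model import LogisticRegression
        return LogisticRegression(max_iter=hp.pop("max_iter", 1000), **hp)
    if spec.family == "linear":
        from sklearn.linear_model import LinearRegression
        return LinearRegression(**hp)
    if spec.family == "knn":
        from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
        est = KNeighborsClassifier if cls else KNeighborsRegressor
        return est(n_neighbors=hp.pop("n_neighbors", 5), **hp)
    if spec.family == "dtree":
        from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor
        est = DecisionTreeClassifier if cls else DecisionTreeRegressor
        return est(max_depth=hp.pop("max_depth", None), random_state=spec.seed, **hp)
    if spec.family == "rforest":
        from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
        est = RandomForestClassifier if cls else RandomForestRegressor
        return est(n_estimators=hp.pop("n_estimators", 100),
                   random_state=spec.seed, **hp)
    if spec.family == "svm":
        from sklearn.svm import SVC, SVR
        if cls:
            return SVC(kernel=hp.pop("kernel", "rbf"), **hp)
        return SVR(kernel=hp.pop("kernel", "rbf"), **hp)
    if spec.family == "gboost":
        from xgboost import XGBClassifier, XGBRegressor
        est = XGBClassifier if cls else XGBRegressor
        return est(n_estimators=hp.pop("n_estimators", 100),
                   max_depth=hp.pop("max_depth", 6),
                   random_state=spec.seed, verbosity=0, **hp)
    raise ValueError(f"unknown classical family {spec.family!r}")


class _NeuralNet:
    """Forward-model wrapper holding layers and the input layout."""

    def __init__(self, spec: ModelSpec, n_features: int, input_shape: tuple[int, ...]):
        hp = spec.hyperparameters
        rng = np.random.default_rng(spec.seed)
        self.spec = spec
        self.input_shape = input_shape  # per-sample shape for structured nets
        fam = spec.family
        if fam == "mlp":
            sizes = tuple(hp.get("hidden_sizes", (64, 32)))
            dims = (n_features,) + sizes
            self.layers = [_nn.Dense(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
            self.head = _nn.Dense(dims[-1], 1, rng)
        elif fam == "cnn1d":
            c_in = input_shape[0]
            chans = hp.get("channels", (16, 32, 32))
            kernels = hp.get("kernels", (7, 5, 3))
            strides = hp.get("strides", (2, 2, 2))
            self.layers = []
            prev = c_in
            for c, k, s in zip(chans, kernels, strides):
                self.layers.append(_nn.Conv1d(prev, c, k, s, rng))
                prev = c
            self.head = _nn.Dense(prev, 1, rng)
        elif fam == "gru":
            width = hp.get("hidden_size", 64)
            self.layers = [_nn.GRU(input_shape[1], width, rng)]
            self.head = _nn.Dense(width, 1, rng)
        elif fam == "transformer":
            d_model = hp.get("d_model", 32)
            n_heads = hp.get("n_heads", 4)
            d_ff = hp.get("d_ff", 64)
            n_blocks = hp.get("n_blocks", 2)
            steps = input_shape[0]
            self.proj = _nn.Dense(input_shape[1], d_model, rng)
            self.pos = _nn.Tensor(rng.normal(0, 0.02, size=(steps, d_model)),
                                  requires_grad=True)
            self.layers = [_nn.TransformerEncoderBlock(d_model, n_heads, d_ff, rng)
                           for _ in range(n_blocks)]
            self.head = _nn.Dense(d_model, 1, rng)
        else:
            raise ValueError(f"unknown neural family {fam!r}")

    def parameters(self) -> list[_nn.Tensor]:
        params: list[_nn.Tensor] = []
        for layer in self.layers:
            params.extend(layer.parameters())
        params.extend(self.head.parameters())
        if hasattr(self, "proj"):
            params.extend(self.proj.parameters())
            params.append(self.pos)
        return params

    def _shape_input(self, x: np.ndarray) -> np.ndarray:
        if self.spec.family in ("cnn1d", "gru", "transformer"):
            return x.reshape((x.shape[0],) + self.input_shape)
        return x

    def forward(self, x: _nn.Tensor) -> _nn.Tensor:
        fam = self.spec.family
        if fam == "mlp":
            h = x
            for layer in self.layers:
                h = _nn.relu(layer(h))
            out = self.head(h)
        elif fam == "cnn1d":
            h = x
            for layer in self.layers:
                h = _nn.relu(layer(h))
            pooled = h.mean(axis=2)  # global average pool over time
            out = self.head(pooled)
        elif fam == "gru":
            out = self.head(self.layers[0](x))
        else:  # transformer
            h = self.proj(x) + self.pos
            for block in self.layers:
                h = block(h)
            out = self.head(h.mean(axis=1))
        return out.reshape(-1)


def _neural_input_shape(spec: ModelSpec, X: np.ndarray) -> tuple[int, ...]:
    hp = spec.hyperparameters
    if spec.family == "mlp":
        return (X.shape[1],)
    if spec.family == "cnn1d":
        if X.ndim == 3:  # samples × channels × time from build_raw_segments
            return X.shape[1:]
        n_channels = hp.get("n_channels")
        if n_channels is None:
            raise ValueError("cnn1d on flat features needs the 'n_channels' "
                             "hyperparameter to recover the channel axis")
        return (n_channels, X.shape[1] // n_channels)
    # gru / transformer: 6 lag steps × per-step features
    steps = hp.get("n_steps", 6)
    if X.shape[1] % steps != 0:
        raise ValueError(f"feature dimension {X.shape[1]} not divisible by "
                         f"{steps} time steps")
    return (steps, X.shape[1] // steps)


def fit(spec: ModelSpec, train: SupervisedSet, val: SupervisedSet | None = None) -> FittedModel:
    """Fit one model family on a supervised set.

    Neural families require a validation set (early stopping monitors its
    loss); classical families fit in a single pass and ignore ``val``.
    """
    if train.n_samples == 0:
        raise ValueError("training set is empty")
    y_train = train.y_class if spec.task == "classification" else train.y_reg
    if spec.task == "classification" and len(np.unique(y_train)) < 2:
        raise ValueError("degenerate training labels: only one class present")
    X = np.asarray(train.X, dtype=float)

    if spec.family in NEURAL_FAMILIES:
        if val is None:
            raise ValueError(f"neural family {spec.family!r} requires a "
                             f"validation set")
        hp = spec.hyperparameters
        net = _NeuralNet(spec, X.shape[1] if X.ndim == 2 else 0,
                         _neural_input_shape(spec, X))
        x_tr = net._shape_input(X)
        x_val = net._shape_input(np.asarray(val.X, dtype=float))
        if spec.task == "classification":
            y_tr = _encode_labels(train.y_class).astype(float)
            y_v = _encode_labels(val.y_class).astype(float)
            loss_fn = _nn.bce_with_logits
        else:
            y_tr = np.asarray(train.y_reg, dtype=float)
            y_v = np.asarray(val.y_reg, dtype=float)
            loss_fn = _nn.mse_loss
        curves = _nn.train_network(
            net.forward, net.parameters(), loss_fn, x_tr, y_tr, x_val, y_v,
            rng=np.random.default_rng(spec.seed + 1),
            lr=hp.get("lr", 1e-3), batch_size=hp.get("batch_size", 32),
            max_epochs=hp.get("max_epochs", 200),
            patience=hp.get("patience", 10))
        return FittedModel(spec, net, X.shape[-1] if X.ndim == 2 else -1,
                           {"curves": curves})

    est = _classical_estimator(spec)
    if spec.task == "classification":
        est.fit(X, _encode_labels(y_train))
    else:
        est.fit(X, np.asarray(y_train, dtype=float))
    return FittedModel(spec, est, X.shape[1])


def predict(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """Labels (classification) or real values (regression) for ``X``."""
    X = np.asarray(X, dtype=float)
    if model.spec.family in NEURAL_FAMILIES:
        net: _NeuralNet = model.state
        logits = net.forward(_nn.Tensor(net._shape_input(X))).data
        if model.spec.task == "classification":
            return _decode_labels(logits >= 0)
        return logits
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(f"feature dimension mismatch: expected "
                         f"{model.n_features}, got {X.shape}")
    out = model.state.predict(X)
    if model.spec.task == "classification":
        return _decode_labels(out)
    return np.asarray(out, dtype=float)


def _complexity_key(hp: dict[str, Any]) -> tuple:
    key = []
    for name in _COMPLEXITY_KEYS:
        value = hp.get(name)
        if value is None:
            key.append(np.inf)
        elif isinstance(value, (tuple, list)):
            key.append(float(sum(value)))
        else:
            key.append(float(value))
    return tuple(key)


def tune(spec: ModelSpec, grid: dict[str, list], train: SupervisedSet,
         val: SupervisedSet) -> ModelSpec:
    """Exhaustive grid search on validation accuracy (classification) or
    MAE (regression); exact ties go to the simplest model (fewest
    neighbors, shallowest tree).
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be non-empty")
    names = sorted(grid)
    points = [dict(zip(names, combo))
              for combo in itertools.product(*(grid[n] for n in names))]
    points.sort(key=_complexity_key)
    best_spec = None
    best_score = -np.inf
    for point in points:
        candidate = replace(spec, hyperparameters={**spec.hyperparameters, **point})
        fitted = fit(candidate, train,
                     val if candidate.family in NEURAL_FAMILIES else None)
        pred = predict(fitted, val.X)
        if spec.task == "classification":
            score = float(np.mean(pred == val.y_class))
        else:
            score = -float(np.mean(np.abs(pred - val.y_reg)))
        if score > best_score:  # strict: ties keep the earlier, simpler point
            best_score = score
            best_spec = candidate
    return best_spec
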