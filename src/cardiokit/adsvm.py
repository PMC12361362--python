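"""Adaptive deep SVM: a tuned feed-forward extractor feeding an RBF-kernel SVM.

The detector is trained in two stages.  First a feed-forward binary
classifier (two hidden layers of equal width, sigmoid output, binary
cross-entropy, Adam) is fit on the weighted features; its penultimate-layer
activations are the learned deep representation.  Second, an RBF-kernel SVM
is fit on those activations and provides the decision head, whose decision
function has the usual dual form

    d(f) = sum_e (mu_e - mu*_e) K(f_e, f) + k

over the support vectors.  Three extractor hyperparameters are exposed to the
metaheuristic: the learning rate in [0.01, 0.99], the per-layer hidden neuron
count in [5, 255], and an activation index in [1, 5] mapping to
{ReLU, sigmoid, tanh, leaky-ReLU, ELU}.  The tuning objective is
1/CSI + FPR on a stratified validation split — minimized, with a global
minimum of exactly 1 at a perfect classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.svm import SVC

from . import eavsro, metrics
from ._autodiff import Adam, Tensor, sigmoid, softplus
from .exceptions import (ConfigurationError, DataError, DegenerateTargetError,
                         MetricError, ShapeError)

__all__ = [
    "ACTIVATION_TABLE",
    "ADSVMHyperparams",
    "ExtractorSpec",
    "DeepFeatureExtractor",
    "SVMHead",
    "ADSVMModel",
    "HYPERPARAM_BOUNDS",
    "map_activation_index",
    "train_extractor",
    "extract_deep_features",
    "train_svm_head",
    "predict",
    "detection_fitness",
    "tune_adsvm",
]

#: activation index -> activation name (the tuned range is [1, 5])
ACTIVATION_TABLE = {1: "relu", 2: "sigmoid", 3: "tanh", 4: "leaky_relu", 5: "elu"}

#: search ranges of the three tuned hyperparameters
HYPERPARAM_BOUNDS = {
    "learning_rate": (0.01, 0.99),
    "hidden_neurons": (5, 255),
    "activation_index": (1, 5),
}

#: fitness assigned to candidates whose training fails
WORST_FITNESS = 1.0e9

_CSI_EPSILON = 1e-12


def map_activation_index(index: int) -> str:
    """Total, fixed mapping from the tuned integer gene to an activation."""
    index = int(index)
    if index not in ACTIVATION_TABLE:
        raise ConfigurationError(f"activation index {index} outside [1, 5]")
    return ACTIVATION_TABLE[index]


def _apply_activation(x: Tensor, name: str) -> Tensor:
    if name == "relu":
        return x.relu()
    if name == "sigmoid":
        return sigmoid(x)
    if name == "tanh":
        return x.tanh()
    if name == "leaky_relu":
        return x.leaky_relu()
    if name == "elu":
        return x.elu()
    raise ConfigurationError(f"unknown activation {name!r}")


@dataclass(frozen=True)
class ADSVMHyperparams:
    """The three tuned extractor hyperparameters."""

    learning_rate: float = 0.05
    hidden_neurons: int = 32
    activation_index: int = 1

    def __post_init__(self):
        lo, hi = HYPERPARAM_BOUNDS["learning_rate"]
        if not lo <= self.learning_rate <= hi:
            raise ConfigurationError(f"learning_rate outside [{lo}, {hi}]")
        lo, hi = HYPERPARAM_BOUNDS["hidden_neurons"]
        if not lo <= self.hidden_neurons <= hi:
            raise ConfigurationError(f"hidden_neurons outside [{lo}, {hi}]")
        map_activation_index(self.activation_index)

    @property
    def activation(self) -> str:
        return map_activation_index(self.activation_index)

    @classmethod
    def from_genes(cls, genes: np.ndarray) -> "ADSVMHyperparams":
        """Decode a 3-gene optimizer candidate (reals within the bounds)."""
        lr = float(np.clip(genes[0], *HYPERPARAM_BOUNDS["learning_rate"]))
        hidden = int(np.clip(np.rint(genes[1]), *HYPERPARAM_BOUNDS["hidden_neurons"]))
        act = int(np.clip(np.rint(genes[2]), *HYPERPARAM_BOUNDS["activation_index"]))
        return cls(learning_rate=lr, hidden_neurons=hidden, activation_index=act)


@dataclass(frozen=True)
class ExtractorSpec:
    """Architecture/training settings of the feed-forward extractor.

    Untuned defaults: batch size 16, base learning rate 0.001, binary
    cross-entropy loss, two equal hidden layers.
    """

    input_dim: int
    hidden_layers: tuple[int, ...] = (32, 32)
    activation: str = "relu"
    epochs: int = 300
    batch_size: int = 16
    learning_rate: float = 0.001
    patience: int = 30


class DeepFeatureExtractor:
    """Feed-forward binary classifier exposing its penultimate activations."""

    def __init__(self, spec: ExtractorSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        dims = [spec.input_dim, *spec.hidden_layers, 1]
        self.params: list[Tensor] = []
        self._weights: list[Tensor] = []
        self._biases: list[Tensor] = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            w = Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)),
                       requires_grad=True)
            b = Tensor(np.zeros((1, fan_out)), requires_grad=True)
            self._weights.append(w)
            self._biases.append(b)
            self.params.extend([w, b])
        self.final_loss: float | None = None

    def _forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (logits, penultimate activations)."""
        h = x
        for w, b in zip(self._weights[:-1], self._biases[:-1]):
            h = _apply_activation(h @ w + b, self.spec.activation)
        logits = h @ self._weights[-1] + self._biases[-1]
        return logits, h

    def logits(self, matrix: np.ndarray) -> np.ndarray:
        z, _ = self._forward(Tensor(matrix))
        return z.data.ravel()

    def predict(self, matrix: np.ndarray) -> np.ndarray:
        return (self.logits(matrix) > 0).astype(int)


def train_extractor(features, labels, hp: ADSVMHyperparams | None = None,
                    spec: ExtractorSpec | None = None, seed: int = 0,
                    validation=None) -> DeepFeatureExtractor:
    """Train the feed-forward extractor for a fixed epoch budget.

    ``features`` may be a raw matrix or a
    :class:`~cardiokit.feature_weighting.WeightedFeatureSet`.  When ``hp`` is
    given, its learning rate / width / activation override the spec defaults.
    ``validation`` is an optional ``(matrix, labels)`` pair used for early
    stopping (patience on validation loss); without it the full epoch budget
    runs.  Deterministic per seed.
    """
    x = np.asarray(getattr(features, "transformed", features), dtype=float)
    y = np.asarray(labels, dtype=float).reshape(-1, 1)
    if not np.all(np.isfinite(x)):
        raise DataError("extractor features contain non-finite values")
    if np.unique(y).size < 2:
        raise DegenerateTargetError("extractor training needs both classes present")

    if spec is None:
        spec = ExtractorSpec(input_dim=x.shape[1])
    if hp is not None:
        spec = replace(spec, hidden_layers=(hp.hidden_neurons, hp.hidden_neurons),
                       activation=hp.activation, learning_rate=hp.learning_rate)
    if spec.input_dim != x.shape[1]:
        raise ShapeError(f"spec input_dim {spec.input_dim} != feature dim {x.shape[1]}")

    rng = np.random.default_rng(seed)
    extractor = DeepFeatureExtractor(spec, seed=seed)
    optimizer = Adam(extractor.params, lr=spec.learning_rate)

    def bce(matrix: np.ndarray, target: np.ndarray) -> Tensor:
        logits, _ = extractor._forward(Tensor(matrix))
        # binary cross-entropy on logits: mean(softplus(z) - y*z)
        return (softplus(logits) - Tensor(target) * logits).mean()

    n = x.shape[0]
    best_val = np.inf
    stale = 0
    for _ in range(spec.epochs):
        order = rng.permutation(n)
        for start in range(0, n, spec.batch_size):
            batch = order[start:start + spec.batch_size]
            optimizer.zero_grad()
            loss = bce(x[batch], y[batch])
            loss.backward()
            optimizer.step()
        if validation is not None:
            val_loss = float(bce(np.asarray(validation[0], dtype=float),
                                 np.asarray(validation[1], dtype=float).reshape(-1, 1)).data)
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                stale = 0
            else:
                stale += 1
                if stale >= spec.patience:
                    break
    extractor.final_loss = float(bce(x, y).data)
    if not np.isfinite(extractor.final_loss):
        raise DataError("extractor training diverged to a non-finite loss")
    return extractor


def extract_deep_features(extractor: DeepFeatureExtractor,
                          matrix: np.ndarray) -> np.ndarray:
    """Penultimate-layer activations, one row per input row."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] != extractor.spec.input_dim:
        raise ShapeError(f"expected matrix with {extractor.spec.input_dim} columns")
    _, penultimate = extractor._forward(Tensor(matrix))
    return penultimate.data


@dataclass
class SVMHead:
    """RBF-kernel SVM decision head in dual form."""

    penalty: float
    kernel_width: float
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    _svc: SVC

    def decision_function(self, deep_features: np.ndarray) -> np.ndarray:
        return self._svc.decision_function(deep_features)

    def decision_function_dual(self, deep_features: np.ndarray) -> np.ndarray:
        """Explicit dual expansion sum_e (mu_e - mu*_e) K(f_e, f) + k;
        matches :meth:`decision_function` and exists to make the stored
        coefficients inspectable."""
        diff = deep_features[:, None, :] - self.support_vectors[None, :, :]
        kernel = np.exp(-self.kernel_width * np.sum(diff**2, axis=2))
        return kernel @ self.dual_coef + self.intercept

    def predict(self, deep_features: np.ndarray) -> np.ndarray:
        return self._svc.predict(deep_features).astype(int)


def train_svm_head(deep_features: np.ndarray, labels, penalty: float = 1.0,
                   kernel_width: float | None = None) -> SVMHead:
    """Fit the RBF-kernel SVM on the deep representation.

    ``kernel_width`` is the RBF gamma; the default is 1 / feature dimension.
    """
    deep_features = np.asarray(deep_features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not np.all(np.isfinite(deep_features)):
        raise DataError("deep features contain non-finite values")
    if np.unique(labels).size < 2:
        raise DegenerateTargetError("SVM training needs both classes present")
    gamma = kernel_width if kernel_width is not None else 1.0 / deep_features.shape[1]
    svc = SVC(kernel="rbf", C=penalty, gamma=gamma)
    svc.fit(deep_features, labels)
    return SVMHead(penalty=penalty, kernel_width=gamma,
                   support_vectors=svc.support_vectors_,
                   dual_coef=svc.dual_coef_.ravel(),
                   intercept=float(svc.intercept_[0]), _svc=svc)


@dataclass
class ADSVMModel:
    """Trained detector: extractor + SVM head + the tuned hyperparameters."""

    extractor: DeepFeatureExtractor
    head: SVMHead
    hyperparams: ADSVMHyperparams
    training_metrics: metrics.ConfusionCounts | None = None


def predict(model: ADSVMModel, matrix: np.ndarray) -> np.ndarray:
    """0/1 disease labels for each row of ``matrix``."""
    deep = extract_deep_features(model.extractor, matrix)
    return model.head.predict(deep)


def detection_fitness(counts: metrics.ConfusionCounts) -> float:
    """Tuning objective 1/CSI + FPR (minimized; >= 1, equality iff perfect).

    CSI = 0 (no true positives among the positives) is guarded with a small
    epsilon so the objective stays finite but heavily penalized.
    """
    if counts.tp + counts.fp + counts.fn == 0:
        raise MetricError("detection_fitness: CSI undefined (tp+fp+fn == 0)")
    csi_value = metrics.csi(counts)
    return 1.0 / (csi_value + _CSI_EPSILON) + metrics.fpr(counts)


def _fit_at(x_train, y_train, hp: ADSVMHyperparams, seed: int,
            epochs: int) -> tuple[DeepFeatureExtractor, SVMHead]:
    spec = ExtractorSpec(input_dim=x_train.shape[1], epochs=epochs)
    extractor = train_extractor(x_train, y_train, hp=hp, spec=spec, seed=seed)
    deep = extract_deep_features(extractor, x_train)
    head = train_svm_head(deep, y_train)
    return extractor, head


def tune_adsvm(features, labels, config: eavsro.OptimizerConfig | None = None,
               epochs: int = 100, val_fraction: float = 0.2) -> ADSVMModel:
    """Tune (learning rate, hidden neurons, activation) with the metaheuristic.

    The provided data is split internally into a stratified train/validation
    pair; every candidate trains on the train part and is scored with
    1/CSI + FPR on the validation part.  Candidates whose training fails
    (divergence, degenerate width, ...) receive a worst-possible fitness.
    The returned model is retrained at the best hyperparameters and carries
    the validation confusion counts.
    """
    from sklearn.model_selection import train_test_split

    if config is None:
        config = eavsro.OptimizerConfig()
    x = np.asarray(getattr(features, "transformed", features), dtype=float)
    y = np.asarray(labels, dtype=int)
    x_tr, x_val, y_tr, y_val = train_test_split(
        x, y, test_size=val_fraction, stratify=y, random_state=config.seed % (2**31))

    bounds = eavsro.Bounds(
        lower=np.array([HYPERPARAM_BOUNDS["learning_rate"][0],
                        float(HYPERPARAM_BOUNDS["hidden_neurons"][0]),
                        float(HYPERPARAM_BOUNDS["activation_index"][0])]),
        upper=np.array([HYPERPARAM_BOUNDS["learning_rate"][1],
                        float(HYPERPARAM_BOUNDS["hidden_neurons"][1]),
                        float(HYPERPARAM_BOUNDS["activation_index"][1])]),
    )
    train_seed = (config.seed + 1) % (2**31)

    def objective(genes: np.ndarray) -> float:
        try:
            hp = ADSVMHyperparams.from_genes(genes)
            extractor, head = _fit_at(x_tr, y_tr, hp, train_seed, epochs)
            y_hat = head.predict(extract_deep_features(extractor, x_val))
            counts = metrics.confusion_from_labels(y_val, y_hat)
            return detection_fitness(counts)
        except Exception:
            return WORST_FITNESS

    trace = eavsro.optimize(objective, bounds, config)
    hp = ADSVMHyperparams.from_genes(trace.best_candidate.genes)
    extractor, head = _fit_at(x_tr, y_tr, hp, train_seed, epochs)
    y_hat = head.predict(extract_deep_features(extractor, x_val))
    counts = metrics.confusion_from_labels(y_val, y_hat)
    return ADSVMModel(extractor=extractor, head=head, hyperparams=hp,
                      training_metrics=counts)
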