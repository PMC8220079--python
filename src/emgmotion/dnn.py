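"""Feed-forward neural-network classifier for standardized sEMG features.

The model is a plain multilayer perceptron: three fully connected hidden
layers of 512, 256 and 256 units, each followed by batch normalization, a
ReLU activation and 20% dropout, then a linear output layer with softmax
over the movement classes (rest included as class 0). Weights are
He-uniform initialized; training minimizes the categorical cross-entropy
with the Adam optimizer at learning rate 0.005 and a per-update decay of
1e-5 (``lr_t = lr / (1 + decay * t)``; interpreting "decay" as L2 weight
decay instead is available as a config switch).

Everything — initialization, shuffling, batching, dropout masks — draws from
a single seeded generator, so training is bit-reproducible on the same
hardware. The implementation is pure numpy: forward and backward passes are
written out explicitly, which keeps the dependency footprint at the
scientific stack and makes the arithmetic auditable.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from .errors import InputError
from .features import FeatureTable, StandardizationParams, apply_standardizer, fit_standardizer

__all__ = [
    "ClassifierSpec",
    "MLPNetwork",
    "TrainedClassifier",
    "build",
    "parameter_count",
    "softmax_probabilities",
    "cross_entropy",
    "train",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.99
_ADAM_BETA1, _ADAM_BETA2, _ADAM_EPS = 0.9, 0.999, 1e-7


@dataclass
class ClassifierSpec:
    """Architecture and optimization hyperparameters.

    The epoch count, batch size and absence of early stopping are library
    defaults chosen for reproducibility; all are overridable.
    """

    n_classes: int
    hidden_widths: tuple[int, ...] = (512, 256, 256)
    dropout_rate: float = 0.2
    learning_rate: float = 0.005
    lr_decay: float = 1e-5
    decay_mode: str = "lr"  # "lr": lr/(1+decay*t); "weight": L2 weight decay
    batch_size: int = 256
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise InputError("n_classes must be >= 2")
        if any(w < 1 for w in self.hidden_widths):
            raise InputError("hidden widths must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise InputError("dropout_rate must be in [0, 1)")
        if self.decay_mode not in ("lr", "weight"):
            raise InputError("decay_mode must be 'lr' or 'weight'")
        self.hidden_widths = tuple(int(w) for w in self.hidden_widths)


def parameter_count(spec: ClassifierSpec, input_dim: int, trainable_only: bool = True) -> int:
    """Closed-form parameter count: each dense layer has
    ``d_in * d_out + d_out`` weights, each batch-norm ``2 * d_out`` trainable
    (gamma, beta) plus ``2 * d_out`` running statistics."""
    total = 0
    d = input_dim
    for h in spec.hidden_widths:
        total += d * h + h  # dense
        total += 2 * h  # gamma, beta
        if not trainable_only:
            total += 2 * h  # running mean/var
        d = h
    total += d * spec.n_classes + spec.n_classes
    return total


def softmax_probabilities(logits: np.ndarray) -> np.ndarray:
    """Row-wise stable softmax; accepts a vector or a matrix."""
    z = np.asarray(logits, dtype=float)
    if not np.all(np.isfinite(z)):
        raise InputError("logits must be finite")
    z = np.atleast_2d(z)
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    return p[0] if np.asarray(logits).ndim == 1 else p


def cross_entropy(probabilities: np.ndarray, one_hot_targets: np.ndarray) -> float:
    """Mean categorical cross-entropy, probabilities clipped to >= 1e-12."""
    p = np.atleast_2d(np.asarray(probabilities, dtype=float))
    t = np.atleast_2d(np.asarray(one_hot_targets, dtype=float))
    if p.shape != t.shape:
        raise InputError(f"shape mismatch: probabilities {p.shape} vs targets {t.shape}")
    return float(-np.mean(np.sum(t * np.log(np.clip(p, 1e-12, None)), axis=1)))


class MLPNetwork:
    """Weights and forward/backward arithmetic of the MLP.

    Not user-facing: :func:`train` produces a :class:`TrainedClassifier`
    wrapping one of these.
    """

    def __init__(self, spec: ClassifierSpec, input_dim: int, rng: np.random.Generator):
        self.spec = spec
        self.input_dim = int(input_dim)
        self.hidden: list[dict[str, np.ndarray]] = []
        d = self.input_dim
        for h in spec.hidden_widths:
            limit = np.sqrt(6.0 / d)  # He uniform
            self.hidden.append(
                {
                    "W": rng.uniform(-limit, limit, size=(d, h)),
                    "b": np.zeros(h),
                    "gamma": np.ones(h),
                    "beta": np.zeros(h),
                    "run_mean": np.zeros(h),
                    "run_var": np.ones(h),
                }
            )
            d = h
        limit = np.sqrt(6.0 / d)
        self.out = {"W": rng.uniform(-limit, limit, size=(d, spec.n_classes)), "b": np.zeros(spec.n_classes)}

    # -- forward -----------------------------------------------------------
    def forward(self, X: np.ndarray, training: bool = False, rng: np.random.Generator | None = None):
        """Return (probabilities, cache); cache is populated when training."""
        a = np.asarray(X, dtype=float)
        cache: list[dict] = []
        keep = 1.0 - self.spec.dropout_rate
        for layer in self.hidden:
            z = a @ layer["W"] + layer["b"]
            if training:
                mu = z.mean(axis=0)
                var = z.var(axis=0)
                layer["run_mean"] = _BN_MOMENTUM * layer["run_mean"] + (1 - _BN_MOMENTUM) * mu
                layer["run_var"] = _BN_MOMENTUM * layer["run_var"] + (1 - _BN_MOMENTUM) * var
            else:
                mu, var = layer["run_mean"], layer["run_var"]
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            zhat = (z - mu) * inv_std
            y = layer["gamma"] * zhat + layer["beta"]
            act = np.maximum(y, 0.0)
            if training and self.spec.dropout_rate > 0:
                mask = (rng.random(act.shape) >= self.spec.dropout_rate) / keep
                out = act * mask
            else:
                mask = None
                out = act
            cache.append({"a_in": a, "z": z, "zhat": zhat, "inv_std": inv_std, "y": y, "mask": mask})
            a = out
        logits = a @ self.out["W"] + self.out["b"]
        probs = softmax_probabilities(logits)
        cache.append({"a_in": a})
        return np.atleast_2d(probs), cache

    # -- backward ----------------------------------------------------------
    def gradients(self, probs: np.ndarray, targets: np.ndarray, cache: list[dict]):
        """Backprop of mean cross-entropy; returns grads mirroring params."""
        m = probs.shape[0]
        grads: list[dict[str, np.ndarray]] = [dict() for _ in self.hidden]
        dlogits = (probs - targets) / m
        a_last = cache[-1]["a_in"]
        gout = {"W": a_last.T @ dlogits, "b": dlogits.sum(axis=0)}
        da = dlogits @ self.out["W"].T
        for li in range(len(self.hidden) - 1, -1, -1):
            layer, c = self.hidden[li], cache[li]
            if c["mask"] is not None:
                da = da * c["mask"]
            dy = da * (c["y"] > 0)
            grads[li]["gamma"] = (dy * c["zhat"]).sum(axis=0)
            grads[li]["beta"] = dy.sum(axis=0)
            dzhat = dy * layer["gamma"]
            # batch-norm backward (population batch statistics)
            dz = (
                dzhat
                - dzhat.mean(axis=0)
                - c["zhat"] * (dzhat * c["zhat"]).mean(axis=0)
            ) * c["inv_std"]
            grads[li]["W"] = c["a_in"].T @ dz
            grads[li]["b"] = dz.sum(axis=0)
            da = dz @ layer["W"].T
        return grads, gout


@dataclass
class TrainedClassifier:
    """A trained network plus everything needed to apply it: the spec, the
    class list (sorted labels seen in training) and the attached
    standardization parameters."""

    spec: ClassifierSpec
    network: MLPNetwork
    class_list: np.ndarray
    standardizer: StandardizationParams | None
    loss_trace: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def input_dim(self) -> int:
        return self.network.input_dim

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_dim:
            raise InputError(f"feature dimension {X.shape[1]} != model input dim {self.input_dim}")
        return X

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities for standardized feature rows."""
        probs, _ = self.network.forward(self._check(X), training=False)
        return probs

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted class labels; exact probability ties go to the lowest
        class index (argmax convention)."""
        return self.class_list[np.argmax(self.predict_proba(X), axis=1)]

    def classify_table(self, table: FeatureTable) -> np.ndarray:
        """Predict labels for a feature table, standardizing it with the
        attached parameters if it is still raw."""
        if not table.standardized:
            if self.standardizer is None:
                raise InputError("table is not standardized and the model has no standardizer")
            table = apply_standardizer(self.standardizer, table)
        return self.predict(table.values)

    # -- serialization -----------------------------------------------------
    def save(self, path: str | os.PathLike) -> None:
        """Single-archive serialization: weight arrays + a JSON manifest."""
        arrays: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.network.hidden):
            for key, val in layer.items():
                arrays[f"h{i}_{key}"] = val
        arrays["out_W"] = self.network.out["W"]
        arrays["out_b"] = self.network.out["b"]
        arrays["class_list"] = self.class_list
        arrays["loss_trace"] = self.loss_trace
        if self.standardizer is not None:
            arrays["std_mean"] = self.standardizer.mean
            arrays["std_std"] = self.standardizer.std
            arrays["std_zero"] = self.standardizer.zero_variance
        manifest = {"spec": asdict(self.spec), "input_dim": self.input_dim, "meta": self.meta}
        arrays["manifest"] = np.frombuffer(json.dumps(manifest).encode(), dtype=np.uint8)
        np.savez(os.fspath(path), **arrays)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "TrainedClassifier":
        with np.load(os.fspath(path)) as data:
            manifest = json.loads(bytes(data["manifest"]).decode())
            spec_dict = manifest["spec"]
            spec_dict["hidden_widths"] = tuple(spec_dict["hidden_widths"])
            spec = ClassifierSpec(**spec_dict)
            net = MLPNetwork(spec, manifest["input_dim"], np.random.default_rng(0))
            for i in range(len(spec.hidden_widths)):
                for key in ("W", "b", "gamma", "beta", "run_mean", "run_var"):
                    net.hidden[i][key] = data[f"h{i}_{key}"]
            net.out = {"W": data["out_W"], "b": data["out_b"]}
            standardizer = None
            if "std_mean" in data:
                standardizer = StandardizationParams(
                    mean=data["std_mean"], std=data["std_std"], zero_variance=data["std_zero"]
                )
            return cls(
                spec=spec,
                network=net,
                class_list=data["class_list"],
                standardizer=standardizer,
                loss_trace=data["loss_trace"],
                meta=manifest["meta"],
            )


def build(spec: ClassifierSpec, input_dim: int) -> MLPNetwork:
    """He-uniform initialized, untrained network for ``input_dim`` features."""
    return MLPNetwork(spec, input_dim, np.random.default_rng(spec.seed))


def train(
    train_table: FeatureTable,
    spec: ClassifierSpec | None = None,
    standardizer: StandardizationParams | None = None,
    **spec_overrides,
) -> TrainedClassifier:
    """Train the network on a feature table.

    The table may be raw or already standardized. A raw table without a
    supplied standardizer gets one fitted internally on itself (flagged in
    the result's ``meta`` as ``standardizer_fit="internal"``). The class
    list is the sorted set of labels present in the table; ``spec.n_classes``
    is derived from it when no spec is given.
    """
    labels = np.unique(train_table.labels)
    if labels.size < 2:
        raise InputError("training table must contain at least 2 classes")
    if spec is None:
        spec = ClassifierSpec(n_classes=int(labels.size), **spec_overrides)
    elif spec_overrides:
        raise InputError("pass either a spec or overrides, not both")
    if spec.n_classes != labels.size:
        raise InputError(f"spec.n_classes={spec.n_classes} but table has {labels.size} classes")

    meta: dict = {"standardizer_fit": "external", "threshold": train_table.threshold_used}
    if not train_table.standardized:
        if standardizer is None:
            standardizer = fit_standardizer(train_table)
            meta["standardizer_fit"] = "internal"
        train_table = apply_standardizer(standardizer, train_table)

    rng = np.random.default_rng(spec.seed)
    net = MLPNetwork(spec, train_table.n_features, rng)
    X = train_table.values
    y_idx = np.searchsorted(labels, train_table.labels)
    targets = np.eye(labels.size)[y_idx]
    n = X.shape[0]

    adam_m: list[dict] = []
    adam_v: list[dict] = []
    for layer in net.hidden:
        adam_m.append({k: np.zeros_like(layer[k]) for k in ("W", "b", "gamma", "beta")})
        adam_v.append({k: np.zeros_like(layer[k]) for k in ("W", "b", "gamma", "beta")})
    adam_m.append({k: np.zeros_like(net.out[k]) for k in ("W", "b")})
    adam_v.append({k: np.zeros_like(net.out[k]) for k in ("W", "b")})

    step = 0
    trace = np.empty(spec.epochs)
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            probs, cache = net.forward(X[idx], training=True, rng=rng)
            epoch_loss += cross_entropy(probs, targets[idx]) * idx.size
            grads, gout = net.gradients(probs, targets[idx], cache)
            step += 1
            if spec.decay_mode == "lr":
                lr_t = spec.learning_rate / (1.0 + spec.lr_decay * step)
                wd = 0.0
            else:
                lr_t = spec.learning_rate
                wd = spec.lr_decay
            bc1 = 1.0 - _ADAM_BETA1**step
            bc2 = 1.0 - _ADAM_BETA2**step

            def update(params: dict, g: dict, m: dict, v: dict) -> None:
                for k, grad in g.items():
                    if wd and k == "W":
                        grad = grad + wd * params[k]
                    m[k] = _ADAM_BETA1 * m[k] + (1 - _ADAM_BETA1) * grad
                    v[k] = _ADAM_BETA2 * v[k] + (1 - _ADAM_BETA2) * grad**2
                    params[k] -= lr_t * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + _ADAM_EPS)

            for li, layer in enumerate(net.hidden):
                update(layer, grads[li], adam_m[li], adam_v[li])
            update(net.out, gout, adam_m[-1], adam_v[-1])
        trace[epoch] = epoch_loss / n

    return TrainedClassifier(
        spec=spec,
        network=net,
        class_list=labels,
        standardizer=standardizer,
        loss_trace=trace,
        meta=meta,
    )
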