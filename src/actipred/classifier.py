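"""Bidirectional-LSTM activity classifier for 2.56 s signal halves.

The classifier labels a (256 x 6) half-epoch — either a measured future half
or a forecasted one — as one of the configured activities.  Architecture:
two Bi-LSTM layers (the second returning only its final concatenated
forward/backward state), ReLU, a hidden dense layer, and a softmax output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Adam, BiLSTM, Dense, softmax_cross_entropy


@dataclass
class ClassifierSpec:
    """Hyperparameters; defaults follow the full-size model (Bi-LSTM layers
    of 64 and 32 units, a 352-neuron hidden layer, 5 output classes)."""

    bilstm_units: tuple[int, int] = (64, 32)
    hidden_neurons: int = 352
    n_classes: int = 5
    input_len: int = 256
    n_channels: int = 6

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if len(self.bilstm_units) != 2:
            raise ValueError("bilstm_units must list exactly two layer widths")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["bilstm_units"] = list(self.bilstm_units)
        return d


def reduced_classifier_spec(**overrides) -> ClassifierSpec:
    """A small CPU-friendly spec for tests and reduced-scale runs."""
    kw = dict(bilstm_units=(16, 8), hidden_neurons=64)
    kw.update(overrides)
    return ClassifierSpec(**kw)


@dataclass
class ClassifierTrainConfig:
    """Defaults follow the full-scale regime: Adam, learning rate 5e-4,
    batch 10, 240 passes, categorical cross-entropy."""

    lr: float = 5e-4
    batch_size: int = 10
    n_passes: int = 240
    seed: int = 0
    clip_norm: float | None = 5.0
    shuffle: bool = True


class BiLSTMClassifier:
    def __init__(self, spec: ClassifierSpec, seed: int = 0,
                 label_names: list[str] | None = None):
        self.spec = spec
        self.label_names = label_names
        rng = np.random.default_rng(seed)
        u1, u2 = spec.bilstm_units
        self.bilstm1 = BiLSTM(spec.n_channels, u1, rng, return_sequences=True,
                              name="bilstm1")
        self.bilstm2 = BiLSTM(2 * u1, u2, rng, return_sequences=False,
                              name="bilstm2")
        self.hidden = Dense(2 * u2, spec.hidden_neurons, rng, activation="relu",
                            name="hidden")
        self.out = Dense(spec.hidden_neurons, spec.n_classes, rng, name="out")
        self._layers = [self.bilstm1, self.bilstm2, self.hidden, self.out]

    def parameters(self):
        params = []
        for layer in self._layers:
            params.extend(layer.parameters())
        return params

    def param_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.value for p in self.parameters()}

    def load_param_dict(self, d: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            p.value[...] = d[p.name]

    def _check_input(self, x: np.ndarray):
        x = np.asarray(x, dtype=float)
        single = x.ndim == 2
        if single:
            x = x[None]
        if x.shape[1:] != (self.spec.input_len, self.spec.n_channels):
            raise ValueError(
                f"expected input shape (*, {self.spec.input_len}, "
                f"{self.spec.n_channels}), got {x.shape}"
            )
        return x, single

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.bilstm1.forward(x, train)
        h = self.bilstm2.forward(h, train)
        # ReLU sits between the Bi-LSTM stack and the hidden layer; the final
        # state is passed through max(., 0) before the dense layers.
        self._relu_in = h
        h = np.maximum(h, 0.0)
        h = self.hidden.forward(h, train)
        return self.out.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.out.backward(dlogits)
        d = self.hidden.backward(d)
        d = d * (self._relu_in > 0)
        d = self.bilstm2.backward(d)
        self.bilstm1.backward(d)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x, single = self._check_input(x)
        z = self.logits(x)
        z = z - z.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)
        return p[0] if single else p


def build_classifier(spec: ClassifierSpec, seed: int = 0,
                     label_names: list[str] | None = None) -> BiLSTMClassifier:
    """Instantiate a classifier with seed-deterministic initial parameters."""
    return BiLSTMClassifier(spec, seed=seed, label_names=label_names)


def fit_classifier(model: BiLSTMClassifier, signals: np.ndarray,
                   labels: np.ndarray,
                   cfg: ClassifierTrainConfig | None = None) -> list[float]:
    """Train on labeled (n, 256, 6) signals; returns per-pass mean loss."""
    cfg = cfg or ClassifierTrainConfig()
    X = np.asarray(signals, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("signals and labels must align")
    if np.unique(y).size < 2:
        raise ValueError("training set must contain at least two classes")
    n = X.shape[0]
    rng = np.random.default_rng(cfg.seed + 2)
    opt = Adam(model.parameters(), lr=cfg.lr, clip_norm=cfg.clip_norm)
    history: list[float] = []
    for _ in range(cfg.n_passes):
        order = rng.permutation(n) if cfg.shuffle else np.arange(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            z = model.logits(X[idx], train=True)
            loss, dz, _ = softmax_cross_entropy(z, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at pass {len(history)}: {loss}"
                )
            opt.zero_grad()
            model.backward(dz)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history


def classify(model: BiLSTMClassifier, signal: np.ndarray):
    """Return (label, probabilities) for one (256 x 6) signal, or arrays for
    a batch.  The label is the argmax class; names are used when the model
    carries ``label_names``."""
    probs = model.predict_proba(signal)
    idx = np.argmax(probs, axis=-1)
    if model.label_names is not None:
        if probs.ndim == 1:
            return model.label_names[int(idx)], probs
        return [model.label_names[int(i)] for i in idx], probs
    return (int(idx) if probs.ndim == 1 else idx), probs
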