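"""Checkpoint save/load for forecasters and classifiers.

Checkpoints are NumPy ``.npz`` archives holding every named parameter plus a
JSON-encoded spec, so a model can be rebuilt and its weights restored
exactly.
"""

from __future__ import annotations

import json

import numpy as np

from .classifier import BiLSTMClassifier, ClassifierSpec, build_classifier
from .forecasters import ForecasterSpec, build_forecaster


def save_model(model, path) -> None:
    """Write a forecaster or classifier checkpoint."""
    if isinstance(model, BiLSTMClassifier):
        kind = "classifier"
        spec = model.spec.to_dict()
        extra = {"label_names": model.label_names}
    else:
        kind = "forecaster"
        spec = model.spec.to_dict()
        extra = {}
    meta = json.dumps({"kind": kind, "spec": spec, **extra})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **model.param_dict())


def load_model(path):
    """Rebuild a model from a checkpoint written by :func:`save_model`."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        params = {k: data[k] for k in data.files if k != "__meta__"}
    if meta["kind"] == "classifier":
        spec = ClassifierSpec(**{**meta["spec"],
                                 "bilstm_units": tuple(meta["spec"]["bilstm_units"])})
        model = build_classifier(spec, label_names=meta.get("label_names"))
    else:
        spec = ForecasterSpec(**meta["spec"])
        model = build_forecaster(spec)
    model.load_param_dict(params)
    return model
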