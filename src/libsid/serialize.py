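"""JSON (de)serialization of trained models.

All model state is stored as plain JSON arrays.  PLS-DA and RBFNN models
round-trip exactly (their predictors are closed-form array operations).
An SVM model stores its training data and tuned (C, gamma) and is refitted
on load — the libsvm solve is deterministic, so predictions round-trip.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .models import SVMConfig, TrainedModel, _fit_svc_precomputed, _sq_dists

__all__ = ["model_to_json", "model_from_json", "save_model", "load_model"]


def _arr(x) -> list:
    return np.asarray(x).tolist()


def model_to_json(model: TrainedModel) -> dict:
    hyper = dict(model.hyperparameters)
    doc = {
        "kind": model.kind,
        "hyperparameters": hyper,
        "training_class_labels": model.training_class_labels,
    }
    st = model.fit_state
    if model.kind == "plsda":
        doc["fit_state"] = {
            "x_mean": _arr(st["x_mean"]),
            "y_mean": _arr(st["y_mean"]),
            "coef": _arr(st["coef"]),
            "coding": st["coding"],
            "threshold": st["threshold"],
        }
    elif model.kind == "rbfnn":
        doc["fit_state"] = {
            "centers": _arr(st["centers"]),
            "weights": _arr(st["weights"]),
            "spread": st["spread"],
        }
    elif model.kind == "svm":
        doc["fit_state"] = {
            "X_train": _arr(st["X_train"]),
            "y_train": _arr(st["y_train"]),
            "C": st["C"],
            "gamma": st["gamma"],
        }
    else:
        raise ValueError(f"unknown model kind {model.kind!r}")
    return doc


def model_from_json(doc: dict) -> TrainedModel:
    kind = doc["kind"]
    st = doc["fit_state"]
    if kind == "plsda":
        fit_state = {
            "x_mean": np.asarray(st["x_mean"], dtype=float),
            "y_mean": np.asarray(st["y_mean"], dtype=float),
            "coef": np.asarray(st["coef"], dtype=float),
            "coding": st["coding"],
            "threshold": st["threshold"],
        }
    elif kind == "rbfnn":
        fit_state = {
            "centers": np.asarray(st["centers"], dtype=float),
            "weights": np.asarray(st["weights"], dtype=float),
            "spread": float(st["spread"]),
        }
    elif kind == "svm":
        X = np.asarray(st["X_train"], dtype=float)
        y = np.asarray(st["y_train"], dtype=int)
        gamma, C = float(st["gamma"]), float(st["C"])
        svc = _fit_svc_precomputed(np.exp(-gamma * _sq_dists(X, X)), y, C)
        fit_state = {"svc": svc, "X_train": X, "y_train": y, "gamma": gamma, "C": C}
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    return TrainedModel(
        kind=kind,
        hyperparameters=dict(doc["hyperparameters"]),
        fit_state=fit_state,
        training_class_labels=[int(c) for c in doc["training_class_labels"]],
    )


def save_model(model: TrainedModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_json(model)))


def load_model(path: str | Path) -> TrainedModel:
    return model_from_json(json.loads(Path(path).read_text()))
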