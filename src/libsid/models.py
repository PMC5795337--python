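"""Classification models and their tuning protocols.

Three classifiers, each with the tuning protocol standard in LIBS
chemometrics:

* **PLS-DA** — partial least squares regression of the integer class code
  on the spectra (one-hot coding available), with the number of latent
  variables chosen by leave-one-out cross-validated classification
  accuracy and continuous predictions mapped to the nearest class with a
  0.5 threshold;
* **RBFNN** — an exact-design radial basis function network: Gaussian
  units ``phi(r) = exp(-(r/spread)^2)`` centered on every calibration row,
  output weights by ridge-regularized least squares onto one-hot targets,
  spread tuned over the grid 0.1..1 (step 0.1) + 1..100 (step 1);
* **SVM** — one-vs-one soft-margin SVM with RBF kernel
  ``exp(-gamma ||x - z||^2)``, (C, gamma) tuned over a log2 grid in
  [2^-8, 2^8]^2.

Hyperparameters are selected by stratified k-fold cross validation on the
calibration set by default (``selection="calibration"`` reselects on
training accuracy instead); ties prefer the simpler model (fewer latent
variables; smaller spread; smaller C then smaller gamma).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .core import SpectrumSet

__all__ = [
    "SplitConfig",
    "PLSDAConfig",
    "RBFNNConfig",
    "SVMConfig",
    "TrainedModel",
    "EvalReport",
    "split_indices",
    "split_calibration_prediction",
    "train_plsda",
    "predict_plsda",
    "train_rbfnn",
    "predict_rbfnn",
    "train_svm",
    "predict_svm",
    "predict",
    "evaluate",
]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances via BLAS (clipped at 0)."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    d2 = (
        (A * A).sum(axis=1)[:, None]
        + (B * B).sum(axis=1)[None, :]
        - 2.0 * (A @ B.T)
    )
    return np.maximum(d2, 0.0)


def _default_spread_grid() -> tuple[float, ...]:
    fine = tuple(round(0.1 * i, 10) for i in range(1, 10))  # 0.1 .. 0.9
    coarse = tuple(float(i) for i in range(1, 101))  # 1 .. 100
    return fine + coarse


# -- configs ---------------------------------------------------------------


@dataclass(frozen=True)
class SplitConfig:
    """Stratified random calibration/prediction split (2:1 by default)."""

    calibration_ratio: float = 2.0 / 3.0
    stratify_by: str = "variety"
    unit: str = "shot"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.calibration_ratio < 1.0:
            raise ValueError("calibration_ratio must be in (0, 1)")
        if self.stratify_by != "variety":
            raise ValueError("stratify_by must be 'variety'")
        if self.unit not in ("shot", "sample"):
            raise ValueError("unit must be 'shot' or 'sample'")


@dataclass(frozen=True)
class PLSDAConfig:
    max_lv: int = 20
    threshold: float = 0.5
    class_coding: str = "integer"

    def __post_init__(self) -> None:
        if self.max_lv < 1:
            raise ValueError("max_lv must be >= 1")
        if self.class_coding not in ("integer", "one_hot"):
            raise ValueError("class_coding must be 'integer' or 'one_hot'")
        if self.class_coding == "integer" and not 0.0 < self.threshold <= 0.5:
            raise ValueError("threshold must be in (0, 0.5] for integer coding")


@dataclass(frozen=True)
class RBFNNConfig:
    spread_grid: tuple[float, ...] = field(default_factory=_default_spread_grid)
    ridge: float = 1e-8
    selection: str = "cv"
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if not self.spread_grid or any(s <= 0 for s in self.spread_grid):
            raise ValueError("spread grid must be nonempty and positive")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")
        if self.selection not in ("cv", "calibration"):
            raise ValueError("selection must be 'cv' or 'calibration'")


@dataclass(frozen=True)
class SVMConfig:
    log2_C_range: tuple[float, float] = (-8.0, 8.0)
    log2_gamma_range: tuple[float, float] = (-8.0, 8.0)
    grid_step_log2: float = 0.2
    multiclass: str = "one_vs_one"
    selection: str = "cv"
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if self.log2_C_range[0] > self.log2_C_range[1]:
            raise ValueError("log2_C_range must be ordered")
        if self.log2_gamma_range[0] > self.log2_gamma_range[1]:
            raise ValueError("log2_gamma_range must be ordered")
        if self.grid_step_log2 <= 0:
            raise ValueError("grid_step_log2 must be > 0")
        if self.multiclass != "one_vs_one":
            raise ValueError("only one_vs_one multiclass is supported")
        if self.selection not in ("cv", "calibration"):
            raise ValueError("selection must be 'cv' or 'calibration'")

    def c_grid(self) -> np.ndarray:
        lo, hi = self.log2_C_range
        return 2.0 ** np.arange(lo, hi + self.grid_step_log2 / 2, self.grid_step_log2)

    def gamma_grid(self) -> np.ndarray:
        lo, hi = self.log2_gamma_range
        return 2.0 ** np.arange(lo, hi + self.grid_step_log2 / 2, self.grid_step_log2)


@dataclass
class TrainedModel:
    kind: str
    hyperparameters: dict[str, Any]
    fit_state: dict[str, Any]
    training_class_labels: list[int]


@dataclass
class EvalReport:
    """Per-class and total accuracy (%) on calibration and prediction sets."""

    classes: list[int]
    per_class_calibration: np.ndarray
    total_calibration: float
    per_class_prediction: np.ndarray
    total_prediction: float

    def to_frame(self, model_name: str = "") -> pd.DataFrame:
        row: dict[str, Any] = {"model": model_name}
        for c, a in zip(self.classes, self.per_class_calibration):
            row[f"cal_{c}"] = a
        row["cal_total"] = self.total_calibration
        for c, a in zip(self.classes, self.per_class_prediction):
            row[f"pred_{c}"] = a
        row["pred_total"] = self.total_prediction
        return pd.DataFrame([row])


# -- calibration/prediction split -----------------------------------------


def split_indices(sset: SpectrumSet, config: SplitConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Row indices of the (calibration, prediction) split.

    Stratified per variety at ``calibration_ratio``; with ``unit="sample"``
    whole physical samples move together (the leakage-safe alternative).
    Disjoint and exhaustive; seeded.
    """
    config = config or SplitConfig()
    rng = np.random.default_rng(config.seed)
    varieties = sset.varieties
    cal: list[int] = []
    pred: list[int] = []
    for v in sorted(set(varieties.tolist())):
        rows = np.flatnonzero(varieties == v)
        if config.unit == "shot":
            if rows.size < 3:
                raise ValueError(f"variety {v} has {rows.size} shots; need >= 3")
            perm = rng.permutation(rows)
            n_cal = min(max(_round_half_up(config.calibration_ratio * rows.size), 1), rows.size - 1)
            cal.extend(perm[:n_cal].tolist())
            pred.extend(perm[n_cal:].tolist())
        else:
            samples = sorted({sset.meta[i].sample_id for i in rows})
            if len(samples) < 3:
                raise ValueError(f"variety {v} has {len(samples)} samples; need >= 3")
            perm = rng.permutation(len(samples))
            n_cal = min(max(_round_half_up(config.calibration_ratio * len(samples)), 1), len(samples) - 1)
            cal_samples = {samples[i] for i in perm[:n_cal]}
            for i in rows:
                (cal if sset.meta[i].sample_id in cal_samples else pred).append(int(i))
    return np.sort(np.array(cal, dtype=int)), np.sort(np.array(pred, dtype=int))


def split_calibration_prediction(
    sset: SpectrumSet, config: SplitConfig | None = None
) -> tuple[SpectrumSet, SpectrumSet]:
    ical, ipred = split_indices(sset, config)
    return sset.subset(ical), sset.subset(ipred)


# -- PLS-DA ----------------------------------------------------------------


def _targets(y: np.ndarray, classes: np.ndarray, coding: str) -> np.ndarray:
    if coding == "integer":
        return y.astype(float)[:, None]
    return (y[:, None] == classes[None, :]).astype(float)


def _fit_pls_components(X: np.ndarray, Y: np.ndarray, k: int):
    """Fit PLS and return (x_mean, y_mean, rotations, y_loadings)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls = PLSRegression(n_components=k, scale=False)
        pls.fit(X, Y)
    return X.mean(axis=0), Y.mean(axis=0), pls.x_rotations_, pls.y_loadings_


def _pls_predictions_all_k(x_mean, y_mean, rotations, y_loadings, X: np.ndarray) -> np.ndarray:
    """Predictions for every truncation 1..K: shape (n, n_targets, K)."""
    T = (X - x_mean) @ rotations  # (n, K)
    contrib = T[:, None, :] * y_loadings[None, :, :]  # (n, t, K)
    return np.cumsum(contrib, axis=2) + y_mean[None, :, None]


def _classify_integer(yhat: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Nearest class to a continuous score; midpoints go to the lower class."""
    c = np.ceil(yhat - 0.5)
    return np.clip(c, classes.min(), classes.max()).astype(int)


def train_plsda(
    X: np.ndarray, y: np.ndarray, config: PLSDAConfig | None = None
) -> TrainedModel:
    """PLS-DA with the LV count chosen by leave-one-out CV accuracy.

    Each left-out fold is fitted once at the maximal LV count; predictions
    for every truncation are recovered from the rotation/loading factors,
    so LOO over all LV choices costs n fits rather than n * max_lv.
    Ties in LOO accuracy prefer fewer latent variables.
    """
    config = config or PLSDAConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, p = X.shape
    classes = np.unique(y)
    k_max = min(config.max_lv, p, n - 2)
    if k_max < config.max_lv:
        warnings.warn(
            f"max_lv capped at {k_max} (data rank/size limit)", RuntimeWarning
        )
    if k_max < 1:
        raise ValueError("too few samples/features for even one latent variable")
    Y = _targets(y, classes, config.class_coding)

    correct = np.zeros(k_max)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        x_mean, y_mean, R, Q = _fit_pls_components(X[mask], Y[mask], k_max)
        preds = _pls_predictions_all_k(x_mean, y_mean, R, Q, X[i : i + 1])  # (1, t, K)
        for k in range(k_max):
            if config.class_coding == "integer":
                label = _classify_integer(preds[0, 0, k], classes)
            else:
                label = classes[int(np.argmax(preds[0, :, k]))]
            correct[k] += label == y[i]
    loo_acc = correct / n
    best_k = int(np.argmax(loo_acc)) + 1  # argmax -> first -> fewest LVs

    x_mean, y_mean, R, Q = _fit_pls_components(X, Y, best_k)
    coef = R @ Q.T  # (p, t)
    return TrainedModel(
        kind="plsda",
        hyperparameters={"n_lv": best_k, "loo_accuracy": float(100.0 * loo_acc[best_k - 1])},
        fit_state={
            "x_mean": x_mean,
            "y_mean": y_mean,
            "coef": coef,
            "coding": config.class_coding,
            "threshold": config.threshold,
        },
        training_class_labels=[int(c) for c in classes],
    )


def predict_plsda(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    st = model.fit_state
    X = np.asarray(X, dtype=float)
    yhat = (X - st["x_mean"]) @ st["coef"] + st["y_mean"]
    classes = np.array(model.training_class_labels)
    if st["coding"] == "integer":
        return _classify_integer(yhat[:, 0], classes)
    return classes[np.argmax(yhat, axis=1)]


# -- RBF neural network ----------------------------------------------------


def _rbf_design(d2: np.ndarray, spread: float) -> np.ndarray:
    return np.exp(-d2 / (spread * spread))


def _rbf_weights(phi: np.ndarray, Y: np.ndarray, ridge: float) -> np.ndarray:
    """Ridge least squares W = (Phi' Phi + lambda I)^-1 Phi' Y."""
    G = phi.T @ phi
    G.flat[:: G.shape[0] + 1] += ridge
    try:
        return np.linalg.solve(G, phi.T @ Y)
    except np.linalg.LinAlgError:
        bumped = max(ridge, 1e-12) * 1e6
        warnings.warn(
            f"RBFNN normal equations singular; raising ridge to {bumped:g}",
            RuntimeWarning,
        )
        G = phi.T @ phi
        G.flat[:: G.shape[0] + 1] += bumped
        return np.linalg.solve(G, phi.T @ Y)


def train_rbfnn(
    X: np.ndarray,
    y: np.ndarray,
    config: RBFNNConfig | None = None,
    random_state: int = 0,
) -> TrainedModel:
    """Exact-design Gaussian RBF network with spread tuned on a grid.

    Centers are all calibration rows.  ``selection="cv"`` scores each
    spread by stratified k-fold accuracy on the calibration set;
    ``"calibration"`` scores on the training rows themselves.  Ties prefer
    the smaller spread.
    """
    config = config or RBFNNConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    counts = np.array([(y == c).sum() for c in classes])
    if counts.min() < 2:
        raise ValueError("need at least 2 calibration rows per class")
    Y = (y[:, None] == classes[None, :]).astype(float)
    spreads = np.array(sorted(set(float(s) for s in config.spread_grid)))
    d2_full = _sq_dists(X, X)

    if config.selection == "cv":
        n_folds = min(config.cv_folds, int(counts.min()))
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=random_state)
        folds = list(skf.split(X, y))
        acc = np.zeros(spreads.size)
        for tr, va in folds:
            d2_tt = d2_full[np.ix_(tr, tr)]
            d2_vt = d2_full[np.ix_(va, tr)]
            for j, s in enumerate(spreads):
                W = _rbf_weights(_rbf_design(d2_tt, s), Y[tr], config.ridge)
                pred = classes[np.argmax(_rbf_design(d2_vt, s) @ W, axis=1)]
                acc[j] += (pred == y[va]).sum()
        acc /= y.size
    else:
        acc = np.zeros(spreads.size)
        for j, s in enumerate(spreads):
            W = _rbf_weights(_rbf_design(d2_full, s), Y, config.ridge)
            pred = classes[np.argmax(_rbf_design(d2_full, s) @ W, axis=1)]
            acc[j] = (pred == y).mean()

    best = int(np.argmax(acc))  # first max -> smallest spread
    spread = float(spreads[best])
    W = _rbf_weights(_rbf_design(d2_full, spread), Y, config.ridge)
    return TrainedModel(
        kind="rbfnn",
        hyperparameters={"spread": spread, "selection_accuracy": float(100.0 * acc[best])},
        fit_state={"centers": X.copy(), "weights": W, "spread": spread},
        training_class_labels=[int(c) for c in classes],
    )


def predict_rbfnn(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    st = model.fit_state
    d2 = _sq_dists(np.asarray(X, dtype=float), st["centers"])
    scores = _rbf_design(d2, st["spread"]) @ st["weights"]
    classes = np.array(model.training_class_labels)
    return classes[np.argmax(scores, axis=1)]


# -- SVM -------------------------------------------------------------------


def _fit_svc_precomputed(K: np.ndarray, y: np.ndarray, C: float) -> SVC:
    svc = SVC(C=C, kernel="precomputed")
    svc.fit(K, y)
    return svc


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    config: SVMConfig | None = None,
    random_state: int = 0,
) -> TrainedModel:
    """RBF-kernel one-vs-one SVM with (C, gamma) grid search.

    Kernels are precomputed once per gamma so the C sweep reuses them.
    Ties in the selection score prefer smaller C, then smaller gamma.
    """
    config = config or SVMConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    counts = np.array([(y == c).sum() for c in classes])
    if counts.min() < 2:
        raise ValueError("need at least 2 calibration rows per class")
    c_grid = config.c_grid()
    g_grid = config.gamma_grid()
    d2_full = _sq_dists(X, X)

    acc = np.zeros((c_grid.size, g_grid.size))
    if config.selection == "cv":
        n_folds = min(config.cv_folds, int(counts.min()))
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=random_state)
        for tr, va in skf.split(X, y):
            d2_tt = d2_full[np.ix_(tr, tr)]
            d2_vt = d2_full[np.ix_(va, tr)]
            for jg, g in enumerate(g_grid):
                K_tt = np.exp(-g * d2_tt)
                K_vt = np.exp(-g * d2_vt)
                for jc, C in enumerate(c_grid):
                    svc = _fit_svc_precomputed(K_tt, y[tr], C)
                    acc[jc, jg] += (svc.predict(K_vt) == y[va]).sum()
        acc /= y.size
    else:
        for jg, g in enumerate(g_grid):
            K = np.exp(-g * d2_full)
            for jc, C in enumerate(c_grid):
                svc = _fit_svc_precomputed(K, y, C)
                acc[jc, jg] = (svc.predict(K) == y).mean()

    flat = int(np.argmax(acc))  # row-major: first max -> smallest C, then gamma
    jc, jg = np.unravel_index(flat, acc.shape)
    C, gamma = float(c_grid[jc]), float(g_grid[jg])
    svc = _fit_svc_precomputed(np.exp(-gamma * d2_full), y, C)
    return TrainedModel(
        kind="svm",
        hyperparameters={
            "C": C,
            "gamma": gamma,
            "selection_accuracy": float(100.0 * acc[jc, jg]),
        },
        fit_state={"svc": svc, "X_train": X.copy(), "gamma": gamma, "C": C, "y_train": y.copy()},
        training_class_labels=[int(c) for c in classes],
    )


def predict_svm(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    st = model.fit_state
    K = np.exp(-st["gamma"] * _sq_dists(np.asarray(X, dtype=float), st["X_train"]))
    return st["svc"].predict(K).astype(int)


# -- generic prediction and evaluation ------------------------------------

_PREDICTORS = {"plsda": predict_plsda, "rbfnn": predict_rbfnn, "svm": predict_svm}


def predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    try:
        return _PREDICTORS[model.kind](model, X)
    except KeyError:
        raise ValueError(f"unknown model kind {model.kind!r}") from None


def evaluate(
    model: TrainedModel,
    calibration: tuple[np.ndarray, np.ndarray],
    prediction: tuple[np.ndarray, np.ndarray],
) -> EvalReport:
    """Per-class and total accuracy (%) on both sets.

    Labels absent from training can never be predicted and count as
    misclassifications (with a warning).
    """
    X_cal, y_cal = calibration
    X_pred, y_pred = prediction
    y_cal = np.asarray(y_cal, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    classes = sorted(set(y_cal.tolist()) | set(y_pred.tolist()))
    unknown = set(classes) - set(model.training_class_labels)
    if unknown:
        warnings.warn(
            f"labels {sorted(unknown)} absent from training; counted as errors",
            RuntimeWarning,
        )

    def _accs(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
        yhat = predict(model, X)
        per_class = np.array(
            [100.0 * np.mean(yhat[y == c] == c) if (y == c).any() else np.nan for c in classes]
        )
        return per_class, float(100.0 * np.mean(yhat == y))

    pc_cal, tot_cal = _accs(np.asarray(X_cal, dtype=float), y_cal)
    pc_pred, tot_pred = _accs(np.asarray(X_pred, dtype=float), y_pred)
    return EvalReport(
        classes=[int(c) for c in classes],
        per_class_calibration=pc_cal,
        total_calibration=tot_cal,
        per_class_prediction=pc_pred,
        total_prediction=tot_pred,
    )
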