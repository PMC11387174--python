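"""Classifiers and evaluation metrics.

Four algorithms behind one interface — an RBF-kernel support vector
machine (the primary model), random forest, binomial-family logistic
regression (GLM), and gradient-boosted trees — plus the rank-based AUROC,
threshold metrics (ACC/Sn/Sp), and the SVM cost/gamma grid search over
C in 2^-3..2^9 and gamma in 2^-15..2^-3.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
import sklearn
from scipy.stats import rankdata
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .encoders import FeatureMatrix

ALGORITHMS = ("SVM_RBF", "RF", "GLM", "GBT")


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUROC: P(random positive outscores random negative).

    Ties count one half — the Mann-Whitney U statistic divided by
    n_pos * n_neg.  Raises if only one class is present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes present")
    ranks = rankdata(s)  # average ranks implement the half-tie convention
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


@dataclass(frozen=True)
class HyperparameterGrid:
    """Exponent lattice for the SVM cost/gamma search.

    Defaults span exactly C in 2^-3..2^9 and gamma in 2^-15..2^-3 with the
    conventional step of 2 in the exponent (7 x 7 = 49 cells).
    """

    log2_C: tuple[int, ...] = tuple(range(-3, 10, 2))
    log2_gamma: tuple[int, ...] = tuple(range(-15, -2, 2))

    def __post_init__(self) -> None:
        if not self.log2_C or not self.log2_gamma:
            raise ValueError("grid axes must be non-empty")


@dataclass
class EvalReport:
    """Held-out evaluation: AUROC plus threshold metrics and confusion counts."""

    auroc: float
    acc: float
    sn: float
    sp: float
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float = 0.5

    @property
    def confusion(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fp, self.tn, self.fn)


@dataclass
class TrainedModel:
    """A fitted classifier with the metadata needed to reuse it safely.

    ``encoder_combo`` and ``window_length`` are populated when the model
    was trained through the window pipeline; prediction on mismatched
    feature layouts is rejected.
    """

    algorithm: str
    hyperparameters: dict
    estimator: object
    blocks: tuple[tuple[str, int], ...] | None = None
    encoder_combo: tuple[str, ...] | None = None
    window_length: int | None = None
    manifest: dict = field(default_factory=dict)


def _data_hash(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()


def make_estimator(
    algorithm: str,
    hyperparameters: dict | None = None,
    seed: int = 0,
    calibration_cv: int = 5,
):
    """Build an unfitted scikit-learn-style estimator for one algorithm.

    The SVM is wrapped in Platt-scaling calibration so user-facing scores
    are probabilities; the sigmoid map is monotone in the decision value,
    so rankings (and hence AUROC) match the raw SVM.
    """
    hp = dict(hyperparameters or {})
    if algorithm == "SVM_RBF":
        base = SVC(
            kernel="rbf",
            C=hp.get("C", 1.0),
            gamma=hp.get("gamma", "scale"),
            random_state=seed,
            cache_size=500,
        )
        return CalibratedClassifierCV(base, method="sigmoid", cv=calibration_cv,
                                      ensemble=False)
    if algorithm == "RF":
        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 100), random_state=seed
        )
    if algorithm == "GLM":
        return LogisticRegression(penalty=None, max_iter=hp.get("max_iter", 1000))
    if algorithm == "GBT":
        return XGBClassifier(
            n_estimators=hp.get("n_estimators", 100),
            random_state=seed,
            eval_metric="logloss",
            verbosity=0,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


def train(
    algorithm: str,
    features: FeatureMatrix | np.ndarray,
    labels: Sequence[int] | None = None,
    hyperparameters: dict | None = None,
    seed: int = 0,
    window_length: int | None = None,
) -> TrainedModel:
    """Fit one algorithm on a feature matrix.

    The GLM is unpenalized logistic regression; if separation prevents
    convergence it falls back to a tiny ridge penalty (1e-6) with a
    warning.  All fits are deterministic under ``seed``.
    """
    if isinstance(features, FeatureMatrix):
        X, blocks = features.X, features.blocks
        y = features.y if labels is None else np.asarray(labels, dtype=int)
        combo = tuple(name for name, _ in blocks)
    else:
        X, blocks, combo = np.asarray(features, dtype=float), None, None
        y = np.asarray(labels, dtype=int)
    if y is None:
        raise ValueError("labels required")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need >= 2 examples per class")
    if np.all(X == X[0:1, :]):
        raise ValueError("all-constant feature matrix")

    min_class = int(min((y == 1).sum(), (y == 0).sum()))
    est = make_estimator(algorithm, hyperparameters, seed,
                         calibration_cv=max(2, min(5, min_class)))
    if algorithm == "GLM":
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            est.fit(X, y)
            if any(issubclass(w.category, ConvergenceWarning) for w in caught):
                warnings.warn(
                    "GLM did not converge unpenalized; refitting with ridge penalty 1e-6",
                    stacklevel=2,
                )
                est = LogisticRegression(penalty="l2", C=1e6, max_iter=1000)
                est.fit(X, y)
    else:
        est.fit(X, y)

    return TrainedModel(
        algorithm=algorithm,
        hyperparameters=dict(hyperparameters or {}),
        estimator=est,
        blocks=blocks,
        encoder_combo=combo,
        window_length=window_length,
        manifest={
            "algorithm": algorithm,
            "hyperparameters": dict(hyperparameters or {}),
            "seed": seed,
            "window_length": window_length,
            "encoder_combo": list(combo) if combo else None,
            "n_train": int(X.shape[0]),
            "n_features": int(X.shape[1]),
            "data_hash": _data_hash(X, y),
            "sklearn_version": sklearn.__version__,
        },
    )


def _check_layout(model: TrainedModel, features: FeatureMatrix | np.ndarray) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        if model.blocks is not None and features.blocks != model.blocks:
            raise ValueError(
                f"feature layout mismatch: model expects {model.blocks}, got {features.blocks}"
            )
        return features.X
    X = np.asarray(features, dtype=float)
    expected = sum(n for _, n in model.blocks) if model.blocks else None
    if expected is not None and X.shape[1] != expected:
        raise ValueError(f"feature width mismatch: model expects {expected}, got {X.shape[1]}")
    return X


def predict(model: TrainedModel, features: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Probability-like scores in [0, 1], one per window, row-order stable."""
    X = _check_layout(model, features)
    est = model.estimator
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    # decision values squashed through a logistic map to satisfy the [0,1] contract
    return 1.0 / (1.0 + np.exp(-est.decision_function(X)))


def evaluate(
    model: TrainedModel,
    features: FeatureMatrix | np.ndarray,
    labels: Sequence[int] | None = None,
    threshold: float = 0.5,
) -> EvalReport:
    """Evaluate on held-out data at a classification threshold.

    AUROC is rank-based; ACC/Sn/Sp come from the confusion matrix at the
    threshold.  With a single-class test set the threshold metrics are
    still reported and AUROC is NaN (with a warning).
    """
    if isinstance(features, FeatureMatrix) and labels is None:
        labels = features.y
    y = np.asarray(labels, dtype=int)
    scores = predict(model, features)
    calls = (scores >= threshold).astype(int)
    tp = int(((calls == 1) & (y == 1)).sum())
    fp = int(((calls == 1) & (y == 0)).sum())
    tn = int(((calls == 0) & (y == 0)).sum())
    fn = int(((calls == 0) & (y == 1)).sum())
    acc = (tp + tn) / len(y) if len(y) else float("nan")
    sn = tp / (tp + fn) if (tp + fn) else float("nan")
    sp = tn / (tn + fp) if (tn + fp) else float("nan")
    try:
        auc = auroc(scores, y)
    except ValueError:
        warnings.warn("single-class test set: AUROC undefined (NaN)", stacklevel=2)
        auc = float("nan")
    return EvalReport(auroc=auc, acc=acc, sn=sn, sp=sp, tp=tp, fp=fp, tn=tn, fn=fn,
                      threshold=threshold)


@dataclass
class GridSearchResult:
    """Outcome of the cost/gamma sweep: the argmax cell and the full surface."""

    best_log2_C: int
    best_log2_gamma: int
    best_auroc: float
    surface: pd.DataFrame  # rows: log2_gamma, cols: log2_C, values: AUROC

    @property
    def best_C(self) -> float:
        return 2.0**self.best_log2_C

    @property
    def best_gamma(self) -> float:
        return 2.0**self.best_log2_gamma


def grid_search_svm(
    features: FeatureMatrix | np.ndarray,
    labels: Sequence[int] | None = None,
    grid: HyperparameterGrid | None = None,
    cv: int = 5,
    seed: int = 0,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> GridSearchResult:
    """Evaluate every (C, gamma) cell of the grid by validation AUROC.

    By default each cell is scored by stratified ``cv``-fold
    cross-validation on the supplied (training) data, so the held-out test
    partition is never touched during tuning.  Passing ``validation``
    scores cells on that external set instead.  Ties break toward smaller
    C, then smaller gamma (the less complex model).  Raw SVM decision
    values are used for ranking — AUROC only depends on score order.
    """
    grid = grid or HyperparameterGrid()
    if isinstance(features, FeatureMatrix):
        X = features.X
        y = features.y if labels is None else np.asarray(labels, dtype=int)
    else:
        X = np.asarray(features, dtype=float)
        y = np.asarray(labels, dtype=int)

    if validation is None:
        skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
        folds = list(skf.split(X, y))
    else:
        folds = None
        X_val, y_val = np.asarray(validation[0], dtype=float), np.asarray(validation[1], dtype=int)

    surface = pd.DataFrame(
        np.full((len(grid.log2_gamma), len(grid.log2_C)), np.nan),
        index=list(grid.log2_gamma),
        columns=list(grid.log2_C),
    )
    surface.index.name = "log2_gamma"
    surface.columns.name = "log2_C"

    best: tuple[float, int, int] | None = None  # (auroc, log2C, log2gamma)
    for lc in grid.log2_C:
        for lg in grid.log2_gamma:
            svc = SVC(kernel="rbf", C=2.0**lc, gamma=2.0**lg, cache_size=500)
            if folds is not None:
                fold_aucs = []
                for tr, va in folds:
                    svc.fit(X[tr], y[tr])
                    fold_aucs.append(auroc(svc.decision_function(X[va]), y[va]))
                cell = float(np.mean(fold_aucs))
            else:
                svc.fit(X, y)
                cell = auroc(svc.decision_function(X_val), y_val)
            surface.loc[lg, lc] = cell
            if best is None or cell > best[0]:
                best = (cell, lc, lg)
    assert best is not None
    return GridSearchResult(
        best_log2_C=best[1], best_log2_gamma=best[2], best_auroc=best[0], surface=surface
    )


def save_model(model: TrainedModel, path: str) -> None:
    """Serialize a model archive (fitted state + manifest) to one file."""
    joblib.dump(
        {
            "algorithm": model.algorithm,
            "hyperparameters": model.hyperparameters,
            "estimator": model.estimator,
            "blocks": model.blocks,
            "encoder_combo": model.encoder_combo,
            "window_length": model.window_length,
            "manifest": model.manifest,
        },
        path,
    )


def load_model(path: str) -> TrainedModel:
    """Load a model archive written by :func:`save_model`."""
    d = joblib.load(path)
    return TrainedModel(
        algorithm=d["algorithm"],
        hyperparameters=d["hyperparameters"],
        estimator=d["estimator"],
        blocks=d["blocks"],
        encoder_combo=d["encoder_combo"],
        window_length=d["window_length"],
        manifest=d["manifest"],
    )
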