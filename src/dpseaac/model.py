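"""RBF-kernel support vector classification with grid-searched C/gamma.

The margin optimisation itself is delegated to scikit-learn's libsvm
binding (``sklearn.svm.SVC``); this module fixes the conventions around
it: +1 = DNA-binding, -1 = non-binding; a decision value of exactly zero
maps to +1; grid-search ties break to the highest CV accuracy, then the
smallest C, then the smallest gamma; the solver tolerance is pinned at
1e-3 and persisted with the model. No feature scaling is applied —
per-stratum features already lie in [0, 1].

Default hyperparameter grids follow the conventional exponential
ladders C in 2^-5..2^15 (step 2^2) and gamma in 2^-15..2^3 (step 2^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .exceptions import EncodingError, ModelLoadError, TrainingError
from .features import EncodingConfig

SOLVER_TOL = 1e-3
MODEL_FORMAT_VERSION = 1

#: Conventional exponential grids for the (C, gamma) search.
DEFAULT_C_GRID = [2.0**k for k in range(-5, 16, 2)]
DEFAULT_GAMMA_GRID = [2.0**k for k in range(-15, 4, 2)]


@dataclass
class TrainedModel:
    """A fitted RBF-SVM plus the encoding it was trained under.

    ``svc.dual_coef_`` holds the label-signed dual coefficients a_i of
    the support vectors (bounded by C in absolute value); together with
    the stored training-set size they feed the discriminant-weight
    computation.
    """

    svc: SVC
    C: float
    gamma: float
    n_train: int
    config: EncodingConfig | None = None
    tol: float = SOLVER_TOL

    @property
    def n_features(self) -> int:
        return int(self.svc.shape_fit_[1])

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """Signed distances to the separating hyperplane, oriented so
        positive means DNA-binding."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise EncodingError(
                f"input has {X.shape[1]} features but the model was trained "
                f"on {self.n_features}"
            )
        return self.svc.decision_function(X)

    def predict(self, vector: np.ndarray) -> tuple[int, float]:
        """Predict one feature vector: ``(label, decision_value)``.

        The label is the sign of the decision value; an exact zero maps
        to +1.
        """
        dv = float(self.decision_values(np.asarray(vector, dtype=float).reshape(1, -1))[0])
        return (+1 if dv >= 0 else -1), dv

    def predict_batch(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Predict a feature matrix: ``(labels, decision_values)``."""
        dv = self.decision_values(X)
        return np.where(dv >= 0, +1, -1), dv


@dataclass
class GridSearchResult:
    """Outcome of an exhaustive (C, gamma) grid search."""

    best_C: float
    best_gamma: float
    best_score: float
    grid_scores: pd.DataFrame  # columns: C, gamma, cv_accuracy


def _validate_training_input(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise TrainingError(
            f"feature matrix {X.shape} does not match {y.shape[0]} labels"
        )
    if not np.isfinite(X).all():
        raise TrainingError("feature matrix contains non-finite values")
    classes = set(np.unique(y))
    if not classes <= {+1, -1}:
        raise TrainingError(f"labels must be +1/-1, got {sorted(classes)}")
    if len(classes) < 2:
        raise TrainingError("training requires both classes to be present")
    return X, y


def train(
    X: np.ndarray,
    y: Sequence[int],
    C: float,
    gamma: float,
    config: EncodingConfig | None = None,
) -> TrainedModel:
    """Fit the RBF-kernel classifier at fixed (C, gamma).

    Training is deterministic: refitting on identical input yields
    identical decision values.
    """
    X, y = _validate_training_input(X, np.asarray(y))
    if C <= 0 or gamma <= 0:
        raise TrainingError(f"C and gamma must be positive, got C={C}, gamma={gamma}")
    svc = SVC(kernel="rbf", C=C, gamma=gamma, tol=SOLVER_TOL, cache_size=256)
    svc.fit(X, y)
    return TrainedModel(svc=svc, C=C, gamma=gamma, n_train=X.shape[0], config=config)


def grid_search(
    X: np.ndarray,
    y: Sequence[int],
    C_grid: Sequence[float] | None = None,
    gamma_grid: Sequence[float] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> GridSearchResult:
    """Exhaustive (C, gamma) search by stratified k-fold CV accuracy.

    Deterministic given ``seed`` (which fixes the fold shuffle). Ties
    break to the smallest C, then the smallest gamma.
    """
    X, y = _validate_training_input(X, np.asarray(y))
    C_grid = list(C_grid) if C_grid is not None else DEFAULT_C_GRID
    gamma_grid = list(gamma_grid) if gamma_grid is not None else DEFAULT_GAMMA_GRID
    if not C_grid or not gamma_grid:
        raise ValueError("hyperparameter grids must be non-empty")
    if folds < 2:
        raise ValueError(f"folds must be >= 2, got {folds}")
    n_minority = min(np.sum(y == +1), np.sum(y == -1))
    if folds > n_minority:
        raise ValueError(
            f"{folds} folds exceed the minority class size {n_minority}"
        )

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    rows = []
    for C in C_grid:
        for gamma in gamma_grid:
            correct = 0
            for train_idx, test_idx in splits:
                svc = SVC(kernel="rbf", C=C, gamma=gamma, tol=SOLVER_TOL,
                          cache_size=256)
                svc.fit(X[train_idx], y[train_idx])
                correct += int(np.sum(svc.predict(X[test_idx]) == y[test_idx]))
            rows.append((C, gamma, correct / len(y)))
    scores = pd.DataFrame(rows, columns=["C", "gamma", "cv_accuracy"])
    best = scores.sort_values(
        ["cv_accuracy", "C", "gamma"], ascending=[False, True, True]
    ).iloc[0]
    return GridSearchResult(
        best_C=float(best["C"]),
        best_gamma=float(best["gamma"]),
        best_score=float(best["cv_accuracy"]),
        grid_scores=scores,
    )


def save_model(model: TrainedModel, path) -> None:
    """Persist a trained model as a self-describing archive.

    The archive records the solver parameters, the support data and the
    full encoding configuration (alphabet profile string, d_max,
    normalization) so prediction can re-encode consistently.
    """
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "svc": model.svc,
        "C": model.C,
        "gamma": model.gamma,
        "tol": model.tol,
        "n_train": model.n_train,
        "encoding": None,
    }
    if model.config is not None:
        payload["encoding"] = {
            "alphabet_name": model.config.alphabet.name,
            "profile": model.config.alphabet.to_profile_string(),
            "d_max": model.config.d_max,
            "normalization": model.config.normalization,
        }
    joblib.dump(payload, path)


def load_model(path) -> TrainedModel:
    """Load a model archive written by :func:`save_model`."""
    from .alphabets import parse_profile

    try:
        payload = joblib.load(path)
    except Exception as e:  # joblib raises a zoo of unpickling errors
        raise ModelLoadError(f"cannot read model file {path}: {e}") from e
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelLoadError(f"{path} is not a model archive")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ModelLoadError(
            f"{path}: format version {payload['format_version']} is not "
            f"supported (expected {MODEL_FORMAT_VERSION})"
        )
    config = None
    enc = payload.get("encoding")
    if enc is not None:
        config = EncodingConfig(
            alphabet=parse_profile(enc["profile"], name=enc["alphabet_name"]),
            d_max=enc["d_max"],
            normalization=enc["normalization"],
        )
    return TrainedModel(
        svc=payload["svc"],
        C=payload["C"],
        gamma=payload["gamma"],
        n_train=payload["n_train"],
        config=config,
        tol=payload["tol"],
    )
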