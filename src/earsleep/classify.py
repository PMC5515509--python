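"""Sleep-stage classification: tasks, feature scaling and cross-validation.

Three staging tasks are supported: wake vs sleep ({W} vs {N1,N2,N3}),
light vs deep ({W,N1} vs {N2,N3}) and the 4-class task (W/N1/N2/N3).  REM
and unscored epochs are rejected — they do not enter classification.

Features are min–max scaled to [0, 1] per fold using training-fold
statistics only (held-out values may fall outside [0, 1] and are not
clipped), and a one-vs-one RBF-kernel SVM is fitted per fold.  Held-out
predictions are pooled over the folds into a single confusion matrix,
matching how staging studies report one matrix per task.  A global
pre-CV scaling mode is config-gated for fidelity to pipelines that
normalise before splitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.svm import SVC

from .containers import STAGES, Hypnogram
from .errors import DegenerateDataError, InputError
from .metrics import EvalReport, classification_report, confusion_matrix


@dataclass(frozen=True)
class TaskSpec:
    """A staging task: a stage→class-index mapping plus class names."""

    name: str
    mapping: tuple[tuple[str, int], ...]
    class_names: tuple[str, ...]

    def stage_to_class(self) -> dict[str, int]:
        return dict(self.mapping)


TASKS: dict[str, TaskSpec] = {
    "wake_vs_sleep": TaskSpec(
        "wake_vs_sleep",
        (("W", 0), ("N1", 1), ("N2", 1), ("N3", 1)),
        ("W", "Sleep"),
    ),
    "wn1_vs_n2n3": TaskSpec(
        "wn1_vs_n2n3",
        (("W", 0), ("N1", 0), ("N2", 1), ("N3", 1)),
        ("W-N1", "N2-N3"),
    ),
    "four_class": TaskSpec(
        "four_class",
        tuple((s, i) for i, s in enumerate(STAGES)),
        STAGES,
    ),
}


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation and SVM settings.

    ``svm_gamma=None`` means 1/n_features; the string ``"grid"`` for
    either hyperparameter enables an inner 3-fold grid search
    (C ∈ 10^{-1..3}, gamma ∈ 10^{-3..1}) on the training folds only.
    """

    k: int = 5
    seed: int = 42
    stratified: bool = True
    svm_C: float | str = 1.0
    svm_gamma: float | str | None = None
    scaling: str = "per_fold"  # or "global"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise InputError(f"k must be >= 2, got {self.k}")
        if self.scaling not in ("per_fold", "global"):
            raise InputError(
                f"scaling must be 'per_fold' or 'global', got {self.scaling!r}"
            )


def collapse_labels(labels: Hypnogram | list, task: TaskSpec) -> np.ndarray:
    """Map stage labels to the task's integer class labels.

    Raises on any label outside {W, N1, N2, N3} — REM or unscored epochs
    must be filtered out upstream.
    """
    if isinstance(labels, Hypnogram):
        labels = labels.labels
    mapping = task.stage_to_class()
    out = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        lab = str(lab)
        if lab not in mapping:
            raise InputError(
                f"stage {lab!r} at epoch {i} has no class under task "
                f"{task.name!r} (REM/UNSCORED epochs cannot be classified)"
            )
        out[i] = mapping[lab]
    return out


def scale_features(
    train: pd.DataFrame | np.ndarray,
    apply_to: pd.DataFrame | np.ndarray | None = None,
):
    """Min–max scale to [0, 1] with statistics from ``train`` only.

    The same affine map is applied to ``apply_to``, whose values may
    legitimately land outside [0, 1] (no clipping).  A constant training
    column carries no information; it is mapped to 0.5 everywhere with a
    warning.

    Returns ``(train_scaled, apply_scaled)`` (the second is None when
    ``apply_to`` is None), preserving DataFrame-ness.
    """
    t = np.asarray(train, dtype=np.float64)
    if t.ndim != 2 or t.shape[0] == 0:
        raise InputError("train must be a non-empty 2-D table")
    lo = t.min(axis=0)
    hi = t.max(axis=0)
    span = hi - lo
    flat = span == 0
    if np.any(flat):
        warnings.warn(
            f"{int(flat.sum())} constant feature column(s) mapped to 0.5",
            stacklevel=2,
        )
    safe_span = np.where(flat, 1.0, span)

    def _apply(x):
        arr = np.asarray(x, dtype=np.float64)
        scaled = (arr - lo) / safe_span
        scaled[:, flat] = 0.5
        if isinstance(x, pd.DataFrame):
            return pd.DataFrame(scaled, index=x.index, columns=x.columns)
        return scaled

    return _apply(train), None if apply_to is None else _apply(apply_to)


def _fit_svm(x_train, y_train, cv_cfg: CVConfig) -> SVC:
    use_grid = cv_cfg.svm_C == "grid" or cv_cfg.svm_gamma == "grid"
    if use_grid:
        grid = {
            "C": [10.0 ** e for e in range(-1, 4)],
            "gamma": [10.0 ** e for e in range(-3, 2)],
        }
        search = GridSearchCV(
            SVC(kernel="rbf"), grid, cv=3, n_jobs=1, scoring="accuracy"
        )
        search.fit(x_train, y_train)
        return search.best_estimator_
    gamma = cv_cfg.svm_gamma
    if gamma is None:
        gamma = 1.0 / x_train.shape[1]
    clf = SVC(kernel="rbf", C=float(cv_cfg.svm_C), gamma=float(gamma))
    clf.fit(x_train, y_train)
    return clf


def cross_validate(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    task: TaskSpec,
    cv: CVConfig = CVConfig(),
) -> tuple[np.ndarray, EvalReport]:
    """Stratified k-fold CV of the one-vs-one RBF-SVM.

    Per fold: scale on the training fold, fit, predict the held-out fold.
    Predictions are pooled across folds and scored once.  Deterministic
    for a fixed seed.

    Returns
    -------
    (ndarray, EvalReport)
        Predicted class indices aligned to the input rows, and the pooled
        agreement report.
    """
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise InputError(
            f"features {x.shape} and labels {y.shape} are not aligned"
        )
    if np.isnan(x).any():
        raise InputError(
            "features contain missing values; drop incomplete epochs before CV"
        )
    present, counts = np.unique(y, return_counts=True)
    if present.size < 2:
        raise DegenerateDataError(
            "cross-validation needs at least two classes present"
        )
    if x.shape[0] < cv.k:
        raise InputError(f"{x.shape[0]} epochs < k={cv.k} folds")
    if cv.stratified and counts.min() < cv.k:
        scarce = task.class_names[int(present[np.argmin(counts)])]
        raise InputError(
            f"class {scarce!r} has only {int(counts.min())} epochs, fewer "
            f"than k={cv.k}; reduce k or disable stratification"
        )

    if cv.scaling == "global":
        x, _ = scale_features(x)

    if cv.stratified:
        splitter = StratifiedKFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)
    else:
        splitter = KFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)
    predictions = np.full(y.shape, -1, dtype=np.int64)
    for train_idx, test_idx in splitter.split(x, y):
        if cv.scaling == "per_fold":
            x_train, x_test = scale_features(x[train_idx], x[test_idx])
        else:
            x_train, x_test = x[train_idx], x[test_idx]
        clf = _fit_svm(x_train, y[train_idx], cv)
        predictions[test_idx] = clf.predict(x_test)

    names = task.class_names
    cm = confusion_matrix(
        [names[i] for i in y], [names[i] for i in predictions], classes=names
    )
    return predictions, classification_report(cm)
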