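"""Screening, classification and the PT-distance prognostic score.

Class imbalance is handled by duplicating minority rows, applied strictly
inside training folds; hyperparameter search likewise never sees test
folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC



__all__ = [
    "ScreenResult",
    "SVMConfig",
    "ClassificationReport",
    "rf_screen",
    "oversample",
    "svm_classify",
    "lr_classify",
    "pt_distance_score",
    "classification_report",
]

LABEL_POSITIVE = "R"


def _encode_labels(labels) -> np.ndarray:
    y = np.asarray([1 if l == LABEL_POSITIVE else 0 for l in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("both classes (R and NR) must be present")
    return y


@dataclass
class ScreenResult:
    marker_pair: tuple[str, str]
    mean_accuracy: float
    mean_auc: float

    @property
    def included(self) -> bool:
        """Excluded iff mean AUC < 0.5 (very low information)."""
        return self.mean_auc >= 0.5

    @property
    def high_confidence(self) -> bool:
        return self.mean_accuracy > 0.7


@dataclass
class SVMConfig:
    """RBF-kernel SVM settings; grids are one point per decade."""

    C: float = 10.0
    gamma: float = 0.001
    folds: int = 6
    grid_search: bool = False
    c_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(-2, 13, 16)
    )
    gamma_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(-9, 3, 13)
    )

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if len(self.c_grid) == 0 or len(self.gamma_grid) == 0:
            raise ValueError("degenerate hyperparameter grid")


@dataclass
class ClassificationReport:
    accuracy: float
    accuracy_std: float
    auc: float | None
    recall: float
    precision: float
    f1: float
    confusion: np.ndarray  # [[TN, FP], [FN, TP]]
    fold_accuracies: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    y_score: np.ndarray


def classification_report(y_true, y_pred, y_score=None) -> ClassificationReport:
    """Standard binary metrics; AUC by the rank statistic.

    With a single-class ``y_true`` the AUC is undefined and reported as
    None with a warning.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    accuracy = (tp + tn) / len(y_true)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    auc = None
    if y_score is not None:
        if len(np.unique(y_true)) < 2:
            warnings.warn("single-class y_true: AUC undefined", stacklevel=2)
        else:
            auc = float(roc_auc_score(y_true, np.asarray(y_score)))
    return ClassificationReport(
        accuracy=float(accuracy),
        accuracy_std=0.0,
        auc=auc,
        recall=float(recall),
        precision=float(precision),
        f1=float(f1),
        confusion=np.array([[tn, fp], [fn, tp]]),
        fold_accuracies=np.array([accuracy]),
        y_true=y_true,
        y_pred=y_pred,
        y_score=np.asarray(y_score) if y_score is not None else y_pred.astype(float),
    )


def oversample(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Duplicate minority rows cyclically until the classes balance."""
    X = np.asarray(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present to oversample")
    if counts[0] == counts[1]:
        return X, y
    minority = classes[np.argmin(counts)]
    deficit = int(abs(counts[0] - counts[1]))
    idx = np.where(y == minority)[0]
    extra = idx[np.arange(deficit) % len(idx)]
    return np.vstack([X, X[extra]]), np.concatenate([y, y[extra]])


def rf_screen(
    features: dict[tuple[str, str], np.ndarray],
    labels,
    n_estimators_range: tuple[int, int] = (20, 100),
    n_iter: int = 10,
    split: float = 0.6,
    seed: int = 0,
) -> list[ScreenResult]:
    """Random-Forest screening of marker pairs on descriptor vectors.

    For each pair: ``n_iter`` stratified train/test splits (``split``
    fraction to training), a forest whose estimator count sweeps the given
    range, and the mean test accuracy/AUC over iterations.  Pairs with mean
    AUC < 0.5 are flagged excluded.  Deterministic given ``seed``.
    """
    y = _encode_labels(labels)
    n_lo, n_hi = n_estimators_range
    if n_lo < 1 or n_hi < n_lo:
        raise ValueError(f"invalid n_estimators range {n_estimators_range}")
    n_estimators = np.linspace(n_lo, n_hi, n_iter).round().astype(int)
    results = []
    for pi, pair in enumerate(sorted(features)):
        X = np.asarray(features[pair])
        if X.shape[0] != len(y):
            raise ValueError(f"feature/label length mismatch for {pair}")
        accs, aucs = [], []
        for it in range(n_iter):
            X_tr, X_te, y_tr, y_te = train_test_split(
                X,
                y,
                train_size=split,
                stratify=y,
                random_state=seed * 10007 + pi * 101 + it,
            )
            if len(np.unique(y_tr)) < 2:
                raise ValueError("single-class training split")
            rf = RandomForestClassifier(
                n_estimators=int(n_estimators[it]),
                random_state=seed * 10007 + pi * 101 + it,
            ).fit(X_tr, y_tr)
            accs.append(accuracy_score(y_te, rf.predict(X_te)))
            aucs.append(roc_auc_score(y_te, rf.predict_proba(X_te)[:, 1]))
        results.append(
            ScreenResult(
                marker_pair=pair,
                mean_accuracy=float(np.mean(accs)),
                mean_auc=float(np.mean(aucs)),
            )
        )
    results.sort(key=lambda r: (-r.mean_auc, -r.mean_accuracy, r.marker_pair))
    return results


def _svc(C: float, gamma: float):
    # features are standardised inside the fold before the RBF kernel: PI
    # pixel scales depend on landmark count, and the fixed (C, gamma)
    # regime assumes unit-scale features
    return make_pipeline(StandardScaler(), SVC(C=C, gamma=gamma, kernel="rbf"))


def _fit_svm(X_tr, y_tr, config: SVMConfig, seed: int):
    if config.grid_search:
        best, best_score = (config.C, config.gamma), -np.inf
        inner_folds = min(3, np.bincount(y_tr).min())
        if inner_folds < 2:
            raise ValueError("not enough minority samples for inner grid search")
        skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
        for C in config.c_grid:
            for gamma in config.gamma_grid:
                scores = []
                for tr, va in skf.split(X_tr, y_tr):
                    clf = _svc(C, gamma).fit(X_tr[tr], y_tr[tr])
                    scores.append(accuracy_score(y_tr[va], clf.predict(X_tr[va])))
                score = np.mean(scores)
                if score > best_score:
                    best, best_score = (C, gamma), score
        C, gamma = best
    else:
        C, gamma = config.C, config.gamma
    return _svc(C, gamma).fit(X_tr, y_tr)


def _cv_classify(X, y, folds, seed, fit_fn, do_oversample) -> ClassificationReport:
    minority = int(np.bincount(y).min())
    if folds > minority:
        warnings.warn(
            f"reducing folds from {folds} to minority count {minority}",
            stacklevel=3,
        )
        folds = minority
    if folds < 2:
        raise ValueError("need at least 2 folds (and 2 minority samples)")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    y_score = np.empty(len(y), float)
    fold_accs = []
    for tr, te in skf.split(X, y):
        X_tr, y_tr = X[tr], y[tr]
        if do_oversample:
            X_tr, y_tr = oversample(X_tr, y_tr)
        clf = fit_fn(X_tr, y_tr)
        pred = clf.predict(X[te])
        y_pred[te] = pred
        if hasattr(clf, "predict_proba"):
            y_score[te] = clf.predict_proba(X[te])[:, 1]
        else:
            y_score[te] = clf.decision_function(X[te])
        fold_accs.append(accuracy_score(y[te], pred))
    report = classification_report(y, y_pred, y_score)
    report.accuracy = float(np.mean(fold_accs))
    report.accuracy_std = float(np.std(fold_accs))
    report.fold_accuracies = np.array(fold_accs)
    return report


def svm_classify(
    pis: np.ndarray,
    labels,
    config: SVMConfig | None = None,
    oversample_minority: bool = True,
    seed: int = 0,
) -> ClassificationReport:
    """Stratified k-fold CV of an RBF SVM on PI feature vectors.

    Hyperparameters are either fixed (C=10, gamma=0.001 by default) or
    grid-searched within each training fold; oversampling happens inside
    training folds only.
    """
    config = config or SVMConfig()
    X = np.asarray(pis, float)
    if not np.isfinite(X).all():
        raise ValueError("PI features must be finite")
    y = _encode_labels(labels)
    return _cv_classify(
        X,
        y,
        config.folds,
        seed,
        lambda Xt, yt: _fit_svm(Xt, yt, config, seed),
        oversample_minority,
    )


def lr_classify(
    pis: np.ndarray,
    labels,
    folds: int = 6,
    oversample_minority: bool = True,
    seed: int = 0,
    coef_shape: tuple[int, int] | None = None,
) -> tuple[ClassificationReport, np.ndarray]:
    """Logistic-regression CV on flattened PIs + decision-function image.

    The coefficient vector of a full-data fit is reshaped to ``coef_shape``
    (or a square guess) for visualisation.
    """
    X = np.asarray(pis, float)
    y = _encode_labels(labels)

    def fit(Xt, yt):
        return LogisticRegression(max_iter=5000, random_state=seed).fit(Xt, yt)

    report = _cv_classify(X, y, folds, seed, fit, oversample_minority)
    X_full, y_full = (oversample(X, y) if oversample_minority else (X, y))
    coef = fit(X_full, y_full).coef_.ravel()
    if coef_shape is None:
        g = int(round(np.sqrt(len(coef))))
        coef_shape = (g, g) if g * g == len(coef) else (1, len(coef))
    return report, coef.reshape(coef_shape)


def pt_distance_score(
    patient_curves: dict,
    mean_nr: dict,
    mean_r: dict,
) -> float:
    """Relapse probability from PT-curve distances to cohort means.

    For each key (marker pair, optionally per dimension), compute Euclidean
    distances d_NR and d_R between the patient's curve counts and the two
    cohort mean curves, score the pair as d_NR / (d_NR + d_R) (0.5 when
    both vanish), and average over keys.
    """
    if not patient_curves:
        raise ValueError("need at least one marker pair")
    if set(patient_curves) != set(mean_nr) or set(patient_curves) != set(mean_r):
        raise ValueError("patient and cohort curves must share the same keys")
    scores = []
    for key, curve in patient_curves.items():
        ref_nr, ref_r = mean_nr[key], mean_r[key]
        if not curve.same_grid(ref_nr) or not curve.same_grid(ref_r):
            raise ValueError(f"tau grid mismatch for {key}")
        d_nr = float(np.linalg.norm(curve.counts - ref_nr.counts))
        d_r = float(np.linalg.norm(curve.counts - ref_r.counts))
        if d_nr == 0.0 and d_r == 0.0:
            scores.append(0.5)
        else:
            scores.append(d_nr / (d_nr + d_r))
    return float(np.mean(scores))
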