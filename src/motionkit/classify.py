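"""Severity classifiers (kNN, ordinal probit regression, polynomial SVM)
with the cross-validation protocols and error metrics used for automated
motor-score assessment.

Feature vectors are expected scaled to [0, 1] (see
:mod:`motionkit.selection`).  Labels are ordinal integers: 0/1 for HC/PD
in the binary problem, 1/2/3 for the three severity classes.  The absolute
class error ``e_c = |C - C'|`` measures how far an automated assessment
falls from the clinician-assigned class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import MotionKitError


# ---------------------------------------------------------------------------
# kNN with the k-decrement tie rule
# ---------------------------------------------------------------------------

def knn_predict(
    X_train: np.ndarray, y_train: np.ndarray, x: np.ndarray, k: int = 3
) -> int:
    """Majority class among the k Euclidean-nearest training points.

    On a vote tie, k is decremented by 1 and the vote repeated until the
    tie breaks (k=1 always breaks it).  Distance ties at the k-th neighbor
    are resolved by stable index order, so predictions are deterministic.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    if X_train.shape[0] == 0:
        raise MotionKitError("empty training set")
    k = min(k, X_train.shape[0])
    d = np.linalg.norm(X_train - np.asarray(x, dtype=float), axis=1)
    order = np.argsort(d, kind="stable")
    while k >= 1:
        votes = y_train[order[:k]]
        classes, counts = np.unique(votes, return_counts=True)
        winners = classes[counts == counts.max()]
        if winners.size == 1:
            return winners[0]
        k -= 1
    return y_train[order[0]]  # unreachable: k=1 has a single vote


# ---------------------------------------------------------------------------
# Ordinal multinomial regression (cumulative probit)
# ---------------------------------------------------------------------------

@dataclass
class OrdinalProbitModel:
    """Cumulative-probit ordinal regression fit; predicts the modal class.

    ``feature_mask`` records which training columns carried information
    (constant columns cannot enter a location-scale ordinal model and are
    dropped); ``result`` is None in the fully degenerate no-feature case,
    where the modal training class is predicted.
    """

    classes: np.ndarray
    result: object
    converged: bool
    feature_mask: np.ndarray
    modal_class: object = None

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))[:, self.feature_mask]
        return np.asarray(self.result.model.predict(self.result.params, exog=X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.result is None:
            return np.full(X.shape[0], self.modal_class, dtype=self.classes.dtype)
        return self.classes[np.argmax(self.predict_proba(X), axis=1)]


def mlr_fit(X: np.ndarray, y: np.ndarray) -> OrdinalProbitModel:
    """Fit a cumulative-probit ordinal regression of class on features.

    Perfect separation drives the thresholds/coefficients toward the
    optimizer box; the fit is flagged (``converged=False``) but prediction
    remains defined.
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or np.any(counts < 2):
        raise MotionKitError("need >= 2 classes with >= 2 members each")
    codes = np.searchsorted(classes, y)
    mask = X.std(axis=0) > 1e-12  # constant columns carry no information
    if not mask.any():
        modal = classes[np.argmax(counts)]
        return OrdinalProbitModel(classes, None, False, mask, modal)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # hasconst=False: no intercept by construction (thresholds absorb
        # it); also avoids spurious implicit-constant detection on nearly
        # collinear feature columns
        model = OrderedModel(codes, X[:, mask], distr="probit", hasconst=False)
        try:
            result = model.fit(method="bfgs", maxiter=200, disp=0)
            converged = bool(result.mle_retvals.get("converged", False))
        except Exception:
            result = model.fit(method="nm", maxiter=2000, disp=0)
            converged = False
    return OrdinalProbitModel(classes, result, converged, mask)


def mlr_predict(model: OrdinalProbitModel, x: np.ndarray) -> int:
    return model.predict(np.atleast_2d(x))[0]


# ---------------------------------------------------------------------------
# Polynomial-kernel SVM, one-vs-one with majority voting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SVMSpec:
    """Polynomial-kernel SVM hyperparameters: K(u,v) = (gamma u.v + r)^d."""

    C: float = 10.0
    gamma: float = 1.0
    r: float = 1.0
    d: int = 2

    def __post_init__(self) -> None:
        if self.C <= 0 or self.d < 1:
            raise ValueError("require C > 0 and integer degree d >= 1")


#: Default hyperparameter grid for the grid search.
DEFAULT_SVM_GRID: tuple[SVMSpec, ...] = tuple(
    SVMSpec(C=C, gamma=g, r=r, d=d)
    for C in (0.1, 1.0, 10.0, 100.0)
    for g in (0.1, 1.0, 10.0)
    for r in (0.0, 1.0)
    for d in (1, 2, 3)
)


@dataclass
class PolySVM:
    """One-vs-one polynomial SVM: one binary machine per class pair, all
    sharing the same hyperparameters, combined by majority vote with ties
    broken by summed decision values."""

    spec: SVMSpec = field(default_factory=SVMSpec)
    classes_: np.ndarray | None = None
    _machines: list[tuple[object, object, object]] = field(default_factory=list)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PolySVM":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise MotionKitError("need >= 2 classes in training data")
        self._machines = []
        for i in range(self.classes_.size):
            for j in range(i + 1, self.classes_.size):
                ci, cj = self.classes_[i], self.classes_[j]
                mask = (y == ci) | (y == cj)
                svc = SVC(
                    kernel="poly",
                    C=self.spec.C,
                    gamma=self.spec.gamma,
                    coef0=self.spec.r,
                    degree=self.spec.d,
                )
                svc.fit(X[mask], (y[mask] == cj).astype(int))
                self._machines.append((ci, cj, svc))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = X.shape[0]
        idx = {c: i for i, c in enumerate(self.classes_)}
        votes = np.zeros((n, self.classes_.size), dtype=int)
        scores = np.zeros((n, self.classes_.size), dtype=float)
        for ci, cj, svc in self._machines:
            dec = svc.decision_function(X)  # positive -> cj
            winner_j = dec > 0
            votes[winner_j, idx[cj]] += 1
            votes[~winner_j, idx[ci]] += 1
            scores[:, idx[cj]] += dec
            scores[:, idx[ci]] -= dec
        out = np.empty(n, dtype=self.classes_.dtype)
        for row in range(n):
            top = votes[row].max()
            tied = np.flatnonzero(votes[row] == top)
            if tied.size == 1:
                out[row] = self.classes_[tied[0]]
            else:  # tie: class with the largest summed decision value
                out[row] = self.classes_[tied[np.argmax(scores[row, tied])]]
        return out


def svm_train(
    X: np.ndarray,
    y: np.ndarray,
    grid: Sequence[SVMSpec] | None = None,
    inner_cv: int = 5,
    seed: int = 0,
) -> tuple[PolySVM, SVMSpec]:
    """Train a one-vs-one polynomial SVM, tuning hyperparameters on a grid.

    Each grid point is scored by stratified inner-CV accuracy; ties go to
    the smaller C, then the smaller degree d.  With ``grid=None`` the
    default grid is searched; pass a single-element grid to fix the
    hyperparameters.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    grid = list(grid) if grid is not None else list(DEFAULT_SVM_GRID)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if len(grid) == 1:
        best = grid[0]
    else:
        _, counts = np.unique(y, return_counts=True)
        n_splits = int(min(inner_cv, counts.min()))
        if n_splits < 2:
            raise MotionKitError("a class is too small for inner CV")
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        splits = list(skf.split(X, y))
        best, best_key = None, None
        for spec in grid:
            correct = 0
            for tr, te in splits:
                pred = PolySVM(spec).fit(X[tr], y[tr]).predict(X[te])
                correct += int(np.sum(pred == y[te]))
            key = (-correct, spec.C, spec.d)  # ties -> smaller C, then smaller d
            if best_key is None or key < best_key:
                best, best_key = spec, key
    return PolySVM(best).fit(X, y), best


def svm_predict(model: PolySVM, x: np.ndarray) -> int:
    return model.predict(np.atleast_2d(x))[0]


# ---------------------------------------------------------------------------
# Cross-validation protocols and error metrics
# ---------------------------------------------------------------------------

def abs_class_error(truth: Sequence, pred: Sequence) -> tuple[np.ndarray, int]:
    """Element-wise absolute ordinal class error and its maximum."""
    truth = np.asarray(truth, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if truth.shape != pred.shape:
        raise ValueError("truth / prediction length mismatch")
    e = np.abs(truth - pred).astype(int)
    return e, int(e.max()) if e.size else 0


@dataclass
class CVReport:
    """Cross-validated performance of one classifier on one task."""

    protocol: str
    accuracy: float                    # overall, percent
    per_class_accuracy: float          # unweighted mean of class recalls, percent
    class_recalls: dict                # class -> recall percent
    e_c: np.ndarray | None             # per-instance absolute class error (LOOCV)
    max_e_c: int | None
    mean_e_c: float | None

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "accuracy": self.accuracy,
            "per_class_accuracy": self.per_class_accuracy,
            "class_recalls": {str(k): v for k, v in self.class_recalls.items()},
            "max_e_c": self.max_e_c,
            "mean_e_c": self.mean_e_c,
        }


def _fit_predict(model: str, X_tr, y_tr, X_te, **kw):
    if model == "knn":
        k = kw.get("k", 3)
        return np.array([knn_predict(X_tr, y_tr, x, k=k) for x in np.atleast_2d(X_te)])
    if model == "mlr":
        return mlr_fit(X_tr, y_tr).predict(X_te)
    if model == "svm":
        grid = kw.get("grid")
        if grid is None:
            grid = [kw.get("spec") or SVMSpec()]
        fitted, _ = svm_train(X_tr, y_tr, grid=grid, seed=kw.get("seed", 0))
        return fitted.predict(X_te)
    raise ValueError(f"unknown model {model!r}")


def _summarize(y: np.ndarray, pred: np.ndarray, protocol: str) -> CVReport:
    classes = np.unique(y)
    recalls = {
        c: 100.0 * float(np.mean(pred[y == c] == c)) for c in classes
    }
    ordinal = np.issubdtype(np.asarray(y).dtype, np.number)
    e_c, max_e = abs_class_error(y, pred) if ordinal else (None, None)
    return CVReport(
        protocol=protocol,
        accuracy=100.0 * float(np.mean(pred == y)),
        per_class_accuracy=float(np.mean(list(recalls.values()))),
        class_recalls=recalls,
        e_c=e_c,
        max_e_c=max_e,
        mean_e_c=float(e_c.mean()) if e_c is not None else None,
    )


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    model: str = "svm",
    protocol: str = "loo",
    repeats: int = 100,
    seed: int = 0,
    **model_kw,
) -> CVReport:
    """Cross-validated assessment accuracy.

    ``protocol='loo'`` is deterministic leave-one-out; ``'kfold10'`` is
    stratified 10-fold repeated ``repeats`` times with seeded shuffles,
    accuracies averaged across repeats.  The report carries the overall
    accuracy, the per-class accuracy (unweighted mean of class recalls) and
    — for ordinal numeric labels — the absolute class error distribution.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if protocol == "loo":
        pred = np.empty_like(y)
        for i in range(len(y)):
            mask = np.ones(len(y), dtype=bool)
            mask[i] = False
            pred[i] = _fit_predict(model, X[mask], y[mask], X[i:i + 1], **model_kw)[0]
        return _summarize(y, pred, "LOOCV")
    if protocol == "kfold10":
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < 10:
            raise MotionKitError(
                f"smallest class ({counts.min()}) < 10 folds: cannot stratify"
            )
        accs, pcas = [], []
        for r in range(repeats):
            skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=seed + r)
            pred = np.empty_like(y)
            for tr, te in skf.split(X, y):
                pred[te] = _fit_predict(model, X[tr], y[tr], X[te], **model_kw)
            rep = _summarize(y, pred, "10-fold")
            accs.append(rep.accuracy)
            pcas.append(rep.per_class_accuracy)
        return CVReport(
            protocol=f"10-fold x{repeats}",
            accuracy=float(np.mean(accs)),
            per_class_accuracy=float(np.mean(pcas)),
            class_recalls={},
            e_c=None,
            max_e_c=None,
            mean_e_c=None,
        )
    raise ValueError("protocol must be 'loo' or 'kfold10'")
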