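"""PCA, PLS-DA (SIMPLS), venetian-blinds cross-validation and metrics.

PLS-DA is PLS2 regression of a two-column 0/1 class dummy matrix on the
spectra, followed by an argmax decision over the predicted responses
(equivalent, for two complementary columns, to a 0.5 threshold on their
difference).  Latent variables are extracted with the SIMPLS algorithm
(de Jong 1993); a NIPALS implementation is kept as an internal
cross-check oracle.  For the dummy coding the centered response matrix
has rank 1, so SIMPLS and NIPALS span identical subspaces and agree on
the continuous responses to numerical precision.

Classification quality is summarized by the standard binary confusion
quantities::

    accuracy%   = 100 (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    class error = 1 - (sensitivity + specificity) / 2

with the cooking class conventionally treated as positive.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np

from .errors import DegenerateLabelsError, ParameterError
from .preprocess import PreprocessChain, build_chain

logger = logging.getLogger(__name__)

__all__ = [
    "PCAModel",
    "PLSDAModel",
    "CVPlan",
    "ConfusionStats",
    "pca_fit",
    "simpls",
    "nipals_pls",
    "plsda_fit",
    "plsda_predict",
    "venetian_blinds",
    "cross_validate",
    "select_n_lv",
    "confusion_stats",
    "class_error_from_rates",
]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PCAModel:
    loadings: np.ndarray  # bands x n_pc, orthonormal columns
    scores: np.ndarray  # samples x n_pc
    explained_variance_pct: np.ndarray  # per-PC share of total variance
    center: np.ndarray  # mean spectrum


def pca_fit(X: np.ndarray, n_pc: int) -> PCAModel:
    """PCA by SVD of the column-centered matrix.

    ``explained_variance_pct[i]`` is the squared-singular-value share of
    PC ``i`` in percent; the shares are non-increasing and sum to <= 100.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    max_pc = min(n - 1, p)
    if not 1 <= n_pc <= max_pc:
        raise ParameterError(f"n_pc must be in [1, {max_pc}], got {n_pc}")
    center = X.mean(axis=0)
    Xc = X - center
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s**2))
    explained = 100.0 * s[:n_pc] ** 2 / total
    return PCAModel(
        loadings=Vt[:n_pc].T.copy(),
        scores=(U[:, :n_pc] * s[:n_pc]),
        explained_variance_pct=explained,
        center=center,
    )


# ---------------------------------------------------------------------------
# PLS cores
# ---------------------------------------------------------------------------


def simpls(Xc: np.ndarray, Yc: np.ndarray, n_components: int):
    """SIMPLS on centered X (n x p) and Y (n x q).

    Returns ``(R, P, Q, T)`` with weights R such that ``T = Xc R`` has
    orthonormal columns, X-loadings P, Y-loadings Q.  The regression
    coefficient matrix truncated to ``a`` components is
    ``R[:, :a] @ Q[:, :a].T``.  Extraction stops early if the covariance
    matrix is numerically exhausted.
    """
    Xc = np.asarray(Xc, dtype=float)
    Yc = np.asarray(Yc, dtype=float)
    n, p = Xc.shape
    q = Yc.shape[1]
    a_max = n_components
    R = np.zeros((p, a_max))
    P = np.zeros((p, a_max))
    Q = np.zeros((q, a_max))
    T = np.zeros((n, a_max))
    V = np.zeros((p, a_max))
    S = Xc.T @ Yc
    n_found = 0
    for i in range(a_max):
        U_s, sv, _ = np.linalg.svd(S, full_matrices=False)
        if sv[0] <= 1e-12:
            break
        r = U_s[:, 0]
        t = Xc @ r
        t = t - t.mean()
        norm_t = float(np.linalg.norm(t))
        if norm_t <= 1e-12:
            break
        t /= norm_t
        r = r / norm_t
        p_load = Xc.T @ t
        q_load = Yc.T @ t
        v = p_load.copy()
        if i > 0:
            v -= V[:, :i] @ (V[:, :i].T @ p_load)
        norm_v = float(np.linalg.norm(v))
        if norm_v <= 1e-12:
            break
        v /= norm_v
        S = S - np.outer(v, v @ S)
        R[:, i], P[:, i], Q[:, i], T[:, i], V[:, i] = r, p_load, q_load, t, v
        n_found = i + 1
    return R[:, :n_found], P[:, :n_found], Q[:, :n_found], T[:, :n_found]


def nipals_pls(Xc: np.ndarray, Yc: np.ndarray, n_components: int, tol: float = 1e-12, max_iter: int = 500):
    """NIPALS PLS2 on centered matrices; internal cross-check oracle.

    Returns the coefficient matrix ``B`` such that ``Yhat = Xc B``.
    """
    Xk = np.asarray(Xc, dtype=float).copy()
    Yk = np.asarray(Yc, dtype=float).copy()
    n, p = Xk.shape
    q = Yk.shape[1]
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((q, n_components))
    n_found = 0
    for i in range(n_components):
        if np.linalg.norm(Yk) <= 1e-12 or np.linalg.norm(Xk) <= 1e-12:
            break
        u = Yk[:, int(np.argmax(Yk.var(axis=0)))].copy()
        t_old = None
        for _ in range(max_iter):
            w = Xk.T @ u
            norm_w = np.linalg.norm(w)
            if norm_w <= 1e-14:
                break
            w /= norm_w
            t = Xk @ w
            qv = Yk.T @ t / (t @ t)
            u = Yk @ qv / (qv @ qv)
            if t_old is not None and np.linalg.norm(t - t_old) <= tol * np.linalg.norm(t):
                break
            t_old = t
        tt = t @ t
        if tt <= 1e-14:
            break
        p_load = Xk.T @ t / tt
        q_load = Yk.T @ t / tt
        Xk -= np.outer(t, p_load)
        Yk -= np.outer(t, q_load)
        W[:, i], P[:, i], Q[:, i] = w, p_load, q_load
        n_found = i + 1
    W, P, Q = W[:, :n_found], P[:, :n_found], Q[:, :n_found]
    B = W @ np.linalg.solve(P.T @ W, Q.T)
    return B


# ---------------------------------------------------------------------------
# PLS-DA model
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PLSDAModel:
    """Fitted PLS-DA model (two classes, dummy-coded responses)."""

    classes: np.ndarray  # length-2 array of class labels; column order of Y
    n_lv: int
    x_mean: np.ndarray
    y_mean: np.ndarray
    x_weights: np.ndarray  # R: bands x n_lv, T = (X - x_mean) R
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    explained_x_variance_pct: np.ndarray  # cumulative, per retained LV
    chain: PreprocessChain | None = None

    @property
    def coefficients(self) -> np.ndarray:
        """bands x classes regression matrix at the model's n_lv."""
        return self.coefficients_at(self.n_lv)

    def coefficients_at(self, a: int) -> np.ndarray:
        a = min(a, self.x_weights.shape[1])
        return self.x_weights[:, :a] @ self.y_loadings[:, :a].T

    def predict_scores(self, X: np.ndarray, n_lv: int | None = None) -> np.ndarray:
        """Continuous response per class (n_samples x 2)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.x_weights.shape[0]:
            raise ParameterError(
                f"{X.shape[1]} bands do not match model ({self.x_weights.shape[0]})"
            )
        a = self.n_lv if n_lv is None else n_lv
        return (X - self.x_mean) @ self.coefficients_at(a) + self.y_mean

    def predict_scores_all_lv(self, X: np.ndarray) -> np.ndarray:
        """Responses for every LV truncation: (n_samples, 2, n_lv_available)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        T_new = (X - self.x_mean) @ self.x_weights  # n x a
        contrib = T_new[:, None, :] * self.y_loadings[None, :, :]  # n x q x a
        return np.cumsum(contrib, axis=2) + self.y_mean[None, :, None]

    def predict(self, X: np.ndarray, n_lv: int | None = None) -> np.ndarray:
        scores = self.predict_scores(X, n_lv)
        return _decide(scores, self.classes)


def _decide(scores: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Argmax decision; ties resolve to the first class and are logged."""
    ties = scores[:, 0] == scores[:, 1]
    if np.any(ties):
        logger.info("argmax decision tie on %d sample(s); first class chosen", ties.sum())
    return classes[(scores[:, 1] > scores[:, 0]).astype(int)]


def _dummy(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    return (np.asarray(y)[:, None] == classes[None, :]).astype(float)


def _resolve_classes(y: np.ndarray, classes: Sequence | None) -> np.ndarray:
    present = np.unique(np.asarray(y))
    if classes is None:
        classes = present
    classes = np.asarray(classes)
    if classes.size != 2:
        raise DegenerateLabelsError(f"exactly 2 classes required, got {classes.size}")
    if present.size < 2:
        raise DegenerateLabelsError(f"only one class present: {present.tolist()}")
    return classes


def plsda_fit(
    X: np.ndarray,
    y: Sequence,
    n_lv: int,
    classes: Sequence | None = None,
    chain: PreprocessChain | None = None,
) -> PLSDAModel:
    """Fit a binary PLS-DA model with ``n_lv`` latent variables.

    ``X`` must already be pre-processed; an optional fitted chain can be
    attached for bookkeeping.  ``n_lv`` is capped at min(n_samples - 1,
    n_bands) and at the numerical rank found by SIMPLS.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    cls = _resolve_classes(y, classes)
    n, p = X.shape
    cap = min(n - 1, p)
    if not 1 <= n_lv <= cap:
        raise ParameterError(f"n_lv must be in [1, {cap}], got {n_lv}")
    x_mean = X.mean(axis=0)
    Y = _dummy(y, cls)
    y_mean = Y.mean(axis=0)
    R, P, Q, T = simpls(X - x_mean, Y - y_mean, n_lv)
    ss_x = float(np.sum((X - x_mean) ** 2))
    per_lv = np.sum(P**2, axis=0) / ss_x * 100.0 if ss_x > 0 else np.zeros(R.shape[1])
    return PLSDAModel(
        classes=cls,
        n_lv=R.shape[1],
        x_mean=x_mean,
        y_mean=y_mean,
        x_weights=R,
        x_loadings=P,
        y_loadings=Q,
        explained_x_variance_pct=np.cumsum(per_lv),
        chain=chain,
    )


def plsda_predict(model: PLSDAModel, X_new: np.ndarray):
    """Predicted labels and continuous per-class responses."""
    scores = model.predict_scores(X_new)
    return _decide(scores, model.classes), scores


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class CVPlan:
    """Venetian-blinds fold assignment over sample order."""

    n_splits: int
    blind_width: int
    assignment: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.assignment.size


def venetian_blinds(n_samples: int, n_splits: int = 10, width: int = 1) -> CVPlan:
    """Interleaved folds: ``fold(i) = floor(i / width) mod n_splits``."""
    if n_splits < 2:
        raise ParameterError(f"n_splits must be >= 2, got {n_splits}")
    if width < 1:
        raise ParameterError(f"width must be >= 1, got {width}")
    if n_samples < n_splits:
        raise ParameterError(f"n_samples={n_samples} < n_splits={n_splits}")
    idx = np.arange(n_samples)
    return CVPlan(n_splits, width, (idx // width) % n_splits)


@dataclasses.dataclass
class ConfusionStats:
    """Binary confusion counts and the derived rates."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else math.nan

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else math.nan

    @property
    def class_error(self) -> float:
        return class_error_from_rates(self.sensitivity, self.specificity)

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n if self.n else math.nan

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "class_error": self.class_error,
            "accuracy_pct": self.accuracy_pct,
        }


def class_error_from_rates(sensitivity: float, specificity: float) -> float:
    """``1 - (sensitivity + specificity) / 2``."""
    return 1.0 - (sensitivity + specificity) / 2.0


def confusion_stats(y_true, y_pred, positive_class) -> ConfusionStats:
    """Confusion counts with the stated positive class (cooking, by convention)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ParameterError("empty label vectors")
    if y_true.shape != y_pred.shape:
        raise ParameterError("y_true and y_pred lengths differ")
    pos_t = y_true == positive_class
    pos_p = y_pred == positive_class
    return ConfusionStats(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def _heldout_scores_per_lv(
    X: np.ndarray,
    y: np.ndarray,
    chain: PreprocessChain | None,
    max_lv: int,
    plan: CVPlan,
    classes: np.ndarray,
):
    """Held-out continuous responses for every LV truncation.

    Returns ``(scores, evaluated)`` where ``scores`` is
    (n_samples, 2, max_lv) with NaN for samples in skipped folds, and
    ``evaluated`` flags the samples with predictions.  Within each fold
    the stateful chain steps are re-fitted on the training portion only,
    and one SIMPLS decomposition at ``max_lv`` yields all truncations.
    """
    n = len(y)
    scores = np.full((n, 2, max_lv), np.nan)
    evaluated = np.zeros(n, dtype=bool)
    for f in range(plan.n_splits):
        test = plan.assignment == f
        train = ~test
        if not test.any():
            continue
        if np.unique(y[train]).size < 2:
            logger.warning("fold %d skipped: single class in training portion", f)
            continue
        if chain is not None and chain.steps:
            ch = chain.clone()
            X_tr = ch.fit_transform(X[train])
            X_te = ch.transform(X[test])
        else:
            X_tr, X_te = X[train], X[test]
        cap = min(max_lv, X_tr.shape[0] - 1, X_tr.shape[1])
        model = plsda_fit(X_tr, y[train], cap, classes=classes)
        s = model.predict_scores_all_lv(X_te)  # n_test x 2 x found
        found = s.shape[2]
        scores[test, :, :found] = s
        if found < max_lv:  # rank exhausted: later truncations equal the last
            scores[test, :, found:] = s[:, :, -1:]
        evaluated |= test
    return scores, evaluated


def cross_validate(
    X: np.ndarray,
    y: Sequence,
    chain: PreprocessChain | str | None,
    n_lv: int,
    plan: CVPlan,
    positive_class=None,
):
    """Venetian-blinds CV of a PLS-DA model at a fixed LV count.

    The pre-processing chain is re-fitted inside each fold on the
    training portion only; held-out predictions are aggregated over all
    folds and scored.  Folds whose training portion holds a single class
    are skipped with a warning.  Returns ``(ConfusionStats, details)``
    where ``details`` carries per-sample predictions, scores and the
    evaluated mask.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if isinstance(chain, str):
        chain = build_chain(chain)
    classes = _resolve_classes(y, None)
    if positive_class is None:
        positive_class = classes[0]
    scores, evaluated = _heldout_scores_per_lv(X, y, chain, n_lv, plan, classes)
    s = scores[evaluated, :, n_lv - 1]
    y_pred = _decide(s, classes)
    stats = confusion_stats(y[evaluated], y_pred, positive_class)
    details = {
        "y_pred": y_pred,
        "scores": s,
        "evaluated": evaluated,
        "classes": classes,
    }
    return stats, details


def _class_error_at_each_lv(scores, y, classes, positive_class, evaluated):
    errors = np.empty(scores.shape[2])
    for a in range(scores.shape[2]):
        pred = _decide(scores[evaluated, :, a], classes)
        errors[a] = confusion_stats(y[evaluated], pred, positive_class).class_error
    return errors


def select_n_lv(
    X: np.ndarray,
    y: Sequence,
    chain: PreprocessChain | str | None,
    max_lv: int,
    plan: CVPlan,
    positive_class=None,
):
    """Choose the LV count minimizing the mean of calibration and CV class error.

    Returns ``(n_lv, curves)`` where ``curves`` holds the calibration,
    cross-validation and combined class-error traces over 1..max_lv.
    Ties resolve to the smallest LV count.
    """
    if max_lv < 1:
        raise ParameterError("max_lv must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if isinstance(chain, str):
        chain = build_chain(chain)
    classes = _resolve_classes(y, None)
    if positive_class is None:
        positive_class = classes[0]
    cap = min(max_lv, X.shape[0] - 1, X.shape[1])

    # calibration curve: one full-data fit, truncations from the decomposition
    if chain is not None and chain.steps:
        ch = chain.clone()
        Xp = ch.fit_transform(X)
    else:
        Xp = X
    model = plsda_fit(Xp, y, cap, classes=classes)
    cal_scores = model.predict_scores_all_lv(Xp)
    found = cal_scores.shape[2]
    if found < cap:
        cal_scores = np.concatenate(
            [cal_scores, np.repeat(cal_scores[:, :, -1:], cap - found, axis=2)], axis=2
        )
    all_true = np.ones(len(y), dtype=bool)
    cal_err = _class_error_at_each_lv(cal_scores, y, classes, positive_class, all_true)

    cv_scores, evaluated = _heldout_scores_per_lv(X, y, chain, cap, plan, classes)
    cv_err = _class_error_at_each_lv(cv_scores, y, classes, positive_class, evaluated)

    combined = (cal_err + cv_err) / 2.0
    n_lv = int(np.argmin(combined)) + 1  # first occurrence = smallest LV on ties
    curves = {
        "n_lv_grid": np.arange(1, cap + 1),
        "calibration_error": cal_err,
        "cv_error": cv_err,
        "combined_error": combined,
    }
    return n_lv, curves
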