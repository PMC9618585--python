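"""Forward interval PLS (iPLS) wavelength selection.

The spectrum is divided into contiguous equidistant intervals (width 1 or
5 bands in the emulated study; a shorter remainder interval keeps full
coverage when the band count is not a multiple).  Forward selection
greedily adds the interval whose inclusion minimizes the root mean
squared error of cross-validation (RMSECV) of the continuous PLS-DA
response, re-optimizing the latent-variable count for every candidate,
and stops when no candidate improves RMSECV by more than a relative
tolerance.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np

from .chemometrics import (
    CVPlan,
    _class_error_at_each_lv,
    _dummy,
    _heldout_scores_per_lv,
    _resolve_classes,
    plsda_fit,
    simpls,
)
from .errors import ParameterError

logger = logging.getLogger(__name__)

__all__ = ["IntervalSet", "IPLSResult", "make_intervals", "rmsecv", "forward_ipls"]


@dataclasses.dataclass(frozen=True)
class IntervalSet:
    """Contiguous half-open band-index ranges covering [0, n_bands)."""

    interval_size: int
    intervals: tuple[tuple[int, int], ...]

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)

    def bands(self, index: int) -> np.ndarray:
        lo, hi = self.intervals[index]
        return np.arange(lo, hi)

    def width(self, index: int) -> int:
        lo, hi = self.intervals[index]
        return hi - lo


def make_intervals(n_bands: int, interval_size: int) -> IntervalSet:
    """Equidistant intervals; the last one holds the remainder bands.

    E.g. 226 bands at width 5 give 46 intervals: 45 of width 5 plus one
    singleton, so no band is dropped.
    """
    if not 1 <= interval_size <= n_bands:
        raise ParameterError(
            f"interval_size must be in [1, {n_bands}], got {interval_size}"
        )
    edges = list(range(0, n_bands, interval_size)) + [n_bands]
    intervals = tuple((edges[i], edges[i + 1]) for i in range(len(edges) - 1))
    return IntervalSet(interval_size, intervals)


def rmsecv(X: np.ndarray, Y: np.ndarray, plan: CVPlan, n_lv: int) -> float:
    """Root mean squared CV error of the continuous PLS response.

    ``Y`` is the (uncentered) dummy response matrix; within each fold a
    PLS model is fitted on the training portion and the held-out
    residuals are pooled over folds and response columns.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != X.shape[0]:
        raise ParameterError("X and Y sample counts differ")
    sq_sum = 0.0
    n_entries = 0
    for f in range(plan.n_splits):
        test = plan.assignment == f
        train = ~test
        if not test.any() or not train.any():
            continue
        X_tr, Y_tr = X[train], Y[train]
        x_mean = X_tr.mean(axis=0)
        y_mean = Y_tr.mean(axis=0)
        cap = min(n_lv, X_tr.shape[0] - 1, X_tr.shape[1])
        R, P, Q, T = simpls(X_tr - x_mean, Y_tr - y_mean, cap)
        B = R @ Q.T
        Y_hat = (X[test] - x_mean) @ B + y_mean
        resid = Y[test] - Y_hat
        sq_sum += float(np.sum(resid**2))
        n_entries += resid.size
    if n_entries == 0:
        raise ParameterError("no evaluable folds")
    return float(np.sqrt(sq_sum / n_entries))


@dataclasses.dataclass
class IPLSResult:
    """Outcome of a forward iPLS run."""

    interval_set: IntervalSet
    selected: list[int]  # interval indices in selection order
    rmsecv_trace: list[float]  # RMSECV after each accepted step
    selected_variables: np.ndarray  # sorted band indices, union of intervals
    n_lv: int  # LV count of the final model
    steps: list[dict]  # per-step log: interval, band range, rmsecv, n_lv

    @property
    def n_selected_variables(self) -> int:
        return int(self.selected_variables.size)


def _score_candidate(X_cols, y, plan, max_lv, classes, positive_class):
    """(rmsecv, n_lv) for a candidate column subset.

    LV count chosen as in ``select_n_lv`` (smallest minimizer of the mean
    of calibration and CV class error), from a single decomposition per
    fold; RMSECV then read off at that LV count.
    """
    cap = min(max_lv, X_cols.shape[0] - 1, X_cols.shape[1])
    Y = _dummy(y, classes)
    cv_scores, evaluated = _heldout_scores_per_lv(X_cols, y, None, cap, plan, classes)
    model = plsda_fit(X_cols, y, cap, classes=classes)
    cal_scores = model.predict_scores_all_lv(X_cols)
    found = cal_scores.shape[2]
    if found < cap:
        cal_scores = np.concatenate(
            [cal_scores, np.repeat(cal_scores[:, :, -1:], cap - found, axis=2)], axis=2
        )
    all_true = np.ones(len(y), dtype=bool)
    cal_err = _class_error_at_each_lv(cal_scores, y, classes, positive_class, all_true)
    cv_err = _class_error_at_each_lv(cv_scores, y, classes, positive_class, evaluated)
    n_lv = int(np.argmin((cal_err + cv_err) / 2.0)) + 1
    resid = Y[evaluated] - cv_scores[evaluated, :, n_lv - 1]
    return float(np.sqrt(np.mean(resid**2))), n_lv


def forward_ipls(
    X: np.ndarray,
    y: Sequence,
    interval_size: int,
    plan: CVPlan,
    max_intervals: int | None = None,
    rel_tol: float = 1e-3,
    max_lv: int = 10,
    positive_class=None,
) -> IPLSResult:
    """Greedy forward interval selection scored by RMSECV.

    At each step every remaining interval is tried jointly with the
    intervals already selected; the one minimizing RMSECV is added.
    Selection stops when the best candidate improves the incumbent
    RMSECV by less than ``rel_tol`` (relative), or when
    ``max_intervals`` intervals have been accepted.  The first interval
    is always accepted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.size == 0:
        raise ParameterError("empty spectra matrix")
    classes = _resolve_classes(y, None)
    if positive_class is None:
        positive_class = classes[0]
    iset = make_intervals(X.shape[1], interval_size)
    if max_intervals is None:
        max_intervals = iset.n_intervals
    remaining = list(range(iset.n_intervals))
    selected: list[int] = []
    selected_bands: list[np.ndarray] = []
    trace: list[float] = []
    steps: list[dict] = []
    best_rmse = np.inf
    final_lv = 1
    while remaining and len(selected) < max_intervals:
        cand_scores = []
        for k in remaining:
            cols = np.concatenate(selected_bands + [iset.bands(k)]) if selected_bands else iset.bands(k)
            score, n_lv = _score_candidate(
                X[:, np.sort(cols)], y, plan, max_lv, classes, positive_class
            )
            cand_scores.append((score, k, n_lv))
        score, k_best, n_lv = min(cand_scores)
        if selected and score >= best_rmse * (1.0 - rel_tol):
            logger.info(
                "iPLS stop after %d interval(s): best candidate RMSECV %.4g "
                "vs incumbent %.4g (rel_tol=%g)",
                len(selected), score, best_rmse, rel_tol,
            )
            break
        selected.append(k_best)
        selected_bands.append(iset.bands(k_best))
        remaining.remove(k_best)
        best_rmse = score
        final_lv = n_lv
        trace.append(score)
        steps.append(
            {
                "step": len(selected),
                "interval": k_best,
                "band_range": iset.intervals[k_best],
                "rmsecv": score,
                "n_lv": n_lv,
            }
        )
    variables = np.sort(np.concatenate(selected_bands))
    return IPLSResult(iset, selected, trace, variables, final_lv, steps)
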