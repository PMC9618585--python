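"""Spectral pre-processing operators and named operator chains.

Implements the operators used throughout NIR chemometrics and their
composition into '+'-joined chains such as ``"SM+SNV+MC"``:

``SM``
    Savitzky-Golay smoothing (15-point window, 2nd-order polynomial).
``SNV``
    Standard normal variate: each spectrum centered and scaled to unit
    standard deviation (sample sd, n-1 denominator).
``MSC``
    Multiplicative scatter correction: each spectrum regressed onto a
    reference spectrum (the calibration-set mean) and the fitted affine
    distortion inverted.
``1D`` / ``2D``
    First/second Savitzky-Golay derivative (15-point window, 2nd-order
    polynomial), reported per nm.
``MC``
    Mean centering with the calibration-set mean spectrum.

MSC and MC are stateful: their reference/mean are learned on the
calibration spectra and re-used unchanged on test spectra, so a fitted
chain is deterministic and fit-then-apply on the training set equals
fit_transform.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .errors import ConfigError, DegenerateSpectrumError, ParameterError

__all__ = [
    "savgol_smooth",
    "savgol_derivative",
    "snv",
    "msc_fit",
    "msc_apply",
    "mc_fit",
    "mc_apply",
    "PreprocessChain",
    "build_chain",
    "CHAIN_NAMES",
]

#: The ten chains compared in the study, by their conventional labels.
CHAIN_NAMES = (
    "None",
    "MC",
    "SM+SNV+MC",
    "SM+MSC+MC",
    "1D+MC",
    "2D+MC",
    "1D+SNV+MC",
    "1D+MSC+MC",
    "2D+SNV+MC",
    "2D+MSC+MC",
)

_STEP_NAMES = {"SM", "SNV", "MSC", "1D", "2D", "MC"}


def _check_savgol(window: int, polyorder: int, n_bands: int) -> None:
    if window % 2 == 0:
        raise ParameterError(f"window must be odd, got {window}")
    if window > n_bands:
        raise ParameterError(f"window {window} exceeds {n_bands} bands")
    if polyorder >= window:
        raise ParameterError(f"polyorder {polyorder} must be < window {window}")


def savgol_smooth(X: np.ndarray, window: int = 15, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothing along the band axis.

    Edges are handled by polynomial-fit extrapolation within the terminal
    window (``mode='interp'``), so the filter is exact on polynomials of
    degree <= ``polyorder`` everywhere, edges included, and no bands are
    lost.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    _check_savgol(window, polyorder, X.shape[1])
    return savgol_filter(X, window, polyorder, axis=1, mode="interp")


def savgol_derivative(
    X: np.ndarray,
    order: int,
    window: int = 15,
    polyorder: int = 2,
    spacing_nm: float = 1.0,
) -> np.ndarray:
    """Savitzky-Golay derivative of each spectrum, scaled to per-nm units.

    ``order`` must be 1 or 2 and not exceed ``polyorder``; the result is
    divided by ``spacing_nm**order`` via the filter's ``delta`` argument.
    """
    if order not in (1, 2):
        raise ParameterError(f"derivative order must be 1 or 2, got {order}")
    if order > polyorder:
        raise ParameterError(f"order {order} exceeds polyorder {polyorder}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    _check_savgol(window, polyorder, X.shape[1])
    return savgol_filter(
        X, window, polyorder, deriv=order, delta=spacing_nm, axis=1, mode="interp"
    )


def snv(X: np.ndarray) -> np.ndarray:
    """Standard normal variate: rows centered and scaled to sample sd 1."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() <= 1e-12)
    if flat.size:
        raise DegenerateSpectrumError(f"flat spectra at rows {flat.tolist()[:10]}")
    return (X - mean) / sd


def msc_fit(X_train: np.ndarray) -> np.ndarray:
    """MSC reference spectrum = mean of the calibration spectra."""
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    reference = X_train.mean(axis=0)
    if np.ptp(reference) <= 1e-12:
        raise DegenerateSpectrumError("MSC reference spectrum is constant")
    return reference


def msc_apply(X: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Regress each spectrum on the reference (s = a + b*ref) and return (s-a)/b."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    reference = np.asarray(reference, dtype=float)
    if X.shape[1] != reference.size:
        raise ParameterError(
            f"{X.shape[1]} bands vs reference of {reference.size}"
        )
    ref_c = reference - reference.mean()
    denom = ref_c @ ref_c
    b = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    bad = np.flatnonzero(np.abs(b) <= 1e-12)
    if bad.size:
        raise DegenerateSpectrumError(
            f"uncorrectable spectra (slope ~ 0) at rows {bad.tolist()[:10]}"
        )
    a = X.mean(axis=1) - b * reference.mean()
    return (X - a[:, None]) / b[:, None]


def mc_fit(X_train: np.ndarray) -> np.ndarray:
    """Mean spectrum of the calibration set."""
    return np.atleast_2d(np.asarray(X_train, dtype=float)).mean(axis=0)


def mc_apply(X: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """Subtract a fitted mean spectrum from every row."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mean = np.asarray(mean, dtype=float)
    if X.shape[1] != mean.size:
        raise ParameterError(f"{X.shape[1]} bands vs mean of {mean.size}")
    return X - mean[None, :]


@dataclasses.dataclass
class PreprocessChain:
    """Ordered pre-processing steps with train-state fitting.

    Build from a '+'-joined label (``"SM+SNV+MC"``; ``"None"`` is the
    identity) or an explicit step list.  ``fit_transform`` learns the MSC
    reference / MC mean from the running calibration matrix at the point
    the step occurs in the chain; ``transform`` re-applies the frozen
    states to new spectra.
    """

    steps: tuple[str, ...]
    spacing_nm: float = 1.0
    window: int = 15
    polyorder: int = 2
    fitted_state: dict = dataclasses.field(default_factory=dict)

    @property
    def name(self) -> str:
        return "+".join(self.steps) if self.steps else "None"

    @property
    def is_fitted(self) -> bool:
        stateful = {"MSC", "MC"} & set(self.steps)
        return all(s in self.fitted_state for s in stateful)

    def clone(self) -> "PreprocessChain":
        """Unfitted copy (fresh states), e.g. for per-fold refitting."""
        return PreprocessChain(self.steps, self.spacing_nm, self.window, self.polyorder)

    def _apply_step(self, step: str, X: np.ndarray, fitting: bool) -> np.ndarray:
        if step == "SM":
            return savgol_smooth(X, self.window, self.polyorder)
        if step == "1D":
            return savgol_derivative(X, 1, self.window, self.polyorder, self.spacing_nm)
        if step == "2D":
            return savgol_derivative(X, 2, self.window, self.polyorder, self.spacing_nm)
        if step == "SNV":
            return snv(X)
        if step == "MSC":
            if fitting:
                self.fitted_state["MSC"] = msc_fit(X)
            return msc_apply(X, self.fitted_state["MSC"])
        if step == "MC":
            if fitting:
                self.fitted_state["MC"] = mc_fit(X)
            return mc_apply(X, self.fitted_state["MC"])
        raise ConfigError(f"unknown step {step!r}")  # pragma: no cover

    def fit_transform(self, X_train: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X_train, dtype=float))
        self.fitted_state = {}
        for step in self.steps:
            X = self._apply_step(step, X, fitting=True)
        return X

    def fit(self, X_train: np.ndarray) -> "PreprocessChain":
        self.fit_transform(X_train)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not self.is_fitted:
            raise ConfigError(f"chain {self.name!r} has unfitted stateful steps")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        for step in self.steps:
            X = self._apply_step(step, X, fitting=False)
        return X


def build_chain(
    spec: str | Sequence[str],
    spacing_nm: float = 1.0,
    window: int = 15,
    polyorder: int = 2,
) -> PreprocessChain:
    """Build an unfitted chain from a '+'-joined label or a step sequence."""
    if isinstance(spec, str):
        steps = () if spec.strip().lower() in ("none", "") else tuple(
            s.strip().upper() for s in spec.split("+")
        )
    else:
        steps = tuple(s.strip().upper() for s in spec)
    unknown = set(steps) - _STEP_NAMES
    if unknown:
        raise ConfigError(f"unknown pre-processing steps {sorted(unknown)}")
    return PreprocessChain(steps, spacing_nm, window, polyorder)
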