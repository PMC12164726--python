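"""Continuous reference decoders: Wiener cascade and per-bin discriminant.

The Wiener cascade regresses tapped latent history onto the target force and
then passes the linear prediction through a static 3rd-order polynomial. The
continuous classifier is a per-bin multiclass linear discriminant over latents
with an explicit null class. Both emit an output at every bin — exactly the
behavior whose instability during holds and cross-effector interference the
gated architecture is designed to avoid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import r2_score
from sklearn.utils.validation import check_is_fitted

NULL_CLASS = -1
POLY_ORDER = 3  # the cascade's static nonlinearity is cubic


def _tapped(Z: np.ndarray, n_taps: int) -> np.ndarray:
    """Design matrix of current + n_taps-1 past bins, zero-padded at the start."""
    n, k = Z.shape
    cols = []
    for lag in range(n_taps):
        shifted = np.zeros_like(Z)
        if lag:
            shifted[lag:] = Z[:-lag]
        else:
            shifted = Z
        cols.append(shifted)
    return np.concatenate(cols, axis=1)


class WienerCascadeRegressor(BaseEstimator, RegressorMixin):
    """Linear stage over tapped latents followed by a cubic static nonlinearity.

    Parameters
    ----------
    n_taps : int
        History length in bins (10 bins = 200 ms at 50 Hz).

    Attributes
    ----------
    linear_weights_ : (n_taps * n_factors,) weights; intercept_ : float
    polynomial_coeffs_ : (4,) cubic coefficients, highest degree first
    fit_report_ : dict with stage-1 and composite training R^2
    ridge_fallback_ : bool, True if the linear stage was rank-deficient
    """

    def __init__(self, n_taps: int = 10):
        self.n_taps = n_taps

    def fit(self, Z: np.ndarray, y: np.ndarray) -> "WienerCascadeRegressor":
        if self.n_taps < 1:
            raise ValueError("n_taps must be >= 1")
        Z = np.asarray(Z, dtype=float)
        y = np.asarray(y, dtype=float)
        if Z.ndim != 2 or y.shape != (Z.shape[0],):
            raise ValueError("Z must be (n_bins, n_factors) with matching target")
        X = _tapped(Z, self.n_taps)
        Xd = np.column_stack([X, np.ones(len(X))])
        sol, _, rank, _ = np.linalg.lstsq(Xd, y, rcond=None)
        self.ridge_fallback_ = rank < Xd.shape[1]
        if self.ridge_fallback_:
            lam = 1e-6 * np.trace(Xd.T @ Xd) / Xd.shape[1]
            sol = np.linalg.solve(Xd.T @ Xd + lam * np.eye(Xd.shape[1]), Xd.T @ y)
        self.linear_weights_ = sol[:-1]
        self.intercept_ = float(sol[-1])

        stage1 = Xd @ sol
        if np.ptp(stage1) < 1e-12:
            # degenerate linear stage: constant polynomial
            self.polynomial_coeffs_ = np.array([0.0, 0.0, 0.0, float(np.mean(y))])
        else:
            self.polynomial_coeffs_ = np.polyfit(stage1, y, POLY_ORDER)
        composite = np.polyval(self.polynomial_coeffs_, stage1)
        self.fit_report_ = {
            "stage1_r2": float(r2_score(y, stage1)) if np.ptp(y) > 0 else 1.0,
            "composite_r2": float(r2_score(y, composite)) if np.ptp(y) > 0 else 1.0,
        }
        self.n_features_in_ = Z.shape[1]
        return self

    def predict(self, Z: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "linear_weights_")
        Z = np.asarray(Z, dtype=float)
        X = _tapped(Z, self.n_taps)
        stage1 = X @ self.linear_weights_ + self.intercept_
        return np.polyval(self.polynomial_coeffs_, stage1)


class ContinuousLDAClassifier(BaseEstimator, ClassifierMixin):
    """Per-bin multiclass discriminant over latents with an explicit null class.

    Stateless at prediction time: permuting bins permutes predictions.
    """

    def __init__(self):
        pass

    def fit(self, Z: np.ndarray, labels: np.ndarray) -> "ContinuousLDAClassifier":
        Z = np.asarray(Z, dtype=float)
        labels = np.asarray(labels)
        classes, counts = np.unique(labels, return_counts=True)
        if classes.size < 2:
            raise ValueError("need at least two classes (including null)")
        starved = classes[counts < 2]
        if starved.size:
            raise ValueError(f"classes with fewer than two bins: {starved.tolist()}")
        self.lda_ = LinearDiscriminantAnalysis().fit(Z, labels)
        self.classes_ = self.lda_.classes_
        self.n_features_in_ = Z.shape[1]
        return self

    def predict(self, Z: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "lda_")
        return self.lda_.predict(np.asarray(Z, dtype=float))

    def predict_proba(self, Z: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "lda_")
        return self.lda_.predict_proba(np.asarray(Z, dtype=float))


def force_target_stream(events: pd.DataFrame, n_bins: int,
                        bin_width: float) -> np.ndarray:
    """Piecewise-constant supervision: cued force inside [onset, offset), 0 outside."""
    target = np.zeros(n_bins)
    times = np.arange(n_bins) * bin_width
    for row in events.itertuples():
        m = (times >= row.onset_time) & (times < row.offset_time)
        target[m] = row.cued_force
    return target


def label_stream(events: pd.DataFrame, n_bins: int, bin_width: float) -> np.ndarray:
    """Per-bin condition labels: cued condition inside [onset, offset), null outside."""
    labels = np.full(n_bins, NULL_CLASS)
    times = np.arange(n_bins) * bin_width
    for row in events.itertuples():
        m = (times >= row.onset_time) & (times < row.offset_time)
        labels[m] = row.condition
    return labels


def fit_wiener(z: np.ndarray, force_target: np.ndarray,
               n_taps: int = 10) -> WienerCascadeRegressor:
    """Fit the force cascade on (n_bins, n_factors) latents."""
    return WienerCascadeRegressor(n_taps=n_taps).fit(z, force_target)


def fit_continuous_classifier(z: np.ndarray,
                              labels: np.ndarray) -> ContinuousLDAClassifier:
    """Fit the per-bin classifier (labels include the null class)."""
    return ContinuousLDAClassifier().fit(z, labels)
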