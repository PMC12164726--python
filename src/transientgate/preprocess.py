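"""Binned spike counts -> smoothed firing-rate estimates.

Counts are square-root transformed and convolved with a causal decaying
exponential (time constant ``tau``, default 400 ms), the standard
variance-stabilized rate estimate used throughout the pipeline. The kernel is
truncated and renormalized to unit sum, so a constant input passes through
with unit DC gain and the output at bin ``t`` depends only on bins ``<= t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the rate-estimation front end.

    Attributes
    ----------
    bin_width : float
        Bin size in seconds (50 Hz binning -> 0.02).
    sqrt_transform : bool
        Apply the variance-stabilizing square root before smoothing.
    tau : float
        Decay time constant of the causal exponential kernel, seconds.
    kernel_truncation : float
        Kernel support, in multiples of ``tau``.
    """

    bin_width: float = 0.02
    sqrt_transform: bool = True
    tau: float = 0.4
    kernel_truncation: float = 5.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.bin_width <= 0:
            raise ValueError(f"bin_width must be positive, got {self.bin_width}")
        if self.kernel_truncation <= 0:
            raise ValueError("kernel_truncation must be positive")


@dataclass
class RateMatrix:
    """Smoothed firing-rate estimates, channels x bins."""

    rates: np.ndarray
    bin_width: float
    provenance: PreprocessConfig = field(default_factory=PreprocessConfig)

    @property
    def n_channels(self) -> int:
        return self.rates.shape[0]

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]


def exponential_kernel(tau: float, bin_width: float, truncation: float = 5.0) -> np.ndarray:
    """Causal exponential kernel h[k] = exp(-k*dt/tau), truncated, unit sum."""
    n_taps = int(np.ceil(truncation * tau / bin_width)) + 1
    h = np.exp(-np.arange(n_taps) * bin_width / tau)
    return h / h.sum()


def smooth_counts(counts: np.ndarray, cfg: PreprocessConfig | None = None) -> RateMatrix:
    """Square-root transform and causally smooth binned counts.

    Parameters
    ----------
    counts : ndarray, shape (n_channels, n_bins)
        Nonnegative integer spike counts.
    cfg : PreprocessConfig, optional

    Returns
    -------
    RateMatrix
        Same shape as ``counts``; finite; causal in time.
    """
    cfg = cfg or PreprocessConfig()
    counts = np.asarray(counts)
    if counts.ndim != 2:
        raise ValueError(f"counts must be 2-D (channels x bins), got shape {counts.shape}")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    x = np.sqrt(counts.astype(float)) if cfg.sqrt_transform else counts.astype(float)
    h = exponential_kernel(cfg.tau, cfg.bin_width, cfg.kernel_truncation)
    rates = lfilter(h, [1.0], x, axis=1)
    return RateMatrix(rates=rates, bin_width=cfg.bin_width, provenance=cfg)


def inverse_filter(template: np.ndarray, tau: float, bin_width: float,
                   truncation: float = 5.0) -> np.ndarray:
    """Exactly undo the causal exponential smoothing of a time course.

    The geometric FIR kernel satisfies a first-order recursion, so its inverse
    is local and exact: x[t] = (y[t] - a*y[t-1]) * S with a = exp(-dt/tau) and
    S the (truncation-dependent) kernel normalizer. Used to measure transient
    widths in the rate domain rather than the smoothed domain.
    """
    a = np.exp(-bin_width / tau)
    n_taps = int(np.ceil(truncation * tau / bin_width)) + 1
    norm = np.exp(-np.arange(n_taps) * bin_width / tau).sum()
    y = np.asarray(template, dtype=float)
    x = (y - a * np.concatenate([[0.0], y[:-1]])) * norm
    return x


class ExponentialRateSmoother(BaseEstimator, TransformerMixin):
    """sklearn-style transformer over (n_bins, n_channels) count arrays.

    Stateless apart from validation; ``fit`` records the channel count.
    """

    def __init__(self, bin_width: float = 0.02, sqrt_transform: bool = True,
                 tau: float = 0.4, kernel_truncation: float = 5.0):
        self.bin_width = bin_width
        self.sqrt_transform = sqrt_transform
        self.tau = tau
        self.kernel_truncation = kernel_truncation

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(bin_width=self.bin_width,
                                sqrt_transform=self.sqrt_transform,
                                tau=self.tau,
                                kernel_truncation=self.kernel_truncation)

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_bins, n_channels)")
        self.n_features_in_ = X.shape[1]
        self._config()  # validates
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X)
        return smooth_counts(X.T, self._config()).rates.T
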