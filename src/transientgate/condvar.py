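"""Condition-dependent latent variance over time.

V(t) is the dispersion of the per-condition mean latent states at each
event-aligned bin: the trace of the across-condition covariance (population
denominator C by default). Its ratio between a 100 ms window 200 ms after the
onset-transient peak (t1) and one 200 ms before the offset-transient peak (t2)
summarizes how quickly action-specific information decays, and the lag
maximizing the correlation between the onset-transient template and V(t)
measures how closely condition coding follows the transient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transients import TransientModel


@dataclass
class VarianceTrace:
    times: np.ndarray          # seconds relative to the alignment event
    V: np.ndarray              # nonnegative, per bin
    alignment: str             # "onset" | "offset"
    n_conditions: int = 0


@dataclass
class CondVarSummary:
    V_t1: float
    V_t2: float
    ratio: float
    t1_center: float
    t2_center: float
    bin_halfwidth: float = 0.05
    lag: float = float("nan")


def condition_variance_trace(per_trial: np.ndarray, labels: np.ndarray,
                             times: np.ndarray, alignment: str = "onset",
                             denominator: str = "population") -> VarianceTrace:
    """Variance across condition-mean latent states, per aligned bin.

    Parameters
    ----------
    per_trial : (n_trials, n_bins, n_factors) aligned latent segments
    labels : (n_trials,) condition labels
    denominator : "population" (divide by C) or "sample" (C - 1)
    """
    per_trial = np.asarray(per_trial, dtype=float)
    labels = np.asarray(labels)
    conds = np.unique(labels)
    if conds.size < 2:
        raise ValueError("need at least two conditions")
    counts = {c: int((labels == c).sum()) for c in conds}
    starved = [c for c, n in counts.items() if n < 2]
    if starved:
        raise ValueError(f"conditions with fewer than two trials: {starved}")
    means = np.stack([per_trial[labels == c].mean(axis=0) for c in conds])
    grand = means.mean(axis=0)
    dev = means - grand
    denom = conds.size if denominator == "population" else conds.size - 1
    V = (dev ** 2).sum(axis=(0, 2)) / denom
    return VarianceTrace(times=np.asarray(times, dtype=float), V=V,
                         alignment=alignment, n_conditions=conds.size)


def _window_mean(trace: VarianceTrace, center: float, halfwidth: float) -> float:
    m = (trace.times >= center - halfwidth) & (trace.times <= center + halfwidth)
    if not m.any():
        raise ValueError(
            f"summary window {center}+-{halfwidth}s lies outside the trace "
            f"({trace.times[0]}..{trace.times[-1]}s)")
    return float(trace.V[m].mean())


def summarize_t1_t2(trace_on: VarianceTrace, trace_off: VarianceTrace,
                    transients: TransientModel, offset_from_peak: float = 0.2,
                    halfwidth: float = 0.05) -> CondVarSummary:
    """Information decay between 100 ms windows tied to the transient peaks."""
    t1 = transients.onset.peak_time + offset_from_peak
    t2 = transients.offset.peak_time - offset_from_peak
    v1 = _window_mean(trace_on, t1, halfwidth)
    v2 = _window_mean(trace_off, t2, halfwidth)
    ratio = v2 / v1 if v1 > 0 else float("nan")
    return CondVarSummary(V_t1=v1, V_t2=v2, ratio=ratio, t1_center=t1,
                          t2_center=t2, bin_halfwidth=halfwidth)


def transient_variance_lag(template: np.ndarray, trace: VarianceTrace,
                           bin_width: float, max_lag: float = 1.0) -> float:
    """Lag (seconds) maximizing the Pearson correlation between the onset
    transient template and the condition-variance trace.

    Positive lag means the variance trace follows the transient. Correlations
    are computed over the overlapping support only (no zero padding); ties go
    to the smallest absolute lag.
    """
    x = np.asarray(template, dtype=float)
    y = np.asarray(trace.V, dtype=float)
    if x.shape != y.shape:
        raise ValueError("template and trace must share the bin grid")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        raise ValueError("zero-variance input: lag undefined")
    n = x.size
    max_bins = int(round(max_lag / bin_width))
    best = None
    for lag in range(-max_bins, max_bins + 1):
        if lag >= 0:
            xs, ys = x[: n - lag], y[lag:]
        else:
            xs, ys = x[-lag:], y[: n + lag]
        if xs.size < 3 or np.std(xs) == 0 or np.std(ys) == 0:
            continue
        r = float(np.corrcoef(xs, ys)[0, 1])
        key = (-r, abs(lag), lag)
        if best is None or key < best[0]:
            best = (key, lag)
    if best is None:
        raise ValueError("no valid overlap at any lag")
    return best[1] * bin_width
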