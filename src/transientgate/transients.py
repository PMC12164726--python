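"""Onset/offset transient component identification.

Trial-averaged latent responses aligned to action onset and offset are split
into onset-unique, offset-unique and shared subspaces by a ratio-of-variance
generalized eigenproblem; within each unique subspace a varimax rotation finds
temporally sparse projections, and the single component with the largest
modulation is taken as the transient. The onset and offset components occupy
orthogonal latent dimensions by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.ndimage import gaussian_filter1d

from .preprocess import inverse_filter

GAUSS_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class AlignmentWindows:
    """Event-relative analysis windows, seconds."""

    onset_window: tuple[float, float] = (-1.5, 2.0)
    offset_window: tuple[float, float] = (-2.0, 1.5)

    def __post_init__(self) -> None:
        for name in ("onset_window", "offset_window"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} start must precede end, got ({lo}, {hi})")


@dataclass
class AlignedResponses:
    """Event-aligned latent segments for one alignment."""

    times: np.ndarray        # window times relative to event, seconds
    per_trial: np.ndarray    # (n_trials, n_window_bins, n_factors)
    avg: np.ndarray          # (n_window_bins, n_factors)
    trial_index: np.ndarray  # retained trial ids (events row order)
    n_dropped: int = 0


@dataclass
class TransientComponent:
    """One identified transient: latent direction plus template statistics."""

    w: np.ndarray            # unit vector, latent space
    template: np.ndarray     # averaged time course over the window (sign-fixed)
    times: np.ndarray
    peak_time: float         # seconds relative to event
    peak_amplitude: float
    fwhm: float              # seconds; rate-domain if smoothing_tau was given
    component_index: int = 0


@dataclass
class TransientModel:
    """Onset and offset transient components of one session."""

    onset: TransientComponent
    offset: TransientComponent
    windows: AlignmentWindows = field(default_factory=AlignmentWindows)

    @property
    def w_on(self) -> np.ndarray:
        return self.onset.w

    @property
    def w_off(self) -> np.ndarray:
        return self.offset.w


def align_events(z: np.ndarray, event_times: np.ndarray, window: tuple[float, float],
                 bin_width: float) -> AlignedResponses:
    """Snap events to the bin grid, extract window segments, average.

    Trials whose window does not fit inside the recording are dropped and
    counted in ``n_dropped``.
    """
    z = np.asarray(z)
    n_bins = z.shape[0]
    lo = int(round(window[0] / bin_width))
    hi = int(round(window[1] / bin_width))
    rel = np.arange(lo, hi)
    segs, kept = [], []
    for i, ev in enumerate(np.asarray(event_times, dtype=float)):
        center = int(round(ev / bin_width))
        idx = center + rel
        if idx[0] < 0 or idx[-1] >= n_bins:
            continue
        segs.append(z[idx])
        kept.append(i)
    if not segs:
        raise ValueError("no trials with a complete alignment window")
    per_trial = np.stack(segs)
    return AlignedResponses(times=rel * bin_width, per_trial=per_trial,
                            avg=per_trial.mean(axis=0),
                            trial_index=np.asarray(kept),
                            n_dropped=len(event_times) - len(kept))


def align_and_average(z: np.ndarray, events: pd.DataFrame,
                      windows: AlignmentWindows, bin_width: float
                      ) -> tuple[AlignedResponses, AlignedResponses]:
    """Onset- and offset-aligned responses, all conditions pooled."""
    on = align_events(z, events["onset_time"].to_numpy(), windows.onset_window,
                      bin_width)
    off = align_events(z, events["offset_time"].to_numpy(), windows.offset_window,
                       bin_width)
    return on, off


def unique_variance_subspaces(avg_on: np.ndarray, avg_off: np.ndarray,
                              var_threshold: float = 0.1,
                              ridge_scale: float = 1e-6,
                              variance_floor: float = 0.05
                              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split the latent space into onset-unique / offset-unique / shared bases.

    Directions maximize v'C_on v / v'(C_on + C_off + eps I) v where C_on and
    C_off are the temporal covariances of the two mean-centered averages. A
    direction is onset-unique if its onset variance fraction is >= 1 -
    var_threshold (and carries at least ``variance_floor`` of the average
    per-direction variance), offset-unique with the roles swapped; the rest is
    shared. The three bases are returned orthonormal and mutually orthogonal
    (Loewdin symmetric orthogonalization).
    """
    a_on = np.asarray(avg_on) - np.asarray(avg_on).mean(axis=0)
    a_off = np.asarray(avg_off) - np.asarray(avg_off).mean(axis=0)
    k = a_on.shape[1]
    c_on = (a_on.T @ a_on) / a_on.shape[0]
    c_off = (a_off.T @ a_off) / a_off.shape[0]
    total = c_on + c_off

    # screen out directions carrying (almost) no variance in either window:
    # the variance-ratio eigenproblem is degenerate there, and with tens of
    # trial-averaged-noise dimensions against ~a few dozen effective time
    # samples its eigenvectors overfit, blending the transients with noise.
    # The floor is relative to the dominant eigenvalue: the transients are by
    # hypothesis large components of the aligned averages.
    tot_evals, tot_evecs = np.linalg.eigh(total)
    floor = variance_floor * max(tot_evals.max(), 1e-30)
    keep = tot_evals >= floor
    P = tot_evecs[:, keep]                                   # (k, m)
    m = P.shape[1]
    if m == 0:
        raise ValueError("aligned averages carry no variance")

    eps = ridge_scale * max(np.trace(total), 1e-30) / k
    lam, v = eigh(P.T @ c_on @ P, P.T @ total @ P + eps * np.eye(m))
    lam = np.clip(lam, 0.0, 1.0)
    is_on = lam >= 1 - var_threshold
    is_off = lam <= var_threshold

    v_on = P @ v[:, is_on]
    v_off = P @ v[:, is_off]
    vv = np.concatenate([v_on, v_off], axis=1)
    n_on, n_off = v_on.shape[1], v_off.shape[1]
    if n_on + n_off:
        # Loewdin V (V'V)^(-1/2): closest jointly orthonormal frame
        g_evals, g_evecs = np.linalg.eigh(vv.T @ vv)
        vv = vv @ g_evecs @ np.diag(1.0 / np.sqrt(g_evals)) @ g_evecs.T
    # shared = full orthogonal complement (intermediate-ratio plus screened-out)
    resid = np.eye(k) - vv @ vv.T
    r_evals, r_evecs = np.linalg.eigh(resid)
    s_shared = r_evecs[:, r_evals > 0.5]
    return vv[:, :n_on], vv[:, n_on:n_on + n_off], s_shared


def varimax_criterion(A: np.ndarray) -> float:
    """Raw varimax objective: sum over columns of the variance of squares."""
    A = np.asarray(A, dtype=float)
    sq = A ** 2
    return float(np.sum(sq.var(axis=0)))


def varimax(A: np.ndarray, max_sweeps: int = 100, tol: float = 1e-12
            ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Varimax rotation by pairwise Jacobi sweeps (Kaiser normalization off).

    Each column pair is rotated by its closed-form optimal angle, so the
    algorithm cannot stall on the saddle points that trap gradient/SVD
    iterations (an exact 45-degree mixture is such a saddle). Returns
    (rotated, R, converged) with rotated = A @ R and R'R = I; a single column
    is returned unchanged. Non-convergence after ``max_sweeps`` returns the
    best iterate with ``converged = False``.
    """
    A = np.asarray(A, dtype=float)
    p, k = A.shape
    R = np.eye(k)
    if k == 1:
        return A.copy(), R, True
    L = A.copy()
    converged = False
    for _ in range(max_sweeps):
        max_angle = 0.0
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = L[:, i], L[:, j]
                u = x ** 2 - y ** 2
                v = 2.0 * x * y
                num = 2.0 * (p * (u @ v) - u.sum() * v.sum())
                den = p * (u @ u - v @ v) - (u.sum() ** 2 - v.sum() ** 2)
                if num == 0.0 and den == 0.0:
                    continue
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-15:
                    continue
                max_angle = max(max_angle, abs(phi))
                c, s = np.cos(phi), np.sin(phi)
                G = np.array([[c, -s], [s, c]])
                L[:, [i, j]] = L[:, [i, j]] @ G
                R[:, [i, j]] = R[:, [i, j]] @ G
        if max_angle < tol:
            converged = True
            break
    return L, R, converged


def varimax_sparse_components(avg_response: np.ndarray, subspace: np.ndarray
                              ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Rotate within-subspace time courses to temporally sparse components.

    Parameters
    ----------
    avg_response : (n_times, n_factors) trial-averaged latent response
    subspace : (n_factors, k) orthonormal basis

    Returns
    -------
    directions : (n_factors, k) rotated component directions
    courses : (n_times, k) rotated time courses
    converged : bool
    """
    courses = np.asarray(avg_response) @ subspace
    rotated, R, converged = varimax(courses)
    return subspace @ R, rotated, converged


def measure_fwhm(course: np.ndarray, times: np.ndarray) -> float:
    """FWHM by linear interpolation at half maximum around the peak."""
    course = np.asarray(course, dtype=float)
    p = int(np.argmax(course))
    half = course[p] / 2.0
    left = np.flatnonzero(course[:p] <= half)
    right = np.flatnonzero(course[p:] <= half)
    if left.size == 0 or right.size == 0:
        raise ValueError("half-maximum level never crossed inside the window")
    i = left[-1]
    t_left = np.interp(half, [course[i], course[i + 1]], [times[i], times[i + 1]])
    j = p + right[0]
    t_right = np.interp(half, [course[j], course[j - 1]], [times[j], times[j - 1]])
    return float(t_right - t_left)


def select_transient(courses: np.ndarray, directions: np.ndarray, times: np.ndarray,
                     window: tuple[float, float] | None = None,
                     baseline_window: tuple[float, float] | None = None,
                     smoothing_tau: float | None = None,
                     fwhm_smooth_bins: float = 2.0,
                     component_index: int | None = None) -> TransientComponent:
    """Pick the component with the largest modulation and characterize it.

    Modulation is the maximum absolute deviation from the baseline-window mean
    inside ``window``. The returned component is sign-flipped so its peak is
    positive. If ``smoothing_tau`` is given, the FWHM is measured after
    exactly inverting the causal exponential acquisition smoothing (the
    transient's width in the rate domain); peak time and amplitude are always
    reported on the observed (smoothed-domain) template. Inverse filtering
    restores the pre-smoothing noise, whose dips bias half-maximum crossings
    inward, so the deconvolved course is lightly re-smoothed
    (``fwhm_smooth_bins`` Gaussian) and the added width is removed from the
    reported FWHM in quadrature.
    """
    courses = np.atleast_2d(np.asarray(courses, dtype=float))
    times = np.asarray(times, dtype=float)
    n_comp = courses.shape[1]
    if n_comp < 1:
        raise ValueError("need at least one component")
    window = window or (times[0], times[-1])
    baseline_window = baseline_window or (times[0], times[0] + 0.5)
    in_win = (times >= window[0]) & (times <= window[1])
    in_base = (times >= baseline_window[0]) & (times <= baseline_window[1])
    if not in_win.any() or not in_base.any():
        raise ValueError("selection or baseline window outside the aligned times")

    base = courses[in_base].mean(axis=0)
    dev = courses - base
    mods = np.abs(dev[in_win]).max(axis=0)
    if np.all(mods < 1e-12):
        raise ValueError("all components are flat: no transient modulation found")
    peak_times = times[in_win][np.abs(dev[in_win]).argmax(axis=0)]
    # argmax modulation; ties broken by earlier peak time
    best = min(range(n_comp), key=lambda j: (-mods[j], peak_times[j]))
    if component_index is not None:
        best = component_index

    course = dev[:, best].copy()
    w = np.asarray(directions)[:, best].copy()
    bin_width = float(times[1] - times[0])
    peak_idx_win = np.abs(course[in_win]).argmax()
    sign = np.sign(course[in_win][peak_idx_win]) or 1.0
    course *= sign
    w *= sign
    w /= np.linalg.norm(w)
    peak_idx = np.flatnonzero(in_win)[np.argmax(course[in_win])]
    correction = 0.0
    if smoothing_tau is not None:
        fwhm_course = inverse_filter(course, smoothing_tau, bin_width)
        if fwhm_smooth_bins > 0:
            fwhm_course = gaussian_filter1d(fwhm_course, fwhm_smooth_bins,
                                            mode="nearest")
            correction = GAUSS_FWHM_FACTOR * fwhm_smooth_bins * bin_width
    else:
        fwhm_course = course
    try:
        fwhm = measure_fwhm(fwhm_course, times)
        fwhm = float(np.sqrt(max(fwhm ** 2 - correction ** 2, 0.0)))
    except ValueError:
        fwhm = float("nan")  # half maximum never crossed inside the window
    return TransientComponent(w=w, template=course, times=times,
                              peak_time=float(times[peak_idx]),
                              peak_amplitude=float(course[peak_idx]),
                              fwhm=fwhm, component_index=int(best))


class TransientIdentifier:
    """End-to-end identification of the onset and offset transients.

    Parameters
    ----------
    windows : AlignmentWindows
    var_threshold : float
        A direction is onset-unique if at most this fraction of its variance
        is offset-related (and vice versa).
    smoothing_tau : float or None
        Acquisition smoothing constant used for rate-domain FWHM measurement.

    Attributes (after ``fit``)
    --------------------------
    model_ : TransientModel
    subspaces_ : (S_on, S_off, S_shared)
    aligned_on_, aligned_off_ : AlignedResponses
    """

    def __init__(self, windows: AlignmentWindows | None = None,
                 var_threshold: float = 0.1, smoothing_tau: float | None = 0.4,
                 onset_baseline: tuple[float, float] = (-1.5, -1.0),
                 offset_baseline: tuple[float, float] = (1.0, 1.5)):
        self.windows = windows or AlignmentWindows()
        self.var_threshold = var_threshold
        self.smoothing_tau = smoothing_tau
        self.onset_baseline = onset_baseline
        self.offset_baseline = offset_baseline

    def fit(self, z: np.ndarray, events: pd.DataFrame, bin_width: float
            ) -> "TransientIdentifier":
        on, off = align_and_average(z, events, self.windows, bin_width)
        s_on, s_off, s_shared = unique_variance_subspaces(
            on.avg, off.avg, var_threshold=self.var_threshold)
        if s_on.shape[1] == 0:
            raise ValueError("no onset-unique subspace found; transients may be "
                             "absent or the alignment windows overlap")
        if s_off.shape[1] == 0:
            raise ValueError("no offset-unique subspace found")
        dirs_on, courses_on, _ = varimax_sparse_components(on.avg, s_on)
        dirs_off, courses_off, _ = varimax_sparse_components(off.avg, s_off)
        comp_on = select_transient(courses_on, dirs_on, on.times,
                                   baseline_window=self.onset_baseline,
                                   smoothing_tau=self.smoothing_tau)
        comp_off = select_transient(courses_off, dirs_off, off.times,
                                    baseline_window=self.offset_baseline,
                                    smoothing_tau=self.smoothing_tau)
        self.model_ = TransientModel(onset=comp_on, offset=comp_off,
                                     windows=self.windows)
        self.subspaces_ = (s_on, s_off, s_shared)
        self.aligned_on_ = on
        self.aligned_off_ = off
        return self
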