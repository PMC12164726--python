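"""Transient-gated decoding: detect, decide, latch, release.

The decoder watches the 20-D latent stream with two binary linear-discriminant
detectors trained on the onset and offset transients. Detection of an onset
transient opens a short decision window in which a feature decoder runs — a
multiclass discriminant for finger identity, or a linear latent-to-force
regression. The decision (the class once its posterior clears a threshold, or
the force prediction at the end of the engagement window) is then latched:
the output is held exactly constant until the offset detector fires, at which
point the output returns to null/zero. Between actions the decoder emits
nothing, whatever the neural stream does — the architectural property that
prevents phantom outputs during non-hand behavior.

Everything is causal: the decision at bin t uses bins <= t only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LinearRegression
from sklearn.utils.validation import check_is_fitted

from .transients import TransientModel

NULL_CLASS = -1

IDLE, DECIDING, LATCHED = 0, 1, 2
STATE_NAMES = {IDLE: "idle", DECIDING: "deciding", LATCHED: "latched"}


@dataclass(frozen=True)
class GateConfig:
    """State-machine thresholds and windows.

    theta_on / theta_off: detector posterior thresholds. k_consecutive:
    debouncing — the posterior must clear the threshold on this many
    consecutive bins. refractory: after any transition the opposite detector
    is disabled for this long. theta_class: classification posterior needed to
    emit a class; class_timeout: emit the argmax anyway after this long.
    force_window: how long the force regression stays engaged after onset
    detection before its output is clamped (the transient lasts about one
    second after smoothing).
    """

    theta_on: float = 0.9
    theta_off: float = 0.9
    k_consecutive: int = 2
    refractory: float = 0.5
    theta_class: float = 0.9
    class_timeout: float = 1.0
    force_window: float = 1.0
    detector_features: str = "latent20"   # or "transient2d"
    label_halfwidth: float = 0.1          # detector positive window, s
    guard_band: float = 0.3               # exclusion zone around positives, s

    def __post_init__(self) -> None:
        for name in ("theta_on", "theta_off", "theta_class"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.k_consecutive < 1:
            raise ValueError("k_consecutive must be >= 1")
        for name in ("refractory", "class_timeout", "force_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.detector_features not in ("latent20", "transient2d"):
            raise ValueError("detector_features must be 'latent20' or 'transient2d'")


@dataclass
class DecodeTrace:
    """Per-bin decoder output with state annotations."""

    times: np.ndarray
    output: np.ndarray           # float force, or int class labels (NULL_CLASS = null)
    state: np.ndarray            # int codes, see STATE_NAMES
    events: list = field(default_factory=list)
    kind: str = "classification"
    bin_width: float = 0.02

    @property
    def state_names(self) -> list[str]:
        return [STATE_NAMES[s] for s in self.state]

    def latched_segments(self) -> list[tuple[int, int]]:
        """Half-open bin ranges where the output is latched."""
        segs = []
        in_seg = False
        start = 0
        for i, s in enumerate(self.state):
            if s == LATCHED and not in_seg:
                in_seg, start = True, i
            elif s != LATCHED and in_seg:
                segs.append((start, i))
                in_seg = False
        if in_seg:
            segs.append((start, len(self.state)))
        return segs


def _detector_labels(times: np.ndarray, centers: np.ndarray, halfwidth: float,
                     guard: float) -> tuple[np.ndarray, np.ndarray]:
    """Positive mask around event centers plus a keep mask excluding the guard."""
    pos = np.zeros(times.size, dtype=bool)
    guard_zone = np.zeros(times.size, dtype=bool)
    for c in centers:
        d = np.abs(times - c)
        pos |= d <= halfwidth
        guard_zone |= (d > halfwidth) & (d <= guard)
    return pos, ~guard_zone


class GatedDecoder(BaseEstimator):
    """Onset/offset-gated feature decoder with output latching.

    Parameters
    ----------
    task : {"classification", "force"}
    config : GateConfig

    Attributes (after ``fit``)
    --------------------------
    onset_detector_, offset_detector_ : binary LDA with posterior outputs
    feature_decoder_ : multiclass LDA or LinearRegression
    classes_ : class labels (classification task)
    """

    def __init__(self, task: str = "classification",
                 config: GateConfig | None = None):
        self.task = task
        self.config = config or GateConfig()

    # -- training ----------------------------------------------------------

    def fit(self, z: np.ndarray, events: pd.DataFrame,
            transients: TransientModel, bin_width: float,
            cued_force: Optional[np.ndarray] = None) -> "GatedDecoder":
        """Train detectors and the feature decoder from one session.

        z : (n_bins, n_factors) latent trajectories; events : trial table with
        onset_time/offset_time/condition; cued_force : per-trial force targets
        (force task; defaults to events["cued_force"]).
        """
        if self.task not in ("classification", "force"):
            raise ValueError("task must be 'classification' or 'force'")
        cfg = self.config
        z = np.asarray(z, dtype=float)
        n_bins = z.shape[0]
        times = np.arange(n_bins) * bin_width

        conds = events["condition"].to_numpy()
        if self.task == "classification" and np.unique(conds).size < 2:
            raise ValueError("need at least two classes to train the finger decoder")
        trial_counts = pd.Series(conds).value_counts()
        if self.task == "classification" and (trial_counts < 2).any():
            raise ValueError("every condition needs at least two trials")

        feats = self._features(z, transients)

        peak_on = events["onset_time"].to_numpy() + transients.onset.peak_time
        peak_off = events["offset_time"].to_numpy() + transients.offset.peak_time
        pos_on, keep_on = _detector_labels(times, peak_on, cfg.label_halfwidth,
                                           cfg.guard_band)
        pos_off, keep_off = _detector_labels(times, peak_off, cfg.label_halfwidth,
                                             cfg.guard_band)
        # each detector's negatives also exclude the other event's guard zone
        keep = keep_on & keep_off
        if pos_on.sum() == 0 or pos_off.sum() == 0:
            raise ValueError("no positive detector bins: check event times")
        self.onset_detector_ = LinearDiscriminantAnalysis().fit(
            feats[keep | pos_on], pos_on[keep | pos_on])
        self.offset_detector_ = LinearDiscriminantAnalysis().fit(
            feats[keep | pos_off], pos_off[keep | pos_off])

        if self.task == "classification":
            mask = np.zeros(n_bins, dtype=bool)
            labels = np.full(n_bins, NULL_CLASS)
            for row in events.itertuples():
                det = row.onset_time + transients.onset.peak_time
                m = (times >= det) & (times < det + cfg.class_timeout)
                mask |= m
                labels[m] = row.condition
            self.feature_decoder_ = LinearDiscriminantAnalysis().fit(
                z[mask], labels[mask])
            self.classes_ = self.feature_decoder_.classes_
        else:
            force = (np.asarray(cued_force, dtype=float) if cued_force is not None
                     else events["cued_force"].to_numpy(dtype=float))
            mask = np.zeros(n_bins, dtype=bool)
            target = np.zeros(n_bins)
            for row, f in zip(events.itertuples(), force):
                m = (times >= row.onset_time) & (times < row.onset_time + cfg.force_window)
                mask |= m
                target[m] = f
            self.feature_decoder_ = LinearRegression().fit(z[mask], target[mask])

        self.bin_width_ = float(bin_width)
        self.transients_ = transients
        self.n_features_in_ = z.shape[1]
        return self

    def _features(self, z: np.ndarray, transients: TransientModel) -> np.ndarray:
        if self.config.detector_features == "transient2d":
            w = np.column_stack([transients.w_on, transients.w_off])
            return z @ w
        return z

    # -- streaming decode --------------------------------------------------

    def decode_stream(self, z: np.ndarray) -> DecodeTrace:
        """Run the causal gating state machine over a latent stream.

        Detector posteriors and feature outputs are static per-bin maps of
        z(t), so precomputing them preserves causality; the state machine
        below consumes them strictly left to right.
        """
        check_is_fitted(self, "onset_detector_")
        cfg = self.config
        z = np.asarray(z, dtype=float)
        if z.ndim != 2 or z.shape[1] != self.n_features_in_:
            raise ValueError(f"expected (n_bins, {self.n_features_in_}) latents")
        n = z.shape[0]
        dt = self.bin_width_
        times = np.arange(n) * dt

        feats = self._features(z, self.transients_)
        post_on = self.onset_detector_.predict_proba(feats)[:, list(
            self.onset_detector_.classes_).index(True)]
        post_off = self.offset_detector_.predict_proba(feats)[:, list(
            self.offset_detector_.classes_).index(True)]
        if self.task == "classification":
            class_post = self.feature_decoder_.predict_proba(z)
            feature_classes = self.feature_decoder_.classes_
            force_pred = None
        else:
            class_post = None
            force_pred = self.feature_decoder_.predict(z)

        return run_state_machine(
            post_on=post_on, post_off=post_off, times=times, cfg=cfg,
            task=self.task, class_post=class_post,
            class_labels=None if self.task == "force" else feature_classes,
            force_pred=force_pred, bin_width=dt)

    # sklearn-flavored alias
    def predict(self, z: np.ndarray) -> np.ndarray:
        return self.decode_stream(z).output


def run_state_machine(post_on: np.ndarray, post_off: np.ndarray,
                      times: np.ndarray, cfg: GateConfig, task: str,
                      class_post: Optional[np.ndarray] = None,
                      class_labels: Optional[np.ndarray] = None,
                      force_pred: Optional[np.ndarray] = None,
                      bin_width: float = 0.02) -> DecodeTrace:
    """The gating state machine on precomputed per-bin detector posteriors.

    Exposed separately so the transition logic is testable on constructed
    posterior sequences. States progress idle -> deciding -> latched -> idle;
    any posterior sequence yields a valid trace (anomalies such as timeout
    emissions are recorded in the event log, never raised).
    """
    n = post_on.size
    is_class = task == "classification"
    output = (np.full(n, NULL_CLASS, dtype=int) if is_class
              else np.zeros(n, dtype=float))
    state = np.full(n, IDLE, dtype=int)
    events: list[dict] = []

    st = IDLE
    consec_on = 0
    consec_off = 0
    onset_enabled_at = -np.inf
    offset_enabled_at = np.inf
    decide_start_t = 0.0
    latch_value = NULL_CLASS if is_class else 0.0
    null_value = NULL_CLASS if is_class else 0.0

    for i in range(n):
        t = times[i]
        # detector debouncing (counted even while disabled? no — a detector
        # in its refractory contributes nothing)
        if st == IDLE:
            consec_on = consec_on + 1 if (post_on[i] >= cfg.theta_on
                                          and t >= onset_enabled_at) else 0
            if consec_on >= cfg.k_consecutive:
                st = DECIDING
                decide_start_t = t
                consec_on = 0
                consec_off = 0
                offset_enabled_at = t + cfg.refractory
                events.append(dict(time=t, event="onset_detected"))
                state[i] = st
                if not is_class:
                    output[i] = force_pred[i]
                continue
            output[i] = null_value
            state[i] = IDLE
            continue

        # offset watch is live in DECIDING and LATCHED (after the refractory)
        consec_off = consec_off + 1 if (post_off[i] >= cfg.theta_off
                                        and t >= offset_enabled_at) else 0
        if consec_off >= cfg.k_consecutive:
            st = IDLE
            consec_off = 0
            onset_enabled_at = t + cfg.refractory
            latch_value = null_value
            events.append(dict(time=t, event="offset_detected"))
            output[i] = null_value
            state[i] = IDLE
            continue

        if st == DECIDING:
            elapsed = t - decide_start_t
            if is_class:
                j = int(np.argmax(class_post[i]))
                if class_post[i, j] >= cfg.theta_class:
                    latch_value = int(class_labels[j])
                    st = LATCHED
                    events.append(dict(time=t, event="class_emitted",
                                       label=latch_value,
                                       posterior=float(class_post[i, j])))
                    output[i] = latch_value
                elif elapsed >= cfg.class_timeout:
                    latch_value = int(class_labels[j])
                    st = LATCHED
                    events.append(dict(time=t, event="class_timeout",
                                       label=latch_value,
                                       posterior=float(class_post[i, j])))
                    output[i] = latch_value
                else:
                    output[i] = null_value
            else:
                if elapsed >= cfg.force_window:
                    latch_value = float(force_pred[i])
                    st = LATCHED
                    events.append(dict(time=t, event="force_clamped",
                                       value=latch_value))
                    output[i] = latch_value
                else:
                    output[i] = force_pred[i]
            state[i] = st
            continue

        # LATCHED
        output[i] = latch_value
        state[i] = LATCHED

    return DecodeTrace(times=times, output=output, state=state, events=events,
                       kind="classification" if is_class else "force",
                       bin_width=bin_width)


def train_gated(z: np.ndarray, events: pd.DataFrame, transients: TransientModel,
                task: str, cfg: GateConfig | None = None,
                bin_width: float = 0.02) -> GatedDecoder:
    """Train a gated decoder ('classification' or 'force') on one session."""
    return GatedDecoder(task=task, config=cfg or GateConfig()).fit(
        z, events, transients, bin_width)


def decode_stream(z: np.ndarray, decoder: GatedDecoder) -> DecodeTrace:
    """Run a trained gated decoder over a latent stream."""
    return decoder.decode_stream(z)
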