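"""Leave-one-out evaluation harness and the offline comparison metrics.

Each trial is held out in turn; the entire pipeline — latent model, transient
identification, gated decoder, continuous baseline — is refit on the remaining
trials, and the held-out trial's continuous stream segment is decoded. Four
metrics summarize a session: epoch-mean force R^2, normalized hold range
(output instability during the middle of the grasp), per-bin classification
accuracy, and click-duration ratio (decoded vs cued click length).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from sklearn.metrics import r2_score

from . import baselines
from .baselines import (ContinuousLDAClassifier, NULL_CLASS,
                        WienerCascadeRegressor, force_target_stream,
                        label_stream)
from .gate import DecodeTrace, GateConfig, GatedDecoder
from .latent import FactorLatentSpace
from .preprocess import PreprocessConfig, smooth_counts
from .synth import FORCE_TASKS, SessionBundle
from .transients import AlignmentWindows, TransientIdentifier


@dataclass
class EvalReport:
    """Per-trial records plus session aggregates of one LOO comparison."""

    trials: pd.DataFrame
    aggregates: dict
    excluded_trials: list = field(default_factory=list)
    failed_folds: list = field(default_factory=list)
    task: str = "classification"


# -- epoch segmentation ----------------------------------------------------

def epoch_segments(trial, bin_width: float) -> dict[str, tuple[int, int]]:
    """Pre/middle/post epoch bin windows (25th-75th percentile of each phase).

    Returns half-open (start_bin, stop_bin) windows; a degenerate phase
    collapses to the single bin at its midpoint.
    """
    start, onset = float(trial.trial_start), float(trial.onset_time)
    offset, end = float(trial.offset_time), float(trial.trial_end)
    if not (start < onset < offset < end):
        raise ValueError("trial phases must be ordered start < onset < offset < end")

    def window(a: float, b: float) -> tuple[int, int]:
        lo = a + 0.25 * (b - a)
        hi = a + 0.75 * (b - a)
        i0, i1 = int(round(lo / bin_width)), int(round(hi / bin_width))
        if i1 <= i0:  # ultra-short phase: one bin at the midpoint
            mid = int(round(0.5 * (a + b) / bin_width))
            return mid, mid + 1
        return i0, i1

    return {"pre": window(start, onset), "middle": window(onset, offset),
            "post": window(offset, end)}


# -- force metrics ---------------------------------------------------------

def force_metrics(trace: DecodeTrace, epochs: dict, target_force: float,
                  segment_start_bin: int = 0) -> dict:
    """Epoch means and middle-epoch stability for one trial.

    ``trace`` may cover only a segment of the session; ``segment_start_bin``
    maps the session-absolute epoch windows into it. Normalized range is
    (max - min) / mean over the middle epoch; a non-positive mean flags the
    record instead of producing a sign-flipped statistic.
    """
    out = np.asarray(trace.output, dtype=float)

    def seg(win: tuple[int, int]) -> np.ndarray:
        lo, hi = win[0] - segment_start_bin, win[1] - segment_start_bin
        lo, hi = max(lo, 0), min(hi, out.size)
        if hi <= lo:
            raise ValueError("epoch window outside the decoded segment")
        return out[lo:hi]

    means = {name: float(seg(win).mean()) for name, win in epochs.items()}
    mid = seg(epochs["middle"])
    mid_mean = float(mid.mean())
    flagged = mid_mean <= 0
    norm_range = float(np.ptp(mid) / mid_mean) if not flagged else float("nan")
    return dict(epoch_means=means, target_force=float(target_force),
                normalized_range=norm_range, range_flagged=flagged)


def session_force_r2(records: list[dict]) -> float:
    """R^2 across pooled (epoch mean, target) pairs with targets (0, F, 0)."""
    preds, targets = [], []
    for r in records:
        m = r["epoch_means"]
        preds += [m["pre"], m["middle"], m["post"]]
        targets += [0.0, r["target_force"], 0.0]
    return float(r2_score(targets, preds))


# -- click metrics ---------------------------------------------------------

def click_metrics(trace: DecodeTrace, trial, bin_width: float,
                  segment_start_bin: int = 0) -> dict:
    """Per-bin accuracy against the cued label stream and click-duration ratio.

    The decoded click is the contiguous non-null run with maximal overlap with
    the cued [onset, offset) interval (ties -> earliest run); no overlapping
    run scores a ratio of 0.
    """
    out = np.asarray(trace.output)
    n = out.size
    on_bin = int(round(trial.onset_time / bin_width)) - segment_start_bin
    off_bin = int(round(trial.offset_time / bin_width)) - segment_start_bin
    cued = np.full(n, NULL_CLASS)
    cued[max(on_bin, 0):min(off_bin, n)] = trial.condition
    accuracy = float(np.mean(out == cued))

    runs = []
    i = 0
    while i < n:
        if out[i] != NULL_CLASS:
            j = i
            while j < n and out[j] == out[i]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    cued_dur = (off_bin - on_bin) * bin_width
    best, best_ov = None, 0
    for (a, b) in runs:
        ov = max(0, min(b, off_bin) - max(a, on_bin))
        if ov > best_ov:
            best, best_ov = (a, b), ov
    if best is None:
        return dict(accuracy=accuracy, duration_ratio=0.0, decoded_label=None,
                    cued_duration=cued_dur)
    dur = (best[1] - best[0]) * bin_width
    return dict(accuracy=accuracy, duration_ratio=float(dur / cued_dur),
                decoded_label=int(out[best[0]]), cued_duration=cued_dur)


# -- standard fold pipeline ------------------------------------------------

@dataclass
class FoldModels:
    """Everything trained on one LOO fold."""

    latent: FactorLatentSpace
    transients: TransientIdentifier
    decoders: dict


def standard_fold_trainer(task: str, n_factors: int = 20,
                          gate_cfg: GateConfig | None = None,
                          windows: AlignmentWindows | None = None,
                          n_taps: int = 10,
                          smoothing_tau: float = 0.4
                          ) -> Callable:
    """Build the per-fold trainer used by ``loo_cv``.

    The returned callable refits, on training bins only: the factor-analysis
    latent space, the transient components, the gated decoder, and the
    continuous baseline (Wiener cascade for force tasks, per-bin LDA for
    classification).
    """
    def trainer(rates: np.ndarray, events_train: pd.DataFrame,
                train_mask: np.ndarray, bin_width: float) -> FoldModels:
        fls = FactorLatentSpace(n_factors=n_factors).fit(rates.T[train_mask])
        z = fls.transform(rates.T)
        ident = TransientIdentifier(windows=windows,
                                    smoothing_tau=smoothing_tau).fit(
            z, events_train, bin_width)
        gated = GatedDecoder(task=task, config=gate_cfg or GateConfig()).fit(
            z[train_mask], events_train_shifted(events_train, train_mask, bin_width),
            ident.model_, bin_width)
        decoders = {"gated": gated}
        if task == "force":
            target = force_target_stream(events_train, rates.shape[1], bin_width)
            decoders["wiener"] = WienerCascadeRegressor(n_taps=n_taps).fit(
                z[train_mask], target[train_mask])
        else:
            labels = label_stream(events_train, rates.shape[1], bin_width)
            decoders["continuous"] = ContinuousLDAClassifier().fit(
                z[train_mask], labels[train_mask])
        return FoldModels(latent=fls, transients=ident, decoders=decoders)

    return trainer


def events_train_shifted(events: pd.DataFrame, train_mask: np.ndarray,
                         bin_width: float) -> pd.DataFrame:
    """Remap event times onto the concatenated training-bin clock.

    The training bins form a compacted stream once the held-out trial's span
    is removed; event times must follow so detector labels and decision
    windows land on the right bins.
    """
    offsets = np.cumsum(~train_mask) * bin_width  # removed time before each bin
    ev = events.copy()
    for col in ("cue_time", "onset_time", "offset_time", "trial_start", "trial_end"):
        bins = np.clip((ev[col].to_numpy() / bin_width).round().astype(int),
                       0, train_mask.size - 1)
        ev[col] = ev[col] - offsets[bins]
    return ev


def loo_cv(bundle: SessionBundle, trainer: Optional[Callable] = None,
           task: Optional[str] = None,
           pre_cfg: PreprocessConfig | None = None,
           windows: AlignmentWindows | None = None,
           gate_cfg: GateConfig | None = None,
           n_factors: int = 20) -> EvalReport:
    """Leave-one-trial-out comparison of the gated and continuous decoders.

    For each fold the full pipeline is refit on the remaining trials (no
    leakage: the held-out trial's bins are excluded from every fit) and the
    held-out trial's [trial_start, trial_end) segment is decoded as a fresh
    stream. Trials on which any compared decoder produces an all-null (or
    non-positive mean force) prediction are excluded from the aggregates, with
    the exclusions reported. A trainer failure marks the fold failed rather
    than dropping it silently.
    """
    events = bundle.events.reset_index(drop=True)
    if len(events) < 3:
        raise ValueError("leave-one-out needs at least three trials")
    task = task or ("force" if bundle.events["task_type"].iloc[0] in FORCE_TASKS
                    else "classification")
    trainer = trainer or standard_fold_trainer(task, n_factors=n_factors,
                                               gate_cfg=gate_cfg, windows=windows)
    dt = bundle.bin_width
    rates = smooth_counts(bundle.counts, pre_cfg or PreprocessConfig(bin_width=dt)).rates
    n_bins = rates.shape[1]

    records: list[dict] = []
    failed: list[dict] = []
    for idx, trial in events.iterrows():
        seg0 = int(round(trial.trial_start / dt))
        seg1 = min(int(round(trial.trial_end / dt)), n_bins)
        train_mask = np.ones(n_bins, dtype=bool)
        train_mask[seg0:seg1] = False
        events_train = events.drop(index=idx)
        try:
            models = trainer(rates, events_train, train_mask, dt)
        except Exception as exc:  # noqa: BLE001 — fold failures are reported
            failed.append(dict(trial_id=int(trial.trial_id), error=str(exc)))
            continue

        z_seg = models.latent.transform(rates.T[seg0:seg1])
        epochs = epoch_segments(trial, dt)
        rec: dict = dict(trial_id=int(trial.trial_id),
                         condition=int(trial.condition))
        for name, dec in models.decoders.items():
            if isinstance(dec, GatedDecoder):
                trace = dec.decode_stream(z_seg)
            elif isinstance(dec, WienerCascadeRegressor):
                trace = DecodeTrace(times=np.arange(seg0, seg1) * dt,
                                    output=dec.predict(z_seg),
                                    state=np.zeros(seg1 - seg0, dtype=int),
                                    kind="force", bin_width=dt)
            else:
                trace = DecodeTrace(times=np.arange(seg0, seg1) * dt,
                                    output=dec.predict(z_seg),
                                    state=np.zeros(seg1 - seg0, dtype=int),
                                    kind="classification", bin_width=dt)
            if task == "force":
                m = force_metrics(trace, epochs, trial.cued_force,
                                  segment_start_bin=seg0)
            else:
                m = click_metrics(trace, trial, dt, segment_start_bin=seg0)
            rec[name] = m
        records.append(rec)

    decoder_names = [k for k in records[0] if k not in ("trial_id", "condition")]

    def is_null(rec: dict, name: str) -> bool:
        m = rec[name]
        if task == "force":
            return m["epoch_means"]["middle"] <= 0
        return m["decoded_label"] is None

    excluded = [r["trial_id"] for r in records
                if any(is_null(r, n) for n in decoder_names)]
    included = [r for r in records if r["trial_id"] not in excluded]
    if not included:
        raise ValueError("every trial was excluded by the all-null rule")

    aggregates: dict = {}
    for name in decoder_names:
        if task == "force":
            aggregates[name] = dict(
                epoch_r2=session_force_r2([r[name] for r in included]),
                median_normalized_range=float(np.median(
                    [r[name]["normalized_range"] for r in included
                     if not r[name]["range_flagged"]])),
            )
        else:
            aggregates[name] = dict(
                timepoint_accuracy=float(np.mean(
                    [r[name]["accuracy"] for r in included])),
                median_duration_ratio=float(np.median(
                    [r[name]["duration_ratio"] for r in included])),
                trial_accuracy=float(np.mean(
                    [r[name]["decoded_label"] == r["condition"]
                     for r in included])),
            )

    flat = []
    for r in records:
        row = dict(trial_id=r["trial_id"], condition=r["condition"],
                   included=r["trial_id"] not in excluded)
        for name in decoder_names:
            for key, val in r[name].items():
                row[f"{name}_{key}"] = val
        flat.append(row)
    return EvalReport(trials=pd.DataFrame(flat), aggregates=aggregates,
                      excluded_trials=excluded, failed_folds=failed, task=task)


def model_fingerprint(models: FoldModels) -> str:
    """Hash of every fitted parameter array — the no-leakage witness."""
    h = hashlib.sha256()
    h.update(models.latent.loadings_.tobytes())
    h.update(models.latent.channel_means_.tobytes())
    h.update(models.transients.model_.w_on.tobytes())
    h.update(models.transients.model_.w_off.tobytes())
    for name in sorted(models.decoders):
        dec = models.decoders[name]
        if isinstance(dec, GatedDecoder):
            h.update(dec.onset_detector_.coef_.tobytes())
            h.update(dec.offset_detector_.coef_.tobytes())
            fd = dec.feature_decoder_
            h.update(getattr(fd, "coef_", np.zeros(1)).tobytes())
        elif isinstance(dec, WienerCascadeRegressor):
            h.update(dec.linear_weights_.tobytes())
            h.update(dec.polynomial_coeffs_.tobytes())
        else:
            h.update(dec.lda_.coef_.tobytes())
    return h.hexdigest()
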