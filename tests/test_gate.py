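"""Gating state machine and gated-decoder training contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transientgate.gate import (DECIDING, IDLE, LATCHED, NULL_CLASS, GateConfig,
                                GatedDecoder, run_state_machine)


def _run(post_on, post_off, task="classification", class_post=None,
         force_pred=None, cfg=None, labels=None):
    n = len(post_on)
    times = np.arange(n) * 0.02
    cfg = cfg or GateConfig()
    if task == "classification" and class_post is None:
        class_post = np.full((n, 2), 0.5)
    if labels is None and task == "classification":
        labels = np.array([0, 1])
    if task == "force" and force_pred is None:
        force_pred = np.zeros(n)
    return run_state_machine(np.asarray(post_on, float), np.asarray(post_off, float),
                             times, cfg, task, class_post=class_post,
                             class_labels=labels, force_pred=force_pred)


def test_debounced_threshold_logic():
    """k=2: two consecutive supra-threshold bins are needed; deciding starts
    on the second (the third bin of the stream)."""
    post_on = [0.3, 0.95, 0.97] + [0.1] * 47
    trace = _run(post_on, [0.0] * 50)
    assert trace.state[0] == IDLE
    assert trace.state[1] == IDLE
    assert trace.state[2] == DECIDING
    assert trace.events[0]["event"] == "onset_detected"


def test_class_emitted_and_latched_until_offset():
    n = 60
    post_on = [0.95] * n
    post_off = [0.0] * 40 + [0.99] * 20
    class_post = np.tile([0.2, 0.8], (n, 1))
    class_post[7] = [0.05, 0.95]  # clears theta_class at bin 7
    cfg = GateConfig(refractory=0.1)
    trace = _run(post_on, post_off, class_post=class_post, cfg=cfg,
                 labels=np.array([3, 7]))
    assert trace.output[7] == 7
    # latched and constant until the offset fires
    assert np.all(trace.output[7:41] == 7)
    assert np.all(trace.state[8:41] == LATCHED)
    assert trace.output[41] == NULL_CLASS
    assert trace.state[41] == IDLE


def test_class_timeout_emits_argmax():
    n = 120
    post_on = [0.95] * n
    class_post = np.tile([0.6, 0.4], (n, 1))  # never clears theta_class
    trace = _run(post_on, [0.0] * n, class_post=class_post)
    timeout_events = [e for e in trace.events if e["event"] == "class_timeout"]
    assert len(timeout_events) == 1
    assert timeout_events[0]["label"] == 0
    assert np.any(trace.output == 0)


def test_force_clamp_is_exact():
    """Rising predictions within the window; after it, constant at the
    window-end value: range over the latched segment is 0 exactly."""
    n = 200
    force_pred = np.linspace(0.2, 1.8, n)
    post_on = [0.95] * n
    trace = _run(post_on, [0.0] * n, task="force", force_pred=force_pred)
    segs = trace.latched_segments()
    assert len(segs) == 1
    a, b = segs[0]
    assert np.ptp(trace.output[a:b]) == 0.0
    clamp = [e for e in trace.events if e["event"] == "force_clamped"][0]
    assert trace.output[a] == pytest.approx(clamp["value"])
    # live regression output before the clamp
    assert np.all(np.diff(trace.output[2:a]) > 0)


def test_no_output_without_detection():
    """Posteriors below threshold -> identically null output, forever."""
    rng = np.random.default_rng(0)
    post_on = rng.uniform(0.0, 0.89, size=500)
    trace = _run(post_on, rng.uniform(0.0, 0.89, size=500))
    assert np.all(trace.output == NULL_CLASS)
    assert np.all(trace.state == IDLE)
    assert trace.events == []


def test_refractory_blocks_immediate_offset():
    n = 100
    post_on = [0.95] * n
    post_off = [0.95] * n  # offset detector screams from the start
    class_post = np.tile([0.05, 0.95], (n, 1))
    cfg = GateConfig(refractory=0.5)
    trace = _run(post_on, post_off, class_post=class_post, cfg=cfg)
    off_events = [e for e in trace.events if e["event"] == "offset_detected"]
    # first possible offset: refractory (25 bins) after the onset transition
    assert off_events[0]["time"] >= trace.events[0]["time"] + 0.5


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_state_machine_totality(seed):
    """Any posterior sequence yields a valid trace with legal transitions."""
    rng = np.random.default_rng(seed)
    n = 150
    post_on = rng.uniform(size=n)
    post_off = rng.uniform(size=n)
    class_post = rng.dirichlet(np.ones(3), size=n)
    trace = _run(post_on, post_off, class_post=class_post,
                 labels=np.array([0, 1, 2]))
    legal = {IDLE: {IDLE, DECIDING}, DECIDING: {DECIDING, LATCHED, IDLE},
             LATCHED: {LATCHED, IDLE}}
    for a, b in zip(trace.state[:-1], trace.state[1:]):
        assert b in legal[a]
    # null output whenever idle; constant output within latched segments
    assert np.all(trace.output[trace.state == IDLE] == NULL_CLASS)
    for a, b in trace.latched_segments():
        assert np.ptp(trace.output[a:b]) == 0


# -- trained decoder ----------------------------------------------------------

def test_training_is_deterministic(fitted_session):
    fs = fitted_session
    d1 = GatedDecoder(task="classification").fit(
        fs.z, fs.bundle.events, fs.identifier.model_, fs.bundle.bin_width)
    d2 = GatedDecoder(task="classification").fit(
        fs.z, fs.bundle.events, fs.identifier.model_, fs.bundle.bin_width)
    assert np.array_equal(d1.onset_detector_.coef_, d2.onset_detector_.coef_)
    assert np.array_equal(d1.feature_decoder_.coef_, d2.feature_decoder_.coef_)


def test_decode_stream_causality(fitted_session):
    """Truncating the stream never changes decisions already made."""
    fs = fitted_session
    dec = GatedDecoder(task="classification").fit(
        fs.z, fs.bundle.events, fs.identifier.model_, fs.bundle.bin_width)
    full = dec.decode_stream(fs.z)
    cut = fs.z.shape[0] // 2
    part = dec.decode_stream(fs.z[:cut])
    assert np.array_equal(full.output[:cut], part.output)
    assert np.array_equal(full.state[:cut], part.state)


def test_detection_hits_planted_onsets(fitted_session_high_snr):
    """On a high-SNR session, detections land within 150 ms of every planted
    action onset (threshold crossing + 2-bin debounce jitters timing by a few
    bins) and the detector raises no false alarms between trials."""
    fs = fitted_session_high_snr
    dec = GatedDecoder(task="classification").fit(
        fs.z, fs.bundle.events, fs.identifier.model_, fs.bundle.bin_width)
    trace = dec.decode_stream(fs.z)
    det = np.array([e["time"] for e in trace.events
                    if e["event"] == "onset_detected"])
    onsets = fs.bundle.events["onset_time"].to_numpy()
    dists = np.array([np.abs(det - t).min() for t in onsets])
    assert np.mean(dists <= 0.15) >= 0.95
    false_alarms = sum(np.abs(onsets - t).min() > 1.0 for t in det)
    assert false_alarms / fs.bundle.duration < 0.05


def test_force_regressor_exact_on_noiseless_linear_coding():
    """Latents that encode cued force linearly are recovered with R^2 = 1."""
    rng = np.random.default_rng(3)
    n_trials, k = 6, 20
    dt = 0.02
    stride = 5.0
    n_bins = int(n_trials * stride / dt)
    w_true = rng.normal(size=k)
    w_true /= np.linalg.norm(w_true)
    z = np.zeros((n_bins, k))
    rows = []
    times = np.arange(n_bins) * dt
    for i in range(n_trials):
        on = 1.0 + i * stride
        off = on + 2.0
        f = float(1 + (i % 2))
        m = (times >= on) & (times < off)
        z[m] = f * w_true
        rows.append(dict(trial_id=i, task_type="grasp_force", condition=i % 2,
                         cued_force=f, cue_time=on - 0.5, onset_time=on,
                         offset_time=off, trial_start=on - 1.0,
                         trial_end=off + 1.0))
    events = pd.DataFrame(rows)

    from transientgate.transients import TransientComponent, TransientModel
    t = np.arange(-0.5, 0.5, dt)
    comp = TransientComponent(w=np.eye(k)[:, 0], template=np.zeros(t.size),
                              times=t, peak_time=0.0, peak_amplitude=1.0, fwhm=0.5)
    model = TransientModel(onset=comp, offset=comp)
    dec = GatedDecoder(task="force").fit(z, events, model, dt)
    pred = dec.feature_decoder_.predict(z)
    mask = np.zeros(n_bins, dtype=bool)
    for row in events.itertuples():
        mask |= (times >= row.onset_time) & (times < row.onset_time + 1.0)
    target = np.array([events.cued_force[np.searchsorted(
        events.onset_time.to_numpy(), times[i], side="right") - 1]
        for i in np.flatnonzero(mask)])
    resid = pred[mask] - target
    assert np.max(np.abs(resid)) < 1e-6


def test_single_class_rejected(fitted_session):
    fs = fitted_session
    ev = fs.bundle.events.copy()
    ev["condition"] = 0
    with pytest.raises(ValueError, match="two classes"):
        GatedDecoder(task="classification").fit(
            fs.z, ev, fs.identifier.model_, fs.bundle.bin_width)


@pytest.mark.parametrize("kwargs", [
    dict(theta_on=0.0), dict(theta_off=1.0), dict(k_consecutive=0),
    dict(refractory=-1.0), dict(force_window=0.0),
    dict(detector_features="pca"),
])
def test_gate_config_validation(kwargs):
    with pytest.raises(ValueError):
        GateConfig(**kwargs)
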