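"""Evaluation harness: epochs, metrics, leave-one-out folding, no leakage."""

from types import SimpleNamespace

import numpy as np
import pytest

from transientgate.evaluation import (click_metrics, epoch_segments, force_metrics,
                                      loo_cv, model_fingerprint,
                                      session_force_r2, standard_fold_trainer)
from transientgate.gate import NULL_CLASS, DecodeTrace
from transientgate.preprocess import smooth_counts
from transientgate.synth import GenConfig, generate_session

EVAL_WORLD = dict(n_channels=96, n_conditions=2, task_type="grasp_force",
                  snr_scale=1.5)


def _trial(start=0.0, onset=2.0, offset=4.0, end=6.0, condition=1, force=2.0):
    return SimpleNamespace(trial_start=start, onset_time=onset,
                           offset_time=offset, trial_end=end,
                           condition=condition, cued_force=force)


def _trace(output, kind="force", state=None, dt=0.02):
    output = np.asarray(output)
    return DecodeTrace(times=np.arange(output.size) * dt, output=output,
                       state=state if state is not None
                       else np.zeros(output.size, dtype=int),
                       kind=kind, bin_width=dt)


# -- epochs -------------------------------------------------------------------

def test_epoch_percentile_arithmetic():
    """start 0, onset 2 -> pre [0.5, 1.5] s; onset 2, offset 4 -> middle
    [2.5, 3.5] s (25th-75th percentile of each phase)."""
    ep = epoch_segments(_trial(), 0.02)
    assert ep["pre"] == (25, 75)
    assert ep["middle"] == (125, 175)
    assert ep["post"] == (225, 275)


def test_epoch_degenerate_phase_single_bin():
    ep = epoch_segments(_trial(start=1.99, onset=2.0), 0.02)
    assert ep["pre"][1] - ep["pre"][0] == 1


def test_epoch_order_validation():
    with pytest.raises(ValueError, match="ordered"):
        epoch_segments(_trial(onset=5.0, offset=4.0), 0.02)


# -- force metrics ------------------------------------------------------------

def test_normalized_range_arithmetic():
    out = np.zeros(300)
    out[125:175] = 1.0
    out[150] = 1.1
    out[151] = 0.9
    m = force_metrics(_trace(out), epoch_segments(_trial(), 0.02), 2.0)
    assert m["normalized_range"] == pytest.approx(0.2, rel=1e-6)


def test_clamped_trace_range_exactly_zero():
    out = np.zeros(300)
    out[100:225] = 1.37
    m = force_metrics(_trace(out), epoch_segments(_trial(), 0.02), 2.0)
    assert m["normalized_range"] == 0.0


def test_nonpositive_mean_flagged():
    m = force_metrics(_trace(np.zeros(300)), epoch_segments(_trial(), 0.02), 2.0)
    assert m["range_flagged"]
    assert np.isnan(m["normalized_range"])


def test_session_r2_definitions():
    """Perfect epoch means give R^2 = 1; the constant-mean predictor gives 0."""
    perfect = [dict(epoch_means=dict(pre=0.0, middle=f, post=0.0),
                    target_force=f) for f in (1.0, 2.0)]
    assert session_force_r2(perfect) == pytest.approx(1.0)
    targets = [0, 1, 0, 0, 2, 0]
    const = np.mean(targets)
    constant = [dict(epoch_means=dict(pre=const, middle=const, post=const),
                     target_force=f) for f in (1.0, 2.0)]
    assert session_force_r2(constant) == pytest.approx(0.0, abs=1e-12)


# -- click metrics ------------------------------------------------------------

def test_click_duration_ratio():
    """Decoded click of 0.8 s against a 1.0 s cue -> ratio 0.8."""
    out = np.full(300, NULL_CLASS)
    out[105:145] = 2  # 0.8 s
    trial = _trial(onset=2.0, offset=3.0, condition=2)
    m = click_metrics(_trace(out, kind="classification"), trial, 0.02)
    assert m["duration_ratio"] == pytest.approx(0.8)
    assert m["decoded_label"] == 2


def test_perfect_trace_metrics():
    out = np.full(300, NULL_CLASS)
    out[100:150] = 4
    trial = _trial(onset=2.0, offset=3.0, condition=4)
    m = click_metrics(_trace(out, kind="classification"), trial, 0.02)
    assert m["accuracy"] == 1.0
    assert m["duration_ratio"] == pytest.approx(1.0)


def test_no_overlapping_run_scores_zero():
    out = np.full(300, NULL_CLASS)
    out[10:20] = 1  # far before the click
    trial = _trial(onset=2.0, offset=3.0, condition=1)
    m = click_metrics(_trace(out, kind="classification"), trial, 0.02)
    assert m["duration_ratio"] == 0.0
    assert m["decoded_label"] is None


def test_max_overlap_run_selected():
    out = np.full(300, NULL_CLASS)
    out[95:105] = 1    # 5 bins overlap
    out[110:148] = 1   # 38 bins overlap -> this run wins
    trial = _trial(onset=2.0, offset=3.0, condition=1)
    m = click_metrics(_trace(out, kind="classification"), trial, 0.02)
    assert m["duration_ratio"] == pytest.approx(38 * 0.02 / 1.0)


# -- leave-one-out harness ------------------------------------------------------

@pytest.fixture(scope="module")
def eval_bundle():
    bundle, _ = generate_session(GenConfig(n_trials=8, seed=21, **EVAL_WORLD))
    return bundle


@pytest.fixture(scope="module")
def eval_report(eval_bundle):
    return loo_cv(eval_bundle)


def test_fold_count_equals_trials(eval_report, eval_bundle):
    assert len(eval_report.trials) == len(eval_bundle.events)
    assert eval_report.failed_folds == []


def test_gated_force_recovery(eval_report):
    assert eval_report.aggregates["gated"]["epoch_r2"] >= 0.9


def test_metrics_invariant_to_trial_order(eval_bundle, eval_report):
    shuffled = eval_bundle.events.sample(frac=1.0, random_state=0)
    from transientgate.synth import SessionBundle
    b2 = SessionBundle(counts=eval_bundle.counts, bin_width=eval_bundle.bin_width,
                       events=shuffled, meta=eval_bundle.meta)
    rep2 = loo_cv(b2)
    for name, agg in eval_report.aggregates.items():
        for key, val in agg.items():
            assert rep2.aggregates[name][key] == pytest.approx(val, rel=1e-9)


def test_no_leakage_from_heldout_labels(eval_bundle):
    """Corrupting the held-out trial's labels leaves the fold's model
    bit-identical (hash over every fitted parameter array)."""
    events = eval_bundle.events.reset_index(drop=True)
    rates = smooth_counts(eval_bundle.counts).rates
    dt = eval_bundle.bin_width
    trial = events.iloc[0]
    seg = slice(int(round(trial.trial_start / dt)), int(round(trial.trial_end / dt)))
    mask = np.ones(rates.shape[1], dtype=bool)
    mask[seg] = False
    trainer = standard_fold_trainer("force")

    models_clean = trainer(rates, events.drop(index=0), mask, dt)
    corrupted = events.copy()
    corrupted.loc[0, "condition"] = 99
    corrupted.loc[0, "cued_force"] = -42.0
    models_dirty = trainer(rates, corrupted.drop(index=0), mask, dt)
    assert model_fingerprint(models_clean) == model_fingerprint(models_dirty)


def test_too_few_trials_rejected(eval_bundle):
    from transientgate.synth import SessionBundle
    b = SessionBundle(counts=eval_bundle.counts, bin_width=eval_bundle.bin_width,
                      events=eval_bundle.events.iloc[:2], meta=eval_bundle.meta)
    with pytest.raises(ValueError, match="three trials"):
        loo_cv(b)


def test_failed_fold_reported_not_dropped(eval_bundle):
    def flaky_trainer(rates, events_train, mask, dt):
        if 0 not in events_train["trial_id"].to_numpy():
            raise RuntimeError("synthetic failure")
        return standard_fold_trainer("force")(rates, events_train, mask, dt)

    rep = loo_cv(eval_bundle, trainer=flaky_trainer, task="force")
    assert [f["trial_id"] for f in rep.failed_folds] == [0]
    assert len(rep.trials) == len(eval_bundle.events) - 1


def test_randomized_labels_fall_to_chance():
    """Label permutation before CV destroys classification — and would expose
    any leakage of the held-out trial into training."""
    cfg = GenConfig(n_channels=96, n_conditions=2, task_type="finger_click",
                    n_trials=10, seed=22, snr_scale=1.5)
    bundle, _ = generate_session(cfg)
    rep_true = loo_cv(bundle)
    rng = np.random.default_rng(0)
    shuffled = bundle.events.copy()
    shuffled["condition"] = rng.permutation(shuffled["condition"].to_numpy())
    from transientgate.synth import SessionBundle
    b2 = SessionBundle(counts=bundle.counts, bin_width=bundle.bin_width,
                       events=shuffled, meta=bundle.meta)
    rep_null = loo_cv(b2)
    assert rep_true.aggregates["gated"]["trial_accuracy"] >= 0.9
    assert rep_null.aggregates["gated"]["trial_accuracy"] <= 0.75
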