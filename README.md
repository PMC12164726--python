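# transientgate

Transient-gated decoding for intracortical brain-computer interfaces, with a
bundled synthetic population-spiking simulator.

## The problem

Continuous BCI decoders estimate an effector command (grasp force, finger
identity) from motor-cortex population activity at every time step. They
generalize poorly across behavioral contexts: a force decoder trained on
grasp-only data emits phantom forces during arm reaching, and its output
drifts through long holds because the action-specific neural code decays
within a second of action onset. Population activity does, however, contain
brief (~500 ms FWHM), condition-invariant *transients* at the onset and
offset of any hand-related action. This package implements the decoding
architecture built on that observation, for researchers working on
intracortical BCI decoding:

1. **Detect** — binary discriminant detectors watch a 20-D latent trajectory
   (factor analysis of smoothed threshold-crossing rates, orthonormalized by
   SVD of the loadings) for the onset transient.
2. **Decide** — on detection, a feature decoder runs in a short window where
   condition information peaks (~200 ms after the transient): per-bin LDA for
   finger identity until its posterior clears a threshold, or a linear
   latent-to-force regression for about one second.
3. **Latch** — the decision is held exactly constant (class emitted, force
   clamped) until the offset transient is detected, then the output returns
   to null. Between actions the decoder emits nothing, whatever the arm does.

The identification pipeline finds the transient components from
trial-averaged latent responses via an onset-unique/offset-unique variance
decomposition (a ratio-of-variance generalized eigenproblem) followed by a
varimax rotation that isolates temporally sparse components. Companion
analyses quantify the condition-dependent variance V(t) across condition-mean
latent states, its decay between 100 ms windows tied to the transient peaks
(t1 = onset peak + 200 ms, t2 = offset peak - 200 ms), and the lag that
maximizes the correlation between the onset transient and V(t). Standard
continuous baselines — a Wiener cascade (tapped linear stage + cubic static
nonlinearity) for force, per-bin LDA with a null class for fingers — and a
leave-one-trial-out harness with epoch-R^2, normalized hold range, per-bin
accuracy and click-duration metrics complete the comparison.

Everything runs on synthetic sessions: `transientgate.synth` generates
seeded Poisson spike counts (~192 channels at 50 Hz) with planted transients,
decaying condition coding, cross-effector translation interference, and the
ground truth needed for recovery tests. No data downloads are required.

## Worked example

```python
import numpy as np
from transientgate import (GenConfig, generate_session, smooth_counts,
                           FactorLatentSpace, TransientIdentifier,
                           condition_variance_trace, summarize_t1_t2, loo_cv)

cfg = GenConfig(task_type="finger_click", n_conditions=5, n_trials=40, seed=1)
bundle, truth = generate_session(cfg)

rates = smooth_counts(bundle.counts)                      # sqrt + 400 ms causal exp
latent = FactorLatentSpace(n_factors=20).fit(rates.rates.T)
z = latent.transform(rates.rates.T)

ident = TransientIdentifier(smoothing_tau=0.4).fit(z, bundle.events,
                                                   bundle.bin_width)
model = ident.model_

labels = bundle.events["condition"].to_numpy()
on, off = ident.aligned_on_, ident.aligned_off_
v_on = condition_variance_trace(on.per_trial, labels[on.trial_index],
                                on.times, "onset")
v_off = condition_variance_trace(off.per_trial, labels[off.trial_index],
                                 off.times, "offset")
summary = summarize_t1_t2(v_on, v_off, model)

report = loo_cv(bundle)   # leave-one-out: gated vs per-bin classifier
g, c = report.aggregates["gated"], report.aggregates["continuous"]

print(f"onset transient : peak {model.onset.peak_time*1e3:.0f} ms after onset, "
      f"FWHM {model.onset.fwhm*1e3:.0f} ms")
print(f"offset transient: peak {model.offset.peak_time*1e3:.0f} ms after offset, "
      f"FWHM {model.offset.fwhm*1e3:.0f} ms")
print(f"recovered onset direction vs planted: |cos| = "
      f"{abs((latent.basis_ @ model.w_on) @ truth.u_on):.3f}")
print(f"information decay V(t2)/V(t1) = {summary.ratio:.2f}  (planted rho = {cfg.rho})")
print(f"gated decoder     : trial accuracy {g['trial_accuracy']:.2f}, "
      f"median click-duration ratio {g['median_duration_ratio']:.2f}")
print(f"per-bin classifier: median click-duration ratio {c['median_duration_ratio']:.2f}")
```

Output:

```
onset transient : peak 220 ms after onset, FWHM 527 ms
offset transient: peak 220 ms after offset, FWHM 498 ms
recovered onset direction vs planted: |cos| = 0.906
information decay V(t2)/V(t1) = 0.33  (planted rho = 0.35)
gated decoder     : trial accuracy 1.00, median click-duration ratio 0.99
per-bin classifier: median click-duration ratio 0.79
```

Reading it: the pipeline recovers the planted onset/offset transient
directions from spikes alone (cosine 0.91 to the ground truth) and their
500 ms width (FWHM is measured after exactly inverting the acquisition
smoothing, which would otherwise widen the template to ~740 ms). Condition
information decays to 33% of its early value by action end (planted 35%).
Under leave-one-out evaluation the gated decoder classifies every held-out
trial correctly and holds each click for ~99% of its cued duration, while the
continuous per-bin classifier fragments clicks (79%) — the instability the
latch removes by construction.

## Command line

```bash
transientgate simulate --task grasp_carry --n-trials 40 --conditions 2 \
    --rho 0.35 --seed 1 -o session.h5
transientgate preprocess session.h5 --tau 0.4
transientgate fit-latent session.h5 --factors 20
transientgate find-transients session.h5
transientgate condvar session.h5
transientgate train-gated session.h5 -o gated.h5
transientgate decode session.h5 --model gated.h5 -o trace.h5
transientgate evaluate session.h5
transientgate run --task finger_click --seed 1 --out-dir run/
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch on a fresh synthetic session —
simulation, rate estimation, latent fit, transient identification,
condition-variance decay, gated and continuous decoder training, and
leave-one-out evaluation — prints a summary, and writes the results file.
The heavier property-based checks (20-seed recovery medians, the lag
estimator, hold-stability and no-intent-silence comparisons) live in
`tests/test_acceptance.py`.

See `docs/methods.md` for the model, the simulator's stated assumptions, and
numerical choices.
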