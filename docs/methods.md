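# Methods

## The problem

Continuous ("asynchronous") intracortical BCI decoders map motor-cortex
population activity to an effector command at every time step. Their weakness
is context: the relation between neural activity and, say, grasp force is not
stationary, so a force decoder trained on grasp-only data produces phantom
forces during arm reaching, and its output drifts during long holds as the
action-specific neural code decays. This package implements the alternative:
split decoding into *detection* and *decision*. Population activity contains
brief, condition-invariant transients at the onset and offset of any
hand-related action. The decoder watches for the onset transient, decodes the
action's specifics (finger identity or grasp force) in a short window where
that information is strongest, latches the decision, and releases it only on
the offset transient. Between actions it emits nothing, whatever the arm is
doing.

## Analysis pipeline

1. **Rate estimation** (`preprocess`). Threshold-crossing counts binned at
   50 Hz are square-root transformed and convolved with a causal exponential
   kernel, decay constant tau = 400 ms, truncated at 5 tau and renormalized to
   unit sum. "400 ms" is read as the decay constant, not the kernel extent
   (configurable). The kernel's unit sum gives DC gain 1; causality is exact.

2. **Latent space** (`latent`). Maximum-likelihood factor analysis with 20
   factors, fit by EM on the channel covariance (mathematically the standard
   FA EM; the covariance form costs O(channels^2) per iteration, which is what
   makes leave-one-out refits affordable). Initialization is deterministic
   (PCA); the log-likelihood is monotone and recorded per iteration. The SVD
   of the loading matrix gives an orthonormal basis; latent trajectories are
   by default the orthonormal projection of centered rates, so variance
   accounting in latent coordinates is exact (posterior-mean scoring is
   available via `scoring="posterior"`).

3. **Transient identification** (`transients`). Latent responses are aligned
   to action onset (-1.5 to +2.0 s) and offset (-2.0 to +1.5 s) and averaged
   over trials, conditions pooled (the transients are condition-invariant by
   hypothesis). The generalized eigenproblem of C_on against C_on + C_off +
   eps*I (temporal covariances of the two mean-centered averages, ridge
   eps = 1e-6 * trace/20) ranks directions by their onset-unique variance
   fraction; directions with fraction >= 0.9 are onset-unique, <= 0.1
   offset-unique, the rest shared. Two safeguards matter in practice:
   - *Variance screen.* Directions carrying less than 5% of the dominant
     eigenvalue of C_on + C_off are excluded from the eigenproblem and left in
     the shared remainder. With ~16 trial-averaged-noise dimensions against a
     few dozen effective time samples, the unscreened eigenproblem overfits
     (random variance-ratio maxima near 26:1) and blends the transient with
     noise. The screen presumes the transients are large components of the
     aligned averages, which is their defining property here.
   - *Loewdin orthogonalization.* The retained eigenvectors are jointly
     symmetrically orthonormalized, so the onset and offset components are
     exactly orthogonal.
   Within each unique subspace a varimax rotation (pairwise Jacobi sweeps with
   closed-form angles; Kaiser normalization off, since columns are latent time
   courses with meaningful scale) isolates temporally sparse components, and
   the single component with the largest modulation against a pre/post-event
   baseline is the transient. Ties break to the earlier peak; the sign makes
   the peak positive.

4. **Transient width.** The acquisition smoothing widens a 500 ms-FWHM bump
   to ~744 ms, so the template width is measured in the rate domain: the
   geometric FIR kernel has an exact two-tap inverse, which is applied to the
   template before the half-maximum interpolation. Inverse filtering restores
   pre-smoothing noise whose dips bias half-max crossings inward by
   ~60-130 ms, so the deconvolved template is re-smoothed with a 2-bin
   Gaussian and that kernel's width removed from the reported FWHM in
   quadrature (residual bias ~ +10 ms). Peak times and amplitudes are always
   reported on the observed (smoothed-domain) template, since the downstream
   t1/t2 windows live there too.

5. **Condition-dependent variance** (`condvar`). V(t) is the mean squared
   deviation of per-condition mean latent states from their grand mean
   (population denominator C; `denominator="sample"` gives C-1). The decay
   summary compares 100 ms windows centered 200 ms after the onset-transient
   peak (t1) and 200 ms before the offset-transient peak (t2). The
   transient-to-variance lag is the argmax over integer-bin lags (default
   +-1 s) of the Pearson correlation between the onset template and V(t),
   computed over the overlapping support only (zero padding would bias the
   lag toward zero); ties break to the smallest absolute lag.

6. **Gated decoder** (`gate`). Binary LDA detectors on the 20-D latents are
   trained with positives in +-100 ms around each trial's transient peak and
   negatives elsewhere (300 ms guard bands excluded); a `transient2d` option
   restricts features to the two transient projections. The causal state
   machine: in *idle*, output is null/zero until the onset posterior clears
   0.9 on 2 consecutive bins; in *deciding*, a per-bin multiclass LDA runs
   until its posterior clears 0.9 (or a 1 s timeout emits the argmax), or a
   linear latent-to-force regression (trained on the first second after
   onset, where condition information peaks) streams its prediction for 1 s
   and is then clamped at its current value; in *latched*, the output is held
   exactly constant until the offset posterior clears its threshold, which
   zeroes the output and returns to idle. After any transition the opposite
   detector is disabled for 0.5 s. Detector posteriors and feature outputs
   are static per-bin maps, so decisions at bin t depend only on bins <= t;
   truncating the stream never changes past decisions.

7. **Baselines and evaluation** (`baselines`, `evaluation`). The Wiener
   cascade regresses 10 tapped bins (200 ms) of latent history onto the force
   target (0 outside grasp, cued force inside) and passes the linear
   prediction through a least-squares cubic; rank deficiency falls back to a
   small ridge with a flag. The continuous classifier is per-bin LDA with an
   explicit null class. Leave-one-out evaluation refits *everything* — latent
   model, transients, decoders — on the remaining trials and decodes the
   held-out trial's segment as a fresh stream; trials where any compared
   decoder is all-null (for force: non-positive middle-epoch mean) are
   excluded and reported. Metrics: R^2 across pooled pre/middle/post epoch
   means (25th-75th percentile of each trial phase) against targets
   (0, F, 0); normalized hold range (max-min)/mean over the middle epoch;
   per-bin accuracy against the cued label stream; and per-click duration of
   the maximal-overlap contiguous non-null run divided by the cued duration.

## The simulator as a stated world

`synth.generate_session` plants, in a 20-D latent space mapped to channels by
a random orthonormal loading matrix (40 Hz population gain per latent unit,
10 Hz baseline, rates rectified at zero, Poisson spiking at 20 ms bins):

- **Transients**: Gaussian bumps, FWHM 500 ms, on two fixed orthogonal
  directions at each trial's onset and offset, identical across conditions,
  amplitude 1.5x the condition-coding scale — the condition-invariant signal
  is the dominant movement-locked component of motor-cortex population
  activity, and at parity the subspace decomposition starts blending it with
  acquisition nonlinearities.
- **Condition coding**: one orthogonal direction per condition (finger or
  force level). The smoothed course is G(t) * sqrt(c0 + c1 * B(t)), with B a
  copy of the smoothed transient bump shifted by `cond_peak_lag` (200 ms) and
  G an engagement gate rising after the cue (anticipatory preparatory tuning,
  ~1.2 s before onset) and falling 200 ms after offset. Squaring — which is
  what the condition-variance analysis does — makes V(t) affine in the
  shifted transient template, so the planted lag is exactly what the paper's
  correlation estimator measures, and the early-bump-plus-sustained-plateau
  phenomenology is preserved. (c0, c1) are solved from the two 100 ms window
  means so that V(t2)/V(t1) equals `rho` (default 0.35) exactly on the
  noiseless latent, *as measured after the canonical smoothing*: the causal
  exponential attenuates the early bump (peak gain 0.62) far more than the
  plateau, so solving against unsmoothed shapes would miss the target by
  ~0.2. The course is planted pre-smoothing via the exact two-tap inverse of
  the acquisition kernel.
- **Cross-effector interference** (carry/drag tasks): activity on a fixed
  direction whose cosine with the condition subspace is `interference_overlap`
  (default 0.3, into the first condition's direction), with a random
  per-trial amplitude (uniform 0.5-1.5 times `interference_gain`) plus a slow
  AR(1) wiggle, active both during a pre-action travel phase (the effector
  moves to the object/target between trial start and cue) and during the
  carry/drag itself. `generate_reach_only_stream` reuses a session's planted
  geometry to produce translation activity with no hand action at all.
- **Noise**: AR(1) (sd 0.2, time constant 200 ms) in all 20 latent
  dimensions, plus the Poisson observation noise.
- **Trial timing**: 2 s pre-onset (cue 1.5 s before onset), 3 s hold, 2 s
  post-offset, 1 s inter-trial gap; onset and offset jittered +-100 ms. The
  3 s default hold is longer than the 1-2 s the offline click tasks used:
  with the standard alignment windows, a 2 s hold puts the full smoothed
  onset transient inside the offset-aligned window and the 0.1
  uniqueness threshold cannot be met by construction. The lag experiments use
  1.5 s holds with windows adapted to that timing (-1.5..+1.0 onset,
  -0.2..+1.5 offset), the regime in which the variance trace falls back
  inside the window and the correlation lag is identifiable.

What the simulator does **not** emulate: electrode nonstationarity and drift,
correlated (non-Poisson) spiking noise, heterogeneous per-channel baselines,
rotation of the condition code over time (its decay is amplitude-only, along
fixed directions), kinematic richness of the translation signal, and any
closed-loop feedback dynamics. A green recovery test therefore establishes
that the pipeline recovers the planted structure under Poisson statistics and
the stated acquisition chain — not that it would survive real-data
pathologies such as code rotation or drift.

## Numerical choices and edge cases

- Event times snap to the nearest 20 ms bin; trials whose alignment window
  leaves the recording are dropped and counted.
- Degenerate epoch phases collapse to the single bin at the phase midpoint;
  a non-positive middle-epoch mean flags the trial instead of producing a
  sign-flipped normalized range.
- Rank-deficient covariances get a ridge (generalized eigenproblem:
  1e-6 * trace/20; Wiener stage 1: lstsq with ridge fallback and a flag).
- EM non-convergence within `max_iter` returns the best iterate with
  `converged_ = False` and a warning, never silently.
- Constant channels are dropped from the factor fit with a warning; their
  loadings are zero and their noise variances floored.
- All randomness in the generator flows from a single `numpy` Generator
  seeded by `GenConfig.seed`; generation is a pure function of the config.
- Detection timing: the posterior threshold crossing plus the 2-bin debounce
  places detections within +-150 ms of the planted onset at high SNR (within
  +-100 ms for ~90% of trials); at default SNR a few percent of trials are
  missed entirely, which the evaluation's exclusion rule reports.
- The lag estimator retains a ~1-2 bin upward bias even in the identifiable
  regime: the engagement gate's causal rise, smeared by the 400 ms filter,
  overlaps the analysis window. Its median error over 20 seeds is exactly at
  the two-bin tolerance.

## Known limitations

- The uniqueness threshold (0.1) and the variance screen (5% of the dominant
  eigenvalue) assume a single large transient per event; multiple weak
  transients below the screen would be missed.
- The force task's supervision is piecewise-constant cued force; graded
  within-trial force profiles are out of scope.
- Cross-session analyses (transient similarity across days) are not
  implemented.
- The continuous-classifier comparison depends on class count: with two
  well-separated classes, per-bin LDA rarely fragments clicks and the gated
  advantage in duration ratio shrinks to noise level; with five classes the
  fragmentation (and the gated advantage) is pronounced.
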