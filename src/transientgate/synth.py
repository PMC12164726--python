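"""Seeded synthetic session generator.

Emulates the latent structure of motor-cortex population spiking around
hand-related actions: condition-invariant Gaussian onset/offset transients
(~500 ms FWHM) in orthogonal latent directions, condition-coding activity that
peaks ~200 ms after the onset transient and decays to a configurable fraction
(``rho``) of its early value by action end, cross-effector (arm translation)
interference during carry/drag phases, AR(1) latent noise, and Poisson spiking
through a random orthonormal loading matrix.

The condition-coding course combines an early bump with a sustained plateau
through a square-root link: the smoothed course is G(t) * sqrt(c0 + c1 * B(t))
with B a shifted copy of the smoothed transient bump and G an engagement gate
(anticipatory rise after the cue, fall shortly after offset). The squared
course — the condition variance the analysis measures — is then affine in the
shifted transient template, making the planted transient-to-variance lag
identifiable, and (c0, c1) are solved so the decay ratio V(t2)/V(t1), measured
the way the pipeline measures it (after the canonical 400 ms causal
exponential smoothing, in 100 ms windows placed 200 ms after/before the
smoothed transient peaks), equals ``rho`` exactly on the noiseless latent.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import ndtr

from scipy.signal import lfilter

from .preprocess import exponential_kernel, inverse_filter

TASK_TYPES = ("grasp_force", "grasp_carry", "finger_click", "click_drag")
CARRY_TASKS = ("grasp_carry", "click_drag")
FORCE_TASKS = ("grasp_force", "grasp_carry")

GAUSS_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM = factor * sigma


@dataclass(frozen=True)
class GenConfig:
    """Synthetic-session parameters. Defaults state the emulated regime:
    ~192 channels binned at 50 Hz, 40 trials, 500 ms FWHM transients,
    condition coding peaking 200 ms after the onset transient and decaying
    to 35% by action end."""

    n_channels: int = 192
    bin_width: float = 0.02
    n_latent_true: int = 20
    task_type: str = "finger_click"
    n_conditions: int = 5
    n_trials: int = 40
    fwhm_on: float = 0.5
    fwhm_off: float = 0.5
    transient_peak_lag: float = 0.0   # transient peak relative to event time, s
    cond_peak_lag: float = 0.2        # condition-coding peak after onset-transient peak, s
    rho: float = 0.35                 # target V(t2)/V(t1)
    interference_gain: float = 1.0
    interference_overlap: float = 0.3
    baseline_rate: float = 10.0       # Hz
    snr_scale: float = 1.0
    seed: int = 0
    # trial timing (template; onset/offset jittered +-jitter uniformly)
    pre_onset: float = 2.0
    hold_duration: float = 3.0
    post_offset: float = 2.0
    intertrial: float = 1.0
    cue_lead: float = 1.5             # cue precedes nominal onset by this much
    jitter: float = 0.1
    # amplitudes / noise (latent z-units)
    amp_on: float = 1.5
    amp_off: float = 1.5
    cond_amp: float = 1.0
    noise_std: float = 0.2
    noise_tau: float = 0.2
    channel_gain: float = 40.0        # Hz of population rate per latent z-unit
    ref_smoothing_tau: float = 0.4    # canonical acquisition smoothing, s

    def __post_init__(self) -> None:
        if self.task_type not in TASK_TYPES:
            raise ValueError(f"task_type must be one of {TASK_TYPES}, got {self.task_type!r}")
        if not (0.0 < self.rho <= 1.0):
            raise ValueError(f"rho must be in (0, 1], got {self.rho}")
        if self.fwhm_on <= 0 or self.fwhm_off <= 0:
            raise ValueError("fwhm_on and fwhm_off must be positive")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.n_conditions < 2:
            raise ValueError("n_conditions must be >= 2")
        if self.interference_gain < 0:
            raise ValueError("interference_gain must be >= 0")
        if not (0.0 <= self.interference_overlap <= 1.0):
            raise ValueError("interference_overlap must be in [0, 1]")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class SessionBundle:
    """One recording session: binned counts, trial events, provenance."""

    counts: np.ndarray          # (n_channels, n_bins), nonnegative ints
    bin_width: float
    events: pd.DataFrame        # trial_id, task_type, condition, cued_force, times
    meta: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def duration(self) -> float:
        return self.n_bins * self.bin_width


@dataclass
class GroundTruth:
    """Planted structure of a synthetic session, for recovery tests."""

    u_on: np.ndarray            # channel-space unit vector of onset transient
    u_off: np.ndarray
    u_cond: np.ndarray          # (n_conditions, n_channels)
    interference_dir: np.ndarray
    event_times: pd.DataFrame
    planted_lag: float
    # latent-space quantities (generator internals, useful for diagnostics)
    d_on: np.ndarray = None
    d_off: np.ndarray = None
    d_cond: np.ndarray = None   # (n_conditions, n_latent)
    d_interference: np.ndarray = None
    loadings: np.ndarray = None       # (n_channels, n_latent), Q * channel_gain
    basis: np.ndarray = None          # orthonormal Q
    baseline_rate: float = 10.0
    z_signal: np.ndarray = None       # noiseless latent trajectory (n_bins, n_latent)
    cond_pedestal: float = 0.0        # c0: sustained (squared) level relative to V(t1)
    cond_bump_gain: float = 0.0       # c1: bump coefficient of the variance course
    smoothed_peak_delay: float = 0.0  # delay of smoothed transient peak vs planted center
    config: GenConfig = None


def _gauss(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _plateau(t: np.ndarray, onset: float, offset: float,
             rise_sigma: float = 0.12, fall_sigma: float = 0.15,
             rise_shift: float = -1.2, fall_shift: float = 0.2) -> np.ndarray:
    """Engagement gate of the sustained condition coding: anticipatory
    (preparatory-tuning) rise after the cue, well before action onset, and
    fall shortly after offset. Rising early keeps the causal-smoothing-smeared
    edge away from the condition bump, so the composite condition signal peaks
    at the stated lag instead of being dragged later by the edge."""
    return (ndtr((t - (onset + rise_shift)) / rise_sigma)
            * ndtr((offset + fall_shift - t) / fall_sigma))


def _calibrate_condition_course(cfg: GenConfig) -> tuple[float, float, float, float]:
    """Solve the condition-course coefficients so the observable decay is rho.

    The condition-coding time course (per condition direction) is planted so
    that after the canonical acquisition smoothing it equals

        s~(t) = G~(t) * sqrt(c0 + c1 * B~(t - onset))

    where B~ is the smoothed, peak-normalized condition bump (a copy of the
    transient bump shifted by cond_peak_lag) and G~ the smoothed engagement
    gate (anticipatory preparatory rise after the cue, fall shortly after
    offset). The condition variance V(t) ~ s~(t)^2 is then affine in the
    shifted bump wherever the gate is saturated — the construction under which
    the template-vs-variance correlation lag is identifiable — and rises to
    its peak exactly cond_peak_lag after the smoothed transient peak. c0 and
    c1 solve the 2x2 system pinning the 100 ms window means of V at t1 (=1)
    and t2 (= rho), the same windows the analysis uses.

    Returns (c0, c1, bump_peak_norm, smoothed_peak_delay).
    """
    dt = cfg.bin_width
    sigma_on = cfg.fwhm_on / GAUSS_FWHM_FACTOR
    h = exponential_kernel(cfg.ref_smoothing_tau, dt)
    # template grid: event (onset) at t=0, long enough to cover the hold + t2
    t = np.arange(-cfg.pre_onset - 1.5, cfg.hold_duration + 2.0, dt)

    def smooth(x: np.ndarray) -> np.ndarray:
        return np.convolve(x, h)[: len(x)]

    bump_on = smooth(_gauss(t, cfg.transient_peak_lag, sigma_on))
    delay = t[np.argmax(bump_on)] - cfg.transient_peak_lag
    # measured transient peaks (relative to their events) land at
    # transient_peak_lag + delay; t1/t2 are the 100 ms windows around
    # peak +- 200 ms, exactly as the condvar summary places them.
    t1 = cfg.transient_peak_lag + delay + 0.2
    t2 = cfg.hold_duration + cfg.transient_peak_lag + delay - 0.2
    if t2 <= t1:
        raise ValueError(f"hold_duration {cfg.hold_duration} too short: "
                         "t2 precedes t1")

    # both bumps share the smoothing delay, so planting the condition bump
    # cond_peak_lag after the transient center keeps the observed peak-to-peak
    # separation at cond_peak_lag
    bump_cond = smooth(_gauss(t, cfg.transient_peak_lag + cfg.cond_peak_lag, sigma_on))
    bmax = float(bump_cond.max())
    B = bump_cond / bmax
    G = smooth(_plateau(t, 0.0, cfg.hold_duration))

    def winmean(x: np.ndarray, center: float) -> float:
        m = (center - 0.05 <= t) & (t <= center + 0.05)
        return float(x[m].mean())

    a = np.array([[winmean(G ** 2, t1), winmean(G ** 2 * B, t1)],
                  [winmean(G ** 2, t2), winmean(G ** 2 * B, t2)]])
    c0, c1 = np.linalg.solve(a, [1.0, cfg.rho])
    if c0 < 0 or c1 <= 0:
        raise ValueError(f"rho={cfg.rho} not reachable with this trial timing "
                         f"(solved c0={c0:.3f}, c1={c1:.3f})")
    return float(c0), float(c1), bmax, float(delay)


def _make_events(cfg: GenConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Trial table with jittered onset/offset times on an absolute clock."""
    rows = []
    stride = cfg.pre_onset + cfg.hold_duration + cfg.post_offset + cfg.intertrial
    conditions = np.tile(np.arange(cfg.n_conditions),
                         int(np.ceil(cfg.n_trials / cfg.n_conditions)))[: cfg.n_trials]
    rng.shuffle(conditions)
    for i in range(cfg.n_trials):
        start = 1.0 + i * stride
        onset = start + cfg.pre_onset + rng.uniform(-cfg.jitter, cfg.jitter)
        offset = start + cfg.pre_onset + cfg.hold_duration + rng.uniform(-cfg.jitter, cfg.jitter)
        end = start + cfg.pre_onset + cfg.hold_duration + cfg.post_offset
        c = int(conditions[i])
        rows.append(dict(trial_id=i, task_type=cfg.task_type, condition=c,
                         cued_force=float(c + 1) if cfg.task_type in FORCE_TASKS else 0.0,
                         cue_time=onset - cfg.cue_lead, onset_time=onset,
                         offset_time=offset, trial_start=start, trial_end=end))
    return pd.DataFrame(rows)


def _orthonormal_directions(n_latent: int, n_dirs: int, rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(n_latent, n_dirs)))
    # fix signs for reproducibility across LAPACK builds
    q *= np.sign(q[np.abs(q).argmax(axis=0), np.arange(n_dirs)])
    return q


def _ar1_noise(n_bins: int, n_dims: int, std: float, tau: float, dt: float,
               rng: np.random.Generator) -> np.ndarray:
    from scipy.signal import lfiltic

    phi = np.exp(-dt / tau)
    eps = rng.normal(scale=std * np.sqrt(1 - phi ** 2), size=(n_bins, n_dims))
    x0 = rng.normal(scale=std, size=n_dims)  # stationary start
    zi = np.stack([lfiltic([1.0], [1.0, -phi], [x]) for x in x0])
    out, _ = lfilter([1.0], [1.0, -phi], eps, axis=0, zi=zi.T)
    return out


def generate_session(cfg: GenConfig) -> tuple[SessionBundle, GroundTruth]:
    """Generate one synthetic session. Pure function of the config (incl. seed)."""
    rng = np.random.default_rng(cfg.seed)
    dt = cfg.bin_width
    k = cfg.n_latent_true
    n_dirs = cfg.n_conditions + 3
    if n_dirs > k:
        raise ValueError("n_latent_true too small for the requested structure")

    warnings: list[str] = []
    if cfg.task_type not in CARRY_TASKS and cfg.interference_gain > 0:
        warnings.append("interference_gain ignored: task has no carry/drag phase")

    dirs = _orthonormal_directions(k, n_dirs, rng)
    d_on, d_off, d_perp = dirs[:, 0], dirs[:, 1], dirs[:, 2]
    d_cond = dirs[:, 3:].T                                   # (C, k)
    o = cfg.interference_overlap
    d_int = np.sqrt(max(0.0, 1 - o ** 2)) * d_perp + o * d_cond[0]

    events = _make_events(cfg, rng)
    stride = cfg.pre_onset + cfg.hold_duration + cfg.post_offset + cfg.intertrial
    n_bins = int(round((1.0 + cfg.n_trials * stride + 1.0) / dt))
    t = np.arange(n_bins) * dt

    sigma_on = cfg.fwhm_on / GAUSS_FWHM_FACTOR
    sigma_off = cfg.fwhm_off / GAUSS_FWHM_FACTOR
    c0, c1, bmax, delay = _calibrate_condition_course(cfg)
    h = exponential_kernel(cfg.ref_smoothing_tau, dt)

    def smooth(x: np.ndarray) -> np.ndarray:
        return lfilter(h, [1.0], x)

    z = np.zeros((n_bins, k))
    for row in events.itertuples():
        on, off = row.onset_time, row.offset_time
        z += np.outer(cfg.amp_on * _gauss(t, on + cfg.transient_peak_lag, sigma_on), d_on)
        z += np.outer(cfg.amp_off * _gauss(t, off + cfg.transient_peak_lag, sigma_off), d_off)
        # condition course: sqrt-link target in the smoothed domain, planted
        # via the exact inverse of the acquisition kernel
        B = smooth(_gauss(t, on + cfg.transient_peak_lag + cfg.cond_peak_lag,
                          sigma_on)) / bmax
        G = smooth(_plateau(t, on, off))
        s_target = G * np.sqrt(np.maximum(c0 + c1 * B, 0.0))
        s = inverse_filter(s_target, cfg.ref_smoothing_tau, dt)
        z += np.outer(cfg.cond_amp * s, d_cond[row.condition])
        if cfg.task_type in CARRY_TASKS and cfg.interference_gain > 0:
            # translation engagement: the effector travels to the object/target
            # before the action (between trial start and cue) and again during
            # the carry/drag phase, with independent random speed profiles
            for a, b in ((row.trial_start + 0.2, row.cue_time), (on, off)):
                gamma = rng.uniform(0.5, 1.5)
                wiggle = _ar1_noise(n_bins, 1, 0.3, 0.5, dt, rng)[:, 0]
                profile = _plateau(t, a, b, rise_sigma=0.2, fall_sigma=0.2,
                                   rise_shift=0.0, fall_shift=0.0)
                z += np.outer(cfg.interference_gain * profile * (gamma + wiggle),
                              d_int)

    z_signal = cfg.snr_scale * z
    z_total = z_signal + _ar1_noise(n_bins, k, cfg.noise_std, cfg.noise_tau, dt, rng)

    q = _orthonormal_directions(cfg.n_channels, k, rng)      # (channels, k)
    rates = np.maximum(0.0, cfg.baseline_rate + cfg.channel_gain * (z_total @ q.T))
    counts = rng.poisson(rates * dt).astype(np.int32).T      # (channels, bins)

    meta = dict(seed=cfg.seed, config=asdict(cfg), config_hash=cfg.config_hash(),
                schema_version=1, warnings=warnings, kind="synthetic")
    bundle = SessionBundle(counts=counts, bin_width=dt, events=events, meta=meta)
    truth = GroundTruth(
        u_on=q @ d_on, u_off=q @ d_off, u_cond=(q @ d_cond.T).T,
        interference_dir=q @ d_int, event_times=events.copy(),
        planted_lag=cfg.cond_peak_lag,
        d_on=d_on, d_off=d_off, d_cond=d_cond, d_interference=d_int,
        loadings=cfg.channel_gain * q, basis=q, baseline_rate=cfg.baseline_rate,
        z_signal=z_signal, cond_pedestal=c0, cond_bump_gain=c1,
        smoothed_peak_delay=delay, config=cfg)
    return bundle, truth


def generate_reach_only_stream(cfg: GenConfig, truth: GroundTruth,
                               n_events: int = 10, seed: int = 1234
                               ) -> SessionBundle:
    """A stream with arm-translation interference but no hand action.

    Reuses the planted loading matrix and interference direction of an
    existing session so decoders trained on that session see a matched
    channel geometry. No onset/offset transients and no condition coding are
    planted; the events table is empty.
    """
    rng = np.random.default_rng(seed)
    dt = cfg.bin_width
    k = cfg.n_latent_true
    stride = 5.0
    n_bins = int(round((2.0 + n_events * stride) / dt))
    t = np.arange(n_bins) * dt

    z = np.zeros((n_bins, k))
    gain = cfg.interference_gain if cfg.interference_gain > 0 else 1.0
    for i in range(n_events):
        start = 1.0 + i * stride + rng.uniform(-0.2, 0.2)
        dur = rng.uniform(2.0, 3.0)
        gamma = rng.uniform(0.5, 1.5)
        wiggle = _ar1_noise(n_bins, 1, 0.3, 0.5, dt, rng)[:, 0]
        profile = _plateau(t, start, start + dur, rise_sigma=0.2, fall_sigma=0.2,
                           rise_shift=0.0, fall_shift=0.0)
        z += np.outer(gain * profile * (gamma + wiggle), truth.d_interference)

    z_total = cfg.snr_scale * z + _ar1_noise(n_bins, k, cfg.noise_std, cfg.noise_tau,
                                             dt, rng)
    rates = np.maximum(0.0, truth.baseline_rate
                       + z_total @ truth.loadings.T)
    counts = rng.poisson(rates * dt).astype(np.int32).T
    events = pd.DataFrame(columns=["trial_id", "task_type", "condition", "cued_force",
                                   "cue_time", "onset_time", "offset_time",
                                   "trial_start", "trial_end"])
    meta = dict(seed=seed, config=asdict(cfg), config_hash=cfg.config_hash(),
                schema_version=1, warnings=[], kind="synthetic_reach_only")
    return SessionBundle(counts=counts, bin_width=dt, events=events, meta=meta)
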