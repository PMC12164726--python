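"""Transient identification: alignment, subspace split, varimax, selection."""

import numpy as np
import pytest

from transientgate.transients import (AlignmentWindows, TransientIdentifier,
                                      align_and_average, align_events,
                                      measure_fwhm, select_transient,
                                      unique_variance_subspaces, varimax,
                                      varimax_criterion,
                                      varimax_sparse_components)


def _bump(times, center, sigma=0.1):
    return np.exp(-0.5 * ((times - center) / sigma) ** 2)


# -- alignment ---------------------------------------------------------------

def test_average_of_identical_trials_is_the_segment():
    dt = 0.02
    n = 500
    z = np.zeros((n, 3))
    seg = np.column_stack([_bump(np.arange(50) * dt, 0.5, 0.1)] * 3)
    z[100:150] = seg
    z[300:350] = seg
    al = align_events(z, np.array([100 * dt, 300 * dt]), (0.0, 1.0), dt)
    assert al.per_trial.shape[0] == 2
    assert np.allclose(al.avg, al.per_trial[0])
    assert np.allclose(al.avg[:, 0], seg[:, 0])


def test_edge_trials_dropped_and_counted():
    z = np.zeros((100, 2))
    al = align_events(z, np.array([0.1, 1.0, 1.9]), (-0.5, 0.5), 0.02)
    assert al.n_dropped == 2
    assert list(al.trial_index) == [1]
    with pytest.raises(ValueError, match="no trials"):
        align_events(z, np.array([0.1]), (-1.0, 1.0), 0.02)


def test_window_validation():
    with pytest.raises(ValueError):
        AlignmentWindows(onset_window=(1.0, -1.0))


# -- subspace decomposition ---------------------------------------------------

def test_disjoint_activity_separates_cleanly():
    t = np.arange(100) * 0.02
    avg_on = np.zeros((100, 6))
    avg_off = np.zeros((100, 6))
    avg_on[:, 0] = _bump(t, 1.0)
    avg_off[:, 1] = _bump(t, 1.0)
    s_on, s_off, s_shared = unique_variance_subspaces(avg_on, avg_off)
    e0, e1 = np.eye(6)[:, 0], np.eye(6)[:, 1]
    assert np.abs(s_on.T @ e0).max() >= 0.999
    assert np.abs(s_off.T @ e1).max() >= 0.999
    assert s_on.shape[1] + s_off.shape[1] + s_shared.shape[1] == 6


def test_identical_averages_all_shared():
    t = np.arange(100) * 0.02
    avg = np.column_stack([_bump(t, 1.0), _bump(t, 0.5)])
    s_on, s_off, s_shared = unique_variance_subspaces(avg, avg)
    assert s_on.shape[1] == 0
    assert s_off.shape[1] == 0
    assert s_shared.shape[1] == 2


def test_subspaces_mutually_orthonormal():
    rng = np.random.default_rng(0)
    t = np.arange(120) * 0.02
    avg_on = np.column_stack([_bump(t, 0.8), 0.1 * rng.normal(size=120),
                              _bump(t, 1.2), np.zeros(120)])
    avg_off = np.column_stack([0.1 * rng.normal(size=120), _bump(t, 0.6),
                               _bump(t, 1.2), np.zeros(120)])
    s_on, s_off, s_shared = unique_variance_subspaces(avg_on, avg_off)
    basis = np.concatenate([s_on, s_off, s_shared], axis=1)
    assert np.abs(basis.T @ basis - np.eye(basis.shape[1])).max() < 1e-8


# -- varimax ------------------------------------------------------------------

def _brute_force_varimax_2d(A):
    """Exhaustive rotation-angle search: 0.1-degree grid, then a fine pass."""
    def crit(th):
        r = np.radians(th)
        R = np.array([[np.cos(r), -np.sin(r)], [np.sin(r), np.cos(r)]])
        return varimax_criterion(A @ R)

    coarse = np.arange(0.0, 90.0, 0.1)
    best = coarse[np.argmax([crit(th) for th in coarse])]
    fine = np.arange(best - 0.1, best + 0.1, 1e-4)
    vals = [crit(th) for th in fine]
    return max(vals), fine[int(np.argmax(vals))]


def test_varimax_recovers_disjoint_bumps_vs_brute_force():
    """A 45-degree mixture of temporally disjoint bumps is unmixed; the
    criterion value matches an exhaustive rotation-angle search."""
    t = np.arange(200) * 0.02
    pure = np.column_stack([_bump(t, 1.0), _bump(t, 3.0)])
    theta = np.radians(45.0)
    mix = pure @ np.array([[np.cos(theta), -np.sin(theta)],
                           [np.sin(theta), np.cos(theta)]])
    rotated, R, converged = varimax(mix)
    assert converged
    brute_c, _ = _brute_force_varimax_2d(mix)
    assert abs(varimax_criterion(rotated) - brute_c) < 1e-6
    # recovered columns match the pure bumps up to sign/permutation
    corr = np.abs(np.corrcoef(rotated.T, pure.T)[:2, 2:])
    assert corr.max(axis=1).min() >= 0.99


def test_varimax_fixed_point_on_sparse_input():
    t = np.arange(200) * 0.02
    pure = np.column_stack([_bump(t, 1.0), _bump(t, 3.0)])
    rotated, R, _ = varimax(pure)
    assert varimax_criterion(rotated) >= varimax_criterion(pure) - 1e-12
    perm = np.abs(R)
    assert np.allclose(perm @ perm.T, np.eye(2), atol=1e-6)


def test_varimax_preserves_variance_and_orthogonality(rng):
    A = rng.normal(size=(80, 5))
    rotated, R, _ = varimax(A)
    assert np.abs(R.T @ R - np.eye(5)).max() < 1e-8
    assert np.isclose(rotated.var(axis=0).sum(), A.var(axis=0).sum(), rtol=1e-8)


def test_varimax_single_column_identity(rng):
    A = rng.normal(size=(50, 1))
    rotated, R, converged = varimax(A)
    assert converged
    assert np.array_equal(rotated, A)
    assert R == pytest.approx(1.0)


def test_varimax_against_statsmodels(rng):
    from statsmodels.multivariate.factor_rotation import rotate_factors
    A = rng.normal(size=(60, 3)) ** 2
    ours, _, _ = varimax(A)
    theirs, _ = rotate_factors(A, "varimax")
    assert np.isclose(varimax_criterion(ours), varimax_criterion(theirs),
                      rtol=1e-6)


# -- component selection ------------------------------------------------------

def test_select_largest_modulation():
    t = np.arange(-1.0, 2.0, 0.02)
    courses = np.column_stack([0.2 * _bump(t, 0.5), 1.4 * _bump(t, 0.5),
                               0.7 * _bump(t, 0.5)])
    dirs = np.eye(3)
    comp = select_transient(courses, dirs, t, baseline_window=(-1.0, -0.5))
    assert comp.component_index == 1
    assert comp.peak_amplitude == pytest.approx(1.4, abs=1e-6)


def test_negative_bump_sign_flipped():
    t = np.arange(-1.0, 2.0, 0.02)
    courses = (-1.0 * _bump(t, 0.5))[:, None]
    comp = select_transient(courses, np.eye(1), t, baseline_window=(-1.0, -0.5))
    assert comp.peak_amplitude > 0
    assert comp.template.max() == pytest.approx(1.0, abs=1e-6)
    assert np.isclose(np.linalg.norm(comp.w), 1.0)


def test_flat_components_rejected():
    t = np.arange(-1.0, 1.0, 0.02)
    with pytest.raises(ValueError, match="flat"):
        select_transient(np.zeros((t.size, 2)), np.eye(2), t)


def test_fwhm_linear_interpolation():
    t = np.arange(-2.0, 2.0, 0.02)
    sigma = 0.5 / (2 * np.sqrt(2 * np.log(2)))
    course = np.exp(-0.5 * (t / sigma) ** 2)
    assert abs(measure_fwhm(course, t) - 0.5) < 0.02


# -- planted-session recovery -------------------------------------------------

def test_planted_recovery(fitted_session):
    """End to end on one seeded session: directions, orthogonality, timing."""
    fs = fitted_session
    m = fs.identifier.model_
    w_on_ch = fs.latent.basis_ @ m.w_on
    w_off_ch = fs.latent.basis_ @ m.w_off
    assert abs(w_on_ch @ fs.truth.u_on) >= 0.9
    assert abs(w_off_ch @ fs.truth.u_off) >= 0.9
    assert abs(m.w_on @ m.w_off) < 1e-8
    # smoothed peak lands near the planted (smoothed) peak time
    assert abs(m.onset.peak_time - fs.truth.smoothed_peak_delay) <= 0.1
    # average onset response projected on the true direction is a single bump
    proj = fs.identifier.aligned_on_.avg @ (
        fs.latent.basis_.T @ fs.truth.u_on)
    peak_t = fs.identifier.aligned_on_.times[np.argmax(proj)]
    assert abs(peak_t - fs.truth.smoothed_peak_delay) <= 0.06


def test_varimax_sparse_components_shapes(fitted_session):
    fs = fitted_session
    s_on = fs.identifier.subspaces_[0]
    dirs, courses, _ = varimax_sparse_components(
        fs.identifier.aligned_on_.avg, s_on)
    assert dirs.shape == (20, s_on.shape[1])
    assert courses.shape[0] == fs.identifier.aligned_on_.avg.shape[0]
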