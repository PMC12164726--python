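"""Shared fixtures: synthetic sessions at two scales.

``fitted_session`` is a full-size (192-channel) finger-click session run
through smoothing, the 20-factor latent fit and transient identification —
expensive, so session-scoped and shared by every test that needs a realistic
planted world. ``small_bundle`` is a fast 64-channel session for harness and
I/O tests where recovery quality is irrelevant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pytest

from transientgate.latent import FactorLatentSpace
from transientgate.preprocess import smooth_counts
from transientgate.synth import GenConfig, GroundTruth, SessionBundle, generate_session
from transientgate.transients import TransientIdentifier


@dataclass
class FittedSession:
    cfg: GenConfig
    bundle: SessionBundle
    truth: GroundTruth
    rates: np.ndarray          # channels x bins
    latent: FactorLatentSpace
    z: np.ndarray              # bins x factors
    identifier: TransientIdentifier


def fit_session(cfg: GenConfig, **ident_kwargs) -> FittedSession:
    bundle, truth = generate_session(cfg)
    rates = smooth_counts(bundle.counts).rates
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        latent = FactorLatentSpace().fit(rates.T)
    z = latent.transform(rates.T)
    ident = TransientIdentifier(**ident_kwargs).fit(z, bundle.events,
                                                    bundle.bin_width)
    return FittedSession(cfg=cfg, bundle=bundle, truth=truth, rates=rates,
                         latent=latent, z=z, identifier=ident)


@pytest.fixture(scope="session")
def fitted_session() -> FittedSession:
    """Full-size planted finger-click session with the pipeline fit."""
    return fit_session(GenConfig(task_type="finger_click", n_conditions=5,
                                 n_trials=40, seed=3))


@pytest.fixture(scope="session")
def fitted_session_high_snr() -> FittedSession:
    """Same world at 1.5x signal scale: detection operates loss-free here."""
    return fit_session(GenConfig(task_type="finger_click", n_conditions=5,
                                 n_trials=40, seed=3, snr_scale=1.5))


@pytest.fixture(scope="session")
def small_bundle():
    """Fast, small session bundle (no pipeline fit)."""
    cfg = GenConfig(n_channels=64, n_trials=8, n_conditions=2,
                    task_type="grasp_force", seed=5)
    bundle, truth = generate_session(cfg)
    return cfg, bundle, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
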