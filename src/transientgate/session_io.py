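"""Session-bundle persistence (HDF5 + CSV), run configuration, pipeline.

One HDF5 container per session holds the binned counts, the trial-event table
and JSON provenance, with optional groups for smoothed rates, fitted models
and decode traces. CSV exports cover the small tables. ``run_pipeline`` wires
the whole workflow — simulate, smooth, fit latents, find transients, condition
variance, train gated + baseline decoders, LOO evaluation — into one
reproducible call.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .condvar import condition_variance_trace, summarize_t1_t2, transient_variance_lag
from .evaluation import loo_cv
from .gate import GateConfig
from .latent import FactorLatentSpace
from .preprocess import PreprocessConfig, smooth_counts
from .synth import GenConfig, SessionBundle, generate_session
from .transients import AlignmentWindows, TransientIdentifier

SCHEMA_VERSION = 1
EVENT_COLUMNS = ["trial_id", "task_type", "condition", "cued_force", "cue_time",
                 "onset_time", "offset_time", "trial_start", "trial_end"]

log = logging.getLogger("transientgate")


class SchemaError(RuntimeError):
    """A session file does not match the expected layout."""


def write_bundle(bundle: SessionBundle, path: str | Path) -> None:
    """Write counts, events and metadata to one HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=np.asarray(bundle.counts, dtype=np.int32),
                         compression="gzip", compression_opts=1)
        f.create_dataset("bin_width", data=float(bundle.bin_width))
        ev = bundle.events
        grp = f.create_group("events")
        for col in EVENT_COLUMNS:
            data = ev[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            grp.create_dataset(col, data=data)
        meta = dict(bundle.meta)
        meta["schema_version"] = SCHEMA_VERSION
        f.create_dataset("meta", data=json.dumps(meta))


def read_bundle(path: str | Path) -> SessionBundle:
    """Read a session container, checking schema version and layout."""
    with h5py.File(path, "r") as f:
        for name in ("counts", "bin_width", "events", "meta"):
            if name not in f:
                raise SchemaError(f"missing dataset or group '{name}' in {path}")
        meta = json.loads(f["meta"][()])
        version = meta.get("schema_version")
        if version != SCHEMA_VERSION:
            raise SchemaError(f"schema version {version}, expected {SCHEMA_VERSION}")
        grp = f["events"]
        cols = {}
        for col in EVENT_COLUMNS:
            if col not in grp:
                raise SchemaError(f"events table missing column '{col}'")
            data = grp[col][()]
            if data.dtype.kind == "S":
                data = data.astype(str)
            cols[col] = data
        events = pd.DataFrame(cols)
        return SessionBundle(counts=f["counts"][()], bin_width=float(f["bin_width"][()]),
                             events=events, meta=meta)


def export_events_csv(bundle: SessionBundle, path: str | Path) -> None:
    bundle.events[EVENT_COLUMNS].to_csv(path, index=False)


def import_events_csv(path: str | Path) -> pd.DataFrame:
    events = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise SchemaError(f"events CSV missing columns {missing}")
    return events[EVENT_COLUMNS]


def export_counts_csv(bundle: SessionBundle, path: str | Path) -> None:
    """Dense counts CSV for small fixtures (channels x bins)."""
    pd.DataFrame(bundle.counts).to_csv(path, index=False)


# -- model and trace persistence ---------------------------------------------

def write_rates(path: str | Path, rates) -> None:
    """Add/replace the smoothed-rate dataset in a session container."""
    with h5py.File(path, "a") as f:
        if "rates" in f:
            del f["rates"]
        f.create_dataset("rates", data=rates.rates, compression="gzip",
                         compression_opts=1)
        f["rates"].attrs["tau"] = rates.provenance.tau
        f["rates"].attrs["sqrt_transform"] = rates.provenance.sqrt_transform


def write_latent_model(path: str | Path, model: FactorLatentSpace) -> None:
    with h5py.File(path, "a") as f:
        if "latent_model" in f:
            del f["latent_model"]
        g = f.create_group("latent_model")
        g.create_dataset("loadings", data=model.loadings_)
        g.create_dataset("channel_means", data=model.channel_means_)
        g.create_dataset("noise_variances", data=model.noise_variances_)
        g.create_dataset("basis", data=model.basis_)
        g.attrs["n_factors"] = model.n_factors
        g.attrs["converged"] = bool(model.converged_)


def read_latent_model(path: str | Path) -> FactorLatentSpace:
    with h5py.File(path, "r") as f:
        if "latent_model" not in f:
            raise SchemaError(f"no latent_model group in {path}")
        g = f["latent_model"]
        model = FactorLatentSpace(n_factors=int(g.attrs["n_factors"]))
        model.loadings_ = g["loadings"][()]
        model.channel_means_ = g["channel_means"][()]
        model.noise_variances_ = g["noise_variances"][()]
        model.basis_ = g["basis"][()]
        model.converged_ = bool(g.attrs["converged"])
        model.n_features_in_ = model.loadings_.shape[0]
        model.active_channels_ = np.flatnonzero(
            model.noise_variances_ > model.psi_floor)
        model.loglike_ = []
        return model


def _write_lda(g, name: str, lda) -> None:
    sub = g.create_group(name)
    sub.create_dataset("coef", data=lda.coef_)
    sub.create_dataset("intercept", data=np.atleast_1d(lda.intercept_))
    sub.create_dataset("classes", data=np.asarray(lda.classes_, dtype=np.int64))


def _read_lda(g, name: str):
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    sub = g[name]
    lda = LinearDiscriminantAnalysis()
    lda.coef_ = sub["coef"][()]
    lda.intercept_ = sub["intercept"][()]
    lda.n_features_in_ = lda.coef_.shape[1]
    classes = sub["classes"][()]
    # detector classes are stored as ints; 0/1 encode False/True
    lda.classes_ = (classes.astype(bool) if sub.attrs.get("boolean", False)
                    else classes)
    return lda


def write_gated_decoder(path: str | Path, decoder) -> None:
    """Persist a trained GatedDecoder (detectors + feature decoder + config)."""
    from dataclasses import asdict as dc_asdict

    with h5py.File(path, "a") as f:
        if "gated_decoder" in f:
            del f["gated_decoder"]
        g = f.create_group("gated_decoder")
        g.attrs["task"] = decoder.task
        g.attrs["bin_width"] = decoder.bin_width_
        g.attrs["config"] = json.dumps(dc_asdict(decoder.config))
        for name, det in (("onset_detector", decoder.onset_detector_),
                          ("offset_detector", decoder.offset_detector_)):
            _write_lda(g, name, det)
            g[name].attrs["boolean"] = True
        if decoder.task == "classification":
            _write_lda(g, "feature_decoder", decoder.feature_decoder_)
        else:
            sub = g.create_group("feature_decoder")
            sub.create_dataset("coef", data=decoder.feature_decoder_.coef_)
            sub.create_dataset("intercept",
                               data=np.atleast_1d(decoder.feature_decoder_.intercept_))
        tm = g.create_group("transients")
        for tag, comp in (("onset", decoder.transients_.onset),
                          ("offset", decoder.transients_.offset)):
            sub = tm.create_group(tag)
            sub.create_dataset("w", data=comp.w)
            sub.create_dataset("template", data=comp.template)
            sub.create_dataset("times", data=comp.times)
            sub.attrs["peak_time"] = comp.peak_time
            sub.attrs["peak_amplitude"] = comp.peak_amplitude
            sub.attrs["fwhm"] = comp.fwhm


def read_gated_decoder(path: str | Path):
    from sklearn.linear_model import LinearRegression

    from .gate import GateConfig, GatedDecoder
    from .transients import TransientComponent, TransientModel

    with h5py.File(path, "r") as f:
        if "gated_decoder" not in f:
            raise SchemaError(f"no gated_decoder group in {path}")
        g = f["gated_decoder"]
        cfg = GateConfig(**json.loads(g.attrs["config"]))
        decoder = GatedDecoder(task=str(g.attrs["task"]), config=cfg)
        decoder.onset_detector_ = _read_lda(g, "onset_detector")
        decoder.offset_detector_ = _read_lda(g, "offset_detector")
        if decoder.task == "classification":
            decoder.feature_decoder_ = _read_lda(g, "feature_decoder")
            decoder.classes_ = decoder.feature_decoder_.classes_
        else:
            reg = LinearRegression()
            reg.coef_ = g["feature_decoder/coef"][()]
            reg.intercept_ = float(g["feature_decoder/intercept"][0])
            decoder.feature_decoder_ = reg

        def comp(tag: str) -> TransientComponent:
            sub = g[f"transients/{tag}"]
            return TransientComponent(w=sub["w"][()], template=sub["template"][()],
                                      times=sub["times"][()],
                                      peak_time=float(sub.attrs["peak_time"]),
                                      peak_amplitude=float(sub.attrs["peak_amplitude"]),
                                      fwhm=float(sub.attrs["fwhm"]))

        decoder.transients_ = TransientModel(onset=comp("onset"),
                                             offset=comp("offset"))
        decoder.bin_width_ = float(g.attrs["bin_width"])
        decoder.n_features_in_ = decoder.transients_.onset.w.size
        return decoder


def write_trace(path: str | Path, trace) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=trace.times)
        f.create_dataset("output", data=trace.output)
        f.create_dataset("state", data=trace.state)
        f.create_dataset("events", data=json.dumps(trace.events))
        f.attrs["kind"] = trace.kind
        f.attrs["bin_width"] = trace.bin_width


def export_trace_csv(trace, path: str | Path) -> None:
    pd.DataFrame(dict(time=trace.times, output=trace.output,
                      state=trace.state_names)).to_csv(path, index=False)


# -- run configuration -----------------------------------------------------

_KNOWN_KEYS = {"generation", "preprocess", "gate", "windows", "n_factors",
               "seed", "out_dir", "log_level"}


def load_run_config(path: str | Path) -> dict:
    """Load and validate a YAML run configuration. Unknown keys are rejected."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return build_run_config(**raw)


def build_run_config(generation: dict | None = None, preprocess: dict | None = None,
                     gate: dict | None = None, windows: dict | None = None,
                     n_factors: int = 20, seed: int = 0,
                     out_dir: str = ".", log_level: str = "INFO") -> dict:
    gen = dict(generation or {})
    gen.setdefault("seed", seed)
    cfg = dict(
        generation=asdict(GenConfig(**gen)),
        preprocess=asdict(PreprocessConfig(**(preprocess or {}))),
        gate=asdict(GateConfig(**(gate or {}))),
        windows=asdict(AlignmentWindows(**{k: tuple(v) for k, v in
                                           (windows or {}).items()})),
        n_factors=int(n_factors),
        seed=int(seed),
        out_dir=str(out_dir),
        log_level=str(log_level),
    )
    return cfg


def save_run_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=True)


# -- end-to-end pipeline ---------------------------------------------------

def run_pipeline(cfg: dict) -> dict:
    """simulate -> smooth -> latents -> transients -> condvar -> LOO evaluate.

    Returns the JSON-serializable report; artifacts (session.h5, report.json)
    are written under cfg["out_dir"]. Fully reproducible from (config, seed).
    """
    logging.basicConfig(level=getattr(logging, cfg.get("log_level", "INFO")))
    out_dir = Path(cfg.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        gen_cfg = GenConfig(**cfg["generation"])
        bundle, truth = generate_session(gen_cfg)
        write_bundle(bundle, out_dir / "session.h5")
        log.info("simulate: %d channels x %d bins, %d trials",
                 bundle.counts.shape[0], bundle.n_bins, len(bundle.events))

        stage = "preprocess"
        pre_cfg = PreprocessConfig(**cfg["preprocess"])
        rates = smooth_counts(bundle.counts, pre_cfg)

        stage = "fit-latent"
        fls = FactorLatentSpace(n_factors=cfg.get("n_factors", 20)).fit(rates.rates.T)
        z = fls.transform(rates.rates.T)
        log.info("fit-latent: %d EM iterations, converged=%s", fls.n_iter_,
                 fls.converged_)

        stage = "find-transients"
        windows = AlignmentWindows(**{k: tuple(v) for k, v in cfg["windows"].items()})
        ident = TransientIdentifier(windows=windows,
                                    smoothing_tau=pre_cfg.tau).fit(
            z, bundle.events, bundle.bin_width)
        model = ident.model_

        stage = "condvar"
        labels = bundle.events["condition"].to_numpy()
        on, off = ident.aligned_on_, ident.aligned_off_
        tr_on = condition_variance_trace(on.per_trial, labels[on.trial_index],
                                         on.times, "onset")
        tr_off = condition_variance_trace(off.per_trial, labels[off.trial_index],
                                          off.times, "offset")
        summary = summarize_t1_t2(tr_on, tr_off, model)
        lag = transient_variance_lag(model.onset.template, tr_on, bundle.bin_width)

        stage = "evaluate"
        gate_cfg = GateConfig(**cfg["gate"])
        report = loo_cv(bundle, pre_cfg=pre_cfg, windows=windows,
                        gate_cfg=gate_cfg, n_factors=cfg.get("n_factors", 20))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    out = dict(
        config=cfg,
        config_hash=gen_cfg.config_hash(),
        session=dict(n_channels=int(bundle.counts.shape[0]),
                     n_bins=int(bundle.n_bins), n_trials=len(bundle.events),
                     task_type=gen_cfg.task_type),
        transients=dict(
            peak_time_on=model.onset.peak_time, peak_time_off=model.offset.peak_time,
            fwhm_on=model.onset.fwhm, fwhm_off=model.offset.fwhm,
            amplitude_on=model.onset.peak_amplitude,
            amplitude_off=model.offset.peak_amplitude,
            w_on_dot_w_off=float(model.w_on @ model.w_off)),
        condition_variance=dict(V_t1=summary.V_t1, V_t2=summary.V_t2,
                                ratio=summary.ratio, lag=lag),
        evaluation=dict(task=report.task, aggregates=report.aggregates,
                        excluded_trials=report.excluded_trials,
                        failed_folds=report.failed_folds,
                        n_folds=len(report.trials)),
    )
    with open(out_dir / "report.json", "w") as f:
        json.dump(out, f, indent=2, sort_keys=True, default=float)
    log.info("report written to %s", out_dir / "report.json")
    return out
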