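"""End-to-end pipeline: simulate/ingest -> calibrate -> segment -> extract ->
pretreat (all configured chains) -> PLSR + metrics -> feature selection ->
reduced models -> prediction maps; with a YAML config, stage logging and a
reproducible run manifest.

The config is validated against a small schema before any stage runs; the
manifest records the config, seeds, package version and SHA-256 hashes of
every output file so any artifact is attributable to an exact (config,
seed) pair.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import build_wavelength_grid
from .chemometrics import evaluate_chain_model, split_calibration_prediction
from .feature_selection import (PRESET_FEATURE_WAVELENGTHS_NM,
                                build_reduced_model, preset_reduced_model,
                                reduction_percent, select_feature_wavelengths)
from .io import spectra_matrix, write_spectra_csv
from .mapping import predict_map, render_map
from .preprocessing import STANDARD_CHAINS, apply_chain, parse_chain
from .segmentation import extract_mean_spectra, segment, split_regions
from .synthetic import PhantomSpec, generate_phantom_hypercube

log = logging.getLogger("hsiph.pipeline")

__all__ = ["RunConfig", "run_pipeline", "load_config"]

_SCHEMA = {
    "out_dir": str,
    "seed": int,
    "grid": dict,          # start_nm, stop_nm, step_nm
    "simulate": dict,      # n_samples, shape, noise_sd, gain_sd, offset_sd, ph_range
    "segmentation": dict,  # band_index, threshold, k_regions
    "split": dict,         # fraction, by_sample
    "model": dict,         # n_latent, cv_scheme, cv_k
    "chains": list,        # chain label strings (applied in both domains)
    "feature_selection": dict,  # k, min_separation_bands, preset (bool), source_chain
    "map": dict,           # scale (null or [lo, hi]), palette
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``load_config``)."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    grid: dict = field(default_factory=lambda: {"start_nm": 350, "stop_nm": 1100,
                                                "step_nm": 5})
    simulate: dict = field(default_factory=lambda: {
        "n_samples": 33, "shape": [48, 72], "noise_sd": 0.003,
        "gain_sd": 0.03, "offset_sd": 0.01, "ph_range": [4.44, 6.46]})
    segmentation: dict = field(default_factory=lambda: {
        "band_index": 70, "threshold": 0.075, "k_regions": 5})
    split: dict = field(default_factory=lambda: {"fraction": 2 / 3,
                                                 "by_sample": False})
    model: dict = field(default_factory=lambda: {"n_latent": 8,
                                                 "cv_scheme": "kfold", "cv_k": 10})
    chains: list = field(default_factory=lambda: list(STANDARD_CHAINS))
    feature_selection: dict = field(default_factory=lambda: {
        "k": 12, "min_separation_bands": 2, "preset": False,
        "source_chain": "Raw"})
    map: dict = field(default_factory=lambda: {"scale": [4.4, 6.5],
                                               "palette": "jet"})


def load_config(path: str | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML config; unknown keys or wrong types abort
    before any stage runs."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        raw.update(overrides)
    unknown = set(raw) - set(_SCHEMA)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, value in raw.items():
        want = _SCHEMA[key]
        if want is int and isinstance(value, bool):
            raise ValueError(f"config key {key!r} must be int")
        if not isinstance(value, want):
            raise ValueError(f"config key {key!r} must be {want.__name__}")
    config = RunConfig(**raw)
    for label in config.chains:
        parse_chain(label)  # raises on unknown chain names before running
    return config


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow on simulated scenes; returns the manifest."""
    t0 = time.time()
    os.makedirs(config.out_dir, exist_ok=True)
    outputs: list = []
    rng = np.random.default_rng(config.seed)
    grid = build_wavelength_grid(config.grid["start_nm"], config.grid["stop_nm"],
                                 config.grid["step_nm"])

    # --- simulate + segment + extract -----------------------------------
    sim = config.simulate
    seg = config.segmentation
    ph_lo, ph_hi = sim["ph_range"]
    tables = []
    truths = {}
    cubes = {}
    log.info("simulating %d scenes", sim["n_samples"])
    for i in range(sim["n_samples"]):
        code = f"S{i + 1:03d}"
        spec = PhantomSpec(
            shape=tuple(sim["shape"]), ph_value=float(rng.uniform(ph_lo, ph_hi)),
            noise_sd=sim["noise_sd"], gain_sd=sim["gain_sd"],
            offset_sd=sim["offset_sd"], n_regions=seg["k_regions"],
            seed=int(rng.integers(2**31)), grid=grid)
        cube, truth = generate_phantom_hypercube(spec)
        mask = segment(cube, seg["band_index"], seg["threshold"])
        labels = split_regions(mask, seg["k_regions"])
        tables.append(extract_mean_spectra(cube, labels, code, spec.ph_value))
        if i < 2:  # keep a couple of scenes for mapping
            truths[code], cubes[code] = truth, cube
    table = pd.concat(tables, ignore_index=True)
    table_path = os.path.join(config.out_dir, "spectra.csv")
    write_spectra_csv(table, table_path)
    outputs.append(table_path)

    # --- split + chains + PLSR metrics ----------------------------------
    cal, pred = split_calibration_prediction(
        table, config.split["fraction"], seed=config.seed,
        by_sample=config.split["by_sample"])
    log.info("split: %d calibration rows, %d prediction rows", len(cal), len(pred))

    model_cfg = config.model
    metric_rows = []
    models = {}
    for domain, dtable_cal, dtable_pred in (
            ("reflectance", cal, pred),
            ("absorbance", _table_absorbance(cal, grid), _table_absorbance(pred, grid))):
        for label in config.chains:
            chain = parse_chain(label, domain=domain)
            model, metrics = evaluate_chain_model(
                dtable_cal, dtable_pred, chain, grid, model_cfg["n_latent"],
                cv_scheme=model_cfg["cv_scheme"], cv_k=model_cfg.get("cv_k"),
                cv_seed=config.seed)
            models[(domain, label)] = model
            metric_rows.append({"domain": domain, "treatment": label,
                                **metrics.as_dict()})
            log.info("%s / %s: Rc2=%.4f RMSEC=%.4f", domain, label,
                     metrics.Rc2, metrics.RMSEC)
    metrics_frame = pd.DataFrame(metric_rows)
    metrics_path = os.path.join(config.out_dir, "metrics_full.csv")
    metrics_frame.to_csv(metrics_path, index=False)
    outputs.append(metrics_path)

    # --- feature selection + reduced models ------------------------------
    fs = config.feature_selection
    if fs.get("preset"):
        wavelengths = list(PRESET_FEATURE_WAVELENGTHS_NM)
    else:
        source = models[("reflectance", fs.get("source_chain", "Raw"))]
        wavelengths = select_feature_wavelengths(
            source, grid, k=fs["k"],
            min_separation_bands=fs["min_separation_bands"])
    log.info("selected %d feature wavelengths (%d%% reduction)",
             len(wavelengths), reduction_percent(len(wavelengths), grid.n_bands))

    reduced_rows = []
    reduced_models = {}
    for domain, dtable_cal, dtable_pred in (
            ("reflectance", cal, pred),
            ("absorbance", _table_absorbance(cal, grid), _table_absorbance(pred, grid))):
        for label in config.chains:
            chain = parse_chain(label, domain=domain)
            linear, metrics = build_reduced_model(
                dtable_cal, wavelengths, chain, grid, model_cfg["n_latent"],
                pred=dtable_pred, cv_scheme=model_cfg["cv_scheme"],
                cv_k=model_cfg.get("cv_k"), cv_seed=config.seed)
            reduced_models[(domain, label)] = linear
            reduced_rows.append({"domain": domain, "treatment": label,
                                 **metrics.as_dict()})
    reduced_frame = pd.DataFrame(reduced_rows)
    reduced_path = os.path.join(config.out_dir, "metrics_reduced.csv")
    reduced_frame.to_csv(reduced_path, index=False)
    outputs.append(reduced_path)

    model_path = os.path.join(config.out_dir, "reduced_model.json")
    map_model = reduced_models[("reflectance", "Raw")]
    map_model.to_json(model_path)
    outputs.append(model_path)

    # --- prediction maps --------------------------------------------------
    scale = config.map["scale"]
    for code, cube in cubes.items():
        pmap = predict_map(cube, map_model, truths[code].mask)
        png = os.path.join(config.out_dir, f"map_{code}.png")
        render_map(pmap, png, palette=config.map["palette"],
                   scale=tuple(scale) if scale else None)
        outputs.append(png)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: getattr(config, k) for k in _SCHEMA},
        "n_rows": int(len(table)),
        "n_calibration": int(len(cal)),
        "n_prediction": int(len(pred)),
        "feature_wavelengths_nm": [float(w) for w in wavelengths],
        "outputs": {os.path.basename(p): _sha256(p) for p in outputs},
        "elapsed_s": round(time.time() - t0, 2),
    }
    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    log.info("pipeline finished in %.1f s", manifest["elapsed_s"])
    return manifest


def _table_absorbance(table: pd.DataFrame, grid) -> pd.DataFrame:
    """Reflectance spectra table -> absorbance (-log10, floored at 1e-6)."""
    from .core import to_absorbance
    from .io import wavelength_columns
    out = table.copy()
    cols = wavelength_columns(grid)
    out[cols] = to_absorbance(spectra_matrix(table, grid), clip=True)
    return out
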