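"""Config-driven orchestration of simulate → analyze stage chains.

A run config (YAML/JSON/dict) names an ordered list of stages with
parameters; the pipeline executes them in order inside an output
directory, writes every artifact through the deterministic writers in
:mod:`.io`, echoes the fully resolved config next to the outputs, and
records a checksum manifest.  Deterministic configs (every stage seeded)
reproduce bit-identical manifests on re-run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any

import numpy as np

from . import io as mio
from . import morphometry, synthgen, tracking, velocimetry
from .io import Manifest
from .mechanics import GEOMETRY_PRESETS, MechParams, fit_relaxation

log = logging.getLogger("monolayer_mech")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Resolved pipeline configuration.

    ``stages`` is an ordered list of ``{"stage": name, **params}``
    mappings; ``seed`` is the root seed from which per-stage seeds are
    derived deterministically (stage i uses seed + i unless it sets its
    own).
    """

    out_dir: Path
    stages: list[dict]
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict, out_dir=None) -> "RunConfig":
        return cls(
            out_dir=Path(out_dir or d.get("out_dir", ".")),
            stages=list(d.get("stages", [])),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_file(cls, path, out_dir=None) -> "RunConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh), out_dir=out_dir)

    def resolved(self) -> dict:
        # the output location is a runtime choice, not part of the run's
        # scientific identity, so it is not echoed (keeps re-runs of the
        # same config bit-identical wherever they land)
        return {"seed": self.seed, "stages": self.stages}


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def _write_json(path, obj) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def run_pipeline(config: RunConfig) -> Manifest:
    """Execute the configured stages in order; returns the manifest.

    Any stage error aborts the run with the stage name and parameters in
    the exception message.  Inputs are never modified on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest([])
    for i, stage_cfg in enumerate(config.stages):
        params = dict(stage_cfg)
        name = params.pop("stage")
        params.setdefault("seed", config.seed + i)
        log.info("stage %d: %s %s", i, name, params)
        try:
            _STAGES[name](out, manifest, **params)
        except Exception as e:
            raise RuntimeError(f"stage {i} ({name}) failed with inputs {params}: {e}") from e
    cfg_path = out / "run_config.json"
    _write_json(cfg_path, config.resolved())
    manifest.add(cfg_path, "config")
    manifest.write(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stage implementations (thin wrappers over the library API)


def _stage_simulate_field(out, manifest, seed=0, n_frames=1, **params):
    fields = []
    truth = None
    for k in range(n_frames):
        f, truth = synthgen.gen_velocity_field(seed=seed + k, **_tupled(params))
        f.t_min = k * 7.5
        fields.append(f)
    path = out / "velocity_field.csv"
    mio.write_vector_field_csv(path, fields)
    mio.write_truth_json(out / "velocity_field.truth.json", truth)
    manifest.add(path, "simulate_field")
    manifest.add(out / "velocity_field.truth.json", "simulate_field")


def _tupled(params):
    p = dict(params)
    for key in ("shape", "drift", "frame_shape", "migration_axis"):
        if key in p and isinstance(p[key], list):
            p[key] = tuple(p[key])
    return p


def _stage_velocimetry(out, manifest, seed=0, input="velocity_field.csv", normalize=True, **_):
    fields = mio.read_vector_field_csv(out / input)
    orders = [velocimetry.order_parameter(f) for f in fields]
    curves = []
    for f in fields:
        ac = velocimetry.spatial_autocorrelation(f)
        curves.append(velocimetry.radial_average(ac, f.spacing_um))
    mean_ac = np.mean([c.ac for c in curves], axis=0)
    curve = velocimetry.CorrelationCurve(curves[0].r_um, mean_ac, curves[0].n_pairs)
    L = velocimetry.correlation_length(curve, normalize=normalize)
    path = out / "velocimetry.json"
    _write_json(
        path,
        {
            "order_parameter_per_frame": orders,
            "order_parameter": float(np.mean(orders)),
            "correlation_length_um": L,
        },
    )
    manifest.add(path, "velocimetry")


def _stage_simulate_tracks(out, manifest, seed=0, **params):
    df, truth = synthgen.gen_tracks(seed=seed, **params)
    path = out / "detections.csv"
    mio.write_tracks_csv(path, df, meta={"dt_min": params.get("dt_min", 7.5)})
    mio.write_truth_json(out / "detections.truth.json", truth)
    manifest.add(path, "simulate_tracks")
    manifest.add(out / "detections.truth.json", "simulate_tracks")


def _stage_msd(out, manifest, seed=0, input="detections.csv", dt_min=7.5,
               max_disp_um=20.0, memory_frames=4, min_length=5,
               fit_lo_min=0.0, fit_hi_min=60.0, **_):
    df = mio.read_detections_csv(out / input)
    cfg = tracking.LinkConfig(max_disp_um, memory_frames, min_length)
    tracks = tracking.link(df, cfg, dt_min=dt_min)
    curve = tracking.ensemble_msd(tracks)
    fit = tracking.fit_power_law(curve, (fit_lo_min, fit_hi_min))
    speeds = [tracking.mean_speed(t) for t in tracks]
    path = out / "msd.json"
    _write_json(
        path,
        {
            "n_tracks": len(tracks),
            "mean_speed_um_per_h": float(np.mean(speeds)),
            "msd_exponent_n": fit.n,
            "msd_amplitude_a": fit.a_um2,
            "msd_at_60min_um2": fit.msd_at(60.0),
        },
    )
    manifest.add(path, "msd")


def _stage_simulate_tessellation(out, manifest, seed=0, **params):
    labels, truth = synthgen.gen_tessellation(seed=seed, **_tupled(params))
    path = out / "labels.tiff"
    mio.write_labels_tiff(path, labels)
    mio.write_truth_json(out / "labels.truth.json", truth)
    manifest.add(path, "simulate_tessellation")
    manifest.add(out / "labels.truth.json", "simulate_tessellation")


def _stage_morphometry(out, manifest, seed=0, input="labels.tiff", pixel_um=1.0, **_):
    labels = mio.read_labels_tiff(out / input, pixel_um)
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        records = morphometry.extract_cells(labels, pixel_um)
    area_mm2 = labels.shape[0] * labels.shape[1] * pixel_um**2 / 1e6
    stats = morphometry.population_stats(records, area_mm2)
    path = out / "morphometry.json"
    _write_json(
        path,
        {
            "n_cells": stats.n_cells,
            "density_per_mm2": stats.density_per_mm2,
            "area_skewness": stats.area_skewness,
            "mean_area_um2": float(np.mean([r.area_um2 for r in records])),
            "mean_aspect_ratio": float(np.mean([r.aspect_ratio for r in records])),
        },
    )
    manifest.add(path, "morphometry")


def _stage_simulate_force_curve(out, manifest, seed=0, preset="wt",
                                T0=0.35, KA0=0.02, beta=0.5, t0_s=1.0,
                                delta_frac=0.8, n_samples=500, dwell_s=0.5,
                                noise_rel=0.01, **_):
    geom = GEOMETRY_PRESETS[preset]
    delta = delta_frac * geom.cap_height_um
    times = np.linspace(1e-3, dwell_s, n_samples)
    curve, truth = synthgen.gen_force_curve(
        geom, MechParams(T0, KA0, beta, t0_s), delta, times, noise_rel, seed
    )
    path = out / "force_curve.csv"
    mio.write_force_curve(path, curve, geom, t0_s)
    mio.write_truth_json(out / "force_curve.truth.json", truth)
    manifest.add(path, "simulate_force_curve")
    manifest.add(out / "force_curve.truth.json", "simulate_force_curve")


def _stage_mech_fit(out, manifest, seed=0, input="force_curve.csv", **_):
    curve, geom, t0_s = mio.read_force_curve(out / input)
    fit = fit_relaxation(curve, geom, t0_s)
    path = out / "mech_fit.json"
    p = fit.params
    _write_json(
        path,
        {
            "converged": fit.converged,
            "collinear": fit.collinear,
            "residual_rms_N": fit.residual_rms,
            "T0_mN_per_m": p.T0_mN_per_m if p else None,
            "KA0_mN_per_m": p.KA0_mN_per_m if p else None,
            "beta": p.beta if p else None,
            "t0_s": t0_s,
        },
    )
    manifest.add(path, "mech_fit")


_STAGES = {
    "simulate_field": _stage_simulate_field,
    "velocimetry": _stage_velocimetry,
    "simulate_tracks": _stage_simulate_tracks,
    "msd": _stage_msd,
    "simulate_tessellation": _stage_simulate_tessellation,
    "morphometry": _stage_morphometry,
    "simulate_force_curve": _stage_simulate_force_curve,
    "mech_fit": _stage_mech_fit,
}
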