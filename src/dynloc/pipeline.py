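"""End-to-end pipeline: design → HRTF synthesis/conditions → simulated
responses → metrics → mixed-model contrasts, with provenance logging.

Rendering (audio synthesis) is decoupled from the behavioral path:
simulated responses are generated from cue parameters, not by decoding
rendered audio, so the metrics and stats outputs are identical with or
without the rendering step.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analyze import compute_metrics, qc_filter
from .coords import DirectionSph
from .design import make_source_grid
from .hrtf import flatten_spectrum, freeze_spectrum, interpolate_to_dense, mesh_directions, subdivide, triangulate
from .render import make_noise_burst, render_dynamic
from .simulate import ListenerParams, make_synthetic_hrtf, simulate_experiment, simulate_trajectory
from .sofa import write_sofa
from .stats import analyze_and_test

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Serializable configuration of one pipeline run."""

    seed: int = 0
    n_subjects: int = 2
    static_reps: int = 1
    dynamic_reps: int = 1
    fs: float = 48000.0
    subdivisions: int = 1
    flatten_band_hz: tuple[float, float] = (1000.0, 16000.0)
    flatten_contrast: float = 0.0
    freeze_reference: tuple[float, float] = (0.0, 0.0)
    render_examples: int = 2
    skip_render: bool = False
    listener_params: dict | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("flatten_band_hz", "freeze_reference"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _params_from_config(cfg: PipelineConfig) -> ListenerParams:
    if cfg.listener_params is None:
        return ListenerParams()
    d = dict(cfg.listener_params)
    if "cells" in d:
        d["cells"] = {tuple(k.split("|")): tuple(v) for k, v in d["cells"].items()}
    for key in ("vmax_yaw", "vmax_pitch", "reaction"):
        if key in d:
            d[key] = tuple(d[key])
    return ListenerParams(**d)


def run_pipeline(cfg: PipelineConfig, out_dir) -> Path:
    """Run the full pipeline, writing all artifacts under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    seed_hrtf, seed_sim, seed_render = ss.spawn(3)

    # --- design ---------------------------------------------------------
    grid = make_source_grid()
    grid.to_frame().to_csv(out / "source_grid.csv", index=False)

    # --- HRTF synthesis and cue conditions ------------------------------
    sparse = make_synthetic_hrtf(fs=cfg.fs, seed=seed_hrtf)
    write_sofa(sparse, out / "hrtf_sparse.sofa")
    mesh = subdivide(triangulate(sparse.az_deg, sparse.el_deg), cfg.subdivisions)
    dense_az, dense_el = mesh_directions(mesh)
    dense = interpolate_to_dense(sparse, dense_az, dense_el)
    write_sofa(dense, out / "hrtf_dense_full.sofa")
    flat = flatten_spectrum(dense, *cfg.flatten_band_hz, cfg.flatten_contrast)
    write_sofa(flat, out / "hrtf_dense_flat.sofa")
    ref_az, ref_el = cfg.freeze_reference
    ref_i = int(np.argmin(
        (dense.az_deg - ref_az) ** 2 + (dense.el_deg - ref_el) ** 2
    ))
    frozen = freeze_spectrum(dense, dense.az_deg[ref_i], dense.el_deg[ref_i])
    write_sofa(frozen, out / "hrtf_dense_frozen.sofa")

    # --- example rendered trials (not on the metrics path) ---------------
    if not cfg.skip_render:
        from scipy.io import wavfile

        stim = make_noise_burst(cfg.fs, duration_ms=500.0, seed=seed_render)
        for i, arrow in enumerate(("left", "up")):
            if i >= cfg.render_examples:
                break
            traj = simulate_trajectory(arrow, seed=seed_render.spawn(1)[0])
            sig = render_dynamic(
                stim, DirectionSph(30.0, 0.0), traj, dense,
                condition="full",
                gate_axis="yaw" if arrow in ("left", "right") else "pitch",
            )
            scaled = np.int16(np.clip(sig.T, -1, 1) * 32767)
            wavfile.write(out / f"example_trial_{arrow}.wav", int(cfg.fs), scaled)

    # --- behavioral simulation ------------------------------------------
    params = _params_from_config(cfg)
    responses, truth = simulate_experiment(
        n_subjects=cfg.n_subjects,
        params=params,
        seed=seed_sim,
        static_reps=cfg.static_reps,
        dynamic_reps=cfg.dynamic_reps,
        grid=grid,
    )
    responses.to_csv(out / "responses.csv", index=False)
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))

    # --- analysis --------------------------------------------------------
    filtered, qc_report = qc_filter(responses)
    (out / "qc_report.json").write_text(json.dumps(qc_report, indent=2))
    metrics = compute_metrics(filtered)
    metrics.to_csv(out / "metrics.csv", index=False)

    # --- stats -----------------------------------------------------------
    contrasts = analyze_and_test(responses)
    contrasts.to_csv(out / "contrasts.csv", index=False)

    # --- provenance -------------------------------------------------------
    log = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "dynloc_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "dense_grid_size": int(len(dense)),
        "n_trials_simulated": int(len(responses)),
        "n_trials_after_qc": int(len(filtered)),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return out
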