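"""End-to-end orchestration: simulate → detect → extract → stats.

Every run writes a manifest (full config echo, seed, package version) next
to its outputs, so a result can be regenerated byte-for-byte from the
manifest alone.  All randomness flows from the single run seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig
from .detect import ROI, measure_sequence
from .io import (read_frames, read_trace, write_frames, write_ground_truth,
                 write_params_json, write_trace)
from .synthetic import generate_ground_truth, render_sequence
from .trace import (TraceExcludedError, build_trace, detect_blinks,
                    extract_flash_train, extract_single_flash)

logger = logging.getLogger(__name__)


def default_roi(config: RunConfig) -> ROI:
    if config.roi is not None:
        return ROI(*config.roi)
    h, w = config.scene.image_size_px
    return ROI(0, 0, h, w)


def write_manifest(out_dir: Path, config: RunConfig) -> None:
    manifest = {"config": config.to_dict(), "seed": config.seed,
                "pupilkit_version": __version__}
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1))


def simulate_stage(config: RunConfig, out_dir: Path) -> Path:
    """Render the configured eye video with ground truth to disk."""
    scene = dataclasses.replace(config.scene, seed=config.seed)
    truth = generate_ground_truth(config.model, config.protocol,
                                  blink_intervals=config.blink_intervals)
    frames = render_sequence(scene, truth)
    frames_dir = out_dir / "frames"
    write_frames(frames_dir, frames)
    write_ground_truth(out_dir / "ground_truth.csv", truth)
    logger.info("simulate: %d frames -> %s", len(frames), frames_dir)
    return frames_dir


def detect_stage(config: RunConfig, frames_dir: Path, out_dir: Path) -> Path:
    """Measure every frame and write the pupillogram trace."""
    frames = read_frames(frames_dir, fps=config.protocol.fps)
    roi = default_roi(config)
    measurements, iris = measure_sequence(
        frames, roi, config.detect, fps=config.protocol.fps)
    if iris is None:
        raise RuntimeError("detect: iris could not be measured on any frame")
    n_invalid = sum(not m.valid for m in measurements)
    logger.info("detect: %d frames read, %d invalid, iris %.2f px",
                len(frames), n_invalid, iris)
    trace = build_trace(measurements, config.protocol.fps, config.protocol,
                        iris)
    trace_path = out_dir / "trace.csv"
    write_trace(trace_path, trace, measurements)
    return trace_path


def extract_stage(config: RunConfig, trace_path: Path, out_dir: Path
                  ) -> Path:
    """Extract protocol parameters; an excluded recording is reported."""
    trace = read_trace(trace_path, protocol=config.protocol)
    report = detect_blinks(trace, config.extraction)
    logger.info("extract: %d blink intervals, excluded=%s",
                report.blink_count, report.excluded)
    params_path = out_dir / "params.json"
    try:
        if config.protocol.n_flashes > 1:
            params = extract_flash_train(trace, config.extraction)
        else:
            params = extract_single_flash(trace, config.extraction)
    except TraceExcludedError as exc:
        payload = {"excluded": True, "blink_count": report.blink_count,
                   "reason": str(exc)}
        params_path.write_text(json.dumps(payload, sort_keys=True, indent=1))
        return params_path
    write_params_json(params_path, params,
                      extra={"excluded": False,
                             "blink_count": report.blink_count})
    return params_path


def stats_stage(config: RunConfig, cohort_csv: Path, out_dir: Path) -> Path:
    """Group statistics over a per-subject cohort parameter table."""
    import pandas as pd

    from .stats import build_results_table, results_to_frame

    cohort = pd.read_csv(cohort_csv)
    if "excluded" in cohort.columns:
        n0 = len(cohort)
        cohort = cohort[~cohort["excluded"].astype(bool)]
        logger.info("stats: %d of %d subjects excluded by the blink rule",
                    n0 - len(cohort), n0)
    results = build_results_table(cohort, alpha=config.alpha)
    out = out_dir / "stats.csv"
    results_to_frame(results).to_csv(out, index=False)
    return out


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the requested stages end to end; returns the artifact paths.

    Simulates when no frames directory is configured; statistics run only
    when a cohort CSV is configured.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_manifest(out_dir, config)
    artifacts: dict = {"manifest": out_dir / "manifest.json"}
    if config.frames_dir is not None:
        frames_dir = Path(config.frames_dir)
    else:
        frames_dir = simulate_stage(config, out_dir)
        artifacts["frames"] = frames_dir
        artifacts["ground_truth"] = out_dir / "ground_truth.csv"
    if config.trace_csv is not None:
        trace_path = Path(config.trace_csv)
    else:
        trace_path = detect_stage(config, frames_dir, out_dir)
        artifacts["trace"] = trace_path
    artifacts["params"] = extract_stage(config, trace_path, out_dir)
    if config.cohort_csv is not None:
        artifacts["stats"] = stats_stage(config, Path(config.cohort_csv),
                                         out_dir)
    return artifacts
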