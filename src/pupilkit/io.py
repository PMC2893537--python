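"""Readers and writers for the toolkit's on-disk formats.

Frames: directory of 8-bit grayscale PNG/TIFF files (ordered by the numeric
index embedded in the filename) or one multi-frame TIFF.  Traces: CSV with a
JSON sidecar carrying the recording metadata (fps, iris radius, flash
times), so that a written trace round-trips losslessly.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .detect import EyeFrame, FrameMeasurement, CircleFit
from .synthetic import FlashProtocol, GroundTruthTrace
from .trace import PupilTrace

logger = logging.getLogger(__name__)

_FRAME_EXTS = {".png", ".tif", ".tiff"}
TRACE_COLUMNS = ["frame", "time_s", "pupil_radius_px", "pupil_row",
                 "pupil_col", "score", "valid", "iris_radius_px"]

# ITU-R 601 luminance weights for incidental color input
_LUMA = np.array([0.299, 0.587, 0.114])


def _to_gray8(arr: np.ndarray, name: str) -> np.ndarray:
    if arr.ndim == 3:
        logger.warning("%s: color input converted to grayscale by "
                       "luminance", name)
        arr = arr[..., :3] @ _LUMA
    if arr.ndim != 2:
        raise ValueError(f"{name}: expected a 2-D grayscale image")
    return np.clip(np.rint(np.asarray(arr, dtype=float)), 0, 255
                   ).astype(np.uint8)


def read_frames(path: str | Path, fps: float = 30.0) -> list[EyeFrame]:
    """Read an ordered frame sequence from a directory or multi-frame TIFF.

    Directory filenames must embed a numeric frame index; the indices must
    be consecutive (a missing frame is an error naming the gap).  All frames
    must share one size.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in _FRAME_EXTS)
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF frames in {path}")
        indexed = []
        for p in files:
            m = re.search(r"(\d+)(?!.*\d)", p.stem)
            if not m:
                raise ValueError(f"cannot parse frame index from {p.name}")
            indexed.append((int(m.group(1)), p))
        indexed.sort()
        indices = [i for i, _ in indexed]
        expect = list(range(indices[0], indices[0] + len(indices)))
        if indices != expect:
            missing = sorted(set(expect) - set(indices))[0]
            raise ValueError(f"frame index {missing} missing from {path}")
        stacks = []
        for i, p in indexed:
            try:
                arr = iio.imread(p)
            except Exception as exc:
                raise ValueError(f"unreadable frame {p.name}: {exc}") from exc
            stacks.append(_to_gray8(arr, p.name))
        shapes = {a.shape for a in stacks}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent frame sizes in {path}: {shapes}")
        base = indices[0]
        return [EyeFrame(pixels=a, frame_index=i - base,
                         time_s=(i - base) / fps)
                for (i, _), a in zip(indexed, stacks)]
    # multi-frame TIFF
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return [EyeFrame(pixels=_to_gray8(a, f"{path.name}[{i}]"),
                     frame_index=i, time_s=i / fps)
            for i, a in enumerate(arr)]


def write_frames(out_dir: str | Path, frames: np.ndarray,
                 prefix: str = "frame") -> list[Path]:
    """Write a (n, h, w) uint8 stack as zero-padded PNG files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = out_dir / f"{prefix}_{i:04d}.png"
        iio.imwrite(p, np.asarray(frame, dtype=np.uint8))
        paths.append(p)
    return paths


def write_ground_truth(path: str | Path, truth: GroundTruthTrace) -> None:
    """Ground truth as CSV (frame, time_s, radius_px, blink)."""
    df = pd.DataFrame({
        "frame": np.arange(len(truth)),
        "time_s": truth.times_s,
        "radius_px": truth.radii_px,
        "blink": [i in truth.blink_frames for i in range(len(truth))],
    })
    df.to_csv(path, index=False)


def read_ground_truth(path: str | Path) -> GroundTruthTrace:
    df = pd.read_csv(path)
    blink = frozenset(df.loc[df["blink"], "frame"].astype(int))
    return GroundTruthTrace(df["time_s"].to_numpy(),
                            df["radius_px"].to_numpy(), blink)


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_trace(path: str | Path, trace: PupilTrace,
                measurements: Sequence[FrameMeasurement] | None = None,
                ) -> None:
    """Per-frame trace CSV plus a JSON metadata sidecar.

    The sidecar (``<name>.meta.json``) records fps, iris radius and the
    flash protocol so the trace round-trips without external context.
    """
    path = Path(path)
    n = len(trace)
    rows = {
        "frame": np.arange(n),
        "time_s": trace.times_s,
        "pupil_radius_px": trace.radii_px,
        "pupil_row": np.full(n, np.nan),
        "pupil_col": np.full(n, np.nan),
        "score": np.full(n, np.nan),
        "valid": trace.valid,
        "iris_radius_px": np.full(n, trace.iris_radius_px),
    }
    if measurements is not None:
        for i, m in enumerate(measurements):
            if m.pupil is not None:
                rows["pupil_row"][i] = m.pupil.center_px[0]
                rows["pupil_col"][i] = m.pupil.center_px[1]
                rows["score"][i] = m.pupil.score
    pd.DataFrame(rows).to_csv(path, index=False)
    meta = {
        "fps": trace.fps,
        "iris_radius_px": trace.iris_radius_px,
        "flash_times_s": list(trace.protocol.flash_times_s),
        "recording_duration_s": trace.protocol.recording_duration_s,
    }
    _meta_path(path).write_text(json.dumps(meta, sort_keys=True, indent=1))


def read_trace(path: str | Path,
               protocol: FlashProtocol | None = None) -> PupilTrace:
    """Read a trace CSV (and its metadata sidecar) back into a PupilTrace."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"empty trace CSV: {path}")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"malformed trace CSV {path}: missing columns {missing}; "
            f"expected {TRACE_COLUMNS}")
    meta_p = _meta_path(path)
    if protocol is None:
        if not meta_p.exists():
            raise ValueError(f"no protocol given and no sidecar {meta_p}")
        meta = json.loads(meta_p.read_text())
        protocol = FlashProtocol(tuple(meta["flash_times_s"]),
                                 meta["recording_duration_s"],
                                 fps=meta["fps"])
    fps = protocol.fps
    iris = float(df["iris_radius_px"].iloc[0])
    return PupilTrace(times_s=df["time_s"].to_numpy(),
                      radii_px=df["pupil_radius_px"].to_numpy(),
                      valid=df["valid"].to_numpy(dtype=bool),
                      fps=fps, iris_radius_px=iris, protocol=protocol)


def write_params_json(path: str | Path, params, extra: dict | None = None,
                      ) -> None:
    """Parameter set as JSON (stable key order for reproducible bytes)."""
    payload = dict(params.to_dict())
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))


def write_params_csv(path: str | Path, params_rows: list[dict]) -> None:
    """Flat one-row-per-recording parameter CSV."""
    pd.DataFrame(params_rows).to_csv(path, index=False)
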