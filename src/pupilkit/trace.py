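"""Pupillogram construction and pupil-light-reflex parameter extraction.

A pupillogram is the pupil radius as a function of time over one recording.
From it, the single-flash protocol yields: the pre-flash (resting) radius,
the latency to the start of constriction (radius falling to 90% of the
pre-flash value), the minimum radius and its latency, the latency to the
recovery plateau (radius regaining 75% of the pre-flash value), the duration
of constriction, the reflex amplitude (resting minus minimum radius) and the
constriction velocity.  Radius parameters are also reported as pupil/iris
ratios, the size-normalized measure.  The 25-flash protocol reports the
pre-flash and minimum radii around the 1st, 10th and 25th flashes plus the
post-train recovery plateau.

Blink handling: invalid frames (failed fits) and >10 px/frame jumps are
grouped into blink intervals; recordings with more than three blinks are
excluded from parameter extraction.

Conventions: level crossings are linearly interpolated between adjacent
valid frames (sub-frame); minima are frame-aligned (no interpolation);
invalid frames are never interpolated across.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .detect import FrameMeasurement
from .synthetic import FlashProtocol


class TraceExcludedError(RuntimeError):
    """Recording excluded by the blink rule (more than three blinks)."""


class ParameterNotFound(RuntimeError):
    """Internal signal: a level crossing does not occur in the window."""


@dataclass(frozen=True)
class PupilTrace:
    """Per-frame pupil radius series with validity flags (the pupillogram)."""

    times_s: np.ndarray
    radii_px: np.ndarray
    valid: np.ndarray
    fps: float
    iris_radius_px: float
    protocol: FlashProtocol

    def __post_init__(self) -> None:
        times = np.asarray(self.times_s, dtype=float)
        radii = np.asarray(self.radii_px, dtype=float)
        valid = np.asarray(self.valid, dtype=bool)
        object.__setattr__(self, "times_s", times)
        object.__setattr__(self, "radii_px", radii)
        object.__setattr__(self, "valid", valid)
        if not (times.shape == radii.shape == valid.shape):
            raise ValueError("times, radii and valid must have equal length")
        if times.size == 0:
            raise ValueError("trace must be non-empty")
        if self.iris_radius_px <= 0:
            raise ValueError("iris_radius_px must be positive")
        finite = radii[valid]
        if finite.size and np.nanmax(finite) >= self.iris_radius_px:
            raise ValueError("iris radius must exceed every pupil radius")

    def __len__(self) -> int:
        return int(self.times_s.size)


@dataclass(frozen=True)
class SingleFlashParams:
    """Single-flash parameter set (None marks a missing parameter)."""

    ratio_PI_darkness: float | None
    latency_to_constriction_s: float | None
    ratio_PI_largest_constriction: float | None
    latency_to_largest_constriction_s: float | None
    ratio_PI_plateau: float | None
    latency_to_plateau_s: float | None
    duration_of_constriction_s: float | None
    reflex_amplitude_px: float | None
    velocity_of_constriction_px_per_s: float | None
    baseline_radius_px: float | None = None
    min_radius_px: float | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class TrainParams:
    """25-flash parameter set around the 1st, 10th and 25th flashes."""

    ratio_PI_pre_1st: float | None
    ratio_PI_min_after_1st: float | None
    ratio_PI_pre_10th: float | None
    ratio_PI_min_after_10th: float | None
    latency_to_constriction_10th_s: float | None
    latency_to_largest_constriction_10th_s: float | None
    ratio_PI_pre_25th: float | None
    ratio_PI_min_after_25th: float | None
    latency_to_constriction_25th_s: float | None
    latency_to_largest_constriction_25th_s: float | None
    ratio_PI_plateau: float | None
    latency_to_plateau_s: float | None
    duration_of_constriction_s: float | None
    pre_1st_radius_px: float | None = None
    pre_10th_radius_px: float | None = None
    pre_25th_radius_px: float | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class BlinkReport:
    """Blink intervals and the exclusion decision (> 3 blinks excluded)."""

    blink_intervals: tuple[tuple[int, int], ...]
    blink_count: int
    excluded: bool


@dataclass(frozen=True)
class ExtractionConfig:
    """Choices the published parameter definitions leave open.

    ``duration_definition``: endpoint pair of the duration of constriction —
    ``"sustained_redilation"`` (onset crossing to the first run of >= 3
    consecutive rising valid frames after the minimum, the default),
    ``"to_minimum"`` (onset to minimum) or ``"to_plateau"`` (onset to the
    75% recovery crossing).  ``velocity_denominator``: ``"duration"``
    (amplitude / duration, the literal definition) or ``"to_minimum"``.
    """

    onset_fraction: float = 0.9
    plateau_fraction: float = 0.75
    post_flash_window_s: float = 1.5
    duration_definition: str = "sustained_redilation"
    velocity_denominator: str = "duration"
    redilation_run_frames: int = 3
    blink_jump_px: float = 10.0
    max_blinks: int = 3

    def __post_init__(self) -> None:
        if self.duration_definition not in (
                "sustained_redilation", "to_minimum", "to_plateau"):
            raise ValueError("unknown duration_definition")
        if self.velocity_denominator not in ("duration", "to_minimum"):
            raise ValueError("unknown velocity_denominator")


# --------------------------------------------------------------------------
# trace assembly and blink handling
# --------------------------------------------------------------------------

def build_trace(measurements: Sequence[FrameMeasurement], fps: float,
                protocol: FlashProtocol, iris_radius_px: float) -> PupilTrace:
    """Assemble a pupillogram from per-frame measurements.

    Invalid frames are carried as gaps (NaN radius, valid=False); no
    interpolation is performed.
    """
    if len(measurements) == 0:
        raise ValueError("no measurements")
    n = len(measurements)
    radii = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    times = np.empty(n)
    for i, m in enumerate(measurements):
        times[i] = m.time_s if m.time_s else m.frame_index / fps
        if m.valid and m.pupil is not None:
            radii[i] = m.pupil.radius_px
            valid[i] = True
    return PupilTrace(times_s=times, radii_px=radii, valid=valid, fps=fps,
                      iris_radius_px=iris_radius_px, protocol=protocol)


def detect_blinks(trace: PupilTrace,
                  config: ExtractionConfig | None = None) -> BlinkReport:
    """Group invalid frames (and large frame-to-frame jumps) into blinks.

    A blink interval is a maximal run of affected frames; the recording is
    excluded when the number of intervals exceeds ``max_blinks``.
    """
    if config is None:
        config = ExtractionConfig()
    affected = ~trace.valid.copy()
    last_valid_r = None
    for i in range(len(trace)):
        if trace.valid[i]:
            r = trace.radii_px[i]
            if (last_valid_r is not None and
                    abs(r - last_valid_r) > config.blink_jump_px):
                affected[i] = True
            else:
                last_valid_r = r
    intervals: list[tuple[int, int]] = []
    i = 0
    n = len(trace)
    while i < n:
        if affected[i]:
            j = i
            while j + 1 < n and affected[j + 1]:
                j += 1
            intervals.append((i, j))
            i = j + 1
        else:
            i += 1
    count = len(intervals)
    return BlinkReport(blink_intervals=tuple(intervals), blink_count=count,
                       excluded=count > config.max_blinks)


# --------------------------------------------------------------------------
# primitive queries
# --------------------------------------------------------------------------

def baseline_radius(trace: PupilTrace, flash_time_s: float) -> float:
    """Radius of the last valid frame strictly before the flash."""
    mask = (trace.times_s < flash_time_s) & trace.valid
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise ValueError("no valid frame precedes the flash")
    return float(trace.radii_px[idx[-1]])


def crossing_time(trace: PupilTrace, level_px: float,
                  window: tuple[float, float], direction: str) -> float:
    """First time the radius crosses ``level_px`` within ``window``.

    Linear interpolation between the two straddling frames; only pairs of
    adjacent valid frames are considered (gaps are never bridged).  Raises
    :class:`ParameterNotFound` when no crossing occurs.
    """
    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    t0, t1 = window
    t, r, v = trace.times_s, trace.radii_px, trace.valid
    for i in range(len(trace) - 1):
        if not (v[i] and v[i + 1]):
            continue
        if t[i + 1] < t0 or t[i] > t1:
            continue
        if direction == "down":
            hit = r[i] >= level_px > r[i + 1]
        else:
            hit = r[i] <= level_px < r[i + 1]
        if hit:
            if r[i] == level_px:
                tc = t[i]
            else:
                frac = (level_px - r[i]) / (r[i + 1] - r[i])
                tc = t[i] + frac * (t[i + 1] - t[i])
            if t0 <= tc <= t1:
                return float(tc)
    raise ParameterNotFound(
        f"no {direction}ward crossing of {level_px:.3f} in {window}")


def _frame_minimum(trace: PupilTrace, window: tuple[float, float]
                   ) -> tuple[float, float]:
    """Frame-aligned minimum (radius, time) over valid frames in window."""
    t0, t1 = window
    mask = (trace.times_s > t0) & (trace.times_s <= t1) & trace.valid
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise ParameterNotFound("no valid frames in the post-flash window")
    k = idx[np.argmin(trace.radii_px[idx])]
    return float(trace.radii_px[k]), float(trace.times_s[k])


def _sustained_redilation_time(trace: PupilTrace, t_min: float,
                               run: int) -> float:
    """Time of the first frame opening a run of ``run`` consecutive rises."""
    t, r, v = trace.times_s, trace.radii_px, trace.valid
    start = int(np.searchsorted(t, t_min))
    for i in range(start, len(trace) - run):
        seg = slice(i, i + run + 1)
        if not v[seg].all():
            continue
        diffs = np.diff(r[seg])
        if (diffs > 0).all():
            return float(t[i])
    raise ParameterNotFound("no sustained redilation after the minimum")


# --------------------------------------------------------------------------
# parameter extraction
# --------------------------------------------------------------------------

def _maybe(fn, *args):
    try:
        return fn(*args)
    except ParameterNotFound:
        return None


def _check_not_excluded(trace: PupilTrace, config: ExtractionConfig) -> None:
    report = detect_blinks(trace, config)
    if report.excluded:
        raise TraceExcludedError(
            f"recording excluded: {report.blink_count} blinks "
            f"(> {config.max_blinks} allowed)")


def _flash_response(trace: PupilTrace, flash_t: float, window_end: float,
                    config: ExtractionConfig) -> dict:
    """Baseline / onset / minimum measurements for one flash window."""
    base = baseline_radius(trace, flash_t)
    out = {"baseline": base, "onset_t": None, "min_r": None, "min_t": None}
    mm = _maybe(_frame_minimum, trace, (flash_t, window_end))
    if mm is not None:
        out["min_r"], out["min_t"] = mm
        onset = _maybe(crossing_time, trace, config.onset_fraction * base,
                       (flash_t, out["min_t"]), "down")
        out["onset_t"] = onset
    return out


def _duration(trace: PupilTrace, resp: dict, plateau_t: float | None,
              config: ExtractionConfig) -> float | None:
    if resp["onset_t"] is None:
        return None
    if config.duration_definition == "to_minimum":
        end = resp["min_t"]
    elif config.duration_definition == "to_plateau":
        end = plateau_t
    else:
        end = (None if resp["min_t"] is None else
               _maybe(_sustained_redilation_time, trace, resp["min_t"],
                      config.redilation_run_frames))
    if end is None:
        return None
    return float(end - resp["onset_t"])


def extract_single_flash(trace: PupilTrace,
                         config: ExtractionConfig | None = None,
                         ) -> SingleFlashParams:
    """Extract the full single-flash parameter set from a pupillogram.

    Refuses recordings excluded by the blink rule.  Parameters whose level
    crossing does not occur are reported as None, never fabricated.
    """
    if config is None:
        config = ExtractionConfig()
    _check_not_excluded(trace, config)
    flash_t = trace.protocol.flash_times_s[0]
    window_end = min(flash_t + config.post_flash_window_s,
                     float(trace.times_s[-1]))
    resp = _flash_response(trace, flash_t, window_end, config)
    base, min_r, min_t = resp["baseline"], resp["min_r"], resp["min_t"]
    iris = trace.iris_radius_px

    plateau_t = None
    plateau_r = None
    if min_t is not None:
        level = config.plateau_fraction * base
        plateau_t = _maybe(crossing_time, trace, level,
                           (min_t, float(trace.times_s[-1])), "up")
        if plateau_t is not None:
            plateau_r = level  # radius at the crossing is the level itself

    duration = _duration(trace, resp, plateau_t, config)
    amplitude = None if min_r is None else float(base - min_r)
    velocity = None
    if amplitude is not None:
        if config.velocity_denominator == "duration":
            denom = duration
        else:
            denom = (None if resp["onset_t"] is None or min_t is None
                     else min_t - resp["onset_t"])
        if denom is not None and denom > 0:
            velocity = amplitude / denom

    def lat(t):
        return None if t is None else float(t - flash_t)

    return SingleFlashParams(
        ratio_PI_darkness=base / iris,
        latency_to_constriction_s=lat(resp["onset_t"]),
        ratio_PI_largest_constriction=(None if min_r is None
                                       else min_r / iris),
        latency_to_largest_constriction_s=lat(min_t),
        ratio_PI_plateau=(None if plateau_r is None else plateau_r / iris),
        latency_to_plateau_s=lat(plateau_t),
        duration_of_constriction_s=duration,
        reflex_amplitude_px=amplitude,
        velocity_of_constriction_px_per_s=velocity,
        baseline_radius_px=base,
        min_radius_px=min_r,
    )


def extract_flash_train(trace: PupilTrace,
                        config: ExtractionConfig | None = None,
                        ) -> TrainParams:
    """Extract the 25-flash parameter set (1st, 10th, 25th flash windows).

    Each flash's window runs to the next flash (the last window extends to
    the end of the recording); the recovery plateau is computed after the
    last flash against 75% of the pre-last-flash baseline.
    """
    if config is None:
        config = ExtractionConfig()
    _check_not_excluded(trace, config)
    flashes = trace.protocol.flash_times_s
    n = len(flashes)
    t_end = float(trace.times_s[-1])

    def window_end(k: int) -> float:
        return flashes[k + 1] if k + 1 < n else t_end

    iris = trace.iris_radius_px
    picks = {}
    for label, k in (("1st", 0), ("10th", min(9, n - 1)),
                     ("25th", n - 1)):
        picks[label] = _flash_response(trace, flashes[k], window_end(k),
                                       config)

    last = picks["25th"]
    plateau_t = None
    plateau_r = None
    if last["min_t"] is not None:
        level = config.plateau_fraction * last["baseline"]
        plateau_t = _maybe(crossing_time, trace, level,
                           (last["min_t"], t_end), "up")
        if plateau_t is not None:
            plateau_r = level
    duration = _duration(trace, last, plateau_t, config)

    def lat(resp, key, flash_t):
        v = resp[key]
        return None if v is None else float(v - flash_t)

    def ratio(v):
        return None if v is None else v / iris

    return TrainParams(
        ratio_PI_pre_1st=ratio(picks["1st"]["baseline"]),
        ratio_PI_min_after_1st=ratio(picks["1st"]["min_r"]),
        ratio_PI_pre_10th=ratio(picks["10th"]["baseline"]),
        ratio_PI_min_after_10th=ratio(picks["10th"]["min_r"]),
        latency_to_constriction_10th_s=lat(picks["10th"], "onset_t",
                                           flashes[min(9, n - 1)]),
        latency_to_largest_constriction_10th_s=lat(picks["10th"], "min_t",
                                                   flashes[min(9, n - 1)]),
        ratio_PI_pre_25th=ratio(picks["25th"]["baseline"]),
        ratio_PI_min_after_25th=ratio(picks["25th"]["min_r"]),
        latency_to_constriction_25th_s=lat(picks["25th"], "onset_t",
                                           flashes[n - 1]),
        latency_to_largest_constriction_25th_s=lat(picks["25th"], "min_t",
                                                   flashes[n - 1]),
        ratio_PI_plateau=ratio(plateau_r),
        latency_to_plateau_s=(None if plateau_t is None
                              else float(plateau_t - flashes[n - 1])),
        duration_of_constriction_s=duration,
        pre_1st_radius_px=picks["1st"]["baseline"],
        pre_10th_radius_px=picks["10th"]["baseline"],
        pre_25th_radius_px=picks["25th"]["baseline"],
    )
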