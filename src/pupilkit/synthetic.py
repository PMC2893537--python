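"""Synthetic eye scenes and pupil-light-reflex (PLR) dynamics.

The acquisition this emulates: an IR-illuminated close-up of one eye inside a
dark cone, recorded at 30 frames/s while a white-light flash (10 ms, 250 cd)
is fired once (3 s recording) or 25 times at 1 Hz (30 s recording).  The pupil
appears as a dark disk (gray level ~35) on a brighter iris annulus, with four
specular IR-LED glints near the pupil center.  Every generated frame carries
an analytic ground-truth pupil radius, so the detection and parameter
extraction stages can be validated against known truth.

The reflex model is piecewise: constant baseline until a physiological onset
latency after the flash, linear constriction to the minimum, then exponential
redilation toward a plateau.  Under the 1-Hz flash train the effective
pre-flash baseline shrinks geometrically toward a steady state (pupillary
adaptation to repeated stimulation).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GROUP_LABELS = ("healthy", "diabetic_no_CAN", "diabetic_CAN")


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PLRModel:
    """Generative pupil-light-reflex parameters (ground truth for tests).

    Parameters
    ----------
    baseline_radius_px : float
        Dark-adapted pupil radius before the first flash, in pixels.
    min_radius_px : float
        Radius at the largest constriction after a flash from the initial
        baseline; for adapted flashes the minimum scales proportionally.
    latency_onset_s : float
        Physiological delay between the flash and the start of constriction.
    time_to_min_s : float
        Time from the flash to the largest constriction.
    recovery_plateau_fraction : float
        Asymptote of the exponential redilation, as a fraction of the
        (effective) baseline.  Must exceed 0.75 for the measured
        75%-of-baseline plateau crossing to exist.
    recovery_tau_s : float
        Time constant of the exponential redilation.
    train_adaptation_fraction : float
        Steady-state pre-flash baseline under the 1-Hz train, as a fraction
        of the initial baseline (1.0 = no adaptation).
    train_adaptation_rate : float
        Geometric ratio with which the pre-flash baseline approaches its
        steady state from one flash to the next.
    """

    baseline_radius_px: float = 60.0
    min_radius_px: float = 44.0
    latency_onset_s: float = 0.2
    time_to_min_s: float = 0.9
    recovery_plateau_fraction: float = 0.83
    recovery_tau_s: float = 5.0
    train_adaptation_fraction: float = 1.0
    train_adaptation_rate: float = 0.7

    def __post_init__(self) -> None:
        if self.baseline_radius_px <= 0 or self.min_radius_px <= 0:
            raise ValueError("radii must be positive")
        if self.min_radius_px >= self.baseline_radius_px:
            raise ValueError("min_radius_px must be < baseline_radius_px")
        if self.latency_onset_s < 0:
            raise ValueError("latency_onset_s must be >= 0")
        if self.time_to_min_s <= self.latency_onset_s:
            raise ValueError("time_to_min_s must exceed latency_onset_s")
        if not 0.0 < self.recovery_plateau_fraction <= 1.0:
            raise ValueError("recovery_plateau_fraction must be in (0, 1]")
        if self.recovery_tau_s <= 0:
            raise ValueError("recovery_tau_s must be positive")
        if not 0.0 < self.train_adaptation_fraction <= 1.0:
            raise ValueError("train_adaptation_fraction must be in (0, 1]")
        if not 0.0 < self.train_adaptation_rate < 1.0:
            raise ValueError("train_adaptation_rate must be in (0, 1)")
        plateau = self.recovery_plateau_fraction * self.baseline_radius_px
        if plateau < self.min_radius_px:
            raise ValueError("plateau radius must be >= min_radius_px")


@dataclass(frozen=True)
class FlashProtocol:
    """Stimulus timing: flash instants, fixed 10 ms / 250 cd flashes."""

    flash_times_s: tuple[float, ...]
    recording_duration_s: float
    fps: float = 30.0
    flash_duration_ms: float = 10.0
    flash_intensity_cd: float = 250.0

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.flash_times_s)
        object.__setattr__(self, "flash_times_s", times)
        if not times:
            raise ValueError("at least one flash is required")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("flash times must be strictly increasing")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if times[-1] >= self.recording_duration_s:
            raise ValueError("recording must cover all flashes")

    @property
    def n_flashes(self) -> int:
        return len(self.flash_times_s)

    @property
    def n_frames(self) -> int:
        return int(round(self.recording_duration_s * self.fps))


def single_flash_protocol(flash_time_s: float = 0.5,
                          recording_duration_s: float = 3.0,
                          fps: float = 30.0) -> FlashProtocol:
    """One flash, 3 s recording (dark-adapted single-flash experiment)."""
    return FlashProtocol((flash_time_s,), recording_duration_s, fps)


def flash_train_protocol(first_flash_s: float = 1.0,
                         n_flashes: int = 25,
                         interval_s: float = 1.0,
                         recording_duration_s: float = 30.0,
                         fps: float = 30.0) -> FlashProtocol:
    """25 flashes at 1 Hz, 30 s recording (flash-train experiment)."""
    times = tuple(first_flash_s + i * interval_s for i in range(n_flashes))
    return FlashProtocol(times, recording_duration_s, fps)


def healthy_train_model() -> PLRModel:
    """Default generative model for the 25-flash protocol.

    Faster per-window dynamics than the single-flash default so that each
    1-s inter-flash window contains a complete constriction/redilation cycle,
    with geometric baseline adaptation toward 55% of the initial baseline.
    """
    return PLRModel(
        baseline_radius_px=60.0,
        min_radius_px=42.0,
        latency_onset_s=0.25,
        time_to_min_s=0.68,
        recovery_plateau_fraction=0.83,
        recovery_tau_s=0.12,
        train_adaptation_fraction=0.55,
        train_adaptation_rate=0.7,
    )


@dataclass(frozen=True)
class EyeSceneSpec:
    """Static appearance of the rendered eye.

    Gray levels are 8-bit.  The pupil is rendered at gray 35 (the level the
    recording geometry produces for every subject under fixed IR
    illumination); four glints sit symmetrically about the pupil center.
    """

    image_size_px: tuple[int, int] = (240, 320)
    pupil_center_px: tuple[float, float] = (120.0, 160.0)
    iris_radius_px: float = 110.0
    pupil_gray: int = 35
    iris_gray: int = 100
    background_gray: int = 30
    glint_offsets_px: tuple[tuple[float, float], ...] = (
        (-8.0, -8.0), (-8.0, 8.0), (8.0, -8.0), (8.0, 8.0))
    glint_radius_px: float = 3.0
    glint_gray: int = 250
    eyelid_coverage_fraction: float = 0.0
    eyelid_gray: int = 90
    noise_sigma_gray: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size_px
        cy, cx = self.pupil_center_px
        r = self.iris_radius_px
        if r <= 0 or self.glint_radius_px <= 0:
            raise ValueError("radii must be positive")
        if not (cy - r >= 0 and cy + r <= h - 1 and
                cx - r >= 0 and cx + r <= w - 1):
            raise ValueError("iris annulus must lie fully inside the image")
        if not self.pupil_gray < self.iris_gray < self.glint_gray:
            raise ValueError("require pupil_gray < iris_gray < glint_gray")
        if not 0.0 <= self.eyelid_coverage_fraction < 0.5:
            raise ValueError(
                "eyelid coverage must leave at least half the pupil "
                "circumference visible (fraction < 0.5)")
        if self.noise_sigma_gray < 0:
            raise ValueError("noise_sigma_gray must be >= 0")


@dataclass(frozen=True)
class GroundTruthTrace:
    """Per-frame true pupil radius, with blink frames rendered eye-closed."""

    times_s: np.ndarray
    radii_px: np.ndarray
    blink_frames: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        times = np.asarray(self.times_s, dtype=float)
        radii = np.asarray(self.radii_px, dtype=float)
        object.__setattr__(self, "times_s", times)
        object.__setattr__(self, "radii_px", radii)
        object.__setattr__(self, "blink_frames", frozenset(self.blink_frames))
        if times.shape != radii.shape:
            raise ValueError("times and radii must have equal length")
        if times.size == 0:
            raise ValueError("trace must be non-empty")

    def __len__(self) -> int:
        return int(self.times_s.size)


# --------------------------------------------------------------------------
# dynamics
# --------------------------------------------------------------------------

def effective_baselines(model: PLRModel, n_flashes: int) -> np.ndarray:
    """Pre-flash effective baseline for flashes 1..n (geometric adaptation).

    B_k = B_inf + (B_1 - B_inf) * rate**(k-1) with
    B_inf = train_adaptation_fraction * B_1.
    """
    b0 = model.baseline_radius_px
    b_inf = model.train_adaptation_fraction * b0
    k = np.arange(n_flashes)
    return b_inf + (b0 - b_inf) * model.train_adaptation_rate ** k


def plr_radius(model: PLRModel, protocol: FlashProtocol, t):
    """True pupil radius at time(s) ``t`` (seconds) under the given protocol.

    Piecewise per flash window: effective baseline until the onset latency,
    linear constriction to the (proportionally adapted) minimum, exponential
    redilation toward the next window's baseline (toward
    ``recovery_plateau_fraction`` x baseline for the final window).
    """
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    if np.any(t_arr < 0) or np.any(t_arr > protocol.recording_duration_s):
        raise ValueError("t outside the recording interval")

    flashes = np.asarray(protocol.flash_times_s)
    n = flashes.size
    bases = effective_baselines(model, n)
    min_frac = model.min_radius_px / model.baseline_radius_px
    mins = bases * min_frac
    # recovery target: next effective baseline; plateau for the last window
    targets = np.empty(n)
    targets[:-1] = bases[1:]
    targets[-1] = model.recovery_plateau_fraction * bases[-1]

    win = np.searchsorted(flashes, t_arr, side="right") - 1
    out = np.empty_like(t_arr)
    pre = win < 0
    out[pre] = bases[0]
    active = ~pre
    k = win[active]
    tl = t_arr[active] - flashes[k]
    bk, mk, rk = bases[k], mins[k], targets[k]
    lat, tmin, tau = (model.latency_onset_s, model.time_to_min_s,
                      model.recovery_tau_s)
    r = np.where(
        tl < lat,
        bk,
        np.where(
            tl < tmin,
            bk + (mk - bk) * (tl - lat) / (tmin - lat),
            rk - (rk - mk) * np.exp(-(tl - tmin) / tau),
        ),
    )
    out[active] = r
    return float(out[0]) if scalar else out


def generate_ground_truth(model: PLRModel, protocol: FlashProtocol,
                          fps: float | None = None,
                          blink_intervals: Sequence[tuple[int, int]] = (),
                          ) -> GroundTruthTrace:
    """Sample the analytic reflex at frame times; mark blink frames.

    ``blink_intervals`` are inclusive (start_frame, end_frame) pairs during
    which the eye is rendered closed.  Deterministic given its arguments.
    """
    if fps is None:
        fps = protocol.fps
    n = int(round(protocol.recording_duration_s * fps))
    times = np.arange(n) / fps
    radii = plr_radius(model, protocol, times)
    blinks: set[int] = set()
    for start, end in blink_intervals:
        if start < 0 or end >= n or end < start:
            raise ValueError(f"blink interval ({start}, {end}) out of range")
        blinks.update(range(start, end + 1))
    return GroundTruthTrace(times, radii, frozenset(blinks))


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def _disk_coverage(dist: np.ndarray, radius: float) -> np.ndarray:
    # fractional pixel coverage of a disk boundary, ~1 px anti-alias band
    return np.clip(radius - dist + 0.5, 0.0, 1.0)


def render_eye_frame(scene: EyeSceneSpec, pupil_radius_px: float,
                     blink: bool = False,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Render one 8-bit grayscale eye frame with the given pupil radius.

    Anti-aliased pupil disk on an iris annulus, four glints, optional eyelid
    occluder over the top of the pupil, additive clipped Gaussian noise.
    ``blink=True`` renders a fully occluded (eyelid-gray) frame.
    """
    if not blink and pupil_radius_px >= scene.iris_radius_px:
        raise ValueError("pupil radius must be smaller than the iris radius")
    h, w = scene.image_size_px
    if blink:
        img = np.full((h, w), float(scene.eyelid_gray))
    else:
        cy, cx = scene.pupil_center_px
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        d = np.hypot(yy - cy, xx - cx)
        img = np.full((h, w), float(scene.background_gray))
        cov_iris = _disk_coverage(d, scene.iris_radius_px)
        img += cov_iris * (scene.iris_gray - scene.background_gray)
        cov_pupil = _disk_coverage(d, pupil_radius_px)
        img += cov_pupil * (scene.pupil_gray - scene.iris_gray)
        for gy, gx in scene.glint_offsets_px:
            dg = np.hypot(yy - (cy + gy), xx - (cx + gx))
            cov = _disk_coverage(dg, scene.glint_radius_px)
            img = img + cov * (scene.glint_gray - img)
        if scene.eyelid_coverage_fraction > 0:
            lid_edge = (cy - pupil_radius_px +
                        scene.eyelid_coverage_fraction * 2 * pupil_radius_px)
            cov_lid = np.clip(lid_edge - yy + 0.5, 0.0, 1.0)
            img = img + cov_lid * (scene.eyelid_gray - img)
    if scene.noise_sigma_gray > 0:
        if rng is None:
            rng = np.random.default_rng(scene.seed)
        img = img + rng.normal(0.0, scene.noise_sigma_gray, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def render_sequence(scene: EyeSceneSpec,
                    truth: GroundTruthTrace) -> np.ndarray:
    """Render one frame per ground-truth sample; deterministic under seed."""
    if len(truth) == 0:
        raise ValueError("truth trace is empty")
    rng = np.random.default_rng(scene.seed)
    frames = np.empty((len(truth), *scene.image_size_px), dtype=np.uint8)
    for i, radius in enumerate(truth.radii_px):
        frames[i] = render_eye_frame(scene, float(radius),
                                     blink=i in truth.blink_frames, rng=rng)
    return frames


# --------------------------------------------------------------------------
# synthetic cohorts
# --------------------------------------------------------------------------

_MODEL_FIELDS = [f.name for f in dataclasses.fields(PLRModel)]


def default_group_specs(iris_radius_px: float = 110.0) -> dict:
    """Per-group PLR parameter distributions (mean, SD) for cohort sampling.

    Baseline and minimum radii are anchored to the published pupil/iris
    ratios of the three groups (healthy 0.55/0.40, diabetic without CAN
    0.42/0.30, diabetic with CAN 0.35/0.26, each with the reported SDs),
    scaled by the scene iris radius; time parameters follow the reported
    single-flash latencies.
    """
    def radial(mean_ratio, sd_ratio):
        return (mean_ratio * iris_radius_px, sd_ratio * iris_radius_px)

    return {
        "healthy": {
            "baseline_radius_px": radial(0.55, 0.056),
            "min_radius_px": radial(0.40, 0.050),
            "latency_onset_s": (0.10, 0.04),
            "time_to_min_s": (0.90, 0.147),
            "recovery_plateau_fraction": (0.83, 0.02),
            "recovery_tau_s": (5.0, 1.0),
        },
        "diabetic_no_CAN": {
            "baseline_radius_px": radial(0.42, 0.045),
            "min_radius_px": radial(0.30, 0.031),
            "latency_onset_s": (0.15, 0.04),
            "time_to_min_s": (1.01, 0.192),
            "recovery_plateau_fraction": (0.83, 0.02),
            "recovery_tau_s": (5.4, 1.2),
        },
        "diabetic_CAN": {
            "baseline_radius_px": radial(0.35, 0.077),
            "min_radius_px": radial(0.26, 0.065),
            "latency_onset_s": (0.18, 0.05),
            "time_to_min_s": (0.91, 0.089),
            "recovery_plateau_fraction": (0.83, 0.02),
            "recovery_tau_s": (4.2, 0.9),
        },
    }


def generate_synthetic_cohort(group_specs: Mapping[str, Mapping] | None = None,
                              n_per_group=None,
                              seed: int = 0) -> pd.DataFrame:
    """Sample per-subject PLR models for each group.

    Parameters are drawn from per-group normal distributions and clipped to
    the model's validity region (minimum strictly below baseline, positive
    time constants, plateau fraction above the 75% crossing level).

    Returns a table with ``subject_id``, ``group`` and one column per
    PLRModel field.
    """
    if group_specs is None:
        group_specs = default_group_specs()
    if n_per_group is None:
        n_per_group = {"healthy": 16, "diabetic_no_CAN": 16,
                       "diabetic_CAN": 8}
    if isinstance(n_per_group, int):
        n_per_group = {g: n_per_group for g in group_specs}
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for group, spec in group_specs.items():
        n = int(n_per_group.get(group, 0))
        if n <= 0:
            raise ValueError(f"n_per_group for '{group}' must be positive")
        for _ in range(n):
            params = {f.name: f.default for f in dataclasses.fields(PLRModel)}
            for name, (mean, sd) in spec.items():
                params[name] = float(rng.normal(mean, sd))
            # clip into the model's validity region
            params["baseline_radius_px"] = max(params["baseline_radius_px"],
                                               10.0)
            params["min_radius_px"] = float(np.clip(
                params["min_radius_px"], 2.0,
                0.74 * params["baseline_radius_px"]))
            params["latency_onset_s"] = max(params["latency_onset_s"], 0.0)
            params["time_to_min_s"] = max(params["time_to_min_s"],
                                          params["latency_onset_s"] + 0.1)
            params["recovery_plateau_fraction"] = float(np.clip(
                params["recovery_plateau_fraction"], 0.78, 0.98))
            params["recovery_tau_s"] = max(params["recovery_tau_s"], 0.05)
            PLRModel(**params)  # validate
            rows.append({"subject_id": f"S{sid:03d}", "group": group,
                         **params})
            sid += 1
    return pd.DataFrame(rows)


def cohort_to_models(cohort: pd.DataFrame) -> list[tuple[str, str, PLRModel]]:
    """(subject_id, group, PLRModel) triples from a cohort table."""
    out = []
    for _, row in cohort.iterrows():
        model = PLRModel(**{f: row[f] for f in _MODEL_FIELDS})
        out.append((row["subject_id"], row["group"], model))
    return out


def extract_cohort_parameters(cohort: pd.DataFrame,
                              protocol: FlashProtocol | None = None,
                              iris_radius_px: float = 110.0) -> pd.DataFrame:
    """Single-flash parameter table for a synthetic cohort.

    Runs the analytic generator and the pupillogram extractor (no image
    rendering) for every subject, producing one parameter row per subject —
    the input shape expected by the cohort statistics stage.
    """
    from .trace import PupilTrace, extract_single_flash

    if protocol is None:
        protocol = single_flash_protocol()
    rows = []
    for sid, group, model in cohort_to_models(cohort):
        truth = generate_ground_truth(model, protocol)
        trace = PupilTrace(
            times_s=truth.times_s, radii_px=truth.radii_px,
            valid=np.ones(len(truth), dtype=bool), fps=protocol.fps,
            iris_radius_px=iris_radius_px, protocol=protocol)
        params = extract_single_flash(trace)
        rows.append({"subject_id": sid, "group": group, **params.to_dict()})
    return pd.DataFrame(rows)
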