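"""Pupil and iris radius detection on IR eye images.

Three-step offline algorithm per frame:

1. **Glint elimination** — the four IR-LED specular reflections are outlined
   with a high-threshold Canny detector (0.8 on normalized gradient
   magnitude), the closed contours are filled, and the masked pixels are
   replaced by the pupil gray level (35).
2. **Edge enhancement** — high-boost filtering (``A*I - box3(I)``) followed by
   a 0.6-gamma intensity transformation.
3. **Edge detection and circle fitting** — a 0.5-threshold Canny edge map is
   correlated with anti-aliased annular ring templates over a 20–90 px radius
   range at 0.2 px resolution; the (center, radius) pair maximizing the
   normalized correlation is the pupil fit.  The iris is localized separately
   with a circular Hough transform over a larger radius range.

Scores are normalized per unit ring mass, so a full, perfectly aligned edge
ring scores the same regardless of radius and partial occlusion lowers the
score proportionally to the missing arc.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, replace
import math

import numpy as np
from scipy import ndimage as ndi
from scipy.fft import irfft2, next_fast_len, rfft2
from skimage.feature import canny
from skimage.morphology import disk
from skimage.transform import hough_circle, hough_circle_peaks


class NoFitError(RuntimeError):
    """Raised when no circle can be fitted (empty edges, no Hough peak)."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EyeFrame:
    """One grayscale frame of the recording."""

    pixels: np.ndarray
    frame_index: int = 0
    time_s: float = 0.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest, 0-based, half-open intervals."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("ROI must have positive size")
        if self.top < 0 or self.left < 0:
            raise ValueError("ROI origin must be non-negative")


@dataclass(frozen=True)
class CircleFit:
    """Fitted circle: center (row, col) and radius in pixels, plus score."""

    center_px: tuple[float, float]
    radius_px: float
    score: float
    converged: bool = True


@dataclass(frozen=True)
class DetectConfig:
    """All tunable constants of the detection pipeline.

    The defaults are the algorithm's published operating point: Canny 0.8 for
    glints and 0.5 for the pupil edge (interpreted as the high hysteresis
    threshold on normalized gradient magnitude, low = 0.4 x high), fill gray
    35, 0.6-gamma, and a 20–90 px radius search at 0.2 px resolution.
    """

    glint_canny_threshold: float = 0.8
    glint_fill_gray: int = 35
    glint_dilation_px: int = 2
    boost_factor: float = 2.0
    gamma: float = 0.6
    edge_canny_threshold: float = 0.5
    canny_low_ratio: float = 0.4
    canny_sigma: float = 1.0
    radius_min_px: float = 20.0
    radius_max_px: float = 90.0
    radius_step_px: float = 0.2
    ring_thickness_px: float = 1.0
    coarse_radius_step_px: float = 2.0
    refine_center: bool = True
    refine_center_step_px: float = 0.25
    refine_center_halfwidth_px: float = 1.5
    refine_radius_subgrid: bool = True
    score_floor_fraction: float = 0.25
    full_ring_score: float = 0.7
    iris_radius_min_px: float = 95.0
    iris_radius_max_px: float = 140.0
    iris_accum_floor: float = 0.25

    def __post_init__(self) -> None:
        for name in ("glint_canny_threshold", "edge_canny_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 4.0:
                raise ValueError(f"{name} must be in (0, 4)")
        if self.boost_factor <= 1.0:
            raise ValueError("boost_factor must be > 1")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must be in (0, 1]")
        if self.radius_min_px >= self.radius_max_px:
            raise ValueError("radius_min_px must be < radius_max_px")
        if self.radius_step_px <= 0 or self.ring_thickness_px <= 0:
            raise ValueError("radius step and ring thickness must be > 0")

    @property
    def score_floor(self) -> float:
        return self.score_floor_fraction * self.full_ring_score

    def radius_grid(self) -> np.ndarray:
        """The discrete radius search grid (inclusive of both ends)."""
        n = int(math.floor((self.radius_max_px - self.radius_min_px)
                           / self.radius_step_px + 1e-9)) + 1
        return self.radius_min_px + self.radius_step_px * np.arange(n)


@dataclass(frozen=True)
class FrameMeasurement:
    """Per-frame result: pupil fit (and optional iris fit) with validity."""

    frame_index: int
    time_s: float
    pupil: CircleFit | None
    iris: CircleFit | None = None
    valid: bool = False


# --------------------------------------------------------------------------
# step 0: cropping
# --------------------------------------------------------------------------

def crop_roi(frame: EyeFrame | np.ndarray, roi: ROI) -> np.ndarray:
    """Extract the ROI subimage; downstream fits add back the ROI offset."""
    px = frame.pixels if isinstance(frame, EyeFrame) else np.asarray(frame)
    h, w = px.shape
    if roi.top + roi.height > h or roi.left + roi.width > w:
        raise ValueError(
            f"ROI {roi} exceeds frame bounds {(h, w)}")
    return px[roi.top:roi.top + roi.height, roi.left:roi.left + roi.width]


# --------------------------------------------------------------------------
# step 1: glint elimination
# --------------------------------------------------------------------------

def _close_against_border(edges: np.ndarray) -> np.ndarray:
    """Close contours cut by the image border so hole filling is defined."""
    out = edges.copy()
    for border in (out[0, :], out[-1, :], out[:, 0], out[:, -1]):
        idx = np.nonzero(border)[0]
        if idx.size >= 2:
            border[idx[0]:idx[-1] + 1] = True
    return out


def detect_glints(sub: np.ndarray, threshold: float = 0.8,
                  config: DetectConfig | None = None) -> np.ndarray:
    """Binary mask of the IR-LED reflections.

    High-threshold Canny outlines only the strongest (glint) edges; the
    closed one-pixel contours are filled and slightly dilated to cover the
    anti-aliased halo around each reflection.
    """
    if config is None:
        config = DetectConfig(glint_canny_threshold=threshold)
    img = np.asarray(sub, dtype=float) / 255.0
    high = config.glint_canny_threshold
    edges = canny(img, sigma=config.canny_sigma,
                  low_threshold=config.canny_low_ratio * high,
                  high_threshold=high)
    if not edges.any():
        return np.zeros_like(edges)
    closed = _close_against_border(edges)
    mask = ndi.binary_fill_holes(closed)
    if config.glint_dilation_px > 0:
        mask = ndi.binary_dilation(mask, disk(config.glint_dilation_px))
    return mask


def remove_glints(sub: np.ndarray, mask: np.ndarray,
                  fill_gray: int = 35) -> np.ndarray:
    """Replace masked (glint) pixels by the pupil gray level."""
    sub = np.asarray(sub)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != sub.shape:
        raise ValueError("mask shape must match the subimage")
    out = sub.copy()
    out[mask] = fill_gray
    return out


# --------------------------------------------------------------------------
# step 2: edge enhancement
# --------------------------------------------------------------------------

def enhance(sub: np.ndarray, boost_factor: float = 2.0,
            gamma: float = 0.6) -> np.ndarray:
    """High-boost filtering then gamma intensity transformation.

    ``A*I - box3(I)`` on normalized intensities, clipped to [0, 1], followed
    by ``s = r**gamma``; returned as 8-bit.
    """
    if boost_factor <= 1.0:
        raise ValueError("boost_factor must be > 1")
    img = np.asarray(sub, dtype=float) / 255.0
    blurred = ndi.uniform_filter(img, size=3, mode="nearest")
    hb = np.clip(boost_factor * img - blurred, 0.0, 1.0)
    out = hb ** gamma
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)


# --------------------------------------------------------------------------
# step 3: edge detection
# --------------------------------------------------------------------------

def pupil_edges(enhanced: np.ndarray, threshold: float = 0.5,
                config: DetectConfig | None = None) -> np.ndarray:
    """Canny edge map of the pupil-iris frontier on the enhanced image."""
    if config is None:
        config = DetectConfig(edge_canny_threshold=threshold)
    img = np.asarray(enhanced, dtype=float) / 255.0
    high = config.edge_canny_threshold
    return canny(img, sigma=config.canny_sigma,
                 low_threshold=config.canny_low_ratio * high,
                 high_threshold=high)


# --------------------------------------------------------------------------
# circle-template correlation fit
# --------------------------------------------------------------------------

def _ring_template(radius: float, half_width: float) -> np.ndarray:
    """Anti-aliased annular ring: tent weight in the radial direction."""
    r_out = int(math.ceil(radius + half_width)) + 1
    side = 2 * r_out + 1
    yy, xx = np.mgrid[-r_out:r_out + 1, -r_out:r_out + 1].astype(float)
    d = np.hypot(yy, xx)
    return np.clip(1.0 - np.abs(d - radius) / half_width, 0.0, 1.0)


class RingCorrelator:
    """FFT cross-correlation of an edge map with a bank of ring templates.

    Template spectra are cached (LRU) per radius so that repeated fits on
    same-shaped frames — a video — reuse them.  Scores are the template-mass
    normalized correlation, i.e. the tent-weighted fraction of the ring lying
    on edge pixels.
    """

    def __init__(self, shape: tuple[int, int], config: DetectConfig,
                 max_cache: int = 400):
        self.shape = shape
        self.config = config
        pad = int(math.ceil(config.radius_max_px +
                            self._half_width(coarse=True))) + 2
        self.fshape = (next_fast_len(shape[0] + pad),
                       next_fast_len(shape[1] + pad))
        self._cache: OrderedDict = OrderedDict()
        self._max_cache = max_cache

    def _half_width(self, coarse: bool) -> float:
        hw = (self.config.ring_thickness_px + 1.0) / 2.0
        if coarse:
            # widen the coarse tent so adjacent coarse radii overlap the peak
            hw = max(hw, self.config.coarse_radius_step_px / 2.0 + 0.5)
        return hw

    def _template_fft(self, radius: float, coarse: bool):
        key = (round(radius, 3), coarse)
        if key in self._cache:
            self._cache.move_to_end(key)
            return self._cache[key]
        tmpl = _ring_template(radius, self._half_width(coarse))
        r_out = tmpl.shape[0] // 2
        wrapped = np.zeros(self.fshape)
        fh, fw = self.fshape
        for dy in range(-r_out, r_out + 1):
            wrapped[dy % fh, (np.arange(-r_out, r_out + 1)) % fw] += \
                tmpl[dy + r_out, :]
        entry = (rfft2(wrapped).astype(np.complex64), float(tmpl.sum()))
        self._cache[key] = entry
        if len(self._cache) > self._max_cache:
            self._cache.popitem(last=False)
        return entry

    def edges_fft(self, edges: np.ndarray):
        return rfft2(np.asarray(edges, dtype=float), s=self.fshape)

    def score_map(self, efft, radius: float, coarse: bool = False
                  ) -> np.ndarray:
        """Normalized score for every integer center position."""
        tfft, mass = self._template_fft(radius, coarse)
        full = irfft2(efft * tfft, s=self.fshape)
        h, w = self.shape
        return full[:h, :w] / mass


def _best_over_maps(score_fn, radii) -> tuple[float, tuple[int, int], float]:
    """Scan radii in ascending order, strict improvement — ties break toward
    the smaller radius; within a map, toward the first row-major cell."""
    best = (-np.inf, None, None)
    for r in radii:
        smap = score_fn(r)
        idx = np.unravel_index(int(np.argmax(smap)), smap.shape)
        s = float(smap[idx])
        if s > best[0]:
            best = (s, idx, float(r))
    return best


def _refine_fit(edges: np.ndarray, center: tuple[int, int], radius: float,
                config: DetectConfig) -> tuple[tuple[float, float], float,
                                               float]:
    """Sub-pixel center search on a fractional grid, same ring functional.

    Evaluates the tent-weighted ring score directly from edge-pixel
    distances for candidate centers on a ``refine_center_step_px`` grid and
    radii on the 0.2 px grid around the current fit.
    """
    ys, xs = np.nonzero(edges)
    cy0, cx0 = center
    hw = (config.ring_thickness_px + 1.0) / 2.0
    d0 = np.hypot(ys - cy0, xs - cx0)
    sel = np.abs(d0 - radius) < (4.0 + config.refine_center_halfwidth_px)
    ys, xs = ys[sel].astype(float), xs[sel].astype(float)
    if ys.size == 0:
        return (float(cy0), float(cx0)), radius, 0.0

    step = config.refine_center_step_px
    half = config.refine_center_halfwidth_px
    offs = np.arange(-half, half + step / 2, step)
    oy, ox = np.meshgrid(offs, offs, indexing="ij")
    cys = cy0 + oy.ravel()
    cxs = cx0 + ox.ravel()
    # distances: (n_centers, n_edge_px)
    d = np.hypot(ys[None, :] - cys[:, None], xs[None, :] - cxs[:, None])

    grid = config.radius_grid()
    rsel = grid[np.abs(grid - radius) <= 1.0 + 1e-9]
    best_s, best_c, best_r = -np.inf, (float(cy0), float(cx0)), radius
    best_i = 0
    for r in rsel:
        w = np.clip(1.0 - np.abs(d - r) / hw, 0.0, 1.0).sum(axis=1)
        w /= 2.0 * math.pi * r * hw
        i = int(np.argmax(w))
        if w[i] > best_s:
            best_s = float(w[i])
            best_c = (float(cys[i]), float(cxs[i]))
            best_r = float(r)
            best_i = i

    if config.refine_radius_subgrid:
        # parabolic vertex of the score profile across the radius grid,
        # clamped to half a grid step — sub-resolution radius estimate
        step = config.radius_step_px

        def s_at(r):
            w = np.clip(1.0 - np.abs(d[best_i] - r) / hw, 0.0, 1.0).sum()
            return w / (2.0 * math.pi * r * hw)

        vm, v0, vp = s_at(best_r - step), best_s, s_at(best_r + step)
        denom = vm - 2.0 * v0 + vp
        if denom < 0:
            delta = 0.5 * (vm - vp) / denom
            best_r += float(np.clip(delta, -0.5, 0.5)) * step
    return best_c, best_r, best_s


def fit_pupil_circle(edges: np.ndarray, config: DetectConfig | None = None,
                     correlator: RingCorrelator | None = None,
                     radius_window: tuple[float, float] | None = None,
                     ) -> CircleFit:
    """Staged circle-template search for the pupil boundary.

    Coarse scan (wide-tent rings every ``coarse_radius_step_px``) over all
    integer centers via FFT correlation, then a fine scan on the full 0.2 px
    radius grid near the coarse optimum, then optional sub-pixel center
    refinement.  With ``refine_center=False`` the result is exactly the
    maximizer over the integer-center × 0.2 px-radius grid.
    """
    if config is None:
        config = DetectConfig()
    edges = np.asarray(edges, dtype=bool)
    if not edges.any():
        raise NoFitError("empty edge map")
    if correlator is None or correlator.shape != edges.shape:
        correlator = RingCorrelator(edges.shape, config)
    efft = correlator.edges_fft(edges)

    grid = config.radius_grid()
    if radius_window is not None:
        lo, hi = radius_window
        sub = grid[(grid >= lo - 1e-9) & (grid <= hi + 1e-9)]
        if sub.size:
            grid = sub
    every = max(1, int(round(config.coarse_radius_step_px
                             / config.radius_step_px)))
    coarse = grid[::every]
    if coarse[-1] != grid[-1]:
        coarse = np.append(coarse, grid[-1])
    _, _, r_coarse = _best_over_maps(
        lambda r: correlator.score_map(efft, r, coarse=True), coarse)

    window = config.coarse_radius_step_px + 1.0
    fine = grid[np.abs(grid - r_coarse) <= window + 1e-9]
    score, idx, radius = _best_over_maps(
        lambda r: correlator.score_map(efft, r, coarse=False), fine)

    center = (float(idx[0]), float(idx[1]))
    if config.refine_center:
        center, radius, score = _refine_fit(edges, idx, radius, config)
    return CircleFit(center_px=center, radius_px=float(radius),
                     score=float(score),
                     converged=bool(score >= config.score_floor))


def exhaustive_circle_search(edges: np.ndarray,
                             config: DetectConfig | None = None) -> CircleFit:
    """Reference brute-force search: direct spatial correlation of every
    radius on the 0.2 px grid over every integer center.

    Independent of the staged FFT path (scipy.ndimage direct convolution);
    used as the correctness oracle for :func:`fit_pupil_circle`.
    """
    if config is None:
        config = DetectConfig()
    edges_f = np.asarray(edges, dtype=float)
    if not edges_f.any():
        raise NoFitError("empty edge map")
    hw = (config.ring_thickness_px + 1.0) / 2.0
    best = (-np.inf, None, None)
    for r in config.radius_grid():
        tmpl = _ring_template(float(r), hw)
        smap = ndi.convolve(edges_f, tmpl, mode="constant", cval=0.0)
        smap /= tmpl.sum()
        idx = np.unravel_index(int(np.argmax(smap)), smap.shape)
        s = float(smap[idx])
        if s > best[0]:
            best = (s, idx, float(r))
    score, idx, radius = best
    return CircleFit(center_px=(float(idx[0]), float(idx[1])),
                     radius_px=radius, score=score,
                     converged=bool(score >= config.score_floor))


# --------------------------------------------------------------------------
# iris fit (circular Hough transform)
# --------------------------------------------------------------------------

def fit_iris_circle(sub: np.ndarray,
                    config: DetectConfig | None = None) -> CircleFit:
    """Hough-transform iris localization on a glint-free subimage.

    Canny edges (0.5 threshold), circular Hough accumulation over radii
    above the pupil search range, peak cell plus quadratic sub-cell radius
    interpolation.
    """
    if config is None:
        config = DetectConfig()
    img = np.asarray(sub, dtype=float) / 255.0
    high = config.edge_canny_threshold
    edges = canny(img, sigma=config.canny_sigma,
                  low_threshold=config.canny_low_ratio * high,
                  high_threshold=high)
    radii = np.arange(int(config.iris_radius_min_px),
                      int(config.iris_radius_max_px) + 1)
    accums = hough_circle(edges, radii)
    peaks = hough_circle_peaks(accums, radii, total_num_peaks=1)
    accum, cx, cy, rad = (a[0] if len(a) else None for a in peaks)
    if accum is None or accum < config.iris_accum_floor:
        raise NoFitError("no iris-scale circle found")
    ri = int(np.nonzero(radii == rad)[0][0])
    radius = float(rad)
    if 0 < ri < len(radii) - 1:
        vm, v0, vp = (float(accums[ri - 1, cy, cx]), float(accum),
                      float(accums[ri + 1, cy, cx]))
        denom = vm - 2.0 * v0 + vp
        if denom < 0:
            radius += 0.5 * (vm - vp) / denom
    return CircleFit(center_px=(float(cy), float(cx)), radius_px=radius,
                     score=float(accum), converged=True)


# --------------------------------------------------------------------------
# per-frame / per-sequence composition
# --------------------------------------------------------------------------

def measure_frame(frame: EyeFrame | np.ndarray, roi: ROI,
                  config: DetectConfig | None = None,
                  fit_iris: bool = False,
                  correlator: RingCorrelator | None = None,
                  radius_window: tuple[float, float] | None = None,
                  ) -> FrameMeasurement:
    """Full detection pipeline on one frame.

    Fit failures (blink, heavy occlusion) are flagged results
    (``valid=False``), not exceptions; configuration errors propagate.
    """
    if config is None:
        config = DetectConfig()
    if isinstance(frame, EyeFrame):
        index, time_s = frame.frame_index, frame.time_s
    else:
        index, time_s = 0, 0.0
    sub = crop_roi(frame, roi)
    mask = detect_glints(sub, config.glint_canny_threshold, config=config)
    cleaned = remove_glints(sub, mask, config.glint_fill_gray)
    enhanced = enhance(cleaned, config.boost_factor, config.gamma)
    edges = pupil_edges(enhanced, config.edge_canny_threshold, config=config)
    try:
        fit = fit_pupil_circle(edges, config, correlator=correlator,
                               radius_window=radius_window)
    except NoFitError:
        fit = None
    if fit is not None:
        fit = replace(fit, center_px=(fit.center_px[0] + roi.top,
                                      fit.center_px[1] + roi.left))
    iris = None
    if fit_iris:
        try:
            iris = fit_iris_circle(cleaned, config)
            iris = replace(iris, center_px=(iris.center_px[0] + roi.top,
                                            iris.center_px[1] + roi.left))
        except NoFitError:
            iris = None
    valid = fit is not None and fit.converged
    return FrameMeasurement(frame_index=index, time_s=time_s, pupil=fit,
                            iris=iris, valid=valid)


def measure_sequence(frames, roi: ROI, config: DetectConfig | None = None,
                     fps: float = 30.0, fit_iris: bool = True,
                     track: bool = True, track_halfwidth_px: float = 8.0,
                     ) -> tuple[list[FrameMeasurement], float | None]:
    """Measure every frame of a recording.

    The iris is fitted once, on the first valid frame, and reused for the
    recording.  When ``track`` is on, the radius search of each frame is
    restricted to a window around the previous valid radius, falling back to
    the full 20–90 px scan whenever the windowed fit does not converge.

    Returns the measurement list (frame order) and the iris radius (or None).
    """
    if config is None:
        config = DetectConfig()
    shape = None
    results: list[FrameMeasurement] = []
    iris_radius: float | None = None
    correlator: RingCorrelator | None = None
    prev_radius: float | None = None
    for i, frame in enumerate(frames):
        if isinstance(frame, EyeFrame):
            ef = frame
        else:
            ef = EyeFrame(pixels=frame, frame_index=i, time_s=i / fps)
        if correlator is None:
            correlator = RingCorrelator((roi.height, roi.width), config)
        window = None
        if track and prev_radius is not None:
            window = (prev_radius - track_halfwidth_px,
                      prev_radius + track_halfwidth_px)
        m = measure_frame(ef, roi, config, fit_iris=False,
                          correlator=correlator, radius_window=window)
        if window is not None and not m.valid:
            m = measure_frame(ef, roi, config, fit_iris=False,
                              correlator=correlator)
        if m.valid and iris_radius is None:
            sub = crop_roi(ef, roi)
            mask = detect_glints(sub, config.glint_canny_threshold,
                                 config=config)
            cleaned = remove_glints(sub, mask, config.glint_fill_gray)
            try:
                iris_fit = fit_iris_circle(cleaned, config)
                iris_radius = iris_fit.radius_px
                m = replace(m, iris=iris_fit)
            except NoFitError:
                pass
        if m.valid:
            prev_radius = m.pupil.radius_px
        results.append(m)
    return results, iris_radius
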