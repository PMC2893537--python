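# Methods

`pupilkit` implements a complete dynamic-pupillometry analysis chain for
infrared eye-video recordings of the pupil light reflex (PLR): a synthetic
scene/dynamics generator standing in for the recording hardware, per-frame
pupil and iris radius detection, pupillogram parameterization for a
single-flash and a 25-flash protocol, and the group statistics used to
compare healthy and diabetic cohorts. This note documents the models, the
numerical choices, and what the synthetic validation does and does not
establish.

## The reflex model (synthetic generator)

The generator's job is to provide recordings with *known* ground truth at
the acquisition conditions of the original instrument: 30 frames/s, 10 ms
flashes of 250 cd, one flash with a 3 s recording or 25 flashes at 1 Hz
with a 30 s recording, dark-adapted baseline.

The radius trajectory after each flash is piecewise:

- constant effective baseline `B_k` until a physiological onset latency
  `L` after flash `k`;
- linear constriction from `B_k` to the minimum `m_k` at time-to-minimum
  `T`;
- exponential redilation with time constant `tau` toward a recovery
  target.

For a single flash the recovery target is `p·B` with plateau fraction
`p in (0.75, 1]`, so the measured "latency to plateau" (the upward
crossing of 75% of baseline) exists and has a closed form:
`t_plateau = T + tau·ln((pB − m)/(pB − 0.75·B))`.

Under the 1 Hz train the effective pre-flash baseline adapts geometrically
toward a steady state,

    B_k = B_inf + (B_1 − B_inf) · rate^(k−1),   B_inf = f · B_1,

with steady-state fraction `f` (`train_adaptation_fraction`) and per-flash
ratio `rate` (`train_adaptation_rate`, default 0.7). Within the k-th 1-s
window the redilation relaxes toward the *next* baseline `B_{k+1}`
(toward `p·B_25` for the final window), which keeps the
frame-preceding-flash radius — the measured quantity — equal to the
effective baseline up to a sub-pixel recovery residual, and keeps the
trace free of inter-window jumps large enough to trip the blink detector.

Minima scale proportionally (`m_k = B_k · m/B`), i.e. the constriction
*fraction* is flash-invariant; this is the simplest mechanism that yields
distinct, predictable pre-10th and pre-25th flash values.

Default parameters (healthy single-flash): baseline 60 px, minimum 44 px,
onset latency 0.20 s, time-to-minimum 0.90 s, plateau fraction 0.83,
recovery tau 5.0 s. With an iris of 110 px these reproduce the magnitude
of the published healthy-group measures (pupil/iris ratio in darkness
0.55, ratio at largest constriction 0.40, plateau latency ≈ 1.85 s). The
train default (`healthy_train_model`) uses faster per-window dynamics
(time-to-minimum 0.68 s, tau 0.12 s) so each 1-s window contains a
complete cycle, with `f = 0.55`.

## Scene rendering

Frames are 8-bit grayscale, 240×320 by default (the source instrument's
image dimensions are unknown; all geometry is in pixels). The pupil disk
renders at gray 35 — the level the fixed IR illumination produces for
every subject — on an iris annulus at gray 100 over a dark cone interior
at gray 30, with four glints (gray 250, radius 3 px) symmetric about the
pupil center. Edges are anti-aliased by fractional pixel coverage over a
one-pixel band, which is what makes sub-pixel radius recovery a
well-posed target. Optional additions: an eyelid occluder covering a
stated fraction of the pupil's vertical extent from the top (at most half
the circumference may be hidden), additive clipped Gaussian noise, and
blink frames rendered as a fully closed (eyelid-gray) image.

The iris and background grays are package choices: the pupil–iris and
iris–background contrasts must stay below the 0.8 glint threshold on the
normalized gradient scale (see below) while remaining above the 0.5
pupil/iris edge threshold. At iris 100 / background 30 the three edge
classes separate cleanly: glints ≈ 2.1, iris rim ≈ 0.72, pupil–iris
≈ 0.67 before enhancement.

What the generator does **not** emulate: iris texture, corneal
refraction, gaze deviation and perspective foreshortening (real pupils
image as ellipses off-axis), illumination drift, and sensor artifacts
beyond white noise. Passing the synthetic suite therefore demonstrates
the correctness and numerical behavior of the algorithms at the stated
conditions, not field performance on clinical recordings.

## Detection

Per frame, inside a user-specified ROI:

1. **Glint elimination.** Canny with high hysteresis threshold 0.8
   outlines only the strongest edges (the specular IR reflections). The
   one-pixel contours are closed against the ROI border where cut,
   filled, dilated by 2 px to cover the anti-aliased halo, and the masked
   pixels replaced by gray 35.
2. **Enhancement.** High-boost filtering `A·I − box3(I)` (A = 2) on
   normalized intensities, clipped to [0,1], then a 0.6-gamma intensity
   transformation.
3. **Pupil edge + circle fit.** Canny at threshold 0.5 yields the
   pupil–iris frontier. Anti-aliased annular templates (tent-weighted,
   1 px thick) over radii 20–90 px in 0.2 px steps are cross-correlated
   with the edge map over all integer centers (FFT, cached template
   spectra); the score is normalized per unit ring mass so it is
   comparable across radii and degrades proportionally under occlusion.
   The staged search (coarse wide-tent radii every 2 px, then the full
   0.2 px grid near the coarse optimum) is exactly equivalent to brute
   force over the (integer center × radius grid) space — a contract the
   suite verifies against a direct spatial-convolution implementation.
4. **Refinement.** The center is then refined on a 0.25 px grid (±1.5 px)
   using the identical ring functional evaluated from edge-pixel
   distances, and the radius by parabolic interpolation of the score
   across the radius grid, clamped to half a step. Refinement is a
   separate stage: disabling it returns the pure grid maximizer.
5. **Iris.** Canny edges of the glint-free subimage feed a circular Hough
   transform over 95–140 px; the peak cell is refined by quadratic
   interpolation across radius. The iris is measured once per recording
   (first valid frame) and reused — ratio denominators are
   per-recording.

Canny convention: the published single thresholds (0.8, 0.5) are read as
the *high* hysteresis threshold on the gradient magnitude of the [0,1]
image after Gaussian smoothing (sigma = 1.0), with low = 0.4·high. The
gradient scale is scikit-image's (unnormalized Sobel of the smoothed
image). Ties in the circle search break toward the smaller radius;
within one score map, toward the first cell in row-major order. A fit
whose score falls below 25% of the nominal full-ring score (0.7) is
flagged unconverged — the blink/occlusion signal.

Measured behavior at these settings (recomputed by the suite and
`scripts/acceptance.py`): max radius error ≈ 0.03 px over the 20–90 px
grid on clean frames, ≈ 0.11 px under a 25% eyelid occluder, bit-level
insensitivity to glint removal, and per-frame runtime of roughly 0.1 s
(tracking mode) on one CPU.

For video, `measure_sequence` restricts each frame's radius scan to
±8 px around the previous valid radius, falling back to the full scan
whenever the windowed fit does not converge; this is a pure speed
optimization and does not change single-frame semantics.

## Pupillogram parameterization

Level crossings (onset = radius falling to 90% of the pre-flash value;
plateau = radius regaining 75% of it) are linearly interpolated between
adjacent *valid* frames — gaps are never bridged, and a blink can
therefore never fabricate a crossing. Minima are frame-aligned (no
interpolation), matching frame-based reporting. The pre-flash baseline is
the last valid frame strictly before the flash. The single-flash minimum
is searched in a 1.5 s post-flash window; train minima within each
flash's own 1 s window. The plateau radius is reported as the crossing
level itself (the published definition is ambiguous between the crossing
value and a later steady value; the crossing is used).

Two published quantities are under-defined and are exposed as
configuration rather than guessed:

- **Duration of constriction** has no stated endpoints (and the published
  group means exceed the latency-to-minimum, so onset→minimum cannot be
  it). Default: onset crossing to the first sustained redilation (three
  consecutive rising valid frames after the minimum); `to_minimum` and
  `to_plateau` are selectable.
- **Velocity of constriction** defaults to the literal definition,
  amplitude ÷ duration; an onset→minimum denominator is selectable.
  Velocity × duration = amplitude holds exactly as constructed.

Blink handling follows the published exclusion rule: maximal runs of
invalid frames (or frame-to-frame jumps above 10 px/frame) are blink
intervals, and a recording with more than three is refused outright.

## Cohort statistics

Per parameter: mean ± sample SD (n−1) by group; one-way ANOVA across the
three groups with Bonferroni post-hoc pairwise t-tests using the pooled
within-group variance on N−k degrees of freedom (p1: healthy vs diabetic
without CAN, p2: healthy vs with CAN); Kruskal–Wallis with tie correction
between the two diabetic groups (p3). Significance at alpha = 0.05 with
the source's marker notation (* / # / $ for p < 0.05 / 0.01 / 0.001); no
correction across parameters, matching the source analysis. Degenerate
all-constant input uses F = 0, p = 1 (and H = 0, p = 1).

These are deliberately written out from the classical formulas; the test
suite cross-checks them against scipy.stats to 1e-10 relative tolerance
and verifies the simulated type-I error at the null.

The synthetic cohort generator draws per-subject reflex models from
per-group normal distributions anchored to the published group means and
SDs of the pupil/iris ratios (healthy 0.55/0.40, without CAN 0.42/0.30,
with CAN 0.35/0.26), clipped to the model's validity region — these are
used as *distribution parameters* for power/null simulations, not as
reproduced clinical results.

## Problem sizes and determinism

Desk-scale validation uses: 15 rendered radii for the accuracy grid, 20
random 64×64 instances for search equivalence, 10 scenes for occlusion,
one 90-frame single-flash video and one 900-frame 25-flash video for
end-to-end recovery, and 1000 replicates for the type-I simulation —
sizes chosen so the whole suite re-runs in a few minutes on one CPU.
All randomness flows from explicit seeds; a seeded pipeline run is
byte-reproducible, and every run writes a manifest (config echo, seed,
version) sufficient to regenerate its outputs.

## Known limitations

- Circles only: no ellipse fitting, so off-axis gaze would bias radii.
- The adaptation model is phenomenological; it encodes *that* repeated
  stimulation shrinks the baseline geometrically, not the underlying
  autonomic mechanism.
- The score floor and blink-jump threshold are heuristics calibrated on
  the synthetic scenes; clinical recordings may need retuning.
- CAN status is an input label throughout; nothing here diagnoses CAN.
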