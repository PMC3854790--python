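# Methods

This note documents the models, estimators and numerical choices behind
`spermbeat`, and what the synthetic-data validation does and does not
establish about real recordings.

## Synthetic movies

The generator renders a single mouse sperm — elliptical head, a one-sided
hook bulge, and a flagellum — as a bright object on a dark background,
emulating stroboscopic dark-field movies. The flagellar shape is a
tangent-angle model

    psi(s, t) = psi0 + kappa_geom * s + A * sin(2*pi*(s/lambda - f*t))

integrated along arc length s from the tether point (trapezoid rule,
0.1 µm step; halving the step moves the 120 µm endpoint by < 0.1 µm). The
signed static curvature parameter kappa0 is defined hook-relative —
positive bends away from the hook ("anti-hook") — so internally
`kappa_geom = -hook_sign * kappa0`.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| flagellum length L | 120 µm | mouse sperm flagellum |
| head | 8 × 4 µm ellipse | mouse sperm head scale |
| beat frequency f | 6 Hz | reported beat frequency of tethered cells |
| wavelength λ | 120 µm | one wave on the flagellum |
| tangent amplitude A | 0.44 rad | calibrated so the midpoint peak-to-peak excursion is ~31 µm, the reported amplitude scale |
| static curvature κ₀ | 0 (grid up to ±0.01 µm⁻¹) | ±0.01 µm⁻¹ yields asymmetry indices ≈ ±0.3 rad, bracketing reported values (~0.26) |
| frame rates | 200 / 95 / 60 / 12 fps | the acquisition rates of waveform, flash, free-swim and Ca²⁺ recordings |
| pixel size | 1.0 µm/px | 10× objective + EMCCD-class sensor; configurable |
| intensities | background 100, head 1000, flagellum 0.6× | dark-field: the compact head scatters far more light than the ~1 µm flagellum |
| noise | additive Gaussian, σ = 20 counts (≈2% of range) | EMCCD read/excess noise proxy; tests push it to 10% |

Rendering is done on a 4× supersampled grid and block-averaged down
(pixel integration). This is not cosmetic: at 1 µm/px the head covers
only ~25 pixels, and naive boolean rasterization misorients the ellipse
by up to ±0.1 rad depending on angle and subpixel position — larger than
the index tolerances the pipeline is validated to. Photon (Poisson)
noise, motion blur within the strobe pulse, 3-D beating and rolling are
not modeled; the stroboscopic exposure is metadata only.

Free-swimming movies move the whole cell along a straight path with a
zero-mean lateral yaw oscillation; with `stage_follows` the net drift is
transferred to a logged stage offset, as when an experimenter keeps the
cell centered. Flash experiments switch the waveform parameters at a
given frame and emit a fluorescence trace that steps down at the flash.

Ground truth carries the analytic midlines and the asymmetry index
evaluated on them by the same definition the pipeline uses, so recovery
can be scored without circularity in geometry but with an identical index
convention.

## Segmentation and midline

* **Target-area threshold.** The threshold scan descends over the unique
  intensity values of the (lightly denoised, σ = 1 px Gaussian) frame and
  returns the highest threshold whose foreground reaches the expected
  cell area. Exact and resolution-independent; the frame minimum is not a
  valid threshold (it would select everything), so blank frames fail
  loudly. The expected area defaults to 350 µm², matching a 120 µm
  flagellum at ~1 µm thickness plus the head with a modest halo; it is a
  config value, in µm², converted to pixels.
* **Mask cleaning.** Largest 8-connected component, holes filled.
* **Midline.** The mask skeleton becomes an 8-connected graph with
  Euclidean edge weights; leaf branches shorter than 5 µm that end at a
  junction are pruned; the midline is the longest geodesic from the
  skeleton node nearest the head. Points within the annulus inner radius
  (8 µm) of the head centroid are trimmed so the trace starts at the
  neck, and the polyline is smoothed with a 5-point moving average using
  odd-reflection padding (preserves straight segments and endpoints).
  Traces shorter than 20 µm are rejected; within a movie, traces shorter
  than 70% of the movie-median length are dropped as self-crossing
  artifacts. Dropped frames are never interpolated — windowed statistics
  simply skip them.
* **Head pose.** The head blob is the brightest connected region of the
  mask. Its axis is refined on the continuous intensity of the two *end
  slabs* of the head (|along-axis| within roughly 2.2–5 µm, both
  transverse sides): every along-axis column of the symmetric head has
  its transverse centroid on the axis, the mid-head region — where the
  one-sided hook sits — is excluded, and the two symmetric end cuts
  cancel each other's truncation bias while giving the fit a long lever
  arm. The hook side is the sign of the transverse third central moment
  of the full blob. For tethered movies the pose is fitted once on the
  temporal median image (4× spline-upsampled): the head is static by
  definition of tethering, the beating flagellum averages out of the
  median, and per-frame pose fits showed beat-phase-dependent error.
  Pose accuracy on the validation grid is ≤ 0.02 rad and ≤ 0.2 µm across
  orientations and noise up to 10% of the dynamic range.
* **Neck.** Centroid of the foreground inside an annulus of 16 µm inner /
  20 µm outer diameter around the head centroid — the annulus covers the
  head, so only the proximal flagellum remains in the band. The azimuth
  orients the symmetry axis tail-ward (flipping the axis flips the hook
  sign with it).

## Beat parameters

* **Asymmetry index** α = −hook · ∠(axis, head→midline-midpoint), radians.
  "Middle of the flagellum" is read as the arc-length midpoint of the
  traced midline (the only parameter-free reading); the axis of symmetry
  is the head principal axis oriented through the neck. With this
  hook-referenced sign, flipping the hook annotation negates α exactly,
  while mirroring the whole image leaves α unchanged (the bending and the
  hook side flip together) — both properties are tested. Units are
  radians, which puts reported values (~0.26) at a plausible ~15°.
* **Windowing.** Mean over ±0.5 s around the center frame, truncated at
  movie edges and at the flash; if truncation leaves less than a 300 ms
  window, a one-sided 300 ms window on the valid side is used. With a
  window covering the whole movie this reduces to the plain mean. The
  windowed index averages *signed* per-frame angles, so a symmetric beat
  alternating ±θ averages to ~0.
* **Frequency.** Hann-tapered periodogram of the mean-subtracted angle
  series, zero-frequency bin excluded, parabolic interpolation of the
  peak (1 s windows give 1 Hz bins otherwise). Constant series → 0.
* **Amplitude.** Peak-to-peak transverse distance of the flagellar
  midpoint to the symmetry axis across the window; a `tip` mode is
  provided since the reported amplitude could also refer to the tip.
* **Flash response.** Windowed index centered 1 s before vs 1 s after the
  flash (windows never cross it); the relative change post/pre is NaN when
  |pre| < 0.01 rad (the ratio is meaningless near zero).
* **Envelope.** Frames are resampled so the head centroid maps to the
  image center and the neck azimuth to angle 0, then reduced by maximum
  projection (envelope of all flagellar positions; mean available).
  Bilinear interpolation leaves sub-percent residuals in the bulk of the
  image; sharp edges can locally exceed any small pixel tolerance, which
  is why the alignment test scores the 99th percentile and the mean of
  the pixel difference.

## Motility

Head tracking is normalized cross-correlation of a head template
(±6 µm patch) within a ±10 µm search window around the previous position,
with 1-D parabolic subpixel refinement and template refresh every 10
frames; correlations below 0.5 flag the frame invalid, and more than 5
consecutive invalid frames abort the track. World coordinates are image
positions plus logged stage offsets. VSL uses the outermost valid frames
(first-to-last reading of "straight-line path") and requires ≥ 1 s of
track; it is invariant under rigid motion and time reversal.

## Photometry and calibration

F/F₀ is (raw − background) divided by its pre-event mean, making the
pre-event mean exactly 1 and the operation idempotent; the baseline uses
all pre-event samples (the number used in the original recordings is not
stated). Ratio traces divide donor by acceptor and normalize the ratio
the same way. Null-point calibration interpolates the zero crossing of
the fluorescence-change series in log concentration — indicator responses
are approximately log-linear — with a linear option; an exact zero on a
grid point is returned as-is, and a series that never changes sign raises
an out-of-range error naming the bracket.

## Study statistics

Values are summarized as mean ± sample s.d. (n−1); the 95% confidence
half-width is 1.96 × s.e.m. Group comparisons use the classic
pooled-variance two-sample Student's t test (two-sided, df = n₁+n₂−2),
with Welch's form as an option; zero pooled variance yields t = 0, p = 1
for equal means and ±inf, p = 0 otherwise. Percentages are rounded
half-up at the displayed precision, matching how count-derived rates are
conventionally printed; pooled rates sum successes and totals before
dividing.

## Validation scope and limitations

The test suite validates parameter recovery on the generator's grid:
static curvature κ₀ ∈ {0, ±0.0025, ±0.005, ±0.01} µm⁻¹ at noise up to 10%
of the dynamic range (index 0 ± 0.03 rad at κ₀ = 0, monotone in κ₀,
within 0.05 rad of the analytic oracle), frequency recovery for 3/6/10 Hz
at 200 fps within the 1 Hz spectral resolution, and VSL within 5% with
and without stage compensation. Movies of 0.5–1 s (100–200 frames) are
used for these checks and 4 s for the flash protocol; these sizes give
the windowed estimators full 1 s windows while keeping the suite quick.

Passing on synthetic data shows the estimators are internally consistent
and robust to the modeled noise; it does not certify performance on real
movies, where debris, multiple cells, uneven illumination, focus drift,
head rolling and genuinely 3-D beating occur and are not modeled. The
planar tangent-angle waveform is a deliberate simplification: real
flagella carry richer curvature profiles, and the asymmetry index — a
single projection of the waveform — is exactly the kind of summary that
transfers, which is why it, and not full waveform reconstruction, is the
validated output.
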