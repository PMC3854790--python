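# spermbeat

Quantification of sperm flagellar beating and motility from dark-field
time-lapse movies, with a synthetic-movie generator that provides analytic
ground truth for validation.

Mouse sperm have a hook-shaped head, which makes the *direction* of
flagellar bending observable: the flagellum can curve toward the hook
("pro-hook") or away from it ("anti-hook"). Ca²⁺-dependent switching
between symmetric and asymmetric beating underlies hyperactivated
motility, and quantifying it requires a pipeline that segments the cell,
traces the flagellar midline, and measures bending relative to the cell's
own symmetry axis. `spermbeat` implements that pipeline for head-tethered
cells, plus head tracking and straight-line velocity (VSL) for
free-swimming cells, baseline normalization of Ca²⁺-indicator photometry,
null-point calibration of resting [Ca²⁺]ᵢ, and the study-level summary
statistics used to compare genotypes.

## The asymmetry index

For each frame the cell silhouette is binarized by lowering the threshold
until the foreground reaches an expected cell area, skeletonized, and the
longest skeleton path from the head is taken as the flagellar midline.
With **c** the head centroid, **û** the cell symmetry axis (oriented
tail-ward through the neck) and **M** the point at 50% arc length of the
midline ("the middle of the flagellum"), the asymmetry index is the signed
angle

&nbsp;&nbsp;&nbsp;&nbsp;α = −h · ∠(**û**, **M** − **c**)

where h = ±1 is the hook side, so that anti-hook deflection is positive
and a symmetric beat averages to α = 0. Per-frame values are averaged in a
1 s window around each frame; near movie edges or a UV flash the window
shrinks to a one-sided ~300 ms window and never mixes pre- and post-flash
frames. Beat frequency is the dominant peak of the Hann-tapered
periodogram of the per-frame angle series; beat amplitude is the
peak-to-peak transverse excursion of the flagellar midpoint. The neck is
located with an annular mask around the head (16 µm inner / 20 µm outer
diameter), and beat envelopes are built by rotating every frame by the
neck azimuth about the head centroid and maximum-projecting.

VSL (straight-line velocity) is the Euclidean distance between the first
and last head positions of a track divided by elapsed time, after adding
recorded motorized-stage offsets back to the image-frame positions.

## A worked example

```sh
python examples/01_tethered_beat_analysis.py
```

simulates a tethered cell with an anti-hook static curvature of
0.0087 µm⁻¹ beating at 6 Hz, runs the full image pipeline, and prints

```
frames analyzed      : 200/200
asymmetry index (rad): +0.254   (ground truth +0.244)
beat frequency  (Hz) : 6.00   (ground truth 6.00)
beat amplitude  (µm) : 31.6
```

i.e. the pipeline recovers the planted asymmetry to ~0.01 rad, the beat
frequency exactly (1 Hz spectral resolution at a 1 s window), and a
midpoint excursion of ~31 µm. The other scripts in `examples/` cover the
UV-flash response, VSL tracking with stage compensation, envelope
superposition, photometry/calibration, and the summary statistics.

A thin CLI exposes the same stages for shell use
(`spermbeat simulate|segment|beat|envelope|track|photometry|stats`); each
run writes its outputs plus a `manifest.json` with the exact
configuration.

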