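# Methods

`cortios` analyses widefield cortical reflectance recordings from
lens-free, head-mounted contact imagers: stimulus-locked intrinsic optical
signals (IOS) on one hand, and kymographic erythrocyte velocimetry on the
other.  Because no public recordings from such devices exist, the package
ships a synthetic-data generator whose ground truth exercises every stage
of both analyses.

## The stimulus-locked IOS chain

A recording is an `(H, W, T)` grayscale stack with frame rate `F` (fps)
and pixel pitch `dP` (um).  Given stimulus onset frames, the chain is:

1. **Trial segmentation.** Each onset contributes a window of `n_pre`
   frames before and `n_post` from the onset; the onset frame sits at
   index `n_pre`.  Windows that overrun the recording are dropped with a
   warning.  At the reference acquisition rate (132.82 fps) the defaults
   are `n_pre = 400` (~3 s) and `n_post = 2600` (~19.6 s), i.e. 3000
   frames per trial; at other rates choose `n_pre`/`n_post` to preserve
   the ~3 s / ~19 s windows.
2. **Fractional change.** `dI/I0 = I / I0 - 1` per pixel and trial, with
   `I0` the per-pixel mean over the trial window, so each pixel's series
   has exactly zero temporal mean.  Pixels with non-positive mean become
   NaN and are excluded (never zero-filled) by all later reductions.
3. **Detrending** (per trial, before averaging, so trial-specific drifts
   cancel): `first_difference` (length-preserving, `y[0] = 0`), `linear`
   (least-squares line removed), or `none`.  `analyze_session` defaults to
   `linear`: first differencing turns the triphasic waveform into its
   derivative, relocating the extrema to inflection points, whereas the
   line fit leaves the waveform shape essentially intact (for the presets
   the induced extremum shift is < 1 ms, from the regression of the
   template on time).
4. **Trial averaging**, then **baseline normalisation**: subtraction of
   the per-pixel mean over the final 2 s before onset, so the prestimulus
   mean is zero.
5. **ROI traces**: spatial means over 20 x 20 px rectangles (150 x 150 um
   at 7.5 um pitch) placed in parenchyma — vascular pixels carry flow
   artifacts and are avoided.
6. **Smoothing**: centered 20-frame moving average with shrinking windows
   at the edges (length-preserving, no phase shift; even windows are
   offset by half a frame).
7. **Activity maps**: disjoint consecutive bins of 200 frames (1.5 s at
   132.82 fps) averaged into spatial maps; an incomplete tail bin is
   dropped.  The **contrast metric** clips the maps to the display LUT,
   rescales to 8-bit gray levels, and reports the population SD of the
   pooled histogram.
8. **Response features**: the initial dip is the global minimum within
   (0, 5] s after onset, the overshoot peak the global maximum after the
   dip, the undershoot the minimum after the peak; amplitudes are measured
   from the prestimulus mean.  A response is significant when the dip
   magnitude exceeds 0.5 prestimulus standard deviations.  If no
   dip < peak < undershoot ordering exists, features are reported absent
   rather than raising.

All operations are deterministic; stage order and parameters are recorded
in the result's provenance.

## The triphasic response model

The stimulus-locked response is modelled as three Gaussian lobes (initial
dip, overshoot, undershoot), zero before onset.  Extrema then fall exactly
at the lobe centres, which makes recovery testable.  Presets:

| preset | dip | peak | undershoot | amplitudes (dI/I0) | widths (s) |
|--------|-----|------|------------|--------------------|------------|
| green (volumetric, ~535 nm isosbestic) | 2.5 s | 7.0 s | 13.0 s | -2.0e-3 / +1.2e-3 / -0.5e-3 | 1.0 / 1.6 / 0.7 |
| red (oximetric, ~625 nm) | 1.0 s | 3.5 s | 7.0 s | -0.4e-3 / +0.35e-3 / -0.25e-3 | 0.4 / 0.9 / 0.9 |

Amplitudes sit inside the display LUT ranges used for each illumination
(green -2.3e-3..1.5e-3; red +-0.5e-3); widths follow the reported phase
durations.  Lobe overlap perturbs the analytic extrema by ~0.01-0.02 s,
below one frame period at the rates of interest.

## The synthetic-data generator

`make_vessel_scene` draws smooth spline vessels (parabolic absorbance
profile, ~35 % centerline attenuation) over a ~20,000-count parenchymal
baseline with a +-10 % smooth illumination field.  Every vessel pixel is
tagged with the arclength of its nearest centerline sample.

`render_ios_stack` implements the forward model

    frame(t) = baseline * (1 + response(t) * kernel + artifacts(t)) + noise

with a 2-D Gaussian activation kernel (default sigma 8 px) centred on the
parenchymal point farthest from vessels and borders, heartbeat (10 Hz) and
respiration (2 Hz) sinusoids with random phases, a linear drift, and
Gaussian noise with SD `shot_noise_scale * sqrt(intensity)`.

**Artifact and noise defaults are calibrated, not raw-sensor values.** The
generator exists to verify that the pipeline recovers the timing it
encodes, so its stimulus-locked SNR must leave that recovery identifiable:
an argmax over a lobe of amplitude `A` and width `w` wanders by roughly
`sqrt(4 * sigma * w^2 / A)` under trace noise `sigma`, and the flattest
preset lobe (red overshoot: A = 3.5e-4, w = 0.9 s) therefore requires the
smoothed, ROI- and trial-averaged trace noise to stay below ~5e-6.  The
defaults (shot scale 0.1, i.e. ~0.07 % relative per pixel-frame;
heartbeat 5e-5; respiration 2.5e-5; drift 2e-5/s) satisfy this with
margin for the 5-trial scaled protocol.  They emulate a deeply averaged
widefield signal.  Real raw data differ in ways the generator does not
model: per-pixel photon noise is an order of magnitude larger, artifacts
are spatially structured and vessel-locked rather than global, there is
motion, and the two illuminations mix oxy-/deoxyhemoglobin absorption
rather than scaling one template.  Passing tests therefore demonstrate
correctness of the computations and identifiability under the stated
conditions, not performance on raw in-vivo recordings.

`render_flow_movie` advects a sinusoidal absorbance pattern (default
period 60 um, contrast 0.3) along each vessel's arclength at a known
speed.  The modulation is a pure function of the phase `s - u*t`
(`u` = pixels of arclength per frame), so the pattern between frames `k`
and `k+n` is an exact shift by `u*n` pixels; a smooth Poisson-derived
contrast envelope rides on the same phase variable, perturbing band
strength without breaking the shift.  Parenchyma stays static.

All randomness flows through one integer seed; identical configurations
produce bit-identical outputs.

## Kymograph velocimetry

A kymograph samples a movie along a vessel polyline resampled at
unit-pixel arclength spacing (bilinear interpolation), one column per
frame, so one row step equals one pixel pitch.  Static structure is first
removed by subtracting a temporally averaged reference image (1000 frames
by default, ~7.5 s at 132.82 fps; window start selectable).

Striation orientation is estimated by Radon-transform variance
maximisation: the sinogram column whose projection has maximal variance is
aligned with the bands; for rows = arclength and columns = time the
striation angle is `90 deg - argmax`, refined by quadratic interpolation
on the default 0.5-degree grid.  The isotropy score (max/mean projection
variance) gates the estimate: white noise scores ~1.5-1.9 and clean bands
score > 30 in calibration, so the decision threshold is 2.5 and a
sub-threshold kymograph yields a no-estimate result rather than an
exception.  A structure-tensor estimator (mean-tensor eigenvector,
coherence-gated at 0.2) is available as an independent cross-check.

Speed follows from the striation angle:

    v = F * dP * tan|theta|,   tan(theta) = band slope in px/frame

reported in mm/s.  `theta` is signed (positive = motion toward increasing
arclength); the magnitude enters the speed.  This reading of the angle is
the one consistent with the units of the relation; the convention is fixed
here rather than exposed as a flag.

## Numerical choices and degenerate inputs

* Zero-mean of dI/I0 holds to ~1e-12 (float64 throughout the pipeline).
* Time-to-frame conversions round to the nearest frame.
* Even smoothing windows bias timings by half a frame period at most.
* Orientation estimates are clipped to a +-80 degree search range; angles
  at +-90 degrees (infinite speed) are rejected in `flow_speed`.
* Degenerate inputs raise early: empty schedules, windows that do not fit,
  degenerate LUTs, out-of-bounds ROIs/polylines, kymographs smaller than
  8 x 8 or containing non-finite values.
* The sensor's imaged area uses the active-array dimensions
  (900 x 1920 um = 1.728 mm^2), which the datasheet-style tables print
  (truncated to 1.72); pixel count x pitch would give 1.87 mm^2 — the two
  are inconsistent at the source, and the active-array figure is the one
  used.

## Scaled-down verification protocol

The stochastic end-to-end checks run on 64 x 64 px sessions at 30 fps with
5 trials, ISI drawn uniformly from 23-27 s (randomised, which decorrelates
artifact phase across trials exactly as a randomised ISI does at full
scale), `n_pre = 90` (3 s), `n_post = 570` (19 s), 45-frame activity-map
bins (1.5 s), and a 20 x 20 px ROI centred on the known activation centre.
These sizes keep a 10-session replicate set to well under a minute while
preserving the time structure of the full protocol (20 trials, 90-240 s
ISI, 132.82 fps) that the defaults describe.

## Known limitations

* No motion correction or image registration; the generator produces
  motion-free data.
* No spectral unmixing into HbO/HbR concentrations; illuminations are
  treated as independent channels.
* No optical point-spread or fiber-optic-plate transfer modelling, and no
  photon-accurate sensor simulation.
* Kymograph speeds assume bands move along the sampled polyline; off-axis
  flow components are not recovered.
* The grayscale-SD contrast metric depends on the LUT and 8-bit
  quantisation convention and is meaningful for comparisons within one
  convention only.
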