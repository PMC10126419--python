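# Methods

## Input model

A recording is an ordered stack of 2-D grayscale frames with a frame rate
(frames/s) and a pixel size (µm/pixel).  Color input is collapsed to
luminance with Rec. 601 weights; 16-bit input is kept at native depth.
Image series are ordered by natural numeric filename sort (`frame_2` before
`frame_10`), since lexicographic order would shuffle unpadded frame numbers.
Frame skipping (keep every k-th frame, dividing the frame rate by k) is
applied before trimming; trimming is anchored at the start of the recording,
the natural choice when acquisitions are started manually and run long.  At
least six frames are required, because morphology is read from the first six.

## Segmentation

The heart ROI is the bounding box (plus a small margin, default 3 px) of the
largest connected component above a primary intensity threshold on the
temporal maximum projection.  Thresholds are intensity *quantiles* (primary
default 0.90, secondary default 0.60 within the ROI) rather than absolute
values, making them robust to exposure differences between instruments.

Within the ROI, a per-frame secondary quantile threshold separates the
bright chambers from the dimmer atrioventricular canal (AVC).  The threshold
is recomputed per frame so chamber borders track intensity fluctuations
during contraction — per-frame areas are the whole point of the measurement.
Each chamber claims the supra-threshold connected component that maximally
overlaps its seed polygon; seeds are user-supplied in ROI coordinates (after
any rigid rotation about the ROI center, bilinear interpolation) and chamber
identity is taken from the config, never inferred.  When both seeds land on
the same component — e.g. the AVC stays above threshold and bridges the
chambers — the shared pixels are split by distance to the seed centroids and
a warning is emitted.  A chamber whose seed overlaps no component in more
than half the frames raises a segmentation failure naming the chamber.
Masks of the two chambers are disjoint in every frame by construction.

The quantile defaults are deliberate compromises: on a field of view where
the heart occupies only a few percent of pixels the 0.90 primary quantile
sits in the background tail and the heart (chambers + AVC) forms one
component, while within the much smaller ROI the appropriate secondary
quantile depends on how much of the box the chambers fill.  When the 0.60
default lands below the AVC intensity the chambers merge and are split by
the centroid rule; frequency and rhythm outputs are unaffected (each half
still tracks its own chamber), but chamber areas then include part of the
canal, diluting contractility estimates.  Users should raise the secondary
quantile until the canal drops out; the ROI preview exists for exactly this
kind of tuning.

## Heartbeat traces

Per chamber and frame, two signals are read: the sum of pixel intensities
inside the mask and the chamber area (pixel count × pixel size²).  Each is
linearly detrended — photobleaching and focus drift otherwise bias both
frequency estimators — then min–max normalized to [0, 1] (which also makes
every frequency output invariant to global intensity rescaling).  The
combined signal, the mean of the two, is what all estimators consume.  A
signal with no variation left after detrending is flagged constant and
propagates as a fit failure, never an exception.

## Frequency estimation

**Sine fit.**  `y(t) = A·sin(2πft + φ) + c`, refined by least squares
(`scipy.optimize.curve_fit`) from 30 starting frequencies spaced uniformly
over [0.25, min(6, Nyquist)] s⁻¹ — 6 s⁻¹ (360 beats/min) comfortably covers
embryonic zebrafish heart rates.  The refinement with the highest Pearson
correlation between raw and fitted signal wins.  The same sweep runs on the
first quarter of the trace, and whichever of the two fits scores higher on
its own support is kept (ties prefer the full fit, which uses more data);
this rescues recordings where the beat destabilizes partway through.  A
winning score below 0.1 is reported as a failure with no frequency.
Amplitude and frequency signs are canonicalized into the phase.

**FFT.**  The frequency of the largest-magnitude non-DC bin of the discrete
Fourier transform of the mean-subtracted combined signal; the "first
harmonic" is read as the dominant non-DC component, not literally bin 1
(bin 1 is always 1/duration regardless of signal).  Resolution is
frame_rate / n_samples.

The sine route is preferred at frame rates ≥ 9 f/s and may alias below
that; the FFT route is the default below 9 f/s (exact for on-bin
frequencies even at 6 f/s).  The cutoff is exposed as config.

**Autocorrelation score.**  The maximum of the unbiased normalized
autocorrelation over lags in [2 samples, n/2], clipped to [−1, 1]; a
data-quality metric (≈1 for periodic signals, small for noise, 0 for
constants by convention).  The exact functional form of this published
quality metric is not standardized; the max-over-lags convention used here
is implementation-defined.

## Phenotypes

- **Heart size**: median of the summed chamber areas over the first six
  frames — early frames, before bleaching, and a median so single bad
  segmentations cannot dominate.
- **Extremes**: max. dilation and max. contraction are the 95th and 5th
  percentiles of the per-frame area trace rather than the literal min/max,
  again to resist single-frame glitches.
- **Contractility**: absolute = dilation − contraction (µm²);
  relative = 100 × absolute / dilation (%).
- **Ejection fraction**: volumes are approximated from projected areas by
  V ∝ A^{3/2} (isotropic scaling), so
  EF = 100·(1 − (A_contr/A_dil)^{3/2}).  The exponent is configurable; 3/2
  is the default because the chambers scale roughly isotropically during
  contraction.  Note EF ≥ relative contractility always (1 − x^{3/2} ≥ 1 − x
  on (0,1)).
- **Arrhythmia score**: beats are peaks of the combined signal above its
  mid-range, separated by at least half the expected period when a frequency
  estimate exists.  The score is min(1, CV/0.5) where CV is the coefficient
  of variation (population SD) of the inter-beat intervals; fewer than three
  beats leave it indeterminate.  Scores ≥ 0.7 are flagged arrhythmic.  The
  score's functional form is implementation-defined — only the 0.7 flag
  threshold is anchored externally — and was chosen so the threshold has a
  natural meaning (flagging at an interval CV of 0.35; intervals alternating
  0.3/0.7 s give CV 0.4, score 0.8).
- **Conduction score**: |f_a − f_v| / max(f_a, f_v), with the FFT
  frequencies preferred below 9 f/s.  The measured ratio f_a/f_v is snapped
  to the nearest simple beat ratio (1:1, 3:2, 2:1, 3:1, 4:1; ±15% relative
  tolerance; reciprocal ratios are labelled with the chambers swapped) and,
  when a snap succeeds, the score is evaluated on the snapped ratio — a true
  2:1 block then scores exactly 0.5 and a 1:1 rhythm exactly 0.  This
  matters because 2:1 sits exactly at the 0.5 flag threshold: scoring the
  raw frequency estimates would let estimation noise flip the flag
  arbitrarily.  Unsnappable ("irregular") ratios are scored on the raw
  frequencies.  Scores ≥ 0.5 flag a conduction defect; a flagged 2:1 ratio
  is annotated "2:1 block (Mobitz-II-like)".  Like the arrhythmia score,
  the formula is implementation-defined with only the 0.5 threshold
  anchored.

## Brightfield module

Brightfield videos have no label to segment; the beating heart is instead
the dominant moving structure.  The 10 pixels with the highest temporal
standard deviation (ties broken in row-major order) *are* the heart
selection — no separate region step — and their averaged intensity trace is
detrended, normalized and passed through the same sine/FFT estimators.  The
reported heart rate uses the frame-rate-appropriate estimator.

## Synthetic generator

Two bright ellipses on a dark background, joined by a short, thinner AVC
bridge at a configurable fraction (default 0.5) of the chamber intensity.
Chamber areas follow A(t) = A₀ − amp·(1 + sin(2πft + φ))/2; both semi-axes
scale by √(A/A₀) so the rasterized area tracks the waveform (up to pixel
quantization).  Chambers carry a mild radial intensity falloff (bright core,
rim at 75%), as real fluorescence does, which also makes quantile thresholds
degrade gracefully instead of all-or-nothing at a flat plateau.  Additive
Gaussian pixel noise, seeded; identical parameters and seed give
bit-identical stacks.

Defaults mirror a realistic acquisition: 6 s at 6 f/s, 4 µm/pixel on a
120×160 field (the heart occupies a few percent of the frame, as in a
96-well image), atrium/ventricle base areas 6 000/8 000 µm² with contraction
amplitudes 2 100/3 200 µm² (35%/40% relative contractility), chamber
intensity 200 on background 10, noise SD 4.  Rhythm modes: `regular`;
`block_2to1` (ventricle locked to half the atrial frequency);
`flutter` (ventricle at half rate with the *atrial* amplitude reduced to
30% — fast shallow atrial beats); `irregular` (inter-beat intervals
log-normal with configurable CV, applied through a warped time axis shared
by both chambers).  Ground truth records per-frame chamber masks and areas
(always equal to mask pixel count × pixel size²), resolved frequencies, beat
times, and the heart size.

The brightfield variant renders a dark disk pulsing on a bright static
texture — motion contrast rather than fluorescence.

What the generator does *not* emulate: optical blur/PSF, out-of-focus
drift, yolk autofluorescence, neighboring embryos, heart looping or
translation within the frame, and intensity changes from wall thickening.
Passing tests therefore demonstrate correctness of the measurement chain on
idealized geometry, not robustness to every real-world artifact; the
validation correlations on synthetic data are upper bounds on real-data
performance.

The synthetic screen table draws control and null-compound heart rates from
one normal distribution (160 ± 10 beats/min, a typical 2-dpf range) and
shifts spiked compounds by a configurable number of control SDs with random
sign.

## Screen statistics

Fold change divides each embryo's heart rate by the mean of the DMSO
controls of the same experiment.  Z-scores use the sample (n−1) SD over the
fold changes of all compound rows of the screen — one pooled population for
power, not per-plate; control rows are standardized against the same scale
but never define it.  Hit thresholds are the two-sided standard-normal
critical values rounded to two decimals: 1.64 (90% CI, fewer false
negatives, primary screening) and 1.96 (95% CI, α = 0.05).

ToxScore = edema fraction + developmental-delay fraction +
1[|HR z| ≥ 1.64] + 2 × cardiac-arrest fraction, capped at 5; deceased
embryos score 5 outright.  The HR term is an indicator on the compound-level
z-score crossing the 90% CI threshold.

The validation correlation fits a least-squares line, drops points whose
residual exceeds 3 residual SDs (with a guard treating numerically
negligible residual spread as zero), and reports Pearson r on the remainder
plus the number excluded.

## Problem sizes and numerical choices

The test suite and acceptance script run synthetic studies at desk scale:
6-s videos on a 120×160 field (72 frames at 12 f/s or 36 at 6 f/s), batches
of 20–100 videos per question, and 1 000-compound screens with 3 replicates
— sizes chosen so a full run completes in a few minutes on one CPU while
leaving the statistical assertions well-powered.  Sine refinement is capped
at 400 function evaluations per start; diverged starts are skipped.
Degenerate inputs (constant signals, empty masks, zero control spread,
all-dark frames) are contracts with explicit error types, tested per module.

## Known limitations

- Chamber seeds come from a config file, not interactive drawing; authoring
  them requires one preview round-trip.
- A single global pair of threshold quantiles may not suit hearts whose
  chamber/background ratio changes drastically during the recording.
- The arrhythmia and conduction scores are implementation-defined stand-ins
  anchored only at their flag thresholds (0.7, 0.5); absolute values are not
  comparable to other tools.
- Brightfield analysis returns a single heart rate; chamber-specific outputs
  require fluorescence.
- AVI/MP4 decoding requires an imageio backend with video support; TIFF/PNG
  series, multi-page TIFF and GIF always work.
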