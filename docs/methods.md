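# Methods

This note documents the models, parameter choices and numerical decisions
behind `nirsmotion`, and what the synthetic benchmark does and does not
show about real recordings.

## Signal model and units

Time is in seconds, sample indexing 0-based, every segment/epoch interval
half-open `[start, end)` in samples. Intensity is strictly positive in
arbitrary units; optical density is `ΔOD(t) = −log10(I(t)/Ī)` with the
channel's temporal mean as the default reference (configurable: first
sample, or an explicit baseline). Concentrations are in μM via the modified
Beer–Lambert law with extinction coefficients from the Gratzer/Kollias
tabulation (690 nm: ε_HbO 276, ε_HbR 2051.96; 830 nm: 974, 693.04, in
cm⁻¹/M), source–detector distance 3 cm (typical adult separation; affects
only absolute scaling) and pathlength correction factor 6. The extinction
matrix is checked for conditioning (> 1e8 is rejected).

## HRF kernel

The injected response is a compact-support gamma variant

    h(t) = (t/p)^a · ((D−t)/(D−p))^(a(D−p)/p),  a = 3,

with peak time p = 6 s and duration D = 16 s: identically zero outside
(0, D), unique maximum of exactly 1 at t = p, smooth decay to zero at D.
This satisfies the design constraints (6 s peak, exactly 16 s support,
unit peak) without the truncation discontinuity a plain gamma density
would have at t = D; its width (FWHM ≈ 6 s) matches the canonical adult
HRF. Amplitudes are +10 μM HbO and −4 μM HbR in concentration mode; in
percent mode the peak fractional intensity change per wavelength is set
directly (0.9% at 690 nm, 2.0% at 830 nm) with the sign each wavelength
takes under the forward model (intensity rises at 690 nm, falls at 830 nm,
during activation).

## Stimulus design

Onsets follow the `gap_after_response` policy: onset-to-onset spacing is
`D + U(5, 10)` s, so trials never overlap and the block average is an
unbiased HRF estimator (~15 trials per 6-min run). The alternative
`onset_to_onset` policy draws the spacing itself from U(5, 10). The first
onset sits at a fixed 2 s guard, giving every trial a full pre-stimulus
baseline window, and all onsets are snapped to the sample grid — without
snapping, sub-sample misalignment biases the block-averaged peak by
~3·10⁻⁴ μM at 25 Hz, which would mask genuine round-trip errors in the
1e-6-tolerance recovery checks.

## Synthetic physiology and artifacts

Physiology is a deliberately simple stand-in, not a hemodynamic model:
sinusoids at 1 Hz (cardiac, 0.5% of baseline intensity), 0.25 Hz
(respiration, 1%) and 0.1 Hz (Mayer waves, 0.5%) with per-channel random
phases, a ±0.5%/min linear drift, and 0.2% white noise. A validation bound
guarantees strictly positive intensity.

Artifact events are Poisson with 6 events/min by default, mirroring the
emulated protocol of 35 deliberate movements per 6-min run. Two classes,
half/half by default:

* **spikes** — Gaussian-windowed oscillatory bursts (0.25–1 s, 2–5 Hz
  carrier), truncated to exactly zero outside ±4 envelope SDs so the
  labelled supports are exact;
* **baseline shifts** — steps ramped over 2 samples that persist to the
  end of the run.

Event amplitude is 0.4 OD ± 25% with random sign — several times the
physiological fluctuations, as in heavily contaminated recordings. One
temporal profile drives all channels, scaled by per-channel log-normal
gains whose ±2σ range spans [1/3, 3] (`gain_spread = 3`); an
independent-per-channel mode exists for stress testing. Randomness is
split into named substreams (onsets, physiology, artifacts) spawned from
one seed, so changing one spec never perturbs the other draws; an optional
`onset_seed` re-randomizes only the onsets against a fixed contamination.

## Detection

Every sample-aligned window of length `tMotion = 0.5 s` is flagged when its
`max − min` excursion exceeds `STDthresh = 20` times the channel's noise
scale **or** the absolute `AMPthresh = 5` OD; flagged windows are dilated
by `tMask = 1 s` on each side. The noise scale is the standard deviation of
the channel's *first-difference*. This matters: with the SD of the raw
time course, any artifact occupying more than ~0.25% of the run inflates σ
enough that the 20σ criterion can never fire, regardless of amplitude —
the threshold would be unusable at its standard value. The
first-difference scale tracks fast noise, so slow physiology and the
artifacts themselves do not mask abrupt excursions. At the default 5 OD
the amplitude criterion essentially never triggers (ΔOD of 5 is a 10⁵-fold
intensity change); it is interpreted as absolute OD. A brute-force
all-windows oracle in the test suite pins these semantics exactly.
Detection is recomputed from scratch on corrected data at each tPCA pass.

## Correction

**Targeted PCA.** Per pass: detect → union mask over channels → segment;
concatenate the OD rows at all artifact samples into one time×channel
matrix; column-center (the epoch mean must not masquerade as a component);
SVD; project out the smallest number of leading components whose
cumulative variance reaches `nsv = 0.97` ("remove up to 97%" read as
*at-least*; an *at-most* reading is available as a flag); restore the
column means; write the rows back and stitch; repeat for 3 total passes,
stopping early when nothing is detected. Fewer artifact rows than channels
is fine (thin SVD); zero artifact samples is an exact identity.

**Stitching.** `shift_segments` offsets each segment (left to right) by
the difference between the previous and current segment means, which
preserves within-segment differences. Its default uses full-segment means,
making every output segment mean equal the first segment's — the correct
reading of the segment-shift rule in isolation, and the behaviour its unit
tests pin. The correctors, however, stitch with *junction windows* (1 s on
each side of the boundary): the shift aligns the adjoining time points, as
in the MARA procedure the method descends from. The distinction matters at
realistic artifact density: with ~80 segments per run, forcing all segment
means equal acts as a high-pass at the segmentation rate and was measured
to halve the recovered HRF amplitude, whereas junction alignment leaves
slow structure intact. `join_window_s=None` restores full-segment means.

**Spline.** Each channel uses its own mask. Artifact segments get a cubic
smoothing spline fit (MATLAB `csaps` parameter p = 0.99, mapped to the
penalty weight λ = (1−p)/p with time in seconds) subtracted; segments
shorter than 5 samples (the smoothing-spline solver's minimum) fall back
to a linear detrend, logged, not an error.

**Wavelet.** Non-decimated (stationary) wavelet transform, 4-tap Daubechies
(`db2`), depth = the deepest level whose approximation band lies below
0.01 Hz (11 levels at 25 Hz), tying the untouched band to the later
high-pass cutoff. Runs are symmetric-padded to the needed multiple of
2^level and truncated after the inverse. Per detail level a robust
Gaussian (center = median, scale = IQR/1.349) is fitted and coefficients
beyond the two-tailed α = 0.1 quantile are zeroed. The redundant transform
is essential: with a decimated DWT the deep levels hold only a handful of
coefficients, the robust scale collapses, and the HRF's own coefficients
are zeroed wholesale. Even so, the method thresholds the HRF band and
measurably shrinks response amplitude on clean data — the known cost of a
maskless filter, and the reason it trails the targeted methods in the
benchmark.

**Whole-run PCA** applies the identical component-removal math to the full
time series (no stitching, no iteration) as the comparison baseline.

## Pipeline and metrics

Fixed order: OD → detect → correct → band-pass → MBLL → block average.
The band-pass is a 3rd-order Butterworth, 0.01–0.5 Hz, zero-phase
(forward–backward; causal mode available). Zero-phase filtering is padded
~95 s (3/(π·low_hz)) beyond the run so the 0.01 Hz corner's ~32 s settling
transient does not bleed into the data. Block averaging uses a
[−2 s, +16 s) window with pre-window-mean baseline subtraction; trials
truncated by run edges are dropped and counted. MSE (μM²) and Pearson r
(with r² reported alongside) are computed on HbO and HbR separately over
the [0, 16 s) post-onset window against the injected ground truth.

The benchmark groups its 25 runs into 5 "subjects": within a subject the
physiology and artifact realization is fixed and only the stimulus onsets
are redrawn, so paired method contrasts compare recoveries of the same
contamination — the design that makes the paired t-test informative.
Paired two-sided t-tests are computed across runs without multiple-testing
correction; identical inputs return (t = 0, p = 1), and a constant
non-zero difference (infinite t) is reported as a sign-capped statistic
with p = 0.

## Problem sizes and determinism

Default runs are 360 s at 25 Hz (9000 samples) on 8 channels; the standard
benchmark is 25 runs × 5 methods and completes in well under a minute on
one core. Every stochastic quantity derives from explicit integer seeds
through `numpy.random.SeedSequence`; identical configurations give
bit-identical outputs.

## Limitations

The generator's physiology is stationary and sinusoidal; real recordings
have nonstationary amplitudes, serial correlation, superficial-layer
contamination and task-correlated systemic effects, none of which are
modelled. Artifacts here are temporally uncorrelated with stimulation; the
targeted approach is expected to degrade when movement is stimulus-locked
(e.g. overt speech), since the artifact epochs then contain a biased share
of the response. Passing tests therefore demonstrate correctness of the
algorithms and their relative behaviour under the stated synthetic
conditions, not performance guarantees on arbitrary real data. Only
two-wavelength CW probes are supported; frequency/time-domain NIRS, GLM
estimation and short-separation regression are out of scope.
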