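# nirsmotion

Motion-artifact correction for continuous-wave functional near-infrared
spectroscopy (fNIRS), built around **targeted principal component analysis
(tPCA)** and the methods it is usually compared against: cubic-spline
artifact modelling and wavelet outlier filtering. The package is aimed at
fNIRS researchers who want to correct motion-contaminated optical-density
recordings, and at method developers who need a fully synthetic,
ground-truth-controlled benchmark of hemodynamic-response recovery.

## The problem and the methods

Subject movement decouples optodes from the scalp and produces signal
excursions far larger than the hemodynamic signals of interest — brief
high-frequency spikes and abrupt baseline shifts, typically shared across
channels. Left uncorrected they corrupt the block-averaged hemodynamic
response function (HRF).

Given a ΔOD matrix **Y** (time × channels):

* **Detection** flags, channel by channel, every window of length
  `tMotion = 0.5 s` whose excursion `max − min` exceeds
  `STDthresh·σ` (σ = SD of the channel's first-difference, `STDthresh = 20`)
  or the absolute `AMPthresh = 5` OD, and dilates flagged windows by
  `tMask = 1 s`.
* **tPCA** concatenates the rows of **Y** at all artifact samples (flagged
  on *any* channel) into one matrix, takes its SVD, and projects out the
  `N_tPCA` leading components — the smallest number holding ≥ 97% of the
  epoch variance. The corrected epochs are stitched back by mean-shifting
  adjacent segments so their adjoining time points align, and the whole
  detect → correct cycle is run 3 times.
* **Spline** fits a cubic smoothing spline (p = 0.99) to each artifact
  segment of each channel's own mask, subtracts it, and stitches.
* **Wavelet** decomposes each channel with a non-decimated discrete wavelet
  transform, models each detail level's coefficients as Gaussian
  (median/IQR-robust fit), and zeroes coefficients with two-tailed tail
  probability below α = 0.1.
* **MBLL**: ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR]·d·PPF converts
  optical density at 690/830 nm into HbO/HbR concentration changes (μM),
  with source–detector distance d = 3 cm and pathlength factor PPF = 6.

The synthetic generator emulates a 6-min, 25 Hz run on a 2-source ×
4-detector probe: a gamma-shaped HRF (peak 6 s, 16 s duration, +10 μM HbO,
−4 μM HbR) injected at randomized onsets (5–10 s inter-stimulus gap),
sinusoidal physiology + drift + noise, and Poisson motion events (6/min,
half spikes, half baseline shifts) driven by one shared temporal profile
with log-normal per-channel gains.

## Worked example

```python
import nirsmotion as nm

result = nm.run_benchmark(nm.BenchmarkConfig(seed=1, n_runs=25))
print(result.format_summary())
```

prints (abridged):

```
HRF recovery by correction method (mean +/- SD over runs)
  none     HbO: MSE =     7.1420 +/-    4.8985 uM^2   R^2 = 0.851 +/- 0.090
  pca      HbO: MSE =     9.9677 +/-    3.7598 uM^2   R^2 = 0.796 +/- 0.109
  spline   HbO: MSE =     4.2948 +/-    2.5099 uM^2   R^2 = 0.896 +/- 0.044
  tpca     HbO: MSE =     3.4143 +/-    2.0588 uM^2   R^2 = 0.980 +/- 0.023
  wavelet  HbO: MSE =     6.1820 +/-    1.5349 uM^2   R^2 = 0.952 +/- 0.027
Paired t-tests vs no correction (per chromophore):
  tpca     vs none     [HbO] mse: t =    -4.186, p = 0.000329
  tpca     vs none     [HbO] r2: t =     7.636, p = 7.12e-08
  ...
```

Each line is the mean ± SD over 25 synthetic runs of the mean squared error
(μM², lower is better) and squared Pearson correlation (higher is better)
between the block-averaged HbO estimate and the injected ground-truth HRF.
Targeted PCA recovers the response best; spline is next; wavelet filtering
suppresses spikes but leaves baseline shifts; whole-run PCA removes
hemodynamic signal along with the artifacts.

The same pipeline is scriptable from the shell:

```bash
nirsmotion simulate --seed 7 --format snirf --out-dir out/
nirsmotion correct out/run.snirf --method tpca --out-dir out/
nirsmotion evaluate out/run.snirf out/run.truth.json --method tpca --out-dir out/
nirsmotion benchmark --seed 1 --n-runs 25 --out-dir out/
```

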