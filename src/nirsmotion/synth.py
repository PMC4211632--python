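"""Synthetic motion-contaminated fNIRS recordings with a known injected HRF.

The generator emulates the benchmark conditions of the study this package
reproduces: 6-minute continuous-wave runs on a 2-source x 4-detector probe at
690/830 nm, a gamma-shaped hemodynamic response (peak 6 s, 16 s duration,
+10 uM HbO / -4 uM HbR), randomized stimulus onsets with a 5-10 s
inter-stimulus gap, sinusoidal physiology plus drift and white noise, and
motion artifacts of two classes (high-frequency spike bursts and baseline
shifts) that share one temporal profile across channels with per-channel
log-normal gains.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .core import (
    DEFAULT_WAVELENGTHS_NM,
    IntensityRecording,
    MBLLParams,
    ProbeGeometry,
    StimulusDesign,
    ValidationError,
    default_probe,
)

__all__ = [
    "HRFSpec", "ArtifactSpec", "PhysioSpec", "GeneratorConfig",
    "ArtifactEvent", "GroundTruth",
    "hrf_value", "make_hrf_regressor", "make_onsets", "inject_hrf",
    "generate_run", "write_ground_truth", "read_ground_truth",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class HRFSpec:
    """Shape and amplitude of the synthetic hemodynamic response.

    ``mode='concentration'`` injects the response through the MBLL forward
    model at (amp_hbo_um, amp_hbr_um); ``mode='percent'`` sets the peak
    fractional intensity change per wavelength directly (study values: 0.9%
    at 690 nm, 2% at 830 nm).
    """

    peak_time_s: float = 6.0
    duration_s: float = 16.0
    amp_hbo_um: float = 10.0
    amp_hbr_um: float = -4.0
    mode: str = "concentration"
    percent_amp_by_wavelength: dict[float, float] = field(
        default_factory=lambda: {690.0: 0.009, 830.0: 0.020})

    def __post_init__(self) -> None:
        if not 0 < self.peak_time_s < self.duration_s:
            raise ValidationError("require 0 < peak_time_s < duration_s")
        if self.mode not in ("concentration", "percent"):
            raise ValidationError("mode must be 'concentration' or 'percent'")
        if self.amp_hbo_um * self.amp_hbr_um > 0:
            warnings.warn("HbO and HbR amplitudes share a sign; outside the usual "
                          "physiological regime", stacklevel=2)


@dataclass
class ArtifactSpec:
    """Motion-artifact event model.

    ``rate_per_min`` is the expected Poisson event rate; the default of 6
    events/min mirrors the study protocol of 35 deliberate movements per
    6-minute run.  ``spike_fraction``
    splits events between high-frequency bursts (Gaussian-windowed 2-5 Hz
    oscillations lasting 0.25-1 s) and baseline shifts (steps smoothed over
    2 samples that persist to the end of the run).  With ``shared_profile``
    one temporal profile drives all channels, scaled by per-channel
    log-normal gains whose +/-2 SD range spans ``[1/gain_spread,
    gain_spread]``.
    """

    rate_per_min: float = 6.0
    spike_fraction: float = 0.5
    shared_profile: bool = True
    amplitude_od: float = 0.4
    gain_spread: float = 3.0

    def __post_init__(self) -> None:
        if self.rate_per_min < 0:
            raise ValidationError("rate_per_min must be >= 0")
        if not 0 <= self.spike_fraction <= 1:
            raise ValidationError("spike_fraction must be in [0, 1]")
        if self.amplitude_od <= 0:
            raise ValidationError("amplitude_od must be > 0")
        if self.gain_spread < 1:
            raise ValidationError("gain_spread must be >= 1")


@dataclass
class PhysioSpec:
    """Stand-in physiology: sinusoidal cardiac/respiratory/Mayer components
    with per-channel random phases, a linear drift, and white noise, all as
    fractional intensity modulations around ``baseline_intensity``."""

    cardiac_hz: float = 1.0
    resp_hz: float = 0.25
    mayer_hz: float = 0.1
    cardiac_amp: float = 0.005
    resp_amp: float = 0.01
    mayer_amp: float = 0.005
    drift_slope: float = 0.005  # fraction per minute, random sign per channel
    white_noise_sd: float = 0.002
    baseline_intensity: float = 1.0

    def __post_init__(self) -> None:
        for name in ("cardiac_amp", "resp_amp", "mayer_amp", "white_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.baseline_intensity <= 0:
            raise ValidationError("baseline_intensity must be > 0")

    def total_modulation_bound(self, run_length_s: float) -> float:
        return (self.cardiac_amp + self.resp_amp + self.mayer_amp
                + abs(self.drift_slope) * run_length_s / 60.0 / 2.0
                + 6.0 * self.white_noise_sd)


def quiet_physio() -> PhysioSpec:
    """Physiology spec with every stochastic/oscillatory component zeroed."""
    return PhysioSpec(cardiac_amp=0.0, resp_amp=0.0, mayer_amp=0.0,
                      drift_slope=0.0, white_noise_sd=0.0)


@dataclass
class GeneratorConfig:
    seed: int = 0
    #: When set, the stimulus-onset substream is seeded independently of
    #: ``seed`` so many onset randomizations can share one physiology +
    #: artifact realization (the study's per-subject design).
    onset_seed: int | None = None
    run_length_s: float = 360.0
    fs_hz: float = 25.0
    probe: ProbeGeometry = field(default_factory=default_probe)
    physio: PhysioSpec = field(default_factory=PhysioSpec)
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)
    hrf: HRFSpec = field(default_factory=HRFSpec)
    isi_min_s: float = 5.0
    isi_max_s: float = 10.0
    onset_policy: str = "gap_after_response"  # or "onset_to_onset"
    mbll: MBLLParams = field(default_factory=MBLLParams)

    def __post_init__(self) -> None:
        if self.isi_min_s > self.isi_max_s:
            raise ValidationError("isi_min_s must be <= isi_max_s")
        if self.onset_policy not in ("gap_after_response", "onset_to_onset"):
            raise ValidationError("unknown onset_policy")
        if self.run_length_s < self.hrf.duration_s:
            raise ValidationError("run must cover at least one full HRF")


def quiet_config(seed: int = 0, **kwargs) -> GeneratorConfig:
    """Artifact-free, noise-free, flat-baseline configuration (for oracles)."""
    cfg = GeneratorConfig(seed=seed, physio=quiet_physio(),
                          artifacts=ArtifactSpec(rate_per_min=0.0), **kwargs)
    return cfg


# ---------------------------------------------------------------------------
# HRF kernel
# ---------------------------------------------------------------------------

_RISE_EXPONENT = 3.0


def hrf_value(t: np.ndarray, spec: HRFSpec | None = None) -> np.ndarray:
    """Evaluate the unit-peak HRF kernel at arbitrary times (s).

    The kernel is a compact-support gamma variant
    ``h(t) = (t/p)^a * ((D-t)/(D-p))^(a*(D-p)/p)`` with ``a = 3``: it is
    identically zero outside ``(0, D)``, attains its unique maximum of
    exactly 1 at ``t = p`` (the 6 s peak by default), and decays smoothly to
    zero at the 16 s duration ``D``.
    """
    spec = spec or HRFSpec()
    p, D = spec.peak_time_s, spec.duration_s
    a = _RISE_EXPONENT
    b = a * (D - p) / p
    t = np.asarray(t, float)
    out = np.zeros_like(t)
    inside = (t > 0) & (t < D)
    ti = t[inside]
    out[inside] = (ti / p) ** a * ((D - ti) / (D - p)) ** b
    return out


def make_hrf_regressor(spec: HRFSpec | None = None, fs_hz: float = 25.0) -> np.ndarray:
    """Sample the unit-peak HRF kernel on the ``[0, duration_s)`` grid."""
    spec = spec or HRFSpec()
    if fs_hz <= 2.0 / spec.duration_s:
        raise ValidationError("fs_hz too low to sample the HRF")
    n = int(round(spec.duration_s * fs_hz))
    return hrf_value(np.arange(n) / fs_hz, spec)


# ---------------------------------------------------------------------------
# stimulus onsets
# ---------------------------------------------------------------------------

_FIRST_ONSET_S = 2.0  # fixed pre-stimulus guard for the baseline window


def make_onsets(cfg: GeneratorConfig, rng: np.random.Generator | None = None
                ) -> StimulusDesign:
    """Randomized stimulus onsets, snapped to the sample grid.

    Under the default ``gap_after_response`` policy consecutive onsets are
    separated by ``duration_s + U(isi_min, isi_max)`` so trials never
    overlap; under ``onset_to_onset`` the draw itself is the onset spacing.
    The first onset sits at a fixed 2 s guard so every trial has a full
    pre-stimulus baseline window.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    dur, fs = cfg.hrf.duration_s, cfg.fs_hz
    if _FIRST_ONSET_S + dur > cfg.run_length_s:
        raise ValidationError("run too short for a single stimulus trial")
    snap = lambda t: round(t * fs) / fs
    onsets = [snap(_FIRST_ONSET_S)]
    while True:
        gap = rng.uniform(cfg.isi_min_s, cfg.isi_max_s)
        step = dur + gap if cfg.onset_policy == "gap_after_response" else gap
        nxt = snap(onsets[-1] + step)
        if nxt + dur > cfg.run_length_s:
            break
        onsets.append(nxt)
    return StimulusDesign(np.asarray(onsets), dur)


def _stim_convolution(times_s: np.ndarray, spec: HRFSpec,
                      design: StimulusDesign) -> np.ndarray:
    """Sum of unit-peak kernels, one per onset, evaluated analytically."""
    out = np.zeros_like(times_s, dtype=float)
    for onset in design.onsets_s:
        out += hrf_value(times_s - onset, spec)
    return out


# ---------------------------------------------------------------------------
# HRF injection
# ---------------------------------------------------------------------------

def _percent_sign(ext_row: np.ndarray, spec: HRFSpec) -> float:
    """Sign of the intensity change at one wavelength during activation."""
    dod = ext_row[0] * spec.amp_hbo_um + ext_row[1] * spec.amp_hbr_um
    return -1.0 if dod > 0 else 1.0


def inject_hrf(rec: IntensityRecording, spec: HRFSpec, design: StimulusDesign,
               mbll: MBLLParams | None = None
               ) -> tuple[IntensityRecording, dict[str, np.ndarray]]:
    """Inject the synthetic HRF into a recording.

    In concentration mode the kernel scaled to ``(amp_hbo_um, amp_hbr_um)``
    is pushed through the MBLL forward model to per-wavelength optical
    density and applied multiplicatively as ``I * 10**(-dOD)``.  In percent
    mode the peak fractional intensity change at each wavelength equals the
    configured percentage exactly, with the sign each wavelength would take
    under the forward model.

    Returns the new recording and the ground truth: the regressor (unit-peak
    convolution of kernel with onsets) and the true HbO/HbR time courses.
    """
    mbll = mbll or MBLLParams(wavelengths=tuple(rec.probe.wavelengths))
    if design.onsets_s.size and (design.onsets_s[-1] + design.hrf_duration_s
                                 > rec.n_samples / rec.fs_hz + 1e-9):
        raise ValidationError("stimulus trial extends beyond the recording")
    conv = _stim_convolution(rec.times_s, spec, design)
    wl_sorted = sorted(rec.probe.wavelengths)
    data = rec.data.copy()
    for idx, (si, di, wl) in enumerate(rec.probe.channels):
        row = mbll.extinction[wl_sorted.index(float(wl))]
        if spec.mode == "concentration":
            d = (mbll.sd_distance_cm if mbll.sd_distance_cm is not None
                 else rec.probe.sd_distance_cm[idx])
            dod = (row[0] * spec.amp_hbo_um + row[1] * spec.amp_hbr_um) * d * mbll.ppf
            data[:, idx] *= 10.0 ** (-dod * conv)
        else:
            pct = spec.percent_amp_by_wavelength[float(wl)]
            data[:, idx] *= 1.0 + _percent_sign(row, spec) * pct * conv
    truth = {
        "regressor": conv,
        "hbo_um": spec.amp_hbo_um * conv,
        "hbr_um": spec.amp_hbr_um * conv,
    }
    out = IntensityRecording(rec.fs_hz, data, rec.probe,
                             StimulusDesign(design.onsets_s, design.hrf_duration_s))
    return out, truth


# ---------------------------------------------------------------------------
# full run generation
# ---------------------------------------------------------------------------

@dataclass
class ArtifactEvent:
    kind: str  # "spike" | "shift"
    t_start_s: float
    t_end_s: float  # for shifts this is the run end (the offset persists)
    amplitude_od: float  # signed profile amplitude
    gains: np.ndarray  # per-channel multiplicative gains


@dataclass
class GroundTruth:
    """Everything the generator knows about a run, for scoring and tests."""

    design: StimulusDesign
    hrf: HRFSpec
    regressor: np.ndarray  # unit-peak kernel convolved with onsets
    hbo_um: np.ndarray
    hbr_um: np.ndarray
    events: list[ArtifactEvent]
    artifact_od: np.ndarray  # time x channel OD contributed by artifacts
    physio_modulation: np.ndarray  # time x channel multiplicative factor
    baseline_intensity: float


def _spike_profile(times: np.ndarray, t0: float, duration: float, freq: float,
                   phase: float) -> np.ndarray:
    """Gaussian-windowed oscillatory burst, exactly zero outside +/-4 sigma."""
    sigma = duration / 4.0
    prof = np.zeros_like(times)
    sel = np.abs(times - t0) <= 4.0 * sigma
    ts = times[sel] - t0
    prof[sel] = np.exp(-0.5 * (ts / sigma) ** 2) * np.sin(2 * np.pi * freq * ts + phase)
    return prof


def _shift_profile(times: np.ndarray, t0: float, fs: float) -> np.ndarray:
    """Unit step at t0, ramped over 2 samples, persisting to the run end."""
    prof = np.clip((times - t0) * fs / 2.0, 0.0, 1.0)
    return prof


def _make_artifacts(cfg: GeneratorConfig, rng: np.random.Generator,
                    times: np.ndarray) -> tuple[np.ndarray, list[ArtifactEvent]]:
    spec = cfg.artifacts
    n_ch = cfg.probe.n_channels
    od = np.zeros((times.size, n_ch))
    events: list[ArtifactEvent] = []
    n_events = rng.poisson(spec.rate_per_min * cfg.run_length_s / 60.0)
    sigma_log = np.log(spec.gain_spread) / 2.0
    for _ in range(n_events):
        kind = "spike" if rng.random() < spec.spike_fraction else "shift"
        amp = spec.amplitude_od * rng.uniform(0.75, 1.25) * rng.choice([-1.0, 1.0])
        if kind == "spike":
            duration = rng.uniform(0.25, 1.0)
            t0 = rng.uniform(2.0 * duration, cfg.run_length_s - 2.0 * duration)
            profile = amp * _spike_profile(times, t0, duration,
                                           freq=rng.uniform(2.0, 5.0),
                                           phase=rng.uniform(0, 2 * np.pi))
            t_start, t_end = t0 - duration, t0 + duration
        else:
            t0 = rng.uniform(1.0, cfg.run_length_s - 1.0)
            profile = amp * _shift_profile(times, t0, cfg.fs_hz)
            t_start, t_end = t0, cfg.run_length_s
        if spec.shared_profile:
            gains = rng.lognormal(0.0, sigma_log, size=n_ch)
            od += profile[:, None] * gains[None, :]
        else:
            gains = np.ones(n_ch)
            for ch in range(n_ch):
                gains[ch] = rng.lognormal(0.0, sigma_log)
                od[:, ch] += profile * gains[ch] * rng.choice([-1.0, 1.0])
        events.append(ArtifactEvent(kind, t_start, t_end, amp, gains))
    return od, events


def _make_physio(cfg: GeneratorConfig, rng: np.random.Generator,
                 times: np.ndarray) -> np.ndarray:
    ph = cfg.physio
    if ph.total_modulation_bound(cfg.run_length_s) >= 0.95:
        raise ValidationError("physiology amplitudes could drive intensity <= 0")
    n_ch = cfg.probe.n_channels
    mod = np.ones((times.size, n_ch))
    for amp, freq in ((ph.cardiac_amp, ph.cardiac_hz), (ph.resp_amp, ph.resp_hz),
                      (ph.mayer_amp, ph.mayer_hz)):
        phases = rng.uniform(0, 2 * np.pi, size=n_ch)
        if amp > 0:
            mod += amp * np.sin(2 * np.pi * freq * times[:, None] + phases[None, :])
    slopes = rng.uniform(-1.0, 1.0, size=n_ch) * ph.drift_slope
    if ph.drift_slope != 0:
        mod += slopes[None, :] * (times[:, None] - cfg.run_length_s / 2.0) / 60.0
    if ph.white_noise_sd > 0:
        mod += rng.normal(0.0, ph.white_noise_sd, size=mod.shape)
    return mod


def generate_run(cfg: GeneratorConfig) -> tuple[IntensityRecording, GroundTruth]:
    """Generate one synthetic run: physiology x artifacts x injected HRF.

    Deterministic given ``cfg`` (bit-identical for identical configs).  Three
    named substreams (onsets, physiology, artifacts) are spawned from the
    seed so changing one spec does not perturb the draws of the others.
    """
    ss = np.random.SeedSequence(cfg.seed)
    onset_ss, physio_ss, art_ss = ss.spawn(3)
    if cfg.onset_seed is not None:
        onset_ss = np.random.SeedSequence(cfg.onset_seed)
    rng_onsets, rng_physio, rng_art = (np.random.default_rng(s)
                                       for s in (onset_ss, physio_ss, art_ss))
    n = int(round(cfg.run_length_s * cfg.fs_hz))
    times = np.arange(n) / cfg.fs_hz

    design = make_onsets(cfg, rng_onsets)
    physio = _make_physio(cfg, rng_physio, times)
    artifact_od, events = _make_artifacts(cfg, rng_art, times)

    intensity = cfg.physio.baseline_intensity * physio * 10.0 ** (-artifact_od)
    if np.any(intensity <= 0):
        raise ValidationError("generated intensity is not strictly positive")
    base = IntensityRecording(cfg.fs_hz, intensity, cfg.probe, design)
    rec, truth_hrf = inject_hrf(base, cfg.hrf, design, cfg.mbll)
    truth = GroundTruth(design=design, hrf=cfg.hrf,
                        regressor=truth_hrf["regressor"],
                        hbo_um=truth_hrf["hbo_um"], hbr_um=truth_hrf["hbr_um"],
                        events=events, artifact_od=artifact_od,
                        physio_modulation=physio,
                        baseline_intensity=cfg.physio.baseline_intensity)
    return rec, truth


# ---------------------------------------------------------------------------
# ground-truth sidecar
# ---------------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Serialize the scalar/event ground truth as a JSON sidecar (no arrays)."""
    payload = {
        "onsets_s": truth.design.onsets_s.tolist(),
        "hrf": {
            "peak_time_s": truth.hrf.peak_time_s,
            "duration_s": truth.hrf.duration_s,
            "amp_hbo_um": truth.hrf.amp_hbo_um,
            "amp_hbr_um": truth.hrf.amp_hbr_um,
            "mode": truth.hrf.mode,
        },
        "baseline_intensity": truth.baseline_intensity,
        "events": [
            {"kind": e.kind, "t_start_s": e.t_start_s, "t_end_s": e.t_end_s,
             "amplitude_od": e.amplitude_od, "gains": np.asarray(e.gains).tolist()}
            for e in truth.events
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
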