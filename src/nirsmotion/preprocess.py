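"""The processing stream: optical density, MBLL, band-pass, block average.

Pipeline order is fixed as OD -> detect -> correct -> band-pass -> MBLL ->
block average; the correction stages live in :mod:`nirsmotion.correct`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import (
    ConcSeries,
    IntensityRecording,
    MBLLParams,
    ODSeries,
    StimulusDesign,
    ValidationError,
)

__all__ = [
    "FilterParams", "BlockAverageParams", "BlockAverage",
    "intensity_to_od", "od_to_intensity", "od_to_concentration",
    "concentration_to_od", "bandpass", "block_average",
]


@dataclass
class FilterParams:
    """Butterworth band-pass: 3rd order, 0.01-0.5 Hz, zero-phase by default."""

    order: int = 3
    low_hz: float = 0.01
    high_hz: float = 0.5
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValidationError("require 0 < low_hz < high_hz")
        if self.order < 1:
            raise ValidationError("order must be >= 1")


@dataclass
class BlockAverageParams:
    pre_s: float = 2.0
    post_s: float = 16.0
    baseline: str = "pre_window_mean"  # or "none"

    def __post_init__(self) -> None:
        if self.pre_s < 0 or self.post_s <= 0:
            raise ValidationError("require pre_s >= 0 and post_s > 0")
        if self.baseline not in ("pre_window_mean", "none"):
            raise ValidationError("baseline must be 'pre_window_mean' or 'none'")


# ---------------------------------------------------------------------------
# optical density
# ---------------------------------------------------------------------------

def intensity_to_od(rec: IntensityRecording,
                    baseline: str | np.ndarray = "mean") -> ODSeries:
    """Convert intensity to change in optical density.

    Per channel, ``dOD(t) = -log10(I(t) / I_ref)``.  ``baseline`` selects the
    reference: the channel's temporal mean (default), ``"first"`` for the
    first sample, or an explicit per-channel array/scalar.
    """
    data = rec.data
    if np.any(data <= 0):
        t, ch = np.argwhere(data <= 0)[0]
        raise ValidationError(f"non-positive intensity at sample {t}, channel {ch}")
    if isinstance(baseline, str):
        if baseline == "mean":
            ref = data.mean(axis=0)
        elif baseline == "first":
            ref = data[0]
        else:
            raise ValidationError(f"unknown OD baseline '{baseline}'")
    else:
        ref = np.broadcast_to(np.asarray(baseline, float), (data.shape[1],))
        if np.any(ref <= 0):
            raise ValidationError("OD baseline must be strictly positive")
    return ODSeries(rec.fs_hz, -np.log10(data / ref), rec.probe)


def od_to_intensity(od: ODSeries, baseline: np.ndarray | float,
                    stim: StimulusDesign | None = None) -> IntensityRecording:
    """Exact inverse of :func:`intensity_to_od` for a known reference."""
    ref = np.broadcast_to(np.asarray(baseline, float), (od.data.shape[1],))
    data = ref * 10.0 ** (-od.data)
    return IntensityRecording(od.fs_hz, data, od.probe,
                              stim or StimulusDesign(np.array([])))


# ---------------------------------------------------------------------------
# modified Beer-Lambert law
# ---------------------------------------------------------------------------

def _pair_distance(od: ODSeries, mbll: MBLLParams,
                   cols: dict[float, int]) -> float:
    if mbll.sd_distance_cm is not None:
        return float(mbll.sd_distance_cm)
    return float(od.probe.sd_distance_cm[next(iter(cols.values()))])


def od_to_concentration(od: ODSeries, mbll: MBLLParams | None = None) -> ConcSeries:
    """Invert the MBLL per SD pair and time point (2x2 linear solve).

    Model: ``dOD(lambda) = [eps_HbO(lambda) dHbO + eps_HbR(lambda) dHbR]
    * d * PPF`` with concentrations in uM, distances in cm.
    """
    mbll = mbll or MBLLParams(wavelengths=tuple(od.probe.wavelengths))
    wl_sorted = sorted(mbll.wavelengths)
    pairs = od.probe.sd_pairs()
    pair_cols = od.probe.pair_channel_indices()
    out = np.empty((od.n_samples, 2 * len(pairs)))
    inv = np.linalg.inv(mbll.extinction)
    for k, pair in enumerate(pairs):
        cols = pair_cols[pair]
        if set(cols) != set(float(w) for w in wl_sorted):
            missing = set(float(w) for w in wl_sorted) - set(cols)
            raise ValidationError(
                f"SD pair S{pair[0] + 1}-D{pair[1] + 1} is missing wavelength(s) "
                f"{sorted(missing)}")
        d = _pair_distance(od, mbll, cols)
        dod = np.column_stack([od.data[:, cols[float(w)]] for w in wl_sorted])
        conc = dod @ inv.T / (d * mbll.ppf)
        out[:, 2 * k] = conc[:, 0]
        out[:, 2 * k + 1] = conc[:, 1]
    return ConcSeries(od.fs_hz, out, pairs)


def concentration_to_od(conc: ConcSeries, probe, mbll: MBLLParams | None = None
                        ) -> ODSeries:
    """MBLL forward model: concentrations back to per-wavelength dOD."""
    mbll = mbll or MBLLParams(wavelengths=tuple(probe.wavelengths))
    wl_sorted = sorted(mbll.wavelengths)
    pair_cols = probe.pair_channel_indices()
    out = np.zeros((conc.data.shape[0], probe.n_channels))
    for k, pair in enumerate(conc.pairs):
        cols = pair_cols[pair]
        d = (float(mbll.sd_distance_cm) if mbll.sd_distance_cm is not None
             else float(probe.sd_distance_cm[next(iter(cols.values()))]))
        c = conc.data[:, 2 * k:2 * k + 2]
        dod = c @ mbll.extinction.T * d * mbll.ppf
        for j, w in enumerate(wl_sorted):
            out[:, cols[float(w)]] = dod[:, j]
    return ODSeries(conc.fs_hz, out, probe)


# ---------------------------------------------------------------------------
# band-pass filter
# ---------------------------------------------------------------------------

def design_bandpass(fp: FilterParams, fs_hz: float) -> np.ndarray:
    """Second-order sections of the Butterworth band-pass (exposed for audit)."""
    if fp.high_hz >= fs_hz / 2:
        raise ValidationError("high_hz must lie below the Nyquist frequency")
    return signal.butter(fp.order, [fp.low_hz, fp.high_hz], btype="bandpass",
                         fs=fs_hz, output="sos")


def bandpass(od: ODSeries, fp: FilterParams | None = None) -> ODSeries:
    """Band-pass each channel; zero-phase (forward-backward) by default."""
    fp = fp or FilterParams()
    sos = design_bandpass(fp, od.fs_hz)
    if fp.zero_phase:
        # pad well past the low-corner settling time (tau ~ 1/(pi * low_hz))
        # so filtfilt edge transients do not bleed into the run
        padlen = min(od.n_samples - 1,
                     int(round(3.0 * od.fs_hz / (np.pi * fp.low_hz))))
        out = signal.sosfiltfilt(sos, od.data, axis=0, padlen=padlen)
    else:
        out = signal.sosfilt(sos, od.data, axis=0)
    return ODSeries(od.fs_hz, np.ascontiguousarray(out), od.probe)


# ---------------------------------------------------------------------------
# block average
# ---------------------------------------------------------------------------

@dataclass
class BlockAverage:
    """Mean stimulus-locked epoch and the per-trial epochs behind it."""

    t_rel_s: np.ndarray  # relative time axis, [-pre, post)
    mean: np.ndarray  # epoch x channel
    trials: np.ndarray  # trial x epoch x channel
    n_used: int
    n_dropped: int

    @property
    def post_mask(self) -> np.ndarray:
        """Samples of the epoch at or after stimulus onset."""
        return self.t_rel_s >= -1e-12


def block_average(x: ConcSeries | ODSeries, design: StimulusDesign,
                  bp: BlockAverageParams | None = None) -> BlockAverage:
    """Arithmetic mean over trials of baseline-adjusted stimulus epochs.

    Trials truncated by the run edges are dropped (and counted); with
    ``baseline='pre_window_mean'`` each trial's mean over ``[-pre, 0)`` is
    subtracted per channel before averaging.
    """
    bp = bp or BlockAverageParams()
    fs = x.fs_hz
    data = x.data
    n = data.shape[0]
    n_pre = int(round(bp.pre_s * fs))
    n_post = int(round(bp.post_s * fs))
    epochs = []
    n_dropped = 0
    for onset in design.onsets_s:
        i_on = int(round(onset * fs))
        i0, i1 = i_on - n_pre, i_on + n_post
        if i0 < 0 or i1 > n:
            n_dropped += 1
            continue
        ep = data[i0:i1].astype(float, copy=True)
        if bp.baseline == "pre_window_mean" and n_pre > 0:
            ep -= data[i0:i_on].mean(axis=0, keepdims=True)
        epochs.append(ep)
    if not epochs:
        raise ValidationError("no stimulus trial has full support inside the run")
    trials = np.stack(epochs)
    t_rel = (np.arange(-n_pre, n_post)) / fs
    return BlockAverage(t_rel_s=t_rel, mean=trials.mean(axis=0), trials=trials,
                        n_used=len(epochs), n_dropped=n_dropped)
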