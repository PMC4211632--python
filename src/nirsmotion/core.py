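"""Domain types, validation, and SNIRF/CSV I/O for continuous-wave fNIRS.

Conventions used throughout the package:

* time is in seconds, sample indexing is 0-based;
* all segment/epoch intervals are half-open ``[start, end)`` in samples;
* intensity matrices are time x channel, strictly positive;
* optical density is dimensionless, concentrations are in micromolar (uM).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger("nirsmotion")

DEFAULT_WAVELENGTHS_NM = (690.0, 830.0)

#: Molar extinction coefficients (HbO, HbR) in cm^-1 / M at the default
#: wavelengths, from the Gratzer/Kollias compilation as bundled with the
#: common fNIRS analysis toolboxes.  Users can override via MBLLParams.
EXTINCTION_CM1_PER_M = {
    690.0: (276.0, 2051.96),
    830.0: (974.0, 693.04),
}


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class NirsError(Exception):
    """Base class for all package errors."""


class ValidationError(NirsError, ValueError):
    """Invalid data or parameters."""


class FormatError(NirsError, IOError):
    """Malformed or unreadable file."""


class SamplingError(FormatError):
    """Time vector is non-uniform or non-monotone."""


class NumericalError(NirsError):
    """Ill-conditioned or degenerate numerical problem."""


# ---------------------------------------------------------------------------
# probe geometry
# ---------------------------------------------------------------------------

@dataclass
class ProbeGeometry:
    """Optode layout and the source-detector channels measured on it.

    ``channels`` is an ordered list of ``(source_index, detector_index,
    wavelength_nm)`` with 0-based optode indices; column *i* of every data
    matrix in the package corresponds to ``channels[i]``.
    """

    source_positions: np.ndarray  # (n_sources, 3), cm
    detector_positions: np.ndarray  # (n_detectors, 3), cm
    channels: list[tuple[int, int, float]]
    sd_distance_cm: np.ndarray | None = None  # per channel; derived if None

    def __post_init__(self) -> None:
        self.source_positions = np.atleast_2d(np.asarray(self.source_positions, float))
        self.detector_positions = np.atleast_2d(np.asarray(self.detector_positions, float))
        if not self.channels:
            raise ValidationError("probe has zero channels")
        ns, nd = len(self.source_positions), len(self.detector_positions)
        seen = set()
        for si, di, wl in self.channels:
            if not (0 <= si < ns and 0 <= di < nd):
                raise ValidationError(
                    f"channel (S{si + 1}, D{di + 1}) references a missing optode")
            key = (si, di, float(wl))
            if key in seen:
                raise ValidationError(f"duplicate channel {key}")
            seen.add(key)
        if self.sd_distance_cm is None:
            d = [np.linalg.norm(self.source_positions[si] - self.detector_positions[di])
                 for si, di, _ in self.channels]
            self.sd_distance_cm = np.asarray(d, float)
        else:
            self.sd_distance_cm = np.asarray(self.sd_distance_cm, float)
        if len(self.sd_distance_cm) != len(self.channels):
            raise ValidationError("sd_distance_cm length != number of channels")
        if np.any(self.sd_distance_cm <= 0):
            raise ValidationError("sd_distance_cm must be > 0 for every channel")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def wavelengths(self) -> list[float]:
        """Sorted unique wavelengths present in the channel list."""
        return sorted({wl for _, _, wl in self.channels})

    def channel_names(self) -> list[str]:
        return [f"S{si + 1}_D{di + 1}_{int(round(wl))}" for si, di, wl in self.channels]

    def sd_pairs(self) -> list[tuple[int, int]]:
        """Unique (source, detector) pairs in first-appearance order."""
        out: list[tuple[int, int]] = []
        for si, di, _ in self.channels:
            if (si, di) not in out:
                out.append((si, di))
        return out

    def pair_channel_indices(self) -> dict[tuple[int, int], dict[float, int]]:
        """Map each SD pair to {wavelength: channel column index}."""
        out: dict[tuple[int, int], dict[float, int]] = {}
        for idx, (si, di, wl) in enumerate(self.channels):
            out.setdefault((si, di), {})[float(wl)] = idx
        return out


def default_probe(sd_distance_cm: float = 3.0,
                  wavelengths: tuple[float, ...] = DEFAULT_WAVELENGTHS_NM) -> ProbeGeometry:
    """The study probe: 2 sources x 4 detectors, 4 SD pairs, 2 wavelengths.

    Each source is paired with its two nearest detectors at ``sd_distance_cm``,
    giving 4 SD pairs and ``4 * len(wavelengths)`` channels (8 by default).
    """
    d = float(sd_distance_cm)
    sources = np.array([[0.0, 0.0, 0.0], [3 * d, 0.0, 0.0]])
    detectors = np.array([[d, 0.0, 0.0], [0.0, d, 0.0],
                          [4 * d, 0.0, 0.0], [3 * d, d, 0.0]])
    pairs = [(0, 0), (0, 1), (1, 2), (1, 3)]
    channels = [(si, di, float(wl)) for si, di in pairs for wl in wavelengths]
    return ProbeGeometry(sources, detectors, channels)


# ---------------------------------------------------------------------------
# stimulus design and series containers
# ---------------------------------------------------------------------------

@dataclass
class StimulusDesign:
    """Stimulus onset times (s) and the duration of the evoked response."""

    onsets_s: np.ndarray
    hrf_duration_s: float = 16.0

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, float).ravel()
        if self.onsets_s.size and np.any(np.diff(self.onsets_s) <= 0):
            raise ValidationError("stimulus onsets must be strictly increasing")
        if np.any(self.onsets_s < 0):
            raise ValidationError("stimulus onsets must be non-negative")
        if self.hrf_duration_s <= 0:
            raise ValidationError("hrf_duration_s must be > 0")


def _check_matrix(data: np.ndarray, n_channels: int, what: str) -> np.ndarray:
    data = np.asarray(data, float)
    if data.ndim != 2:
        raise ValidationError(f"{what} must be a time x channel matrix")
    if data.shape[1] != n_channels:
        raise ValidationError(
            f"{what} has {data.shape[1]} columns but the probe has {n_channels} channels")
    if not np.all(np.isfinite(data)):
        raise ValidationError(f"{what} contains non-finite values")
    return data


@dataclass
class IntensityRecording:
    """Raw light-intensity time series (arbitrary units, strictly positive)."""

    fs_hz: float
    data: np.ndarray  # time x channel
    probe: ProbeGeometry
    stim: StimulusDesign = field(default_factory=lambda: StimulusDesign(np.array([])))

    def __post_init__(self) -> None:
        if self.fs_hz <= 1.0:
            raise ValidationError("fs_hz must exceed 1 Hz to resolve the 0.5 Hz band edge")
        self.data = _check_matrix(self.data, self.probe.n_channels, "intensity")
        if np.any(self.data <= 0):
            t, ch = np.argwhere(self.data <= 0)[0]
            raise ValidationError(
                f"non-positive intensity at sample {t}, channel "
                f"{self.probe.channel_names()[ch]}")
        if self.stim.onsets_s.size:
            run_len = self.data.shape[0] / self.fs_hz
            if self.stim.onsets_s[-1] >= run_len:
                raise ValidationError("stimulus onset beyond the end of the run")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz


@dataclass
class ODSeries:
    """Change in optical density, dimensionless, time x channel."""

    fs_hz: float
    data: np.ndarray
    probe: ProbeGeometry

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValidationError("fs_hz must be positive")
        self.data = _check_matrix(self.data, self.probe.n_channels, "optical density")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz

    def copy(self) -> "ODSeries":
        return ODSeries(self.fs_hz, self.data.copy(), self.probe)


@dataclass
class ConcSeries:
    """Hemoglobin concentration changes (uM), time x (SD pair x chromophore).

    Columns are pair-major with the chromophore fastest: column ``2k`` is HbO
    of SD pair *k*, column ``2k + 1`` its HbR.
    """

    fs_hz: float
    data: np.ndarray
    pairs: list[tuple[int, int]]
    chromophores: tuple[str, str] = ("HbO", "HbR")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 2 or self.data.shape[1] != 2 * len(self.pairs):
            raise ValidationError("concentration matrix must have 2 columns per SD pair")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("concentration matrix contains non-finite values")
        if tuple(self.chromophores) != ("HbO", "HbR"):
            raise ValidationError("chromophores must be ('HbO', 'HbR')")

    @property
    def hbo(self) -> np.ndarray:
        return self.data[:, 0::2]

    @property
    def hbr(self) -> np.ndarray:
        return self.data[:, 1::2]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.data.shape[0]) / self.fs_hz


@dataclass
class MBLLParams:
    """Modified Beer-Lambert law parameters.

    ``extinction`` maps wavelength (sorted ascending) x chromophore (HbO, HbR)
    to extinction coefficients in 1/(uM*cm); the default is the bundled
    Gratzer/Kollias tabulation at 690/830 nm.  ``ppf`` is the pathlength
    correction factor (study value 6).  ``sd_distance_cm`` overrides the
    per-channel probe distances when set.
    """

    extinction: np.ndarray | None = None  # (n_wavelengths, 2) in 1/(uM*cm)
    ppf: float = 6.0
    sd_distance_cm: float | None = None
    wavelengths: tuple[float, ...] = DEFAULT_WAVELENGTHS_NM

    def __post_init__(self) -> None:
        if self.extinction is None:
            self.extinction = np.array(
                [EXTINCTION_CM1_PER_M[wl] for wl in sorted(self.wavelengths)]) * 1e-6
        self.extinction = np.asarray(self.extinction, float)
        if self.ppf <= 0:
            raise ValidationError("ppf must be > 0")
        if self.extinction.shape != (len(self.wavelengths), 2):
            raise ValidationError("extinction must be (n_wavelengths, 2)")
        if not np.all(np.isfinite(self.extinction)):
            raise ValidationError("extinction matrix must be finite")
        cond = np.linalg.cond(self.extinction)
        if not np.isfinite(cond) or cond > 1e8:
            raise NumericalError(f"extinction matrix is ill-conditioned (cond={cond:.3g})")


# ---------------------------------------------------------------------------
# SNIRF I/O (continuous-wave amplitude only)
# ---------------------------------------------------------------------------

_REQUIRED_SNIRF = ("nirs1/data1/dataTimeSeries", "nirs1/data1/time", "nirs1/probe")


def write_snirf(rec: IntensityRecording, path: str | Path) -> None:
    """Write a recording as a SNIRF (HDF5) continuous-wave amplitude file."""
    import h5py

    path = Path(path)
    wavelengths = rec.probe.wavelengths
    str_dt = h5py.string_dtype(encoding="utf-8")
    try:
        f = h5py.File(path, "w")
    except OSError as exc:  # unwritable path
        raise FormatError(f"cannot write SNIRF file {path}: {exc}") from exc
    with f:
        f.create_dataset("formatVersion", data="1.1", dtype=str_dt)
        nirs = f.create_group("nirs1")
        meta = nirs.create_group("metaDataTags")
        for key, val in (("SubjectID", "synthetic"), ("MeasurementDate", "unknown"),
                         ("MeasurementTime", "unknown"), ("LengthUnit", "cm"),
                         ("TimeUnit", "s"), ("FrequencyUnit", "Hz")):
            meta.create_dataset(key, data=val, dtype=str_dt)
        data = nirs.create_group("data1")
        data.create_dataset("dataTimeSeries", data=rec.data)
        data.create_dataset("time", data=rec.times_s)
        for i, (si, di, wl) in enumerate(rec.probe.channels, start=1):
            ml = data.create_group(f"measurementList{i}")
            ml.create_dataset("sourceIndex", data=si + 1)
            ml.create_dataset("detectorIndex", data=di + 1)
            ml.create_dataset("wavelengthIndex", data=wavelengths.index(float(wl)) + 1)
            ml.create_dataset("dataType", data=1)  # CW amplitude
            ml.create_dataset("dataTypeIndex", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(wavelengths, float))
        probe.create_dataset("sourcePos3D", data=rec.probe.source_positions)
        probe.create_dataset("detectorPos3D", data=rec.probe.detector_positions)
        stim = nirs.create_group("stim1")
        stim.create_dataset("name", data="stim", dtype=str_dt)
        onsets = rec.stim.onsets_s
        stim_data = np.column_stack([onsets,
                                     np.full_like(onsets, rec.stim.hrf_duration_s),
                                     np.ones_like(onsets)]) if onsets.size else \
            np.empty((0, 3))
        stim.create_dataset("data", data=stim_data)


def read_snirf(path: str | Path) -> IntensityRecording:
    """Read a continuous-wave SNIRF file written by :func:`write_snirf`.

    The sampling rate is inferred from the time vector, which must be uniform
    to within 1% jitter.
    """
    import h5py

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise FormatError(f"not a readable HDF5/SNIRF file: {path}: {exc}") from exc
    with f:
        for group in _REQUIRED_SNIRF:
            if group not in f:
                raise FormatError(f"SNIRF file missing required group '{group}'")
        time = np.asarray(f["nirs1/data1/time"][()], float).ravel()
        if time.size < 2:
            raise SamplingError("time vector must contain at least 2 samples")
        dt = np.diff(time)
        if np.any(dt <= 0):
            raise SamplingError("time vector is not strictly increasing")
        dt0 = np.median(dt)
        if np.max(np.abs(dt - dt0)) > 0.01 * dt0:
            raise SamplingError("time vector jitter exceeds 1% of the sample interval")
        fs = 1.0 / dt0
        data = np.asarray(f["nirs1/data1/dataTimeSeries"][()], float)
        if data.ndim != 2 or data.shape[1] == 0:
            raise FormatError("dataTimeSeries has zero channels")
        ml_names = sorted((k for k in f["nirs1/data1"] if k.startswith("measurementList")),
                          key=lambda k: int(k[len("measurementList"):]))
        if len(ml_names) != data.shape[1]:
            raise FormatError("measurementList entries do not match data columns")
        wavelengths = np.asarray(f["nirs1/probe/wavelengths"][()], float).ravel()
        channels = []
        for name in ml_names:
            ml = f[f"nirs1/data1/{name}"]
            channels.append((int(ml["sourceIndex"][()]) - 1,
                             int(ml["detectorIndex"][()]) - 1,
                             float(wavelengths[int(ml["wavelengthIndex"][()]) - 1])))
        for key in ("sourcePos3D", "sourcePos2D"):
            if f"nirs1/probe/{key}" in f:
                spos = np.asarray(f[f"nirs1/probe/{key}"][()], float)
                break
        else:
            raise FormatError("SNIRF file missing required group 'nirs1/probe/sourcePos3D'")
        for key in ("detectorPos3D", "detectorPos2D"):
            if f"nirs1/probe/{key}" in f:
                dpos = np.asarray(f[f"nirs1/probe/{key}"][()], float)
                break
        else:
            raise FormatError("SNIRF file missing required group 'nirs1/probe/detectorPos3D'")
        if spos.shape[1] == 2:
            spos = np.column_stack([spos, np.zeros(len(spos))])
        if dpos.shape[1] == 2:
            dpos = np.column_stack([dpos, np.zeros(len(dpos))])
        probe = ProbeGeometry(spos, dpos, channels)
        onsets = np.empty(0)
        duration = 16.0
        if "nirs1/stim1/data" in f:
            sdata = np.asarray(f["nirs1/stim1/data"][()], float)
            if sdata.size:
                sdata = np.atleast_2d(sdata)
                onsets = sdata[:, 0]
                duration = float(sdata[0, 1])
        stim = StimulusDesign(onsets, duration)
    return IntensityRecording(fs_hz=fs, data=data, probe=probe, stim=stim)


# ---------------------------------------------------------------------------
# CSV fixtures
# ---------------------------------------------------------------------------

def write_csv_fixture(rec: IntensityRecording, path: str | Path) -> None:
    """Write a recording as a plain-text CSV fixture.

    Column 1 is time in seconds, remaining columns are channels named
    ``S{i}_D{j}_{wavelength}``; all numbers use 12 significant digits.
    """
    import pandas as pd

    df = pd.DataFrame(rec.data, columns=rec.probe.channel_names())
    df.insert(0, "time_s", rec.times_s)
    df.to_csv(path, index=False, float_format="%.12g")


def _parse_channel_name(name: str) -> tuple[int, int, float]:
    try:
        s, d, wl = name.split("_")
        if not (s.startswith("S") and d.startswith("D")):
            raise ValueError
        return int(s[1:]) - 1, int(d[1:]) - 1, float(wl)
    except ValueError as exc:
        raise FormatError(f"cannot parse channel name '{name}' as S{{i}}_D{{j}}_{{nm}}") from exc


def read_csv_fixture(path: str | Path,
                     stim: StimulusDesign | None = None,
                     sd_distance_cm: float = 3.0) -> IntensityRecording:
    """Read a CSV fixture written by :func:`write_csv_fixture`.

    Probe geometry is synthesised from the channel names: optodes are placed
    on a line so every referenced SD pair sits at ``sd_distance_cm``.
    """
    import pandas as pd

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError("CSV fixture must contain a time column and >= 1 channel")
    time = df.iloc[:, 0].to_numpy(float)
    if np.any(np.diff(time) <= 0):
        raise SamplingError("non-monotone time column")
    dt = np.diff(time)
    dt0 = np.median(dt)
    if np.max(np.abs(dt - dt0)) > 0.01 * dt0:
        raise SamplingError("time column jitter exceeds 1% of the sample interval")
    channels = [_parse_channel_name(c) for c in df.columns[1:]]
    n_src = max(si for si, _, _ in channels) + 1
    n_det = max(di for _, di, _ in channels) + 1
    # optodes on a line: |S_i - D_j| == sd_distance for the (i, j) pairs used
    spos = np.zeros((n_src, 3))
    dpos = np.zeros((n_det, 3))
    spos[:, 0] = np.arange(n_src) * 10.0 * sd_distance_cm
    for si, di, _ in channels:
        dpos[di] = spos[si] + np.array([0.0, sd_distance_cm, 0.0])
    probe = ProbeGeometry(spos, dpos, channels)
    data = df.iloc[:, 1:].to_numpy(float)
    return IntensityRecording(fs_hz=1.0 / dt0, data=data, probe=probe,
                              stim=stim or StimulusDesign(np.array([])))


def recordings_allclose(a: IntensityRecording, b: IntensityRecording,
                        tol: float = 1e-9) -> bool:
    """True when two recordings agree in layout and data to tolerance."""
    return (a.probe.channels == b.probe.channels
            and a.data.shape == b.data.shape
            and abs(a.fs_hz - b.fs_hz) <= tol * a.fs_hz
            and np.allclose(a.data, b.data, rtol=tol, atol=tol)
            and a.stim.onsets_s.shape == b.stim.onsets_s.shape
            and np.allclose(a.stim.onsets_s, b.stim.onsets_s, atol=tol))
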