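"""Motion-artifact correction: spline, wavelet, targeted PCA, whole-run PCA.

All correctors take and return :class:`~nirsmotion.core.ODSeries` and also
return a correction report.  Spline and targeted PCA are identity on runs
where detection finds nothing; the wavelet corrector at ``alpha = 0`` is a
perfect-reconstruction round trip.

Targeted PCA (tPCA) is the central algorithm: detection (any channel) marks
artifact epochs, the OD rows at all artifact samples are concatenated into a
single time-points x channels matrix, the leading principal components
accounting for (at least) 97% of the variance are projected out, the
corrected epochs are stitched back with mean-shift alignment, and the whole
procedure is iterated (3 passes by default) on freshly re-detected data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pywt
from scipy.interpolate import make_smoothing_spline
from scipy.stats import norm

from .core import ODSeries, ValidationError
from .detect import (
    DetectionParams,
    MotionMask,
    SegmentList,
    detect_motion_by_channel,
    mask_to_segments,
    shift_segments,
)

logger = logging.getLogger("nirsmotion")

__all__ = [
    "SplineParams", "WaveletParams", "TPCAParams",
    "CorrectionReport", "TPCAIteration",
    "spline_correct", "wavelet_correct", "tpca_select_components",
    "tpca_correct", "pca_correct_full",
]


@dataclass
class SplineParams:
    """Cubic smoothing-spline parameter, MATLAB ``csaps`` convention:
    p = 1 interpolates, p = 0 is a straight-line fit (study value 0.99)."""

    p: float = 0.99
    #: junction window for mean-shift stitching (None = full-segment means)
    join_window_s: float | None = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValidationError("spline parameter p must be in [0, 1]")


@dataclass
class WaveletParams:
    """Wavelet outlier filter: ``alpha`` is the two-tailed outlier
    probability (study value 0.1); ``family`` a 4-tap Daubechies by default;
    ``max_level`` caps the decomposition depth (None = deepest level whose
    approximation band lies below ``approx_band_hz``)."""

    alpha: float = 0.1
    family: str = "db2"
    max_level: int | None = None
    approx_band_hz: float = 0.01

    def __post_init__(self) -> None:
        if not 0 <= self.alpha < 1:
            raise ValidationError("alpha must be in [0, 1)")


@dataclass
class TPCAParams:
    """Targeted-PCA settings: remove the smallest number of components whose
    cumulative variance reaches ``nsv`` (0.97), over ``n_iter`` total
    detection->correction passes (3), with column centering of the epoch
    matrix."""

    nsv: float = 0.97
    n_iter: int = 3
    center: bool = True
    select_mode: str = "at_least"  # or "at_most"
    #: junction window for mean-shift stitching (None = full-segment means)
    join_window_s: float | None = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.nsv <= 1:
            raise ValidationError("nsv must be in (0, 1]")
        if self.n_iter < 1:
            raise ValidationError("n_iter must be >= 1")
        if self.select_mode not in ("at_least", "at_most"):
            raise ValidationError("select_mode must be 'at_least' or 'at_most'")


@dataclass
class TPCAIteration:
    n_artifact_samples: int
    n_segments: int
    n_components: int
    variance_fractions: np.ndarray
    variance_removed: float


@dataclass
class CorrectionReport:
    method: str
    corrected_samples_per_channel: np.ndarray
    iterations: list[TPCAIteration] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "corrected_samples_per_channel":
                np.asarray(self.corrected_samples_per_channel).tolist(),
            "iterations": [
                {"n_artifact_samples": it.n_artifact_samples,
                 "n_segments": it.n_segments,
                 "n_components": it.n_components,
                 "variance_fractions": np.asarray(it.variance_fractions).tolist(),
                 "variance_removed": it.variance_removed}
                for it in self.iterations],
            "notes": list(self.notes),
        }


# ---------------------------------------------------------------------------
# spline interpolation (MARA-style)
# ---------------------------------------------------------------------------

_MIN_SPLINE_SAMPLES = 5  # smoothing-spline solver needs >= 5 points


def _spline_residual(t: np.ndarray, y: np.ndarray, p: float,
                     notes: list[str]) -> np.ndarray:
    """Segment minus its cubic smoothing-spline model (csaps parameter p)."""
    if y.size < _MIN_SPLINE_SAMPLES or p == 0.0:
        if y.size < _MIN_SPLINE_SAMPLES:
            notes.append(f"segment of {y.size} samples: linear detrend fallback")
        coef = np.polyfit(t, y, 1) if y.size > 1 else np.array([0.0, y[0]])
        return y - np.polyval(coef, t)
    lam = (1.0 - p) / p  # csaps p -> penalty weight
    fit = make_smoothing_spline(t, y, lam=lam)(t)
    return y - fit


def spline_correct(od: ODSeries, mask: MotionMask | None = None,
                   sp: SplineParams | None = None,
                   dp: DetectionParams | None = None
                   ) -> tuple[ODSeries, CorrectionReport]:
    """Spline artifact correction with per-channel masks.

    Each channel uses its own detection mask: a cubic smoothing spline
    (parameter ``p``) is fitted to every artifact segment and subtracted,
    then the channel's alternating segment list is mean-shift stitched.
    Channels with no detected artifacts are returned untouched.
    """
    sp = sp or SplineParams()
    if mask is None:
        mask = detect_motion_by_channel(od, dp)
    if mask.per_channel.shape != od.data.shape:
        raise ValidationError("mask shape does not match the OD matrix")
    out = od.data.copy()
    counts = np.zeros(od.data.shape[1], dtype=int)
    notes: list[str] = []
    for ch in range(od.data.shape[1]):
        col_mask = mask.per_channel[:, ch]
        if not col_mask.any():
            continue
        segs = mask_to_segments(col_mask)
        x = od.data[:, ch]
        replacements = {}
        for seg in segs.artifact_segments:
            t = np.arange(seg.start, seg.end) / od.fs_hz
            replacements[seg.start] = _spline_residual(t, x[seg.start:seg.end],
                                                       sp.p, notes)
            counts[ch] += len(seg)
        out[:, ch] = shift_segments(x, segs, replacements,
                                    join_window_s=sp.join_window_s, fs_hz=od.fs_hz)
    if notes:
        logger.info("spline_correct: %d fallback(s) to linear detrend", len(notes))
    return (ODSeries(od.fs_hz, out, od.probe),
            CorrectionReport("spline", counts, notes=notes))


# ---------------------------------------------------------------------------
# wavelet filtering (Molavi-Dumont style)
# ---------------------------------------------------------------------------

def _needed_level(fs_hz: float, approx_band_hz: float) -> int:
    """Deepest level whose approximation band [0, fs/2^(L+1)] is below the cut."""
    level = 1
    while fs_hz / 2.0 ** (level + 1) > approx_band_hz:
        level += 1
    return level


def wavelet_correct(od: ODSeries, wp: WaveletParams | None = None
                    ) -> tuple[ODSeries, CorrectionReport]:
    """Wavelet outlier filtering, channel by channel (maskless).

    Each channel is decomposed with a non-decimated (stationary) multi-level
    wavelet transform; per detail level a robust Gaussian is fitted
    (center = median, scale = IQR/1.349) and coefficients with two-tailed
    tail probability below ``alpha`` are set to zero.  The approximation
    band is untouched.  Arbitrary run lengths are handled by symmetric
    padding to the needed multiple of ``2**level`` and truncation after the
    inverse transform.
    """
    wp = wp or WaveletParams()
    wavelet = pywt.Wavelet(wp.family)
    n = od.n_samples
    if n < wavelet.dec_len:
        raise ValidationError("run shorter than one wavelet filter length")
    level = wp.max_level or _needed_level(od.fs_hz, wp.approx_band_hz)
    level = max(1, min(level, int(np.log2(max(2, n))) + 1))
    n_pad = int(np.ceil(n / 2 ** level)) * 2 ** level
    z = np.inf if wp.alpha == 0 else norm.ppf(1.0 - wp.alpha / 2.0)
    out = np.empty_like(od.data)
    counts = np.zeros(od.data.shape[1], dtype=int)
    for ch in range(od.data.shape[1]):
        x = np.pad(od.data[:, ch], (0, n_pad - n), mode="symmetric") \
            if n_pad > n else od.data[:, ch]
        coeffs = pywt.swt(x, wavelet, level=level, trim_approx=True, norm=True)
        for d in coeffs[1:]:  # detail bands only; coeffs[0] is the approximation
            if not np.isfinite(z):
                continue
            center = np.median(d)
            q1, q3 = np.percentile(d, [25, 75])
            scale = (q3 - q1) / 1.349
            if scale <= 0:
                continue
            outliers = np.abs(d - center) > scale * z
            counts[ch] += int(outliers.sum())
            d[outliers] = 0.0
        out[:, ch] = pywt.iswt(coeffs, wavelet, norm=True)[:n]
    return (ODSeries(od.fs_hz, out, od.probe),
            CorrectionReport("wavelet", counts))


# ---------------------------------------------------------------------------
# targeted PCA
# ---------------------------------------------------------------------------

def tpca_select_components(variance_fractions: np.ndarray, nsv: float,
                           mode: str = "at_least") -> int:
    """Number of leading components to project out for a variance target.

    ``at_least`` (default): the smallest N whose cumulative variance
    fraction reaches ``nsv``.  ``at_most``: the largest N whose cumulative
    fraction does not exceed ``nsv`` (minimum 1).
    """
    frac = np.asarray(variance_fractions, float)
    if frac.size == 0:
        raise ValidationError("empty variance-fraction list")
    if np.any(frac < -1e-12) or abs(frac.sum() - 1.0) > 1e-9:
        raise ValidationError("variance fractions must be non-negative and sum to 1")
    cum = np.cumsum(frac)
    if mode == "at_least":
        return min(int(np.searchsorted(cum, nsv - 1e-12)) + 1, frac.size)
    hits = np.flatnonzero(cum <= nsv + 1e-12)
    return int(hits[-1] + 1) if hits.size else 1


def _project_out(y: np.ndarray, nsv: float, center: bool, mode: str,
                 n_components: int | None = None
                 ) -> tuple[np.ndarray, int, np.ndarray]:
    """Remove leading principal components of a time x channel matrix."""
    mu = y.mean(axis=0, keepdims=True) if center else np.zeros((1, y.shape[1]))
    yc = y - mu
    u, s, vt = np.linalg.svd(yc, full_matrices=False)
    total = float(np.sum(s ** 2))
    if total == 0.0:
        return y.copy(), 0, np.zeros(0)
    frac = s ** 2 / total
    if n_components is None:
        n_components = tpca_select_components(frac, nsv, mode)
    n_components = min(n_components, s.size)
    if n_components == 0:
        return y.copy(), 0, frac
    basis = vt[:n_components]
    corrected = yc - (yc @ basis.T) @ basis + mu
    return corrected, n_components, frac


def tpca_correct(od: ODSeries, dp: DetectionParams | None = None,
                 tp: TPCAParams | None = None
                 ) -> tuple[ODSeries, CorrectionReport]:
    """Targeted PCA: iterated PCA filtering of the artifact epochs only.

    Per pass: (1) detect artifacts channel by channel and take the union
    mask over channels; (2) concatenate the OD rows at all artifact samples
    into one matrix; (3) project out the leading components holding >= 97%
    of its variance; (4) stitch the corrected epochs back per channel with
    mean-shift alignment; (5) repeat on the corrected data (3 passes total),
    stopping early when nothing is detected.
    """
    dp = dp or DetectionParams()
    tp = tp or TPCAParams()
    if od.data.shape[1] < 2:
        raise ValidationError("targeted PCA needs at least 2 channels")
    x = od.data.copy()
    report = CorrectionReport("tpca", np.zeros(od.data.shape[1], dtype=int))
    for it in range(tp.n_iter):
        mask = detect_motion_by_channel(ODSeries(od.fs_hz, x, od.probe), dp)
        if not mask.any_flagged:
            if it == 0:
                return od.copy(), report  # nothing to correct: exact identity
            break
        segs = mask_to_segments(mask.union)
        art_idx = np.flatnonzero(mask.union)
        y = x[art_idx, :]
        corrected, n_comp, frac = _project_out(y, tp.nsv, tp.center, tp.select_mode)
        x[art_idx, :] = corrected
        for ch in range(x.shape[1]):
            x[:, ch] = shift_segments(x[:, ch], segs,
                                      join_window_s=tp.join_window_s, fs_hz=od.fs_hz)
        report.corrected_samples_per_channel += art_idx.size
        report.iterations.append(TPCAIteration(
            n_artifact_samples=int(art_idx.size),
            n_segments=len(segs.artifact_segments),
            n_components=n_comp,
            variance_fractions=frac,
            variance_removed=float(frac[:n_comp].sum()) if frac.size else 0.0))
        logger.debug("tPCA pass %d: %d artifact samples, N=%d (%.1f%% variance)",
                     it + 1, art_idx.size, n_comp,
                     100 * (frac[:n_comp].sum() if frac.size else 0))
    return ODSeries(od.fs_hz, x, od.probe), report


# ---------------------------------------------------------------------------
# whole-run PCA baseline
# ---------------------------------------------------------------------------

def pca_correct_full(od: ODSeries, n_components: int | None = None,
                     nsv: float | None = None, center: bool = True
                     ) -> tuple[ODSeries, CorrectionReport]:
    """Standard PCA filtering of the entire run (comparison baseline).

    Identical component-removal math to targeted PCA but applied to the full
    time series, with no stitching and no iteration.  Give either an
    explicit ``n_components`` or a cumulative variance target ``nsv``.
    """
    if od.data.shape[1] < 2:
        raise ValidationError("PCA needs at least 2 channels")
    if n_components is None and nsv is None:
        raise ValidationError("give n_components or nsv")
    if n_components == 0:
        return od.copy(), CorrectionReport("pca", np.zeros(od.data.shape[1], int))
    corrected, n_comp, frac = _project_out(od.data, nsv if nsv is not None else 1.0,
                                           center, "at_least", n_components)
    report = CorrectionReport("pca", np.full(od.data.shape[1], od.n_samples))
    report.iterations.append(TPCAIteration(
        n_artifact_samples=od.n_samples, n_segments=1, n_components=n_comp,
        variance_fractions=frac,
        variance_removed=float(frac[:n_comp].sum()) if frac.size else 0.0))
    return ODSeries(od.fs_hz, corrected, od.probe), report
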