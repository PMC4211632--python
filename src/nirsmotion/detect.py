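"""Channel-wise motion-artifact detection, segmentation, and stitching.

Detection follows the windowed-threshold rule of the HOMER-style
``hmrMotionArtifactByChannel`` procedure: every sample-aligned window of
length ``t_motion`` is flagged when the signal excursion (max - min) within
it exceeds ``std_thresh`` times the channel's noise scale or the absolute
``amp_thresh`` (in OD units); flagged windows are dilated by ``t_mask`` on
each side.  The noise scale is the standard deviation of the channel's
first-difference, so slow physiology and the artifacts themselves do not
mask abrupt excursions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ODSeries, ValidationError

__all__ = [
    "DetectionParams", "MotionMask", "Segment", "SegmentList",
    "detect_motion_by_channel", "mask_to_segments", "shift_segments",
    "channel_noise_scale", "export_mask_intervals",
]


@dataclass
class DetectionParams:
    """Thresholds of the windowed artifact detector (study values)."""

    amp_thresh: float = 5.0  # OD units
    std_thresh: float = 20.0  # multiples of the channel noise scale
    t_motion_s: float = 0.5
    t_mask_s: float = 1.0

    def __post_init__(self) -> None:
        if min(self.amp_thresh, self.std_thresh, self.t_motion_s, self.t_mask_s) <= 0:
            raise ValidationError("all detection parameters must be > 0")


@dataclass
class MotionMask:
    per_channel: np.ndarray  # time x channel, bool
    union: np.ndarray  # time, bool

    def __post_init__(self) -> None:
        self.per_channel = np.asarray(self.per_channel, bool)
        self.union = np.asarray(self.union, bool)
        if self.per_channel.ndim != 2 or self.union.shape != (self.per_channel.shape[0],):
            raise ValidationError("mask shapes are inconsistent")
        if not np.array_equal(self.union, self.per_channel.any(axis=1)):
            raise ValidationError("union mask must be the OR over channels")

    @property
    def any_flagged(self) -> bool:
        return bool(self.union.any())


@dataclass(frozen=True)
class Segment:
    start: int  # inclusive
    end: int  # exclusive
    kind: str  # "clean" | "artifact"

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SegmentList:
    """Alternating clean/artifact segments tiling ``[0, n_samples)``."""

    segments: list[Segment]

    def __post_init__(self) -> None:
        segs = self.segments
        if not segs:
            raise ValidationError("segment list is empty")
        if segs[0].start != 0:
            raise ValidationError("segments must start at sample 0")
        for a, b in zip(segs, segs[1:]):
            if a.end != b.start:
                raise ValidationError("segments must tile the run without gaps")
            if a.kind == b.kind:
                raise ValidationError("segment kinds must alternate")
        for s in segs:
            if s.end <= s.start or s.kind not in ("clean", "artifact"):
                raise ValidationError(f"invalid segment {s}")

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def n_samples(self) -> int:
        return self.segments[-1].end

    @property
    def artifact_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.kind == "artifact"]


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def channel_noise_scale(x: np.ndarray) -> float:
    """Noise scale of one channel: SD of its first-difference."""
    return float(np.std(np.diff(np.asarray(x, float))))


def _detect_one_channel(x: np.ndarray, w: int, m: int, thresh: float) -> np.ndarray:
    """Flag samples of one channel; windows are sample-aligned, length w."""
    n = x.size
    windows = np.lib.stride_tricks.sliding_window_view(x, w)
    excursion = windows.max(axis=1) - windows.min(axis=1)
    starts = np.flatnonzero(excursion > thresh)
    mask = np.zeros(n + 1, dtype=np.int64)
    if starts.size:
        lo = np.clip(starts - m, 0, n)
        hi = np.clip(starts + w + m, 0, n)
        np.add.at(mask, lo, 1)
        np.add.at(mask, hi, -1)
    return np.cumsum(mask[:-1]) > 0


def detect_motion_by_channel(od: ODSeries, dp: DetectionParams | None = None
                             ) -> MotionMask:
    """Windowed motion-artifact detection, channel by channel.

    A window ``[t, t + t_motion)`` is flagged when its max-min excursion
    exceeds ``std_thresh * sigma_channel`` or ``amp_thresh``; flagged windows
    are dilated by ``t_mask`` on each side.  The union mask ORs the channels.
    """
    dp = dp or DetectionParams()
    fs = od.fs_hz
    w = int(round(dp.t_motion_s * fs))
    if w < 2:
        raise ValidationError("t_motion_s must span at least 2 samples at this fs")
    if od.n_samples <= w:
        raise ValidationError("run shorter than t_motion")
    m = int(round(dp.t_mask_s * fs))
    per = np.zeros(od.data.shape, dtype=bool)
    for ch in range(od.data.shape[1]):
        x = od.data[:, ch]
        thresh = min(dp.std_thresh * channel_noise_scale(x), dp.amp_thresh)
        per[:, ch] = _detect_one_channel(x, w, m, thresh)
    return MotionMask(per_channel=per, union=per.any(axis=1))


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def mask_to_segments(mask: np.ndarray) -> SegmentList:
    """Contiguous runs of a boolean vector as alternating segments."""
    mask = np.asarray(mask, bool).ravel()
    if mask.size == 0:
        raise ValidationError("empty mask")
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    bounds = np.concatenate([[0], edges + 1, [mask.size]])
    segs = [Segment(int(a), int(b), "artifact" if mask[a] else "clean")
            for a, b in zip(bounds[:-1], bounds[1:])]
    return SegmentList(segs)


# ---------------------------------------------------------------------------
# mean-shift stitching
# ---------------------------------------------------------------------------

def shift_segments(x: np.ndarray, segs: SegmentList,
                   corrected: dict[int, np.ndarray] | None = None,
                   join_window_s: float | None = None,
                   fs_hz: float | None = None) -> np.ndarray:
    """Stitch a channel back together by mean-shifting successive segments.

    ``corrected`` optionally maps an artifact segment's start sample to its
    replacement values (same length); segments without replacements keep
    their original values.  Walking left to right, each segment after the
    first is offset by (mean of the previous, already-shifted segment) -
    (mean of the current segment), so within-segment differences are
    preserved and every output segment mean equals the first segment's mean.

    With ``join_window_s`` set (requires ``fs_hz``), the two means are
    instead taken over a window of at most that length on each side of the
    junction, clipped to the adjacent segment lengths.  This aligns the
    adjoining time points while preserving each segment's slow structure,
    and is what the spline/targeted-PCA correctors use.
    """
    x = np.asarray(x, float)
    if x.ndim != 1 or x.size != segs.n_samples:
        raise ValidationError("series length does not match the segment list")
    y = x.copy()
    if corrected:
        for seg in segs.artifact_segments:
            if seg.start in corrected:
                rep = np.asarray(corrected[seg.start], float)
                if rep.size != len(seg):
                    raise ValidationError(
                        f"replacement for segment [{seg.start}, {seg.end}) has "
                        f"length {rep.size}, expected {len(seg)}")
                y[seg.start:seg.end] = rep
        extra = set(corrected) - {s.start for s in segs.artifact_segments}
        if extra:
            raise ValidationError(f"replacements do not align with artifact "
                                  f"segments: starts {sorted(extra)}")
    if join_window_s is not None and fs_hz is None:
        raise ValidationError("join_window_s requires fs_hz")
    w = None if join_window_s is None else max(1, int(round(join_window_s * fs_hz)))
    for prev, seg in zip(segs.segments, segs.segments[1:]):
        if w is None:
            prev_mean = y[prev.start:prev.end].mean()
            cur_mean = y[seg.start:seg.end].mean()
        else:
            prev_mean = y[max(prev.start, prev.end - w):prev.end].mean()
            cur_mean = y[seg.start:min(seg.end, seg.start + w)].mean()
        y[seg.start:seg.end] += prev_mean - cur_mean
    return y


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_mask_intervals(mask: MotionMask, fs_hz: float) -> list[tuple[int, float, float]]:
    """Mask as (channel, start_s, end_s) rows, for plotting or audit files."""
    rows = []
    for ch in range(mask.per_channel.shape[1]):
        col = mask.per_channel[:, ch]
        if not col.any():
            continue
        for seg in mask_to_segments(col).artifact_segments:
            rows.append((ch, seg.start / fs_hz, seg.end / fs_hz))
    return rows
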