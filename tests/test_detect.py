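"""Motion detection, mask algebra, segmentation, mean-shift stitching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nirsmotion as nm
from nirsmotion.core import ValidationError
from nirsmotion.detect import Segment, SegmentList, channel_noise_scale

from _oracles import brute_force_motion_mask
from conftest import make_od


def _random_signal(rng, n=1000):
    """Noise plus occasional abrupt steps/spikes so masks are non-trivial."""
    x = np.cumsum(rng.normal(0, 0.005, size=n))
    for _ in range(rng.integers(0, 3)):
        i = rng.integers(10, n - 10)
        if rng.random() < 0.5:
            x[i:] += rng.normal(0, 2.0)
        else:
            x[i] += rng.normal(0, 3.0)
    return x


class TestDetection:
    def test_flat_channel_has_empty_mask(self):
        od = make_od(np.zeros((500, 2)))
        od.data[:, :] += 1e-9 * np.random.default_rng(0).normal(size=(500, 2))
        mask = nm.detect_motion_by_channel(od)
        # tiny noise: excursions never reach 20 sigma of the diff
        assert not mask.any_flagged

    def test_matches_brute_force_oracle_on_random_signals(self):
        dp = nm.DetectionParams()
        rng = np.random.default_rng(123)
        for _ in range(30):
            x = _random_signal(rng)
            od = make_od(np.column_stack([x, x[::-1]]))
            mask = nm.detect_motion_by_channel(od, dp)
            for ch in range(2):
                oracle = brute_force_motion_mask(od.data[:, ch], 25.0, dp)
                assert np.array_equal(mask.per_channel[:, ch], oracle)
            assert np.array_equal(mask.union, mask.per_channel.any(axis=1))

    def test_step_mask_extent(self):
        # flat channel with one abrupt step: windows straddling the step are
        # flagged, so the mask is the dilated union of their supports
        n, k, fs = 1000, 500, 25.0
        x = np.zeros(n)
        x[k:] += 1.0
        od = make_od(x)
        mask = nm.detect_motion_by_channel(od)
        w = int(0.5 * fs)
        m = int(1.0 * fs)
        expected = np.zeros(n, bool)
        expected[k - w + 1 - m:k - 1 + w + m] = True
        assert np.array_equal(mask.per_channel[:, 0], expected)

    def test_high_threshold_disables_detection(self):
        n, k = 1000, 500
        x = np.zeros(n)
        x[k:] += 1.0
        sigma = channel_noise_scale(x)
        od = make_od(x)
        dp = nm.DetectionParams(std_thresh=1.1 / sigma, amp_thresh=5.0)
        assert not nm.detect_motion_by_channel(od, dp).any_flagged

    def test_amp_thresh_criterion(self):
        # huge std_thresh but a small absolute threshold: amp criterion trips
        x = np.zeros(1000)
        x[500:] += 1.0
        od = make_od(x)
        dp = nm.DetectionParams(std_thresh=1e9, amp_thresh=0.5)
        assert nm.detect_motion_by_channel(od, dp).any_flagged

    def test_mask_dilation_monotone_in_t_mask(self):
        rng = np.random.default_rng(5)
        od = make_od(_random_signal(rng, 600))
        small = nm.detect_motion_by_channel(od, nm.DetectionParams(t_mask_s=0.5))
        large = nm.detect_motion_by_channel(od, nm.DetectionParams(t_mask_s=2.0))
        assert np.all(large.per_channel[small.per_channel])

    def test_window_too_short_rejected(self):
        od = make_od(np.zeros((100, 2)), fs_hz=2.0)
        with pytest.raises(ValidationError):
            nm.detect_motion_by_channel(od, nm.DetectionParams(t_motion_s=0.5))


class TestSegments:
    def test_all_clean(self):
        segs = nm.mask_to_segments(np.zeros(50, bool))
        assert len(segs) == 1
        assert segs.segments[0] == Segment(0, 50, "clean")

    def test_all_artifact(self):
        segs = nm.mask_to_segments(np.ones(50, bool))
        assert segs.segments == [Segment(0, 50, "artifact")]

    def test_two_artifact_intervals(self):
        mask = np.zeros(50, bool)
        mask[10:20] = True
        mask[30:40] = True
        segs = nm.mask_to_segments(mask)
        assert [(s.start, s.end, s.kind) for s in segs] == [
            (0, 10, "clean"), (10, 20, "artifact"), (20, 30, "clean"),
            (30, 40, "artifact"), (40, 50, "clean")]

    @given(st.lists(st.booleans(), min_size=1, max_size=200))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_tiling_invariant(self, bits):
        segs = nm.mask_to_segments(np.asarray(bits, bool))
        assert segs.segments[0].start == 0
        assert segs.n_samples == len(bits)
        covered = np.zeros(len(bits), int)
        for s in segs:
            covered[s.start:s.end] += 1
        assert np.all(covered == 1)


class TestShiftSegments:
    def _segs(self, *lengths, first="clean"):
        kinds = ["clean", "artifact"] if first == "clean" else ["artifact", "clean"]
        out, pos = [], 0
        for i, ln in enumerate(lengths):
            out.append(Segment(pos, pos + ln, kinds[i % 2]))
            pos += ln
        return SegmentList(out)

    def test_hand_computed_shift(self):
        x = np.array([1.0, 1, 1, 1, 5, 5, 6, 6])
        y = nm.shift_segments(x, self._segs(4, 4))
        assert np.allclose(y, [1, 1, 1, 1, 0.5, 0.5, 1.5, 1.5])

    def test_noop_when_means_equal(self):
        x = np.array([1.0, 1, 1, 1, 1, 1])
        y = nm.shift_segments(x, self._segs(3, 3))
        assert np.array_equal(y, x)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_all_segment_means_equal_first(self, seed):
        rng = np.random.default_rng(seed)
        lengths = rng.integers(2, 20, size=rng.integers(2, 6))
        x = rng.normal(0, 3, size=int(lengths.sum()))
        segs = self._segs(*lengths)
        y = nm.shift_segments(x, segs)
        m0 = y[segs.segments[0].start:segs.segments[0].end].mean()
        for s in segs:
            assert y[s.start:s.end].mean() == pytest.approx(m0, abs=1e-9)
            # within-segment differences unchanged
            assert np.allclose(np.diff(y[s.start:s.end]),
                               np.diff(x[s.start:s.end]), atol=1e-12)

    def test_replacement_length_mismatch_rejected(self):
        x = np.zeros(8)
        with pytest.raises(ValidationError):
            nm.shift_segments(x, self._segs(4, 4), {4: np.zeros(3)})

    def test_junction_window_preserves_slow_trend(self):
        # a linear ramp split into segments: junction-mode stitching keeps
        # most of the ramp (bias ~ slope * window per junction) while
        # full-segment means level the segments onto a common mean
        x = np.linspace(0.0, 1.0, 100)
        segs = self._segs(40, 20, 40)
        y_junction = nm.shift_segments(x, segs, join_window_s=0.2, fs_hz=25.0)
        y_full = nm.shift_segments(x, segs)
        for s in segs:  # within-segment shape always preserved
            assert np.allclose(np.diff(y_junction[s.start:s.end]),
                               np.diff(x[s.start:s.end]), atol=1e-12)
        trend = x[-1] - x[0]
        assert abs((y_junction[-1] - y_junction[0]) - trend) < 0.15 * trend
        assert (y_full[-1] - y_full[0]) < (y_junction[-1] - y_junction[0])


def test_export_mask_intervals():
    from nirsmotion.detect import export_mask_intervals
    mask = np.zeros((100, 2), bool)
    mask[10:20, 0] = True
    mm = nm.MotionMask(mask, mask.any(axis=1))
    assert export_mask_intervals(mm, 25.0) == [(0, 0.4, 0.8)]
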