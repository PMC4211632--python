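"""Spline, wavelet, targeted-PCA and whole-run-PCA correctors."""

import numpy as np
import pytest

import nirsmotion as nm
from nirsmotion.core import ValidationError
from nirsmotion.detect import MotionMask

from conftest import make_od


def _artifact_free_od(seed=4):
    """Realistic physiology + HRF, zero artifact events: nothing to detect."""
    cfg = nm.GeneratorConfig(seed=seed,
                             artifacts=nm.ArtifactSpec(rate_per_min=0.0))
    rec, _ = nm.generate_run(cfg)
    return nm.intensity_to_od(rec)


def _burst_od(n=1500, k=700, fs=25.0, gains=(1.0, 0.5), amp=1.0):
    """Zero background with one shared oscillatory burst (exactly rank 1)."""
    t = np.arange(n) / fs
    profile = np.zeros(n)
    sel = np.abs(t - t[k]) < 1.0
    profile[sel] = amp * np.exp(-0.5 * ((t[sel] - t[k]) / 0.25) ** 2) \
        * np.sin(2 * np.pi * 3.0 * (t[sel] - t[k]))
    return make_od(np.column_stack([profile * g for g in gains]), fs), profile


class TestSpline:
    def test_identity_on_artifact_free_run(self):
        od = _artifact_free_od()
        out, report = nm.spline_correct(od)
        assert np.array_equal(out.data, od.data)
        assert np.all(report.corrected_samples_per_channel == 0)

    def test_smooth_polynomial_segment_flattened_at_p_one(self):
        # a cubic-polynomial artifact is reproduced exactly by the
        # interpolating spline, so the residual segment is constant
        n, fs = 1000, 25.0
        x = np.zeros(n)
        t = np.arange(300, 500) / fs
        x[300:500] = 5.0 + 0.3 * (t - 14) ** 3 - 2.0 * (t - 14)
        mask = np.zeros((n, 2), bool)
        mask[300:500, :] = True
        od = make_od(x)
        out, _ = nm.spline_correct(od, MotionMask(mask, mask.any(axis=1)),
                                   nm.SplineParams(p=1.0))
        seg = out.data[300:500, 0]
        assert np.max(np.abs(seg - seg.mean())) < 1e-6

    def test_step_artifact_offset_removed(self):
        n = 2000
        x = np.zeros(n)
        x[1000:] += 1.0  # +1 OD baseline shift
        mask = np.zeros((n, 2), bool)
        mask[990:1010, :] = True
        od = make_od(x)
        out, _ = nm.spline_correct(od, MotionMask(mask, mask.any(axis=1)))
        assert abs(out.data[1010:, 0].mean() - out.data[:990, 0].mean()) < 0.01

    def test_short_segment_linear_fallback(self):
        n = 500
        x = np.random.default_rng(0).normal(0, 0.01, n)
        mask = np.zeros((n, 2), bool)
        mask[100:103, :] = True  # 3 samples: below the spline minimum
        od = make_od(x)
        out, report = nm.spline_correct(od, MotionMask(mask, mask.any(axis=1)))
        assert out.data.shape == od.data.shape
        assert any("linear detrend" in note for note in report.notes)


class TestWavelet:
    def test_alpha_zero_is_identity_nondyadic_length(self):
        rng = np.random.default_rng(1)
        od = make_od(rng.normal(size=(1007, 2)))
        out, _ = nm.wavelet_correct(od, nm.WaveletParams(alpha=0.0))
        assert np.allclose(out.data, od.data, atol=1e-8)

    def test_spike_suppressed_sine_preserved(self):
        fs = 25.0
        t = np.arange(0, 240, 1 / fs)
        sine = np.sin(2 * np.pi * 0.05 * t)
        x = sine.copy()
        k = t.size // 2
        x[k] += 20.0
        out, _ = nm.wavelet_correct(make_od(x), nm.WaveletParams(alpha=0.1))
        res = out.data[:, 0]
        assert abs(res[k] - sine[k]) <= 0.1 * 20.0  # spike down >= 90%
        idx = np.arange(t.size)
        body = (idx > 250) & (idx < t.size - 250) & (np.abs(idx - k) > 50)
        rms_change = np.sqrt(np.mean((res - x)[body] ** 2))
        assert rms_change < 0.1 * np.sqrt(np.mean(sine ** 2))

    def test_gaussian_tail_calibration(self):
        rng = np.random.default_rng(9)
        od = make_od(rng.normal(size=(8192, 2)))
        wp = nm.WaveletParams(alpha=0.1, max_level=6)
        _, report = nm.wavelet_correct(od, wp)
        n_detail = 6 * 8192
        frac = report.corrected_samples_per_channel / n_detail
        assert np.all(np.abs(frac - 0.1) < 0.03)

    def test_too_short_run_rejected(self):
        od = make_od(np.zeros((3, 2)))
        with pytest.raises(ValidationError):
            nm.wavelet_correct(od)


class TestComponentSelection:
    @pytest.mark.parametrize("fractions, nsv, expected", [
        ([0.90, 0.06, 0.03, 0.01], 0.97, 3),
        ([0.98, 0.02], 0.97, 1),
        ([1.0], 0.5, 1),
        ([0.5, 0.5], 1.0, 2),
    ])
    def test_smallest_count_reaching_target(self, fractions, nsv, expected):
        assert nm.tpca_select_components(fractions, nsv) == expected

    def test_at_most_reading(self):
        assert nm.tpca_select_components([0.90, 0.06, 0.03, 0.01], 0.97,
                                         mode="at_most") == 2
        assert nm.tpca_select_components([0.98, 0.02], 0.5, mode="at_most") == 1

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            nm.tpca_select_components([], 0.97)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValidationError):
            nm.tpca_select_components([0.7, 0.7], 0.97)


class TestTargetedPCA:
    def test_identity_on_artifact_free_run(self):
        od = _artifact_free_od()
        out, report = nm.tpca_correct(od)
        assert np.array_equal(out.data, od.data)
        assert report.iterations == []

    def test_rank_one_artifact_removed_in_one_pass(self):
        od, profile = _burst_od()
        tp = nm.TPCAParams(n_iter=1)
        out, report = nm.tpca_correct(od, tp=tp)
        assert report.iterations[0].n_components == 1
        pre = np.sum(od.data ** 2)
        post = np.sum(out.data ** 2)
        assert post < 0.05 * pre

    def test_nsv_one_flattens_artifact_segments(self):
        od, _ = _burst_od(gains=(1.0, 0.7))
        mask = nm.detect_motion_by_channel(od)
        assert mask.any_flagged
        out, _ = nm.tpca_correct(od, tp=nm.TPCAParams(nsv=1.0, n_iter=1))
        segs = nm.mask_to_segments(mask.union)
        for seg in segs.artifact_segments:
            for ch in range(2):
                assert np.std(out.data[seg.start:seg.end, ch]) < 1e-9

    def test_clean_segment_shapes_preserved(self):
        od, _ = _burst_od()
        mask = nm.detect_motion_by_channel(od)
        out, _ = nm.tpca_correct(od, tp=nm.TPCAParams(n_iter=1))
        segs = nm.mask_to_segments(mask.union)
        for seg in segs:
            if seg.kind == "clean":
                assert np.allclose(np.diff(out.data[seg.start:seg.end, 0]),
                                   np.diff(od.data[seg.start:seg.end, 0]),
                                   atol=1e-9)

    def test_single_channel_rejected(self):
        probe = nm.ProbeGeometry([[0, 0, 0]], [[3, 0, 0]], [(0, 0, 690.0)])
        od = nm.ODSeries(25.0, np.zeros((100, 1)), probe)
        with pytest.raises(ValidationError):
            nm.tpca_correct(od)

    def test_degenerate_full_mask_equals_whole_run_pca(self):
        rng = np.random.default_rng(17)
        od = make_od(rng.normal(size=(600, 2)))
        dp = nm.DetectionParams(amp_thresh=1e-12)  # every window trips
        tp = nm.TPCAParams(n_iter=1, join_window_s=None)
        out_t, rep = nm.tpca_correct(od, dp, tp)
        assert rep.iterations[0].n_artifact_samples == 600
        out_p, _ = nm.pca_correct_full(od, nsv=tp.nsv)
        assert np.allclose(out_t.data, out_p.data, atol=1e-9)


class TestWholeRunPCA:
    def test_zero_components_is_identity(self):
        od = make_od(np.random.default_rng(0).normal(size=(200, 2)))
        out, _ = nm.pca_correct_full(od, n_components=0)
        assert np.array_equal(out.data, od.data)

    def test_rank_one_data_annihilated(self):
        t = np.linspace(0, 1, 300)
        profile = np.sin(2 * np.pi * 3 * t)
        od = make_od(np.column_stack([profile, 0.3 * profile]))
        out, _ = nm.pca_correct_full(od, n_components=1, center=False)
        assert np.sum(out.data ** 2) < 1e-9 * np.sum(od.data ** 2)

    def test_residual_energy_monotone_in_component_count(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(500, 6)) @ rng.normal(size=(6, 6))
        probe = nm.ProbeGeometry(
            [[0, 0, 0]], [[3, 0, 0], [0, 3, 0], [6, 0, 0]],
            [(0, d, wl) for d in range(3) for wl in (690.0, 830.0)])
        od = nm.ODSeries(25.0, data, probe)
        energies = []
        for n_comp in range(0, 7):
            out, _ = nm.pca_correct_full(od, n_components=n_comp)
            energies.append(np.sum((out.data - out.data.mean(0)) ** 2))
        assert np.all(np.diff(energies) <= 1e-9)


def test_all_correctors_identity_on_artifact_free_input():
    od = _artifact_free_od()
    assert np.array_equal(nm.spline_correct(od)[0].data, od.data)
    assert np.array_equal(nm.tpca_correct(od)[0].data, od.data)
    out_w, _ = nm.wavelet_correct(od, nm.WaveletParams(alpha=0.0))
    assert np.allclose(out_w.data, od.data, atol=1e-8)
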