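import numpy as np
import pandas as pd
import pytest

from locsrr.errors import DegenerateInputError
from locsrr.evaluation import (
    DetectionParams,
    bottom_hat_detect,
    bottom_hat_map,
    fscore,
    score_detection,
    size_stratified_fscore,
    threshold_sweep,
    windowed_spectrum,
)
from locsrr.phantom import PhantomTruth


def _truth_from_labels(labels):
    rows = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        idx = np.argwhere(labels == lab)
        rows.append(
            {"id": int(lab), "size_vox": len(idx), "cx_mm": 0.0, "cy_mm": 0.0, "cz_mm": 0.0}
        )
    return PhantomTruth(labels, pd.DataFrame(rows))


class TestFScore:
    def test_printed_formula(self):
        assert fscore(0.5, 1.0) == pytest.approx(2 / 3)
        assert fscore(1.0, 1.0) == 1.0
        assert fscore(0.0, 0.0) == 0.0


class TestBottomHatDetect:
    def test_flat_volume_yields_nothing(self):
        params = DetectionParams(boundary_margin_vox=0, percentile=99.0)
        labels = bottom_hat_detect(np.ones((20, 20, 20)), params)
        assert labels.max() == 0

    def test_small_dark_spot_found_as_single_component(self):
        vol = np.ones((24, 24, 24))
        vol[10:12, 12, 10:12] = 0.1  # 2x2x1 dark spot in the (x,z) plane
        params = DetectionParams(boundary_margin_vox=0, percentile=99.9)
        labels = bottom_hat_detect(vol, params)
        assert labels.max() == 1
        assert labels[10, 12, 10] == 1

    def test_large_disk_responds_only_at_rim(self):
        # a dark disk much larger than the 5x5 element: closing cannot fill
        # it, so the interior response is zero and matches the direct
        # morphological oracle
        from scipy import ndimage as ndi

        vol = np.ones((40, 3, 40))
        X, Z = np.meshgrid(np.arange(40), np.arange(40), indexing="ij")
        disk = (X - 20) ** 2 + (Z - 20) ** 2 <= 7.5**2
        vol[:, 1, :][disk] = 0.2
        params = DetectionParams(boundary_margin_vox=0)
        bh = bottom_hat_map(vol, params)
        # oracle: per-slice grayscale closing minus image with a 5x5 square
        oracle = np.empty_like(vol)
        for j in range(vol.shape[1]):
            closing = ndi.grey_closing(vol[:, j, :], footprint=np.ones((5, 5)))
            oracle[:, j, :] = closing - vol[:, j, :]
        assert np.allclose(bh, oracle)
        interior = disk & (ndi.binary_erosion(disk, iterations=4))
        assert np.allclose(bh[:, 1, :][interior], 0.0)

    def test_empty_mask_after_erosion_rejected(self):
        params = DetectionParams(boundary_margin_vox=4)
        tiny_mask = np.zeros((12, 12, 12), bool)
        tiny_mask[5:7, 5:7, 5:7] = True
        with pytest.raises(DegenerateInputError):
            bottom_hat_detect(np.ones((12, 12, 12)), params, mask=tiny_mask)


class TestScoreDetection:
    def test_perfect_detection(self):
        labels = np.zeros((10, 10, 10), int)
        labels[2:4, 2:4, 2:4] = 1
        labels[6:8, 6:8, 6:8] = 2
        truth = _truth_from_labels(labels)
        res = score_detection(labels.copy(), truth)
        assert res.precision == res.recall == res.f_score == 1.0

    def test_empty_detection_scores_zero(self):
        labels = np.zeros((10, 10, 10), int)
        labels[2:4, 2:4, 2:4] = 1
        truth = _truth_from_labels(labels)
        res = score_detection(np.zeros_like(labels), truth)
        assert res.precision == 0.0 and res.recall == 0.0 and res.f_score == 0.0

    def test_half_precision_full_recall(self):
        truth_labels = np.zeros((10, 10, 10), int)
        truth_labels[2:4, 2:4, 2:4] = 1
        truth = _truth_from_labels(truth_labels)
        detected = truth_labels.copy()
        detected[7:9, 7:9, 7:9] = 2  # one spurious component
        res = score_detection(detected, truth)
        assert res.precision == 0.5
        assert res.recall == 1.0
        assert res.f_score == pytest.approx(2 / 3)

    def test_grid_mismatch_rejected(self):
        truth = _truth_from_labels(np.zeros((4, 4, 4), int))
        with pytest.raises(ValueError):
            score_detection(np.zeros((5, 5, 5), int), truth)

    def test_matching_is_one_to_one_by_overlap(self):
        truth_labels = np.zeros((12, 12, 12), int)
        truth_labels[2:6, 2:6, 2:6] = 1
        truth = _truth_from_labels(truth_labels)
        # two detections overlapping the one truth object: only the larger
        # overlap may match; the other is a false positive
        detected = np.zeros_like(truth_labels)
        detected[2:5, 2:6, 2:6] = 1
        detected[5, 2:6, 2:6] = 2
        res = score_detection(detected, truth)
        assert res.precision == 0.5
        assert res.recall == 1.0
        assert res.tp_ids == [1]


def _noisy_scene(rng):
    vol = np.ones((32, 32, 32)) + rng.normal(0, 0.02, (32, 32, 32))
    truth_labels = np.zeros((32, 32, 32), int)
    spots = [((8, 16, 8), 1), ((22, 16, 22), 2), ((8, 16, 24), 3)]
    for (i, j, k), lab in spots:
        vol[i : i + 2, j, k : k + 2] = 0.1
        truth_labels[i : i + 2, j, k : k + 2] = lab
    return vol, _truth_from_labels(truth_labels)


class TestThresholdSweep:
    def test_single_percentile_equals_direct_call(self, rng):
        vol, truth = _noisy_scene(rng)
        params = DetectionParams(percentiles=(99.5,), boundary_margin_vox=0)
        table, best_pct, best = threshold_sweep(vol, truth, params)
        direct_labels = bottom_hat_detect(vol, params, percentile=99.5)
        direct = score_detection(direct_labels, truth)
        assert best_pct == 99.5
        assert len(table) == 1
        assert best.f_score == direct.f_score

    def test_curve_matches_per_percentile_loop(self, rng):
        vol, truth = _noisy_scene(rng)
        params = DetectionParams(
            percentiles=(95.0, 99.0, 99.9), boundary_margin_vox=0
        )
        table, _, _ = threshold_sweep(vol, truth, params)
        for pct, f_expected in zip(table["percentile"], table["f_score"]):
            labels = bottom_hat_detect(vol, params, percentile=pct)
            assert score_detection(labels, truth).f_score == f_expected

    def test_percentile_100_empty_detection(self, rng):
        vol, truth = _noisy_scene(rng)
        params = DetectionParams(percentiles=(100.0,), boundary_margin_vox=0)
        table, best_pct, best = threshold_sweep(vol, truth, params)
        assert best.f_score == 0.0

    def test_tie_broken_toward_higher_percentile(self, rng):
        vol, truth = _noisy_scene(rng)
        params = DetectionParams(
            percentiles=(99.97, 99.98), boundary_margin_vox=0
        )
        table, best_pct, _ = threshold_sweep(vol, truth, params)
        f = table["f_score"]
        if f.iloc[0] == f.iloc[1]:
            assert best_pct == 99.98


class TestSizeStratified:
    def test_cutoff_zero_equals_overall_f(self, rng):
        vol, truth = _noisy_scene(rng)
        params = DetectionParams(percentile=99.8, boundary_margin_vox=0)
        detected = bottom_hat_detect(vol, params)
        overall = score_detection(detected, truth).f_score
        table = size_stratified_fscore(vol, truth, params, [0], detected=detected)
        assert table["f_score"].iloc[0] == overall

    def test_cutoff_beyond_largest_object_is_missing(self, rng):
        vol, truth = _noisy_scene(rng)
        params = DetectionParams(percentile=99.8, boundary_margin_vox=0)
        table = size_stratified_fscore(vol, truth, params, [0, 1000])
        assert np.isnan(table["f_score"].iloc[1])

    def test_cutoffs_must_ascend(self, rng):
        vol, truth = _noisy_scene(rng)
        with pytest.raises(ValueError):
            size_stratified_fscore(vol, truth, DetectionParams(), [5, 2])


class TestWindowedSpectrum:
    def test_constant_slice_has_no_high_frequency_energy(self):
        res = windowed_spectrum(np.full((32, 32), 3.0), spacing_mm=0.13)
        assert res.hf_fraction == pytest.approx(0.0, abs=1e-12)

    def test_sinusoid_peaks_at_its_frequency(self):
        n, spacing = 64, 0.5
        f0 = 0.25  # cycles/mm
        x = np.arange(n) * spacing
        slice_2d = np.outer(np.sin(2 * np.pi * f0 * x), np.ones(n))
        res = windowed_spectrum(slice_2d, spacing_mm=spacing, window="none")
        peak = np.unravel_index(np.argmax(res.spectrum), res.spectrum.shape)
        assert abs(abs(res.freq_x[peak[0]]) - f0) < 1.0 / (n * spacing)

    def test_blurring_reduces_high_frequency_fraction(self, rng):
        from scipy import ndimage as ndi

        sharp = rng.normal(size=(48, 48))
        blurred = ndi.gaussian_filter(sharp, 2.0)
        hf_sharp = windowed_spectrum(sharp, 0.13).hf_fraction
        hf_blurred = windowed_spectrum(blurred, 0.13).hf_fraction
        assert hf_sharp >= hf_blurred

    def test_degenerate_slice_rejected(self):
        with pytest.raises(ValueError):
            windowed_spectrum(np.ones((4, 4)), 0.13)
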