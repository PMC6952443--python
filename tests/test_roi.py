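"""ROI segmentation, persistence rule, classification, trace extraction."""

import numpy as np
import pytest

from astroca import roi as R
from astroca import synthetic as syn


def _iou(a, b):
    return (a & b).sum() / (a | b).sum()


@pytest.fixture(scope="module")
def segmented():
    p = syn.SyntheticMovieParams(height=128, width=128, n_frames=60,
                                 rigid_shift_amplitude=0.0,
                                 nonrigid_amplitude=0.0, noise_sd=5.0,
                                 seed=3)
    movie, truth = syn.generate_movie(p)
    rois = R.segment_rois(movie.structural, R.SegmentationParams())
    rois = R.classify_compartments(rois, vessel_map=truth.vessel_mask)
    return movie, truth, rois


class TestSegmentRois:
    def test_uniform_stack_yields_zero_rois(self):
        stack = np.full((5, 64, 64), 10.0)
        rois = R.segment_rois(stack, R.SegmentationParams())
        assert rois.n_rois == 0

    def test_planted_rois_recovered_with_good_iou(self, segmented):
        _, truth, rois = segmented
        for i in range(1, truth.n_rois + 1):
            tm = truth.label_image == i
            best = max(_iou(tm, rois.label_image == j)
                       for j in range(1, rois.n_rois + 1))
            assert best >= 0.7

    def test_persistence_rule_is_strict_majority(self):
        # identical squares bright in 60% / 50% / 40% of frames:
        # only the strict-majority one survives
        n = 20
        stack = np.full((n, 64, 64), 10.0)
        for t in range(n):
            if t < 12:
                stack[t, 5:15, 5:15] = 100.0      # 60% → kept
            if t < 10:
                stack[t, 25:35, 25:35] = 100.0    # exactly 50% → dropped
            if t < 8:
                stack[t, 45:55, 45:55] = 100.0    # 40% → dropped
        rois = R.segment_rois(stack, R.SegmentationParams())
        assert rois.n_rois == 1
        assert rois.label_image[10, 10] == 1
        assert rois.label_image[30, 30] == 0
        assert rois.label_image[50, 50] == 0

    def test_labels_partition_foreground(self, segmented):
        _, _, rois = segmented
        assert rois.label_image.min() == 0
        assert set(np.unique(rois.label_image)) == set(
            range(rois.n_rois + 1))
        assert np.all(rois.areas >= R.SegmentationParams().min_roi_area)

    def test_invariant_to_affine_intensity_rescale(self, segmented):
        movie, _, rois = segmented
        params = R.SegmentationParams()
        scaled = R.segment_rois(3.0 * movie.structural + 17.0,
                                R.SegmentationParams(
                                    contrast_floor=3.0 * params.contrast_floor))
        np.testing.assert_array_equal(scaled.label_image > 0,
                                      rois.label_image > 0)

    def test_even_block_size_rejected(self):
        with pytest.raises(ValueError):
            R.segment_rois(np.zeros((3, 16, 16)),
                           R.SegmentationParams(block_size=10))


class TestClassifyCompartments:
    def test_generator_labels_mostly_recovered(self, segmented):
        _, truth, rois = segmented
        from collections import Counter
        hits = total = 0
        for i in range(1, truth.n_rois + 1):
            tm = truth.label_image == i
            ov = rois.label_image[tm]
            ov = ov[ov > 0]
            if ov.size == 0:
                continue
            j = Counter(ov).most_common(1)[0][0]
            total += 1
            hits += rois.compartments[j - 1] == truth.compartments[i - 1]
        assert total >= 10
        assert hits / total >= 0.8

    def test_endfeet_require_vessel_map(self, segmented):
        movie, _, _ = segmented
        rois = R.segment_rois(movie.structural, R.SegmentationParams())
        rois = R.classify_compartments(rois, vessel_map=None)
        assert "endfoot" not in rois.compartments

    def test_empty_roiset_rejected(self):
        empty = R.ROISet(label_image=np.zeros((8, 8), int), compartments=[],
                         areas=np.array([], int), centroids=np.empty((0, 2)))
        with pytest.raises(ValueError):
            R.classify_compartments(empty)


class TestExtractTraces:
    def test_single_pixel_roi_returns_that_pixel(self):
        movie = np.random.default_rng(0).random((30, 8, 8))
        lab = np.zeros((8, 8), int)
        lab[3, 4] = 1
        rois = R.ROISet(label_image=lab, compartments=["soma"],
                        areas=np.array([1]), centroids=np.array([[3., 4.]]))
        traces = R.extract_traces(movie, rois)
        np.testing.assert_allclose(traces[0], movie[:, 3, 4])

    def test_zero_movie_gives_zero_traces(self):
        lab = np.zeros((8, 8), int)
        lab[2:4, 2:4] = 1
        rois = R.ROISet(label_image=lab, compartments=["soma"],
                        areas=np.array([4]), centroids=np.array([[2.5, 2.5]]))
        traces = R.extract_traces(np.zeros((10, 8, 8)), rois)
        np.testing.assert_allclose(traces, 0.0)

    def test_disjoint_rois_recover_their_own_events(self):
        T = 200
        a = np.zeros(T); a[40:60] = 1.0
        b = np.zeros(T); b[120:140] = 1.0
        movie = np.zeros((T, 16, 16))
        movie[:, 2:6, 2:6] = a[:, None, None]
        movie[:, 10:14, 10:14] = b[:, None, None]
        lab = np.zeros((16, 16), int)
        lab[2:6, 2:6] = 1
        lab[10:14, 10:14] = 2
        rois = R.ROISet(label_image=lab, compartments=["soma", "soma"],
                        areas=np.array([16, 16]),
                        centroids=np.array([[3.5, 3.5], [11.5, 11.5]]))
        tr = R.extract_traces(movie, rois)
        assert np.corrcoef(tr[0], a)[0, 1] > 0.9
        assert np.corrcoef(tr[1], b)[0, 1] > 0.9
        assert abs(np.corrcoef(tr[0], b)[0, 1]) < 0.3


class TestBulkTrace:
    def test_constant_movie_is_flat_zero(self):
        movie = np.full((20, 8, 8), 40.0)
        mask = np.ones((8, 8), bool)
        np.testing.assert_allclose(R.bulk_trace(movie, mask), 0.0)

    def test_planted_step_recovered(self):
        movie = np.full((30, 8, 8), 100.0)
        movie[15:] = 110.0
        tr = R.bulk_trace(movie, np.ones((8, 8), bool),
                          prestimulus_frames=10)
        assert tr[20] == pytest.approx(0.10, abs=0.001)

    def test_half_mask_halves_localized_response(self):
        movie = np.full((30, 8, 8), 100.0)
        movie[15:, :, :4] = 120.0       # response only in left half
        full = R.bulk_trace(movie, np.ones((8, 8), bool), 10)
        left = np.zeros((8, 8), bool)
        left[:, :4] = True
        half = R.bulk_trace(movie, left, 10)
        # full-mask amplitude is ~half the left-mask amplitude
        assert full[25] == pytest.approx(0.5 * half[25] * (100 / 100), rel=0.05)

    def test_empty_mask_and_window_rejected(self):
        movie = np.zeros((10, 4, 4))
        with pytest.raises(ValueError):
            R.bulk_trace(movie, np.zeros((4, 4), bool))
        with pytest.raises(ValueError):
            R.bulk_trace(np.ones((10, 4, 4)), np.ones((4, 4), bool),
                         prestimulus_frames=(5, 5))
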