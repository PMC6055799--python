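"""Segmentation: contrast, feature bank, classifier, threshold, closing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ernet.evaluation import jaccard
from ernet.phantom import PhantomSpec, generate_network_graph, render_phantom
from ernet.segmentation import (CLASS_BACKGROUND, CLASS_ER, CLASS_REJECTED,
                                close_mask, enhance_contrast,
                                extract_pixel_features, segment_image,
                                train_pixel_classifier)

from conftest import noiseless_spec


class TestEnhanceContrast:
    def test_constant_frame_degenerate_range(self):
        out = enhance_contrast(np.full((16, 16), 3.0))
        assert np.all(out == 0.0)

    def test_linear_map_without_saturation(self):
        frame = np.array([[10.0, 50.0], [90.0, 30.0]])
        out = enhance_contrast(frame, saturation_fraction=0.0)
        assert out[0, 0] == pytest.approx(0.0)
        assert out[1, 0] == pytest.approx(1.0)
        assert out[0, 1] == pytest.approx(0.5)

    def test_rank_order_preserved(self, rng):
        frame = rng.normal(size=(32, 32))
        out = enhance_contrast(frame, saturation_fraction=0.1)
        flat_in, flat_out = frame.ravel(), out.ravel()
        order = np.argsort(flat_in, kind="mergesort")
        assert np.all(np.diff(flat_out[order]) >= 0)

    def test_invalid_saturation_rejected(self):
        with pytest.raises(ValueError):
            enhance_contrast(np.zeros((4, 4)), saturation_fraction=0.5)


class TestFeatures:
    def test_constant_frame_zero_derivatives(self):
        feats = extract_pixel_features(np.full((20, 20), 2.0), scales=(1.0, 2.0))
        # per scale: [smoothed, gradient, LoG, DoG]; derivative features must
        # vanish (up to the discretized Gaussian-derivative kernel residual)
        for k in range(2):
            assert np.allclose(feats[..., 4 * k + 1:4 * k + 4], 0.0, atol=5e-4)

    def test_shape_contract(self, rng):
        frame = rng.normal(size=(24, 30))
        feats = extract_pixel_features(frame, scales=(1.0, 2.0, 4.0))
        assert feats.shape == (24, 30, 12)

    def test_smoothed_variance_nonincreasing_in_scale(self, rng):
        frame = rng.normal(size=(64, 64))
        scales = (1.0, 2.0, 4.0, 8.0)
        feats = extract_pixel_features(frame, scales=scales)
        variances = [feats[..., 4 * k].var() for k in range(len(scales))]
        assert np.all(np.diff(variances) <= 1e-12)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            extract_pixel_features(np.zeros((8, 8)), scales=(1.0, -2.0))


def _labels_from_truth(truth, rng, n_er=1500, n_bg=1500, n_rej=500):
    labels = np.full(truth.er_mask.shape, -1, dtype=int)

    def sample(mask, cls, n):
        idx = np.argwhere(mask)
        sel = idx[rng.choice(len(idx), size=min(n, len(idx)), replace=False)]
        labels[sel[:, 0], sel[:, 1]] = cls

    sample(truth.er_mask & ~truth.distractor_mask, CLASS_ER, n_er)
    sample(~truth.er_mask & ~truth.distractor_mask & truth.roi_mask,
           CLASS_BACKGROUND, n_bg)
    sample(truth.distractor_mask, CLASS_REJECTED, n_rej)
    return labels


class TestClassifier:
    @pytest.fixture(scope="class")
    def trained(self):
        spec = PhantomSpec(seed=7, n_distractors=5, peak_photons=100,
                           read_noise=0.01)
        graph = generate_network_graph(spec)
        stack, truth = render_phantom(graph, spec)
        frame = enhance_contrast(stack.frame(0), 0.01, 1.0)
        feats = extract_pixel_features(frame)
        labels = _labels_from_truth(truth, np.random.default_rng(0))
        clf = train_pixel_classifier(feats, labels, seed=0)
        return frame, feats, truth, clf

    def test_separable_three_level_phantom_perfect_recall(self):
        frame = np.zeros((30, 30))
        frame[:10] = 0.0
        frame[10:20] = 0.5
        frame[20:] = 1.0
        labels = np.full(frame.shape, -1, dtype=int)
        labels[:10] = CLASS_BACKGROUND
        labels[10:20] = CLASS_ER
        labels[20:] = CLASS_REJECTED
        feats = extract_pixel_features(frame, scales=(1.0,))
        clf = train_pixel_classifier(feats, labels, scales=(1.0,), seed=0)
        assert all(r == 1.0 for r in clf.training_recall.values())

    def test_rejected_class_recall_on_distractors(self, trained):
        frame, feats, truth, clf = trained
        seg = segment_image(frame, classifier=clf)
        recall = (seg.class_map[truth.distractor_mask] == CLASS_REJECTED).mean()
        assert recall >= 0.95
        # distractor pixels are excluded from the ER mask
        assert not (seg.er_mask & truth.distractor_mask).sum() > \
            0.05 * truth.distractor_mask.sum()

    def test_training_deterministic(self, trained):
        frame, feats, truth, clf = trained
        labels = _labels_from_truth(truth, np.random.default_rng(0))
        clf2 = train_pixel_classifier(feats, labels, seed=0)
        p1 = clf.model.predict(feats.reshape(-1, feats.shape[-1]))
        p2 = clf2.model.predict(feats.reshape(-1, feats.shape[-1]))
        assert np.array_equal(p1, p2)

    def test_missing_class_rejected_with_name(self):
        feats = extract_pixel_features(np.zeros((20, 20)), scales=(1.0,))
        labels = np.full((20, 20), -1, dtype=int)
        labels[:10] = CLASS_BACKGROUND
        labels[10:] = CLASS_ER
        with pytest.raises(ValueError, match="rejected"):
            train_pixel_classifier(feats, labels, scales=(1.0,))


class TestSegmentation:
    def test_zero_noise_threshold_equals_truth(self, clean_phantom):
        _, _, stack, truth = clean_phantom
        seg = segment_image(stack.frame(0), threshold=0.3)
        assert np.array_equal(seg.er_mask, truth.er_mask)

    def test_background_only_frame_nearly_empty(self, rng):
        noise = rng.normal(0.05, 0.01, size=(128, 128))
        seg = segment_image(noise, threshold=0.3)
        assert seg.er_mask.mean() < 0.01

    def test_noisy_phantom_jaccard(self):
        spec = PhantomSpec(seed=7, peak_photons=50, read_noise=0.01)
        graph = generate_network_graph(spec)
        stack, truth = render_phantom(graph, spec)
        frame = enhance_contrast(stack.frame(0), 0.01, 1.0)
        er = close_mask(segment_image(frame).er_mask, 2, 1) & truth.roi_mask
        assert jaccard(er, truth.er_mask) >= 0.8

    def test_quality_monotone_in_snr(self):
        scores = []
        for peak in (20, 50, 200):
            spec = PhantomSpec(seed=3, peak_photons=peak, read_noise=0.01)
            graph = generate_network_graph(spec)
            stack, truth = render_phantom(graph, spec)
            frame = enhance_contrast(stack.frame(0), 0.01, 1.0)
            er = close_mask(segment_image(frame).er_mask, 2, 1) & truth.roi_mask
            scores.append(jaccard(er, truth.er_mask))
        assert scores[0] <= scores[1] <= scores[2]


class TestCloseMask:
    def test_seals_one_pixel_gap(self):
        from scipy import ndimage as ndi
        mask = np.zeros((20, 40), bool)
        mask[9:12, 2:18] = True
        mask[9:12, 19:38] = True  # 1-px gap at column 18
        _, n_before = ndi.label(mask)
        closed = close_mask(mask, radius_px=2)
        _, n_after = ndi.label(closed)
        assert n_before == 2 and n_after == 1

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_extensive_for_any_mask(self, seed):
        mask = np.random.default_rng(seed).random((32, 32)) > 0.7
        closed = close_mask(mask, radius_px=2)
        assert np.all(closed[mask])

    def test_idempotent_beyond_first_iteration(self, rng):
        mask = rng.random((48, 48)) > 0.75
        once = close_mask(mask, radius_px=2, iterations=1)
        again = close_mask(once, radius_px=2, iterations=1)
        assert np.array_equal(once, again)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            close_mask(np.zeros((4, 4), bool), radius_px=0)
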