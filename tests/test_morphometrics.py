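"""Morphometrics: enclosed polygons, cisternae isolation, skeleton analysis."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.morphology import disk

from ernet.morphometrics import (cisternae_fraction, detect_junctions_endpoints,
                                 extract_polygons, isolate_cisternae,
                                 junction_density, skeletonize_tubules,
                                 summarize_cell)
from ernet.phantom import PhantomSpec, generate_network_graph, render_phantom

from conftest import noiseless_spec

PX = 0.05  # um/px used throughout


def full_roi(shape):
    return np.ones(shape, bool)


class TestExtractPolygons:
    def test_single_ring_one_polygon(self):
        er = np.zeros((32, 32), bool)
        er[8:24, 8:24] = True
        er[11:21, 11:21] = False  # 10x10 interior
        polys = extract_polygons(er, full_roi(er.shape), PX)
        assert polys.count == 1
        assert polys.areas_px2[0] == 100
        assert polys.areas_um2[0] == pytest.approx(100 * PX ** 2)

    def test_grid_of_closed_cells(self):
        # 3x3 grid of 5x5 cells drawn with 1-px walls
        er = np.zeros((40, 40), bool)
        for k in range(4):
            er[5 + 6 * k, 5:24] = True
            er[5:24, 5 + 6 * k] = True
        polys = extract_polygons(er, full_roi(er.shape), PX)
        assert polys.count == 9

    def test_open_region_touching_roi_border_excluded(self):
        er = np.zeros((32, 32), bool)
        er[10, :] = True  # single line: nothing enclosed
        polys = extract_polygons(er, full_roi(er.shape), PX)
        assert polys.count == 0
        assert polys.excluded_count >= 1

    def test_empty_er_mask_gives_empty_set(self):
        polys = extract_polygons(np.zeros((16, 16), bool),
                                 full_roi((16, 16)), PX)
        assert polys.count == 0

    def test_phantom_count_matches_truth_faces(self):
        spec = noiseless_spec(seed=6, cisternae_fraction=0.0)
        graph = generate_network_graph(spec)
        _, truth = render_phantom(graph, spec)
        polys = extract_polygons(truth.er_mask, truth.roi_mask, PX)
        assert polys.count == truth.interior_face_count

    def test_area_partition_of_roi(self):
        # polygon area + ER area + excluded background = ROI area
        spec = noiseless_spec(seed=2, cisternae_fraction=0.0)
        graph = generate_network_graph(spec)
        _, truth = render_phantom(graph, spec)
        polys = extract_polygons(truth.er_mask, truth.roi_mask, PX)
        roi_px = truth.roi_mask.sum()
        er_px = (truth.er_mask & truth.roi_mask).sum()
        poly_px = polys.areas_px2.sum()
        excl_px = ((~truth.er_mask & truth.roi_mask) & (polys.labels == 0)).sum()
        assert poly_px + er_px + excl_px == roi_px


class TestCisternae:
    def test_thin_tubules_erased(self):
        er = np.zeros((40, 40), bool)
        er[10:12, 5:35] = True  # 2-px-wide bar
        cis = isolate_cisternae(er, open_radius_px=3, iterations=1,
                                min_area_um2=0.0, pixel_size_um=PX)
        assert not cis.mask.any()

    def test_disk_survives_with_predicted_area(self):
        er = np.zeros((40, 40), bool)
        rr, cc = np.ogrid[:40, :40]
        er[(rr - 20) ** 2 + (cc - 20) ** 2 <= 10 ** 2] = True
        cis = isolate_cisternae(er, open_radius_px=3, iterations=1,
                                min_area_um2=0.0, pixel_size_um=PX)
        # same structuring element applied directly is the oracle
        expected = ndi.binary_opening(er, structure=disk(3))
        assert np.array_equal(cis.mask, expected & er)
        assert cis.mask.sum() > 0

    def test_tubules_plus_disk_keeps_only_disk(self):
        er = np.zeros((60, 60), bool)
        er[29:31, :] = True
        rr, cc = np.ogrid[:60, :60]
        blob = (rr - 30) ** 2 + (cc - 40) ** 2 <= 10 ** 2
        er |= blob
        cis = isolate_cisternae(er, open_radius_px=3, iterations=1,
                                min_area_um2=0.0, pixel_size_um=PX)
        assert cis.mask.any()
        assert not (cis.mask & ~ndi.binary_dilation(blob, iterations=2)).any()

    def test_anti_extensive_and_monotone_in_iterations(self):
        spec = noiseless_spec(seed=4)
        graph = generate_network_graph(spec)
        _, truth = render_phantom(graph, spec)
        prev = truth.er_mask
        for iters in (1, 2, 3):
            cis = isolate_cisternae(truth.er_mask, 3, iters, 0.0, PX)
            assert not (cis.mask & ~truth.er_mask).any()
            assert not (cis.mask & ~prev).any()  # never grows with iterations
            prev = cis.mask

    def test_fraction_endpoints(self):
        roi = full_roi((20, 20))
        assert cisternae_fraction(np.zeros((20, 20), bool), roi) == 0.0
        assert cisternae_fraction(roi.copy(), roi) == 100.0
        with pytest.raises(ValueError):
            cisternae_fraction(roi, np.zeros((20, 20), bool))

    def test_phantom_fraction_recovered(self):
        spec = noiseless_spec(seed=5, cisternae_fraction=0.10)
        graph = generate_network_graph(spec)
        _, truth = render_phantom(graph, spec)
        cis = isolate_cisternae(truth.er_mask, 3, 3, 0.25, PX)
        est = cisternae_fraction(cis, truth.roi_mask)
        assert est == pytest.approx(10.0, abs=1.5)


class TestSkeleton:
    def test_bar_thins_to_single_path(self):
        er = np.zeros((20, 60), bool)
        er[8:13, 10:50] = True
        skel = skeletonize_tubules(er)
        sg = detect_junctions_endpoints(skel)
        assert sg.junction_count == 0
        assert sg.endpoint_count == 2
        # 1-px wide: no pixel has more than 2 neighbours
        nb = ndi.convolve(skel.astype(int), np.ones((3, 3), int),
                          mode="constant") - skel.astype(int)
        assert nb[skel].max() <= 2

    def test_skeleton_subset_of_mask_and_disjoint_from_cisternae(self):
        spec = noiseless_spec(seed=3)
        graph = generate_network_graph(spec)
        _, truth = render_phantom(graph, spec)
        cis = isolate_cisternae(truth.er_mask, 3, 3, 0.25, PX)
        skel = skeletonize_tubules(truth.er_mask, cis)
        assert not (skel & ~truth.er_mask).any()
        assert not (skel & cis.mask).any()

    def test_empty_mask_empty_skeleton(self):
        assert not skeletonize_tubules(np.zeros((8, 8), bool)).any()

    def test_plus_shape_one_junction_four_endpoints(self):
        skel = np.zeros((21, 21), bool)
        skel[10, :] = True
        skel[:, 10] = True
        sg = detect_junctions_endpoints(skel)
        assert sg.junction_count == 1
        assert sg.endpoint_count == 4
        assert sg.junction_coords[0] == pytest.approx((10, 10))

    def test_straight_line_no_junctions(self):
        skel = np.zeros((5, 30), bool)
        skel[2, 3:27] = True
        sg = detect_junctions_endpoints(skel)
        assert sg.junction_count == 0
        assert sg.endpoint_count == 2

    def test_phantom_junction_recovery_noiseless(self):
        spec = noiseless_spec(seed=8, cisternae_fraction=0.0)
        graph = generate_network_graph(spec)
        _, truth = render_phantom(graph, spec)
        skel = skeletonize_tubules(truth.er_mask)
        sg = detect_junctions_endpoints(skel)
        n_truth = len(truth.junction_coords)
        assert abs(sg.junction_count - n_truth) / n_truth <= 0.05


class TestDensityAndSummary:
    def test_density_arithmetic(self):
        assert junction_density(10, 100.0) == pytest.approx(0.1)
        assert junction_density(0, 50.0) == 0.0
        with pytest.raises(ValueError):
            junction_density(3, 0.0)

    def test_density_scale_invariance(self):
        # same physical scene sampled at 0.05 and 0.025 um/px: detected
        # junction densities in um^-2 agree within 10%
        dens = []
        for scale in (1, 2):
            spec = noiseless_spec(
                seed=9, shape=(256 * scale, 256 * scale),
                roi_margin_px=8 * scale, n_seeds=40,
                min_edge_px=6.0 * scale, min_tubule_clearance_px=4.5 * scale,
                tubule_width_px=3.0 * scale,
                cisternae_fraction=0.0, vertex_jitter_px=1.5 * scale,
                pixel_size_um=0.05 / scale)
            graph = generate_network_graph(spec)
            _, truth = render_phantom(graph, spec)
            skel = skeletonize_tubules(truth.er_mask)
            sg = detect_junctions_endpoints(skel)
            roi_um2 = truth.roi_mask.sum() * spec.pixel_size_um ** 2
            dens.append(junction_density(sg.junction_count, roi_um2))
        assert abs(dens[0] - dens[1]) / dens[0] <= 0.10

    def test_empty_mask_summary_zeros(self):
        s = summarize_cell(np.zeros((64, 64), bool), full_roi((64, 64)),
                           pixel_size_um=PX)
        assert s.polygon_count == 0
        assert s.cisternae_percent == 0.0
        assert s.junction_count == 0

    def test_summary_row_stable_columns(self, clean_phantom):
        spec, _, _, truth = clean_phantom
        s = summarize_cell(truth.er_mask, truth.roi_mask, spec.pixel_size_um)
        row = s.to_row()
        for key in ("polygon_count", "polygon_area_mean_um2",
                    "cisternae_percent", "junction_count",
                    "junctions_per_um2", "endpoint_count", "roi_area_um2",
                    "param_open_radius_px"):
            assert key in row

    def test_cisternae_detection_degrades_monotonically_with_noise(self):
        from ernet.evaluation import jaccard
        from ernet.segmentation import close_mask, enhance_contrast, segment_image
        # fixed threshold so that noise is the only corruption varied
        scores = []
        for peak in (400, 30, 8):
            spec = PhantomSpec(seed=6, cisternae_fraction=0.10,
                               peak_photons=peak, read_noise=0.01)
            graph = generate_network_graph(spec)
            stack, truth = render_phantom(graph, spec)
            er = close_mask(segment_image(stack.frame(0), threshold=0.4).er_mask,
                            2, 1) & truth.roi_mask
            cis = isolate_cisternae(er, 3, 3, 0.25, PX)
            scores.append(jaccard(cis.mask, truth.cisternae_mask))
        # non-increasing up to per-realization sampling jitter
        assert scores[0] >= scores[1] - 0.015 >= scores[2] - 0.015
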