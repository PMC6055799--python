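"""Dynamics: persistency maps, CFI statistics, tracking, motion classes."""

import numpy as np
import pytest

from ernet.dynamics import (CFIResult, DynamicsSummary, PunctaTrackSet, Track,
                            cfi_ratio_curve, classify_motion, compute_cfi,
                            persistency_composite, track_puncta)
from ernet.evaluation import match_tracks
from ernet.image import ImageStack
from ernet.phantom import (MotionSpec, PhantomSpec, generate_network_graph,
                           generate_timelapse)

from conftest import noiseless_spec


def gaussian_spot(shape, r, c, sigma=2.0, amp=1.0):
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                         indexing="ij")
    return amp * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma ** 2))


@pytest.fixture(scope="module")
def frozen_and_mobile():
    spec = noiseless_spec(seed=3)
    graph = generate_network_graph(spec)
    frozen, _ = generate_timelapse(graph, spec,
                                   MotionSpec(n_frames=20, mobile_fraction=0.0))
    mobile, _ = generate_timelapse(
        graph, spec, MotionSpec(n_frames=20, mobile_fraction=1.0,
                                jitter_scale_px=2.0))
    return frozen, mobile


class TestPersistency:
    def test_static_stack_all_white(self, frozen_and_mobile):
        frozen, _ = frozen_and_mobile
        pmap = persistency_composite(frozen, frame_indices=(0, 10, 19))
        occupied = pmap.occupancy > 0
        assert np.all(pmap.occupancy[occupied] == 3)
        assert np.all(pmap.composite[occupied] == 1.0)

    def test_transient_punctum_keeps_first_frame_colour(self):
        frames = np.zeros((3, 32, 32))
        frames[:, 10:22, 10:13] = 1.0  # static bar in all frames
        frames[0] += gaussian_spot((32, 32), 25, 25, sigma=1.5)
        stack = ImageStack(frames)
        pmap = persistency_composite(stack, frame_indices=(0, 1, 2),
                                     threshold=0.5)
        assert pmap.occupancy[25, 25] == 1
        from matplotlib import colormaps
        frame0_colour = colormaps["jet"](0.0)[:3]
        assert pmap.composite[25, 25] == pytest.approx(frame0_colour)

    def test_occupancy_equals_brute_force(self, rng):
        frames = (rng.random((6, 24, 24)) > 0.6).astype(float)
        stack = ImageStack(frames)
        pmap = persistency_composite(stack, threshold=0.5)
        brute = (frames > 0.5).sum(axis=0)
        assert np.array_equal(pmap.occupancy, brute)

    def test_selection_by_time_and_range_check(self, frozen_and_mobile):
        frozen, _ = frozen_and_mobile
        pmap = persistency_composite(frozen, at_seconds=(0, 20, 38))
        assert pmap.frame_indices == (0, 10, 19)
        with pytest.raises(ValueError):
            persistency_composite(frozen, frame_indices=(0, 99))


class TestCFI:
    def test_frozen_stack_cfi_equals_n_frames(self, frozen_and_mobile):
        frozen, _ = frozen_and_mobile
        cfi = compute_cfi(frozen)
        assert np.all(cfi.values == frozen.n_frames)

    def test_wandering_punctum_all_ones(self):
        frames = np.zeros((4, 32, 32))
        for t in range(4):
            frames[t, 5, 5 + 8 * t] = 1.0  # disjoint pixels, one visit each
        cfi = compute_cfi(ImageStack(frames), threshold=0.5)
        assert np.all(cfi.values == 1)

    def test_conservation_invariant(self, rng):
        frames = (rng.random((7, 20, 20)) > 0.5).astype(float)
        cfi = compute_cfi(ImageStack(frames), threshold=0.5)
        assert cfi.cfi_map.sum() == int((frames > 0.5).sum())

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            compute_cfi(ImageStack(np.zeros((3, 8, 8))), threshold=0.5)

    def test_frozen_dominates_mobile(self, frozen_and_mobile):
        frozen, mobile = frozen_and_mobile
        curve = cfi_ratio_curve(compute_cfi(frozen), compute_cfi(mobile))
        assert curve.p_more_static < 0.01
        assert float(compute_cfi(frozen).values.mean()) > \
            float(compute_cfi(mobile).values.mean())
        # frozen is over-represented in the top CFI bin
        assert curve.ratio[-1] > 1

    def test_self_ratio_is_one(self, frozen_and_mobile):
        _, mobile = frozen_and_mobile
        cfi = compute_cfi(mobile)
        curve = cfi_ratio_curve(cfi, cfi)
        defined = ~np.isnan(curve.ratio)
        assert np.allclose(curve.ratio[defined], 1.0)

    def test_normalization_invariance(self):
        base = np.zeros((10, 10), int)
        base[:3] = 5
        base[3:5] = 2
        small = CFIResult(base, 5)
        big = CFIResult(np.tile(base, (1, 10)), 5)
        c1 = cfi_ratio_curve(small, small)
        c2 = cfi_ratio_curve(big, small)
        assert np.allclose(np.nan_to_num(c1.ratio), np.nan_to_num(c2.ratio))


class TestTracking:
    def test_single_stationary_punctum(self):
        frames = np.stack([gaussian_spot((32, 32), 16, 16) for _ in range(30)])
        ts = track_puncta(ImageStack(frames), threshold=0.5)
        assert ts.n_tracks == 1
        tr = ts.tracks[0]
        assert tr.n_points == 30
        assert tr.max_displacement() < 0.5

    def test_two_puncta_converging_merge(self):
        # two well-separated spots collapse onto one position at frame k
        frames = []
        k = 5
        for t in range(10):
            if t < k:
                frames.append(gaussian_spot((32, 40), 16, 12, sigma=1.5)
                              + gaussian_spot((32, 40), 16, 28, sigma=1.5))
            else:
                frames.append(gaussian_spot((32, 40), 16, 20, sigma=1.5))
        ts = track_puncta(ImageStack(np.stack(frames)), threshold=0.5,
                          max_link_px=10)
        assert len(ts.merge_events) == 1
        assert ts.merge_events[0]["frame"] == k
        assert sum(1 for t in ts.tracks if t.fate == "merged") == 1

    def test_phantom_track_recovery(self):
        spec = PhantomSpec(seed=2, peak_photons=200, read_noise=0.01)
        graph = generate_network_graph(spec)
        motion = MotionSpec(n_frames=20, n_puncta=20, puncta_amplitude=1.6,
                            network_intensity_scale=0.4,
                            puncta_mobile_fraction=0.6,
                            puncta_directed_fraction=0.4,
                            puncta_speed_px=1.0, puncta_step_sd_px=1.0)
        stack, truth = generate_timelapse(graph, spec, motion)
        ts = track_puncta(stack, threshold=0.9, min_area_px=3,
                          max_area_px=300, max_link_px=5)
        assert match_tracks(truth.tracks, ts) >= 0.9

    def test_empty_stack_warns(self):
        with pytest.warns(UserWarning):
            ts = track_puncta(ImageStack(np.zeros((3, 16, 16))), threshold=0.5)
        assert ts.n_tracks == 0


class TestMotionClassification:
    @staticmethod
    def _track(tid, positions):
        return Track(tid, list(range(len(positions))),
                     [tuple(p) for p in positions],
                     [5.0] * len(positions))

    def test_zero_displacement_stationary(self):
        ts = PunctaTrackSet([self._track(0, [(5, 5)] * 10)], [])
        summary = classify_motion(ts)
        assert summary.fixed == 1 and summary.moved == 0
        assert ts.tracks[0].motion_class == "stationary"

    def test_straight_constant_velocity_directed(self):
        ts = PunctaTrackSet([self._track(0, [(5, 5 + 1.5 * t)
                                             for t in range(10)])], [])
        summary = classify_motion(ts)
        assert summary.moved == 1
        assert ts.tracks[0].motion_class == "directed"

    def test_moved_fixed_accounting_90_puncta(self):
        # 59 tracks displace beyond the gate, 31 stay put: the fractions are
        # 66% moved / 34% fixed
        tracks = []
        for i in range(59):
            tracks.append(self._track(i, [(10, 10), (10, 18)]))
        for i in range(59, 90):
            tracks.append(self._track(i, [(10, 10), (10, 10.5)]))
        summary = classify_motion(PunctaTrackSet(tracks, []), d_min_px=2.0)
        assert summary.total == 90
        assert summary.moved == 59 and summary.fixed == 31
        assert round(100 * summary.moved_fraction) == 66
        assert round(100 * summary.fixed_fraction) == 34

    def test_from_counts_arithmetic(self):
        s = DynamicsSummary.from_counts(total=90, moved=59, fused=16,
                                        absorbed=7)
        assert s.fixed == 31
        assert s.moved_fraction == pytest.approx(59 / 90)
        with pytest.raises(ValueError):
            DynamicsSummary.from_counts(total=5, moved=6)
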