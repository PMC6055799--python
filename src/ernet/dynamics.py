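"""Time-lapse dynamics: persistency maps, cumulative occupancy (CFI),
puncta tracking and motion classification.

Persistency mapping asks which parts of the network stay put: selected frames
are binarized and per-pixel occupancy is summed; pixels occupied at every
sampled time render white in the composite, while transient pixels carry the
colour of the last frame in which they were occupied. The cumulative
fluorescence intensity (CFI) statistic extends this to every frame of a
video: each ever-occupied pixel gets the count of frames it was occupied in,
and the distribution of those counts summarizes network mobility — a heavier
high-CFI tail means a more static network. Conditions are compared as
per-bin frequency ratios against a control plus a one-sided rank test on the
per-pixel values.

Puncta tracking follows bright compact particles (labelled junctions or small
cisternae) by nearest-neighbour linking under a displacement gate, detecting
merges and absorption into persistent sheets, and classifies each track as
stationary, directed, or mobile-undirected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from matplotlib import colormaps
from scipy import ndimage as ndi
from scipy.stats import mannwhitneyu
from skimage.filters import threshold_otsu

from .image import ImageStack


def _binarize_frame(frame: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Per-frame occupancy via a global threshold (Otsu by default)."""
    frame = np.asarray(frame, dtype=float)
    if threshold is None:
        if np.ptp(frame) == 0:
            return np.zeros(frame.shape, dtype=bool)
        threshold = float(threshold_otsu(frame))
    return frame > threshold


@dataclass
class PersistencyMap:
    """Occupancy counts over selected frames plus the time-coded composite."""

    occupancy: np.ndarray  # int, in [0, n_selected]
    composite: np.ndarray  # (H, W, 3) float RGB in [0, 1]
    frame_indices: tuple[int, ...]
    times_s: tuple[float, ...]

    @property
    def n_selected(self) -> int:
        return len(self.frame_indices)


def persistency_composite(stack: ImageStack, frame_indices=None,
                          at_seconds=None, threshold: float | None = None,
                          cmap: str = "jet") -> PersistencyMap:
    """Temporal colour-coding of binarized frames.

    Frames may be selected by index or by acquisition time (``at_seconds``,
    e.g. ``(0, 30, 60)``; nearest frames are used). Pixels occupied in all
    selected frames are rendered white (persistent structure); otherwise the
    hue encodes the latest frame in which the pixel was occupied, with the
    colormap's top colour marking the most recently mobile regions.
    """
    if at_seconds is not None:
        times = stack.times_s()
        frame_indices = tuple(int(np.argmin(np.abs(times - s))) for s in at_seconds)
    if frame_indices is None:
        frame_indices = tuple(range(stack.n_frames))
    frame_indices = tuple(int(i) for i in frame_indices)
    if len(frame_indices) < 2:
        raise ValueError("need at least 2 selected frames")
    for i in frame_indices:
        if not (0 <= i < stack.n_frames):
            raise ValueError(f"frame index {i} out of range 0..{stack.n_frames - 1}")

    masks = np.stack([_binarize_frame(stack.frame(i), threshold)
                      for i in frame_indices])
    occupancy = masks.sum(axis=0).astype(int)
    n = len(frame_indices)

    h, w = stack.shape
    composite = np.zeros((h, w, 3))
    colors = colormaps[cmap](np.linspace(0.0, 1.0, n))[:, :3]
    # latest selected frame in which each pixel is occupied
    latest = np.full((h, w), -1, dtype=int)
    for k in range(n):
        latest[masks[k]] = k
    for k in range(n):
        composite[(latest == k) & (occupancy < n)] = colors[k]
    composite[occupancy == n] = 1.0
    times = stack.times_s()
    return PersistencyMap(occupancy, composite, frame_indices,
                          tuple(float(times[i]) for i in frame_indices))


@dataclass
class CFIResult:
    """Per-pixel cumulative occupancy over all frames of a video."""

    cfi_map: np.ndarray  # int counts; 0 where never occupied
    n_frames: int

    @property
    def values(self) -> np.ndarray:
        """CFI values of ever-occupied pixels (each in 1..n_frames)."""
        return self.cfi_map[self.cfi_map > 0]

    def distribution(self) -> np.ndarray:
        """Normalized frequency of CFI values 1..n_frames (sums to 1)."""
        counts = np.bincount(self.values, minlength=self.n_frames + 1)[1:]
        total = counts.sum()
        if total == 0:
            raise ValueError("no occupied pixels")
        return counts / total


def compute_cfi(stack: ImageStack, threshold: float | None = None) -> CFIResult:
    """Cumulative fluorescence intensity: frames-occupied count per pixel."""
    if stack.n_frames < 2:
        raise ValueError("need at least 2 frames")
    acc = np.zeros(stack.shape, dtype=int)
    for t in range(stack.n_frames):
        acc += _binarize_frame(stack.frame(t), threshold)
    if not acc.any():
        raise ValueError("all frames are empty after binarization")
    return CFIResult(acc, stack.n_frames)


@dataclass
class CFIRatioCurve:
    """Sample/control CFI frequency ratio per CFI bin, plus a rank test."""

    cfi_bins: np.ndarray  # 1..n_frames
    ratio: np.ndarray  # NaN where the control bin is empty
    sample_freq: np.ndarray
    control_freq: np.ndarray
    p_more_static: float  # one-sided: sample CFI values larger than control
    u_statistic: float


def cfi_ratio_curve(sample: CFIResult, control: CFIResult) -> CFIRatioCurve:
    """Express a condition's CFI distribution as a ratio to a control.

    A control compared against itself gives a ratio of exactly 1 in every
    defined bin. Bins where the control frequency is zero are reported as NaN
    (undefined), not zero. Significance of a shift toward a more static
    network is assessed with a one-sided rank test on per-pixel CFI values.
    """
    if sample.n_frames != control.n_frames:
        raise ValueError("sample and control must have the same n_frames")
    fs = sample.distribution()
    fc = control.distribution()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(fc > 0, fs / np.where(fc > 0, fc, 1.0), np.nan)
    u, p = mannwhitneyu(sample.values, control.values, alternative="greater")
    return CFIRatioCurve(
        cfi_bins=np.arange(1, sample.n_frames + 1),
        ratio=ratio, sample_freq=fs, control_freq=fc,
        p_more_static=float(p), u_statistic=float(u),
    )


# ---------------------------------------------------------------------------
# Puncta tracking


@dataclass
class Track:
    """One linked punctum trajectory."""

    track_id: int
    frames: list[int] = field(default_factory=list)
    positions: list[tuple[float, float]] = field(default_factory=list)
    areas: list[float] = field(default_factory=list)
    fate: str = "persisted"  # persisted | merged | absorbed-into-sheet | lost
    motion_class: str = ""

    @property
    def n_points(self) -> int:
        return len(self.frames)

    def displacements_from_origin(self) -> np.ndarray:
        p = np.asarray(self.positions)
        return np.hypot(p[:, 0] - p[0, 0], p[:, 1] - p[0, 1])

    def max_displacement(self) -> float:
        return float(self.displacements_from_origin().max()) if self.n_points else 0.0

    def straightness(self) -> float:
        """Net displacement over path length (1 = perfectly straight)."""
        p = np.asarray(self.positions)
        if len(p) < 2:
            return 0.0
        path = float(np.hypot(np.diff(p[:, 0]), np.diff(p[:, 1])).sum())
        net = float(np.hypot(*(p[-1] - p[0])))
        return net / path if path > 0 else 0.0


@dataclass
class PunctaTrackSet:
    """All tracks of one video plus linkage events."""

    tracks: list[Track]
    merge_events: list[dict]  # {"frame", "into", "consumed"}
    params: dict = field(default_factory=dict)

    @property
    def n_tracks(self) -> int:
        return len(self.tracks)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.tracks:
            for f, (r, c), a in zip(t.frames, t.positions, t.areas):
                rows.append({"track_id": t.track_id, "frame": f, "row": r,
                             "col": c, "area_px2": a, "fate": t.fate,
                             "motion_class": t.motion_class})
        return pd.DataFrame(rows)


def _detect_puncta(frame: np.ndarray, threshold: float,
                   min_area_px: int, max_area_px: int):
    """Bright compact components within a size window → (centroids, areas)."""
    mask = np.asarray(frame) > threshold
    labels, n = ndi.label(mask, structure=np.ones((3, 3), bool))
    cents, areas = [], []
    if n:
        sizes = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))
        coms = ndi.center_of_mass(mask, labels, index=np.arange(1, n + 1))
        for (size, com) in zip(sizes, coms):
            if min_area_px <= size <= max_area_px:
                cents.append(com)
                areas.append(float(size))
    return np.asarray(cents, float).reshape(-1, 2), np.asarray(areas)


def track_puncta(stack: ImageStack, threshold: float = 0.5,
                 min_area_px: int = 3, max_area_px: int = 200,
                 max_link_px: float = 5.0,
                 cisternae_mask: np.ndarray | None = None) -> PunctaTrackSet:
    """Detect and link puncta across frames.

    Puncta are detected per frame as bright compact components within a size
    window and linked frame-to-frame by greedy nearest-neighbour assignment
    under a maximum-displacement gate. When two tracks map to the same
    detection a merge is logged (the nearer track continues). A track whose
    last detection overlaps ``cisternae_mask`` is labelled
    absorbed-into-sheet; otherwise a track that ends early is 'lost'.
    """
    if stack.n_frames < 2:
        raise ValueError("need at least 2 frames")
    detections = [_detect_puncta(stack.frame(t), threshold, min_area_px,
                                 max_area_px) for t in range(stack.n_frames)]
    if all(len(c) == 0 for c, _ in detections):
        warnings.warn("no puncta detected in any frame")
        return PunctaTrackSet([], [], params={"threshold": threshold,
                                              "max_link_px": max_link_px})

    tracks: list[Track] = []
    merge_events: list[dict] = []
    active: dict[int, int] = {}  # track_id -> detection index in previous frame
    next_id = 0

    cents0, areas0 = detections[0]
    for i in range(len(cents0)):
        tracks.append(Track(next_id, [0], [tuple(cents0[i])], [areas0[i]]))
        active[next_id] = i
        next_id += 1

    for t in range(1, stack.n_frames):
        cents, areas = detections[t]
        prev_cents, _ = detections[t - 1]
        # candidate links: (distance, track_id, det_idx), greedy by distance
        cands = []
        for tid, pi in active.items():
            p = prev_cents[pi]
            if len(cents) == 0:
                continue
            d = np.hypot(cents[:, 0] - p[0], cents[:, 1] - p[1])
            for j in np.flatnonzero(d <= max_link_px):
                cands.append((float(d[j]), tid, int(j)))
        cands.sort()
        assigned_tracks: set[int] = set()
        det_to_track: dict[int, int] = {}
        new_active: dict[int, int] = {}
        for d, tid, j in cands:
            if tid in assigned_tracks:
                continue
            if j in det_to_track:
                # a second track maps onto an already-claimed detection: merge
                winner = det_to_track[j]
                merge_events.append({"frame": t, "into": winner,
                                     "consumed": tid})
                tracks[tid].fate = "merged"
                assigned_tracks.add(tid)
                continue
            det_to_track[j] = tid
            assigned_tracks.add(tid)
            tracks[tid].frames.append(t)
            tracks[tid].positions.append(tuple(cents[j]))
            tracks[tid].areas.append(float(areas[j]))
            new_active[tid] = j
        # unmatched detections start new tracks
        for j in range(len(cents)):
            if j not in det_to_track:
                tracks.append(Track(next_id, [t], [tuple(cents[j])],
                                    [float(areas[j])]))
                new_active[next_id] = j
                next_id += 1
        # tracks that found no link end here
        for tid in active:
            if tid not in assigned_tracks and tracks[tid].fate == "persisted":
                tracks[tid].fate = "lost"
        active = new_active

    if cisternae_mask is not None:
        cmask = np.asarray(cisternae_mask, bool)
        for tr in tracks:
            if tr.fate in ("lost", "persisted") and tr.frames[-1] < stack.n_frames - 1:
                r, c = tr.positions[-1]
                ri, ci = int(round(r)), int(round(c))
                if 0 <= ri < cmask.shape[0] and 0 <= ci < cmask.shape[1] and cmask[ri, ci]:
                    tr.fate = "absorbed-into-sheet"

    return PunctaTrackSet(tracks, merge_events,
                          params={"threshold": threshold,
                                  "min_area_px": min_area_px,
                                  "max_area_px": max_area_px,
                                  "max_link_px": max_link_px})


@dataclass
class DynamicsSummary:
    """Moved/fixed/fused/absorbed accounting over a set of puncta tracks."""

    total: int
    moved: int
    fixed: int
    directed: int
    fused: int
    absorbed: int
    params: dict = field(default_factory=dict)

    @property
    def moved_fraction(self) -> float:
        return self.moved / self.total if self.total else 0.0

    @property
    def fixed_fraction(self) -> float:
        return self.fixed / self.total if self.total else 0.0

    @classmethod
    def from_counts(cls, total: int, moved: int, fused: int = 0,
                    absorbed: int = 0) -> "DynamicsSummary":
        """Summary arithmetic on externally tallied counts."""
        if moved > total:
            raise ValueError("moved cannot exceed total")
        return cls(total=total, moved=moved, fixed=total - moved, directed=0,
                   fused=fused, absorbed=absorbed)


def classify_motion(trackset: PunctaTrackSet, d_min_px: float = 2.0,
                    straightness_min: float = 0.7) -> DynamicsSummary:
    """Classify tracks and tally the moved/fixed/fused/absorbed accounting.

    A punctum *moved* if its maximum displacement from origin exceeds
    ``d_min_px``; a moved punctum is *directed* when its net/path-length
    straightness is at least ``straightness_min``; otherwise it is
    mobile-undirected. Non-movers are stationary.
    """
    moved = fixed = directed = 0
    for tr in trackset.tracks:
        if tr.n_points < 2:
            tr.motion_class = "stationary"
            fixed += 1
            continue
        if tr.max_displacement() > d_min_px:
            moved += 1
            if tr.straightness() >= straightness_min:
                tr.motion_class = "directed"
                directed += 1
            else:
                tr.motion_class = "mobile-undirected"
        else:
            tr.motion_class = "stationary"
            fixed += 1
    fused = sum(1 for tr in trackset.tracks if tr.fate == "merged")
    absorbed = sum(1 for tr in trackset.tracks if tr.fate == "absorbed-into-sheet")
    return DynamicsSummary(
        total=len(trackset.tracks), moved=moved, fixed=fixed,
        directed=directed, fused=fused, absorbed=absorbed,
        params={"d_min_px": d_min_px, "straightness_min": straightness_min,
                **trackset.params},
    )
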