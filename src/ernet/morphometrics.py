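"""Network morphometrics: enclosed polygons, cisternae, skeleton junctions.

Given a binary ER mask and a cell ROI, this module computes the three
morphological readouts used to compare ER phenotypes:

* areas of polygonal lacunae completely enclosed by the tubule network,
* the percentage of the cell surface classified as cisternae (sheet regions
  isolated by iterated morphological opening, which erases thin tubules),
* the density of three-way junctions of the skeletonized tubular network,
  normalized to ROI area.

Digital-topology conventions: foreground (ER) is 8-connected, background
lacunae are 4-connected — the standard duality that prevents diagonal leakage
through a 1-pixel tubule. "Completely enclosed" is operationalized as a
background component that touches neither the ROI border nor any non-ROI
pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import regionprops
from skimage.morphology import disk, skeletonize

_FOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_EIGHT = np.ones((3, 3), dtype=bool)

#: smallest background component counted as a polygonal lacuna, in pixels;
#: anything below this is a raster/segmentation sliver, not a real polygon
MIN_LACUNA_PX = 4


@dataclass
class PolygonSet:
    """Enclosed background lacunae within the ROI."""

    labels: np.ndarray  # 0 = not a polygon; 1..n polygon ids
    areas_px2: np.ndarray
    areas_um2: np.ndarray
    centroids: np.ndarray  # (n, 2) row/col
    excluded_count: int  # background components touching ROI border / outside

    @property
    def count(self) -> int:
        return len(self.areas_px2)


@dataclass
class CisternaeMask:
    """Sheet regions surviving iterative opening of the ER mask."""

    mask: np.ndarray
    component_areas_um2: np.ndarray
    open_radius_px: int
    iterations: int
    min_area_um2: float


@dataclass
class SkeletonGraph:
    """1-px skeleton with junction clusters and endpoints."""

    skeleton: np.ndarray
    junction_coords: np.ndarray  # (n, 2) cluster centroids
    junction_pixel_count: int
    endpoint_coords: np.ndarray

    @property
    def junction_count(self) -> int:
        return len(self.junction_coords)

    @property
    def endpoint_count(self) -> int:
        return len(self.endpoint_coords)


@dataclass
class MorphometricSummary:
    """Per-cell morphometric readout with parameter echo."""

    polygon_areas_um2: np.ndarray
    cisternae_percent: float
    junction_count: int
    junctions_per_um2: float
    endpoint_count: int
    roi_area_um2: float
    params: dict = field(default_factory=dict)

    @property
    def polygon_count(self) -> int:
        return len(self.polygon_areas_um2)

    @property
    def mean_polygon_area_um2(self) -> float:
        return float(np.mean(self.polygon_areas_um2)) if self.polygon_count else 0.0

    @property
    def median_polygon_area_um2(self) -> float:
        return float(np.median(self.polygon_areas_um2)) if self.polygon_count else 0.0

    def to_row(self) -> dict:
        """One flat CSV row per cell with stable column names."""
        row = {
            "polygon_count": self.polygon_count,
            "polygon_area_mean_um2": self.mean_polygon_area_um2,
            "polygon_area_median_um2": self.median_polygon_area_um2,
            "cisternae_percent": self.cisternae_percent,
            "junction_count": self.junction_count,
            "junctions_per_um2": self.junctions_per_um2,
            "endpoint_count": self.endpoint_count,
            "roi_area_um2": self.roi_area_um2,
        }
        row.update({f"param_{k}": v for k, v in self.params.items()})
        return row


def extract_polygons(er_mask: np.ndarray, roi_mask: np.ndarray,
                     pixel_size_um: float = 0.05,
                     min_area_px: float = MIN_LACUNA_PX) -> PolygonSet:
    """Label background lacunae completely enclosed by the ER network.

    Background components (4-connected) inside the ROI are kept only when no
    pixel touches the image border, the ROI border, or a non-ROI pixel — i.e.
    they are bounded entirely by ER foreground — and their area is at least
    ``min_area_px`` (sub-resolution slivers are not polygons). Areas are
    reported in px^2 and um^2.
    """
    er_mask = np.asarray(er_mask, bool)
    roi_mask = np.asarray(roi_mask, bool)
    if er_mask.shape != roi_mask.shape:
        raise ValueError("ER mask and ROI mask shapes differ")
    if not roi_mask.any():
        raise ValueError("empty ROI")
    bg = ~er_mask & roi_mask
    labels, n = ndi.label(bg, structure=_FOUR)

    # components 4-adjacent to anything outside the ROI (or the image border)
    outside = ~roi_mask
    outside_pad = np.pad(outside, 1, constant_values=True)
    touch = ndi.binary_dilation(outside_pad, structure=_FOUR)[1:-1, 1:-1]
    excluded_ids = np.unique(labels[touch & (labels > 0)])

    keep = np.setdiff1d(np.arange(1, n + 1), excluded_ids)
    if len(keep):
        sizes = ndi.sum_labels(bg, labels, index=keep)
        keep = keep[sizes >= min_area_px]
    relabel = np.zeros(n + 1, dtype=np.int32)
    relabel[keep] = np.arange(1, len(keep) + 1)
    out_labels = relabel[labels]

    areas_px2, centroids = [], []
    for prop in regionprops(out_labels):
        areas_px2.append(prop.area)
        centroids.append(prop.centroid)
    areas_px2 = np.asarray(areas_px2, dtype=float)
    return PolygonSet(
        labels=out_labels,
        areas_px2=areas_px2,
        areas_um2=areas_px2 * pixel_size_um ** 2,
        centroids=np.asarray(centroids, dtype=float).reshape(-1, 2),
        excluded_count=int(len(excluded_ids)),
    )


def isolate_cisternae(er_mask: np.ndarray, open_radius_px: int = 3,
                      iterations: int = 3, min_area_um2: float = 0.25,
                      pixel_size_um: float = 0.05) -> CisternaeMask:
    """Isolate sheet regions by iterated morphological opening.

    ``iterations`` erosions with a disk element followed by the same number of
    dilations erase structures thinner than roughly twice the accumulated
    radius (tubules) while sheets survive. Components smaller than
    ``min_area_um2`` are discarded. The result is anti-extensive
    (mask is a subset of the input).
    """
    if open_radius_px < 1:
        raise ValueError("open_radius_px must be >= 1")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    er_mask = np.asarray(er_mask, bool)
    opened = ndi.binary_opening(er_mask, structure=disk(open_radius_px),
                                iterations=iterations)
    opened &= er_mask  # guard the anti-extensivity contract at the border
    labels, n = ndi.label(opened, structure=_EIGHT)
    if n:
        sizes = ndi.sum_labels(opened, labels, index=np.arange(1, n + 1))
        min_px = min_area_um2 / pixel_size_um ** 2
        keep = sizes >= min_px
        opened = np.isin(labels, np.flatnonzero(keep) + 1)
        areas = sizes[keep] * pixel_size_um ** 2
    else:
        areas = np.zeros(0)
    return CisternaeMask(opened, np.asarray(areas, float), open_radius_px,
                         iterations, min_area_um2)


def cisternae_fraction(cisternae: CisternaeMask | np.ndarray,
                       roi_mask: np.ndarray) -> float:
    """Percentage of ROI area classified as cisternae."""
    mask = cisternae.mask if isinstance(cisternae, CisternaeMask) else cisternae
    roi_mask = np.asarray(roi_mask, bool)
    roi_area = float(roi_mask.sum())
    if roi_area == 0:
        raise ValueError("zero ROI area")
    return 100.0 * float((np.asarray(mask, bool) & roi_mask).sum()) / roi_area


def _fill_small_holes(mask: np.ndarray, max_px: int) -> np.ndarray:
    """Fill enclosed background components smaller than ``max_px`` pixels."""
    bg, n = ndi.label(~mask, structure=_FOUR)
    if n == 0:
        return mask
    sizes = np.bincount(bg.ravel())
    border = np.unique(np.concatenate(
        [bg[0], bg[-1], bg[:, 0], bg[:, -1]]))
    small = np.zeros(n + 1, dtype=bool)
    small[1:] = sizes[1:] < max_px
    small[border] = False
    return mask | small[bg]


def _neighbour_counts(skel: np.ndarray) -> np.ndarray:
    return ndi.convolve(skel.astype(np.uint8), _EIGHT.astype(np.uint8),
                        mode="constant") - skel.astype(np.uint8)


def _remove_redundant_corners(skel: np.ndarray) -> np.ndarray:
    """Delete pixels with exactly two mutually-adjacent neighbours.

    Thinning leaves an extra pixel at some L-corners; that pixel turns the
    corner into a spurious triple point. Removing it never disconnects the
    skeleton (its two neighbours touch each other). Pixels are processed in
    raster order against the current mask, so the result is deterministic.
    """
    skel = np.asarray(skel, bool).copy()
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    changed = True
    while changed:
        changed = False
        for r, c in np.argwhere(skel):
            nbrs = [(r + dr, c + dc) for dr, dc in offsets
                    if 0 <= r + dr < skel.shape[0] and 0 <= c + dc < skel.shape[1]
                    and skel[r + dr, c + dc]]
            if len(nbrs) == 2:
                (r1, c1), (r2, c2) = nbrs
                if max(abs(r1 - r2), abs(c1 - c2)) <= 1:
                    skel[r, c] = False
                    changed = True
    return skel


def prune_spurs(skel: np.ndarray, max_length: int = 4) -> np.ndarray:
    """Remove terminal side branches of at most ``max_length`` pixels.

    Thinning a few-pixel-wide tubule emits short spurs near junctions; each
    spur fabricates a spurious triple point. A branch is walked inward from
    its endpoint and deleted only if it reaches a junction pixel within
    ``max_length`` steps, so genuine open tubule ends are kept at full length.
    """
    skel = np.asarray(skel, bool).copy()
    if max_length < 1:
        return skel
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    changed = True
    while changed:
        changed = False
        nb = _neighbour_counts(skel)
        endpoints = np.argwhere(skel & (nb == 1))
        for r0, c0 in endpoints:
            if not skel[r0, c0]:
                continue
            walk = [(int(r0), int(c0))]
            prev = None
            cur = (int(r0), int(c0))
            hit_junction = False
            for _ in range(max_length):
                nxt = [(cur[0] + dr, cur[1] + dc) for dr, dc in offsets
                       if 0 <= cur[0] + dr < skel.shape[0]
                       and 0 <= cur[1] + dc < skel.shape[1]
                       and skel[cur[0] + dr, cur[1] + dc]
                       and (cur[0] + dr, cur[1] + dc) != prev]
                if len(nxt) != 1:
                    hit_junction = len(nxt) > 1
                    break
                prev, cur = cur, nxt[0]
                if nb[cur] >= 3:
                    hit_junction = True
                    break
                walk.append(cur)
            if hit_junction:
                for r, c in walk:
                    skel[r, c] = False
                changed = True
    return skel


def skeletonize_tubules(er_mask: np.ndarray,
                        cisternae: CisternaeMask | np.ndarray | None = None,
                        spur_max_px: int = 4,
                        fill_holes_px: int = 8) -> np.ndarray:
    """Thin the ER mask to a 1-px skeleton and subtract cisternae pixels.

    Background holes smaller than ``fill_holes_px`` (sub-resolution raster or
    segmentation artifacts, far below any real lacuna) are filled first so
    they cannot seed spurious skeleton loops. Thinning is topology-preserving
    with deterministic raster-order tie-breaking, followed by spur pruning
    (terminal branches up to ``spur_max_px``, thinning artifacts at
    junctions); the returned skeleton is a subset of the ER mask and is
    disjoint from the cisternae mask.
    """
    er_mask = np.asarray(er_mask, bool)
    if not er_mask.any():
        return np.zeros_like(er_mask)
    filled = _fill_small_holes(er_mask, fill_holes_px)
    skel = skeletonize(filled) & er_mask
    if cisternae is not None:
        cmask = cisternae.mask if isinstance(cisternae, CisternaeMask) else cisternae
        skel = skel & ~np.asarray(cmask, bool)
    # pruning can expose redundant corner pixels and vice versa; iterate
    while True:
        cleaned = _remove_redundant_corners(prune_spurs(skel, spur_max_px))
        if np.array_equal(cleaned, skel):
            return skel
        skel = cleaned


def detect_junctions_endpoints(skeleton: np.ndarray) -> SkeletonGraph:
    """Find junction clusters and endpoints on a 1-px skeleton.

    A junction pixel has >= 3 skeleton 8-neighbours; 8-adjacent junction
    pixels (thinning can emit 2-px clusters) are merged into one junction,
    reported at the cluster centroid. Endpoints have exactly one neighbour.
    """
    skel = np.asarray(skeleton, bool)
    nb = ndi.convolve(skel.astype(np.uint8), _EIGHT.astype(np.uint8),
                      mode="constant") - skel.astype(np.uint8)
    junction_px = skel & (nb >= 3)
    endpoints = skel & (nb == 1)
    labels, n = ndi.label(junction_px, structure=_EIGHT)
    if n:
        centroids = np.asarray(ndi.center_of_mass(junction_px, labels,
                                                  index=np.arange(1, n + 1)))
    else:
        centroids = np.zeros((0, 2))
    return SkeletonGraph(
        skeleton=skel,
        junction_coords=centroids.reshape(-1, 2),
        junction_pixel_count=int(junction_px.sum()),
        endpoint_coords=np.argwhere(endpoints).astype(float),
    )


def junction_density(junction_count: int, roi_area_um2: float) -> float:
    """Three-way junctions per um^2 of cell surface."""
    if roi_area_um2 <= 0:
        raise ValueError("ROI area must be positive")
    return junction_count / roi_area_um2


def summarize_cell(er_mask: np.ndarray, roi_mask: np.ndarray,
                   pixel_size_um: float = 0.05, open_radius_px: int = 3,
                   open_iterations: int = 3,
                   min_cisterna_area_um2: float = 0.25) -> MorphometricSummary:
    """Run the full morphometric chain on one cell and package the results."""
    roi_mask = np.asarray(roi_mask, bool)
    roi_area_um2 = float(roi_mask.sum()) * pixel_size_um ** 2
    stage = "extract_polygons"
    try:
        polys = extract_polygons(er_mask, roi_mask, pixel_size_um)
        stage = "isolate_cisternae"
        cis = isolate_cisternae(er_mask, open_radius_px, open_iterations,
                                min_cisterna_area_um2, pixel_size_um)
        stage = "cisternae_fraction"
        cis_pct = cisternae_fraction(cis, roi_mask)
        stage = "skeletonize_tubules"
        skel = skeletonize_tubules(er_mask, cis)
        stage = "detect_junctions_endpoints"
        sg = detect_junctions_endpoints(skel)
        stage = "junction_density"
        dens = junction_density(sg.junction_count, roi_area_um2)
    except Exception as exc:
        raise RuntimeError(f"morphometrics stage '{stage}' failed: {exc}") from exc
    return MorphometricSummary(
        polygon_areas_um2=polys.areas_um2,
        cisternae_percent=cis_pct,
        junction_count=sg.junction_count,
        junctions_per_um2=dens,
        endpoint_count=sg.endpoint_count,
        roi_area_um2=roi_area_um2,
        params={
            "pixel_size_um": pixel_size_um,
            "open_radius_px": open_radius_px,
            "open_iterations": open_iterations,
            "min_cisterna_area_um2": min_cisterna_area_um2,
        },
    )


def summaries_to_frame(summaries, group_labels=None) -> pd.DataFrame:
    """Stack per-cell summaries into a tidy DataFrame (one row per cell)."""
    rows = [s.to_row() for s in summaries]
    df = pd.DataFrame(rows)
    if group_labels is not None:
        df.insert(0, "group", list(group_labels))
    return df
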