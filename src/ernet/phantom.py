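"""Synthetic cortical-ER phantoms with exact ground truth.

The cortical endoplasmic reticulum of a leaf epidermal cell is, to a good
approximation, a planar network of membrane tubules meeting at three-way
junctions and enclosing polygonal lacunae, with flat cisternal sheets embedded
in the network. This module generates such scenes with a known vector-level
ground truth (tubule graph, faces, junctions, cisternae and distractor masks,
puncta trajectories) and renders them through a simple confocal forward model
(Gaussian PSF, Poisson photon noise, Gaussian read noise), so that every
downstream quantification stage can be validated against truth without
microscope data.

Geometry: the tubule graph is the Voronoi ridge network of random seed points
inside the ROI — this produces three-way-dominant junctions and convex-ish
polygonal lacunae resembling real cortical ER. Vertices are jittered, edges
shorter than the imaging resolution are contracted into single higher-degree
vertices, and dangling chains are pruned.

Coordinates are 0-based (row, col) with pixel centers at integer coordinates;
areas convert to um^2 via pixel_size_um**2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy.spatial import Voronoi
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon
from scipy import ndimage as ndi

from .image import ImageStack

__all__ = [
    "PhantomSpec",
    "MotionSpec",
    "MotionEvent",
    "TubuleGraph",
    "Face",
    "PunctaTrack",
    "PhantomTruth",
    "roi_mask_for",
    "generate_network_graph",
    "render_phantom",
    "generate_timelapse",
]


# ---------------------------------------------------------------------------
# Specs


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic ER scene.

    Sizes are in pixels unless suffixed otherwise. Defaults emulate a single
    cortical-ER cell patch imaged at high resolution (0.05 um/px): tubules
    ~0.15 um wide, lacunae of order 1 um^2, cisternae of order 1-3 um^2.
    """

    shape: tuple[int, int] = (256, 256)
    roi_margin_px: int = 8
    n_seeds: int = 40
    vertex_jitter_px: float = 1.5
    min_edge_px: float = 6.0
    min_tubule_clearance_px: float = 4.5
    min_edge_angle_deg: float = 30.0
    tubule_width_px: float = 3.0
    cisternae_fraction: float = 0.08
    cisterna_radius_px: tuple[float, float] = (12.0, 18.0)
    cisterna_aspect: tuple[float, float] = (0.75, 1.0)
    n_distractors: int = 0
    distractor_radius_px: tuple[float, float] = (3.0, 6.0)
    psf_sigma_px: float = 1.0
    peak_photons: float | None = 200.0
    read_noise: float = 0.01
    background: float = 0.05
    tubule_intensity: float = 0.6
    cisterna_intensity: float = 0.85
    distractor_intensity: float = 1.0
    pixel_size_um: float = 0.05
    frame_interval_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if not (0.0 <= self.cisternae_fraction < 1.0):
            raise ValueError("cisternae_fraction must lie in [0, 1)")
        for name in ("tubule_width_px", "pixel_size_um", "frame_interval_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        h, w = self.shape
        if min(h, w) - 2 * self.roi_margin_px <= 0:
            raise ValueError("ROI is degenerate: margin leaves no interior")


@dataclass(frozen=True)
class MotionEvent:
    """A scheduled puncta event: kind in {'merge', 'split', 'absorb'}.

    ``ids`` are puncta indices: merge takes two (second is consumed), split
    and absorb take one.
    """

    frame: int
    kind: str
    ids: tuple[int, ...]


@dataclass(frozen=True)
class MotionSpec:
    """Time-lapse motion model.

    A spatial fraction of the ROI (rightmost columns) is designated mobile;
    tubule-graph vertices inside it follow a mean-reverting (AR(1) /
    discretised Ornstein-Uhlenbeck) displacement process with stationary
    standard deviation ``jitter_scale_px`` and lag-1 correlation
    ``jitter_corr``, producing bounded Brownian-like network motion without
    tearing. Puncta (bright compact particles riding on the network, emulating
    protein-labelled junctions and small cisternae) are split into stationary,
    directed (constant velocity along a tubule direction) and mobile-undirected
    classes, with optional scheduled merge/split/absorb events.
    """

    n_frames: int = 30
    mobile_fraction: float = 0.0
    jitter_scale_px: float = 1.5
    jitter_corr: float = 0.8
    n_puncta: int = 0
    puncta_amplitude: float = 1.0
    puncta_sigma_px: float = 2.0
    puncta_mobile_fraction: float = 0.6
    puncta_directed_fraction: float = 0.4
    puncta_speed_px: float = 1.0
    puncta_step_sd_px: float = 1.0
    puncta_max_step_px: float = 4.0
    network_intensity_scale: float = 1.0
    events: tuple[MotionEvent, ...] = ()

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not (0.0 <= self.mobile_fraction <= 1.0):
            raise ValueError("mobile_fraction must lie in [0, 1]")
        if not (0.0 < self.jitter_corr < 1.0):
            raise ValueError("jitter_corr must lie in (0, 1)")
        for ev in self.events:
            if not (0 <= ev.frame < self.n_frames):
                raise ValueError(f"event frame {ev.frame} outside 0..{self.n_frames - 1}")
            if ev.kind not in ("merge", "split", "absorb"):
                raise ValueError(f"unknown event kind {ev.kind!r}")
            n_ids = 2 if ev.kind == "merge" else 1
            if len(ev.ids) != n_ids:
                raise ValueError(f"{ev.kind} event needs {n_ids} puncta id(s)")
            for i in ev.ids:
                if not (0 <= i < self.n_puncta):
                    raise ValueError(f"event references unknown punctum id {i}")


# ---------------------------------------------------------------------------
# Graph ground truth


@dataclass
class Face:
    """One bounded face (polygonal lacuna) of the tubule graph."""

    cycle: list[int]
    area_px2: float
    area_um2: float


@dataclass
class TubuleGraph:
    """Planar embedded tubule network: the vector ground truth.

    ``vertices`` are (row, col) float coordinates; ``edges`` are index pairs.
    Bounded faces are enumerated by half-edge traversal of the embedding; for
    a connected planar graph their count equals E - V + 1.
    """

    vertices: np.ndarray
    edges: list[tuple[int, int]]
    pixel_size_um: float
    bounded_faces: list[Face] = field(default_factory=list)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_vertices, dtype=int)
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    @property
    def junction_indices(self) -> np.ndarray:
        """Indices of degree >= 3 vertices (ground-truth junctions)."""
        return np.flatnonzero(self.degrees >= 3)

    @property
    def junction_coords(self) -> np.ndarray:
        return self.vertices[self.junction_indices]

    def edge_lengths(self) -> np.ndarray:
        p = self.vertices
        return np.array([np.hypot(*(p[u] - p[v])) for u, v in self.edges])


def _face_cycles(vertices: np.ndarray, edges: list[tuple[int, int]]) -> list[list[int]]:
    """Enumerate bounded face cycles of a planar straight-line embedding.

    Standard rotational-system traversal: at each vertex the incident
    neighbours are ordered by angle; following each directed half-edge with
    the 'previous neighbour in counter-clockwise order' rule traces every face
    exactly once. The outer face (largest absolute signed area) is discarded.
    """
    nbrs: dict[int, list[int]] = {}
    for u, v in edges:
        nbrs.setdefault(u, []).append(v)
        nbrs.setdefault(v, []).append(u)
    for u, vs in nbrs.items():
        vs.sort(key=lambda v: math.atan2(vertices[v][0] - vertices[u][0],
                                         vertices[v][1] - vertices[u][1]))
    pos = {u: {v: i for i, v in enumerate(vs)} for u, vs in nbrs.items()}

    half_edges = [(u, v) for u, v in edges] + [(v, u) for u, v in edges]
    visited: set[tuple[int, int]] = set()
    cycles: list[list[int]] = []
    areas: list[float] = []
    for u0, v0 in half_edges:
        if (u0, v0) in visited:
            continue
        cycle = []
        u, v = u0, v0
        while (u, v) not in visited:
            visited.add((u, v))
            cycle.append(u)
            vs = nbrs[v]
            w = vs[(pos[v][u] - 1) % len(vs)]
            u, v = v, w
        # signed (shoelace) area over the tail vertices of the cycle
        pts = vertices[cycle]
        x, y = pts[:, 1], pts[:, 0]
        area = 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        cycles.append(cycle)
        areas.append(area)
    if not cycles:
        return []
    outer = int(np.argmax(np.abs(areas)))
    return [c for i, c in enumerate(cycles) if i != outer]


def _polygon_area(vertices: np.ndarray, cycle: list[int]) -> float:
    pts = vertices[cycle]
    x, y = pts[:, 1], pts[:, 0]
    return abs(0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


def roi_mask_for(spec: PhantomSpec) -> np.ndarray:
    """Rectangular ROI: the frame inset by ``roi_margin_px`` on each side."""
    h, w = spec.shape
    m = spec.roi_margin_px
    roi = np.zeros((h, w), dtype=bool)
    roi[m:h - m, m:w - m] = True
    return roi


def generate_network_graph(spec: PhantomSpec) -> TubuleGraph:
    """Generate a connected planar tubule graph inside the ROI.

    The graph is the largest connected component of the Voronoi ridge network
    of ``n_seeds`` random points, with dangling chains pruned, vertices
    jittered (capped so edges cannot cross) and sub-resolution edges
    (< ``min_edge_px``) contracted into single higher-degree vertices.
    Reproducible for a fixed seed.
    """
    roi = roi_mask_for(spec)
    if not roi.any():
        raise ValueError("degenerate ROI: zero area")
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xE57]))
    h, w = spec.shape
    m = spec.roi_margin_px
    seeds = _poisson_disk_seeds(rng, spec.n_seeds, (m + 1, h - m - 1),
                                (m + 1, w - m - 1))

    if spec.n_seeds < 4:
        # Too few points for a tessellation: a point or a short chain.
        order = np.argsort(seeds[:, 1])
        verts = seeds[order]
        edges = [(i, i + 1) for i in range(len(verts) - 1)]
        return TubuleGraph(verts, edges, spec.pixel_size_um, [])

    vor = Voronoi(seeds[:, ::-1])  # Voronoi wants (x, y)
    vcoords = vor.vertices[:, ::-1]  # back to (row, col)
    g = nx.Graph()
    inset = spec.tubule_width_px  # keep the network strictly inside the ROI
    lo_r, hi_r = m + inset, h - m - 1 - inset
    lo_c, hi_c = m + inset, w - m - 1 - inset

    def inside(i: int) -> bool:
        r, c = vcoords[i]
        return lo_r <= r <= hi_r and lo_c <= c <= hi_c

    for a, b in vor.ridge_vertices:
        if a >= 0 and b >= 0 and inside(a) and inside(b):
            g.add_edge(a, b)
    if g.number_of_edges() == 0:
        raise ValueError(
            "no tubule edges fall inside the ROI; increase n_seeds or the ROI")
    g = g.subgraph(max(nx.connected_components(g), key=len)).copy()

    # prune dangling chains (degree-1 vertices, iteratively)
    while True:
        leaves = [n for n in g.nodes if g.degree[n] <= 1]
        if not leaves:
            break
        g.remove_nodes_from(leaves)
    if g.number_of_edges() == 0:
        raise ValueError("network degenerated while pruning; increase n_seeds")

    nodes = sorted(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    verts = vcoords[nodes].copy()
    edges = [(index[u], index[v]) for u, v in g.edges]

    # jitter, capped at 30% of the shortest incident edge so straight-line
    # planarity is preserved
    if spec.vertex_jitter_px > 0:
        min_inc = np.full(len(verts), np.inf)
        for u, v in edges:
            d = float(np.hypot(*(verts[u] - verts[v])))
            min_inc[u] = min(min_inc[u], d)
            min_inc[v] = min(min_inc[v], d)
        delta = rng.normal(0.0, spec.vertex_jitter_px, size=verts.shape)
        norms = np.hypot(delta[:, 0], delta[:, 1])
        cap = 0.3 * min_inc
        scale = np.where(norms > cap, cap / np.maximum(norms, 1e-12), 1.0)
        verts = verts + delta * scale[:, None]
        verts[:, 0] = np.clip(verts[:, 0], lo_r, hi_r)
        verts[:, 1] = np.clip(verts[:, 1], lo_c, hi_c)

    verts, edges = _contract_short_edges(verts, edges, spec.min_edge_px)
    verts, edges = _enforce_min_angle(verts, edges, spec.min_edge_angle_deg)
    verts, edges = _enforce_edge_clearance(verts, edges,
                                           spec.min_tubule_clearance_px)

    faces = []
    for cycle in _face_cycles(verts, edges):
        a_px2 = _polygon_area(verts, cycle)
        faces.append(Face(cycle, a_px2, a_px2 * spec.pixel_size_um ** 2))
    return TubuleGraph(verts, edges, spec.pixel_size_um, faces)


def _contract_short_edges(verts: np.ndarray, edges: list[tuple[int, int]],
                          min_len: float):
    """Contract edges shorter than ``min_len`` (merge endpoints at midpoint)."""
    g = nx.Graph()
    g.add_nodes_from(range(len(verts)))
    g.add_edges_from(edges)
    pos = {i: verts[i].copy() for i in range(len(verts))}
    changed = True
    while changed:
        changed = False
        for u, v in list(g.edges):
            if not (g.has_node(u) and g.has_node(v) and g.has_edge(u, v)):
                continue
            if float(np.hypot(*(pos[u] - pos[v]))) < min_len:
                mid = 0.5 * (pos[u] + pos[v])
                for nbr in list(g.neighbors(v)):
                    if nbr != u:
                        g.add_edge(u, nbr)
                g.remove_node(v)
                pos[u] = mid
                del pos[v]
                changed = True
    # drop any degree-1 remnants the contraction may have produced
    while True:
        leaves = [n for n in g.nodes if g.degree[n] <= 1]
        if not leaves:
            break
        g.remove_nodes_from(leaves)
    nodes = sorted(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    new_verts = np.array([pos[n] for n in nodes]) if nodes else np.zeros((0, 2))
    new_edges = [(index[u], index[v]) for u, v in g.edges]
    return new_verts, new_edges


def _poisson_disk_seeds(rng, n: int, r_range, c_range) -> np.ndarray:
    """Blue-noise (dart-throwing) seed points with a minimum pairwise spacing.

    Voronoi cells of blue-noise points are far more regular than those of
    uniform random points — matching the fairly even polygon sizes of real
    cortical ER — and avoid the sliver cells whose short edges and shallow
    junction angles are unresolvable at the rendered tubule width. Spacing is
    relaxed geometrically if dart throwing stalls, so any requested ``n`` is
    eventually placed.
    """
    area = (r_range[1] - r_range[0]) * (c_range[1] - c_range[0])
    dmin = 0.72 * math.sqrt(area / max(n, 1))
    pts: list[np.ndarray] = []
    while len(pts) < n:
        placed_any = False
        for _ in range(200 * n):
            if len(pts) >= n:
                break
            cand = np.array([rng.uniform(*r_range), rng.uniform(*c_range)])
            if all(float(np.hypot(*(cand - p))) >= dmin for p in pts):
                pts.append(cand)
                placed_any = True
        if len(pts) < n and not placed_any:
            dmin *= 0.85
    return np.asarray(pts)


def _enforce_min_angle(verts: np.ndarray, edges: list[tuple[int, int]],
                       min_angle_deg: float):
    """Remove edges subtending less than ``min_angle_deg`` at a shared vertex.

    Two tubules leaving a vertex at a very shallow angle overlap in the
    raster for many pixels and only fork far from the vertex, so the detected
    triple point cannot coincide with the graph vertex; the generator forbids
    such configurations. The longer edge of an offending pair is dropped when
    that keeps the graph connected.
    """
    thr = math.radians(min_angle_deg)
    g = nx.Graph(edges)
    changed = True
    while changed:
        changed = False
        for v in list(g.nodes):
            nbrs_v = list(g.neighbors(v))
            done = False
            for i in range(len(nbrs_v)):
                for j in range(i + 1, len(nbrs_v)):
                    a, b = nbrs_v[i], nbrs_v[j]
                    u1 = verts[a] - verts[v]
                    u2 = verts[b] - verts[v]
                    c = float(u1 @ u2) / max(
                        float(np.hypot(*u1) * np.hypot(*u2)), 1e-12)
                    if math.acos(min(max(c, -1.0), 1.0)) >= thr:
                        continue
                    cand = sorted(
                        [(v, a), (v, b)],
                        key=lambda e: -float(np.hypot(*(verts[e[0]] - verts[e[1]]))))
                    for u, w in cand:
                        g.remove_edge(u, w)
                        if nx.is_connected(g):
                            changed = done = True
                            break
                        g.add_edge(u, w)
                    if done:
                        break
                if done:
                    break
    while True:
        leaves = [n for n in g.nodes if g.degree[n] <= 1]
        if not leaves:
            break
        g.remove_nodes_from(leaves)
    nodes = sorted(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    return (verts[nodes].copy() if nodes else np.zeros((0, 2)),
            [(index[u], index[v]) for u, v in g.edges])


def _segment_distance(p1, p2, p3, p4) -> float:
    """Minimum distance between segments p1-p2 and p3-p4."""
    def pt_seg(p, a, b):
        d = b - a
        l2 = float(d @ d)
        if l2 == 0:
            return float(np.hypot(*(p - a)))
        t = np.clip(float((p - a) @ d) / l2, 0.0, 1.0)
        return float(np.hypot(*(p - (a + t * d))))

    def orient(a, b, c):
        return (b[1] - a[1]) * (c[0] - a[0]) - (b[0] - a[0]) * (c[1] - a[1])

    if (orient(p1, p2, p3) * orient(p1, p2, p4) < 0
            and orient(p3, p4, p1) * orient(p3, p4, p2) < 0):
        return 0.0
    return min(pt_seg(p1, p3, p4), pt_seg(p2, p3, p4),
               pt_seg(p3, p1, p2), pt_seg(p4, p1, p2))


def _enforce_edge_clearance(verts: np.ndarray, edges: list[tuple[int, int]],
                            min_clear: float):
    """Remove non-bridge edges that pass within ``min_clear`` of a
    non-adjacent edge.

    Two tubule strokes closer than the rendered width touch in the raster and
    fabricate junctions that exist in no graph vertex; the generator therefore
    guarantees that distinct tubules keep at least one stroke width of
    clearance.
    """
    g = nx.Graph(edges)
    removed = True
    while removed:
        removed = False
        es = list(g.edges)
        for i in range(len(es)):
            a, b = es[i]
            if not g.has_edge(a, b):
                continue
            for j in range(i + 1, len(es)):
                c, d = es[j]
                if not g.has_edge(c, d) or {a, b} & {c, d}:
                    continue
                if _segment_distance(verts[a], verts[b],
                                     verts[c], verts[d]) < min_clear:
                    # drop the longer offender unless it is a bridge
                    cand = sorted(
                        [(a, b), (c, d)],
                        key=lambda e: -float(np.hypot(*(verts[e[0]] - verts[e[1]]))))
                    for u, v in cand:
                        g.remove_edge(u, v)
                        if nx.is_connected(g):
                            removed = True
                            break
                        g.add_edge(u, v)
                    if removed:
                        break
            if removed:
                break
    while True:
        leaves = [n for n in g.nodes if g.degree[n] <= 1]
        if not leaves:
            break
        g.remove_nodes_from(leaves)
    nodes = sorted(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    return (verts[nodes].copy() if nodes else np.zeros((0, 2)),
            [(index[u], index[v]) for u, v in g.edges])


# ---------------------------------------------------------------------------
# Rendering


@dataclass
class PunctaTrack:
    """Ground-truth trajectory of one punctum."""

    track_id: int
    motion_class: str  # stationary | directed | mobile-undirected
    fate: str  # persisted | merged | absorbed-into-sheet | split-parent
    frames: list[int] = field(default_factory=list)
    positions: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class PhantomTruth:
    """Exact ground truth accompanying a rendered phantom."""

    er_mask: np.ndarray
    cisternae_mask: np.ndarray
    distractor_mask: np.ndarray
    roi_mask: np.ndarray
    graph: TubuleGraph
    junction_coords: np.ndarray
    cisternae_fraction_achieved: float
    interior_face_count: int
    tracks: list[PunctaTrack] = field(default_factory=list)
    events: list[MotionEvent] = field(default_factory=list)
    vertex_displacements: np.ndarray | None = None  # (T, n_mobile, 2)
    mobile_vertex_indices: np.ndarray | None = None


def _raster_tubules(shape, verts, edges, width) -> np.ndarray:
    """Pixels whose centers lie within width/2 of any edge segment."""
    h, w = shape
    half = width / 2.0
    mask = np.zeros(shape, dtype=bool)
    pad = int(math.ceil(half)) + 1
    for u, v in edges:
        p, q = verts[u], verts[v]
        r0 = max(0, int(math.floor(min(p[0], q[0]))) - pad)
        r1 = min(h, int(math.ceil(max(p[0], q[0]))) + pad + 1)
        c0 = max(0, int(math.floor(min(p[1], q[1]))) - pad)
        c1 = min(w, int(math.ceil(max(p[1], q[1]))) + pad + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        d = q - p
        l2 = float(d @ d)
        if l2 == 0:
            dist = np.hypot(rr - p[0], cc - p[1])
        else:
            t = ((rr - p[0]) * d[0] + (cc - p[1]) * d[1]) / l2
            t = np.clip(t, 0.0, 1.0)
            dist = np.hypot(rr - (p[0] + t * d[0]), cc - (p[1] + t * d[1]))
        mask[r0:r1, c0:c1] |= dist <= half
    return mask


@dataclass
class _CisternaPatch:
    anchor_vertex: int
    center: np.ndarray  # (row, col), offset baked in
    r_major: float
    r_minor: float
    rotation: float
    scale: float = 1.0


def _raster_patch(shape, patch: _CisternaPatch, offset=(0.0, 0.0)) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_ellipse(
        patch.center[0] + offset[0], patch.center[1] + offset[1],
        max(patch.r_major * patch.scale, 0.5),
        max(patch.r_minor * patch.scale, 0.5),
        shape=shape, rotation=patch.rotation,
    )
    mask[rr, cc] = True
    return mask


def _sample_cisterna_patches(spec: PhantomSpec, graph: TubuleGraph,
                             roi: np.ndarray, rng) -> list[_CisternaPatch]:
    """Place convex elliptical sheets at junctions/faces until the target
    area fraction of the ROI is met (within ~1 pixel ring of the last patch)."""
    if spec.cisternae_fraction <= 0:
        return []
    target = spec.cisternae_fraction * float(roi.sum())
    anchors: list[tuple[int, np.ndarray]] = []
    for i in graph.junction_indices:
        anchors.append((int(i), graph.vertices[i]))
    for f in graph.bounded_faces:
        anchors.append((int(f.cycle[0]), graph.vertices[f.cycle].mean(axis=0)))
    if not anchors:
        anchors = [(0, graph.vertices[0])]
    order = rng.permutation(len(anchors))

    patches: list[_CisternaPatch] = []
    acc = np.zeros(spec.shape, dtype=bool)
    for k in range(min(500, 8 * len(anchors) + 50)):
        ai, center = anchors[order[k % len(anchors)]]
        r = rng.uniform(*spec.cisterna_radius_px)
        aspect = rng.uniform(*spec.cisterna_aspect)
        theta = rng.uniform(0.0, math.pi)
        patch = _CisternaPatch(ai, np.asarray(center, float), r, r * aspect, theta)
        pm = _raster_patch(spec.shape, patch) & roi
        new = acc | pm
        if float(new.sum()) < target:
            acc = new
            patches.append(patch)
            continue
        # overshoot: binary-search the scale of this last patch onto the target
        lo, hi = 0.0, 1.0
        best, best_err = None, np.inf
        for _ in range(22):
            mid = 0.5 * (lo + hi)
            patch_mid = replace(patch, scale=mid)
            area = float((acc | (_raster_patch(spec.shape, patch_mid) & roi)).sum())
            err = abs(area - target)
            if err < best_err:
                best, best_err = mid, err
            if area < target:
                lo = mid
            else:
                hi = mid
        if best and best * min(patch.r_major, patch.r_minor) >= 1.0:
            patches.append(replace(patch, scale=best))
        return patches
    return patches


def _raster_cisternae(shape, patches, roi,
                      displacements: dict[int, np.ndarray] | None = None) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for p in patches:
        off = (0.0, 0.0)
        if displacements is not None and p.anchor_vertex in displacements:
            off = tuple(displacements[p.anchor_vertex])
        mask |= _raster_patch(shape, p, off)
    return mask & roi


def _sample_distractors(spec: PhantomSpec, roi: np.ndarray,
                        er_mask: np.ndarray, rng) -> np.ndarray:
    """Bright non-ER blobs (e.g. mitochondria) disjoint from the ER mask."""
    mask = np.zeros(spec.shape, dtype=bool)
    if spec.n_distractors <= 0:
        return mask
    forbidden = ndi.binary_dilation(er_mask, iterations=2)
    placed = 0
    for _ in range(400 * spec.n_distractors):
        if placed >= spec.n_distractors:
            break
        r0 = rng.uniform(*spec.distractor_radius_px)
        aspect = rng.uniform(0.5, 1.0)
        center = (rng.uniform(0, spec.shape[0]), rng.uniform(0, spec.shape[1]))
        if not roi[int(center[0]) % spec.shape[0], int(center[1]) % spec.shape[1]]:
            continue
        blob = np.zeros(spec.shape, dtype=bool)
        rr, cc = draw_ellipse(center[0], center[1], r0, r0 * aspect,
                              shape=spec.shape, rotation=rng.uniform(0, math.pi))
        blob[rr, cc] = True
        blob &= roi
        if not blob.any():
            continue
        halo = ndi.binary_dilation(blob, iterations=2)
        if (halo & forbidden).any() or (halo & mask).any():
            continue
        mask |= blob
        placed += 1
    if placed < spec.n_distractors:
        raise ValueError(
            f"could only place {placed}/{spec.n_distractors} distractors without overlap")
    return mask


def _resolvable_interior_faces(graph: TubuleGraph, spec: PhantomSpec,
                               er_mask: np.ndarray) -> int:
    """Count lacunae that survive rasterization at the rendered tubule width.

    Independent enclosure route: each bounded face of the vector graph is
    polygon-filled, foreground (tubules + cisternae) is removed, and surviving
    4-connected components are counted per face.
    """
    from .morphometrics import MIN_LACUNA_PX

    count = 0
    four = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    for f in graph.bounded_faces:
        pts = graph.vertices[f.cycle]
        rr, cc = draw_polygon(pts[:, 0], pts[:, 1], shape=spec.shape)
        if rr.size == 0:
            continue
        fill = np.zeros(spec.shape, dtype=bool)
        fill[rr, cc] = True
        fill &= ~er_mask
        if not fill.any():
            continue
        labels, n = ndi.label(fill, structure=four)
        if n:
            sizes = ndi.sum_labels(fill, labels, index=np.arange(1, n + 1))
            count += int(np.sum(sizes >= MIN_LACUNA_PX))
    return count


def _scene_rngs(spec: PhantomSpec):
    ss = np.random.SeedSequence([int(spec.seed), 0x5CE])
    scene, noise, motion = ss.spawn(3)
    return (np.random.default_rng(scene), np.random.default_rng(noise),
            np.random.default_rng(motion))


def _build_scene(graph: TubuleGraph, spec: PhantomSpec):
    roi = roi_mask_for(spec)
    rng_scene, rng_noise, rng_motion = _scene_rngs(spec)
    if spec.tubule_width_px < 1:
        raise ValueError("tubule_width_px must be >= 1")
    tub = _raster_tubules(spec.shape, graph.vertices, graph.edges,
                          spec.tubule_width_px)
    patches = _sample_cisterna_patches(spec, graph, roi, rng_scene)
    cis = _raster_cisternae(spec.shape, patches, roi)
    er = tub | cis
    dis = _sample_distractors(spec, roi, er, rng_scene)
    return roi, tub, patches, cis, er, dis, rng_noise, rng_motion


def _compose_intensity(spec: PhantomSpec, tub, cis, dis, scale=1.0):
    img = np.full(spec.shape, spec.background, dtype=float)
    img[tub] = np.maximum(img[tub], spec.tubule_intensity * scale)
    img[cis] = np.maximum(img[cis], spec.cisterna_intensity * scale)
    img[dis] = np.maximum(img[dis], spec.distractor_intensity)
    return img


def _apply_optics(img: np.ndarray, spec: PhantomSpec, rng) -> np.ndarray:
    out = img
    if spec.psf_sigma_px > 0:
        out = ndi.gaussian_filter(out, spec.psf_sigma_px, mode="reflect")
    if spec.peak_photons:
        out = rng.poisson(np.clip(out, 0, None) * spec.peak_photons) / spec.peak_photons
    if spec.read_noise > 0:
        out = out + rng.normal(0.0, spec.read_noise, size=out.shape)
    return out


def render_phantom(graph: TubuleGraph, spec: PhantomSpec):
    """Render one frame and its ground truth.

    Returns ``(ImageStack, PhantomTruth)``; truth masks are pre-noise, and the
    achieved cisternae fraction (of ROI area) is recorded in the truth.
    """
    roi, tub, patches, cis, er, dis, rng_noise, _ = _build_scene(graph, spec)
    img = _apply_optics(_compose_intensity(spec, tub, cis, dis), spec, rng_noise)
    truth = PhantomTruth(
        er_mask=er, cisternae_mask=cis, distractor_mask=dis, roi_mask=roi,
        graph=graph, junction_coords=graph.junction_coords,
        cisternae_fraction_achieved=float(cis.sum()) / float(roi.sum()),
        interior_face_count=_resolvable_interior_faces(graph, spec, er),
    )
    stack = ImageStack(img[None], spec.pixel_size_um, spec.frame_interval_s)
    return stack, truth


# ---------------------------------------------------------------------------
# Time lapse


def _puncta_trajectories(graph: TubuleGraph, spec: PhantomSpec,
                         motion: MotionSpec, roi: np.ndarray, rng,
                         cisternae_centers: list[np.ndarray]):
    """Precompute puncta positions per frame plus truth tracks/events."""
    T, n = motion.n_frames, motion.n_puncta
    if n == 0:
        return np.zeros((T, 0, 2)), [], []
    jc = graph.junction_coords
    if len(jc) >= n:
        starts = jc[rng.choice(len(jc), size=n, replace=False)]
    else:
        extra = np.column_stack([
            rng.uniform(roi.shape[0] * 0.1, roi.shape[0] * 0.9, size=n - len(jc)),
            rng.uniform(roi.shape[1] * 0.1, roi.shape[1] * 0.9, size=n - len(jc)),
        ])
        starts = np.vstack([jc, extra]) if len(jc) else extra

    n_mobile = int(round(motion.puncta_mobile_fraction * n))
    mobile_ids = rng.choice(n, size=n_mobile, replace=False)
    n_directed = int(round(motion.puncta_directed_fraction * n_mobile))
    directed_ids = set(int(i) for i in mobile_ids[:n_directed])
    mobile_set = set(int(i) for i in mobile_ids)

    lo = np.array([2.0, 2.0])
    hi = np.array([roi.shape[0] - 3.0, roi.shape[1] - 3.0])
    pos = np.zeros((T, n, 2))
    classes = []
    for i in range(n):
        p = starts[i].astype(float).copy()
        if i in directed_ids:
            classes.append("directed")
            ang = rng.uniform(0, 2 * math.pi)
            vel = motion.puncta_speed_px * np.array([math.sin(ang), math.cos(ang)])
            for t in range(T):
                pos[t, i] = np.clip(p, lo, hi)
                p = p + vel
                # reflect at ROI bounds
                for d in range(2):
                    if p[d] < lo[d] or p[d] > hi[d]:
                        vel[d] = -vel[d]
                        p[d] = np.clip(p[d], lo[d], hi[d])
        elif i in mobile_set:
            classes.append("mobile-undirected")
            for t in range(T):
                pos[t, i] = np.clip(p, lo, hi)
                step = rng.normal(0.0, motion.puncta_step_sd_px, 2)
                nrm = float(np.hypot(*step))
                if nrm > motion.puncta_max_step_px:
                    step *= motion.puncta_max_step_px / nrm
                p = np.clip(p + step, lo, hi)
        else:
            classes.append("stationary")
            for t in range(T):
                pos[t, i] = p

    # scheduled events rewrite trajectories and define fates
    alive = np.ones((T, n), dtype=bool)
    fates = {i: "persisted" for i in range(n)}
    events_out: list[MotionEvent] = []
    for ev in sorted(motion.events, key=lambda e: e.frame):
        f = ev.frame
        if ev.kind == "merge":
            i, j = ev.ids
            # j converges linearly onto i's position and is consumed at f
            for t in range(f):
                a = t / max(f, 1)
                pos[t, j] = (1 - a) * pos[t, j] + a * pos[f, i]
            pos[f, j] = pos[f, i]
            alive[f + 1:, j] = False
            fates[j] = "merged"
            events_out.append(ev)
        elif ev.kind == "split":
            (i,) = ev.ids
            # nearest free slot: reuse a dead punctum or ignore if none —
            # simplest honest semantics: the parent continues, a child track is
            # appended at render time by duplicating the parent with divergence
            events_out.append(ev)
            fates[i] = "split-parent"
        elif ev.kind == "absorb":
            (i,) = ev.ids
            if cisternae_centers:
                tgt = min(cisternae_centers,
                          key=lambda c: float(np.hypot(*(c - pos[0, i]))))
                for t in range(min(f + 1, T)):
                    a = t / max(f, 1)
                    pos[t, i] = (1 - a) * pos[t, i] + a * tgt
            alive[f + 1:, i] = False
            fates[i] = "absorbed-into-sheet"
            events_out.append(ev)

    # split children
    child_pos = []
    child_tracks = []
    next_id = n
    for ev in events_out:
        if ev.kind != "split":
            continue
        (i,) = ev.ids
        f = ev.frame
        traj = np.full((T, 2), np.nan)
        drift = rng.normal(0, 1, 2)
        drift = drift / max(float(np.hypot(*drift)), 1e-9) * 1.2
        p = pos[f, i].copy()
        for t in range(f, T):
            traj[t] = np.clip(p, lo, hi)
            p = p + drift
        child_pos.append(traj)
        child_tracks.append((next_id, "directed", f))
        next_id += 1

    tracks: list[PunctaTrack] = []
    for i in range(n):
        frames = [t for t in range(T) if alive[t, i]]
        tracks.append(PunctaTrack(
            track_id=i, motion_class=classes[i], fate=fates[i],
            frames=frames,
            positions=[tuple(pos[t, i]) for t in frames]))
    full = np.full((T, n + len(child_pos), 2), np.nan)
    for i in range(n):
        for t in range(T):
            if alive[t, i]:
                full[t, i] = pos[t, i]
    for k, traj in enumerate(child_pos):
        full[:, n + k] = traj
        cid, cls, f0 = child_tracks[k]
        frames = [t for t in range(T) if not np.isnan(traj[t, 0])]
        tracks.append(PunctaTrack(track_id=cid, motion_class=cls,
                                  fate="persisted", frames=frames,
                                  positions=[tuple(traj[t]) for t in frames]))
    return full, tracks, events_out


def generate_timelapse(graph: TubuleGraph, spec: PhantomSpec,
                       motion: MotionSpec):
    """Render a seeded time-lapse with ground-truth motion and puncta tracks.

    Frame 0 equals the :func:`render_phantom` output for the same spec (the
    scene and per-frame noise draw from the same seeded streams). Vertices in
    the mobile region follow a mean-reverting AR(1) displacement started at
    zero; cisternae ride on their anchor vertices; scheduled puncta events are
    executed and logged in the truth tracks.
    """
    roi, tub0, patches, cis0, er0, dis, rng_noise, rng_motion = _build_scene(graph, spec)
    h, w = spec.shape
    T = motion.n_frames

    # spatial mobile region: rightmost fraction of ROI columns
    col_thresh = w - motion.mobile_fraction * w
    mobile_idx = np.flatnonzero(graph.vertices[:, 1] >= col_thresh)
    rho = motion.jitter_corr
    innov = motion.jitter_scale_px * math.sqrt(1.0 - rho * rho)

    cis_centers = [p.center for p in patches]
    puncta_pos, tracks, events = _puncta_trajectories(
        graph, spec, motion, roi, rng_motion, cis_centers)

    frames = np.zeros((T, h, w))
    disp = np.zeros((len(mobile_idx), 2))
    disp_hist = np.zeros((T, len(mobile_idx), 2))
    verts = graph.vertices
    for t in range(T):
        if t > 0 and len(mobile_idx):
            disp = rho * disp + rng_motion.normal(0.0, innov, size=disp.shape)
        disp_hist[t] = disp
        if t == 0 or not len(mobile_idx):
            tub, cis = tub0, cis0
        else:
            vt = verts.copy()
            vt[mobile_idx] += disp
            tub = _raster_tubules(spec.shape, vt, graph.edges, spec.tubule_width_px)
            dmap = {int(i): disp[k] for k, i in enumerate(mobile_idx)}
            cis = _raster_cisternae(spec.shape, patches, roi, dmap)
        img = _compose_intensity(spec, tub, cis, dis,
                                 scale=motion.network_intensity_scale)
        # puncta as Gaussian spots
        for i in range(puncta_pos.shape[1]):
            p = puncta_pos[t, i]
            if np.isnan(p[0]):
                continue
            s = motion.puncta_sigma_px
            r0, r1 = max(0, int(p[0] - 4 * s)), min(h, int(p[0] + 4 * s) + 1)
            c0, c1 = max(0, int(p[1] - 4 * s)), min(w, int(p[1] + 4 * s) + 1)
            rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
            blob = motion.puncta_amplitude * np.exp(
                -((rr - p[0]) ** 2 + (cc - p[1]) ** 2) / (2 * s * s))
            img[r0:r1, c0:c1] = np.maximum(img[r0:r1, c0:c1], blob)
        frames[t] = _apply_optics(img, spec, rng_noise)

    truth = PhantomTruth(
        er_mask=er0, cisternae_mask=cis0, distractor_mask=dis, roi_mask=roi,
        graph=graph, junction_coords=graph.junction_coords,
        cisternae_fraction_achieved=float(cis0.sum()) / float(roi.sum()),
        interior_face_count=_resolvable_interior_faces(graph, spec, er0),
        tracks=tracks, events=list(events),
        vertex_displacements=disp_hist, mobile_vertex_indices=mobile_idx,
    )
    stack = ImageStack(frames, spec.pixel_size_um, spec.frame_interval_s)
    return stack, truth
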