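"""Evaluation helpers for validating pipeline output against phantom truth.

These are scoring utilities only — they compare a result with ground truth
and never participate in producing the result.
"""

from __future__ import annotations

import numpy as np

from .dynamics import PunctaTrackSet
from .phantom import PunctaTrack


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = float((a | b).sum())
    return float((a & b).sum()) / union if union else 1.0


def match_tracks(truth_tracks: list[PunctaTrack], detected: PunctaTrackSet,
                 max_mean_dist_px: float = 4.0,
                 min_overlap: float = 0.5) -> float:
    """Fraction of truth tracks recovered one-to-one by the tracker.

    Greedy assignment by mean centroid distance over shared frames: a
    detected track is a candidate match for a truth track when they share at
    least ``min_overlap`` of the truth track's frames and their mean distance
    on shared frames is within ``max_mean_dist_px``. Each detected track can
    claim at most one truth track (and vice versa).
    """
    if not truth_tracks:
        return 1.0
    cands = []
    for ti, tt in enumerate(truth_tracks):
        t_pos = {f: p for f, p in zip(tt.frames, tt.positions)}
        for di, dt in enumerate(detected.tracks):
            shared = [f for f in dt.frames if f in t_pos]
            if len(shared) < min_overlap * len(tt.frames):
                continue
            d_pos = {f: p for f, p in zip(dt.frames, dt.positions)}
            dist = float(np.mean([np.hypot(t_pos[f][0] - d_pos[f][0],
                                           t_pos[f][1] - d_pos[f][1])
                                  for f in shared]))
            if dist <= max_mean_dist_px:
                cands.append((dist, ti, di))
    cands.sort()
    used_t: set[int] = set()
    used_d: set[int] = set()
    for _, ti, di in cands:
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
    return len(used_t) / len(truth_tracks)
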