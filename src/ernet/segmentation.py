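"""ER segmentation: contrast enhancement, trainable pixel classification
with an explicit rejected class, and connectivity-repairing closing.

Mirrors the interactive workflow used on real micrographs — smooth/enhance,
classify pixels into {ER, background, rejected distractor} with a trained
ensemble (distractors such as mitochondria picked up by lipophilic dyes are
explicitly rejected rather than lumped into background), binarize, then close
small gaps so the network stays connected. A plain global-threshold fallback
(Otsu when no threshold is given) is provided for clean images and as a
baseline.

Foreground connectivity is 8-connected throughout; all filters use reflect
padding at the image boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from sklearn.ensemble import RandomForestClassifier

CLASS_BACKGROUND = 0
CLASS_ER = 1
CLASS_REJECTED = 2
CLASS_NAMES = {CLASS_BACKGROUND: "background", CLASS_ER: "ER",
               CLASS_REJECTED: "rejected"}

FEATURES_PER_SCALE = 4  # smoothed, gradient magnitude, LoG, DoG


@dataclass
class SegmentationMask:
    """Per-pixel class map plus the binary ER mask derived from it."""

    class_map: np.ndarray  # int in {0 background, 1 ER, 2 rejected}
    er_mask: np.ndarray
    provenance: str

    def __post_init__(self) -> None:
        if self.class_map.shape != self.er_mask.shape:
            raise ValueError("class map and ER mask shapes differ")


def enhance_contrast(frame: np.ndarray, saturation_fraction: float = 0.0,
                     smooth_sigma: float = 0.0) -> np.ndarray:
    """Monotone rescale to [0, 1], clipping extreme pixels.

    ``saturation_fraction`` is the total fraction of pixels allowed to
    saturate (half at each tail). An optional small-sigma Gaussian smoothing
    is applied first to reduce shot noise. A constant frame maps to zeros.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    if not (0.0 <= saturation_fraction < 0.5):
        raise ValueError("saturation_fraction must lie in [0, 0.5)")
    if smooth_sigma > 0:
        frame = ndi.gaussian_filter(frame, smooth_sigma, mode="reflect")
    lo = np.quantile(frame, saturation_fraction / 2.0)
    hi = np.quantile(frame, 1.0 - saturation_fraction / 2.0)
    if hi <= lo:
        return np.zeros_like(frame)
    return np.clip((frame - lo) / (hi - lo), 0.0, 1.0)


def extract_pixel_features(frame: np.ndarray,
                           scales=(1.0, 2.0, 4.0)) -> np.ndarray:
    """Multi-scale per-pixel feature stack of shape (H, W, n_features).

    Per scale sigma: Gaussian-smoothed intensity, Gaussian gradient magnitude,
    Laplacian of Gaussian (ridge/edge response) and difference of smoothings
    (sigma vs 1.6 sigma). Deterministic; reflect boundary handling.
    """
    frame = np.asarray(frame, dtype=float)
    scales = list(scales)
    if not scales:
        raise ValueError("scales must be non-empty")
    if any(s <= 0 for s in scales):
        raise ValueError("scales must be positive")
    feats = []
    for s in scales:
        sm = ndi.gaussian_filter(frame, s, mode="reflect")
        grad = ndi.gaussian_gradient_magnitude(frame, s, mode="reflect")
        log = ndi.gaussian_laplace(frame, s, mode="reflect")
        dog = sm - ndi.gaussian_filter(frame, 1.6 * s, mode="reflect")
        feats.extend([sm, grad, log, dog])
    return np.stack(feats, axis=-1)


@dataclass
class PixelClassifier:
    """Seeded decision-tree-ensemble pixel classifier over the feature bank."""

    model: RandomForestClassifier
    scales: tuple[float, ...]
    training_recall: dict[str, float] = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return len(self.scales) * FEATURES_PER_SCALE

    def params_json(self) -> str:
        return json.dumps({
            "scales": list(self.scales),
            "n_estimators": self.model.n_estimators,
            "classes": [CLASS_NAMES[int(c)] for c in self.model.classes_],
            "training_recall": self.training_recall,
        })


def train_pixel_classifier(features: np.ndarray, label_mask: np.ndarray,
                           scales=(1.0, 2.0, 4.0), seed: int = 0,
                           n_estimators: int = 50,
                           min_per_class: int = 50) -> PixelClassifier:
    """Train the three-class pixel classifier from a sparse label mask.

    ``label_mask`` holds -1 for unlabelled pixels and class ids
    {0 background, 1 ER, 2 rejected} elsewhere; each class needs at least
    ``min_per_class`` labelled pixels. Training is seeded and reports
    per-class training recall.
    """
    features = np.asarray(features)
    label_mask = np.asarray(label_mask)
    if features.shape[:2] != label_mask.shape:
        raise ValueError("features and label mask shapes differ")
    sel = label_mask >= 0
    x = features[sel].reshape(-1, features.shape[-1])
    y = label_mask[sel].astype(int)
    for cls in (CLASS_BACKGROUND, CLASS_ER, CLASS_REJECTED):
        n = int((y == cls).sum())
        if n < min_per_class:
            raise ValueError(
                f"class '{CLASS_NAMES[cls]}' has {n} labelled pixels; "
                f"need >= {min_per_class}")
    model = RandomForestClassifier(
        n_estimators=n_estimators, random_state=int(seed), n_jobs=1,
        min_samples_leaf=2)
    model.fit(x, y)
    pred = model.predict(x)
    recall = {CLASS_NAMES[c]: float((pred[y == c] == c).mean())
              for c in np.unique(y)}
    return PixelClassifier(model=model, scales=tuple(scales),
                           training_recall=recall)


def segment_image(frame: np.ndarray,
                  classifier: PixelClassifier | None = None,
                  threshold: float | None = None) -> SegmentationMask:
    """Segment one frame into {ER, background, rejected} and a binary ER mask.

    With a trained classifier, rejected-class pixels (distractors) are
    excluded from the ER mask. Without one, a global threshold is used
    (Otsu's between-class-variance criterion when ``threshold`` is None);
    threshold mode has no rejected class.
    """
    frame = np.asarray(frame, dtype=float)
    if classifier is not None:
        feats = extract_pixel_features(frame, classifier.scales)
        if feats.shape[-1] != classifier.n_features:
            raise ValueError("frame/model feature-scale mismatch")
        pred = classifier.model.predict(
            feats.reshape(-1, feats.shape[-1])).reshape(frame.shape)
        er = pred == CLASS_ER
        return SegmentationMask(pred.astype(np.int8), er, "classifier")
    if threshold is None:
        threshold = float(threshold_otsu(frame))
        prov = f"otsu={threshold:.4g}"
    else:
        prov = f"threshold={threshold:.4g}"
    er = frame > threshold
    cmap = np.where(er, CLASS_ER, CLASS_BACKGROUND).astype(np.int8)
    return SegmentationMask(cmap, er, prov)


def close_mask(mask: np.ndarray, radius_px: int = 2,
               iterations: int = 1) -> np.ndarray:
    """Morphological closing with a disk element, iterated.

    Closing is extensive (never removes foreground): the output is padded
    internally so foreground is preserved at the image border too.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    mask = np.asarray(mask, bool)
    selem = disk(radius_px)
    pad = radius_px * iterations + 1
    padded = np.pad(mask, pad, mode="constant")
    closed = ndi.binary_closing(padded, structure=selem, iterations=iterations)
    out = closed[pad:-pad, pad:-pad]
    return out | mask
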