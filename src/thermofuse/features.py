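"""Scale-invariant feature detection and descriptor matching.

Detection uses a difference-of-Gaussians scale-space detector with
gradient-orientation-histogram descriptors (scikit-image's SIFT); the
descriptors are re-normalized to unit length so that Euclidean descriptor
distance is the matching metric.  Matching is mutual nearest-neighbor with
Lowe's ratio test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from skimage.feature import SIFT

__all__ = ["FeatureSet", "MatchSet", "detect_features", "match_features"]


@dataclass(frozen=True)
class FeatureSet:
    """Sub-pixel keypoint positions (x=col, y=row), scales and unit-norm
    descriptors for one image."""

    positions: np.ndarray  # (N, 2) as (x, y)
    scales: np.ndarray  # (N,)
    descriptors: np.ndarray  # (N, D), unit rows

    def __len__(self) -> int:
        return len(self.positions)

    @classmethod
    def empty(cls, dim: int = 128) -> "FeatureSet":
        return cls(np.empty((0, 2)), np.empty(0), np.empty((0, dim)))


@dataclass
class MatchSet:
    """One-to-one descriptor correspondences between two images.

    ``pairs[i] = (index_a, index_b)``; ``inlier_mask`` is filled by geometric
    verification and defaults to all-True.
    """

    pairs: np.ndarray  # (M, 2) int
    inlier_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        if self.inlier_mask is None:
            self.inlier_mask = np.ones(len(self.pairs), dtype=bool)
        self.inlier_mask = np.asarray(self.inlier_mask, dtype=bool)
        for col in (0, 1):
            vals = self.pairs[:, col]
            if len(np.unique(vals)) != len(vals):
                raise ValueError("matches must be one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def inliers(self) -> np.ndarray:
        return self.pairs[self.inlier_mask]


def detect_features(
    image: np.ndarray,
    max_features: int | None = None,
    c_dog: float = 0.0005,
    c_edge: float = 10.0,
) -> FeatureSet:
    """Detect DoG keypoints with orientation-histogram descriptors.

    Deterministic for a fixed image.  A blank image yields an empty set;
    images smaller than 32x32 are rejected.  With ``max_features`` set, the
    strongest (largest-scale) keypoints are kept.  The DoG contrast
    threshold ``c_dog`` defaults well below the photographic convention:
    intensified thermograms carry genuinely low-contrast texture, which is
    the very reason the intensification stage exists.
    """
    img = np.asarray(image)
    if img.ndim != 2 or min(img.shape) < 32:
        raise ValueError(f"image must be 2D and at least 32x32, got {img.shape}")
    img = img.astype(float) / 255.0 if img.dtype == np.uint8 else img.astype(float)
    if img.max() == img.min():
        return FeatureSet.empty()
    det = SIFT(c_dog=c_dog, c_edge=c_edge)
    try:
        det.detect_and_extract(img)
    except RuntimeError:  # no extrema found
        return FeatureSet.empty()
    pos = det.positions[:, ::-1].astype(float)  # (row, col) -> (x, y)
    scales = det.sigmas.astype(float)
    desc = det.descriptors.astype(float)
    # rootSIFT-style normalization (L1 + sqrt, then L2): markedly better
    # matching precision on low-contrast texture than plain L2
    l1 = np.abs(desc).sum(axis=1, keepdims=True)
    l1[l1 == 0] = 1.0
    desc = np.sqrt(desc / l1)
    norms = np.linalg.norm(desc, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    desc = desc / norms
    if max_features is not None and len(pos) > max_features:
        order = np.argsort(-np.abs(det.dog_responses)) if hasattr(det, "dog_responses") else None
        if order is None:
            order = np.argsort(-scales)
        keep = np.sort(order[:max_features])
        pos, scales, desc = pos[keep], scales[keep], desc[keep]
    return FeatureSet(pos, scales, desc)


def match_features(a: FeatureSet, b: FeatureSet, ratio: float = 0.8) -> MatchSet:
    """Mutual nearest-neighbor matching with Lowe's ratio test.

    A pair (i, j) is kept iff j is i's nearest neighbor in b, i is j's
    nearest neighbor in a, and d1/d2 < ratio where d1, d2 are the distances
    to the nearest and second-nearest neighbor of i.  Empty inputs yield an
    empty match set.
    """
    if not (0.0 < ratio < 1.0):
        raise ValueError("ratio must lie in (0, 1)")
    if len(a) == 0 or len(b) == 0:
        return MatchSet(np.empty((0, 2), dtype=int))
    d = cdist(a.descriptors, b.descriptors)
    nn_ab = np.argmin(d, axis=1)
    nn_ba = np.argmin(d, axis=0)
    i_idx = np.arange(len(a))
    mutual = nn_ba[nn_ab] == i_idx
    if d.shape[1] >= 2:
        two = np.partition(d, 1, axis=1)[:, :2]
        with np.errstate(divide="ignore", invalid="ignore"):
            passes = two[:, 0] < ratio * two[:, 1]
        mutual &= passes
    pairs = np.column_stack([i_idx[mutual], nn_ab[mutual]])
    return MatchSet(pairs)
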