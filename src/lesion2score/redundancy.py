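"""Pairwise lesion-image distances and per-image redundancy scores.

Three pseudo-metrics on binary masks:

``centroid``
    Euclidean distance between lesion centroids (voxel units).
``topological``
    Both lesions are translated so their (rounded) centroids coincide, both
    are cropped to the bounding box of the larger lesion, and the voxelwise
    Euclidean distance is taken — shape similarity irrespective of location.
``raw``
    Plain voxelwise Euclidean distance in the common space — captures
    location and shape together.

An image's redundancy is the number of other images closer to it than its
row-specific threshold mean(row) - SD(row), the self-distance excluded from
both the statistics and the count; the cohort is then median-split into
high/low redundancy groups (ties to high).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .exceptions import DegeneracyError, GridError, ValidationError
from .imaging import GRID_SHAPE, LesionImage

METRIC_LABELS = ("centroid", "topological", "raw")


def _mask_of(image) -> np.ndarray:
    mask = image.voxels if isinstance(image, LesionImage) else np.asarray(image)
    if mask.shape != GRID_SHAPE:
        raise GridError(f"mask shape {mask.shape} != {GRID_SHAPE}")
    return mask.astype(bool)


def centroid_of(lesion) -> np.ndarray:
    """Arithmetic mean of the nonzero voxel coordinates (voxel units)."""
    mask = _mask_of(lesion)
    coords = np.argwhere(mask)
    if coords.size == 0:
        raise DegeneracyError("centroid undefined for an empty mask")
    return coords.mean(axis=0)


def centroid_distance(a, b) -> float:
    """Euclidean distance between the lesion centroids."""
    return float(np.linalg.norm(centroid_of(a) - centroid_of(b)))


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (coordinates here are non-negative)."""
    return np.where(x >= 0, np.floor(x + 0.5), np.ceil(x - 0.5)).astype(int)


def _centered_coords(lesion) -> np.ndarray:
    """Voxel coordinates relative to the rounded centroid."""
    mask = _mask_of(lesion)
    coords = np.argwhere(mask)
    if coords.size == 0:
        raise DegeneracyError("topological distance undefined for an empty mask")
    return coords - _round_half_away(centroid_of(mask))


def _topo_from_coords(ca: np.ndarray, cb: np.ndarray) -> float:
    larger = ca if ca.shape[0] >= cb.shape[0] else cb
    lo, hi = larger.min(axis=0), larger.max(axis=0)

    def in_crop(c: np.ndarray) -> np.ndarray:
        keep = ((c >= lo) & (c <= hi)).all(axis=1)
        return c[keep]

    ka, kb = in_crop(ca), in_crop(cb)
    dims = hi - lo + 1
    fa = np.ravel_multi_index((ka - lo).T, dims) if ka.size else np.array([], dtype=int)
    fb = np.ravel_multi_index((kb - lo).T, dims) if kb.size else np.array([], dtype=int)
    common = np.intersect1d(fa, fb, assume_unique=True).size
    return float(np.sqrt(fa.size + fb.size - 2 * common))


def topological_distance(a, b) -> float:
    """Voxelwise distance after centroid alignment and larger-lesion crop.

    For binary masks this is sqrt(#disagreeing voxels within the crop);
    voxels that fall outside the crop are treated as background.
    """
    return _topo_from_coords(_centered_coords(a), _centered_coords(b))


def raw_distance(a, b) -> float:
    """Voxelwise Euclidean distance with no alignment (location-sensitive)."""
    ma, mb = _mask_of(a), _mask_of(b)
    return float(np.sqrt(np.logical_xor(ma, mb).sum()))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances under one metric."""

    values: np.ndarray
    metric_label: str
    patient_ids: list | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValidationError("distance matrix must be symmetric")
        if (np.diag(v) != 0).any() or (v < 0).any():
            raise ValidationError("distances must be >= 0 with zero diagonal")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path) -> None:
        ids = self.patient_ids or [str(i) for i in range(self.n)]
        pd.DataFrame(self.values, index=ids, columns=ids).to_csv(path)

    @classmethod
    def from_csv(cls, path, metric_label: str = "unknown") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(), metric_label, patient_ids=list(df.index))


def distance_matrix(images, metric_label: str) -> DistanceMatrix:
    """Full pairwise distance matrix under the named metric."""
    if metric_label not in METRIC_LABELS:
        raise ValidationError(
            f"unknown metric {metric_label!r}; choose from {METRIC_LABELS}"
        )
    n = len(images)
    if n < 2:
        raise ValidationError("distance matrix needs at least 2 images")
    ids = [
        im.patient_id if isinstance(im, LesionImage) else None for im in images
    ]
    if any(i is None for i in ids):
        ids = None

    if metric_label == "centroid":
        try:
            cents = np.stack([centroid_of(im) for im in images])
        except DegeneracyError as exc:
            raise DegeneracyError(f"empty mask in cohort: {exc}") from exc
        D = cdist(cents, cents)
    elif metric_label == "raw":
        flat = np.stack([_mask_of(im).reshape(-1).astype(np.float32) for im in images])
        vol = flat.sum(axis=1, dtype=np.float64)
        inner = (flat @ flat.T).astype(np.float64)  # exact: binary masks
        sq = vol[:, None] + vol[None, :] - 2 * inner
        D = np.sqrt(np.maximum(sq, 0.0))
    else:
        coords = [_centered_coords(im) for im in images]
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = _topo_from_coords(coords[i], coords[j])
    np.fill_diagonal(D, 0.0)
    D = 0.5 * (D + D.T)
    return DistanceMatrix(D, metric_label, patient_ids=ids)


@dataclass
class RedundancyScore:
    """Per-image redundancy counts and the row thresholds that produced them."""

    counts: np.ndarray
    thresholds: np.ndarray
    metric_label: str
    patient_ids: list | None = None


def redundancy_counts(D: DistanceMatrix) -> RedundancyScore:
    """Count, per row, the other images strictly below mean(row) - SD(row).

    The self-distance (diagonal zero) is excluded from the row statistics and
    from the count; the SD is the population SD of the off-diagonal row.
    """
    n = D.n
    if n < 3:
        raise DegeneracyError("redundancy counts need at least 3 images")
    counts = np.zeros(n, dtype=int)
    thresholds = np.zeros(n)
    for i in range(n):
        row = np.delete(D.values[i], i)
        thr = row.mean() - row.std()
        thresholds[i] = thr
        counts[i] = int((row < thr).sum())
    return RedundancyScore(
        counts=counts,
        thresholds=thresholds,
        metric_label=D.metric_label,
        patient_ids=D.patient_ids,
    )


def split_groups(scores: RedundancyScore) -> np.ndarray:
    """Median split of the counts into 'high'/'low' labels (ties to high)."""
    counts = np.asarray(scores.counts)
    if np.all(counts == counts[0]):
        raise DegeneracyError("all redundancy counts identical; no split possible")
    median = np.median(counts)
    labels = np.where(counts >= median, "high", "low")
    if (labels == "high").all() or (labels == "low").all():
        raise DegeneracyError("median split produced an empty group")
    return labels
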