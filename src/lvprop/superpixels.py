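"""SLIC oversegmentation, per-region descriptors and the 7-class training partition.

Superpixels are the classification unit: an image is oversegmented into
roughly ``M`` compact regions (M = 400 by default), each region is described
by a fixed-length feature vector, and at training time regions are assigned
to 7 classes — class 1 is the left ventricle (myocardium and blood pool
merged, forced by the mask labels), classes 2..7 partition the remaining
regions by k-means appearance clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.measure import regionprops
from skimage.segmentation import slic
from skimage.transform import resize
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "RegionInfo",
    "SuperpixelPartition",
    "RegionFeaturizer",
    "oversegment",
    "extract_features",
    "fit_pca",
    "build_training_classes",
    "PATCH_SIZE",
    "RAW_FEATURE_DIM",
]

PATCH_SIZE = 16
RAW_FEATURE_DIM = PATCH_SIZE * PATCH_SIZE + 3  # patch + (log area, mean, sd)


@dataclass(frozen=True)
class RegionInfo:
    """Geometry of one superpixel: id, pixel count, centroid (row, col), box."""

    region_id: int
    area: int
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]  # (x1, y1, x2, y2) half-open


@dataclass
class SuperpixelPartition:
    """Integer label map over an image plus per-region geometry.

    Labels are contiguous ``0..K-1`` and every pixel belongs to exactly one
    region.
    """

    label_map: np.ndarray
    regions: list[RegionInfo]

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @classmethod
    def from_label_map(cls, label_map: np.ndarray) -> "SuperpixelPartition":
        label_map = np.asarray(label_map)
        ids = np.unique(label_map)
        # relabel to contiguous 0..K-1
        lut = np.zeros(ids.max() + 1, dtype=np.int32)
        lut[ids] = np.arange(ids.size, dtype=np.int32)
        label_map = lut[label_map]
        regions = []
        for rp in regionprops(label_map + 1):
            r1, c1, r2, c2 = rp.bbox
            regions.append(
                RegionInfo(
                    region_id=rp.label - 1,
                    area=int(rp.area),
                    centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                    bbox=(c1, r1, c2, r2),
                )
            )
        regions.sort(key=lambda r: r.region_id)
        return cls(label_map=label_map, regions=regions)

    def region_mask(self, region_id: int) -> np.ndarray:
        return self.label_map == region_id


def oversegment(
    image: np.ndarray, n_segments: int = 400, compactness: float = 0.1
) -> SuperpixelPartition:
    """Oversegment a grayscale image into ~``n_segments`` SLIC superpixels.

    Compactness trades spatial regularity against edge adherence; the
    default 0.1 is tuned for intensities on [0, 1] so that region borders
    snap to the blood-pool and epicardial edges.  Connectivity is enforced,
    so every region is a single connected component.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    if n_segments > image.size:
        raise ValueError("n_segments exceeds the number of pixels")
    labels = slic(
        image,
        n_segments=n_segments,
        compactness=compactness,
        channel_axis=None,
        start_label=0,
        enforce_connectivity=True,
    )
    return SuperpixelPartition.from_label_map(labels)


def extract_features(
    image: np.ndarray, partition: SuperpixelPartition
) -> np.ndarray:
    """Raw descriptor per region: normalized 16x16 patch + (log area, mean, sd).

    The bounding-box crop of each region is resampled to 16x16 and
    standardized to zero mean / unit variance (a constant crop maps to
    zeros); the region's log-area, mean intensity and intensity sd are
    appended.  Rows align with region ids.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != partition.label_map.shape:
        raise ValueError("image and partition shapes differ")
    feats = np.zeros((partition.n_regions, RAW_FEATURE_DIM))
    for r in partition.regions:
        x1, y1, x2, y2 = r.bbox
        crop = image[y1:y2, x1:x2]
        patch = resize(
            crop,
            (PATCH_SIZE, PATCH_SIZE),
            order=1,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        ).ravel()
        sd = patch.std()
        patch = (patch - patch.mean()) / sd if sd > 1e-12 else np.zeros_like(patch)
        vals = image[partition.label_map == r.region_id]
        feats[r.region_id] = np.concatenate(
            [patch, [np.log(r.area), vals.mean(), vals.std()]]
        )
    return feats


class RegionFeaturizer(BaseEstimator, TransformerMixin):
    """Standardize raw region descriptors and compress them by PCA.

    Thin sklearn transformer: ``fit`` standardizes each descriptor column
    (so the three appended photometric/size statistics are not drowned by
    the 256 patch dimensions) and learns the PCA projection on training
    descriptors; ``transform`` applies both to any region's raw descriptor.
    If the requested dimensionality exceeds the data rank the projection is
    reduced with a warning.  Set ``standardize=False`` for plain PCA.
    """

    def __init__(self, n_components: int = 64, standardize: bool = True):
        self.n_components = n_components
        self.standardize = standardize

    def fit(self, X: np.ndarray, y=None) -> "RegionFeaturizer":
        X = np.asarray(X, dtype=float)
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            sd[sd < 1e-9] = 1.0
            self.scale_ = sd
            X = (X - self.mean_) / self.scale_
        limit = min(X.shape[0], X.shape[1])
        k = min(self.n_components, limit)
        if k < self.n_components:
            warnings.warn(
                f"n_components reduced from {self.n_components} to {k} "
                "(data rank limit)",
                stacklevel=2,
            )
        self.pca_ = PCA(n_components=k, svd_solver="full").fit(X)
        self.n_components_ = k
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "pca_")
        X = np.asarray(X, dtype=float)
        if self.standardize:
            X = (X - self.mean_) / self.scale_
        return self.pca_.transform(X)

    @property
    def explained_variance_ratio_(self) -> np.ndarray:
        check_is_fitted(self, "pca_")
        return self.pca_.explained_variance_ratio_


def fit_pca(
    features: np.ndarray, retained_dims: int = 64, standardize: bool = False
) -> RegionFeaturizer:
    """Fit the PCA basis used to compress region descriptors."""
    return RegionFeaturizer(
        n_components=retained_dims, standardize=standardize
    ).fit(features)


def region_overlap_fractions(
    partition: SuperpixelPartition, lv_mask: np.ndarray
) -> np.ndarray:
    """Fraction of each region's pixels lying inside the LV mask."""
    lv_mask = np.asarray(lv_mask, dtype=bool)
    if lv_mask.shape != partition.label_map.shape:
        raise ValueError("mask and partition shapes differ")
    k = partition.n_regions
    inside = np.bincount(partition.label_map[lv_mask].ravel(), minlength=k)
    total = np.bincount(partition.label_map.ravel(), minlength=k)
    return inside / np.maximum(total, 1)


def build_training_classes(
    features: np.ndarray,
    partitions: list[SuperpixelPartition],
    lv_masks: list[np.ndarray],
    overlap_threshold: float = 0.5,
    n_classes: int = 7,
    seed: int = 0,
) -> np.ndarray:
    """Assign every training region to one of ``n_classes`` classes.

    Regions whose pixel overlap with the LV mask reaches
    ``overlap_threshold`` form class 1 — this deliberately merges the
    myocardium and the blood pool into a single labeled type.  All other
    regions are clustered by seeded k-means (10 restarts) into classes
    ``2..n_classes``.  ``features`` rows must be the concatenation of the
    per-image region descriptors, in partition order.
    """
    features = np.asarray(features, dtype=float)
    if len(partitions) != len(lv_masks):
        raise ValueError("need one mask per partition")
    fracs = np.concatenate(
        [region_overlap_fractions(p, m) for p, m in zip(partitions, lv_masks)]
    )
    if fracs.shape[0] != features.shape[0]:
        raise ValueError("feature rows do not match total region count")
    labels = np.zeros(features.shape[0], dtype=int)
    is_lv = fracs >= overlap_threshold
    if not np.any(is_lv):
        raise ValueError("no region overlaps the LV mask; cannot form the LV class")
    labels[is_lv] = 1
    rest = ~is_lv
    km = KMeans(n_clusters=n_classes - 1, n_init=10, random_state=seed)
    labels[rest] = km.fit_predict(features[rest]) + 2
    return labels
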