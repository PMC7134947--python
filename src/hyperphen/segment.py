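"""Pixel classification of plot scenes.

A radiance hypercube is segmented into k (default six) spectral
clusters by K-means, and the clusters are then given semantic names —
sunlit leaf, shaded leaf, soil, reference panel, platform shadow,
non-biological matter — from two simple physical cues: broadband
brightness (the Teflon panel is the brightest thing in the scene,
platform shadow the darkest non-vegetation) and a red-edge NDVI
computed on the cluster centroid (vegetation reflects strongly at
800 nm and absorbs at 670 nm).  Clustering runs on radiance, before
any reflectance conversion, matching the pipeline phase order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .envi import HyperCube, Unit

__all__ = [
    "SemanticClass",
    "PixelClassMap",
    "kmeans_segment",
    "assign_semantics",
    "transfer_semantics",
    "extract_class_spectra",
    "DegenerateClusteringError",
    "LabelingError",
]

logger = logging.getLogger(__name__)

# semantic class names (shared vocabulary with simulate.CLASS_NAMES)
SemanticClass = str
UNASSIGNED: SemanticClass = "unassigned"

# NDVI-on-centroid thresholds: > VEGETATION_NDVI is vegetation;
# non-vegetation below SOIL_NDVI is soil.  Config-exposed because they
# are heuristics, not physical constants.
VEGETATION_NDVI = 0.5
SOIL_NDVI_MAX = 0.3


class DegenerateClusteringError(ValueError):
    """Fewer spectrally distinct pixels than requested clusters."""


class LabelingError(ValueError):
    """Semantic labeling failed (e.g. no vegetation cluster found)."""


@dataclass
class PixelClassMap:
    labels: np.ndarray  # (lines, samples) cluster ids in [0, k)
    k: int
    centroids: np.ndarray  # (k, bands) radiance
    semantic: dict[int, SemanticClass] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.labels.min() < 0 or self.labels.max() >= self.k:
            raise ValueError("labels must lie in [0, k)")

    def clusters_for(self, which: SemanticClass) -> list[int]:
        return [c for c, s in self.semantic.items() if s == which]


def kmeans_segment(
    cube: HyperCube,
    k: int = 6,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
) -> PixelClassMap:
    """Segment per-pixel spectra into k clusters.

    Lloyd's algorithm with k-means++ starts, Euclidean metric, best of
    ``n_init`` restarts by within-cluster sum of squares; deterministic
    under ``seed``.  Semantics are initialized to unassigned.
    """
    if cube.unit is not Unit.RADIANCE:
        raise ValueError("segmentation expects a radiance cube")
    pixels = cube.pixel_matrix()
    distinct: set[bytes] = set()
    for row in pixels:  # early exit once k distinct spectra are seen
        distinct.add(row.tobytes())
        if len(distinct) >= k:
            break
    if len(distinct) < k:
        raise DegenerateClusteringError(
            f"fewer than k={k} spectrally distinct pixels"
        )
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        max_iter=max_iter,
        algorithm="lloyd",
        random_state=seed,
    ).fit(pixels)
    labels = km.labels_.reshape(cube.lines, cube.samples)
    return PixelClassMap(
        labels=labels,
        k=k,
        centroids=km.cluster_centers_,
        semantic={c: UNASSIGNED for c in range(k)},
        seed=seed,
    )


def _nearest_band(wavelengths: np.ndarray, target: float) -> int:
    return int(np.argmin(np.abs(np.asarray(wavelengths) - target)))


def _centroid_ndvi(centroids: np.ndarray, wavelengths: np.ndarray) -> np.ndarray:
    """Red-edge index (R800 - R670)/(R800 + R670) per centroid, using
    the nearest available bands.  The ratio cancels illumination, so it
    works on radiance."""
    i800 = _nearest_band(wavelengths, 800.0)
    i670 = _nearest_band(wavelengths, 670.0)
    r800 = centroids[:, i800]
    r670 = centroids[:, i670]
    denom = r800 + r670
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(denom > 0, (r800 - r670) / denom, 0.0)
    return ndvi


def assign_semantics(
    cmap: PixelClassMap,
    cube: HyperCube,
    vegetation_ndvi: float = VEGETATION_NDVI,
    soil_ndvi_max: float = SOIL_NDVI_MAX,
) -> PixelClassMap:
    """Name the clusters from brightness and centroid NDVI.

    Panel = brightest cluster by mean broadband radiance.  Among the
    rest, NDVI > ``vegetation_ndvi`` marks vegetation; vegetation at or
    above the vegetation-brightness median is sunlit leaf, below it
    shaded leaf.  Non-vegetation is split by brightness: darkest =
    platform shadow, brightest = non-biological, intermediates = soil
    when NDVI < ``soil_ndvi_max``, else non-biological.  Brightness
    ties break toward the lower cluster id.
    """
    brightness = cmap.centroids.mean(axis=1)
    ndvi = _centroid_ndvi(cmap.centroids, cube.wavelengths_nm)
    present = np.unique(cmap.labels)
    semantic: dict[int, SemanticClass] = {
        int(c): UNASSIGNED for c in range(cmap.k)
    }

    # stable order: descending brightness, lower id wins ties
    by_brightness = sorted(present, key=lambda c: (-brightness[c], c))
    panel = int(by_brightness[0])
    semantic[panel] = "panel"

    rest = [int(c) for c in by_brightness if c != panel]
    veg = [c for c in rest if ndvi[c] > vegetation_ndvi]
    nonveg = [c for c in rest if ndvi[c] <= vegetation_ndvi]
    if not veg:
        raise LabelingError("no vegetation cluster found (non-vegetated scene?)")

    veg_median = float(np.median(brightness[veg]))
    for c in veg:
        semantic[c] = "sunlit_leaf" if brightness[c] >= veg_median else "shaded_leaf"

    if nonveg:
        ascending = sorted(nonveg, key=lambda c: (brightness[c], c))
        semantic[ascending[0]] = "platform_shadow"
        if len(ascending) > 1:
            semantic[ascending[-1]] = "non_biological"
        for c in ascending[1:-1]:
            semantic[c] = "soil" if ndvi[c] < soil_ndvi_max else "non_biological"

    cmap.semantic = semantic
    return cmap


def transfer_semantics(
    cmap: PixelClassMap, reference: PixelClassMap
) -> PixelClassMap:
    """Name clusters by majority vote against a co-registered, already
    labeled class map.

    The NDVI cue in :func:`assign_semantics` needs the 670/800 nm
    bands, which only the VNIR camera carries; the NIR camera's
    clusters are instead labeled from the spatial overlap with the
    labeled VNIR map (the cameras image the same plot).
    """
    if cmap.labels.shape != reference.labels.shape:
        raise ValueError("class maps must be co-registered (equal shape)")
    ref_sem = np.array(
        [reference.semantic.get(c, UNASSIGNED) for c in range(reference.k)]
    )
    ref_named = ref_sem[reference.labels]
    semantic: dict[int, SemanticClass] = {}
    for c in range(cmap.k):
        mask = cmap.labels == c
        if not mask.any():
            semantic[c] = UNASSIGNED
            continue
        names, counts = np.unique(ref_named[mask], return_counts=True)
        semantic[c] = str(names[np.argmax(counts)])
    cmap.semantic = semantic
    return cmap


def extract_class_spectra(
    cube: HyperCube, cmap: PixelClassMap, which: SemanticClass
) -> np.ndarray:
    """All per-pixel spectra whose cluster is mapped to ``which``, as an
    (n_pixels, bands) array.  An absent class yields an empty array and
    a logged warning, not an error."""
    clusters = cmap.clusters_for(which)
    if not clusters:
        msg = f"no cluster is mapped to class {which!r}; returning empty set"
        logger.warning(msg)
        warnings.warn(msg)
        return np.empty((0, cube.bands))
    mask = np.isin(cmap.labels, clusters)
    spectra = cube.data[mask]
    logger.info("extracted %d pixels for class %s", spectra.shape[0], which)
    return spectra
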