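"""Phase I: locally adaptive Otsu thresholding on watershed regions.

A global Otsu threshold locates rough objects (mask ``G``); the frame is
then partitioned into one watershed region per object, with region
boundaries equidistant from the nearest objects' boundaries; finally each
region containing a sufficiently large object is re-thresholded with its
own Otsu threshold, recovering dim nuclei a single global threshold misses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .image import as_array
from skimage.measure import label as cc_label

__all__ = [
    "RegionPartition",
    "otsu_threshold",
    "global_binarize",
    "build_watershed_regions",
    "watershed_regions_from_labels",
    "local_threshold",
]

logger = logging.getLogger(__name__)


def connectivity_value(connectivity: str, ndim: int) -> int:
    """Map {'faces','full'} to skimage connectivity ranks (1 or ndim)."""
    if connectivity == "faces":
        return 1
    if connectivity == "full":
        return ndim
    raise ValueError("connectivity must be 'faces' or 'full'")


@dataclass
class RegionPartition:
    """Assignment of every pixel/voxel to exactly one watershed region.

    ``data`` holds region ids >= 1 (full frame coverage); ``region_of_object``
    maps each seed object id to its region id (here the identity map: region
    ids equal the object labels they were grown from).
    """

    data: np.ndarray
    region_of_object: dict[int, int] = field(default_factory=dict)

    @property
    def n_regions(self) -> int:
        return len(self.region_of_object)


def otsu_threshold(values: np.ndarray) -> tuple[float, bool]:
    """Otsu's threshold over a 256-bin histogram of ``values``.

    Returns ``(threshold, degenerate)``.  Pixels strictly below the
    threshold are classified foreground (dark).  A constant input is
    degenerate: the constant itself is returned with the flag set, and
    callers treat the region as all-background.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("otsu_threshold requires a non-empty input")
    if not np.all(np.isfinite(values)):
        raise ValueError("otsu_threshold requires finite values")
    vmin, vmax = values.min(), values.max()
    if vmin == vmax:
        return float(vmin), True
    # threshold_otsu returns the *center* of the last foreground bin; shift
    # to its upper edge so "value < threshold" captures the whole bin.
    center = float(threshold_otsu(values, nbins=256))
    half_width = (vmax - vmin) / 256.0 / 2.0
    return center + half_width, False


def global_binarize(img) -> np.ndarray:
    """Global Otsu binarization: ``G = data < threshold`` (dark foreground)."""
    data = as_array(img)
    t, degenerate = otsu_threshold(data)
    if degenerate:
        logger.warning("global Otsu degenerate (constant image); empty mask")
        return np.zeros(data.shape, dtype=bool)
    return data < t


def watershed_regions_from_labels(labels: np.ndarray) -> RegionPartition:
    """Partition the frame into nearest-object regions around labeled seeds.

    Every pixel is assigned to the object whose boundary is nearest
    (Euclidean distance); region boundaries therefore keep equal distances
    from the neighboring objects.  Distance ties go to the lower object id.
    """
    labels = np.asarray(labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise ValueError("no objects: cannot build watershed regions")
    best_dist = np.full(labels.shape, np.inf)
    region = np.zeros(labels.shape, dtype=np.int32)
    for obj_id in ids:
        # Distance from each pixel to this object (0 inside it); strict
        # comparison means earlier (lower) ids win ties.
        d = ndi.distance_transform_edt(labels != obj_id)
        closer = d < best_dist
        region[closer] = obj_id
        best_dist[closer] = d[closer]
    return RegionPartition(region, {int(i): int(i) for i in ids})


def build_watershed_regions(G: np.ndarray, connectivity: str = "full") -> RegionPartition:
    """Build one watershed region around each connected object of ``G``."""
    G = np.asarray(G, dtype=bool)
    if not G.any():
        raise ValueError("no objects: cannot build watershed regions")
    lab = cc_label(G, connectivity=connectivity_value(connectivity, G.ndim))
    return watershed_regions_from_labels(lab)


def local_threshold(
    img,
    regions: RegionPartition,
    G: np.ndarray,
    omega_min: int,
    connectivity: str = "full",
) -> np.ndarray:
    """Per-region Otsu thresholding producing the phase-I mask ``B``.

    Only regions whose enclosed object of ``G`` exceeds ``0.1 * omega_min``
    pixels (strictly) are processed; this skips thresholding regions around
    negligible specks.  Skipped or degenerate regions contribute no
    foreground.
    """
    data = as_array(img)
    G = np.asarray(G, dtype=bool)
    B = np.zeros(data.shape, dtype=bool)
    size_floor = 0.1 * omega_min
    # Object size per region: G-objects coincide with region seeds, so the
    # G-pixels inside a region are exactly its object.
    region_ids = np.asarray(sorted(regions.region_of_object.values()))
    obj_sizes = ndi.sum_labels(G.astype(np.int64), regions.data, region_ids)
    for rid, obj_size in zip(region_ids, obj_sizes):
        if obj_size <= size_floor:
            continue
        in_region = regions.data == rid
        t, degenerate = otsu_threshold(data[in_region])
        if degenerate:
            logger.info("region %d: degenerate Otsu, no foreground", rid)
            continue
        B |= in_region & (data < t)
    return B
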