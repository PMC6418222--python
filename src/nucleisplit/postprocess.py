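"""Phases III-IV: model-based merging and correction.

Nuclei are modelled by two discriminant features, size and convexity
(solidity): object pixel count divided by the pixel count of its filled
convex hull.  Merging rejoins over-split fragments when the merged object
is *more* convex than its parts on average and stays under a maximum size
of ``10 * omega_min``; correction then re-thresholds each object's local
region (replacing the object if a more convex one is found), removes
objects smaller than ``omega_min``, and keeps the rest.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import Delaunay, QhullError

from .image import as_array
from .regions import connectivity_value, otsu_threshold, watershed_regions_from_labels
from .splitting import _relabel_raster

__all__ = [
    "ObjectModelStats",
    "convexity",
    "adjacency",
    "merge_objects",
    "correct_objects",
]

logger = logging.getLogger(__name__)


@dataclass
class ObjectModelStats:
    """Size, convexity and neighborhood of one labeled object."""

    label: int
    size: int
    convexity: float
    neighbors: set[int] = field(default_factory=set)


def _points_in_hull(hull_points: np.ndarray, query: np.ndarray) -> np.ndarray:
    tri = Delaunay(hull_points)
    return tri.find_simplex(query, tol=1e-9) >= 0


def convexity(mask: np.ndarray) -> float:
    """Solidity: object size over the size of its discretized convex hull.

    The hull is taken over pixel centers and rasterized by counting the
    grid centers inside it (boundary-inclusive), so convex objects score
    1.0 up to discretization.  Degenerate objects whose centers are
    collinear/coplanar fall back to a hull of the pixel-square corners and
    still score <= 1.
    """
    mask = np.asarray(mask, dtype=bool)
    size = int(mask.sum())
    if size == 0:
        raise ValueError("convexity of an empty mask is undefined")
    if size <= mask.ndim:
        return 1.0
    sl = ndi.find_objects(mask.astype(np.int8))[0]
    sub = mask[sl]
    pts = np.argwhere(sub).astype(float)
    grid = np.reshape(np.indices(sub.shape), (sub.ndim, -1)).T.astype(float)
    try:
        inside = _points_in_hull(pts, grid)
    except QhullError:
        # Collinear/coplanar centers: use the corners of the pixel squares.
        offs = np.array(list(itertools.product((-0.5, 0.5), repeat=sub.ndim)))
        corners = (pts[:, None, :] + offs[None, :, :]).reshape(-1, sub.ndim)
        inside = _points_in_hull(corners, grid)
    hull_size = int(inside.sum())
    return size / max(hull_size, size)


def _half_offsets(ndim: int, connectivity: str) -> list[tuple[int, ...]]:
    """Lexicographically-positive neighbor offsets for the connectivity."""
    offs = []
    for off in itertools.product((-1, 0, 1), repeat=ndim):
        if off == (0,) * ndim or off <= (0,) * ndim:
            continue
        if connectivity == "faces" and sum(abs(o) for o in off) != 1:
            continue
        offs.append(off)
    return offs


def adjacency(R: np.ndarray, connectivity: str = "full") -> dict[int, set[int]]:
    """Neighbor map: labels sharing a common border under the connectivity."""
    R = np.asarray(R)
    neigh: dict[int, set[int]] = {int(i): set() for i in np.unique(R) if i > 0}
    for off in _half_offsets(R.ndim, connectivity):
        src = tuple(slice(max(o, 0), R.shape[a] + min(o, 0)) for a, o in enumerate(off))
        dst = tuple(slice(max(-o, 0), R.shape[a] + min(-o, 0)) for a, o in enumerate(off))
        a, b = R[src], R[dst]
        touching = (a > 0) & (b > 0) & (a != b)
        for u, v in set(zip(a[touching].tolist(), b[touching].tolist())):
            neigh[u].add(v)
            neigh[v].add(u)
    return neigh


def _union_convexity(R: np.ndarray, labels: tuple[int, ...]) -> float:
    mask = np.isin(R, labels)
    return convexity(mask)


def _groups(neigh: dict[int, set[int]]) -> list[list[int]]:
    """Connected components of the adjacency graph with >= 2 members."""
    seen: set[int] = set()
    groups = []
    for start in sorted(neigh):
        if start in seen or not neigh[start]:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in neigh[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        if len(comp) >= 2:
            groups.append(sorted(comp))
    return groups


def merge_objects(
    R: np.ndarray,
    omega_min: int,
    connectivity: str = "full",
    max_size: int | None = None,
    merge_log: list | None = None,
) -> np.ndarray:
    """Merge over-split fragments, groups first, then pairs, to a fixpoint.

    A candidate merge is accepted iff (1) the merged object's convexity
    strictly exceeds the average convexity of its parts and (2) the merged
    size stays strictly under ``max_size`` (default ``10 * omega_min``).
    For each connected group of adjacent labels, the whole-group merge is
    tried first; if it fails, adjacent pairs are tried in order of
    decreasing convexity gain.  The pass repeats until no merge is
    accepted, so the operation is idempotent.
    """
    R = np.asarray(R).copy()
    cap = 10 * omega_min if max_size is None else max_size
    while True:
        neigh = adjacency(R, connectivity)
        if not neigh:
            break
        sizes = {lab: int(np.sum(R == lab)) for lab in neigh}
        convs = {lab: convexity(R == lab) for lab in neigh}
        merged_any = False
        consumed: set[int] = set()
        for group in _groups(neigh):
            if any(g in consumed for g in group):
                continue
            group_size = sum(sizes[g] for g in group)
            accepted: tuple[int, ...] | None = None
            if group_size < cap and len(group) > 2:
                c_union = _union_convexity(R, tuple(group))
                c_avg = float(np.mean([convs[g] for g in group]))
                if c_union > c_avg:
                    accepted = tuple(group)
            if accepted is None:
                # Pair merging: adjacent pairs ranked by convexity gain.
                candidates = []
                for u in group:
                    for v in neigh[u]:
                        if v <= u:
                            continue
                        if sizes[u] + sizes[v] >= cap:
                            continue
                        c_union = _union_convexity(R, (u, v))
                        c_avg = (convs[u] + convs[v]) / 2.0
                        if c_union > c_avg:
                            candidates.append((c_union - c_avg, u, v))
                if candidates:
                    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
                    _, u, v = candidates[0]
                    accepted = (u, v)
            if accepted is not None:
                target = min(accepted)
                if merge_log is not None:
                    merge_log.append(
                        {
                            "labels_in": list(accepted),
                            "label_out": target,
                            "sizes": [sizes[g] for g in accepted],
                            "convexities": [convs[g] for g in accepted],
                            "merged_size": sum(sizes[g] for g in accepted),
                            "merged_convexity": _union_convexity(R, accepted),
                        }
                    )
                R[np.isin(R, accepted)] = target
                consumed.update(accepted)
                merged_any = True
        if not merged_any:
            break
    return _relabel_raster(R)


def correct_objects(
    R: np.ndarray,
    img,
    omega_min: int,
    connectivity: str = "full",
) -> np.ndarray:
    """Model-based correction of each object in its own watershed region.

    Local regions are drawn around the current objects exactly as in
    phase I; each object is then (1) replaced by the re-thresholded
    object if that has strictly larger convexity, (2) removed if smaller
    than ``omega_min``, or (3) kept as is.  Output labels are contiguous.
    """
    R = np.asarray(R)
    data = as_array(img)
    out = R.copy()
    labels = [int(i) for i in np.unique(R) if i > 0]
    if labels:
        partition = watershed_regions_from_labels(R)
        conn = connectivity_value(connectivity, R.ndim)
        for lab in labels:
            region = partition.data == lab
            orig = R == lab
            t, degenerate = otsu_threshold(data[region])
            if degenerate:
                continue
            fg = region & (data < t)
            if not fg.any():
                logger.info("label %d: empty re-threshold, keeping original", lab)
                continue
            comps, n = ndi.label(fg, structure=ndi.generate_binary_structure(R.ndim, conn))
            overlap = [i for i in range(1, n + 1) if np.any((comps == i) & orig)]
            if not overlap:
                continue
            best = max(overlap, key=lambda i: np.sum(comps == i))
            new = comps == best
            if convexity(new) > convexity(orig):
                out[orig] = 0
                out[new] = lab
    # Remove small objects (strictly below the minimum nucleus size).
    ids, counts = np.unique(out[out > 0], return_counts=True)
    for lab, size in zip(ids, counts):
        if size < omega_min:
            out[out == lab] = 0
    return _relabel_raster(out)
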