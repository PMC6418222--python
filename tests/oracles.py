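"""Independent brute-force oracles used by the test-suite.

Each function re-derives a quantity by the most direct possible method
(exhaustive search, all-pairs scans, naive tallies), deliberately sharing
no code path with the package implementation.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import MultiPoint, Point


def otsu_bruteforce(values: np.ndarray) -> float:
    """Exhaustive 256-bin Otsu: maximize between-class variance over all
    cut-points; returns the upper edge of the last foreground bin (first
    maximum wins ties)."""
    values = np.asarray(values, dtype=float).ravel()
    hist, edges = np.histogram(values, bins=256, range=(values.min(), values.max()))
    best_var, best_cut = -1.0, 0
    total = hist.sum()
    mids = (edges[:-1] + edges[1:]) / 2.0
    for cut in range(1, 256):
        w0 = hist[:cut].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:cut] * mids[:cut]).sum() / w0
        mu1 = (hist[cut:] * mids[cut:]).sum() / w1
        var = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
        if var > best_var + 1e-15:
            best_var, best_cut = var, cut
    return float(edges[best_cut])


def nearest_object_partition(labels: np.ndarray) -> np.ndarray:
    """All-pairs nearest-object assignment; lower object id wins ties."""
    labels = np.asarray(labels)
    ids = [int(i) for i in np.unique(labels) if i > 0]
    coords = {i: np.argwhere(labels == i) for i in ids}
    out = np.zeros(labels.shape, dtype=int)
    for idx in np.ndindex(labels.shape):
        p = np.asarray(idx)
        best_d, best_id = np.inf, 0
        for i in ids:  # ascending id: strict < keeps the lower id on ties
            d = np.sqrt(((coords[i] - p) ** 2).sum(axis=1)).min()
            if d < best_d - 1e-12:
                best_d, best_id = d, i
        out[idx] = best_id
    return out


def distance_map_bruteforce(mask: np.ndarray) -> np.ndarray:
    """All-pairs Euclidean distance to nearest background (frame outside
    the array is background)."""
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1)
    bg = np.argwhere(~padded)
    out = np.zeros(mask.shape, dtype=float)
    for idx in np.argwhere(mask):
        p = idx + 1
        out[tuple(idx)] = np.sqrt(((bg - p) ** 2).sum(axis=1)).min()
    return out


def adjacency_bruteforce(R: np.ndarray, connectivity: str = "full") -> dict[int, set[int]]:
    """All-pairs neighbor scan over every pixel pair."""
    R = np.asarray(R)
    neigh: dict[int, set[int]] = {int(i): set() for i in np.unique(R) if i > 0}
    pix = np.argwhere(R > 0)
    for a in pix:
        for b in pix:
            diff = np.abs(a - b)
            if diff.max() == 0 or diff.max() > 1:
                continue
            if connectivity == "faces" and diff.sum() != 1:
                continue
            la, lb = int(R[tuple(a)]), int(R[tuple(b)])
            if la != lb:
                neigh[la].add(lb)
    return neigh


def convexity_bruteforce_2d(mask: np.ndarray) -> float:
    """2D solidity via GEOS: hull of pixel centers, boundary-inclusive
    rasterization by counting grid centers covered by the hull."""
    mask = np.asarray(mask, dtype=bool)
    pts = np.argwhere(mask)
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull.buffer(1e-9)
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    count = 0
    for y in range(lo[0], hi[0] + 1):
        for x in range(lo[1], hi[1] + 1):
            if hull.covers(Point(y, x)):
                count += 1
    return mask.sum() / max(count, int(mask.sum()))


def convexity_bruteforce_3d(mask: np.ndarray) -> float:
    """3D solidity: a grid center is in the hull iff adding it leaves the
    hull volume unchanged (Qhull volume test)."""
    from scipy.spatial import ConvexHull

    mask = np.asarray(mask, dtype=bool)
    pts = np.argwhere(mask).astype(float)
    base = ConvexHull(pts)
    lo = pts.min(axis=0).astype(int)
    hi = pts.max(axis=0).astype(int)
    count = 0
    for idx in np.ndindex(*(hi - lo + 1)):
        q = np.asarray(idx) + lo
        grown = ConvexHull(np.vstack([pts, q]))
        if grown.volume <= base.volume + 1e-9:
            count += 1
    return mask.sum() / max(count, int(mask.sum()))


def pixel_tally_bruteforce(pred: np.ndarray, truth: np.ndarray) -> dict[str, int]:
    """Per-pixel confusion tally with an explicit Python loop."""
    tp = fp = fn = tn = 0
    for p, t in zip(np.asarray(pred, bool).ravel(), np.asarray(truth, bool).ravel()):
        if p and t:
            tp += 1
        elif p:
            fp += 1
        elif t:
            fn += 1
        else:
            tn += 1
    return {"tp": tp, "fp": fp, "fn": fn, "tn": tn}


def max_matching_bruteforce(pred, truth, radius: float) -> int:
    """Maximum-cardinality matching under the distance constraint, by
    exhaustive branch and bound (small instances only)."""
    pred = [np.asarray(p, float) for p in pred]
    truth = [np.asarray(t, float) for t in truth]
    pairs = [
        (i, j)
        for i in range(len(pred))
        for j in range(len(truth))
        if np.linalg.norm(pred[i] - truth[j]) < radius
    ]
    best = 0

    def rec(k: int, used_p: frozenset, used_t: frozenset, cur: int) -> None:
        nonlocal best
        if cur + (len(pairs) - k) <= best:
            return
        if k == len(pairs):
            best = max(best, cur)
            return
        i, j = pairs[k]
        if i not in used_p and j not in used_t:
            rec(k + 1, used_p | {i}, used_t | {j}, cur + 1)
        rec(k + 1, used_p, used_t, cur)

    rec(0, frozenset(), frozenset(), 0)
    return best
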