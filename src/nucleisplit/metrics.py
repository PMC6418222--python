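"""Segmentation scoring: pixel-wise and centroid-based metrics.

Pixel mode counts a per-pixel confusion matrix between the predicted and
ground-truth foregrounds and reports

    p = tp/(tp+fp),  r = tp/(tp+fn),  f1 = 2tp/(2tp+fp+fn),
    a = (tp+tn)/total,  j = tp/(tp+fp+fn)          (Jaccard, |A∩G|/|A∪G|).

Centroid mode matches predicted to ground-truth centroids: a pair closer
than the matching radius (default 10 pixels, strict) is a true positive
and both centroids are excluded from further comparison; leftover
predictions are false positives and leftover truths false negatives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial.distance import cdist

__all__ = [
    "MetricsReport",
    "pixel_metrics",
    "match_centroids",
    "centroids_from_labels",
]


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    return (num / den, False) if den else (0.0, True)


@dataclass
class MetricsReport:
    """Confusion counts and derived scores for one comparison."""

    mode: str
    tp: int
    fp: int
    fn: int
    tn: int | None = None
    p: float = 0.0
    r: float = 0.0
    f1: float = 0.0
    a: float | None = None
    j: float | None = None
    degenerate: bool = False

    @classmethod
    def from_counts(cls, mode: str, tp: int, fp: int, fn: int, tn: int | None = None):
        p, d1 = _safe_div(tp, tp + fp)
        r, d2 = _safe_div(tp, tp + fn)
        f1, d3 = _safe_div(2 * tp, 2 * tp + fp + fn)
        rep = cls(mode=mode, tp=tp, fp=fp, fn=fn, tn=tn, p=p, r=r, f1=f1,
                  degenerate=d1 or d2 or d3)
        if mode == "pixel":
            assert tn is not None
            rep.a, da = _safe_div(tp + tn, tp + tn + fp + fn)
            rep.j, dj = _safe_div(tp, tp + fp + fn)
            rep.degenerate = rep.degenerate or da or dj
        return rep

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.mode == "centroid":
            for k in ("tn", "a", "j"):
                d.pop(k, None)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def pixel_metrics(pred_mask: np.ndarray, truth_mask: np.ndarray) -> MetricsReport:
    """Pixel-wise confusion between two same-shape boolean foregrounds."""
    pred = np.asarray(pred_mask, dtype=bool)
    truth = np.asarray(truth_mask, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    return MetricsReport.from_counts("pixel", tp, fp, fn, tn)


def match_centroids(
    pred_centroids: np.ndarray,
    truth_centroids: np.ndarray,
    radius: float = 10.0,
    spacing: tuple[float, ...] | None = None,
) -> MetricsReport:
    """Greedy nearest-pair-first centroid matching within ``radius``.

    Candidate pairs with Euclidean distance strictly below ``radius`` are
    matched in order of increasing distance; each match removes both
    centroids from further comparison.  ``spacing`` optionally weights the
    axes for anisotropic data (distances are then in physical units).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    pred = np.atleast_2d(np.asarray(pred_centroids, dtype=float))
    truth = np.atleast_2d(np.asarray(truth_centroids, dtype=float))
    n_pred = 0 if pred.size == 0 else pred.shape[0]
    n_truth = 0 if truth.size == 0 else truth.shape[0]
    tp = 0
    if n_pred and n_truth:
        if spacing is not None:
            w = np.asarray(spacing, dtype=float)
            dists = cdist(pred * w, truth * w)
        else:
            dists = cdist(pred, truth)
        ii, jj = np.nonzero(dists < radius)
        order = np.lexsort((jj, ii, dists[ii, jj]))
        used_p: set[int] = set()
        used_t: set[int] = set()
        for k in order:
            i, j = int(ii[k]), int(jj[k])
            if i in used_p or j in used_t:
                continue
            used_p.add(i)
            used_t.add(j)
            tp += 1
    return MetricsReport.from_counts("centroid", tp, n_pred - tp, n_truth - tp)


def centroids_from_labels(labels: np.ndarray) -> np.ndarray:
    """Per-label arithmetic mean of pixel coordinates, ordered by label id."""
    labels = np.asarray(labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return np.zeros((0, labels.ndim))
    return np.asarray(ndi.center_of_mass(np.ones_like(labels), labels, ids), dtype=float)
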