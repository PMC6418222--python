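"""Synthetic clustered-nuclei images with exact ground truth.

Emulates the intensity structure the segmentation pipeline exploits:
elliptical nuclei that are darker at the centroid and lighter near the
rim, a smooth heterogeneous background illumination field, additive
Gaussian noise, and a controllable fraction of nuclei placed in touching
clumps (adjacent nuclei share boundaries with at most ~2 px of overlap,
resolved by nearest-center ownership).  Works in 2D and 3D and exports
ground-truth labels and centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image import IntensityImage
from .metrics import centroids_from_labels

__all__ = ["SyntheticSpec", "generate", "clustered_fixture"]

_MAX_ATTEMPTS = 10_000


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic image.

    Defaults describe a moderately crowded 2D field of view: a 256x256
    frame with 40 nuclei of 8-13 px radius, half of them in touching
    clumps, nuclei ramping from 0.2 at the centroid to 0.5 at the rim on
    a 0.85 background with a gentle illumination gradient and sigma=0.03
    Gaussian noise (dark-foreground convention: center < rim < background).
    """

    shape: tuple[int, ...] = (256, 256)
    n_nuclei: int = 40
    radius_range: tuple[float, float] = (8.0, 13.0)
    eccentricity_range: tuple[float, float] = (0.7, 1.0)
    cluster_fraction: float = 0.5
    center_darkness: float = 0.2
    rim_darkness: float = 0.5
    background_level: float = 0.85
    illumination_gradient: float = 0.06
    noise_sigma: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.center_darkness < self.rim_darkness < self.background_level):
            raise ValueError("require center_darkness < rim_darkness < background_level")
        if len(self.shape) not in (2, 3):
            raise ValueError("shape must be 2D or 3D")
        if not 0.0 <= self.cluster_fraction <= 1.0:
            raise ValueError("cluster_fraction must lie in [0, 1]")


@dataclass(eq=False)
class _Nucleus:
    center: np.ndarray          # float, (z,)y,x
    semi_axes: np.ndarray       # per-axis semi-axis lengths
    angle: float                # in-plane rotation (2D only; 0 in 3D)

    def radius_along(self, direction: np.ndarray) -> float:
        """Boundary distance from the center along a unit direction."""
        d = np.asarray(direction, dtype=float)
        if self.center.size == 2 and self.angle:
            c, s = np.cos(self.angle), np.sin(self.angle)
            d = np.array([c * d[0] + s * d[1], -s * d[0] + c * d[1]])
        return 1.0 / np.sqrt(np.sum((d / self.semi_axes) ** 2))

    @property
    def max_axis(self) -> float:
        return float(self.semi_axes.max())


def _fits(center: np.ndarray, axes: np.ndarray, shape: tuple[int, ...]) -> bool:
    lo = center - axes
    hi = center + axes
    return bool(np.all(lo >= 1.0) and np.all(hi <= np.asarray(shape) - 2.0))


def _draw_nucleus(rng: np.random.Generator, spec: SyntheticSpec, center: np.ndarray) -> _Nucleus:
    ndim = len(spec.shape)
    r = rng.uniform(*spec.radius_range)
    ecc = rng.uniform(*spec.eccentricity_range)
    if ndim == 2:
        axes = np.array([r * ecc, r])
        angle = rng.uniform(0.0, np.pi)
    else:
        # Anisotropic stacks are shallow in z: clip the z semi-axis to fit.
        z_cap = max((spec.shape[0] - 3) / 2.0, 1.0)
        axes = np.array([min(r * ecc, z_cap), r * ecc, r])
        angle = 0.0
    # Shrink to fit the frame if the draw landed close to a border.
    for ax in range(ndim):
        room = min(center[ax] - 1.0, spec.shape[ax] - 2.0 - center[ax])
        axes[ax] = min(axes[ax], max(room, 1.0))
    return _Nucleus(center, axes, angle)


def _random_center(rng: np.random.Generator, spec: SyntheticSpec, margin: float) -> np.ndarray:
    # Shallow axes (e.g. thin z-stacks) cap the margin at their midpoint.
    return np.array(
        [rng.uniform(min(margin, (s - 2) / 2.0), max(s - 1 - margin, s / 2.0)) for s in spec.shape],
        dtype=float,
    )


def _pair_clearance(a: _Nucleus, b: _Nucleus) -> float:
    """Signed boundary gap along the center line (negative = overlap)."""
    delta = b.center - a.center
    dist = float(np.linalg.norm(delta))
    if dist == 0.0:
        return -(a.max_axis + b.max_axis)
    u = delta / dist
    return dist - a.radius_along(u) - b.radius_along(-u)


def _separated(candidate: _Nucleus, others: list[_Nucleus], gap: float) -> bool:
    return all(_pair_clearance(candidate, other) >= gap for other in others)


def _place_nuclei(rng: np.random.Generator, spec: SyntheticSpec) -> list[_Nucleus]:
    n = spec.n_nuclei
    n_clustered = int(round(spec.cluster_fraction * n))
    nuclei: list[_Nucleus] = []
    clumps: list[list[_Nucleus]] = []
    attempts = 0

    def try_place(check_against: list[_Nucleus], center: np.ndarray) -> _Nucleus | None:
        nuc = _draw_nucleus(rng, spec, center)
        if _fits(nuc.center, nuc.semi_axes, spec.shape) and _separated(nuc, check_against, 3.0):
            return nuc
        return None

    # Touching clumps of 2-5 members.
    remaining = n_clustered
    while remaining > 0:
        size = int(min(remaining, rng.integers(2, 6)))
        clump: list[_Nucleus] = []
        member_tries = 0
        while len(clump) < size:
            attempts += 1
            member_tries += 1
            if attempts > _MAX_ATTEMPTS:
                raise RuntimeError(
                    f"could not place requested nuclei (placed {len(nuclei)} of {n})"
                )
            if member_tries > 200 and len(clump) >= 2:
                break  # geometry too tight here; close the clump early
            others = [x for x in nuclei if x not in clump]
            if not clump:
                center = _random_center(rng, spec, margin=spec.radius_range[1] + 2)
                nuc = try_place(others, center)
            else:
                anchor = clump[rng.integers(len(clump))]
                direction = rng.normal(size=len(spec.shape))
                if len(spec.shape) == 3:
                    # Thin stacks: clumps grow mostly laterally.
                    direction[0] *= spec.shape[0] / max(spec.shape)
                direction /= np.linalg.norm(direction)
                probe = _draw_nucleus(rng, spec, anchor.center)  # sample shape only
                overlap = rng.uniform(0.5, 2.0)
                dist = anchor.radius_along(direction) + probe.radius_along(-direction) - overlap
                center = anchor.center + direction * dist
                nuc = _draw_nucleus(rng, spec, center)
                nuc.semi_axes = probe.semi_axes.copy()
                nuc.angle = probe.angle
                ok = (
                    _fits(center, nuc.semi_axes, spec.shape)
                    and _separated(nuc, others, 3.0)
                    # Touching is wanted inside the clump, but overlap with
                    # any member stays within ~2 px.
                    and all(_pair_clearance(nuc, m) >= -2.0 for m in clump)
                )
                if not ok:
                    nuc = None
            if nuc is not None:
                clump.append(nuc)
                nuclei.append(nuc)
                member_tries = 0
        clumps.append(clump)
        remaining -= len(clump)

    # Isolated nuclei: clear background gap to everything already placed.
    while len(nuclei) < n:
        attempts += 1
        if attempts > _MAX_ATTEMPTS:
            raise RuntimeError(
                f"could not place requested nuclei (placed {len(nuclei)} of {n})"
            )
        center = _random_center(rng, spec, margin=spec.radius_range[1] + 2)
        nuc = try_place(nuclei, center)
        if nuc is not None:
            nuclei.append(nuc)
    return nuclei


def _rasterize(
    nuclei: list[_Nucleus], shape: tuple[int, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Truth labels (nearest-center ownership) and owner's normalized radius."""
    labels = np.zeros(shape, dtype=np.int32)
    rho_owner = np.zeros(shape, dtype=float)
    best_center_dist = np.full(shape, np.inf)
    for idx, nuc in enumerate(nuclei, start=1):
        lo = np.maximum(np.floor(nuc.center - nuc.semi_axes - 1).astype(int), 0)
        hi = np.minimum(np.ceil(nuc.center + nuc.semi_axes + 2).astype(int), shape)
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        coords = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij")
        delta = [c - ctr for c, ctr in zip(coords, nuc.center)]
        if len(shape) == 2 and nuc.angle:
            c, s = np.cos(nuc.angle), np.sin(nuc.angle)
            delta = [c * delta[0] + s * delta[1], -s * delta[0] + c * delta[1]]
        rho = np.sqrt(sum((d / a) ** 2 for d, a in zip(delta, nuc.semi_axes)))
        inside = rho <= 1.0
        cdist = np.sqrt(sum((c - ctr) ** 2 for c, ctr in zip(coords, nuc.center)))
        take = inside & (cdist < best_center_dist[sl])
        labels[sl][take] = idx
        rho_owner[sl][take] = rho[take]
        bview = best_center_dist[sl]
        bview[take] = cdist[take]
    return labels, rho_owner


def _illumination(rng: np.random.Generator, shape: tuple[int, ...], amplitude: float) -> np.ndarray:
    """Smooth low-order polynomial field in [-amplitude/2, amplitude/2]."""
    if amplitude == 0:
        return np.zeros(shape)
    coords = np.meshgrid(
        *[np.linspace(-1.0, 1.0, s) for s in shape], indexing="ij"
    )
    coeffs = rng.uniform(-1.0, 1.0, size=(len(shape), 2))
    fieldv = sum(c[0] * x + c[1] * x**2 for c, x in zip(coeffs, coords))
    fieldv = np.asarray(fieldv, dtype=float)
    span = fieldv.max() - fieldv.min()
    if span == 0:
        return np.zeros(shape)
    return (fieldv - fieldv.min()) / span * amplitude - amplitude / 2.0


def generate(spec: SyntheticSpec) -> tuple[IntensityImage, np.ndarray, np.ndarray]:
    """Generate one image; returns (image, truth labels, truth centroids).

    Reproducible per seed; centroids are the label-wise coordinate means
    of the truth labels (axis order (z,)y,x).
    """
    rng = np.random.default_rng(spec.seed)
    nuclei = _place_nuclei(rng, spec)
    labels, rho = _rasterize(nuclei, spec.shape)
    img = np.full(spec.shape, spec.background_level)
    img += _illumination(rng, spec.shape, spec.illumination_gradient)
    fg = labels > 0
    ramp = spec.center_darkness + (spec.rim_darkness - spec.center_darkness) * rho
    img[fg] = ramp[fg]
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    img = np.clip(img, 0.0, 1.0)
    centroids = centroids_from_labels(labels)
    return IntensityImage(img), labels, centroids


# ---------------------------------------------------------------------------
# Deterministic named fixtures used across the test-suite.

def _disk_mask(shape: tuple[int, int], center: tuple[float, float], r: float) -> np.ndarray:
    yy, xx = np.indices(shape)
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= r**2


def clustered_fixture(kind: str) -> dict:
    """Named deterministic fixtures mirroring the tricky clustering cases.

    Kinds: ``small_holes`` (mask with punched 1-px holes and one large
    hole), ``dumbbell`` (two-lobed mask joined by a neck), ``
    intensity_valley_clump`` (five touching nuclei with zero background
    gap, separable only through their intensity valleys), and
    ``dim_nucleus_pair`` (a dark and a dim nucleus in separate watershed
    regions; the dim one is missed by the global threshold).
    """
    if kind == "small_holes":
        mask = _disk_mask((48, 48), (24.0, 24.0), 14.0)
        holes_small = [(24, 24), (20, 18)]
        for y, x in holes_small:
            mask[y, x] = False
        mask[28:31, 26:29] = False  # 9-px hole: above the mean, kept
        return {"mask": mask, "small_holes": holes_small, "big_hole_size": 9}

    if kind == "dumbbell":
        mask = np.zeros((11, 21), dtype=bool)
        mask |= _disk_mask((11, 21), (5.0, 5.0), 4.5)
        mask |= _disk_mask((11, 21), (5.0, 15.0), 4.5)
        mask[4:7, 5:16] = True  # neck
        return {"mask": mask, "n_lobes": 2, "lobe_centers": [(5.0, 5.0), (5.0, 15.0)]}

    if kind == "intensity_valley_clump":
        shape = (40, 77)
        centers = [(20.0, 14.0 + 12.0 * k) for k in range(5)]
        r = 10.0
        yy, xx = np.indices(shape)
        best = np.full(shape, np.inf)
        labels = np.zeros(shape, dtype=np.int32)
        rho_owner = np.zeros(shape)
        for idx, (cy, cx) in enumerate(centers, start=1):
            d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
            take = (d <= r) & (d < best)
            labels[take] = idx
            rho_owner[take] = d[take] / r
            best[take] = d[take]
        img = np.full(shape, 0.85)
        fg = labels > 0
        img[fg] = 0.2 + 0.3 * rho_owner[fg]
        return {
            "image": IntensityImage(img),
            "mask": fg,
            "truth": labels,
            "n_true": 5,
            "centroids": centroids_from_labels(labels),
        }

    if kind == "dim_nucleus_pair":
        shape = (72, 72)
        img = np.full(shape, 0.8)
        dark = _disk_mask(shape, (20.0, 20.0), 13.0)
        img[dark] = 0.2
        dim = _disk_mask(shape, (54.0, 54.0), 8.0)
        img[dim] = 0.6
        img[53:56, 53:56] = 0.25  # dark core keeps a seed object in G
        return {
            "image": IntensityImage(img),
            "dark_mask": dark,
            "dim_mask": dim,
            "n_true": 2,
        }

    raise ValueError(f"unknown fixture kind {kind!r}")
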