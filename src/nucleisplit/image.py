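"""Image, label and centroid I/O with polarity normalization.

All arrays use 0-based indices with axis order ``(z,) y, x``.  Intensity
images are scaled to ``[0, 1]`` on load and follow the dark-foreground
convention: after :func:`normalize_polarity` nuclei have *lower* values
than the background.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from skimage.util import img_as_float

__all__ = [
    "IntensityImage",
    "load_image",
    "normalize_polarity",
    "write_labels",
    "read_labels",
    "write_centroids",
    "read_centroids",
]

_CHANNELS = ("gray", "red", "green", "blue")


def as_array(img) -> np.ndarray:
    """Coerce an IntensityImage or bare array to a float ndarray."""
    if isinstance(img, IntensityImage):
        return img.data
    return np.asarray(img, dtype=float)


@dataclass
class IntensityImage:
    """A 2D ``[y, x]`` or 3D ``[z, y, x]`` grayscale image in ``[0, 1]``.

    Parameters
    ----------
    data:
        Float array of intensities in ``[0, 1]``.
    spacing:
        Optional physical size per axis (micrometres), same axis order as
        ``data``.
    source_channel:
        Which channel of the source file ``data`` came from.
    """

    data: np.ndarray
    spacing: tuple[float, ...] | None = None
    source_channel: str = "gray"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"image must be 2D or 3D, got {self.data.ndim}D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image contains non-finite values")
        if self.data.size and (self.data.min() < 0 or self.data.max() > 1):
            raise ValueError("image values must lie in [0, 1]")
        if self.source_channel not in _CHANNELS:
            raise ValueError(f"unknown channel {self.source_channel!r}")

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


def _extract_channel(arr: np.ndarray, channel: str) -> np.ndarray:
    """Reduce a possibly-RGB(A) array to one grayscale plane."""
    has_color = arr.ndim >= 3 and arr.shape[-1] in (3, 4)
    if channel == "gray":
        if has_color:
            # Rec. 601 luma, the standard gray conversion.
            rgb = img_as_float(arr[..., :3])
            return rgb @ np.array([0.299, 0.587, 0.114])
        return img_as_float(arr)
    if not has_color:
        raise ValueError(
            f"channel {channel!r} requested but image has no color channels"
        )
    idx = {"red": 0, "green": 1, "blue": 2}[channel]
    return img_as_float(arr[..., idx])


def load_image(
    path: str | os.PathLike,
    channel: str = "gray",
    spacing: tuple[float, ...] | None = None,
) -> IntensityImage:
    """Load a PNG or (multi-page) TIFF as a float image in ``[0, 1]``.

    Multi-page TIFFs become 3D stacks with shape ``(pages, y, x)``.  Integer
    inputs are rescaled by their dtype range (e.g. uint8 values divide by
    255), so an 8-bit value of 128 maps to 128/255.
    """
    if channel not in _CHANNELS:
        raise ValueError(f"channel must be one of {_CHANNELS}, got {channel!r}")
    path = os.fspath(path)
    try:
        if path.lower().endswith((".tif", ".tiff")):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read image file {path!r}: {exc}") from exc
    data = _extract_channel(np.asarray(arr), channel)
    data = np.clip(data, 0.0, 1.0)
    return IntensityImage(data, spacing=spacing, source_channel=channel)


def normalize_polarity(img: IntensityImage, foreground_polarity: str) -> IntensityImage:
    """Ensure nuclei are darker than background.

    ``foreground_polarity`` describes the *input*: ``"dark"`` leaves the
    image unchanged, ``"bright"`` complements it (``1 - data``).  Applying
    ``"bright"`` twice returns the original image.
    """
    if foreground_polarity == "dark":
        return img
    if foreground_polarity == "bright":
        return IntensityImage(
            1.0 - img.data, spacing=img.spacing, source_channel=img.source_channel
        )
    raise ValueError("foreground_polarity must be 'dark' or 'bright'")


def write_labels(labels: np.ndarray, path: str | os.PathLike) -> None:
    """Save a label image as an integer TIFF (16- or 32-bit, whichever fits)."""
    labels = np.asarray(labels)
    if labels.size and labels.max() > np.iinfo(np.uint32).max:
        raise ValueError("label ids exceed 32-bit range")
    dtype = np.uint16 if (labels.size == 0 or labels.max() <= np.iinfo(np.uint16).max) else np.uint32
    tifffile.imwrite(os.fspath(path), labels.astype(dtype))


def read_labels(path: str | os.PathLike) -> np.ndarray:
    """Load a label TIFF back as an integer array."""
    return np.asarray(tifffile.imread(os.fspath(path)), dtype=np.int64)


def write_centroids(centroids: np.ndarray, path: str | os.PathLike, ndim: int | None = None) -> None:
    """Save centroids as CSV with header ``z,y,x`` (3D) or ``y,x`` (2D)."""
    pts = np.asarray(centroids, dtype=float)
    if pts.size == 0:
        if ndim is None:
            raise ValueError("ndim required to write an empty centroid set")
        pts = pts.reshape(0, ndim)
    cols = ["z", "y", "x"][-pts.shape[1]:]
    pd.DataFrame(pts, columns=cols).to_csv(os.fspath(path), index=False)


def read_centroids(path: str | os.PathLike) -> np.ndarray:
    """Load a centroid CSV written by :func:`write_centroids`."""
    df = pd.read_csv(os.fspath(path))
    return df.to_numpy(dtype=float)
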