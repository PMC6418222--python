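"""Four-phase segmentation pipeline.

Phase I: locally adaptive thresholding on watershed regions.
Phase II: splitting clustered nuclei (saliency watershed).
Phase III: model-based merging of over-split fragments.
Phase IV: model-based correction (replace / remove / keep).

Phases form a strict prefix chain: later phases require the earlier
ones.  The single scientifically meaningful parameter is ``omega_min``,
the minimum nucleus size in pixels (2D) or voxels (3D).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label

from . import postprocess, regions, splitting
from .image import as_array
from .regions import connectivity_value

__all__ = ["SegmentationParams", "run_pipeline", "PHASES"]

logger = logging.getLogger(__name__)

PHASES = ("I", "II", "III", "IV")


@dataclass
class SegmentationParams:
    """User-facing parameters of the pipeline.

    ``omega_min`` is the minimum object size; ``connectivity`` chooses
    face-only or full (8/26) neighborhoods; ``phases`` must be a prefix of
    (I, II, III, IV); ``max_merge_size`` defaults to ``10 * omega_min``.
    """

    omega_min: int = 50
    connectivity: str = "full"
    phases: tuple[str, ...] = PHASES
    use_intensity: bool = True
    max_merge_size: int | None = None
    seed: int | None = None  # reserved; no randomized tie-breaking is used

    def __post_init__(self) -> None:
        if self.omega_min < 1:
            raise ValueError("omega_min must be >= 1")
        self.phases = tuple(self.phases)
        if self.phases != PHASES[: len(self.phases)] or not self.phases:
            raise ValueError(f"phases must be a non-empty prefix of {PHASES}")
        connectivity_value(self.connectivity, 2)  # validates the name


def run_pipeline(
    img,
    params: SegmentationParams,
    return_intermediates: bool = False,
):
    """Run the enabled phases in order and return the final label image.

    ``img`` must already be polarity-normalized (nuclei darker than
    background).  With ``return_intermediates=True`` a dict is returned
    instead, mapping each enabled phase name to the label image after that
    phase (plus ``"G"``, ``"B"`` and the merge log) — ablation studies can
    thereby reuse a single run.  An empty foreground after phase I yields
    all-zero labels with a warning.
    """
    data = as_array(img)
    conn = params.connectivity
    out: dict[str, object] = {}

    # Phase I: global Otsu, watershed regions, per-region local Otsu.
    G = regions.global_binarize(data)
    out["G"] = G
    if not G.any():
        logger.warning("empty foreground after global thresholding")
        zeros = np.zeros(data.shape, dtype=np.int32)
        for ph in params.phases:
            out[ph] = zeros
        return out if return_intermediates else zeros
    partition = regions.build_watershed_regions(G, conn)
    B = regions.local_threshold(data, partition, G, params.omega_min, conn)
    out["B"] = B
    labels = splitting._relabel_raster(
        cc_label(B, connectivity=connectivity_value(conn, B.ndim))
    )
    out["I"] = labels
    logger.info("phase I: %d objects", int(labels.max()))
    if not B.any():
        logger.warning("empty foreground after local thresholding")

    if "II" in params.phases and B.any():
        labels = splitting.split_clusters(
            data, B, params.omega_min, conn, use_intensity=params.use_intensity
        )
        out["II"] = labels
        logger.info("phase II: %d objects", int(labels.max()))

        if "III" in params.phases:
            merge_log: list = []
            labels = postprocess.merge_objects(
                labels, params.omega_min, conn,
                max_size=params.max_merge_size, merge_log=merge_log,
            )
            out["III"] = labels
            out["merge_log"] = merge_log
            logger.info("phase III: %d objects (%d merges)", int(labels.max()), len(merge_log))

            if "IV" in params.phases:
                labels = postprocess.correct_objects(labels, data, params.omega_min, conn)
                out["IV"] = labels
                logger.info("phase IV: %d objects", int(labels.max()))
    else:
        for ph in params.phases[1:]:
            out[ph] = labels
    return out if return_intermediates else labels
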