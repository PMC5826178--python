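"""End-to-end counting pipeline wiring the stage modules together.

Stages: graying -> illumination correction + histogram equalization ->
Otsu threshold + Canny edges -> membrane fusion -> small-component removal
and morphological cleanup -> (optional scripted edits) -> inversion + hole
filling -> (optional watershed re-segmentation) -> connected-domain
labeling, minimum-area filtering and per-cell statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import cell_counting, membrane_segmentation, preprocessing, resegmentation
from .cell_counting import CellRecord, EditOp
from .config import default_config
from .preprocessing import GaussianSpec
from .resegmentation import MorphoParams, WatershedFilterParams

__all__ = ["PipelineResult", "count_cells"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Final labels and statistics plus the intermediate images."""

    labels: np.ndarray
    records: list[CellRecord]
    n_cells: int
    membrane: np.ndarray
    interior: np.ndarray
    intermediates: dict[str, np.ndarray] = field(default_factory=dict)


def count_cells(
    image: np.ndarray,
    config: dict | None = None,
    edits: Sequence[EditOp] | None = None,
    keep_intermediates: bool = False,
) -> PipelineResult:
    """Run the full counting pipeline on an RGB (or grayscale) image.

    ``config`` is a validated config dict (see :mod:`adipocount.config`);
    missing -> all defaults.  ``edits`` are scripted manual corrections
    applied to the cleaned membrane mask before the final count.
    """
    cfg = config or default_config()
    pp, seg, rs, cnt = cfg["preprocessing"], cfg["segmentation"], cfg["reseg"], cfg["count"]

    image = np.asarray(image)
    gray = preprocessing.to_gray(image) if image.ndim == 3 else image.astype(np.uint8)

    if pp["illumination_correction"]:
        corrected = preprocessing.illumination_correct(
            gray,
            g1=GaussianSpec(pp["g1_sigma"], pp["g1_size"]),
            g2=GaussianSpec(pp["g2_sigma"], pp["g2_size"]),
        )
    else:
        # without DoG correction the membrane is dark; invert so that the
        # thresholding branch still sees membrane as high intensity
        corrected = (255 - gray).astype(np.uint8)
    equalized = preprocessing.equalize_histogram(gray)

    otsu = membrane_segmentation.otsu_threshold(corrected)
    low = None if seg["canny_low"] == "auto" else float(seg["canny_low"])
    high = None if seg["canny_high"] == "auto" else float(seg["canny_high"])
    edges = membrane_segmentation.canny_edges(
        equalized, low=low, high=high, sigma=seg["canny_sigma"]
    )
    membrane = membrane_segmentation.combine_membrane(otsu.mask, edges)

    membrane = resegmentation.remove_small_components(membrane, rs["area_threshold"])
    membrane = resegmentation.morph_cleanup(
        membrane,
        MorphoParams(
            area_threshold=rs["area_threshold"],
            open_radius=rs["open_radius"],
            close_radius=rs["close_radius"],
            dilate_radius=rs["dilate_radius"],
        ),
    )

    if edits:
        membrane = cell_counting.apply_edits(membrane, edits)

    interior = resegmentation.cell_interior_mask(membrane)

    if rs["enabled"]:
        labels = resegmentation.resegment(
            interior,
            WatershedFilterParams(
                max_length=rs["max_length"], max_area_ratio=rs["max_area_ratio"]
            ),
            h_maxima=rs["h_maxima"],
        )
    else:
        labels, _ = cell_counting.label_components(
            interior, connectivity=cnt["connectivity"]
        )

    labels, n = cell_counting.filter_min_area(labels, cnt["min_cell_area"])
    if cnt["exclude_border"]:
        labels, n = cell_counting.exclude_border_cells(labels)

    records = cell_counting.cell_statistics(labels)
    logger.info("counted %d cells", n)

    result = PipelineResult(
        labels=labels,
        records=records,
        n_cells=n,
        membrane=membrane,
        interior=interior,
    )
    if keep_intermediates:
        result.intermediates = {
            "gray": gray,
            "corrected": corrected,
            "equalized": equalized,
            "otsu_mask": otsu.mask,
            "canny_edges": edges,
        }
    return result
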