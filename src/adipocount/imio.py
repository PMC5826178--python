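"""Image and table I/O: PNG/TIFF/JPEG images, 16-bit label maps, cell CSVs."""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .cell_counting import CellRecord

__all__ = [
    "read_image",
    "write_image",
    "write_label_png",
    "read_label_png",
    "write_cells_csv",
]

CSV_COLUMNS = [
    "id",
    "centroid_row",
    "centroid_col",
    "area_px",
    "diameter_px",
    "bbox_min_row",
    "bbox_min_col",
    "bbox_max_row",
    "bbox_max_col",
]


def read_image(path: str | Path) -> np.ndarray:
    """Load an image as H x W x 3 uint8 RGB (grayscale inputs are expanded)."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_image(path: str | Path, img: np.ndarray) -> None:
    Image.fromarray(np.asarray(img)).save(path)


def write_label_png(path: str | Path, labels: np.ndarray) -> None:
    """Write a label map as a 16-bit grayscale PNG."""
    labels = np.asarray(labels)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("label map exceeds 16-bit range")
    Image.fromarray(labels.astype(np.uint16)).save(path)


def read_label_png(path: str | Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im).astype(np.int32)


def write_cells_csv(
    path: str | Path,
    records: Sequence[CellRecord],
    microns_per_pixel: float | None = None,
) -> None:
    """One row per cell, fixed column order, UTF-8 with header.

    When a physical calibration is provided it is passed through as an
    extra ``microns_per_pixel`` column on every row.
    """
    columns = list(CSV_COLUMNS)
    if microns_per_pixel is not None:
        columns.append("microns_per_pixel")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for rec in records:
            row = [
                rec.id,
                f"{rec.centroid[0]:.3f}",
                f"{rec.centroid[1]:.3f}",
                rec.area,
                f"{rec.diameter:.3f}",
                *rec.bbox,
            ]
            if microns_per_pixel is not None:
                row.append(microns_per_pixel)
            writer.writerow(row)
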