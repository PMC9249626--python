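"""TMA spot detection and cropping from a stitched slide raster.

Tissue cores are darker than the illuminated slide background, so foreground
comes from a global Otsu threshold on luminance followed by morphological
closing; connected regions of sufficient equivalent diameter become spots,
ordered row-major by centroid with grid-style ids r{i}c{j}. Touching or
merged cores are not split (no grid-model dearraying). Coordinates are
0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from ._histogram import DegenerateHistogramError, otsu_threshold
from ._morph import disk_footprint


@dataclass(frozen=True)
class SpotBox:
    spot_id: str
    row_min: int
    row_max: int
    col_min: int
    col_max: int
    source_slide: str = ""

    def __post_init__(self):
        if not (self.row_min < self.row_max and self.col_min < self.col_max):
            raise ValueError("degenerate spot box")


def detect_spots(
    slide: np.ndarray,
    min_spot_diameter: float,
    padding: int = 0,
    source_slide: str = "",
) -> list[SpotBox]:
    """One padded, clipped box per tissue region of sufficient size."""
    slide = np.asarray(slide)
    if slide.ndim != 3 or slide.shape[2] != 3:
        raise ValueError("slide must be an RGB raster (rows, cols, 3)")
    gray = slide.mean(axis=2)
    try:
        thr = otsu_threshold(gray)
    except DegenerateHistogramError:
        return []  # uniform slide: no tissue
    fg = gray < thr  # tissue darker than background
    close_r = max(1, int(round(min_spot_diameter / 10)))
    fg = ndimage.binary_closing(fg, structure=disk_footprint(close_r))
    labels, n = ndimage.label(fg)
    if n == 0:
        return []
    rows, cols = gray.shape
    regions = []
    for lab in range(1, n + 1):
        ys, xs = np.nonzero(labels == lab)
        area = ys.size
        if 2.0 * np.sqrt(area / np.pi) < min_spot_diameter:
            continue
        box = (
            max(int(ys.min()) - padding, 0),
            min(int(ys.max()) + 1 + padding, rows),
            max(int(xs.min()) - padding, 0),
            min(int(xs.max()) + 1 + padding, cols),
        )
        regions.append((float(ys.mean()), float(xs.mean()), box))
    if not regions:
        return []
    # group centroids into rows, then order columns within each row
    regions.sort(key=lambda r: r[0])
    row_tol = min_spot_diameter / 2.0
    grouped: list[list] = []
    for reg in regions:
        if grouped and abs(reg[0] - np.mean([g[0] for g in grouped[-1]])) <= row_tol:
            grouped[-1].append(reg)
        else:
            grouped.append([reg])
    boxes = []
    for i, row_regs in enumerate(grouped):
        row_regs.sort(key=lambda r: r[1])
        for j, (_, _, box) in enumerate(row_regs):
            boxes.append(
                SpotBox(
                    spot_id=f"r{i}c{j}",
                    row_min=box[0],
                    row_max=box[1],
                    col_min=box[2],
                    col_max=box[3],
                    source_slide=source_slide,
                )
            )
    return boxes


def crop(slide: np.ndarray, boxes: list[SpotBox]) -> list[tuple[SpotBox, np.ndarray]]:
    """Pixel-exact sub-rasters for each box, paired with the box metadata."""
    out = []
    for b in boxes:
        out.append((b, slide[b.row_min : b.row_max, b.col_min : b.col_max].copy()))
    return out


def boxes_manifest(boxes: list[SpotBox]) -> pd.DataFrame:
    return pd.DataFrame([b.__dict__ for b in boxes])
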