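"""Per-cell marker signal integration and positive-control QC.

Nonspecific staining manifests as saturated regions in the marker channel:
seed pixels within the 5 darkest of 256 display bins of chromogen saturation
(signal intensity >= 1 - 5/256; dark = strong stain on the display
convention) are masked and expanded by a 10 px disk. Marker signal is then
summed over each expanded cell segment, excluding masked pixels from both
the intensity sum and the area so per-cell mean intensity stays unbiased.
Spots are filtered by positive-control (housekeeping gene) expression with a
two-class Otsu split of the spot-level weighted means.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from ._histogram import DegenerateHistogramError, otsu_threshold
from ._morph import disk_footprint

log = logging.getLogger(__name__)

DEFAULT_SEED_THRESHOLD = 1.0 - 5.0 / 256.0
DEFAULT_MASK_RADIUS = 10.0


def mask_nonspecific(
    marker: np.ndarray,
    seed_threshold: float = DEFAULT_SEED_THRESHOLD,
    radius: float = DEFAULT_MASK_RADIUS,
) -> np.ndarray:
    """Exclusion mask of saturated (nonspecific) marker regions."""
    seeds = np.asarray(marker, float) >= seed_threshold
    if radius > 0 and seeds.any():
        return ndimage.binary_dilation(seeds, structure=disk_footprint(radius))
    return seeds


def integrate_cell_signal(
    expanded_labels: np.ndarray,
    marker: np.ndarray,
    exclusion_mask: np.ndarray | None = None,
    cell_classes=None,
    spot_id: str = "",
    patient_id: str = "",
) -> pd.DataFrame:
    """Sum marker signal per expanded cell, excluding masked pixels.

    Returns one row per retained cell: identifiers, class, area (unmasked
    pixel count), intensity (summed signal) and centroid. Fully masked cells
    are dropped with a logged count.
    """
    labels = np.asarray(expanded_labels)
    marker = np.asarray(marker, float)
    if exclusion_mask is None:
        exclusion_mask = np.zeros(labels.shape, dtype=bool)
    if labels.shape != marker.shape or labels.shape != exclusion_mask.shape:
        raise ValueError("labels, marker and mask must share one shape")
    usable = ~exclusion_mask
    nmax = int(labels.max())
    if nmax == 0:
        return pd.DataFrame(
            columns=[
                "patient_id", "spot_id", "cell_id", "cell_class",
                "area", "intensity", "centroid_row", "centroid_col",
            ]
        )
    flat = labels.ravel()
    area = np.bincount(flat[usable.ravel()], minlength=nmax + 1)
    intensity = np.bincount(
        flat[usable.ravel()], weights=marker.ravel()[usable.ravel()], minlength=nmax + 1
    )
    full_area = np.bincount(flat, minlength=nmax + 1)
    rows_idx, cols_idx = np.nonzero(labels)
    cy = np.bincount(labels[rows_idx, cols_idx], weights=rows_idx, minlength=nmax + 1)
    cx = np.bincount(labels[rows_idx, cols_idx], weights=cols_idx, minlength=nmax + 1)
    ids = np.nonzero(full_area[1:])[0] + 1
    dropped = int(np.sum(area[ids] == 0))
    if dropped:
        log.info("dropped %d fully masked cells in spot %s", dropped, spot_id)
    keep = ids[area[ids] > 0]
    classes = (
        [cell_classes[int(i)] if cell_classes is not None else "" for i in keep]
    )
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "spot_id": spot_id,
            "cell_id": keep.astype(int),
            "cell_class": classes,
            "area": area[keep].astype(float),
            "intensity": intensity[keep],
            "centroid_row": cy[keep] / full_area[keep],
            "centroid_col": cx[keep] / full_area[keep],
        }
    )


def spot_qc(spot_means: pd.Series) -> pd.DataFrame:
    """Two-class Otsu QC over spot-level positive-control mean intensities.

    Spots below the threshold fail; identical values everywhere pass all
    spots with a warning (no split exists).
    """
    values = spot_means.astype(float)
    if len(values) < 2 or values.nunique() <= 1:
        warnings.warn("positive-control values identical; all spots pass QC")
        return pd.DataFrame(
            {
                "spot_id": values.index,
                "ppib_mean": values.to_numpy(),
                "threshold": -np.inf,
                "passed": True,
            }
        )
    try:
        thr = otsu_threshold(values.to_numpy(), nbins=256)
    except DegenerateHistogramError:
        warnings.warn("degenerate positive-control histogram; all spots pass QC")
        thr = -np.inf
    return pd.DataFrame(
        {
            "spot_id": values.index,
            "ppib_mean": values.to_numpy(),
            "threshold": thr,
            "passed": values.to_numpy() >= thr,
        }
    )
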