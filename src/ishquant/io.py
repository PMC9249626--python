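"""Raster I/O for pipeline intermediates.

Scalar channels (optical densities, signal intensities) are stored as 32-bit
float TIFF; label maps as 16-bit unsigned TIFF; RGB spots as 8-bit PNG/TIFF.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
from PIL import Image


def save_channel(path, channel: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(channel, dtype=np.float32))


def load_channel(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(float)


def save_labels(path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("label map exceeds 16-bit range")
    tifffile.imwrite(str(path), labels.astype(np.uint16))


def load_labels(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int32)


def load_rgb(path) -> np.ndarray:
    """8-bit RGB raster to float [0, 1]."""
    return np.asarray(Image.open(path).convert("RGB"), dtype=float) / 255.0


def save_rgb(path, image: np.ndarray) -> None:
    arr = np.round(np.clip(image, 0.0, 1.0) * 255).astype(np.uint8)
    Image.fromarray(arr).save(str(path))


def dump_spot_artifacts(out_dir, result: dict) -> None:
    """Write one spot's intermediate rasters for inspection."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ch = result["channels"]
    save_channel(out / "nucleus.tif", ch.nucleus)
    save_channel(out / "marker.tif", ch.marker)
    save_channel(out / "restored.tif", result["restored"])
    save_labels(out / "labels.tif", result["labels"])
    save_labels(out / "expanded.tif", result["expanded"])
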