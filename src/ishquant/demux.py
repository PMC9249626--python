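"""Color demultiplexing of chromogenic ISH images.

A brightfield chromogenic image superimposes the blue nuclear counterstain
(hematoxylin) and the brown RNA chromogen (DAB) on a single RGB raster.
Under the Beer-Lambert law, absorbances (optical densities) mix linearly:

    OD_c = -ln(I_c / I0_c) = C_H * h_c + C_D * d_c

with ``h`` and ``d`` unit stain vectors. Inverting this 3x3 linear system
per pixel separates the two stains; the marker concentration is then mapped
to a bounded "signal intensity" in [0, 1] (1 = chromogen saturation), and
background is suppressed with Renyi entropy thresholding of the signal
histogram.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._histogram import DegenerateHistogramError, otsu_threshold

#: Standard H-DAB stain vectors (unit optical-density directions).
HEMATOXYLIN = np.array([0.650, 0.704, 0.286])
DAB = np.array([0.269, 0.568, 0.778])

#: Intensities below this floor are clamped before taking logs.
OD_EPS = 1.0 / 512.0

#: Marker optical density that maps to signal intensity 1.0.
DEFAULT_SATURATION_OD = 2.0


class CollinearStainsError(ValueError):
    """Raised when the two stain vectors do not span a separable plane."""


@dataclass(frozen=True)
class StainMatrix:
    """Two unit stain vectors plus a residual direction and white reference.

    The residual column is the normalized cross product of the two stains,
    completing an invertible 3x3 unmixing matrix.
    """

    hematoxylin: np.ndarray
    dab: np.ndarray
    white: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self):
        h = np.asarray(self.hematoxylin, dtype=float)
        d = np.asarray(self.dab, dtype=float)
        w = np.broadcast_to(np.asarray(self.white, dtype=float), (3,)).copy()
        if h.shape != (3,) or d.shape != (3,):
            raise ValueError("stain vectors must be 3-vectors")
        if np.any(w <= 0) or np.any(w > 1.0 + 1e-9):
            raise ValueError("white reference must lie in (0, 1]")
        h = h / np.linalg.norm(h)
        d = d / np.linalg.norm(d)
        r = np.cross(h, d)
        nr = np.linalg.norm(r)
        if nr < 1e-6:
            raise CollinearStainsError(
                "hematoxylin and DAB stain vectors are collinear; unmixing is singular"
            )
        object.__setattr__(self, "hematoxylin", h)
        object.__setattr__(self, "dab", d)
        object.__setattr__(self, "white", w)
        object.__setattr__(self, "_residual", r / nr)

    @property
    def residual(self) -> np.ndarray:
        return self._residual

    @property
    def matrix(self) -> np.ndarray:
        """Columns: hematoxylin, DAB, residual."""
        return np.stack([self.hematoxylin, self.dab, self.residual], axis=1)

    def to_dict(self) -> dict:
        return {
            "hematoxylin": self.hematoxylin.tolist(),
            "dab": self.dab.tolist(),
            "white": self.white.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StainMatrix":
        return cls(
            np.asarray(d["hematoxylin"], float),
            np.asarray(d["dab"], float),
            np.asarray(d.get("white", [1.0, 1.0, 1.0]), float),
        )


DEFAULT_STAINS = StainMatrix(HEMATOXYLIN, DAB)


@dataclass
class StainChannels:
    """Demultiplexed channels of one spot.

    nucleus: hematoxylin concentration (>= 0, optical-density units).
    marker:  marker signal intensity in [0, 1] (DAB OD / saturation constant).
    marker_od: unclipped-by-saturation DAB concentration (for round trips).
    marker_mask: suprathreshold marker pixels (set by ``suppress_background``).
    """

    nucleus: np.ndarray
    marker: np.ndarray
    marker_od: np.ndarray
    marker_mask: np.ndarray | None = None
    threshold: float | None = None


def estimate_white(spot: np.ndarray, fallback: float = 1.0) -> np.ndarray:
    """Per-channel white reference from the background of a spot.

    Background = pixels at or above the Otsu luminance threshold (tissue is
    darker than the illuminated background); white = their 99th percentile.
    """
    lum = spot.mean(axis=2)
    try:
        t = otsu_threshold(lum)
    except DegenerateHistogramError:
        return np.full(3, fallback)
    bg = lum >= t
    if not bg.any():
        return np.full(3, fallback)
    return np.percentile(spot[bg], 99, axis=0)


def rgb_to_optical_density(spot: np.ndarray, white=1.0) -> np.ndarray:
    """Absorbance transform OD_c = -ln(max(I_c, eps) / white_c)."""
    spot = np.asarray(spot, dtype=float)
    if spot.ndim != 3 or spot.shape[2] != 3:
        raise ValueError("spot must be an RGB image (rows, cols, 3)")
    white = np.broadcast_to(np.asarray(white, dtype=float), (3,))
    if np.any(white <= 0):
        raise ValueError("white reference must be positive")
    return -np.log(np.maximum(spot, OD_EPS) / white)


def deconvolve(
    od: np.ndarray,
    stains: StainMatrix = DEFAULT_STAINS,
    saturation_od: float = DEFAULT_SATURATION_OD,
) -> StainChannels:
    """Per-pixel linear unmixing of an OD image into stain concentrations.

    Solves OD = M c exactly (M invertible 3x3), clips negative concentrations
    to zero, and rescales the DAB concentration to a [0, 1] signal intensity
    by the saturation constant.
    """
    od = np.asarray(od, dtype=float)
    minv = np.linalg.inv(stains.matrix)
    conc = od @ minv.T
    conc = np.clip(conc, 0.0, None)
    c_h = conc[..., 0]
    c_d = conc[..., 1]
    marker = np.clip(c_d / saturation_od, 0.0, 1.0)
    return StainChannels(nucleus=c_h, marker=marker, marker_od=c_d)


def _class_entropies(p: np.ndarray, alpha: float) -> np.ndarray:
    """Sum of background+foreground Renyi entropies for every split point.

    ``p`` is a normalized histogram; entry t of the result corresponds to
    background bins [0..t], foreground (t..n). Invalid splits (empty class)
    are -inf.
    """
    n = p.size
    cum = np.cumsum(p)
    total = cum[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        if abs(alpha - 1.0) < 1e-8:
            # Shannon limit (Kapur's maximum-entropy criterion)
            plogp = np.where(p > 0, p * np.log(p), 0.0)
            cum_plogp = np.cumsum(plogp)
            pb, pf = cum[:-1], total - cum[:-1]
            hb = np.log(pb) - cum_plogp[:-1] / pb
            hf = np.log(pf) - (cum_plogp[-1] - cum_plogp[:-1]) / pf
        else:
            pa = np.where(p > 0, p, 0.0) ** alpha
            cum_pa = np.cumsum(pa)
            pb, pf = cum[:-1], total - cum[:-1]
            hb = (np.log(cum_pa[:-1]) - alpha * np.log(pb)) / (1.0 - alpha)
            hf = (np.log(cum_pa[-1] - cum_pa[:-1]) - alpha * np.log(pf)) / (1.0 - alpha)
    out = hb + hf
    out[(cum[:-1] <= 0) | (total - cum[:-1] <= 0)] = -np.inf
    assert out.size == n - 1
    return out


def renyi_threshold(marker: np.ndarray, alpha: float = 0.5, nbins: int = 256) -> float:
    """Renyi-entropy threshold of a [0, 1] signal image.

    Maximizes the sum of the background and foreground Renyi entropies of
    order ``alpha`` over the normalized class histograms (256 fixed bins over
    [0, 1]); ties break to the lowest threshold. ``alpha`` -> 1 recovers the
    Shannon maximum-entropy (Kapur) threshold.
    """
    if alpha <= 0:
        raise ValueError("Renyi order alpha must be positive")
    v = np.asarray(marker, dtype=float).ravel()
    hist, edges = np.histogram(v, bins=nbins, range=(0.0, 1.0))
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("degenerate histogram")
    p = hist / hist.sum()
    crit = _class_entropies(p, alpha)
    t = int(np.argmax(crit))
    return float(edges[t + 1])


def suppress_background(marker: np.ndarray, threshold: float):
    """Zero sub-threshold marker pixels; mask = marker >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    mask = marker >= threshold
    cleaned = np.where(mask, marker, 0.0)
    return cleaned, mask


def demux_spot(
    spot: np.ndarray,
    stains: StainMatrix = DEFAULT_STAINS,
    alpha: float = 0.5,
    saturation_od: float = DEFAULT_SATURATION_OD,
    estimate_background: bool = True,
) -> StainChannels:
    """Full demultiplexing of one RGB spot: OD, unmixing, background suppression.

    The white reference is estimated from the spot background unless the
    stain matrix's is to be used verbatim.
    """
    white = estimate_white(spot) if estimate_background else stains.white
    od = rgb_to_optical_density(spot, white)
    channels = deconvolve(od, stains, saturation_od)
    try:
        thr = renyi_threshold(channels.marker, alpha)
    except DegenerateHistogramError:
        warnings.warn("constant marker channel; falling back to an empty marker mask")
        channels.marker_mask = np.zeros(channels.marker.shape, dtype=bool)
        channels.threshold = math.inf
        return channels
    cleaned, mask = suppress_background(channels.marker, thr)
    channels.marker = cleaned
    channels.marker_mask = mask
    channels.threshold = thr
    return channels


def scale_fluorescent(marker: np.ndarray, low: float, high: float) -> np.ndarray:
    """Min-max scale a pre-separated fluorescent marker channel to [0, 1].

    Fluorescent mode bypasses color unmixing; fixed configured bounds keep
    the scaling comparable across slides.
    """
    if not high > low:
        raise ValueError("fluorescent scaling bounds must satisfy high > low")
    return np.clip((np.asarray(marker, float) - low) / (high - low), 0.0, 1.0)
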