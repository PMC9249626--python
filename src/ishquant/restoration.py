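"""Restoration of the nuclear channel under chromogen voids.

Strong chromogenic marker signal destroys the counterstain underneath it, so
the demultiplexed nucleus channel has voids exactly where dots sit. This
module derives a void mask from the suprathreshold marker mask and fills the
voids by discrete harmonic interpolation (Laplace equation with Dirichlet
boundary from the surrounding intact counterstain), which is deterministic,
preserves constants and linear ramps, and obeys the maximum principle: a
filled value never leaves the range of its void-boundary values. Segmentation
needs plausible continuity, not texture fidelity, so smooth interpolation is
sufficient; the interface is pluggable should a patch-synthesis backend be
wanted later.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve

from ._morph import disk_footprint


@dataclass
class VoidMask:
    mask: np.ndarray
    dilation_radius: float

    @property
    def fraction(self) -> float:
        return float(self.mask.mean())

    @property
    def flagged(self) -> bool:
        """True when the void covers >= 90% of the image (dubious spot)."""
        return self.fraction >= 0.9


def build_void_mask(marker_mask: np.ndarray, dilation_radius: float = 2.0) -> VoidMask:
    """Dilate the marker mask by a Euclidean disk to cover dot halos."""
    if marker_mask.dtype != bool:
        raise TypeError("marker_mask must be boolean")
    if dilation_radius > 0:
        mask = ndimage.binary_dilation(marker_mask, structure=disk_footprint(dilation_radius))
    else:
        mask = marker_mask.copy()
    return VoidMask(mask=mask, dilation_radius=dilation_radius)


def inpaint(channel: np.ndarray, voids: VoidMask | np.ndarray) -> np.ndarray:
    """Harmonic fill of void pixels; all other pixels pass through bit-exact.

    Solves the 5-point discrete Laplace equation over the void pixels with
    the surrounding known pixels as Dirichlet data (mirror boundary at the
    image edge). A void component with no known neighbor anywhere (the void
    covers the whole image) is an error.
    """
    mask = voids.mask if isinstance(voids, VoidMask) else np.asarray(voids, bool)
    channel = np.asarray(channel, dtype=float)
    if mask.shape != channel.shape:
        raise ValueError("void mask shape must match the channel")
    if not mask.any():
        return channel.copy()
    if mask.all():
        raise ValueError("void covers the entire image; nothing to interpolate from")

    rows, cols = channel.shape
    idx = -np.ones(channel.shape, dtype=np.int64)
    ys, xs = np.nonzero(mask)
    n = ys.size
    idx[ys, xs] = np.arange(n)

    data, ri, ci = [], [], []
    rhs = np.zeros(n)
    deg = np.zeros(n)
    for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        ny, nx = ys + dy, xs + dx
        inside = (ny >= 0) & (ny < rows) & (nx >= 0) & (nx < cols)
        deg += inside  # mirror boundary: off-image neighbors drop out
        ny, nx = ny[inside], nx[inside]
        which = np.nonzero(inside)[0]
        nb_unknown = mask[ny, nx]
        # unknown neighbor -> -1 coefficient
        ri.extend(which[nb_unknown])
        ci.extend(idx[ny[nb_unknown], nx[nb_unknown]])
        data.extend(-np.ones(int(nb_unknown.sum())))
        # known neighbor -> Dirichlet value to the RHS
        np.add.at(rhs, which[~nb_unknown], channel[ny[~nb_unknown], nx[~nb_unknown]])
    a = sparse.coo_matrix(
        (np.concatenate([deg, np.asarray(data)]), (np.concatenate([np.arange(n), ri]), np.concatenate([np.arange(n), ci]))),
        shape=(n, n),
    ).tocsr()
    out = channel.copy()
    out[ys, xs] = spsolve(a, rhs)
    return out


def restore_nucleus(
    nucleus: np.ndarray, marker_mask: np.ndarray, dilation_radius: float = 2.0
) -> tuple[np.ndarray, VoidMask]:
    """Void mask from the marker mask, then harmonic fill of the nucleus channel."""
    voids = build_void_mask(marker_mask, dilation_radius)
    if voids.mask.all():
        raise ValueError("marker mask covers the entire spot")
    return inpaint(nucleus, voids), voids
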