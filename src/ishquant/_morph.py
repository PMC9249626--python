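"""Exact Euclidean structuring elements.

All dilations in the pipeline use the true lattice disk {(dy, dx): dy^2 + dx^2 <= r^2}
so that dilated areas match analytic lattice-point counts exactly.
"""

from __future__ import annotations

import numpy as np


def disk_footprint(radius: float) -> np.ndarray:
    """Boolean lattice disk of the given Euclidean radius.

    Contains every integer offset within distance ``radius`` of the origin
    (e.g. radius 2 -> 13 points, radius 10 -> 317 points).
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    r = int(np.floor(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    return (dy * dy + dx * dx) <= radius * radius
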