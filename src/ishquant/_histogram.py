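"""Histogram-based global thresholding.

Otsu's criterion is implemented on an explicit fixed-bin histogram with a
bin-edge return convention (lowest bin wins ties), so exhaustive-search
equality is well defined and the threshold shifts exactly with an additive
offset of the data when the histogram range follows the data.
"""

from __future__ import annotations

import numpy as np


class DegenerateHistogramError(ValueError):
    """Raised when a histogram has fewer than two occupied bins."""


def _histogram(values: np.ndarray, nbins: int, value_range) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise DegenerateHistogramError("degenerate histogram: no finite values")
    if value_range is None:
        lo, hi = float(v.min()), float(v.max())
    else:
        lo, hi = map(float, value_range)
    if not hi > lo:
        raise DegenerateHistogramError("degenerate histogram: zero value range")
    hist, edges = np.histogram(v, bins=nbins, range=(lo, hi))
    return hist.astype(float), edges


def otsu_threshold(values, nbins: int = 256, value_range=None) -> float:
    """Threshold maximizing between-class variance over ``nbins`` candidates.

    Returns the upper edge of the last background bin; pixels >= the returned
    value belong to the bright class. Ties resolve to the lowest threshold.
    """
    hist, edges = _histogram(values, nbins, value_range)
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("degenerate histogram: fewer than 2 occupied bins")
    p = hist / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(p)[:-1]
    w1 = 1.0 - w0
    cum_mu = np.cumsum(p * centers)[:-1]
    mu_total = float(np.sum(p * centers))
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = cum_mu / w0
        mu1 = (mu_total - cum_mu) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[(w0 <= 0) | (w1 <= 0)] = -np.inf
    t = int(np.argmax(sigma_b))  # argmax takes the first (lowest) maximizer
    return float(edges[t + 1])
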