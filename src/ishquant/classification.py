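"""Morphology-based cell classification and segment expansion.

Each segmented nucleus is described by four features — area, mean
counterstain intensity, eccentricity, and perimeter-to-area ratio — and
classified with a quadratic Gaussian (QDA) classifier into carcinoma, immune
and stromal cells plus three artifact classes ("small", "irregular",
"large"), trained with uniform class priors. Because cells of the same type
co-localize in tissue, per-class posterior maps are low-pass filtered in log
space with a 100 px disk kernel (about four cell radii), which propagates
class evidence to uncertain neighbors while letting a confidently classified
cell keep its class. Finally, nuclear segments are expanded into unlabeled
space by a class-specific radius (20 px carcinoma, 5 px immune/stromal) to
cover the cytoplasm, with contested pixels going to the nearest segment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import fftconvolve
from scipy.special import logsumexp
from skimage.measure import regionprops_table

from ._morph import disk_footprint

CLASS_NAMES = ("cancer", "immune", "stromal", "small", "irregular", "large")
CELL_CLASSES = ("cancer", "immune", "stromal")
DEFAULT_EXPANSION_RADII = {"cancer": 20.0, "immune": 5.0, "stromal": 5.0}
FEATURES = ("area", "mean_intensity", "eccentricity", "perimeter_to_area")


class MissingClassError(ValueError):
    pass


def extract_features(labels: np.ndarray, channel: np.ndarray) -> pd.DataFrame:
    """Four morphology features plus the centroid for every labeled region.

    Perimeter uses the boundary-step estimator; eccentricity comes from the
    region's second central moments (fitted-ellipse convention).
    """
    labels = np.asarray(labels)
    if labels.max() == 0:
        return pd.DataFrame(
            columns=["cell_id", *FEATURES, "centroid_row", "centroid_col"]
        )
    props = regionprops_table(
        labels,
        intensity_image=channel,
        properties=(
            "label",
            "area",
            "intensity_mean",
            "eccentricity",
            "perimeter",
            "centroid",
        ),
    )
    df = pd.DataFrame(props)
    return pd.DataFrame(
        {
            "cell_id": df["label"].astype(int),
            "area": df["area"].astype(float),
            "mean_intensity": df["intensity_mean"].astype(float),
            "eccentricity": df["eccentricity"].astype(float),
            "perimeter_to_area": df["perimeter"] / df["area"],
            "centroid_row": df["centroid-0"],
            "centroid_col": df["centroid-1"],
        }
    )


@dataclass
class QDAModel:
    """Per-class Gaussian model: mean, covariance, prior (uniform by default)."""

    classes: tuple
    means: np.ndarray  # (K, 4)
    covariances: np.ndarray  # (K, 4, 4)
    priors: np.ndarray  # (K,)

    def to_json(self) -> str:
        return json.dumps(
            {
                "classes": list(self.classes),
                "means": self.means.tolist(),
                "covariances": self.covariances.tolist(),
                "priors": self.priors.tolist(),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "QDAModel":
        d = json.loads(s)
        return cls(
            tuple(d["classes"]),
            np.asarray(d["means"], float),
            np.asarray(d["covariances"], float),
            np.asarray(d["priors"], float),
        )


def fit_qda(features: pd.DataFrame, labels, priors=None) -> QDAModel:
    """Per-class sample mean and covariance, regularized when near-singular.

    Requires >= 5 training cells per class; a class with zero feature spread
    (degenerate covariance even after +eps*I) is an error.
    """
    labels = pd.Series(np.asarray(labels), index=features.index)
    classes = tuple(pd.unique(labels))
    means, covs = [], []
    x = features[list(FEATURES)].to_numpy(float)
    for k in classes:
        xi = x[(labels == k).to_numpy()]
        if xi.shape[0] < 5:
            raise MissingClassError(
                f"class {k!r} has {xi.shape[0]} training cells; at least 5 required"
            )
        mu = xi.mean(axis=0)
        cov = np.cov(xi, rowvar=False)
        tr = np.trace(cov)
        if tr <= 0:
            raise ValueError(f"degenerate training data for class {k!r} (zero spread)")
        eigmin = np.linalg.eigvalsh(cov)[0]
        if eigmin < 1e-10 * tr:
            cov = cov + (1e-6 * tr / len(FEATURES)) * np.eye(len(FEATURES))
        means.append(mu)
        covs.append(cov)
    if priors is None:
        pr = np.full(len(classes), 1.0 / len(classes))
    else:
        pr = np.asarray([priors[k] for k in classes], float)
        pr = pr / pr.sum()
    return QDAModel(classes, np.asarray(means), np.asarray(covs), pr)


def log_densities(model: QDAModel, x: np.ndarray) -> np.ndarray:
    """Per-class Gaussian log density plus log prior, shape (n, K)."""
    x = np.atleast_2d(np.asarray(x, float))
    n, p = x.shape
    out = np.empty((n, len(model.classes)))
    for j, (mu, cov, pr) in enumerate(zip(model.means, model.covariances, model.priors)):
        sign, logdet = np.linalg.slogdet(cov)
        diff = x - mu
        sol = np.linalg.solve(cov, diff.T).T
        maha = np.einsum("ij,ij->i", diff, sol)
        out[:, j] = np.log(pr) - 0.5 * (p * np.log(2 * np.pi) + logdet + maha)
    return out


def log_posteriors(model: QDAModel, features: pd.DataFrame) -> pd.DataFrame:
    """Normalized log posteriors per cell (no underflow: stays in log space)."""
    x = features[list(FEATURES)].to_numpy(float)
    logp = log_densities(model, x)
    logp = logp - logsumexp(logp, axis=1, keepdims=True)
    return pd.DataFrame(logp, columns=list(model.classes), index=features.index)


def posteriors(model: QDAModel, features: pd.DataFrame) -> pd.DataFrame:
    """Normalized class posteriors per cell, computed in log space."""
    return np.exp(log_posteriors(model, features))


def classify(post: pd.DataFrame) -> pd.Series:
    return post.idxmax(axis=1)


def spatial_smooth(
    post: pd.DataFrame,
    features: pd.DataFrame,
    labels: np.ndarray,
    radius: float = 100.0,
    assume_log: bool = False,
) -> tuple[pd.DataFrame, pd.Series]:
    """Disk-kernel low-pass filtering of per-class posterior maps in log space.

    Each labeled pixel carries its cell's log posterior; background pixels
    carry the neutral value log(1/K) so the disk mean pulls isolated cells
    toward the uniform distribution (harmless after renormalization). Maps
    are mean-filtered with a uniform disk of the given radius, read back at
    each cell's centroid, and renormalized; the final class is the argmax.

    Pass normalized log posteriors with ``assume_log=True`` to preserve the
    full dynamic range of confident cells (probabilities underflow at ~1e-300,
    which would flatten all strong evidence to one magnitude).
    """
    if radius <= 0:
        warnings.warn("non-positive smoothing radius; smoothing skipped")
        out = np.exp(post) if assume_log else post.copy()
        return out, classify(out)
    if len(post) == 0:
        return post.copy(), pd.Series(dtype=object)
    classes = list(post.columns)
    neutral = -np.log(len(classes))
    kernel = disk_footprint(radius).astype(float)
    kernel /= kernel.sum()
    labels = np.asarray(labels)
    nmax = int(labels.max())
    if assume_log:
        logpost = post.to_numpy(float)
    else:
        logpost = np.log(np.clip(post.to_numpy(float), 1e-300, None))
    cr = np.clip(np.round(features["centroid_row"]).astype(int), 0, labels.shape[0] - 1)
    cc = np.clip(np.round(features["centroid_col"]).astype(int), 0, labels.shape[1] - 1)
    ids = features["cell_id"].astype(int).to_numpy()

    smoothed_at_cells = np.empty((len(post), len(classes)))
    for j in range(len(classes)):
        lut = np.full(nmax + 1, neutral)
        lut[ids] = logpost[:, j]
        field = lut[labels]
        field[labels == 0] = neutral
        sm = fftconvolve(field, kernel, mode="same")
        smoothed_at_cells[:, j] = sm[cr, cc]
    smoothed_at_cells -= logsumexp(smoothed_at_cells, axis=1, keepdims=True)
    sm_post = pd.DataFrame(np.exp(smoothed_at_cells), columns=classes, index=post.index)
    return sm_post, classify(sm_post)


def expand_segments(
    labels: np.ndarray,
    cell_classes,
    radii: dict | None = None,
) -> np.ndarray:
    """Grow each cell's segment into background by its class radius.

    A background pixel within reach of several cells goes to the one whose
    original segment is nearest (Euclidean); remaining ties go to the lower
    label id via the class iteration order and the distance transform's
    deterministic nearest-index choice. Original labeled pixels never change;
    artifact classes are not expanded.
    """
    radii = dict(DEFAULT_EXPANSION_RADII if radii is None else radii)
    labels = np.asarray(labels)
    if isinstance(cell_classes, pd.Series):
        class_of = {int(i): c for i, c in cell_classes.items()}
    else:
        class_of = {int(i): c for i, c in dict(cell_classes).items()}
    out = labels.copy().astype(np.int32)
    background = labels == 0
    best_dist = np.full(labels.shape, np.inf)
    best_label = np.zeros(labels.shape, dtype=np.int32)
    for cls in sorted(radii):
        r = radii[cls]
        ids = [i for i, c in class_of.items() if c == cls]
        if not ids or r <= 0:
            continue
        member = np.isin(labels, ids)
        if not member.any():
            continue
        dist, (ir, ic) = ndimage.distance_transform_edt(~member, return_indices=True)
        nearest = labels[ir, ic]
        claim = background & (dist <= r)
        better = claim & (
            (dist < best_dist) | ((dist == best_dist) & (nearest < best_label))
        )
        best_dist[better] = dist[better]
        best_label[better] = nearest[better]
    grown = background & (best_label > 0)
    out[grown] = best_label[grown]
    return out
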