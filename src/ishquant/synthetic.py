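"""Synthetic chromogenic ISH spots with complete ground truth.

Renders brightfield TMA-spot images that follow the statistical structure the
quantification pipeline assumes: three morphologically distinct cell classes
(large pale carcinoma nuclei, small dark round immune nuclei, elongated
stromal nuclei), dot-like RNA chromogen placed in the cytoplasmic footprint
of each cell with negative-binomial counts per cell, and Beer-Lambert
absorbance mixing of the counterstain and chromogen so that optical-density
unmixing has an exact inverse to recover.

High chromogen density suppresses the counterstain underneath
(C_H * exp(-occlusion_strength * C_D)), emulating chromogen covering nuclei;
the rendered image remains an exact two-stain mixture, but the nucleus
channel genuinely loses morphology under dense signal, which is what the
restoration stage must repair.

Everything is deterministic given (spec, seed): each cell draws from its own
PRNG stream keyed by (seed, cell index).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .demux import DAB, HEMATOXYLIN

CLASS_NAMES = ("cancer", "immune", "stromal")

#: cytoplasm reach used both for dot placement and for segment expansion
EXPANSION_RADII = {"cancer": 20.0, "immune": 5.0, "stromal": 5.0}


class PlacementError(RuntimeError):
    """Raised when a nucleus cannot be placed without overlap."""


@dataclass(frozen=True)
class ClassGeometry:
    """Nucleus geometry and staining of one cell class."""

    radius_range: tuple[float, float]  # equivalent radius, px
    ecc_range: tuple[float, float]  # fitted-ellipse eccentricity
    od_range: tuple[float, float]  # counterstain optical density

    def __post_init__(self):
        lo, hi = self.ecc_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError("eccentricity range must lie in [0, 1)")
        if self.radius_range[0] <= 0 or self.radius_range[0] > self.radius_range[1]:
            raise ValueError("invalid radius range")


@dataclass(frozen=True)
class DotProcess:
    """Dot-like RNA signal process of one cell class.

    Dot counts per cell are negative binomial with the given mean and
    dispersion k (variance = mu + mu^2 / k), the super-Poisson mean-linked
    variance the variability factor presumes; k = inf gives a Poisson count.
    """

    mean: float
    dispersion: float
    radius: float = 3.0
    peak_od: float = 1.7  # dense chromogen precipitate: dots nearly opaque


@dataclass(frozen=True)
class SyntheticSpotSpec:
    image_size: tuple[int, int] = (1280, 1280)
    counts: dict = field(
        default_factory=lambda: {"cancer": 100, "immune": 50, "stromal": 50}
    )
    geometry: dict = field(
        default_factory=lambda: {
            "cancer": ClassGeometry((20.0, 35.0), (0.0, 0.6), (0.30, 0.50)),
            "immune": ClassGeometry((12.5, 16.0), (0.0, 0.4), (0.80, 1.20)),
            "stromal": ClassGeometry((13.0, 17.0), (0.90, 0.96), (0.60, 0.90)),
        }
    )
    dots: dict = field(
        default_factory=lambda: {
            "cancer": DotProcess(5.0, 2.0),
            "immune": DotProcess(1.0, 2.0),
            "stromal": DotProcess(1.0, 2.0),
        }
    )
    stain_hematoxylin: tuple = tuple(HEMATOXYLIN)
    stain_dab: tuple = tuple(DAB)
    white: float = 0.96
    occlusion_strength: float = 4.0
    noise_sd: float = 1.0 / 255.0  # scanner noise on transmitted intensity, ~1 DN
    # spatial spread of a same-class territory, px; 2*sd must hold the
    # territory's cells at ~50% packing or overflow scatters across classes
    cluster_sd: dict = field(
        default_factory=lambda: {"cancer": 140.0, "immune": 80.0, "stromal": 80.0}
    )
    cells_per_cluster: int = 50
    seed: int = 0
    max_retries: int = 1000

    def __post_init__(self):
        for name, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for class {name!r}")
        h = np.asarray(self.stain_hematoxylin, float)
        d = np.asarray(self.stain_dab, float)
        if np.linalg.norm(np.cross(h / np.linalg.norm(h), d / np.linalg.norm(d))) < 1e-6:
            raise ValueError("stain vectors are collinear")

    def replace(self, **kw) -> "SyntheticSpotSpec":
        from dataclasses import replace

        return replace(self, **kw)

    @classmethod
    def occluded(cls, **kw) -> "SyntheticSpotSpec":
        """Stress preset: dense chromogen occluding ~30% of nuclear area.

        Emulates very high target-RNA abundance covering nuclei; used to
        exercise the nucleus-restoration stage.
        """
        dots = {
            "cancer": DotProcess(100.0, 2.0),
            "immune": DotProcess(10.0, 2.0),
            "stromal": DotProcess(10.0, 2.0),
        }
        return cls(dots=dots, **kw)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, default=list)


@dataclass
class GroundTruth:
    """Per-pixel and per-cell truth of one rendered spot."""

    label_map: np.ndarray  # int32, 0 = background
    classes: dict  # cell id -> class name
    footprints: np.ndarray  # int32 cytoplasmic footprint labels (dot support)
    dot_counts: dict = field(default_factory=dict)  # cell id -> true dots
    dab_per_cell: dict = field(default_factory=dict)  # cell id -> sum C_D
    centroids: dict = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        ids = sorted(self.classes)
        return pd.DataFrame(
            {
                "cell_id": ids,
                "class": [self.classes[i] for i in ids],
                "true_dots": [self.dot_counts.get(i, 0) for i in ids],
                "true_signal": [self.dab_per_cell.get(i, 0.0) for i in ids],
            }
        )


def _cell_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def _ellipse_mask(shape, center, a, b, theta):
    """Boolean mask of the ellipse with semi-axes a >= b, orientation theta."""
    r0 = max(int(np.floor(center[0] - a - 1)), 0)
    r1 = min(int(np.ceil(center[0] + a + 2)), shape[0])
    c0 = max(int(np.floor(center[1] - a - 1)), 0)
    c1 = min(int(np.ceil(center[1] + a + 2)), shape[1])
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy = yy - center[0]
    dx = xx - center[1]
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    local = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return (slice(r0, r1), slice(c0, c1)), local


def render_nucleus_field(spec: SyntheticSpotSpec):
    """Place non-overlapping elliptical nuclei and their counterstain field.

    Returns (GroundTruth, hematoxylin concentration image). Placement is
    rejection sampling with a bounded retry budget per cell; cells keep a
    margin for their cytoplasmic footprint and dot radius so rendered dots
    are never clipped by the image edge. Cells of one class cluster around
    shared territory centers (tumor nests, immune infiltrates, stromal
    bands), the spatial co-localization the classification smoothing stage
    presumes; the first half of a cell's retry budget samples near its
    territory, the second half falls back to uniform placement.
    """
    rows, cols = spec.image_size
    labels = np.zeros((rows, cols), dtype=np.int32)
    hema = np.zeros((rows, cols), dtype=float)
    occupied = np.zeros((rows, cols), dtype=bool)
    truth = GroundTruth(label_map=labels, classes={}, footprints=np.zeros_like(labels))

    territory_rng = _cell_rng(spec.seed, 30_000_017)
    n_clusters = {
        cls: max(1, int(np.ceil(spec.counts.get(cls, 0) / spec.cells_per_cluster)))
        for cls in CLASS_NAMES
    }
    # territories occupy distinct grid sites: compartmentalized tissue
    # (tumor nests / infiltrates / stromal bands), not overlapping mixtures
    total = sum(n_clusters.values())
    gr = int(np.ceil(np.sqrt(total)))
    gc = int(np.ceil(total / gr))
    sites = [
        (
            (i + 0.5) * rows / gr + territory_rng.normal(0, rows / (16 * gr)),
            (j + 0.5) * cols / gc + territory_rng.normal(0, cols / (16 * gc)),
        )
        for i in range(gr)
        for j in range(gc)
    ]
    site_order = territory_rng.permutation(len(sites))
    territories = {}
    cursor = 0
    for cls in CLASS_NAMES:
        chosen = [sites[site_order[cursor + k]] for k in range(n_clusters[cls])]
        territories[cls] = np.asarray(chosen)
        cursor += n_clusters[cls]

    order = [(cls, i) for cls in CLASS_NAMES for i in range(spec.counts.get(cls, 0))]
    cell_id = 0
    for idx, (cls, _) in enumerate(order):
        geom = spec.geometry[cls]
        dot = spec.dots[cls]
        rng = _cell_rng(spec.seed, idx)
        margin = EXPANSION_RADII[cls] + dot.radius + 1
        home = territories[cls][rng.integers(len(territories[cls]))]
        placed = False
        for attempt in range(spec.max_retries):
            r_eq = rng.uniform(*geom.radius_range)
            ecc = rng.uniform(*geom.ecc_range)
            axis_ratio = np.sqrt(1.0 - ecc * ecc)  # b / a
            a = r_eq / axis_ratio**0.5
            b = r_eq * axis_ratio**0.5
            theta = rng.uniform(0.0, np.pi)
            lo_r, hi_r = a + margin, rows - a - margin
            lo_c, hi_c = a + margin, cols - a - margin
            if hi_r <= lo_r or hi_c <= lo_c:
                break
            if attempt < spec.max_retries // 2:
                sd = spec.cluster_sd[cls]
                center = (
                    np.clip(rng.normal(home[0], sd), lo_r, hi_r),
                    np.clip(rng.normal(home[1], sd), lo_c, hi_c),
                )
            else:
                center = (rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c))
            sl, local = _ellipse_mask((rows, cols), center, a + 2.0, b + 2.0, theta)
            if occupied[sl][local].any():  # 2 px clearance between nuclei
                continue
            sl, local = _ellipse_mask((rows, cols), center, a, b, theta)
            cell_id += 1
            labels[sl][local] = cell_id
            occupied[sl][local] = True
            hema[sl][local] = rng.uniform(*geom.od_range)
            truth.classes[cell_id] = cls
            truth.centroids[cell_id] = center
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place a {cls!r} nucleus after {spec.max_retries} retries"
            )
    return truth, hema


def _footprints(truth: GroundTruth) -> np.ndarray:
    """Cytoplasmic footprint labels: nearest-nucleus dilation by class radius."""
    from scipy import ndimage

    labels = truth.label_map
    dist, (ir, ic) = ndimage.distance_transform_edt(labels == 0, return_indices=True)
    nearest = labels[ir, ic]
    radii = np.zeros(int(labels.max()) + 1)
    for cid, cls in truth.classes.items():
        radii[cid] = EXPANSION_RADII[cls]
    out = np.where(dist <= radii[nearest], nearest, 0).astype(np.int32)
    out[labels > 0] = labels[labels > 0]
    return out


def render_cish_image(truth: GroundTruth, hema: np.ndarray, spec: SyntheticSpotSpec):
    """Render the RGB brightfield image and the per-cell truth table.

    Per channel c the transmitted intensity is
    ``I_c = white * exp(-(C_H_occ * h_c + C_D * d_c))`` with
    ``C_H_occ = C_H * exp(-occlusion_strength * C_D)``. The returned image is
    quantized to 8 bits (the on-disk representation); pass
    ``quantize=False`` via :func:`render_spot` internals for an exact float
    render. The truth table records the summed DAB concentration per cell.
    """
    rows, cols = hema.shape
    c_d = np.zeros_like(hema)
    truth.footprints = _footprints(truth)
    ids = sorted(truth.classes)
    # per-cell flat pixel indices of the cytoplasmic footprint
    order = np.argsort(truth.footprints, axis=None, kind="stable")
    flat = truth.footprints.ravel()[order]
    starts = np.searchsorted(flat, ids, side="left")
    ends = np.searchsorted(flat, ids, side="right")

    for idx, cid in enumerate(ids):
        cls = truth.classes[cid]
        dot = spec.dots[cls]
        rng = _cell_rng(spec.seed, 10_000_019 + idx)
        n = _negative_binomial(rng, dot.mean, dot.dispersion)
        truth.dot_counts[cid] = int(n)
        pix = order[starts[idx] : ends[idx]]
        if n == 0 or pix.size == 0:
            truth.dab_per_cell[cid] = 0.0
            continue
        chosen = pix[rng.integers(0, pix.size, size=n)]
        cy, cx = np.unravel_index(chosen, (rows, cols))
        # subpixel jitter keeps dot profiles off the integer lattice
        cy = cy + rng.uniform(-0.5, 0.5, n)
        cx = cx + rng.uniform(-0.5, 0.5, n)
        rad = int(np.ceil(dot.radius))
        sig2 = (dot.radius / 2.0) ** 2
        added = 0.0
        for y, x in zip(cy, cx):
            r0, r1 = int(np.floor(y)) - rad, int(np.floor(y)) + rad + 2
            c0, c1 = int(np.floor(x)) - rad, int(np.floor(x)) + rad + 2
            r0, c0 = max(r0, 0), max(c0, 0)
            r1, c1 = min(r1, rows), min(c1, cols)
            yy, xx = np.mgrid[r0:r1, c0:c1]
            d2 = (yy - y) ** 2 + (xx - x) ** 2
            prof = dot.peak_od * np.exp(-d2 / (2.0 * sig2))
            prof[d2 > dot.radius**2] = 0.0
            c_d[r0:r1, c0:c1] += prof
            added += prof.sum()
        truth.dab_per_cell[cid] = float(added)

    h = np.asarray(spec.stain_hematoxylin, float)
    h = h / np.linalg.norm(h)
    d = np.asarray(spec.stain_dab, float)
    d = d / np.linalg.norm(d)
    hema_occ = hema * np.exp(-spec.occlusion_strength * c_d)
    od = hema_occ[..., None] * h + c_d[..., None] * d
    image = spec.white * np.exp(-od)
    noisy = image
    if spec.noise_sd > 0:
        noise_rng = _cell_rng(spec.seed, 20_000_003)
        noisy = image + noise_rng.normal(0.0, spec.noise_sd, image.shape)
    image8 = np.round(np.clip(noisy, 0.0, 1.0) * 255.0) / 255.0
    return image8, truth.table(), {"c_d": c_d, "c_h": hema_occ, "image_float": image}


def _negative_binomial(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if not np.isfinite(dispersion):
        return int(rng.poisson(mean))
    # Gamma-Poisson mixture: lambda ~ Gamma(k, mean/k)
    lam = rng.gamma(dispersion, mean / dispersion)
    return int(rng.poisson(lam))


def render_spot(spec: SyntheticSpotSpec):
    """Convenience: nucleus field + image render in one call."""
    truth, hema = render_nucleus_field(spec)
    image, table, extras = render_cish_image(truth, hema, spec)
    return image, truth, table, extras


def nuclear_occlusion_fraction(
    truth: GroundTruth, extras: dict, spec: SyntheticSpotSpec, cutoff: float = 0.5
) -> float:
    """Fraction of nuclear pixels whose counterstain is suppressed below
    ``cutoff`` of its unoccluded value (ground-truth dot occlusion)."""
    nuc = truth.label_map > 0
    if not nuc.any():
        return 0.0
    c_d = extras["c_d"][nuc]
    return float(np.mean(np.exp(-spec.occlusion_strength * c_d) < cutoff))


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Multi-spot-per-patient cohort with injected expression structure.

    Each patient draws a log-normal mean dot count (expression level) and a
    log-normal negative-binomial dispersion k (cell-to-cell variability);
    every spot of that patient renders cancer cells from that process, so the
    patient's ground-truth mean and variance follow the injected values in
    expectation. Progression-free-interval (PFI) event times are exponential
    with a log hazard optionally linked to the injected mean or variability
    covariate; overall survival (OS) uses a slower baseline with the same
    link. Emulates a TMA design with several ~1 mm cores per patient.
    """

    n_patients: int = 20
    spots_per_patient: int = 3
    base_spec: SyntheticSpotSpec = field(
        default_factory=lambda: SyntheticSpotSpec(
            image_size=(384, 384),
            counts={"cancer": 12, "immune": 4, "stromal": 4},
            cluster_sd={"cancer": 72.0, "immune": 40.0, "stromal": 40.0},
        )
    )
    mean_dots_median: float = 8.0
    mean_dots_sigma: float = 0.5  # sigma of ln(mean dots) across patients
    dispersion_median: float = 2.0
    dispersion_sigma: float = 1.0  # sigma of ln(k) across patients
    survival_link: str | None = None  # None | "mean" | "variability"
    log_hazard_per_sd: float = 0.7
    baseline_hazard_pfi: float = 1.0 / 18.0  # events per month
    baseline_hazard_os: float = 1.0 / 54.0
    censor_months: float = 120.0

    def __post_init__(self):
        if self.spots_per_patient <= 0:
            raise ValueError("spots_per_patient must be positive")
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.survival_link not in (None, "mean", "variability"):
            raise ValueError("survival_link must be None, 'mean' or 'variability'")


def generate_cohort(cohort_spec: CohortSpec, seed: int, out_dir=None):
    """Generate a full synthetic cohort: spot images, truth, clinical table.

    Returns a dict with per-spot (patient_id, spot_id, image, truth, table,
    extras, spec), the pooled truth table, the clinical DataFrame and the
    per-patient injected covariates. When ``out_dir`` is given, writes 8-bit
    RGB PNG spot images, truth and clinical CSVs and the spec JSON there.
    """
    cs = cohort_spec
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 987_654_321]))
    n = cs.n_patients
    mu = cs.mean_dots_median * np.exp(rng.normal(0.0, cs.mean_dots_sigma, n))
    k = cs.dispersion_median * np.exp(rng.normal(0.0, cs.dispersion_sigma, n))

    if cs.survival_link == "mean":
        cov = np.log(mu)
    elif cs.survival_link == "variability":
        cov = -np.log(k)  # lower k -> more dispersed -> higher hazard
    else:
        cov = np.zeros(n)
    z = (cov - cov.mean()) / cov.std() if cov.std() > 0 else np.zeros(n)

    rate_pfi = cs.baseline_hazard_pfi * np.exp(cs.log_hazard_per_sd * z)
    rate_os = cs.baseline_hazard_os * np.exp(cs.log_hazard_per_sd * z)
    t_pfi = rng.exponential(1.0 / rate_pfi)
    t_os = rng.exponential(1.0 / rate_os)
    clinical = pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(n)],
            "pfi_months": np.minimum(t_pfi, cs.censor_months).round(2),
            "pfi_event": (t_pfi <= cs.censor_months).astype(int),
            "os_months": np.minimum(t_os, cs.censor_months).round(2),
            "os_event": (t_os <= cs.censor_months).astype(int),
        }
    )

    spots = []
    truth_rows = []
    for i in range(n):
        pid = f"P{i:03d}"
        for s in range(cs.spots_per_patient):
            spot_seed = int(
                np.random.SeedSequence([int(seed), i, s]).generate_state(1)[0] % (2**31)
            )
            dots = dict(cs.base_spec.dots)
            dots["cancer"] = DotProcess(
                mean=float(mu[i]),
                dispersion=float(k[i]),
                radius=dots["cancer"].radius,
                peak_od=dots["cancer"].peak_od,
            )
            spec = cs.base_spec.replace(dots=dots, seed=spot_seed)
            image, truth, table, extras = render_spot(spec)
            sid = f"{pid}_s{s}"
            table = table.assign(patient_id=pid, spot_id=sid)
            truth_rows.append(table)
            spots.append(
                {
                    "patient_id": pid,
                    "spot_id": sid,
                    "image": image,
                    "truth": truth,
                    "table": table,
                    "extras": extras,
                    "spec": spec,
                }
            )

    truth_table = pd.concat(truth_rows, ignore_index=True)[
        ["patient_id", "spot_id", "cell_id", "class", "true_dots", "true_signal"]
    ]
    injected = pd.DataFrame(
        {
            "patient_id": clinical["patient_id"],
            "mean_dots": mu,
            "dispersion": k,
            "covariate": cov,
        }
    )
    out = {
        "spots": spots,
        "truth": truth_table,
        "clinical": clinical,
        "injected": injected,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "spots").mkdir(parents=True, exist_ok=True)
        for s in spots:
            arr = np.round(np.clip(s["image"], 0, 1) * 255).astype(np.uint8)
            Image.fromarray(arr).save(out_dir / "spots" / f"{s['spot_id']}.png")
        truth_table.to_csv(out_dir / "truth.csv", index=False)
        clinical.to_csv(out_dir / "clinical.csv", index=False)
        injected.to_csv(out_dir / "injected.csv", index=False)
        (out_dir / "cohort_spec.json").write_text(
            json.dumps(
                {
                    "n_patients": cs.n_patients,
                    "spots_per_patient": cs.spots_per_patient,
                    "seed": int(seed),
                    "base_spec": json.loads(cs.base_spec.to_json()),
                    "survival_link": cs.survival_link,
                },
                indent=2,
            )
        )
    return out
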