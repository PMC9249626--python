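"""Shared fixtures: expensive renders and pipeline runs computed once."""

import numpy as np
import pytest

from ishquant import pipeline, synthetic as syn


@pytest.fixture(scope="session")
def trained_model():
    """QDA model trained on two ground-truth-annotated synthetic spots."""
    cfg = pipeline.PipelineConfig()
    spots = []
    for i in range(2):
        image, truth, _, _ = syn.render_spot(syn.SyntheticSpotSpec(seed=100 + i))
        spots.append({"image": image, "truth": truth})
    return pipeline.train_from_spots(cfg, spots)


@pytest.fixture(scope="session")
def default_spot():
    """One default 200-cell spot (seed fixed) with full ground truth."""
    spec = syn.SyntheticSpotSpec(seed=7)
    image, truth, table, extras = syn.render_spot(spec)
    return {"spec": spec, "image": image, "truth": truth, "table": table, "extras": extras}


@pytest.fixture(scope="session")
def default_spot_run(default_spot, trained_model):
    """Full pipeline result on the default spot."""
    cfg = pipeline.PipelineConfig()
    res = pipeline.run_spot(cfg, default_spot["image"], trained_model, "s7", "P0")
    return res


@pytest.fixture(scope="session")
def occluded_spot():
    """High-abundance stress spot: ~30% of nuclear area occluded by dots."""
    spec = syn.SyntheticSpotSpec.occluded(seed=2)
    image, truth, table, extras = syn.render_spot(spec)
    return {"spec": spec, "image": image, "truth": truth, "table": table, "extras": extras}


@pytest.fixture(scope="session")
def small_spot():
    """A small, quick spot for round-trip style tests."""
    spec = syn.SyntheticSpotSpec(
        image_size=(512, 512),
        counts={"cancer": 30, "immune": 35, "stromal": 35},
        seed=1,
    )
    image, truth, table, extras = syn.render_spot(spec)
    return {"spec": spec, "image": image, "truth": truth, "table": table, "extras": extras}


@pytest.fixture(scope="session")
def cohort_n90():
    """The survival-linked synthetic cohort processed end to end (n = 90).

    Hazard is linked to the injected cell-to-cell variability (negative
    binomial dispersion), not to the mean expression.
    """
    cs = syn.CohortSpec(n_patients=90, spots_per_patient=2, survival_link="variability")
    cohort = syn.generate_cohort(cs, seed=0)
    cfg = pipeline.PipelineConfig(qc=False)
    out = pipeline.run_cohort_frames(cfg, cohort["spots"], cohort["clinical"])
    return {"cohort": cohort, "result": out}


def otsu_criterion_curve(values, nbins=256, value_range=None):
    """Independent exhaustive Otsu criterion: per-split inter-class variance.

    Returns (edges, crit) where crit[t] scores background bins [0..t]; invalid
    splits are -inf.
    """
    v = np.asarray(values, float).ravel()
    if value_range is None:
        value_range = (v.min(), v.max())
    hist, edges = np.histogram(v, bins=nbins, range=value_range)
    p = hist / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    crit = np.full(nbins - 1, -np.inf)
    for t in range(nbins - 1):
        w0 = p[: t + 1].sum()
        w1 = p[t + 1 :].sum()
        if w0 <= 0 or w1 <= 0:
            continue
        mu0 = (p[: t + 1] * centers[: t + 1]).sum() / w0
        mu1 = (p[t + 1 :] * centers[t + 1 :]).sum() / w1
        crit[t] = w0 * w1 * (mu0 - mu1) ** 2
    return edges, crit


def brute_force_otsu(values, nbins=256, value_range=None):
    """Lowest exhaustive maximizer of the Otsu criterion."""
    edges, crit = otsu_criterion_curve(values, nbins, value_range)
    return edges[int(np.argmax(crit)) + 1]


def renyi_criterion_curve(values, alpha, nbins=256):
    """Independent exhaustive Renyi-entropy criterion per split point."""
    hist, edges = np.histogram(np.asarray(values).ravel(), bins=nbins, range=(0, 1))
    p = hist / hist.sum()
    crit = np.full(nbins - 1, -np.inf)
    for t in range(nbins - 1):
        pb = p[: t + 1].sum()
        pf = p[t + 1 :].sum()
        if pb <= 0 or pf <= 0:
            continue
        qb = p[: t + 1][p[: t + 1] > 0] / pb
        qf = p[t + 1 :][p[t + 1 :] > 0] / pf
        if abs(alpha - 1.0) < 1e-8:
            hb = -np.sum(qb * np.log(qb))
            hf = -np.sum(qf * np.log(qf))
        else:
            hb = np.log(np.sum(qb**alpha)) / (1.0 - alpha)
            hf = np.log(np.sum(qf**alpha)) / (1.0 - alpha)
        crit[t] = hb + hf
    return edges, crit


def brute_force_renyi(values, alpha, nbins=256):
    """Lowest exhaustive maximizer of the Renyi criterion."""
    edges, crit = renyi_criterion_curve(values, alpha, nbins)
    return edges[int(np.argmax(crit)) + 1]


def assert_is_maximizer(threshold, edges, crit, tol=1e-9):
    """The implementation's threshold must attain the oracle's maximal
    criterion value (plateau ties are equivalent maximizers)."""
    t = int(np.searchsorted(edges, threshold) - 1)
    t = min(max(t, 0), crit.size - 1)
    best = np.max(crit)
    assert crit[t] >= best - tol * max(1.0, abs(best)), (threshold, crit[t], best)
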