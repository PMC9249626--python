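"""Pipeline orchestration: stage sequence over spots and cohorts.

Chromogenic mode runs demultiplex -> restore -> segment -> classify ->
smooth -> expand -> mask -> integrate per spot; fluorescent mode receives
pre-separated channels and skips demultiplexing and restoration. Cohort runs
add positive-control QC, patient summaries, variability factors, nested
ANOVA and survival grouping, all written as CSV next to a manifest keyed by
the config hash so completed runs are not recomputed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import classification, demux, quantification, restoration, segmentation, stats
from . import survival as surv

log = logging.getLogger("ishquant")


@dataclass
class PipelineConfig:
    mode: str = "chromogenic"  # or "fluorescent"
    stain_hematoxylin: tuple = tuple(demux.HEMATOXYLIN)
    stain_dab: tuple = tuple(demux.DAB)
    renyi_alpha: float = 0.5
    saturation_od: float = demux.DEFAULT_SATURATION_OD
    void_dilation_radius: float = 2.0
    tile_size: int = segmentation.DEFAULT_TILE_SIZE
    smoothing_scale: float = segmentation.DEFAULT_SMOOTHING_SCALE
    min_diameter: float = segmentation.DEFAULT_MIN_DIAMETER
    max_diameter: float = segmentation.DEFAULT_MAX_DIAMETER
    spatial_smoothing: bool = True
    smoothing_radius: float = 100.0
    expansion_radii: dict = field(
        default_factory=lambda: dict(classification.DEFAULT_EXPANSION_RADII)
    )
    mask_seed_threshold: float = quantification.DEFAULT_SEED_THRESHOLD
    mask_radius: float = quantification.DEFAULT_MASK_RADIUS
    restoration: bool = True
    qc: bool = True
    fluor_bounds: tuple = (0.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("chromogenic", "fluorescent"):
            raise ValueError("mode must be 'chromogenic' or 'fluorescent'")
        if any(r <= 0 for r in self.expansion_radii.values()):
            raise ValueError("expansion radii must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=list)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]

    @property
    def stains(self) -> demux.StainMatrix:
        return demux.StainMatrix(
            np.asarray(self.stain_hematoxylin), np.asarray(self.stain_dab)
        )


def run_spot(
    config: PipelineConfig,
    image: np.ndarray,
    model: classification.QDAModel,
    spot_id: str = "",
    patient_id: str = "",
) -> dict:
    """All stages on one spot image; returns the cell table and intermediates.

    An empty segmentation yields an empty table and a warning, not an error.
    """
    if config.mode == "fluorescent":
        # image is (rows, cols, 2): marker channel, nuclear channel
        marker = demux.scale_fluorescent(image[..., 0], *config.fluor_bounds)
        nucleus = np.asarray(image[..., 1], float)
        try:
            thr = demux.renyi_threshold(marker, config.renyi_alpha)
            marker, marker_mask = demux.suppress_background(marker, thr)
        except Exception:
            marker_mask = np.zeros(marker.shape, bool)
        channels = demux.StainChannels(
            nucleus=nucleus, marker=marker, marker_od=marker, marker_mask=marker_mask
        )
    else:
        channels = demux.demux_spot(
            image,
            stains=config.stains,
            alpha=config.renyi_alpha,
            saturation_od=config.saturation_od,
        )
        nucleus = channels.nucleus
    if config.restoration and config.mode == "chromogenic" and channels.marker_mask.any():
        if channels.marker_mask.all():
            warnings.warn(f"spot {spot_id}: marker covers everything; restoration skipped")
            restored = nucleus
        else:
            restored, _ = restoration.restore_nucleus(
                nucleus, channels.marker_mask, config.void_dilation_radius
            )
    else:
        restored = nucleus

    rescaled = segmentation.rescale_channel(restored)
    mask = segmentation.adaptive_otsu_mask(rescaled, config.tile_size, config.smoothing_scale)
    labels = segmentation.declump_by_shape(mask, config.min_diameter)
    labels = segmentation.filter_by_size(labels, config.min_diameter, config.max_diameter)

    feats = classification.extract_features(labels, rescaled)
    if len(feats) == 0:
        warnings.warn(f"spot {spot_id}: empty segmentation")
        table = quantification.integrate_cell_signal(
            np.zeros_like(labels), channels.marker, spot_id=spot_id, patient_id=patient_id
        )
        return {
            "cells": table, "labels": labels, "expanded": labels,
            "channels": channels, "restored": restored, "features": feats,
            "classes": pd.Series(dtype=object), "posteriors": pd.DataFrame(),
        }
    logpost = classification.log_posteriors(model, feats)
    if config.spatial_smoothing:
        post, classes = classification.spatial_smooth(
            logpost, feats, labels, config.smoothing_radius, assume_log=True
        )
    else:
        post = np.exp(logpost)
        classes = classification.classify(post)
    class_of = pd.Series(classes.to_numpy(), index=feats["cell_id"].to_numpy())
    expandable = class_of[class_of.isin(list(config.expansion_radii))]
    expanded = classification.expand_segments(labels, expandable, config.expansion_radii)

    excl = quantification.mask_nonspecific(
        channels.marker, config.mask_seed_threshold, config.mask_radius
    )
    table = quantification.integrate_cell_signal(
        expanded, channels.marker, excl,
        cell_classes=class_of.to_dict(), spot_id=spot_id, patient_id=patient_id,
    )
    log.info("spot %s: %d cells (%d cancer)", spot_id, len(table),
             int((table["cell_class"] == "cancer").sum()))
    return {
        "cells": table, "labels": labels, "expanded": expanded,
        "channels": channels, "restored": restored, "features": feats,
        "classes": class_of, "posteriors": post, "exclusion": excl,
    }


def match_to_truth(features: pd.DataFrame, truth_label_map: np.ndarray, truth_classes: dict):
    """Ground-truth class of each detected cell by centroid lookup (None if
    the centroid falls outside every true nucleus)."""
    out = []
    for _, row in features.iterrows():
        r = int(round(row["centroid_row"]))
        c = int(round(row["centroid_col"]))
        r = min(max(r, 0), truth_label_map.shape[0] - 1)
        c = min(max(c, 0), truth_label_map.shape[1] - 1)
        lab = int(truth_label_map[r, c])
        out.append(truth_classes.get(lab) if lab else None)
    return pd.Series(out, index=features.index)


def train_from_spots(
    config: PipelineConfig, spots: list[dict], min_per_class: int = 20
) -> classification.QDAModel:
    """Fit the QDA classifier from ground-truth-annotated synthetic spots.

    Runs demultiplex/restore/segment on each training spot, labels detected
    cells by their ground-truth class at the centroid, and fits the model
    with uniform priors once every class has enough examples.
    """
    frames = []
    for s in spots:
        channels = demux.demux_spot(
            s["image"], stains=config.stains, alpha=config.renyi_alpha,
            saturation_od=config.saturation_od,
        )
        nucleus = channels.nucleus
        if config.restoration and channels.marker_mask.any() and not channels.marker_mask.all():
            nucleus, _ = restoration.restore_nucleus(
                nucleus, channels.marker_mask, config.void_dilation_radius
            )
        rescaled = segmentation.rescale_channel(nucleus)
        m = segmentation.adaptive_otsu_mask(rescaled, config.tile_size, config.smoothing_scale)
        labels = segmentation.filter_by_size(
            segmentation.declump_by_shape(m, config.min_diameter),
            config.min_diameter, config.max_diameter,
        )
        feats = classification.extract_features(labels, rescaled)
        feats["class"] = match_to_truth(feats, s["truth"].label_map, s["truth"].classes)
        frames.append(feats.dropna(subset=["class"]))
        pooled = pd.concat(frames, ignore_index=True)
        counts = pooled["class"].value_counts()
        if len(counts) >= 3 and (counts >= min_per_class).all():
            break
    pooled = pd.concat(frames, ignore_index=True)
    return classification.fit_qda(pooled, pooled["class"])


def run_cohort_frames(
    config: PipelineConfig,
    spots: list[dict],
    clinical: pd.DataFrame,
    model: classification.QDAModel | None = None,
    ppib_means: pd.Series | None = None,
    split_on: str = "varfactor",
) -> dict:
    """Cohort analysis over in-memory spots: tables, QC, summaries, survival.

    ``spots`` entries need image/patient_id/spot_id (plus truth for
    training when no model is given). Returns cell tables, spot and patient
    summaries, the variability-factor fit, nested ANOVA, and median-split
    survival results on both the average expression and the variability
    factor.
    """
    if model is None:
        model = train_from_spots(config, spots)
    tables = []
    for s in spots:
        res = run_spot(config, s["image"], model, s["spot_id"], s["patient_id"])
        tables.append(res["cells"])
    cells = pd.concat(tables, ignore_index=True)
    spot_summary = stats.summarize(cells, by="spot_id")

    if config.qc:
        if ppib_means is None:
            ppib_means = spot_summary.set_index("spot_id")["m"]
        qc = quantification.spot_qc(ppib_means)
        passed = set(qc.loc[qc["passed"], "spot_id"])
        kept = cells[cells["spot_id"].isin(passed)]
    else:
        qc = None
        kept = cells

    patient_summary = stats.summarize(kept, by="patient_id")
    patient_summary = patient_summary.set_index("patient_id")
    try:
        fit = stats.fit_variability_factor(patient_summary)
        patient_summary["varfactor"] = fit.factors
    except ValueError as e:
        warnings.warn(f"variability factor not estimable: {e}")
        fit = None
        patient_summary["varfactor"] = np.nan

    records = clinical.rename(columns={"pfi_months": "time", "pfi_event": "event"})[
        ["patient_id", "time", "event"]
    ]
    records = records[records["patient_id"].isin(patient_summary.index)]
    results = {}
    for name, col in (("mean", "m"), ("varfactor", "varfactor")):
        try:
            if patient_summary[col].isna().any():
                raise ValueError(f"{col} not available for all patients")
            results[name] = surv.median_split(patient_summary[col], records)
        except ValueError as e:
            results[name] = e

    # variance decomposition of per-cell mean intensity: patient > spot
    anova = None
    cancer = kept[kept["cell_class"] == "cancer"]
    if len(cancer) and cancer["patient_id"].nunique() >= 2:
        anova = stats.nested_anova(
            (cancer["intensity"] / cancer["area"]).to_numpy(),
            cancer[["patient_id", "spot_id"]],
        )
    return {
        "model": model,
        "cells": cells,
        "spot_summary": spot_summary,
        "patient_summary": patient_summary.reset_index(),
        "varfactor_fit": fit,
        "qc": qc,
        "splits": results,
        "anova": anova,
    }


def run_cohort_dir(config: PipelineConfig, cohort_dir, out_dir, split_on="varfactor") -> dict:
    """Directory-based cohort run with manifest-keyed resumability."""
    cohort_dir, out_dir = Path(cohort_dir), Path(out_dir)
    spot_files = sorted((cohort_dir / "spots").glob("*.png")) + sorted(
        (cohort_dir / "spots").glob("*.tif*")
    )
    if not spot_files:
        raise FileNotFoundError(f"no spot images under {cohort_dir / 'spots'}")
    clinical_path = cohort_dir / "clinical.csv"
    if not clinical_path.exists():
        raise FileNotFoundError("clinical.csv missing from cohort directory")
    clinical = pd.read_csv(clinical_path)
    missing = {"patient_id", "pfi_months", "pfi_event"} - set(clinical.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")

    manifest_path = out_dir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        if manifest.get("config_hash") == config.config_hash and (
            out_dir / "patient_summary.csv"
        ).exists():
            log.info("cohort already complete for this config; reusing outputs")
            return {
                "cells": pd.read_csv(out_dir / "cells.csv"),
                "spot_summary": pd.read_csv(out_dir / "spot_summary.csv"),
                "patient_summary": pd.read_csv(out_dir / "patient_summary.csv"),
                "reused": True,
            }

    spots = []
    for f in spot_files:
        img = np.asarray(Image.open(f), dtype=float) / 255.0
        sid = f.stem
        pid = sid.split("_")[0]
        spots.append({"image": img, "spot_id": sid, "patient_id": pid})

    model_path = cohort_dir / "qda_model.json"
    if not model_path.exists():
        raise FileNotFoundError(
            "qda_model.json not found; train a classifier first (train-classifier)"
        )
    model = classification.QDAModel.from_json(model_path.read_text())

    out = run_cohort_frames(config, spots, clinical, model=model, split_on=split_on)
    out_dir.mkdir(parents=True, exist_ok=True)
    out["cells"].to_csv(out_dir / "cells.csv", index=False)
    out["spot_summary"].to_csv(out_dir / "spot_summary.csv", index=False)
    out["patient_summary"].to_csv(out_dir / "patient_summary.csv", index=False)
    if out["qc"] is not None:
        out["qc"].to_csv(out_dir / "qc.csv", index=False)
    split_rows = []
    for name, res in out["splits"].items():
        if isinstance(res, Exception):
            continue
        split_rows.append(
            {"split_on": name, "nominal_p": res.nominal_p,
             "adjusted_p": res.adjusted_p, "statistic": res.statistic}
        )
    pd.DataFrame(split_rows).to_csv(out_dir / "survival_splits.csv", index=False)
    if out.get("anova") is not None:
        out["anova"].to_csv(out_dir / "anova.csv", index=False)
    from . import __version__

    manifest_path.write_text(
        json.dumps(
            {
                "config_hash": config.config_hash,
                "n_spots": len(spots),
                "version": __version__,
            },
            indent=2,
        )
    )
    return out
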