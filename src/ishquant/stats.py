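"""Expression summaries, the variability factor, nested ANOVA and precision.

The spot/patient summary statistics weight each cell's mean intensity by its
area, so large carcinoma cells (whose average is reliably quantified)
dominate and residual small artifacts are weighed out:

    m = sum_i Intensity_i / sum_i Area_i
    v = sum_i (Area_i / sum Area) * (Intensity_i / Area_i - m)^2

Because variance and mean are naturally coupled, expression variability is
summarized by a mean-independent *variability factor*: the residual of an
ordinary least-squares fit of log10 v on log10 m across samples. This
generalizes the Fano factor (variance-to-mean ratio) to a fitted non-unit
power law v = c * m^beta; a sample's factor is how far its variance sits
above or below the power law at its own mean.

The nested ANOVA decomposes cell- or spot-level expression variance over a
patient > phase > spot hierarchy with streaming group means — a single pass
per nesting level — instead of a dense design matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


class EmptySummaryError(ValueError):
    pass


def weighted_mean(cells: pd.DataFrame) -> float:
    """Area-weighted mean cell intensity m = sum(intensity) / sum(area)."""
    if len(cells) == 0 or not (cells["area"] > 0).any():
        raise EmptySummaryError("no cells for summary")
    return float(cells["intensity"].sum() / cells["area"].sum())


def weighted_variance(cells: pd.DataFrame, m: float | None = None) -> float:
    """Area-weighted variance of per-cell mean intensity around m."""
    if len(cells) == 0 or not (cells["area"] > 0).any():
        raise EmptySummaryError("no cells for summary")
    if m is None:
        m = weighted_mean(cells)
    w = cells["area"] / cells["area"].sum()
    x = cells["intensity"] / cells["area"]
    return float(np.sum(w * (x - m) ** 2))


def summarize(cells: pd.DataFrame, by: str, classes=("cancer",)) -> pd.DataFrame:
    """Per-group (spot or patient) weighted mean/variance over given classes."""
    sel = cells[cells["cell_class"].isin(classes)] if "cell_class" in cells else cells
    rows = []
    for key, grp in sel.groupby(by):
        try:
            m = weighted_mean(grp)
            v = weighted_variance(grp, m)
        except EmptySummaryError:
            continue
        row = {by: key, "m": m, "v": v, "n_cells": len(grp)}
        if by == "spot_id" and "patient_id" in grp:
            row["patient_id"] = grp["patient_id"].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class VarFactorFit:
    """OLS fit of log10 v on log10 m and its residuals (variability factors)."""

    intercept: float
    slope: float
    factors: pd.Series  # variability factor per sample (index preserved)
    n_excluded: int = 0
    excluded_index: list = field(default_factory=list)


def fit_variability_factor(samples: pd.DataFrame) -> VarFactorFit:
    """Regress out the mean effect from the raw variance in log10 space.

    ``samples`` needs columns m and v. Samples with m <= 0 or v <= 0 cannot
    enter the log-space fit; they are excluded, reported, and assigned the
    minimum observed factor.
    """
    usable = samples[(samples["m"] > 0) & (samples["v"] > 0)]
    excluded = samples.index.difference(usable.index)
    if len(excluded):
        warnings.warn(
            f"{len(excluded)} samples with non-positive m or v excluded from the "
            "variability fit; assigned the minimum observed factor"
        )
    if len(usable) < 3:
        raise ValueError("need at least 3 samples with m > 0 and v > 0")
    lm = np.log10(usable["m"].to_numpy(float))
    lv = np.log10(usable["v"].to_numpy(float))
    if np.ptp(lm) == 0:
        raise ValueError("mean effect unidentifiable: zero spread in log m")
    slope, intercept = np.polyfit(lm, lv, 1)
    resid = lv - (intercept + slope * lm)
    factors = pd.Series(resid, index=usable.index)
    if len(excluded):
        factors = pd.concat(
            [factors, pd.Series(resid.min(), index=excluded)]
        ).reindex(samples.index)
    return VarFactorFit(
        intercept=float(intercept),
        slope=float(slope),
        factors=factors,
        n_excluded=len(excluded),
        excluded_index=list(excluded),
    )


def nested_anova(values, factors: pd.DataFrame) -> pd.DataFrame:
    """ANOVA of a fully nested factorial design via streaming group means.

    ``factors`` columns are ordered outermost to innermost (e.g. patient,
    phase, spot); each inner factor is nested inside all outer ones. Sums of
    squares come from one pass of group means per nesting level (linear time
    in the number of observations); each factor's F is tested against the
    residual mean square. Degenerate levels yield NaN F values, flagged via
    the ``estimable`` column.
    """
    y = np.asarray(values, float)
    if factors.ndim == 1:
        factors = factors.to_frame()
    factors = factors.reset_index(drop=True)
    n = y.size
    if len(factors) != n:
        raise ValueError("values and factors must align")
    grand = y.mean()
    rows = []
    # mean of y within each nesting prefix, broadcast back to observations
    prev_fit = np.full(n, grand)
    prev_df = 1
    df_used = 1
    for depth in range(1, factors.shape[1] + 1):
        keys = [factors.iloc[:, j] for j in range(depth)]
        grp = pd.Series(y).groupby(keys, observed=True)
        fit = grp.transform("mean").to_numpy()
        n_groups = grp.ngroups
        ss = float(np.sum((fit - prev_fit) ** 2))
        df = n_groups - df_used
        rows.append(
            {"factor": factors.columns[depth - 1], "ss": ss, "df": df}
        )
        prev_fit = fit
        df_used = n_groups
    ss_resid = float(np.sum((y - prev_fit) ** 2))
    df_resid = n - df_used
    ms_resid = ss_resid / df_resid if df_resid > 0 else np.nan
    out = []
    for r in rows:
        estimable = r["df"] > 0
        ms = r["ss"] / r["df"] if estimable else np.nan
        if estimable and df_resid > 0 and ms_resid > 0:
            f = ms / ms_resid
            p = float(sps.f.sf(f, r["df"], df_resid))
        else:
            f, p = np.nan, np.nan
        out.append({**r, "ms": ms, "F": f, "p": p, "estimable": estimable})
    out.append(
        {
            "factor": "residual",
            "ss": ss_resid,
            "df": df_resid,
            "ms": ms_resid,
            "F": np.nan,
            "p": np.nan,
            "estimable": df_resid > 0,
        }
    )
    return pd.DataFrame(out)


@dataclass
class PrecisionResult:
    tp: int
    fp: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp)


def precision_score(annotated, predicted, positive: str = "cancer") -> PrecisionResult:
    """Precision = TP / (TP + FP) of the positive-class calls.

    ``annotated`` and ``predicted`` are aligned class labels; TP counts
    predicted positives whose annotation is also positive.
    """
    annotated = np.asarray(annotated)
    predicted = np.asarray(predicted)
    if annotated.shape != predicted.shape:
        raise ValueError("annotated and predicted labels must align")
    called = predicted == positive
    tp = int(np.sum(called & (annotated == positive)))
    fp = int(np.sum(called & (annotated != positive)))
    if tp + fp == 0:
        raise ValueError("undefined precision: no predicted positives")
    return PrecisionResult(tp=tp, fp=fp)
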