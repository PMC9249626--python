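"""Survival analysis: Kaplan-Meier, log-rank, and expression grouping.

Patients are grouped by a per-patient expression summary (average expression
or variability factor) either at the median or by an optimized three-way
split: candidate threshold pairs on a rank-fraction lattice are each scored
with a log-rank test, the family of nominal p-values is Benjamini-Hochberg
adjusted (controlling for the optimization itself), and the split with the
smallest adjusted p is chosen.

Kaplan-Meier estimation and the k-group log-rank statistic are delegated to
lifelines; BH adjustment to statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from statsmodels.stats.multitest import multipletests

REQUIRED_COLUMNS = ("time", "event")


def _check_records(records: pd.DataFrame):
    for c in REQUIRED_COLUMNS:
        if c not in records:
            raise ValueError(f"records missing column {c!r}")
    if (records["time"] < 0).any():
        raise ValueError("negative survival times")


def km_estimate(records: pd.DataFrame, group_col: str = "group") -> dict[str, pd.DataFrame]:
    """Product-limit survival curve per group.

    Returns, per group, a DataFrame with columns time and survival
    (right-continuous step function; censored records shrink the risk set
    without a step).
    """
    _check_records(records)
    out = {}
    for g, grp in records.groupby(group_col):
        if len(grp) == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(grp["time"], grp["event"].astype(bool))
        sf = kmf.survival_function_
        out[g] = pd.DataFrame(
            {"time": sf.index.to_numpy(float), "survival": sf.iloc[:, 0].to_numpy(float)}
        )
    return out


def logrank(records: pd.DataFrame, group_col: str = "group") -> tuple[float, float]:
    """K-group log-rank test (chi-square with k-1 df) over pooled event times."""
    _check_records(records)
    groups = records[group_col]
    if groups.nunique() < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    if not records["event"].astype(bool).any():
        raise ValueError("test undefined: no events")
    res = multivariate_logrank_test(
        records["time"], groups, records["event"].astype(bool)
    )
    return float(res.test_statistic), float(res.p_value)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment of a p-value family."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class SplitResult:
    thresholds: tuple  # expression values at the chosen cut(s)
    fractions: tuple  # group-size fractions, low to high
    groups: pd.Series  # patient -> group label
    nominal_p: float
    adjusted_p: float
    statistic: float
    candidates: pd.DataFrame = field(default_factory=pd.DataFrame)


def _merge(values: pd.Series, records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    df = df.set_index("patient_id") if "patient_id" in df else df
    df = df.loc[values.index]
    df["value"] = values
    return df


def median_split(values: pd.Series, records: pd.DataFrame) -> SplitResult:
    """Two groups at the median; a patient exactly at the median is 'low'."""
    if len(values) < 2:
        raise ValueError("need at least 2 patients")
    if values.nunique() <= 1:
        raise ValueError("all expression values equal; no split exists")
    med = float(values.median())
    df = _merge(values, records)
    df["group"] = np.where(df["value"] <= med, "low", "high")
    stat, p = logrank(df)
    frac_low = float((df["group"] == "low").mean())
    return SplitResult(
        thresholds=(med,),
        fractions=(frac_low, 1.0 - frac_low),
        groups=df["group"],
        nominal_p=p,
        adjusted_p=p,
        statistic=stat,
    )


def candidate_fraction_grid(max_candidates: int = 20, step: float = 0.05):
    """(f1, f2) cut-fraction pairs on a 5% lattice over (20%, 80%), f1 < f2,
    enumerated in (f1, f2) order and truncated to ``max_candidates``."""
    lattice = np.round(np.arange(0.20, 0.80 + 1e-9, step), 10)
    pairs = [(a, b) for a in lattice for b in lattice if a < b]
    return pairs[:max_candidates] if max_candidates else pairs


def optimize_three_way_split(
    values: pd.Series,
    records: pd.DataFrame,
    fraction_pairs=None,
    max_candidates: int = 20,
) -> SplitResult:
    """Optimized three-way expression grouping with BH multiplicity control.

    Each candidate (f1, f2) cuts the ascending expression ranks into
    low/intermediate/high groups (ties at a threshold stay in the lower
    group); every candidate's log-rank p is computed, the family is BH
    adjusted with family size = number of evaluated candidates, and the
    split with the smallest adjusted p wins (ties -> smaller first cut).
    """
    if fraction_pairs is None:
        fraction_pairs = candidate_fraction_grid(max_candidates)
    df = _merge(values, records)
    n = len(df)
    order = df["value"].sort_values(kind="mergesort")
    rows = []
    for f1, f2 in fraction_pairs:
        k1 = int(round(f1 * n))
        k2 = int(round(f2 * n))
        if not (0 < k1 < k2 < n):
            continue
        t1 = float(order.iloc[k1 - 1])
        t2 = float(order.iloc[k2 - 1])
        group = pd.Series(
            np.where(df["value"] <= t1, "low", np.where(df["value"] <= t2, "mid", "high")),
            index=df.index,
        )
        sizes = group.value_counts()
        if len(sizes) < 3:
            continue
        tmp = df.assign(group=group)
        stat, p = logrank(tmp)
        rows.append(
            {
                "f1": f1, "f2": f2, "t1": t1, "t2": t2,
                "nominal_p": p, "statistic": stat,
                "n_low": int(sizes.get("low", 0)),
                "n_mid": int(sizes.get("mid", 0)),
                "n_high": int(sizes.get("high", 0)),
            }
        )
    if not rows:
        raise ValueError("no candidate split yields three non-empty groups")
    cand = pd.DataFrame(rows)
    cand["adjusted_p"] = bh_adjust(cand["nominal_p"].to_numpy())
    best = cand.sort_values(["adjusted_p", "t1"], kind="mergesort").iloc[0]
    group = pd.Series(
        np.where(
            df["value"] <= best["t1"], "low",
            np.where(df["value"] <= best["t2"], "mid", "high"),
        ),
        index=df.index,
    )
    return SplitResult(
        thresholds=(float(best["t1"]), float(best["t2"])),
        fractions=(
            best["n_low"] / n, best["n_mid"] / n, best["n_high"] / n,
        ),
        groups=group,
        nominal_p=float(best["nominal_p"]),
        adjusted_p=float(best["adjusted_p"]),
        statistic=float(best["statistic"]),
        candidates=cand,
    )
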