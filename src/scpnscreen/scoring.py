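"""Well summaries, the refinement ratio, normalizations, and replicate stats.

The screen's primary statistic is the refinement ratio

    R = n(A+ / B-) / n(A+ / B+)

for the marker pair (A, B) = (CTIP2, SATB2): the count of refined
CTIP2-only nuclei over the count of immature dual expressors. Counts are
pooled across all fields of a well before the ratio is taken (ratio of
pooled counts, not mean of per-field ratios — pooling is stable for rare
categories). A well with no dual expressors has an undefined ratio and is
flagged, never imputed.

Three condition-specific normalizations mirror the screen's readouts:
the ratio is normalized to the mean of the untreated wells, total CTIP2+
counts to the Fezf2-modRNA wells, and total SATB2+ counts to the GFP-modRNA
wells. Replicate comparisons use the two-sided unpaired Student t-test
(pooled variance; Welch available by option) with significance marks at
0.05 and 0.01.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import POSITIVE_CALLS, subtype_column

__all__ = [
    "WellSummary",
    "ConditionStats",
    "summarize_well",
    "summarize_wells",
    "normalize_to_baseline",
    "add_screen_normalizations",
    "composition_proportions",
    "compare_conditions",
    "significance_stars",
]


@dataclass
class WellSummary:
    well: str
    condition: str | None = None
    compound: str | None = None
    dose_um: float | None = None
    replicate: int | None = None
    n_viable: int = 0
    n_a_only: int = 0
    n_b_only: int = 0
    n_dual: int = 0
    n_unlabeled: int = 0
    n_a_total: int = 0  # = n_a_only + n_dual
    n_b_total: int = 0
    ratio: float = math.nan  # undefined (NaN) when n_dual = 0
    ratio_defined: bool = False
    mean_positive_intensity: dict[str, float] | None = None


def summarize_well(nuclei: pd.DataFrame, pair: tuple[str, str] = ("CTIP2", "SATB2"),
                   well: str = "", condition: str | None = None,
                   compound: str | None = None, dose_um: float | None = None,
                   replicate: int | None = None) -> WellSummary:
    """Pool one well's classified viable nuclei into counts and the ratio."""
    a, b = pair
    col = subtype_column(pair)
    if len(nuclei) and col not in nuclei.columns:
        raise ValueError(f"nucleus table lacks subtype column {col!r}")
    sub = nuclei[col] if len(nuclei) else pd.Series(dtype=object)
    n_a_only = int((sub == f"{a.lower()}_only").sum())
    n_b_only = int((sub == f"{b.lower()}_only").sum())
    n_dual = int((sub == "dual").sum())
    n_unlabeled = int((sub == "unlabeled").sum())
    n_viable = len(nuclei)
    ratio = (n_a_only / n_dual) if n_dual > 0 else math.nan
    mean_pos: dict[str, float] = {}
    for marker in pair:
        call_col = f"call_{marker.lower()}"
        if len(nuclei) and call_col in nuclei.columns:
            pos = nuclei[nuclei[call_col].isin(POSITIVE_CALLS)]
            mean_pos[marker] = (float(pos[f"mean_{marker}"].mean())
                                if len(pos) else math.nan)
        else:
            mean_pos[marker] = math.nan
    return WellSummary(
        well=well, condition=condition, compound=compound, dose_um=dose_um,
        replicate=replicate, n_viable=n_viable, n_a_only=n_a_only,
        n_b_only=n_b_only, n_dual=n_dual, n_unlabeled=n_unlabeled,
        n_a_total=n_a_only + n_dual, n_b_total=n_b_only + n_dual,
        ratio=ratio, ratio_defined=n_dual > 0,
        mean_positive_intensity=mean_pos,
    )


def summarize_wells(nuclei: pd.DataFrame, plate_map: pd.DataFrame,
                    pair: tuple[str, str] = ("CTIP2", "SATB2")) -> pd.DataFrame:
    """One summary row per plate-map well (wells with no nuclei included)."""
    rows = []
    groups = dict(tuple(nuclei.groupby("well", sort=False))) if len(nuclei) else {}
    for _, w in plate_map.iterrows():
        sub = groups.get(w["well"])
        if sub is None:
            sub = nuclei.iloc[0:0]
        compound = w["compound"]
        if isinstance(compound, float) and math.isnan(compound):
            compound = None
        s = summarize_well(sub, pair=pair, well=w["well"],
                           condition=w["condition"], compound=compound,
                           dose_um=float(w["dose_uM"]),
                           replicate=int(w["replicate"]))
        row = {k: v for k, v in s.__dict__.items()
               if k != "mean_positive_intensity"}
        for marker, v in (s.mean_positive_intensity or {}).items():
            row[f"mean_pos_{marker}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def normalize_to_baseline(values: pd.Series, conditions: pd.Series,
                          baseline_condition: str) -> pd.Series:
    """Divide every value by the mean of the baseline condition's values.

    NaN values (e.g. undefined ratios) are ignored when forming the
    baseline mean and propagate unchanged through the division.
    """
    base = values[conditions == baseline_condition].dropna()
    if base.empty:
        raise ValueError(
            f"baseline condition {baseline_condition!r} has no defined values")
    mean = float(base.mean())
    if mean == 0:
        raise ValueError(f"baseline condition {baseline_condition!r} mean is zero")
    return values / mean


def add_screen_normalizations(well_df: pd.DataFrame,
                              ratio_baseline: str = "untreated",
                              ctip2_baseline: str = "fezf2_modrna",
                              satb2_baseline: str = "gfp_modrna") -> pd.DataFrame:
    """Attach the three screen normalizations to a well-summary table.

    norm_ratio uses the untreated wells, norm_ctip2_total the Fezf2-modRNA
    wells, and norm_satb2_total the GFP-modRNA wells, each as the mean of
    that baseline condition.
    """
    out = well_df.copy()
    cond = out["condition"]
    out["norm_ratio"] = normalize_to_baseline(out["ratio"], cond, ratio_baseline)
    out["norm_ctip2_total"] = normalize_to_baseline(
        out["n_a_total"].astype(float), cond, ctip2_baseline)
    out["norm_satb2_total"] = normalize_to_baseline(
        out["n_b_total"].astype(float), cond, satb2_baseline)
    return out


def composition_proportions(summary: WellSummary) -> tuple[float, float, float, float]:
    """(A-only, B-only, dual, unlabeled) fractions of viable nuclei."""
    if summary.n_viable <= 0:
        raise ValueError("composition undefined for a well with no viable nuclei")
    n = summary.n_viable
    return (summary.n_a_only / n, summary.n_b_only / n,
            summary.n_dual / n, summary.n_unlabeled / n)


def significance_stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class ConditionStats:
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t: float
    df: float
    p: float
    stars: str


def compare_conditions(values_a, values_b, equal_var: bool = True) -> ConditionStats:
    """Two-sided unpaired t-test between two replicate groups.

    Student (pooled variance) by default; Welch with ``equal_var=False``.
    Requires at least two replicates per group. Two identical groups give
    t = 0, p = 1 by convention even when both variances vanish.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 replicates")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate: no within-group variance
        t = 0.0 if a.mean() == b.mean() else math.inf * np.sign(a.mean() - b.mean())
        p = 1.0 if t == 0.0 else 0.0
        df = float(a.size + b.size - 2)
    else:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        t = float(res.statistic)
        p = float(res.pvalue)
        df = float(res.df)
    return ConditionStats(
        n_a=a.size, n_b=b.size,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sem_a=float(sps.sem(a)), sem_b=float(sps.sem(b)),
        t=t, df=df, p=p, stars=significance_stars(p),
    )
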