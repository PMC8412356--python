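"""Three-level candidate triage downstream of toxicity exclusion.

A compound (at each dose, independently) must survive, in order:

* toxicity exclusion — any replicate well graded moderate/severe removes
  the compound-dose from further consideration;
* L1, ratio enhancement — normalized refinement ratio strictly greater
  than ``min_norm_ratio``;
* L2, CTIP2 preservation — normalized total CTIP2+ count at least
  ``min_norm_ctip2`` (a small tolerance below 1 so true maintainers are
  not rejected by counting noise);
* L3, SATB2 reduction — normalized total SATB2+ count at most
  ``max_norm_satb2``.

Survivors are hits, ranked by descending normalized ratio with ties broken
by ascending normalized SATB2 total, then lexicographic compound id.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "TriageCriteria",
    "CandidateRecord",
    "STAGES",
    "run_triage",
    "triage_report",
    "records_to_frame",
]

STAGES = ("excluded_toxicity", "failed_L1", "failed_L2", "failed_L3", "hit")
_GRADE_ORDER = {"none": 0, "moderate": 1, "severe": 2}
_REQUIRED = ("compound", "dose_um", "qc_grade",
             "norm_ratio", "norm_ctip2_total", "norm_satb2_total")


class TriageCriteria(BaseModel):
    model_config = ConfigDict(frozen=True)
    min_norm_ratio: float = Field(default=1.0, ge=0)
    min_norm_ctip2: float = Field(default=0.8, ge=0)
    max_norm_satb2: float = Field(default=1.0, ge=0)


@dataclass
class CandidateRecord:
    compound: str
    dose_um: float
    qc_grade: str
    norm_ratio: float
    norm_ctip2_total: float
    norm_satb2_total: float
    stage_reached: str
    rank: int | None = None  # among hits only


def run_triage(well_df: pd.DataFrame,
               criteria: TriageCriteria | None = None) -> list[CandidateRecord]:
    """Triage every (compound, dose) from a normalized well-summary table.

    Replicate wells of a compound-dose are aggregated by the mean of each
    normalized metric (wells with undefined ratios are ignored in the
    ratio mean) and by the worst QC grade. A compound-dose whose ratio is
    undefined in every replicate fails L1.
    """
    criteria = criteria or TriageCriteria()
    missing = [c for c in _REQUIRED if c not in well_df.columns]
    if missing:
        raise ValueError(f"well summaries lack required columns: {missing}")
    rows = well_df[well_df["compound"].notna()]
    records: list[CandidateRecord] = []
    for (compound, dose), grp in rows.groupby(["compound", "dose_um"], sort=True):
        grade = max(grp["qc_grade"], key=lambda g: _GRADE_ORDER.get(g, 2))
        nr = float(grp["norm_ratio"].mean(skipna=True))
        nc = float(grp["norm_ctip2_total"].mean(skipna=True))
        ns = float(grp["norm_satb2_total"].mean(skipna=True))
        if grade != "none":
            stage = "excluded_toxicity"
        elif not (nr > criteria.min_norm_ratio):  # NaN fails
            stage = "failed_L1"
        elif not (nc >= criteria.min_norm_ctip2):
            stage = "failed_L2"
        elif not (ns <= criteria.max_norm_satb2):
            stage = "failed_L3"
        else:
            stage = "hit"
        records.append(CandidateRecord(
            compound=str(compound), dose_um=float(dose), qc_grade=grade,
            norm_ratio=nr, norm_ctip2_total=nc, norm_satb2_total=ns,
            stage_reached=stage))
    hits = [r for r in records if r.stage_reached == "hit"]
    hits.sort(key=lambda r: (-r.norm_ratio if not math.isnan(r.norm_ratio) else 0.0,
                             r.norm_satb2_total, r.compound))
    for rank, r in enumerate(hits, start=1):
        r.rank = rank
    return records


def triage_report(records: list[CandidateRecord]) -> dict:
    """Stage-count table plus the ranked hit list (JSON-serializable)."""
    counts = {stage: 0 for stage in STAGES}
    for r in records:
        counts[r.stage_reached] += 1
    hits = sorted((r for r in records if r.stage_reached == "hit"),
                  key=lambda r: r.rank or 0)
    return {
        "n_records": len(records),
        "stage_counts": counts,
        "hits": [asdict(r) for r in hits],
    }


def records_to_frame(records: list[CandidateRecord]) -> pd.DataFrame:
    if not records:
        return pd.DataFrame(columns=["compound", "dose_um", "qc_grade",
                                     "norm_ratio", "norm_ctip2_total",
                                     "norm_satb2_total", "stage_reached", "rank"])
    df = pd.DataFrame([asdict(r) for r in records])
    return df.astype({"rank": "Int64"}) if "rank" in df else df
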