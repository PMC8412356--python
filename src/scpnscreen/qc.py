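"""Per-nucleus viability filtering and per-well toxicity grading.

Viability uses the printed selection criteria with their printed strict
inequalities: a candidate nucleus is viable iff

    area_min < area < area_max  AND  width > width_min  AND
    mean Hoechst < hoechst_max

(defaults 33 um^2 < area < 100 um^2, width > 3.7 um, Hoechst < 900 on the
12-bit scale). Nuclei failing the area ceiling are typically adjacent
double nuclei; nuclei failing the floor are fragments; bright small nuclei
are pyknotic (dying).

The original screen excluded toxic wells by blinded visual inspection;
here that judgment is operationalized quantitatively: a well is graded
severe/moderate when its viable count falls below a fraction of the median
control-well viable count, or when its pyknotic fraction exceeds a cutoff.
Rosette-morphology disruption is deliberately not scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .segment import NucleusCandidate

__all__ = [
    "ViabilityCriteria",
    "ToxicityCutoffs",
    "WellMetrics",
    "WellQCReport",
    "ExcludedCandidate",
    "filter_viable",
    "viability_mask",
    "exclusion_reasons",
    "pyknotic_mask",
    "grade_well_toxicity",
]

GRADES = ("none", "moderate", "severe")


class ViabilityCriteria(BaseModel):
    model_config = ConfigDict(frozen=True)
    area_min: float = Field(default=33.0, gt=0)  # um^2
    area_max: float = Field(default=100.0, gt=0)
    width_min: float = Field(default=3.7, gt=0)  # um
    hoechst_max: float = Field(default=900.0, gt=0)  # intensity units

    @model_validator(mode="after")
    def _check(self) -> "ViabilityCriteria":
        if not self.area_min < self.area_max:
            raise ValueError("area_min must be < area_max")
        return self


class ToxicityCutoffs(BaseModel):
    model_config = ConfigDict(frozen=True)
    severe_count_frac: float = Field(default=0.4, ge=0)
    moderate_count_frac: float = Field(default=0.7, ge=0)
    severe_pyknotic: float = Field(default=0.30, ge=0, le=1)
    moderate_pyknotic: float = Field(default=0.15, ge=0, le=1)


@dataclass
class ExcludedCandidate:
    candidate: NucleusCandidate
    reason: str  # first failing criterion: "area", "width", or "intensity"


@dataclass
class WellMetrics:
    candidate_count: int
    viable_count: int
    pyknotic_fraction: float
    debris_fraction: float = 0.0


@dataclass
class WellQCReport:
    well: str
    candidate_count: int
    viable_count: int
    viable_fraction: float
    pyknotic_fraction: float
    debris_fraction: float
    grade: str


def _viable_one(area: float, width: float, hoechst: float,
                c: ViabilityCriteria) -> str | None:
    """Return None if viable, else the first failing criterion."""
    if not (c.area_min < area < c.area_max):
        return "area"
    if not (width > c.width_min):
        return "width"
    if not (hoechst < c.hoechst_max):
        return "intensity"
    return None


def filter_viable(candidates: list[NucleusCandidate],
                  criteria: ViabilityCriteria | None = None,
                  ) -> tuple[list[NucleusCandidate], list[ExcludedCandidate]]:
    """Partition candidates into viable nuclei and excluded ones with reasons."""
    criteria = criteria or ViabilityCriteria()
    viable: list[NucleusCandidate] = []
    excluded: list[ExcludedCandidate] = []
    for cand in candidates:
        reason = _viable_one(cand.area_um2, cand.width_um,
                             cand.mean_intensity.get("hoechst", 0.0), criteria)
        if reason is None:
            viable.append(cand)
        else:
            excluded.append(ExcludedCandidate(cand, reason))
    return viable, excluded


def viability_mask(df: pd.DataFrame,
                   criteria: ViabilityCriteria | None = None) -> pd.Series:
    """Vectorized viability predicate over a candidate table.

    Expects columns ``area_um2``, ``width_um``, ``mean_hoechst``.
    """
    c = criteria or ViabilityCriteria()
    return ((df["area_um2"] > c.area_min) & (df["area_um2"] < c.area_max)
            & (df["width_um"] > c.width_min)
            & (df["mean_hoechst"] < c.hoechst_max))


def exclusion_reasons(df: pd.DataFrame,
                      criteria: ViabilityCriteria | None = None) -> pd.Series:
    """First failing criterion per row ("" for viable rows)."""
    c = criteria or ViabilityCriteria()
    area_fail = ~((df["area_um2"] > c.area_min) & (df["area_um2"] < c.area_max))
    width_fail = ~(df["width_um"] > c.width_min)
    int_fail = ~(df["mean_hoechst"] < c.hoechst_max)
    reason = np.select(
        [area_fail, width_fail, int_fail],
        ["area", "width", "intensity"],
        default="")
    return pd.Series(reason, index=df.index, name="exclusion_reason")


def pyknotic_mask(df: pd.DataFrame,
                  criteria: ViabilityCriteria | None = None) -> pd.Series:
    """Pyknotic candidates: small (area < area_min) and Hoechst-bright."""
    c = criteria or ViabilityCriteria()
    return (df["area_um2"] < c.area_min) & (df["mean_hoechst"] >= c.hoechst_max)


def grade_well_toxicity(well: str, metrics: WellMetrics,
                        controls: list[WellMetrics],
                        cutoffs: ToxicityCutoffs | None = None) -> WellQCReport:
    """Grade one well against the median control-well viable count.

    severe if viable_count < severe_count_frac x control median OR
    pyknotic_fraction > severe_pyknotic; moderate under the analogous
    looser cutoffs; none otherwise.
    """
    if not controls:
        raise ValueError("toxicity grading requires at least one control well")
    cutoffs = cutoffs or ToxicityCutoffs()
    ctrl_median = float(np.median([c.viable_count for c in controls]))
    if (metrics.viable_count < cutoffs.severe_count_frac * ctrl_median
            or metrics.pyknotic_fraction > cutoffs.severe_pyknotic):
        grade = "severe"
    elif (metrics.viable_count < cutoffs.moderate_count_frac * ctrl_median
          or metrics.pyknotic_fraction > cutoffs.moderate_pyknotic):
        grade = "moderate"
    else:
        grade = "none"
    viable_fraction = (metrics.viable_count / metrics.candidate_count
                       if metrics.candidate_count else 0.0)
    return WellQCReport(
        well=well,
        candidate_count=metrics.candidate_count,
        viable_count=metrics.viable_count,
        viable_fraction=viable_fraction,
        pyknotic_fraction=metrics.pyknotic_fraction,
        debris_fraction=metrics.debris_fraction,
        grade=grade,
    )
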