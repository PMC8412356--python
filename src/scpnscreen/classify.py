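"""Per-nucleus marker-intensity classification and subtype assignment.

Two selectable thresholding policies are implemented:

* ``fixed_bands`` (default): the printed intensity bands per marker
  (CTIP2 low 50-150 / high 150-700, SATB2 low 150-500 / high 500-1500,
  CTIP1 low 50-90 / high 90-400, on the 12-bit scale). Bands are half-open
  [lo, hi); the shared boundary belongs to the high band, and means at or
  above the high ceiling are clamped to high rather than discarded, so the
  brightest expressors are never silently lost.
* ``fraction_of_max``: a per-well, per-marker threshold at a fraction
  (default 0.2) of the maximum per-nucleus mean intensity, the calibration
  appropriate for near-continuum mES-derived populations. Positives are
  reported as ``low`` (no high tier in this mode).

"Positive" means low-or-high; a nucleus is then assigned one of four
subtype calls per ordered marker pair (A, B): A-only, B-only, dual, or
unlabeled. The default pairs are (CTIP2, SATB2) — the refinement axis —
and (CTIP2, CTIP1).
"""

from __future__ import annotations

from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "BandRange",
    "MarkerBands",
    "default_bands",
    "ThresholdPolicy",
    "DEFAULT_PAIRS",
    "POSITIVE_CALLS",
    "calibrate_threshold",
    "classify_marker",
    "classify_marker_array",
    "assign_subtype",
    "subtype_column",
    "classify_nuclei",
]

DEFAULT_PAIRS = (("CTIP2", "SATB2"), ("CTIP2", "CTIP1"))
POSITIVE_CALLS = ("low", "high")


class BandRange(BaseModel):
    model_config = ConfigDict(frozen=True)
    lo: float = Field(ge=0)
    hi: float = Field(ge=0)

    @model_validator(mode="after")
    def _check(self) -> "BandRange":
        if not self.lo < self.hi:
            raise ValueError("band must satisfy lo < hi")
        return self


class MarkerBands(BaseModel):
    """Contiguous low/high bands: low.lo < low.hi = high.lo < high.hi."""

    model_config = ConfigDict(frozen=True)
    low: BandRange
    high: BandRange

    @model_validator(mode="after")
    def _check(self) -> "MarkerBands":
        if self.low.hi != self.high.lo:
            raise ValueError("bands must abut: low.hi must equal high.lo")
        return self


def default_bands() -> dict[str, MarkerBands]:
    b = lambda lo, hi: BandRange(lo=lo, hi=hi)  # noqa: E731
    return {
        "CTIP2": MarkerBands(low=b(50, 150), high=b(150, 700)),
        "SATB2": MarkerBands(low=b(150, 500), high=b(500, 1500)),
        "CTIP1": MarkerBands(low=b(50, 90), high=b(90, 400)),
    }


class ThresholdPolicy(BaseModel):
    model_config = ConfigDict(frozen=True)
    mode: Literal["fixed_bands", "fraction_of_max"] = "fixed_bands"
    fraction: float = Field(default=0.2, gt=0, lt=1)
    bands: dict[str, MarkerBands] = Field(default_factory=default_bands)


def calibrate_threshold(mean_intensities: Sequence[float] | np.ndarray,
                        fraction: float = 0.2) -> float:
    """Positivity threshold = fraction x max of the per-nucleus means.

    Calibrated per well and per marker; raises on an empty list.
    """
    arr = np.asarray(mean_intensities, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot calibrate a threshold from an empty list")
    return float(fraction * arr.max())


def classify_marker_array(means: np.ndarray, marker: str,
                          policy: ThresholdPolicy,
                          threshold: float | None = None) -> np.ndarray:
    """Vectorized negative/low/high calls for one marker."""
    means = np.asarray(means, dtype=float)
    if policy.mode == "fixed_bands":
        if marker not in policy.bands:
            raise ValueError(f"unknown marker {marker!r}")
        b = policy.bands[marker]
        # negative < low.lo <= low < low.hi = high.lo <= high (clamped above)
        return np.select([means < b.low.lo, means < b.low.hi],
                         ["negative", "low"], default="high").astype(object)
    if threshold is None:
        raise ValueError("fraction_of_max mode requires a calibrated threshold")
    return np.where(means < threshold, "negative", "low").astype(object)


def classify_marker(mean: float, marker: str, policy: ThresholdPolicy,
                    threshold: float | None = None) -> str:
    """Classify one nucleus's mean intensity for one marker."""
    return str(classify_marker_array(np.array([mean]), marker, policy,
                                     threshold=threshold)[0])


def assign_subtype(call_a: str, call_b: str) -> str:
    """Pairwise subtype from two marker calls; positive = low or high."""
    a = call_a in POSITIVE_CALLS
    b = call_b in POSITIVE_CALLS
    if a and b:
        return "dual"
    if a:
        return "a_only"
    if b:
        return "b_only"
    return "unlabeled"


def subtype_column(pair: tuple[str, str]) -> str:
    return f"subtype_{pair[0].lower()}_{pair[1].lower()}"


def _named_subtype(generic: np.ndarray, pair: tuple[str, str]) -> np.ndarray:
    a, b = pair
    mapping = {"a_only": f"{a.lower()}_only", "b_only": f"{b.lower()}_only",
               "dual": "dual", "unlabeled": "unlabeled"}
    return np.vectorize(mapping.get, otypes=[object])(generic)


def classify_nuclei(df: pd.DataFrame, policy: ThresholdPolicy | None = None,
                    pairs: Iterable[tuple[str, str]] = DEFAULT_PAIRS,
                    well_col: str = "well") -> pd.DataFrame:
    """Add per-marker calls and per-pair subtype columns to a nucleus table.

    Expects ``mean_<MARKER>`` columns. In fraction_of_max mode the
    threshold is calibrated per well per marker from the rows present.
    """
    policy = policy or ThresholdPolicy()
    pairs = tuple(pairs)
    markers = sorted({m for pair in pairs for m in pair})
    out = df.copy()
    for marker in markers:
        col = f"mean_{marker}"
        if col not in out.columns:
            raise ValueError(f"nucleus table lacks column {col!r}")
        calls = np.empty(len(out), dtype=object)
        if policy.mode == "fraction_of_max" and len(out):
            for _, idx in out.groupby(well_col, sort=False).indices.items():
                means = out[col].to_numpy(float)[idx]
                thr = calibrate_threshold(means, policy.fraction)
                calls[idx] = classify_marker_array(means, marker, policy,
                                                  threshold=thr)
        elif len(out):
            calls = classify_marker_array(out[col].to_numpy(float), marker, policy)
        out[f"call_{marker.lower()}"] = calls
    for pair in pairs:
        ca = out[f"call_{pair[0].lower()}"].to_numpy(object)
        cb = out[f"call_{pair[1].lower()}"].to_numpy(object)
        a_pos = np.isin(ca, POSITIVE_CALLS)
        b_pos = np.isin(cb, POSITIVE_CALLS)
        generic = np.select(
            [a_pos & b_pos, a_pos, b_pos],
            ["dual", "a_only", "b_only"], default="unlabeled").astype(object)
        out[subtype_column(pair)] = _named_subtype(generic, pair)
    return out
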