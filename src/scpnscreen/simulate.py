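"""Seeded synthetic high-content plates with per-nucleus ground truth.

This module generates multichannel immunofluorescence field images (one
Hoechst nuclear channel plus up to three transcription-factor marker
channels: CTIP2, SATB2, CTIP1) together with a ground-truth table of every
simulated nucleus, so that the downstream segmentation, viability QC,
classification, scoring, and triage stages can all be exercised and
benchmarked without any external data.

The generative model mirrors the statistical structure the analysis
assumes:

* a configurable fraction of candidate nuclei are *viable* (default 0.6,
  the baseline observed per imaging field in monolayer cortical cultures);
  the rest are nuclear fragments, adjacent double nuclei (doublets), or
  pyknotic (small, condensed, Hoechst-bright) nuclei;
* viable nuclei belong to one of four subtypes by marker co-expression —
  CTIP2-only, SATB2-only, CTIP2/SATB2 dual expressors, or unlabeled — with
  primary-neuron-like defaults (5/15/20/60 percent) that give ~25 % CTIP2
  positivity and ~35 % SATB2 positivity;
* per-marker mean intensities are drawn either from a trimodal
  negative/low/high mixture (primary-neuron-like cultures) or from a broad
  near-continuum (mES-derived cultures), on a 12-bit intensity scale so that
  the fixed classification bands are on-scale;
* a :class:`CompoundEffect` converts a fraction ``delta`` of dual-positive
  cells into CTIP2-only cells (refinement is conversion, never creation)
  and can superimpose toxicity: removal of a ``kill_fraction`` of cells and
  conversion of a ``pyknotic_fraction`` of survivors into pyknotic nuclei.

All randomness flows from a single plate seed through
``numpy.random.SeedSequence`` children, one per (well, field), so identical
seeds reproduce bit-identical images and tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats as sps

__all__ = [
    "MARKERS",
    "CHANNEL_NAMES",
    "DEFAULT_CHANNEL_MAP",
    "SUBTYPES",
    "CONDITIONS",
    "GaussianComponent",
    "LogNormalComponent",
    "TruncNormal",
    "MarkerIntensityModel",
    "MorphologyModel",
    "PopulationModel",
    "Toxicity",
    "CompoundEffect",
    "NULL_EFFECT",
    "ImageSpec",
    "WellSpec",
    "PlateDesign",
    "PlateData",
    "primary_neuron_model",
    "mes_derived_model",
    "default_models",
    "default_screen_scenario",
    "adjusted_subtype_fractions",
    "sample_population",
    "place_cells",
    "render_field",
    "generate_field",
    "sample_plate_truth",
    "generate_plate",
    "write_plate",
    "truth_to_candidates",
    "load_generator_config",
]

MARKERS = ("CTIP2", "SATB2", "CTIP1")
CHANNEL_NAMES = ("hoechst", "ch488", "ch546", "ch647")
#: laser line -> marker, matching the immunostaining panel
DEFAULT_CHANNEL_MAP = {"ch488": "CTIP2", "ch546": "SATB2", "ch647": "CTIP1"}
SUBTYPES = ("ctip2_only", "satb2_only", "dual", "unlabeled")
CONDITIONS = ("untreated", "dmso", "gfp_modrna", "fezf2_modrna", "compound_fezf2")
NONVIABLE_CLASSES = ("fragment", "doublet", "pyknotic")

_TRUTH_COLUMNS = [
    "well", "field", "cell_id", "x_um", "y_um", "x_px", "y_px",
    "area_um2", "width_um", "eccentricity", "angle_rad",
    "viable", "pyknotic", "nonviable_class", "subtype",
    "comp_ctip2", "comp_satb2", "comp_ctip1",
    "i_hoechst", "i_ctip2", "i_satb2", "i_ctip1",
]


class GaussianComponent(BaseModel):
    """One intensity mixture component (image intensity units)."""

    model_config = ConfigDict(frozen=True)
    loc: float = Field(ge=0)
    scale: float = Field(ge=0)


class LogNormalComponent(BaseModel):
    """Right-skewed continuum component, parameterized by median and log-sd."""

    model_config = ConfigDict(frozen=True)
    median: float = Field(gt=0)
    sigma: float = Field(gt=0)


class TruncNormal(BaseModel):
    """Truncated normal sampler used for morphology and Hoechst intensity."""

    model_config = ConfigDict(frozen=True)
    mean: float
    sd: float = Field(gt=0)
    lo: float
    hi: float

    @model_validator(mode="after")
    def _check(self) -> "TruncNormal":
        if not self.lo < self.hi:
            raise ValueError("truncation bounds must satisfy lo < hi")
        return self

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if n == 0:
            return np.empty(0)
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return sps.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n,
                                 random_state=rng)


class MarkerIntensityModel(BaseModel):
    """Per-marker intensity distributions for both population modes.

    ``negative``/``low``/``high`` are the trimodal mixture components
    (primary-neuron-like wells); ``continuum_negative``/``continuum_positive``
    are the broad overlapping log-normals used in continuum (mES-like) mode.
    """

    model_config = ConfigDict(frozen=True)
    negative: GaussianComponent
    low: GaussianComponent
    high: GaussianComponent
    continuum_negative: LogNormalComponent
    continuum_positive: LogNormalComponent
    p_high_given_positive: float = Field(default=0.6, ge=0, le=1)

    @model_validator(mode="after")
    def _ordered(self) -> "MarkerIntensityModel":
        if not (self.negative.loc < self.low.loc < self.high.loc):
            raise ValueError(
                "trimodal component locations must be strictly ordered "
                "negative < low < high"
            )
        return self


class MorphologyModel(BaseModel):
    """Nucleus size/shape distributions (areas in um^2)."""

    model_config = ConfigDict(frozen=True)
    viable_area: TruncNormal = TruncNormal(mean=55.0, sd=8.0, lo=38.0, hi=94.0)
    fragment_area: TruncNormal = TruncNormal(mean=20.0, sd=4.0, lo=12.0, hi=30.0)
    doublet_area: TruncNormal = TruncNormal(mean=120.0, sd=12.0, lo=104.0, hi=155.0)
    pyknotic_area: TruncNormal = TruncNormal(mean=20.0, sd=4.0, lo=12.0, hi=30.0)
    ecc_lo: float = Field(default=0.3, ge=0, lt=1)
    ecc_hi: float = Field(default=0.7, ge=0, lt=1)

    @model_validator(mode="after")
    def _check(self) -> "MorphologyModel":
        if self.ecc_lo > self.ecc_hi:
            raise ValueError("ecc_lo must be <= ecc_hi")
        return self


def _default_markers() -> dict[str, MarkerIntensityModel]:
    g = GaussianComponent
    ln = LogNormalComponent
    return {
        "CTIP2": MarkerIntensityModel(
            negative=g(loc=10, scale=6), low=g(loc=110, scale=15),
            high=g(loc=400, scale=45),
            continuum_negative=ln(median=15, sigma=0.7),
            continuum_positive=ln(median=120, sigma=0.9)),
        "SATB2": MarkerIntensityModel(
            negative=g(loc=25, scale=12), low=g(loc=300, scale=60),
            high=g(loc=800, scale=150),
            continuum_negative=ln(median=30, sigma=0.7),
            continuum_positive=ln(median=350, sigma=0.9)),
        "CTIP1": MarkerIntensityModel(
            negative=g(loc=8, scale=5), low=g(loc=70, scale=8),
            high=g(loc=200, scale=50),
            continuum_negative=ln(median=10, sigma=0.7),
            continuum_positive=ln(median=100, sigma=0.9)),
    }


class PopulationModel(BaseModel):
    """Generative description of one culture condition's cell mixture."""

    model_config = ConfigDict(frozen=True)
    mode: Literal["trimodal", "continuum"] = "trimodal"
    fraction_viable: float = Field(default=0.6, ge=0, le=1)
    #: (f_ctip2_only, f_satb2_only, f_dual, f_unlabeled) among viable nuclei
    subtype_fractions: tuple[float, float, float, float] = (0.05, 0.15, 0.20, 0.60)
    markers: dict[str, MarkerIntensityModel] = Field(default_factory=_default_markers)
    hoechst_viable: TruncNormal = TruncNormal(mean=500.0, sd=80.0, lo=300.0, hi=820.0)
    hoechst_pyknotic: TruncNormal = TruncNormal(mean=1200.0, sd=120.0, lo=960.0, hi=2000.0)
    morphology: MorphologyModel = MorphologyModel()
    #: expected nuclei per imaging field (Poisson mean)
    density: float = Field(default=300.0, gt=0)
    #: (fragment, doublet, pyknotic) mix among baseline non-viable nuclei
    nonviable_mix: tuple[float, float, float] = (0.4, 0.4, 0.2)
    #: P(CTIP1 positive | subtype); dual expressors are the most immature
    ctip1_positive: dict[str, float] = Field(
        default_factory=lambda: {"ctip2_only": 0.2, "satb2_only": 0.3,
                                 "dual": 0.6, "unlabeled": 0.05})

    @model_validator(mode="after")
    def _check(self) -> "PopulationModel":
        f = self.subtype_fractions
        if any(x < 0 or x > 1 for x in f):
            raise ValueError("subtype fractions must lie in [0, 1]")
        if abs(sum(f) - 1.0) > 1e-9:
            raise ValueError("subtype fractions must sum to 1 within 1e-9")
        if abs(sum(self.nonviable_mix) - 1.0) > 1e-9:
            raise ValueError("nonviable_mix must sum to 1 within 1e-9")
        missing = set(MARKERS) - set(self.markers)
        if missing:
            raise ValueError(f"missing marker intensity models: {sorted(missing)}")
        return self


class Toxicity(str, Enum):
    none = "none"
    moderate = "moderate"
    severe = "severe"


class CompoundEffect(BaseModel):
    """Treatment effect: subtype refinement plus optional toxicity.

    ``refinement_shift`` (delta) is the fraction of dual-positive cells
    converted to CTIP2-only cells. ``ec50_um``, if set, scales delta and the
    toxicity fractions by the Hill factor dose / (dose + ec50), giving
    dose-dependent conversion; by default the effect is dose-independent.
    """

    model_config = ConfigDict(frozen=True)
    refinement_shift: float = Field(default=0.0, ge=0, le=1)
    toxicity: Toxicity = Toxicity.none
    kill_fraction: float = Field(default=0.0, ge=0, le=1)
    pyknotic_fraction: float = Field(default=0.0, ge=0, le=1)
    ec50_um: float | None = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "CompoundEffect":
        if self.toxicity is Toxicity.none and (
                self.kill_fraction != 0 or self.pyknotic_fraction != 0):
            raise ValueError(
                "toxicity 'none' requires kill_fraction = pyknotic_fraction = 0")
        return self

    def at_dose(self, dose_um: float) -> "CompoundEffect":
        """Effect realized at a given dose (Hill scaling if ec50 is set)."""
        if self.ec50_um is None:
            return self
        h = dose_um / (dose_um + self.ec50_um)
        return self.model_copy(update={
            "refinement_shift": self.refinement_shift * h,
            "kill_fraction": self.kill_fraction * h,
            "pyknotic_fraction": self.pyknotic_fraction * h,
            "ec50_um": None,
        })


NULL_EFFECT = CompoundEffect()


class ImageSpec(BaseModel):
    """Camera/field geometry; 12-bit dynamic range in 16-bit containers."""

    model_config = ConfigDict(frozen=True)
    width_px: int = Field(default=675, gt=0)
    height_px: int = Field(default=512, gt=0)
    pixel_scale: float = Field(default=0.65, gt=0)  # um per pixel
    bit_depth: int = Field(default=12, gt=0, le=16)
    background: float = Field(default=20.0, ge=0)
    noise_sd: float = Field(default=5.0, ge=0)

    @property
    def max_value(self) -> int:
        return 2 ** self.bit_depth - 1


class WellSpec(BaseModel):
    model_config = ConfigDict(frozen=True)
    well: str
    condition: str
    compound: str | None = None
    dose_um: float = 0.0
    replicate: int = 1


class PlateDesign(BaseModel):
    """A plate layout plus imaging geometry and the master seed."""

    wells: list[WellSpec]
    fields_per_well: int = Field(default=1, ge=1)
    image_spec: ImageSpec = ImageSpec()
    seed: int = 0
    #: fraction of nuclei that are members of a clumped (overlapping) pair
    clump_fraction: float = Field(default=0.1, ge=0, le=1)
    #: hard-core minimum center spacing for non-clumped nuclei (um)
    min_spacing_um: float = Field(default=10.0, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "PlateDesign":
        ids = [w.well for w in self.wells]
        if len(set(ids)) != len(ids):
            raise ValueError("well ids must be unique")
        per: dict[str, dict[float, int]] = {}
        for w in self.wells:
            if w.compound is not None:
                per.setdefault(w.compound, {}).setdefault(w.dose_um, 0)
                per[w.compound][w.dose_um] += 1
        if per:
            reference = None
            for compound, doses in per.items():
                sig = tuple(sorted(doses.items()))
                if reference is None:
                    reference = sig
                elif sig != reference:
                    raise ValueError(
                        f"unbalanced design: compound {compound!r} has dose/"
                        f"replicate pattern {sig}, expected {reference}")
                counts = {n for _, n in sig}
                if len(counts) != 1:
                    raise ValueError(
                        f"compound {compound!r} has unequal replicate counts "
                        f"across doses: {sig}")
        return self


@dataclass
class PlateData:
    """In-memory result of plate simulation."""

    design: PlateDesign
    truth: pd.DataFrame
    plate_map: pd.DataFrame
    #: (well, field) -> {channel: uint16 array}; empty when images not rendered
    images: dict[tuple[str, int], dict[str, np.ndarray]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# population sampling


def adjusted_subtype_fractions(
        fractions: tuple[float, float, float, float],
        delta: float) -> tuple[float, float, float, float]:
    """Subtype fractions after converting a delta share of duals to CTIP2-only.

    Conversion conserves CTIP2 positivity: f'_co + f'_dual = f_co + f_dual.
    """
    f_co, f_so, f_dual, f_un = fractions
    return (f_co + delta * f_dual, f_so, (1.0 - delta) * f_dual, f_un)


def _ellipse_minor_diameter(area: np.ndarray, ecc: np.ndarray) -> np.ndarray:
    # area = pi*a*b, b = a*sqrt(1-e^2)  =>  2b = 2*sqrt(area*sqrt(1-e^2)/pi)
    return 2.0 * np.sqrt(area * np.sqrt(1.0 - ecc ** 2) / np.pi)


def sample_population(model: PopulationModel, effect: CompoundEffect,
                      n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw ``n`` candidate nuclei, apply the treatment effect, return truth rows.

    Kill removal happens first (a ``kill_fraction`` share of records is
    dropped), then viability, subtype (from the delta-adjusted fractions),
    per-marker components and intensities, morphology, and finally the
    ``pyknotic_fraction`` conversion of survivors.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    cols = [c for c in _TRUTH_COLUMNS if c not in
            ("well", "field", "cell_id", "x_um", "y_um", "x_px", "y_px", "angle_rad")]
    if n == 0:
        return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})

    keep = rng.random(n) < (1.0 - effect.kill_fraction)
    m = int(keep.sum())
    if m == 0:
        return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})

    viable = rng.random(m) < model.fraction_viable
    frac = adjusted_subtype_fractions(model.subtype_fractions,
                                      effect.refinement_shift)
    sub_idx = rng.choice(4, size=m, p=np.asarray(frac))
    subtype = np.array(SUBTYPES, dtype=object)[sub_idx]
    subtype[~viable] = "unlabeled"

    nv_class = np.full(m, "", dtype=object)
    n_nv = int((~viable).sum())
    if n_nv:
        nv_class[~viable] = rng.choice(np.array(NONVIABLE_CLASSES, dtype=object),
                                       size=n_nv, p=np.asarray(model.nonviable_mix))

    # treatment-induced pyknosis: survivors rendered small and Hoechst-bright
    pyk_hit = rng.random(m) < effect.pyknotic_fraction
    viable = viable & ~pyk_hit
    subtype[pyk_hit] = "unlabeled"
    nv_class[pyk_hit] = "pyknotic"
    pyknotic = nv_class == "pyknotic"

    # per-marker component and intensity
    positive = {
        "CTIP2": viable & np.isin(subtype, ("ctip2_only", "dual")),
        "SATB2": viable & np.isin(subtype, ("satb2_only", "dual")),
    }
    p_c1 = np.zeros(m)
    for st, p in model.ctip1_positive.items():
        p_c1[subtype == st] = p
    positive["CTIP1"] = viable & (rng.random(m) < p_c1)

    comp: dict[str, np.ndarray] = {}
    inten: dict[str, np.ndarray] = {}
    for marker in MARKERS:
        mm = model.markers[marker]
        pos = positive[marker]
        c = np.full(m, "negative", dtype=object)
        hi = pos & (rng.random(m) < mm.p_high_given_positive)
        c[pos] = "low"
        c[hi] = "high"
        vals = np.zeros(m)
        if model.mode == "trimodal":
            for name, g in (("negative", mm.negative), ("low", mm.low),
                            ("high", mm.high)):
                sel = c == name
                k = int(sel.sum())
                if k:
                    vals[sel] = np.clip(rng.normal(g.loc, g.scale, size=k), 0, None)
        else:
            for sel, ln in ((~pos, mm.continuum_negative),
                            (pos, mm.continuum_positive)):
                k = int(sel.sum())
                if k:
                    vals[sel] = rng.lognormal(math.log(ln.median), ln.sigma, size=k)
        comp[marker] = c
        inten[marker] = vals

    # morphology
    mo = model.morphology
    area = np.zeros(m)
    for sel, tn in ((viable, mo.viable_area),
                    (nv_class == "fragment", mo.fragment_area),
                    (nv_class == "doublet", mo.doublet_area),
                    (pyknotic, mo.pyknotic_area)):
        k = int(sel.sum())
        if k:
            area[sel] = tn.sample(rng, k)
    ecc = rng.uniform(mo.ecc_lo, mo.ecc_hi, size=m)
    width = _ellipse_minor_diameter(area, ecc)

    hoechst = np.zeros(m)
    normal_h = ~pyknotic
    k = int(normal_h.sum())
    if k:
        hoechst[normal_h] = model.hoechst_viable.sample(rng, k)
    k = int(pyknotic.sum())
    if k:
        hoechst[pyknotic] = model.hoechst_pyknotic.sample(rng, k)

    return pd.DataFrame({
        "area_um2": area, "width_um": width, "eccentricity": ecc,
        "viable": viable, "pyknotic": pyknotic, "nonviable_class": nv_class,
        "subtype": subtype,
        "comp_ctip2": comp["CTIP2"], "comp_satb2": comp["SATB2"],
        "comp_ctip1": comp["CTIP1"],
        "i_hoechst": hoechst, "i_ctip2": inten["CTIP2"],
        "i_satb2": inten["SATB2"], "i_ctip1": inten["CTIP1"],
    })


# ---------------------------------------------------------------------------
# field rendering


def place_cells(cells: pd.DataFrame, spec: ImageSpec, rng: np.random.Generator,
                clump_fraction: float = 0.1,
                min_spacing_um: float = 10.0) -> pd.DataFrame:
    """Assign positions (um) and orientations to sampled cells.

    Non-clumped cells are dart-thrown with a hard-core minimum spacing;
    clumped cells are placed as overlapping pairs at 0.8-1.0 times the sum
    of effective radii to exercise clump splitting downstream.
    """
    n = len(cells)
    out = cells.copy()
    if n == 0:
        for c in ("x_um", "y_um", "x_px", "y_px", "angle_rad"):
            out[c] = pd.Series(dtype=float)
        return out

    area = out["area_um2"].to_numpy(float)
    ecc = out["eccentricity"].to_numpy(float)
    a_semi = np.sqrt(area / (np.pi * np.sqrt(1.0 - ecc ** 2)))  # semi-major, um
    r_eff = np.sqrt(area / np.pi)

    w_um = spec.width_px * spec.pixel_scale
    h_um = spec.height_px * spec.pixel_scale
    margin = float(a_semi.max()) + 2.0 * spec.pixel_scale
    lo_x, hi_x = margin, max(margin + 1e-6, w_um - margin)
    lo_y, hi_y = margin, max(margin + 1e-6, h_um - margin)

    n_pairs = int(n * clump_fraction) // 2
    xs = np.empty(n)
    ys = np.empty(n)
    anchors_x: list[float] = []
    anchors_y: list[float] = []

    # anchors: everything except pair partners (the last n_pairs cells)
    n_anchor = n - n_pairs
    for i in range(n_anchor):
        px = py = None
        for _ in range(200):
            cx = rng.uniform(lo_x, hi_x)
            cy = rng.uniform(lo_y, hi_y)
            if not anchors_x:
                px, py = cx, cy
                break
            d2 = (np.asarray(anchors_x) - cx) ** 2 + (np.asarray(anchors_y) - cy) ** 2
            if d2.min() >= min_spacing_um ** 2:
                px, py = cx, cy
                break
            if px is None:
                px, py = cx, cy  # remember the first draw as fallback
        xs[i], ys[i] = px, py
        anchors_x.append(px)
        anchors_y.append(py)

    # partners overlap their anchor (the first n_pairs anchors)
    for j in range(n_pairs):
        i = n_anchor + j
        anchor = j
        d = rng.uniform(0.8, 1.0) * (r_eff[anchor] + r_eff[i])
        phi = rng.uniform(0, 2 * np.pi)
        xs[i] = np.clip(xs[anchor] + d * np.cos(phi), lo_x, hi_x)
        ys[i] = np.clip(ys[anchor] + d * np.sin(phi), lo_y, hi_y)

    out["x_um"] = xs
    out["y_um"] = ys
    out["x_px"] = xs / spec.pixel_scale
    out["y_px"] = ys / spec.pixel_scale
    out["angle_rad"] = rng.uniform(0, np.pi, size=n)
    return out


def render_field(cells: pd.DataFrame, image_spec: ImageSpec,
                 rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Render placed cells into the four channels of one field.

    Each nucleus contributes a smooth-edged (sub-pixel anti-aliased)
    elliptical footprint: per-pixel coverage ramps linearly over ~1 px at
    the ellipse boundary, so the half-maximum contour encloses the true
    area. Overlapping nuclei combine by maximum, and a Gaussian readout
    noise floor sits on a constant background. Output arrays are uint16
    clipped to the configured bit depth.
    """
    spec = image_spec
    if spec.width_px <= 0 or spec.height_px <= 0 or spec.pixel_scale <= 0:
        raise ValueError("image spec dimensions and pixel scale must be positive")
    h, w = spec.height_px, spec.width_px
    signal = {ch: np.zeros((h, w)) for ch in CHANNEL_NAMES}
    intensity_cols = {"hoechst": "i_hoechst"}
    for ch, marker in DEFAULT_CHANNEL_MAP.items():
        intensity_cols[ch] = f"i_{marker.lower()}"

    if len(cells):
        xs = cells["x_px"].to_numpy(float)
        ys = cells["y_px"].to_numpy(float)
        area_px = cells["area_um2"].to_numpy(float) / spec.pixel_scale ** 2
        ecc = cells["eccentricity"].to_numpy(float)
        ang = cells["angle_rad"].to_numpy(float)
        a_px = np.sqrt(area_px / (np.pi * np.sqrt(1.0 - ecc ** 2)))
        b_px = a_px * np.sqrt(1.0 - ecc ** 2)
        r_eff = np.sqrt(a_px * b_px)
        if (xs < 0).any() or (xs >= w).any() or (ys < 0).any() or (ys >= h).any():
            raise ValueError("cell centroids must fall inside the field")
        vals = {ch: cells[col].to_numpy(float)
                for ch, col in intensity_cols.items()}
        for i in range(len(cells)):
            rad = int(np.ceil(a_px[i])) + 2
            x0 = max(0, int(xs[i]) - rad)
            x1 = min(w, int(xs[i]) + rad + 1)
            y0 = max(0, int(ys[i]) - rad)
            y1 = min(h, int(ys[i]) + rad + 1)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            dx = xx - xs[i]
            dy = yy - ys[i]
            c, s = np.cos(ang[i]), np.sin(ang[i])
            u = dx * c + dy * s
            v = -dx * s + dy * c
            rho = np.sqrt((u / a_px[i]) ** 2 + (v / b_px[i]) ** 2)
            cov = np.clip(0.5 - (rho - 1.0) * r_eff[i], 0.0, 1.0)
            for ch in CHANNEL_NAMES:
                patch = signal[ch][y0:y1, x0:x1]
                np.maximum(patch, cov * vals[ch][i], out=patch)

    images: dict[str, np.ndarray] = {}
    for ch in CHANNEL_NAMES:  # fixed order keeps noise draws reproducible
        arr = signal[ch] + spec.background
        if spec.noise_sd > 0:
            arr = arr + rng.normal(0.0, spec.noise_sd, size=(h, w))
        images[ch] = np.clip(np.round(arr), 0, spec.max_value).astype(np.uint16)
    return images


def generate_field(model: PopulationModel, effect: CompoundEffect,
                   design: PlateDesign, rng: np.random.Generator,
                   render: bool = True) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Sample one field's population, place it, and (optionally) render it."""
    n = int(rng.poisson(model.density))
    cells = sample_population(model, effect, n, rng)
    if not render:
        # table-level route: positions are never consumed downstream
        for c in ("x_um", "y_um", "x_px", "y_px", "angle_rad"):
            cells[c] = np.nan
        return cells, {}
    cells = place_cells(cells, design.image_spec, rng,
                        clump_fraction=design.clump_fraction,
                        min_spacing_um=design.min_spacing_um)
    images = render_field(cells, design.image_spec, rng)
    return cells, images


# ---------------------------------------------------------------------------
# plate generation


def _effect_for(well: WellSpec,
                effects: dict[str, CompoundEffect]) -> CompoundEffect:
    if well.compound is None:
        return NULL_EFFECT
    if well.compound not in effects:
        raise ValueError(f"no CompoundEffect for compound {well.compound!r}")
    return effects[well.compound].at_dose(well.dose_um)


def _plate_map_frame(design: PlateDesign) -> pd.DataFrame:
    return pd.DataFrame({
        "well": [w.well for w in design.wells],
        "condition": [w.condition for w in design.wells],
        "compound": [w.compound for w in design.wells],
        "dose_uM": [w.dose_um for w in design.wells],
        "replicate": [w.replicate for w in design.wells],
    })


def generate_plate(design: PlateDesign, models: dict[str, PopulationModel],
                   effects: dict[str, CompoundEffect],
                   render: bool = True) -> PlateData:
    """Simulate every field of every well; fully reproducible from the seed."""
    for w in design.wells:
        if w.condition not in models:
            raise ValueError(f"no PopulationModel for condition {w.condition!r}")
        _effect_for(w, effects)  # raises early on missing compound effects
    ss = np.random.SeedSequence(design.seed)
    children = ss.spawn(len(design.wells) * design.fields_per_well)
    frames: list[pd.DataFrame] = []
    images: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    cell_id = 0
    for wi, w in enumerate(design.wells):
        model = models[w.condition]
        effect = _effect_for(w, effects)
        for fi in range(design.fields_per_well):
            rng = np.random.default_rng(children[wi * design.fields_per_well + fi])
            cells, imgs = generate_field(model, effect, design, rng, render=render)
            cells.insert(0, "well", w.well)
            cells.insert(1, "field", fi)
            cells.insert(2, "cell_id", np.arange(cell_id, cell_id + len(cells)))
            cell_id += len(cells)
            frames.append(cells)
            if render:
                images[(w.well, fi)] = imgs
    truth = (pd.concat(frames, ignore_index=True) if frames
             else pd.DataFrame(columns=_TRUTH_COLUMNS))
    truth = truth.reindex(columns=_TRUTH_COLUMNS)
    return PlateData(design=design, truth=truth,
                     plate_map=_plate_map_frame(design), images=images)


def sample_plate_truth(design: PlateDesign, models: dict[str, PopulationModel],
                       effects: dict[str, CompoundEffect]) -> PlateData:
    """Table-level simulation: ground truth without image rendering.

    Uses the same per-(well, field) seeding as :func:`generate_plate`, so a
    rendered run of the same design yields the same sampled populations.
    """
    return generate_plate(design, models, effects, render=False)


def write_plate(plate: PlateData, out_dir: str | Path) -> Path:
    """Write images, ground truth, and plate map to ``out_dir``.

    Images are single-channel TIFFs named ``<well>_f<field>_<channel>.tif``.
    """
    import tifffile

    out = Path(out_dir)
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    for (well, fi), channels in plate.images.items():
        for ch, arr in channels.items():
            tifffile.imwrite(img_dir / f"{well}_f{fi}_{ch}.tif", arr)
    plate.truth.to_csv(out / "ground_truth.csv", index=False)
    plate.plate_map.to_csv(out / "plate_map.csv", index=False)
    return out


def truth_to_candidates(truth: pd.DataFrame) -> pd.DataFrame:
    """Recast ground-truth rows as measured-candidate rows.

    This is the generator's table-level route into the analysis stack: true
    areas, widths, and mean intensities stand in for segmentation
    measurements, so viability QC, classification, scoring, and triage can
    be exercised at scale without rendering images.
    """
    df = pd.DataFrame({
        "well": truth["well"],
        "field": truth["field"],
        "label": truth["cell_id"] if "cell_id" in truth else np.arange(len(truth)),
        "area_um2": truth["area_um2"].astype(float),
        "width_um": truth["width_um"].astype(float),
        "mean_hoechst": truth["i_hoechst"].astype(float),
    })
    for marker in MARKERS:
        df[f"mean_{marker}"] = truth[f"i_{marker.lower()}"].astype(float)
    return df


# ---------------------------------------------------------------------------
# default scenarios and config loading


def primary_neuron_model(**overrides) -> PopulationModel:
    """Primary dissociated E12.5-like culture: trimodal marker labeling."""
    return PopulationModel(mode="trimodal", **overrides)


def mes_derived_model(**overrides) -> PopulationModel:
    """mES-derived culture: near-continuum labeling, sparser positivity."""
    defaults = dict(mode="continuum",
                    subtype_fractions=(0.07, 0.17, 0.03, 0.73))
    defaults.update(overrides)
    return PopulationModel(**defaults)


def default_models(mode: str = "trimodal", **overrides) -> dict[str, PopulationModel]:
    """One population model per screening condition.

    All conditions share the same baseline culture; treatment effects are
    carried by :class:`CompoundEffect`, not by condition-specific models.
    """
    base = (primary_neuron_model(**overrides) if mode == "trimodal"
            else mes_derived_model(**overrides))
    return {c: base for c in CONDITIONS}


def _well_id_sequence():
    plate = 1
    while True:
        for row in "ABCDEFGH":
            for col in range(1, 13):
                yield f"P{plate}_{row}{col:02d}"
        plate += 1


def default_screen_scenario(
        n_compounds: int = 30,
        n_enhancers: int = 3,
        n_toxic: int = 5,
        delta: float = 0.5,
        doses: tuple[float, ...] = (10.0, 1.0, 0.1),
        replicates: int = 2,
        control_replicates: int = 2,
        fields_per_well: int = 1,
        seed: int = 0,
        image_spec: ImageSpec | None = None,
        density: float | None = None,
        mode: str = "trimodal",
        ec50_um: float | None = None,
) -> tuple[PlateDesign, dict[str, PopulationModel], dict[str, CompoundEffect]]:
    """A ready-to-run screen: planted enhancers, toxic compounds, and nulls.

    Compounds are treated in ``replicates`` wells at each dose (default
    duplicate wells at 10, 1, and 0.1 uM). The first ``n_enhancers``
    compounds convert a fraction ``delta`` of dual expressors to CTIP2-only;
    the next ``n_toxic`` are severely toxic; the rest are inert.
    """
    if n_enhancers + n_toxic > n_compounds:
        raise ValueError("n_enhancers + n_toxic must not exceed n_compounds")
    ids = _well_id_sequence()
    wells: list[WellSpec] = []
    for cond in ("untreated", "dmso", "gfp_modrna", "fezf2_modrna"):
        for r in range(1, control_replicates + 1):
            wells.append(WellSpec(well=next(ids), condition=cond, replicate=r))
    effects: dict[str, CompoundEffect] = {}
    for ci in range(1, n_compounds + 1):
        name = f"C{ci:03d}"
        if ci <= n_enhancers:
            effects[name] = CompoundEffect(refinement_shift=delta, ec50_um=ec50_um)
        elif ci <= n_enhancers + n_toxic:
            effects[name] = CompoundEffect(
                toxicity=Toxicity.severe, kill_fraction=0.7,
                pyknotic_fraction=0.3, ec50_um=ec50_um)
        else:
            effects[name] = CompoundEffect()
        for dose in doses:
            for r in range(1, replicates + 1):
                wells.append(WellSpec(well=next(ids), condition="compound_fezf2",
                                      compound=name, dose_um=dose, replicate=r))
    overrides = {} if density is None else {"density": density}
    models = default_models(mode=mode, **overrides)
    design = PlateDesign(wells=wells, fields_per_well=fields_per_well,
                         image_spec=image_spec or ImageSpec(), seed=seed)
    return design, models, effects


def load_generator_config(path: str | Path) -> tuple[
        PlateDesign, dict[str, PopulationModel], dict[str, CompoundEffect]]:
    """Build a scenario from a TOML file.

    Recognized tables: ``[design]`` (keyword arguments of
    :func:`default_screen_scenario` plus optional ``[design.image_spec]``),
    ``[models.<condition>]`` (PopulationModel overrides applied on top of
    the scenario default), and ``[effects.<compound>]`` (CompoundEffect
    fields replacing the scenario's planted effect for that compound).
    """
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    dkw = dict(raw.get("design", {}))
    if "image_spec" in dkw:
        dkw["image_spec"] = ImageSpec(**dkw["image_spec"])
    if "doses" in dkw:
        dkw["doses"] = tuple(dkw["doses"])
    design, models, effects = default_screen_scenario(**dkw)
    for cond, overrides in raw.get("models", {}).items():
        base = models.get(cond)
        merged = dict(base.model_dump() if base else {})
        merged.update(overrides)
        models[cond] = PopulationModel(**merged)
    for compound, fields_ in raw.get("effects", {}).items():
        effects[compound] = CompoundEffect(**fields_)
    return design, models, effects
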