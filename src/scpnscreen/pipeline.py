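"""End-to-end orchestration: images + plate map -> tables, report, manifest.

Stages: read TIFF channels per well/field, segment nuclei, apply viability
QC and toxicity grading, classify marker intensities, summarize wells and
normalize, run replicate statistics, and triage compounds. The analysis
stages are seed-free and fully deterministic; only the simulator consumes
randomness. A run manifest records the config hash, per-stage row counts,
wall times, and collected warnings.

The same analysis stack is callable on any measured-candidate table via
:func:`analyze_candidates`, which is how the simulator's table-level route
(true measurements standing in for segmentation output) exercises
everything downstream of segmentation at scale.
"""

from __future__ import annotations

import json
import math
import re
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import classify_nuclei
from .config import PipelineConfig, config_hash
from .qc import (WellMetrics, exclusion_reasons, grade_well_toxicity,
                 pyknotic_mask, viability_mask)
from .scoring import add_screen_normalizations, compare_conditions, summarize_wells
from .segment import FieldImage, candidates_to_frame, segment_field
from .simulate import CONDITIONS
from .triage import records_to_frame, run_triage, triage_report

__all__ = ["AnalysisResult", "PipelineResult", "load_plate_map",
           "analyze_candidates", "run_pipeline", "make_figures"]

_REQUIRED_MAP_COLUMNS = ("well", "condition", "compound", "dose_uM", "replicate")


def load_plate_map(path: str | Path) -> pd.DataFrame:
    """Read and validate a plate map CSV.

    Requires columns well, condition, compound, dose_uM, replicate; well
    ids must be unique and conditions must belong to the known vocabulary.
    """
    df = pd.read_csv(path, dtype={"well": str, "condition": str, "compound": str})
    missing = [c for c in _REQUIRED_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate map is missing required columns: {missing}")
    dupes = df["well"][df["well"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"plate map has duplicate wells: {dupes}")
    unknown = sorted(set(df["condition"]) - set(CONDITIONS))
    if unknown:
        raise ValueError(
            f"unknown condition labels {unknown}; expected one of {CONDITIONS}")
    df["dose_uM"] = df["dose_uM"].astype(float)
    df["replicate"] = df["replicate"].astype(int)
    df["compound"] = df["compound"].where(df["compound"].notna(), None)
    return df


@dataclass
class AnalysisResult:
    """Tables produced by the analysis stages (segmentation excluded)."""

    nuclei: pd.DataFrame
    qc: pd.DataFrame
    wells: pd.DataFrame
    stats: pd.DataFrame
    triage: pd.DataFrame
    report: dict
    warnings: list[str] = field(default_factory=list)


@dataclass
class PipelineResult:
    analysis: AnalysisResult
    manifest: dict
    out_dir: Path | None = None


def _well_debris(stats_by_well: dict[str, tuple[int, int]]) -> dict[str, float]:
    out = {}
    for well, (discarded, detected) in stats_by_well.items():
        out[well] = discarded / detected if detected else 0.0
    return out


def analyze_candidates(candidates: pd.DataFrame, plate_map: pd.DataFrame,
                       config: PipelineConfig | None = None,
                       debris_by_well: dict[str, float] | None = None,
                       ) -> AnalysisResult:
    """Run QC, classification, scoring, stats, and triage on a candidate table.

    ``candidates`` needs columns well, field, area_um2, width_um,
    mean_hoechst, and mean_<MARKER> for every marker used by the
    configured pairs.
    """
    cfg = config or PipelineConfig()
    warnings: list[str] = []
    df = candidates.copy()

    # --- viability -------------------------------------------------------
    crit = cfg.qc.viability
    df["viable"] = viability_mask(df, crit)
    df["exclusion_reason"] = exclusion_reasons(df, crit)
    df["pyknotic"] = pyknotic_mask(df, crit)

    # --- per-well QC -----------------------------------------------------
    grp = df.groupby("well", sort=False)
    counts = grp.size()
    viable_counts = grp["viable"].sum()
    pyk_fracs = grp["pyknotic"].mean()
    metrics: dict[str, WellMetrics] = {}
    for w in plate_map["well"]:
        n = int(counts.get(w, 0))
        metrics[w] = WellMetrics(
            candidate_count=n,
            viable_count=int(viable_counts.get(w, 0)),
            pyknotic_fraction=float(pyk_fracs.get(w, 0.0)) if n else 0.0,
            debris_fraction=(debris_by_well or {}).get(w, 0.0),
        )
    control_wells = plate_map.loc[
        plate_map["condition"] == cfg.qc.control_condition, "well"]
    controls = [metrics[w] for w in control_wells]
    if not controls:
        raise ValueError(
            f"no control wells (condition {cfg.qc.control_condition!r}) "
            "present; toxicity grading is undefined")
    qc_rows = [grade_well_toxicity(w, metrics[w], controls, cfg.qc.toxicity)
               for w in plate_map["well"]]
    qc_df = pd.DataFrame([r.__dict__ for r in qc_rows])

    # --- classification (viable nuclei only) ------------------------------
    viable_df = df[df["viable"]].copy()
    viable_df = classify_nuclei(viable_df, cfg.classification)
    for col in viable_df.columns:
        if col not in df.columns:
            df[col] = pd.Series(index=df.index, dtype=object)
            df.loc[viable_df.index, col] = viable_df[col]

    # --- well summaries and normalization ---------------------------------
    wells = summarize_wells(viable_df, plate_map, pair=cfg.scoring.pair)
    n_undefined = int((~wells["ratio_defined"]).sum())
    if n_undefined:
        warnings.append(
            f"{n_undefined} well(s) have an undefined refinement ratio "
            "(no dual expressors); excluded from condition means")
    wells = add_screen_normalizations(
        wells, ratio_baseline=cfg.scoring.ratio_baseline,
        ctip2_baseline=cfg.scoring.ctip2_baseline,
        satb2_baseline=cfg.scoring.satb2_baseline)
    wells = wells.merge(qc_df[["well", "grade"]], on="well", how="left")
    wells = wells.rename(columns={"grade": "qc_grade"})

    # --- replicate statistics ---------------------------------------------
    base_cond = cfg.scoring.comparison_baseline
    base_vals = wells.loc[wells["condition"] == base_cond, "ratio"].dropna()
    stat_rows = []
    for cond in sorted(set(wells["condition"])):
        if cond == base_cond:
            continue
        vals = wells.loc[wells["condition"] == cond, "ratio"].dropna()
        if len(vals) < 2 or len(base_vals) < 2:
            warnings.append(
                f"skipped t-test for {cond!r} vs {base_cond!r}: "
                "fewer than 2 defined replicates in a group")
            continue
        st = compare_conditions(vals, base_vals, equal_var=cfg.scoring.equal_var)
        stat_rows.append({"condition": cond, "baseline": base_cond,
                          "n": st.n_a, "n_baseline": st.n_b,
                          "mean": st.mean_a, "sem": st.sem_a,
                          "mean_baseline": st.mean_b, "sem_baseline": st.sem_b,
                          "t": st.t, "df": st.df, "p": st.p, "stars": st.stars})
    stats_df = pd.DataFrame(stat_rows, columns=[
        "condition", "baseline", "n", "n_baseline", "mean", "sem",
        "mean_baseline", "sem_baseline", "t", "df", "p", "stars"])

    # --- triage -----------------------------------------------------------
    records = run_triage(wells, cfg.triage)
    report = triage_report(records)

    return AnalysisResult(nuclei=df, qc=qc_df, wells=wells, stats=stats_df,
                          triage=records_to_frame(records), report=report,
                          warnings=warnings)


def _discover_fields(image_dir: Path, well: str) -> list[int]:
    pat = re.compile(re.escape(well) + r"_f(\d+)_hoechst\.tif$")
    fields = sorted(int(m.group(1)) for p in image_dir.iterdir()
                    if (m := pat.match(p.name)))
    return fields


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Full image-based run: segmentation plus :func:`analyze_candidates`."""
    import tifffile

    cfg = config
    t0 = time.perf_counter()
    timings: dict[str, float] = {}
    plate_map = load_plate_map(cfg.paths.plate_map)
    image_dir = Path(cfg.paths.image_dir)
    channels_needed = ["hoechst"] + sorted(cfg.channel_map)

    frames: list[pd.DataFrame] = []
    debris: dict[str, tuple[int, int]] = {}
    for _, w in plate_map.iterrows():
        well = w["well"]
        fields = _discover_fields(image_dir, well)
        if not fields:
            raise FileNotFoundError(
                f"no images found for well {well!r} in {image_dir}")
        discarded = detected = 0
        for fi in fields:
            chans: dict[str, np.ndarray] = {}
            for ch in channels_needed:
                path = image_dir / f"{well}_f{fi}_{ch}.tif"
                if not path.exists():
                    raise FileNotFoundError(
                        f"well {well!r} field {fi} is missing channel "
                        f"{ch!r} ({path.name})")
                chans[ch] = tifffile.imread(path)
            image = FieldImage(channels=chans, pixel_scale=cfg.pixel_scale_um,
                               bit_depth=cfg.bit_depth)
            cands, stats = segment_field(image, cfg.segmentation)
            discarded += stats.n_discarded_small
            detected += stats.n_after_split
            fdf = candidates_to_frame(cands)
            fdf.insert(0, "well", well)
            fdf.insert(1, "field", fi)
            for ch, marker in cfg.channel_map.items():
                fdf[f"mean_{marker}"] = fdf[f"mean_{ch}"]
            frames.append(fdf)
        debris[well] = (discarded, detected)
    candidates = pd.concat(frames, ignore_index=True)
    timings["segmentation"] = time.perf_counter() - t0

    t1 = time.perf_counter()
    analysis = analyze_candidates(candidates, plate_map, cfg,
                                  debris_by_well=_well_debris(debris))
    timings["analysis"] = time.perf_counter() - t1

    manifest = {
        "config_hash": config_hash(cfg),
        "version": __version__,
        "row_counts": {
            "plate_map_wells": int(len(plate_map)),
            "nuclei": int(len(analysis.nuclei)),
            "viable_nuclei": int(analysis.nuclei["viable"].sum()),
            "wells": int(len(analysis.wells)),
            "stats": int(len(analysis.stats)),
            "triage_records": int(len(analysis.triage)),
        },
        "wall_time_s": {k: round(v, 3) for k, v in timings.items()},
        "warnings": analysis.warnings,
    }
    out_dir = None
    if write:
        out_dir = Path(cfg.paths.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        analysis.nuclei.to_csv(out_dir / "nuclei.csv", index=False)
        analysis.qc.to_csv(out_dir / "well_qc.csv", index=False)
        analysis.wells.to_csv(out_dir / "wells.csv", index=False)
        analysis.stats.to_csv(out_dir / "condition_stats.csv", index=False)
        analysis.triage.to_csv(out_dir / "triage.csv", index=False)
        with open(out_dir / "triage_report.json", "w") as fh:
            json.dump(analysis.report, fh, indent=2, sort_keys=True)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(analysis=analysis, manifest=manifest, out_dir=out_dir)


def make_figures(out_dir: str | Path) -> list[Path]:
    """Composition pies per condition and the ranked normalized-ratio bars.

    Reads wells.csv and triage.csv from ``out_dir`` and writes
    deterministic SVGs whose plotted numbers equal the CSV values.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.rcParams["svg.hashsalt"] = "scpnscreen"
    out = Path(out_dir)
    wells = pd.read_csv(out / "wells.csv")
    triage = pd.read_csv(out / "triage.csv")
    paths: list[Path] = []

    conds = sorted(set(wells["condition"]))
    fig, axes = plt.subplots(1, max(1, len(conds)),
                             figsize=(3 * max(1, len(conds)), 3.2))
    axes = np.atleast_1d(axes)
    labels = ["CTIP2+ only", "SATB2+ only", "dual", "unlabeled"]
    for ax, cond in zip(axes, conds):
        sub = wells[wells["condition"] == cond]
        counts = sub[["n_a_only", "n_b_only", "n_dual", "n_unlabeled"]].sum()
        total = counts.sum()
        if total > 0:
            ax.pie(counts / total, labels=labels,
                   autopct=lambda p: f"{p:.0f}%", textprops={"fontsize": 7})
        ax.set_title(cond, fontsize=9)
    fig.suptitle("Viable-nucleus composition by condition", fontsize=11)
    p = out / "composition_pies.svg"
    fig.savefig(p, metadata={"Date": None})
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(8, 3.2))
    if len(triage):
        ranked = triage.sort_values(
            ["norm_ratio", "compound", "dose_um"],
            ascending=[False, True, True]).reset_index(drop=True)
        colors = np.where(ranked["stage_reached"] == "hit", "tab:orange",
                          np.where(ranked["stage_reached"] == "excluded_toxicity",
                                   "tab:gray", "tab:blue"))
        ax.bar(np.arange(len(ranked)), ranked["norm_ratio"].fillna(0.0),
               color=colors)
        ax.axhline(1.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("compound x dose, ranked")
    ax.set_ylabel("normalized refinement ratio")
    ax.set_title("Ranked normalized CTIP2+/SATB2- : dual ratio")
    p = out / "ranked_ratios.svg"
    fig.savefig(p, metadata={"Date": None})
    plt.close(fig)
    paths.append(p)
    return paths
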