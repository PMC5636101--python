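"""End-to-end orchestration: simulate → annotate → transitions → log-linear →
energetics → exposure → report, with a single JSON run manifest.

Stage outputs are written under one run directory with fixed names; reruns
with identical configuration, inputs and seed are byte-identical.  All
intermediate files keep full precision; rounding happens only in the report.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from puma_energetics import __version__
from puma_energetics.annotate import annotate_fixes, daily_exposure
from puma_energetics.config import StudyConfig
from puma_energetics.energetics import day_records, table2_summary
from puma_energetics.exposure import (
    build_exposure_days,
    cohort_summary,
    contrasts_frame,
    fit_exposure_model,
    quartile_contrast,
)
from puma_energetics.io import (
    read_fixes,
    read_habitat,
    read_houses,
    write_fixes,
    write_habitat,
    write_houses,
)
from puma_energetics.markov import (
    ContingencyTable,
    build_transitions,
    classify_intervals,
    select_model,
)
from puma_energetics.simulate import SimScenario, simulate_dataset

STAGE_FILES = {
    "fixes": "fixes.csv",
    "houses": "houses.geojson",
    "habitat": "habitat.geojson",
    "annotated": "annotated.csv",
    "transitions": "transitions.csv",
    "model_comparison": "model_comparison.csv",
    "day_records": "day_records.csv",
    "per_animal": "per_animal.csv",
    "sex_summary": "sex_summary.csv",
    "exposure_days": "exposure_days.csv",
    "daily_exposure": "daily_exposure.csv",
    "quartile_contrasts": "quartile_contrasts.csv",
    "cohort_summary": "cohort_summary.csv",
    "mixed_model": "mixed_model.csv",
    "manifest": "manifest.json",
    "report": "report.txt",
}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def read_annotated(path) -> pd.DataFrame:
    """Read an annotated-fixes CSV back with proper dtypes."""
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    if "near_house" in df.columns:
        df["near_house"] = df["near_house"].astype(str).str.lower().eq("true")
    return df


def study_groups(transitions: pd.DataFrame):
    """Split transition records into the analysis groups.

    Mirrors the study design: a strong sex difference splits males from
    females, and a habitat difference for males splits males by habitat;
    females are pooled across habitats.  Falls back gracefully when S or L
    is absent.
    """
    if "S" not in transitions.columns:
        yield "all", transitions
        return
    for sex, g in transitions.groupby("S", sort=True):
        if sex == "M" and "L" in transitions.columns and g["L"].nunique() > 1:
            for hab, gg in g.groupby("L", sort=True):
                yield f"males_{hab}", gg
        else:
            yield ("females_all" if sex == "F" else "males_all"), g


def run_pipeline(
    config: StudyConfig,
    out_dir,
    fixes_path=None,
    houses_path=None,
    habitat_path=None,
    scenario: SimScenario | None = None,
    seed: int | None = None,
) -> dict:
    """Run every stage; returns the manifest dict (also written to disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": config.to_dict(),
        "inputs": {},
        "counts": {},
        "digests": {},
    }

    # --- stage: inputs -----------------------------------------------------
    try:
        if scenario is not None:
            if seed is None:
                raise ValueError("simulation requires a seed")
            fixes, houses, habitat, truths = simulate_dataset(scenario, seed, config)
            write_fixes(fixes, out / STAGE_FILES["fixes"])
            write_houses(houses, out / STAGE_FILES["houses"])
            write_habitat(habitat, out / STAGE_FILES["habitat"])
            _write_truth(truths, out / "truth.json")
            fixes = read_fixes(out / STAGE_FILES["fixes"], config)
        else:
            if fixes_path is None or houses_path is None:
                raise FileNotFoundError(
                    "fixes and houses inputs are required unless simulating"
                )
            fixes = read_fixes(fixes_path, config)
            houses = read_houses(houses_path)
            habitat = read_habitat(habitat_path) if habitat_path else None
            for name, p in (("fixes", fixes_path), ("houses", houses_path), ("habitat", habitat_path)):
                if p:
                    manifest["inputs"][name] = str(p)
                    manifest["digests"][name] = _sha256(Path(p))
    except Exception as exc:
        raise StageError(f"inputs: {exc}") from exc
    manifest["counts"]["fixes"] = int(len(fixes))

    # --- stage: annotate ---------------------------------------------------
    try:
        annotated = annotate_fixes(fixes, houses, habitat, config)
        _write_csv(annotated, out / STAGE_FILES["annotated"])
    except Exception as exc:
        raise StageError(f"annotate: {exc}") from exc

    # --- stage: transitions ------------------------------------------------
    try:
        intervals = classify_intervals(annotated, config)
        transitions = build_transitions(intervals, annotated)
        _write_csv(transitions, out / STAGE_FILES["transitions"])
    except Exception as exc:
        raise StageError(f"transitions: {exc}") from exc
    manifest["counts"]["intervals"] = int(len(intervals))
    manifest["counts"]["transitions"] = int(len(transitions))

    # --- stage: log-linear model selection ---------------------------------
    try:
        comp_rows = []
        for group, recs in study_groups(transitions):
            table = ContingencyTable.from_records(recs, "BAHT")
            sel = select_model(table)
            comp = sel.comparison.copy()
            comp.insert(0, "group", group)
            comp["selected"] = comp["model"] == sel.best.name
            comp_rows.append(comp)
        comparison = pd.concat(comp_rows, ignore_index=True)
        _write_csv(comparison, out / STAGE_FILES["model_comparison"])
    except Exception as exc:
        raise StageError(f"loglinear: {exc}") from exc
    manifest["counts"]["models_fitted"] = int(len(comparison))

    # --- stage: energetics -------------------------------------------------
    try:
        days = day_records(annotated, config)
        per_animal, sexes = table2_summary(days)
        _write_csv(days, out / STAGE_FILES["day_records"])
        _write_csv(per_animal, out / STAGE_FILES["per_animal"])
        _write_csv(sexes, out / STAGE_FILES["sex_summary"])
    except Exception as exc:
        raise StageError(f"energetics: {exc}") from exc
    manifest["counts"]["days_accepted"] = int(len(days))

    # --- stage: exposure ---------------------------------------------------
    try:
        exp_days = build_exposure_days(annotated, config)
        _write_csv(exp_days, out / STAGE_FILES["exposure_days"])
        daily = _daily_exposure_frame(annotated, houses, config)
        _write_csv(daily, out / STAGE_FILES["daily_exposure"])
        contrasts, excluded = quartile_contrast(days, daily)
        cdf = contrasts_frame(contrasts)
        _write_csv(cdf, out / STAGE_FILES["quartile_contrasts"])
        cohort = cohort_summary(cdf) if len(cdf) else pd.DataFrame()
        _write_csv(cohort, out / STAGE_FILES["cohort_summary"])
        manifest["counts"]["quartile_animals"] = int(len(cdf))
        manifest["counts"]["quartile_excluded"] = len(excluded)
        if exp_days["animal_id"].nunique() >= 2 and len(exp_days) >= 8:
            fit = fit_exposure_model(exp_days)
            coef = fit.coefficients.reset_index(names="term")
            _write_csv(coef, out / STAGE_FILES["mixed_model"])
            manifest["counts"]["mixed_model_singular"] = bool(fit.singular)
    except Exception as exc:
        raise StageError(f"exposure: {exc}") from exc

    # --- manifest + report -------------------------------------------------
    for name, fname in STAGE_FILES.items():
        p = out / fname
        if p.exists() and name not in ("manifest", "report"):
            manifest["digests"][name] = _sha256(p)
    (out / STAGE_FILES["manifest"]).write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str), encoding="utf-8"
    )
    (out / STAGE_FILES["report"]).write_text(render_report(out), encoding="utf-8")
    return manifest


def _daily_exposure_frame(annotated, houses, config) -> pd.DataFrame:
    from puma_energetics.energetics import filter_days

    rows = []
    for (_, _), g in filter_days(annotated, config).groupby(
        ["animal_id", "sampling_day"], sort=True
    ):
        rows.append(daily_exposure(g, houses, config).__dict__)
    return pd.DataFrame(rows)


def _write_truth(truths: dict, path: Path) -> None:
    payload = {}
    for animal, t in truths.items():
        payload[animal] = {
            "sex": t.sex,
            "body_mass_kg": t.body_mass_kg,
            "states": [np.asarray(s).astype(int).tolist() for s in t.states],
            "transition_counts": np.asarray(t.transition_counts).astype(int).tolist(),
            "day_distance_m": list(map(float, t.day_distance_m)),
            "day_raw_kcal_per_kg": list(map(float, t.day_raw_kcal_per_kg)),
        }
    Path(path).write_text(json.dumps(payload, sort_keys=True), encoding="utf-8")


# ---------------------------------------------------------------------------
# report


def _fmt(x, nd=1):
    return "—" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.{nd}f}"


def render_report(run_dir) -> str:
    """Human-readable summary of a completed run directory.

    Rounding follows the reporting precision of the study tables: one
    decimal for deer and percentages, whole kilocalories.
    """
    run = Path(run_dir)
    lines = ["Puma movement & energetics report", "=" * 34, ""]
    comp_p = run / STAGE_FILES["model_comparison"]
    if not comp_p.exists():
        raise FileNotFoundError(f"incomplete bundle: missing {comp_p.name}")
    comp = pd.read_csv(comp_p)
    lines.append("Behavioral transition model selection (per study group)")
    for group, g in comp.groupby("group", sort=True):
        lines.append(f"  {group}:")
        for _, r in g.iterrows():
            mark = " *" if r.get("selected", False) else ""
            aic = 0.0 if abs(r["aic_rel"]) < 1e-9 else r["aic_rel"]
            lines.append(
                f"    {r['model']:<22} aic_rel={aic:8.2f}  "
                f"G2={r['g2']:8.2f}  df={int(r['df'])}{mark}"
            )
    lines.append("")
    sex_p = run / STAGE_FILES["sex_summary"]
    if sex_p.exists():
        sexes = pd.read_csv(sex_p)
        lines.append("Energetics (per sex, day-weighted means of per-animal means)")
        for _, r in sexes.iterrows():
            lines.append(
                f"  {r['sex']}: {int(r['animals'])} animals over {int(r['days'])} days; "
                f"distance {_fmt(r.get('distance_km_weighted'), 2)} km/day; "
                f"{_fmt(r.get('kcal_per_kg_weighted'))} kcal/kg/day; "
                f"{_fmt(r.get('kcal_weighted'), 0)} kcal/day; "
                f"{_fmt(r.get('deer_per_year_weighted'))} deer/yr"
            )
        lines.append("")
    coh_p = run / STAGE_FILES["cohort_summary"]
    lines.append("Housing-exposure quartile contrast (mean ± SE across animals)")
    try:
        coh = pd.read_csv(coh_p) if coh_p.exists() else pd.DataFrame()
    except pd.errors.EmptyDataError:
        coh = pd.DataFrame()
    if len(coh) == 0:
        lines.append("  no eligible animals")
    else:
        for _, r in coh.iterrows():
            lines.append(
                f"  {r['sex']}: Δkcal {r['d_kcal_total_mean']:.0f} ± {_fmt(r['d_kcal_total_se'], 0)}; "
                f"increase {r['percent_increase_mean']:.1f} ± {_fmt(r['percent_increase_se'])} %; "
                f"extra deer/yr {r['d_deer_per_year_mean']:.1f}"
            )
    lines.append("")
    return "\n".join(lines)
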