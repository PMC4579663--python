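"""End-to-end analysis: score → discovery cutoff → validation survival → robustness.

The full run reproduces the study arc on any conforming dataset: load and
validate the cell and clinical tables, compute per-patient colocalization
scores, search the optimal cutoff on the discovery cohort, freeze it, and
quantify prognostic value on the validation cohort; then repeat within
molecular-subtype and treatment strata, and finish with bootstrap and
tissue-subsampling robustness.  Stage ordering guarantees the validation
outcomes are never consulted before the cutoff is frozen.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .patterns import CELL_TABLE_COLUMNS, CELL_CLASSES, read_cell_table, patterns_from_frame
from .tessellation import (
    DEFAULT_MIN_CELLS,
    DEFAULT_SQUARE_SIDE_UM,
    build_square_tessellation,
    build_voronoi_tessellation,
    count_cells,
    filter_low_tissue,
)
from .indices import aggregate_patient_score, immune_abundance
from .survival import (
    apply_administrative_censoring,
    bootstrap_significance,
    cohort_survival_analysis,
    optimal_cutoff_search,
    subtype_stratified_analysis,
    tissue_subsampling_robustness,
)

log = logging.getLogger("ecoloc")

POLYGON_SIZE_SWEEP_UM = (100.0, 250.0, 500.0, 1000.0)


@dataclass
class RunConfig:
    """Configuration of a full analysis run (loadable from YAML)."""

    cell_csv: str
    clinical_csv: str
    output_dir: str = "ecoloc_out"
    tessellation: str = "square"
    polygon_scale_um: float = DEFAULT_SQUARE_SIDE_UM
    min_cells: int = DEFAULT_MIN_CELLS
    cutoff_lo_pct: float = 20.0
    cutoff_hi_pct: float = 80.0
    cutoff_step: float = 1.5
    aggregation: str = "pool"
    subtype_strata: tuple = (("pam50", "LumA"), ("pam50", "HER2"), ("her2", "amplified"))
    treatment_strata: tuple = ("ct", "rt", "ht")
    bootstrap_fraction: float = 0.75
    bootstrap_reps: int = 1000
    subsample_fractions: tuple = (0.75, 0.5, 0.25)
    min_events: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cutoff_lo_pct < self.cutoff_hi_pct < 100:
            raise ValueError("cutoff percentile bounds must satisfy 0 < lo < hi < 100")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "subtype_strata" in raw:
            raw["subtype_strata"] = tuple(tuple(s) for s in raw["subtype_strata"])
        for k in ("treatment_strata", "subsample_fractions"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)


class SchemaError(ValueError):
    """A hard input-schema violation (exit code 2 at the CLI)."""


def validate_inputs(cell_csv: str | Path, clinical_csv: str | Path) -> dict:
    """Validate the two input tables; hard errors raise, join gaps warn.

    Checks column presence, the cell-class vocabulary, coordinate
    finiteness, time positivity and patient-id join coverage.
    """
    errors: list[str] = []
    warnings_: list[str] = []
    cells = pd.read_csv(cell_csv)
    clin = pd.read_csv(clinical_csv)

    missing = [c for c in CELL_TABLE_COLUMNS if c not in cells.columns]
    if missing:
        errors.append(f"cell table missing columns {missing}")
    else:
        bad = sorted(set(cells["cell_class"].unique()) - set(CELL_CLASSES))
        if bad:
            errors.append(
                f"unknown cell_class values {bad}; expected one of {list(CELL_CLASSES)}"
            )
        for col in ("x_um", "y_um"):
            vals = pd.to_numeric(cells[col], errors="coerce")
            n_bad = int(vals.isna().sum() + np.isinf(vals.fillna(0)).sum())
            if n_bad:
                first = int(vals.index[vals.isna()][0]) + 2 if vals.isna().any() else "?"
                errors.append(f"{n_bad} non-finite {col} values (first at line {first})")

    need = ["patient_id", "time", "event", "cohort"]
    missing_c = [c for c in need if c not in clin.columns]
    if missing_c:
        errors.append(f"clinical table missing columns {missing_c}")
    else:
        t = pd.to_numeric(clin["time"], errors="coerce")
        bad_rows = clin.index[(t.isna()) | (t <= 0)]
        if len(bad_rows):
            errors.append(
                f"{len(bad_rows)} clinical rows with non-positive time "
                f"(first at line {int(bad_rows[0]) + 2})"
            )
        if not set(clin["event"].unique()) <= {0, 1}:
            errors.append("event indicator must be 0/1")
        bad_cohort = sorted(set(clin["cohort"].unique()) - {"discovery", "validation"})
        if bad_cohort:
            errors.append(f"unknown cohort labels {bad_cohort}")

    if not errors and "patient_id" in cells.columns:
        cell_ids = set(cells["patient_id"].astype(str))
        clin_ids = set(clin["patient_id"].astype(str))
        only_cells = cell_ids - clin_ids
        only_clin = clin_ids - cell_ids
        if only_cells:
            warnings_.append(f"{len(only_cells)} patients have cells but no clinical row")
        if only_clin:
            warnings_.append(f"{len(only_clin)} patients have clinical rows but no cells")

    report = {"errors": errors, "warnings": warnings_, "ok": not errors,
              "n_cells": len(cells), "n_patients": len(clin)}
    if errors:
        raise SchemaError("; ".join(errors))
    for w in warnings_:
        log.warning(w)
    return report


def score_patients(
    patterns,
    tessellation: str = "square",
    polygon_scale_um: float = DEFAULT_SQUARE_SIDE_UM,
    min_cells: int = DEFAULT_MIN_CELLS,
    aggregation: str = "pool",
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-patient colocalization scores from per-section patterns.

    Each section is tessellated, counted and tissue-filtered; the patient's
    sections are then combined (pooled polygons by default).  For Voronoi
    tessellations the generator count matches the section's number of
    occupied squares at the same length scale, keeping polygon density
    comparable across tessellation kinds.
    """
    rng = np.random.default_rng(seed)
    by_patient: dict[str, list] = {}
    abundance: dict[str, list] = {}
    for pat in patterns:
        if tessellation == "square":
            tess = build_square_tessellation(pat, side=polygon_scale_um)
        elif tessellation == "voronoi":
            sq = count_cells(pat, build_square_tessellation(pat, side=polygon_scale_um))
            n_seeds = max(int((sq.t > 0).sum()), 2)
            tess = build_voronoi_tessellation(
                pat, n_seeds=n_seeds, seed=int(rng.integers(2**31))
            )
        else:
            raise ValueError(f"unknown tessellation kind {tessellation!r}")
        counts = filter_low_tissue(count_cells(pat, tess), min_cells=min_cells)
        by_patient.setdefault(pat.patient_id, []).append(counts)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ia = immune_abundance(pat)
        if ia is not None:
            abundance.setdefault(pat.patient_id, []).append(ia)

    rows = []
    for pid, sections in sorted(by_patient.items()):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            score = aggregate_patient_score(sections, strategy=aggregation)
        rows.append(
            {
                "patient_id": pid,
                "morisita": score.morisita,
                "pearson": score.pearson,
                "immune_abundance": float(np.mean(abundance.get(pid, [np.nan]))),
                "n_polygons_used": score.n_polygons_used,
                "tessellation_kind": score.tessellation_kind,
                "polygon_scale_um": score.polygon_scale,
                "min_cells": score.min_tissue_threshold,
                "aggregation": score.aggregation,
            }
        )
    return pd.DataFrame(rows)


def _measure_analysis(scores, clinical, cfg: RunConfig) -> dict:
    """Discovery cutoff search + per-cohort survival analysis for one measure."""
    disc = (clinical["cohort"] == "discovery").to_numpy()
    val = (clinical["cohort"] == "validation").to_numpy()
    cut = optimal_cutoff_search(
        scores[disc],
        clinical.loc[disc, "time"].to_numpy(dtype=float),
        clinical.loc[disc, "event"].to_numpy(dtype=int),
        cfg.cutoff_lo_pct, cfg.cutoff_hi_pct, cfg.cutoff_step,
    )
    return {
        "cutoff": cut.chosen_cutoff,
        "cutoff_percentile": cut.chosen_percentile,
        "n_candidates": len(cut.candidates),
        "discovery": cohort_survival_analysis(scores[disc], clinical.loc[disc], cut.chosen_cutoff),
        "validation": cohort_survival_analysis(scores[val], clinical.loc[val], cut.chosen_cutoff),
    }


def compare_measures(scores_df: pd.DataFrame, clinical: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Identical cutoff-search + validation protocol for each measure.

    Returns one row per (measure, cohort) with HR, CI and p for direct
    comparison of the Morisita index, Pearson correlation and the
    non-spatial immune-abundance fraction.
    """
    merged = scores_df.merge(clinical, on="patient_id")
    merged = apply_administrative_censoring(merged)
    rows = []
    for measure in ("morisita", "pearson", "immune_abundance"):
        ok = merged[measure].notna()
        sub = merged[ok]
        try:
            res = _measure_analysis(sub[measure].to_numpy(dtype=float), sub, cfg)
        except ValueError as exc:
            log.warning("measure %s skipped: %s", measure, exc)
            continue
        for cohort in ("discovery", "validation"):
            c = res[cohort]
            cox = c.get("cox_univariate")
            row = {
                "measure": measure,
                "cohort": cohort,
                "cutoff": res["cutoff"],
                "n": c["n"],
                "n_high": c["n_high"],
                "n_low": c["n_low"],
                "logrank_p": c.get("logrank_p", np.nan),
            }
            if cox is not None and cox.converged:
                row.update(
                    hr=cox.hr("score_high"),
                    ci_low=float(cox.table.loc["score_high", "ci_low"]),
                    ci_high=float(cox.table.loc["score_high", "ci_high"]),
                    cox_p=float(cox.table.loc["score_high", "p"]),
                    concordance=cox.concordance,
                )
            rows.append(row)
    return pd.DataFrame(rows)


def _cox_rows(tag: str, cohort: str, analysis: dict) -> list[dict]:
    rows = []
    for kind in ("cox_univariate", "cox_multivariate"):
        res = analysis.get(kind)
        if res is None or not res.converged:
            continue
        for term, r in res.table.iterrows():
            rows.append(
                {
                    "stratum": tag,
                    "cohort": cohort,
                    "model": kind.replace("cox_", ""),
                    "term": term,
                    "hr": r["hr"],
                    "ci_low": r["ci_low"],
                    "ci_high": r["ci_high"],
                    "p": r["p"],
                    "concordance": res.concordance,
                    "n": res.n,
                    "events": res.n_events,
                }
            )
    return rows


def run_full_analysis(cfg: RunConfig) -> dict:
    """Execute the whole pipeline and write the analysis report.

    Stages, in order: validate inputs → per-patient scores → discovery
    cutoff search (frozen) → validation KM/log-rank/Cox → subtype strata →
    treatment strata → measure comparison → bootstrap → tissue subsampling.
    Outputs JSON and CSV under ``cfg.output_dir``.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    validation_report = validate_inputs(cfg.cell_csv, cfg.clinical_csv)

    patterns = read_cell_table(cfg.cell_csv)
    clinical = pd.read_csv(cfg.clinical_csv)
    clinical["patient_id"] = clinical["patient_id"].astype(str)
    clinical = apply_administrative_censoring(clinical)

    scores_df = score_patients(
        patterns,
        tessellation=cfg.tessellation,
        polygon_scale_um=cfg.polygon_scale_um,
        min_cells=cfg.min_cells,
        aggregation=cfg.aggregation,
        seed=cfg.seed,
    )
    scores_df.to_csv(outdir / "scores.csv", index=False)

    merged = scores_df.merge(clinical, on="patient_id")
    ok = merged["morisita"].notna()
    if (~ok).any():
        log.warning("%d patients dropped for missing Morisita score", int((~ok).sum()))
    merged = merged[ok].reset_index(drop=True)
    scores = merged["morisita"].to_numpy(dtype=float)

    main = _measure_analysis(scores, merged, cfg)

    # subtype strata: cutoff learned on the discovery subset only
    strata = {}
    for fieldname, value in cfg.subtype_strata:
        strata[f"{fieldname}={value}"] = subtype_stratified_analysis(
            scores, merged, fieldname, value,
            cfg.cutoff_lo_pct, cfg.cutoff_hi_pct, cfg.cutoff_step,
            min_events=cfg.min_events,
        )

    # treatment strata at the frozen all-cancers cutoff (treated vs naive,
    # each split high/low: the four-curve layout)
    treatment = {}
    for flag in cfg.treatment_strata:
        if flag not in merged.columns:
            continue
        arms = {}
        for arm, mask in (
            ("treated", merged[flag] == 1),
            ("naive", merged[flag] == 0),
        ):
            sub = merged[mask.to_numpy()]
            if len(sub) < 4 or sub["event"].sum() < cfg.min_events:
                arms[arm] = {"skipped": True, "reason": "too few patients or events"}
                continue
            arms[arm] = cohort_survival_analysis(
                sub["morisita"].to_numpy(dtype=float), sub, main["cutoff"]
            )
        treatment[flag] = arms

    comparison = compare_measures(scores_df, clinical, cfg)
    comparison.to_csv(outdir / "measure_comparison.csv", index=False)

    val_mask = (merged["cohort"] == "validation").to_numpy()
    boot = bootstrap_significance(
        scores[val_mask], merged[val_mask], main["cutoff"],
        fraction=cfg.bootstrap_fraction, n_reps=cfg.bootstrap_reps, seed=cfg.seed,
    )

    # tissue subsampling on the largest slide's counts
    biggest = max(patterns, key=len)
    tess = build_square_tessellation(biggest, side=cfg.polygon_scale_um)
    counts = filter_low_tissue(count_cells(biggest, tess), min_cells=cfg.min_cells)
    subsampling = tissue_subsampling_robustness(
        counts, fractions=cfg.subsample_fractions, seed=cfg.seed
    )

    report = {
        "config": asdict(cfg),
        "input_validation": validation_report,
        "all_cancers": main,
        "subtype_strata": strata,
        "treatment_strata": treatment,
        "bootstrap": boot,
        "tissue_subsampling": subsampling,
        "seed_manifest": {"seed": cfg.seed},
    }

    # flat CSV of every Cox term
    rows = _cox_rows("all", "discovery", main["discovery"])
    rows += _cox_rows("all", "validation", main["validation"])
    for tag, st in strata.items():
        if st.get("skipped"):
            continue
        rows += _cox_rows(tag, "discovery", st["discovery"])
        rows += _cox_rows(tag, "validation", st["validation"])
    pd.DataFrame(rows).to_csv(outdir / "cox_terms.csv", index=False)

    # KM curve export for plotting
    km_rows = []
    for cohort in ("discovery", "validation"):
        for grp in ("high", "low"):
            km = main[cohort].get(f"km_{grp}")
            if km is None:
                continue
            f = km.to_frame()
            f["group"], f["cohort"] = grp, cohort
            km_rows.append(f)
    if km_rows:
        pd.concat(km_rows, ignore_index=True).to_csv(outdir / "km_curves.csv", index=False)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    return report


def _jsonable(obj):
    import dataclasses

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            k: _jsonable(v) if isinstance(v, (np.ndarray, pd.DataFrame)) else v
            for k, v in dataclasses.asdict(obj).items()
        }
    if hasattr(obj, "to_frame"):
        return obj.to_frame().to_dict(orient="records")
    return str(obj)
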