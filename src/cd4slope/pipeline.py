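"""End-to-end run: generate → pair → endpoints → fit → predict, with a
run manifest and deterministic outputs under a fixed seed."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import GeneratorConfig
from .cohort import ANALYTE_VL, CohortTables, generate_cohort, write_cohort
from .endpoints import (
    build_endpoints,
    eligible_patients,
    model_rows,
    pair_concurrent,
    phase_slope_summary,
    sensitivity_subset,
)
from .mixedlm import forward_select, report_table, univariate_scan
from .model import PHASE_BOUNDARY_DAYS
from .predictor import PatientProfile, build_grid, solve_vl_threshold

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs have been removed."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    versions: dict
    counts: dict
    outputs: dict
    phase_summary: dict = field(default_factory=dict)
    suppression: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def config_hash(config: GeneratorConfig) -> str:
    blob = json.dumps(_jsonable(config.to_dict()), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def suppression_summary(cohort: CohortTables, window_days: int = 90) -> dict:
    """Fraction of patients with VL < 400 copies/mL at the visit nearest 6
    and 12 months (within ±window).  Patients with no VL in a window drop
    out of that denominator; an empty denominator is flagged."""
    vl = cohort.labs[cohort.labs["analyte"] == ANALYTE_VL]
    out: dict = {}
    if len(vl):
        vl = vl.merge(cohort.patients[["patient_id", "cart_start"]], on="patient_id")
        vl["t_days"] = (vl["date"] - vl["cart_start"]).dt.days
    for label, center in (("month6", PHASE_BOUNDARY_DAYS), ("month12", 365)):
        if not len(vl):
            out[label] = {"fraction": float("nan"), "n": 0, "undefined": True}
            continue
        window = vl[(vl["t_days"] - center).abs() <= window_days].copy()
        if not len(window):
            out[label] = {"fraction": float("nan"), "n": 0, "undefined": True}
            continue
        window["dist"] = (window["t_days"] - center).abs()
        nearest = (window.sort_values(["dist", "t_days"], kind="mergesort")
                   .groupby("patient_id").first())
        frac = float((nearest["value"] < 400.0).mean())
        out[label] = {"fraction": frac, "n": int(len(nearest)), "undefined": False}
    return out


def run_all(
    config: GeneratorConfig | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
    select_alpha: float = 0.20,
    criterion: str = "REML",
) -> RunManifest:
    """Run every stage and write cohort/, endpoints.csv, fit.json, report.md,
    grid.tsv, thresholds.tsv and manifest.json under ``out_dir``.

    Any stage failure removes this run's partial outputs and raises
    :class:`StageError` naming the stage.
    """
    if not isinstance(config, GeneratorConfig):
        config = GeneratorConfig.from_yaml(config)
    if seed is not None:
        config = config.replace(seed=int(seed))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "config"

    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("cd4slope")
    root.addHandler(handler)
    written.append(out_dir / "run.log")

    try:
        stage = "cohortgen"
        cohort = generate_cohort(config)
        paths = write_cohort(cohort, out_dir / "cohort")
        written.extend(paths.values())
        log.info("generated %d patients, %d lab rows", len(cohort.patients), len(cohort.labs))

        stage = "endpoints"
        pairs = pair_concurrent(cohort.labs)
        pairs_all = len(pairs)
        from .endpoints import add_t_days

        pairs = add_t_days(pairs, cohort)
        eligible = eligible_patients(cohort, pairs)
        if not eligible:
            raise ValueError("no eligible patients")
        pairs_eligible = pairs[pairs["patient_id"].isin(eligible)]
        endpoints = build_endpoints(cohort, pairs_eligible)
        late = model_rows(endpoints)
        log.info(
            "pairs=%d (eligible patients=%d, their pairs=%d); endpoints=%d "
            "(early discarded for the model=%d)",
            pairs_all, len(eligible), len(pairs_eligible), len(endpoints),
            len(endpoints) - len(late),
        )
        if not len(late):
            raise ValueError("no model endpoints beyond 6 months")
        ep_path = out_dir / "endpoints.csv"
        late.to_csv(ep_path, index=False)
        written.append(ep_path)
        summary = phase_slope_summary(endpoints)

        stage = "fit"
        uni = univariate_scan(late, criterion=criterion)
        final, trace = forward_select(late, alpha=select_alpha, criterion=criterion)
        fit_path = out_dir / "fit.json"
        payload = final.to_dict()
        payload["selection"] = {
            "steps": [[s, t, p] for s, t, p in trace.steps],
            "final_terms": trace.final_terms,
            "dropped_p": trace.dropped_p,
        }
        fit_path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")
        written.append(fit_path)
        report_path = out_dir / "report.md"
        report_path.write_text(report_table(uni, final))
        written.append(report_path)

        stage = "predict"
        profile = PatientProfile()
        grid_path = out_dir / "grid.tsv"
        grid = build_grid(profile, final)
        grid_path.write_text(grid.to_tsv())
        written.append(grid_path)
        thr_path = out_dir / "thresholds.tsv"
        if final.coef.get("log10_vl", 0.0) < 0:
            thr = solve_vl_threshold(profile, final, target_slope=20.0, mode="GRID")
            thr.to_csv(thr_path, sep="\t", index=False)
            written.append(thr_path)
        else:
            log.warning("fitted VL coefficient is not negative; thresholds skipped")

        stage = "manifest"
        supp = suppression_summary(cohort)
        manifest = RunManifest(
            config_hash=config_hash(config),
            seed=int(config.seed),
            versions={
                "cd4slope": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "python": ".".join(map(str, sys.version_info[:3])),
            },
            counts={
                "patients": int(len(cohort.patients)),
                "pairs": int(pairs_all),
                "eligible_patients": int(len(eligible)),
                "endpoints": int(len(endpoints)),
                "model_rows": int(len(late)),
                "model_n_obs": int(final.n_obs),
                "model_n_patients": int(final.n_patients),
            },
            outputs={k: str(p) for k, p in zip(
                ("log", "cohort", "endpoints", "fit", "report", "grid"),
                (out_dir / "run.log", out_dir / "cohort", ep_path, fit_path,
                 report_path, grid_path),
            )},
            phase_summary={
                "mean_slope_early": summary.mean_slope_early,
                "mean_slope_late": summary.mean_slope_late,
                "n_early": summary.n_early,
                "n_late": summary.n_late,
                "p_value": summary.p_value,
            },
            suppression=supp,
        )
        manifest.to_json(out_dir / "manifest.json")
        return manifest
    except Exception as exc:
        for path in written:
            try:
                if path.is_file():
                    path.unlink()
            except OSError:
                pass
        raise StageError(stage, exc) from exc
    finally:
        root.removeHandler(handler)
        handler.close()


def run_sensitivity(
    cohort: CohortTables,
    endpoints: pd.DataFrame,
    criterion: str = "REML",
) -> dict[str, "pd.DataFrame | dict"]:
    """Refit the final-model covariates on the three sensitivity subsets."""
    from .mixedlm import fit_terms

    results = {}
    terms = ["age", "vl", "cd4", "stage", "hepatitis", "period"]
    for rule in ("INITIAL_REGIMEN", "INITIAL_NNRTI", "MIN4"):
        subset = sensitivity_subset(endpoints, cohort, rule)
        entry: dict = {"n_obs": int(len(subset)),
                       "n_patients": int(subset["patient_id"].nunique()) if len(subset) else 0}
        if len(subset) > 20 and subset["patient_id"].nunique() > 5:
            fit = fit_terms(subset, terms, criterion=criterion)
            entry["fit"] = fit
        results[rule] = entry
    return results
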