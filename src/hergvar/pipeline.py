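"""End-to-end runs from a config file, with deterministic reporting.

Three input modes:

* ``simulate`` — generate a multi-lab study from a design (default: the
  145-experiment five-laboratory roster) and run the variability analyses;
* ``potency_table`` — read a CSV of per-experiment pIC50 records
  (drug_id, lab_id, experiment_id, pic50, sd_pic50, group_label, phase) and
  run the variability analyses;
* ``ted`` — read a TED-lite dataset, compute per-cell time courses and QC,
  derive fractional inhibition per cell, fit Hill curves per (lab, drug)
  experiment, and (when the design allows) run the variability analyses.

Outputs: per-cell time-course CSVs, Hill-fit tables, Decomposition and
MetaFit JSON, and a markdown/HTML summary.  All random stages are seeded
from the config; a rerun with the same seed writes byte-identical
machine-readable output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import meta, synthetic, ted, traces
from .errors import ConfigurationError
from .hill import fit_experiments

@dataclass
class PipelineConfig:
    mode: str = "simulate"              # simulate | potency_table | ted
    input_path: str | None = None       # table or dataset root for non-simulate
    out_dir: str = "results/pipeline"
    seed: int = 0
    tau: float = 0.18
    sigma_range: tuple[float, float] = (0.02, 0.15)
    subtraction_mode: str = "trace"     # trace | peak | none
    correction_mode: str = "averaged"   # averaged | per_concentration
    lab_grouping: str = "group_label"
    report_format: str = "markdown"     # markdown | html
    log_level: str = "info"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "potency_table", "ted"):
            raise ConfigurationError(f"unknown input mode {self.mode!r}")
        if self.mode != "simulate" and not self.input_path:
            raise ConfigurationError(f"mode {self.mode!r} requires input_path")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        if "sigma_range" in raw:
            raw["sigma_range"] = tuple(raw["sigma_range"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class StudyReport:
    out_dir: Path
    summary: dict
    files: list[Path] = field(default_factory=list)


def _config_hash(config: PipelineConfig) -> str:
    # analysis-relevant fields only, so the same analysis in a different
    # output directory hashes identically
    payload = dataclasses.asdict(config)
    for key in ("out_dir", "log_level"):
        payload.pop(key, None)
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _round_floats(obj, ndigits=10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        v = float(obj)
        return None if not np.isfinite(v) else round(v, ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _variability_block(records: pd.DataFrame, lab_grouping: str) -> dict:
    decomp = meta.decompose_descriptive(records, lab_grouping=lab_grouping)
    mixed = meta.fit_mixed_effects(records)
    out = {
        "n_experiments": int(len(records)),
        "descriptive": {
            "lab_offsets": decomp.lab_offsets.to_dict(),
            "span_pic50": decomp.span,
            "fold_ratio": decomp.fold_ratio,
        },
        "mixed_effects": {
            "tau": mixed.tau,
            "tau_ci": list(mixed.tau_ci),
            "fold_ratio": mixed.fold_ratio,
            "fold_ratio_ci": list(mixed.fold_ratio_ci),
        },
    }
    groups = records[lab_grouping]
    if groups.nunique() >= 2 and (groups.value_counts() >= 2).all():
        ls = meta.fit_location_scale(records, group_col=lab_grouping)
        out["location_scale"] = {
            "tau": ls.tau,
            "tau_ci": {k: list(v) for k, v in ls.tau_ci.items()},
            "fold_ratio": ls.fold_ratio,
        }
    return out


def _run_simulate(config: PipelineConfig, out: Path) -> tuple[dict, list[Path]]:
    design = synthetic.default_study_design(
        tau=config.tau, sigma_range=config.sigma_range, seed=config.seed)
    records, truth = synthetic.simulate_study(design)
    files = []
    for name, df in (("potency_records.csv", records), ("truth.csv", truth)):
        path = out / name
        df.to_csv(path, index=False, float_format="%.12g")
        files.append(path)
    summary = _variability_block(records, config.lab_grouping)
    wsum = meta.within_experiment_summary(records)
    summary["within_experiment"] = {
        "per_lab": wsum.per_lab.to_dict(orient="records"),
        "correlation_r": wsum.correlation_r,
    }
    return summary, files


def _run_potency_table(config: PipelineConfig, out: Path) -> tuple[dict, list[Path]]:
    path = Path(config.input_path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    records = pd.read_csv(path)
    grouping = config.lab_grouping
    if grouping not in records.columns:
        grouping = "lab_id"
    summary = _variability_block(records, grouping)
    return summary, []


def _run_ted(config: PipelineConfig, out: Path) -> tuple[dict, list[Path]]:
    root = Path(config.input_path)
    if not root.exists():
        raise FileNotFoundError(f"dataset root not found: {root}")
    dataset = ted.read_dataset(root)
    files: list[Path] = []
    tc_dir = out / "time_courses"
    tc_dir.mkdir(parents=True, exist_ok=True)
    points = []
    qc_rows = []
    man = dataset.manifest
    for cell_id, grp in man.groupby("cell_id", sort=True):
        grp = grp.sort_values("sweep_index")
        first = grp.iloc[0]
        cell = ted.CellExperiment(
            cell_id=cell_id, lab_id=first["lab_id"], drug=first["drug_name"],
            sweeps=[dataset.sweeps[(cell_id, int(i))] for i in grp["sweep_index"]],
            phase_per_sweep=list(grp["phase"]),
            conc_per_sweep=[float(c) if pd.notna(c) else float("nan")
                            for c in grp["nominal_concentration_molar"]],
            experiment_id=first["experiment_id"])
        mode = config.subtraction_mode
        if "e4031" not in cell.phases() and mode != "none":
            mode = "none"
        tc = traces.cell_time_course(cell, mode=mode)
        tc_path = tc_dir / f"{cell_id}.csv"
        tc.to_csv(tc_path, index=False, float_format="%.9g")
        files.append(tc_path)
        qc = {"cell_id": cell_id, "lab_id": cell.lab_id, "drug": cell.drug}
        qc.update(traces.cell_qc_summary(cell, mode=mode))
        qc_rows.append(qc)
        points.append(traces.phase_inhibition(cell, mode=mode))
    qc_df = pd.DataFrame(qc_rows)
    qc_path = out / "cell_qc.csv"
    qc_df.to_csv(qc_path, index=False, float_format="%.9g")
    files.append(qc_path)
    pts = pd.concat(points, ignore_index=True) if points else pd.DataFrame()
    summary: dict = {"n_cells": int(man["cell_id"].nunique())}
    if not pts.empty:
        pts_path = out / "inhibition_points.csv"
        pts.to_csv(pts_path, index=False, float_format="%.12g")
        files.append(pts_path)
        fits = fit_experiments(pts)
        fits_path = out / "hill_fits.csv"
        fits.to_csv(fits_path, index=False, float_format="%.12g")
        files.append(fits_path)
        summary["n_experiments"] = int(len(fits))
        ok = fits[fits.get("determined", False) == True]  # noqa: E712
        if {"drug", "lab_id"}.issubset(ok.columns) and \
                ok["drug"].nunique() >= 2 and ok["lab_id"].nunique() >= 2:
            rec = ok.rename(columns={"drug": "drug_id"}).assign(
                experiment_id=lambda d: d["lab_id"] + ":" + d["drug_id"],
                group_label=lambda d: d["lab_id"])
            summary["variability"] = _variability_block(rec, "group_label")
    return summary, files


def run_pipeline(config: PipelineConfig) -> StudyReport:
    """Execute the stages for the configured input mode."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    runner = {"simulate": _run_simulate,
              "potency_table": _run_potency_table,
              "ted": _run_ted}[config.mode]
    try:
        summary, files = runner(config, out)
    except Exception as exc:
        (out / "failure_manifest.json").write_text(json.dumps(
            {"stage": config.mode, "error": type(exc).__name__,
             "message": str(exc)}, indent=1))
        raise
    summary = {
        "mode": config.mode,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        **summary,
    }
    summary = _round_floats(summary)
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    files.append(summary_path)
    report_path = render_report(summary, out, fmt=config.report_format)
    files.append(report_path)
    return StudyReport(out_dir=out, summary=summary, files=files)


# ---------------------------------------------------------------------------
# reporting

def _fmt_pic50(v) -> str:
    return "" if v is None else f"{v:.2f}"


def _fmt_ratio(v) -> str:
    return "" if v is None else f"{v:.2g}"


def render_report(summary: dict, out_dir: str | Path,
                  fmt: str = "markdown") -> Path:
    """Deterministic study-level report; pIC50s at 2 dp, ratios at 2 sf."""
    lines = ["# hERG variability study report", ""]
    if "n_experiments" in summary:
        lines.append(f"Experiments analysed: {summary['n_experiments']}")
        lines.append("")
    desc = summary.get("descriptive")
    if desc:
        lines += ["## Descriptive decomposition", "",
                  "| lab group | offset (pIC50) |", "|---|---|"]
        for lab, off in sorted(desc["lab_offsets"].items()):
            lines.append(f"| {lab} | {_fmt_pic50(off)} |")
        lines += ["",
                  f"Residual 2.5–97.5th percentile span: "
                  f"{_fmt_pic50(desc['span_pic50'])} pIC50 units "
                  f"→ fold-ratio {_fmt_ratio(desc['fold_ratio'])}", ""]
    mix = summary.get("mixed_effects")
    if mix:
        ci = mix["tau_ci"]
        rci = mix["fold_ratio_ci"]
        lines += ["## Random-effects meta-analysis", "",
                  f"tau = {_fmt_pic50(mix['tau'])} "
                  f"(95% CI {_fmt_pic50(ci[0])} to {_fmt_pic50(ci[1])}) → "
                  f"fold-ratio {_fmt_ratio(mix['fold_ratio'])} "
                  f"(95% CI {_fmt_ratio(rci[0])} to {_fmt_ratio(rci[1])})", ""]
    ls = summary.get("location_scale")
    if ls:
        lines += ["## Location-scale model (per-laboratory residual SD)", "",
                  "| lab group | tau | fold-ratio |", "|---|---|---|"]
        for lab in sorted(ls["tau"]):
            lines.append(f"| {lab} | {_fmt_pic50(ls['tau'][lab])} | "
                         f"{_fmt_ratio(ls['fold_ratio'][lab])} |")
        lines.append("")
    text = "\n".join(lines)
    out = Path(out_dir)
    if fmt == "html":
        body = "".join(f"<p>{ln}</p>\n" for ln in lines if ln)
        path = out / "report.html"
        path.write_text(f"<html><body>\n{body}</body></html>\n")
    else:
        path = out / "report.md"
        path.write_text(text + "\n")
    return path
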