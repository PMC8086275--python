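"""End-to-end pipeline: births (real, simulated, or a published table)
→ per-dimension disaggregated tables → summary-measure report.

Outputs land in one directory: ``births.csv`` (simulate mode),
``disaggregated_<dimension>.csv`` per stratifier, ``summary.csv``
(Table-2 shape), and ``manifest.json`` echoing the configuration, the
seed, package/library versions and row counts.  A stage failure is
logged with the stage name, partial outputs are retained, and a
``FAILED`` marker file is written.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .disaggregate import DEFAULT_DIMENSIONS, disaggregate, read_tables_csv, write_table_csv
from .errors import EquimortError
from .io import read_births_csv, write_births_csv, write_summary_csv
from .measures import InequalityAnalysis
from .simulate import SyntheticConfig, generate_births

logger = logging.getLogger("equimort")

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "validate_births_csv", "ValidationReport"]


class PipelineConfig(BaseModel):
    """Configuration of one pipeline run; exactly one input mode."""

    mode: Literal["simulate", "births_csv", "table_csv"]
    births_csv: Optional[str] = None
    table_csv: Optional[str] = None
    simulate: Optional[SyntheticConfig] = None
    dimensions: list[str] = Field(
        default_factory=lambda: list(DEFAULT_DIMENSIONS)
    )
    window_months: int = Field(default=60, ge=1)
    min_n: int = Field(default=200, ge=0)
    ci_method: Literal["parametric", "bootstrap", "none"] = "parametric"
    n_draws: int = 2000
    seed: int = 0
    out_dir: str = "equimort_out"

    @model_validator(mode="after")
    def _check_mode(self):
        sources = {"simulate": self.simulate, "births_csv": self.births_csv,
                   "table_csv": self.table_csv}
        if sources[self.mode] is None:
            raise ValueError(f"mode={self.mode!r} but field {self.mode!r} is unset")
        others = [k for k, v in sources.items() if k != self.mode and v is not None]
        if others:
            raise ValueError(f"mode={self.mode!r} but {others} also set; use exactly one input")
        if self.mode in ("births_csv", "table_csv"):
            p = Path(sources[self.mode])
            if not p.exists():
                raise ValueError(f"{self.mode}: file {p} does not exist")
        if self.ci_method != "none" and self.n_draws < 100:
            raise ValueError("n_draws: must be >= 100 when a CI method is enabled")
        unknown = set(self.dimensions) - set(DEFAULT_DIMENSIONS)
        if unknown:
            raise ValueError(f"dimensions: unknown stratifiers {sorted(unknown)}")
        return self

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.model_validate(data)


@dataclass
class PipelineReport:
    out_dir: Path
    manifest: dict
    summary_path: Path | None = None
    table_paths: dict[str, Path] = field(default_factory=dict)
    errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": json.loads(config.model_dump_json()),
        "seed": config.seed,
        "versions": {
            "equimort": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
    }
    report = PipelineReport(out_dir=out, manifest=manifest)

    births = None
    tables = None
    try:
        if config.mode == "simulate":
            births = generate_births(config.simulate)
            write_births_csv(births, out / "births.csv")
            manifest["stages"]["simulate"] = {
                "n_births": len(births), "seed": config.simulate.seed,
            }
        elif config.mode == "births_csv":
            births = read_births_csv(config.births_csv)
            manifest["stages"]["load_births"] = {"n_births": len(births)}
        else:
            tables = read_tables_csv(config.table_csv)
            manifest["stages"]["load_table"] = {
                "dimensions": sorted(tables),
                "n_rows": sum(len(t.rows) for t in tables.values()),
            }
    except (EquimortError, ValueError, OSError) as exc:
        _fail(report, "input", exc)
        _finalise(report)
        return report

    if tables is None:
        tables = {}
        for dim in config.dimensions:
            spec = DEFAULT_DIMENSIONS[dim]
            try:
                table = disaggregate(
                    births, spec, config.window_months, min_n=config.min_n,
                    ci="bootstrap" if config.ci_method == "bootstrap" else "none",
                    n_boot=config.n_draws, seed=config.seed,
                )
            except (EquimortError, ValueError) as exc:
                _fail(report, f"disaggregate:{dim}", exc)
                continue
            tables[dim] = table
            path = out / f"disaggregated_{dim}.csv"
            write_table_csv(table, path)
            report.table_paths[dim] = path
            manifest["stages"][f"disaggregate:{dim}"] = {
                "subgroups": len(table.rows),
                "national_average": table.national_average,
            }
    else:
        for dim, table in tables.items():
            path = out / f"disaggregated_{dim}.csv"
            write_table_csv(table, path)
            report.table_paths[dim] = path

    try:
        wanted = {d: t for d, t in tables.items() if d in config.dimensions}
        analysis = InequalityAnalysis(wanted, births=births)
        ci = None if config.ci_method == "none" else (
            "parametric" if config.mode == "table_csv" or config.ci_method == "parametric"
            else "bootstrap"
        )
        results = analysis.fit(ci=ci, n_draws=config.n_draws, seed=config.seed)
        report.summary_path = out / "summary.csv"
        write_summary_csv(results.results, report.summary_path, notes=results.notes)
        manifest["stages"]["measures"] = {
            "n_results": len(results.results),
            "notes": results.notes,
            "ci_method": ci,
            "seed": config.seed,
        }
    except (EquimortError, ValueError) as exc:
        _fail(report, "measures", exc)

    _finalise(report)
    return report


def _finalise(report: PipelineReport) -> None:
    out = report.out_dir
    (out / "manifest.json").write_text(
        json.dumps(report.manifest, indent=2, default=str)
    )
    if report.errors:
        (out / "FAILED").write_text("\n".join(report.errors) + "\n")


def _fail(report: PipelineReport, stage: str, exc: Exception) -> None:
    msg = f"{stage}: {exc}"
    logger.error(msg)
    report.errors.append(msg)
    report.manifest["stages"][stage] = {"error": str(exc)}


# ---------------------------------------------------------------------------
# Birth-recode validation

@dataclass
class ValidationReport:
    path: str
    n_records: int
    n_in_window: int
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _rows(mask) -> str:
    idx = list(np.flatnonzero(np.asarray(mask))[:10] + 2)  # +2: header line
    more = int(np.sum(mask)) - len(idx)
    return f"rows {idx}" + (f" (+{more} more)" if more > 0 else "")


def validate_births_csv(path, window_months: int = 60) -> ValidationReport:
    """Column, type and invariant checks on a birth-recode CSV."""
    try:
        df = read_births_csv(path)
    except (ValueError, OSError) as exc:
        return ValidationReport(str(path), 0, 0, errors=[str(exc)])
    rep = ValidationReport(str(path), len(df), 0)

    age = df["interview_cmc"] - df["dob_cmc"]
    rep.n_in_window = int(((age >= 0) & (age < window_months)).sum())

    bad = (age < 0).to_numpy()
    if bad.any():
        rep.errors.append(f"dob_cmc after interview_cmc: {_rows(bad)}")
    bad = (df["weight"] <= 0).to_numpy()
    if bad.any():
        rep.errors.append(f"non-positive weight: {_rows(bad)}")
    has_aad = df["age_at_death_months"].notna().to_numpy()
    alive = df["alive"].to_numpy()
    bad = alive & has_aad
    if bad.any():
        rep.errors.append(f"alive record with age_at_death_months: {_rows(bad)}")
    bad = ~alive & ~has_aad
    if bad.any():
        rep.errors.append(f"death without age_at_death_months: {_rows(bad)}")
    aad = df["age_at_death_months"].to_numpy(dtype=float, na_value=np.nan)
    with np.errstate(invalid="ignore"):
        bad = has_aad & (aad < 0)
        if bad.any():
            rep.errors.append(f"negative age_at_death_months: {_rows(bad)}")
        bad = has_aad & (aad >= age.to_numpy())
        if bad.any():
            rep.errors.append(
                f"age_at_death_months not lived by interview: {_rows(bad)}"
            )
    wq = df["wealth_quintile"].astype(str)
    bad = ~wq.isin(list("12345")).to_numpy()
    if bad.any():
        rep.warnings.append(f"wealth_quintile outside 1..5: {_rows(bad)}")
    bad = ~df["sex"].isin(["male", "female"]).to_numpy()
    if bad.any():
        rep.warnings.append(f"sex not male/female: {_rows(bad)}")
    if rep.n_in_window == 0:
        rep.warnings.append(f"no births in the {window_months}-month window")
    return rep
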