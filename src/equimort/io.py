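"""Readers and writers for the package's CSV formats.

Formats
-------
* simplified birth-recode CSV — one row per live birth, columns
  :data:`equimort.simulate.BIRTH_COLUMNS`; a missing age at death is an
  empty field.  Floats are written in shortest-repr form so write → read
  round-trips bit-exactly.
* DHS Birth Recode converter — maps the standard BR variable names
  (b3, b4, b5, b7, v001, v005, v008, v025, v106, v190) onto the
  simplified schema; DHS weights (v005) are scaled by 1e-6 to unit
  scale.
* summary CSV — Table-2-shaped measure report with 2-decimal display
  columns plus full-precision ``*_full`` columns.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import BIRTH_COLUMNS

__all__ = [
    "write_births_csv",
    "read_births_csv",
    "from_dhs_br",
    "write_summary_csv",
    "read_summary_csv",
]

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False}


def write_births_csv(births: pd.DataFrame, path) -> None:
    out = births.loc[:, list(BIRTH_COLUMNS)].copy()
    out["alive"] = out["alive"].map({True: "true", False: "false"})
    out.to_csv(path, index=False)


def read_births_csv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={
            "sex": str, "education": str, "residence": str, "region": str,
            "wealth_quintile": str, "alive": str,
        },
    )
    missing = set(BIRTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["alive"] = df["alive"].str.lower().map(_BOOL_MAP)
    if df["alive"].isna().any():
        bad = int(df["alive"].isna().idxmax()) + 2
        raise ValueError(f"{path}: unparseable alive value near row {bad}")
    df["alive"] = df["alive"].astype(bool)
    df["age_at_death_months"] = df["age_at_death_months"].astype("Int64")
    return df


# DHS BR variable name → simplified schema.  v005 is the sampling
# weight times 1e6 in DHS recodes.
_DHS_MAP = {
    "b3": "dob_cmc",
    "v001": "cluster_id",
    "v008": "interview_cmc",
}
_DHS_SEX = {1: "male", 2: "female"}
_DHS_RESIDENCE = {1: "urban", 2: "rural"}
_DHS_EDUCATION = {0: "none", 1: "primary", 2: "secondary+", 3: "secondary+"}


def from_dhs_br(br: pd.DataFrame, region_column: str | None = None) -> pd.DataFrame:
    """Convert a DHS Birth Recode extract to the simplified schema."""
    required = {"b3", "b4", "b5", "v001", "v005", "v008", "v025", "v106", "v190"}
    missing = required - set(br.columns)
    if missing:
        raise ValueError(f"DHS BR extract missing variables: {sorted(missing)}")
    out = pd.DataFrame(index=br.index)
    out["child_id"] = np.arange(1, len(br) + 1)
    for src, dst in _DHS_MAP.items():
        out[dst] = br[src].astype(int)
    out["weight"] = br["v005"].astype(float) / 1e6
    out["sex"] = br["b4"].astype(int).map(_DHS_SEX)
    out["alive"] = br["b5"].astype(int) == 1
    aad = pd.array(br["b7"] if "b7" in br else [pd.NA] * len(br), dtype="Int64")
    aad[np.asarray(out["alive"])] = pd.NA
    out["age_at_death_months"] = aad
    out["wealth_quintile"] = br["v190"].astype(int).astype(str)
    out["education"] = br["v106"].astype(int).map(_DHS_EDUCATION)
    out["residence"] = br["v025"].astype(int).map(_DHS_RESIDENCE)
    out["region"] = br[region_column].astype(str) if region_column else "all"
    return out.loc[:, list(BIRTH_COLUMNS)].reset_index(drop=True)


def write_summary_csv(results, path, notes=None) -> None:
    """Write summary measures with display and full-precision columns."""
    rows = []
    for r in results:
        rows.append(
            {
                "dimension": r.dimension,
                "measure": r.measure,
                "estimate": "" if r.estimate is None else f"{r.estimate:.2f}",
                "ci_low": "" if r.ci_low is None else f"{r.ci_low:.2f}",
                "ci_high": "" if r.ci_high is None else f"{r.ci_high:.2f}",
                "estimate_full": r.estimate,
                "ci_low_full": r.ci_low,
                "ci_high_full": r.ci_high,
                "scale": r.scale,
                "reference_subgroup": r.reference_subgroup or "",
                "comparison_subgroup": r.comparison_subgroup or "",
                "note": r.note or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    if notes:
        Path(str(path) + ".notes.txt").write_text("\n".join(notes) + "\n")


def read_summary_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
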