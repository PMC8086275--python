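"""Subgroup-level IMR estimates per equity stratifier.

Produces a disaggregated table in the shape used by equity-monitoring
tools: one row per subgroup with its IMR estimate per 1000, confidence
bounds, and its (unweighted) birth count, plus the national average µ
computed from the full sample.  Tables can also be read directly from a
CSV of published disaggregated estimates, which is how printed tables
enter the summary-measure stage without microdata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TableParseError, UndefinedEstimateError
from .imr import SyntheticCohortIMR, _window_mask, cohort_imr_oracle

__all__ = [
    "DimensionSpec",
    "SubgroupEstimate",
    "DisaggregatedTable",
    "DEFAULT_DIMENSIONS",
    "disaggregate",
    "table_from_csv",
    "read_tables_csv",
    "write_table_csv",
]


@dataclass(frozen=True)
class DimensionSpec:
    """An equity stratifier and its ordering convention.

    ``subgroup_order`` runs from most disadvantaged to most advantaged
    (poorest → richest, no education → secondary+, rural → urban,
    male → female); it is required for ordered and binary dimensions and
    absent for unordered ones (region).  ``adverse_indicator`` is True
    for indicators where higher is worse, which IMR is.
    """

    name: str
    kind: str  # ordered | binary | unordered
    subgroup_order: tuple[str, ...] | None = None
    adverse_indicator: bool = True

    def __post_init__(self):
        if self.kind not in ("ordered", "binary", "unordered"):
            raise ValueError(f"kind must be ordered/binary/unordered, got {self.kind!r}")
        if self.kind in ("ordered", "binary"):
            order = self.subgroup_order
            if order is None or len(order) < 2:
                raise ValueError(f"{self.kind} dimension {self.name!r} needs >= 2 ordered subgroups")
            if len(set(order)) != len(order):
                raise ValueError(f"duplicate subgroups in order for {self.name!r}")
            if self.kind == "binary" and len(order) != 2:
                raise ValueError(f"binary dimension {self.name!r} needs exactly 2 subgroups")
        elif self.subgroup_order is not None:
            raise ValueError(f"unordered dimension {self.name!r} must not carry an order")


DEFAULT_DIMENSIONS: dict[str, DimensionSpec] = {
    "wealth_quintile": DimensionSpec("wealth_quintile", "ordered", ("1", "2", "3", "4", "5")),
    "education": DimensionSpec("education", "ordered", ("none", "primary", "secondary+")),
    "residence": DimensionSpec("residence", "binary", ("rural", "urban")),
    "sex": DimensionSpec("sex", "binary", ("male", "female")),
    "region": DimensionSpec("region", "unordered"),
}


@dataclass
class SubgroupEstimate:
    """One subgroup row of a disaggregated table."""

    dimension: str
    subgroup: str
    estimate_per_1000: float | None
    ci_low: float | None
    ci_high: float | None
    population: int
    population_share: float
    weighted_population: float | None = None
    rank_order: int | None = None
    na_reason: str | None = None

    def __post_init__(self):
        if self.estimate_per_1000 is None and not self.na_reason:
            raise ValueError(
                f"{self.dimension}/{self.subgroup}: NA estimate requires a reason"
            )


@dataclass
class DisaggregatedTable:
    """Subgroup estimates plus the national average µ for one dimension."""

    indicator: str
    dimension: DimensionSpec
    rows: list[SubgroupEstimate]
    national_average: float
    national_population: int | None = None

    def __post_init__(self):
        seen = [r.subgroup for r in self.rows]
        if len(set(seen)) != len(seen):
            raise ValueError(f"duplicate subgroup rows in {self.dimension.name}")
        if self.national_average < 0:
            raise ValueError("national average must be >= 0")

    def estimates(self) -> dict[str, float | None]:
        return {r.subgroup: r.estimate_per_1000 for r in self.rows}

    def row(self, subgroup: str) -> SubgroupEstimate:
        for r in self.rows:
            if r.subgroup == subgroup:
                return r
        raise KeyError(f"no subgroup {subgroup!r} in dimension {self.dimension.name!r}")

    def ordered_rows(self) -> list[SubgroupEstimate]:
        """Rows in disadvantaged → advantaged order (ordered/binary only)."""
        if self.dimension.subgroup_order is None:
            return list(self.rows)
        return [self.row(s) for s in self.dimension.subgroup_order]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "indicator": self.indicator,
                "dimension": r.dimension,
                "subgroup": r.subgroup,
                "estimate": r.estimate_per_1000,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "population": r.population,
                "population_share": r.population_share,
                "national": 0,
            }
            for r in self.rows
        )


def disaggregate(
    births: pd.DataFrame,
    spec: DimensionSpec,
    window_months: int = 60,
    min_n: int = 200,
    ci: str = "none",
    n_boot: int = 1000,
    seed: int | None = None,
    indicator: str = "imr",
) -> DisaggregatedTable:
    """Estimate IMR per subgroup of ``spec`` plus the national average.

    Subgroups with fewer than ``min_n`` births in the window get an NA
    estimate (reason "insufficient sample"), mirroring the suppression
    of small-sample subnational estimates in published tables.
    """
    if spec.name not in births.columns:
        raise ValueError(f"births table has no column {spec.name!r}")
    values = births[spec.name].astype(str)
    if spec.subgroup_order is not None:
        unknown = sorted(set(values) - set(spec.subgroup_order))
        if unknown:
            raise ValueError(
                f"unknown {spec.name} subgroups in data: {unknown}; "
                f"expected {list(spec.subgroup_order)}"
            )
        subgroups = list(spec.subgroup_order)
    else:
        subgroups = sorted(values.unique())

    in_window = _window_mask(births, window_months)
    total_pop = int(in_window.sum())
    national = SyntheticCohortIMR(births, window_months).fit(
        ci=ci, n_boot=n_boot, seed=seed
    )

    rows = []
    for i, sub in enumerate(subgroups):
        sel = births.loc[(values == sub).to_numpy() & in_window]
        pop = len(sel)
        share = pop / total_pop if total_pop else 0.0
        if pop < min_n:
            rows.append(
                SubgroupEstimate(
                    spec.name, sub, None, None, None, pop, share,
                    na_reason="insufficient sample",
                    rank_order=i + 1 if spec.subgroup_order else None,
                )
            )
            continue
        try:
            res = SyntheticCohortIMR(sel, window_months).fit(
                ci=ci, n_boot=n_boot, seed=None if seed is None else seed + i
            )
        except UndefinedEstimateError as exc:
            rows.append(
                SubgroupEstimate(
                    spec.name, sub, None, None, None, pop, share,
                    na_reason=str(exc),
                    rank_order=i + 1 if spec.subgroup_order else None,
                )
            )
            continue
        e = res.estimate
        rows.append(
            SubgroupEstimate(
                spec.name, sub, e.rate_per_1000, e.ci_low, e.ci_high, pop, share,
                weighted_population=e.weighted_births,
                rank_order=i + 1 if spec.subgroup_order else None,
            )
        )
    return DisaggregatedTable(
        indicator=indicator,
        dimension=spec,
        rows=rows,
        national_average=national.rate_per_1000,
        national_population=total_pop,
    )


# ---------------------------------------------------------------------------
# CSV interface (HEAT-style disaggregated tables)

_TABLE_COLUMNS = ["dimension", "subgroup", "estimate", "ci_low", "ci_high", "population"]


def _parse_float(value, row_no: int, col: str, allow_na: bool) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        if allow_na:
            return None
        raise TableParseError(f"row {row_no}: missing value in column {col!r}")
    try:
        return float(value)
    except (TypeError, ValueError):
        raise TableParseError(f"row {row_no}: malformed number {value!r} in column {col!r}")


def read_tables_csv(
    path, specs: dict[str, DimensionSpec] | None = None, indicator: str = "imr"
) -> dict[str, DisaggregatedTable]:
    """Read a HEAT-style disaggregated CSV into one table per dimension.

    The file needs columns dimension, subgroup, estimate, ci_low,
    ci_high, population; an optional ``national`` flag column marks the
    national-average row (dimension ``all`` applies to every dimension).
    A missing estimate is read as NA.  If no national row is present,
    µ is the population-weighted mean of the subgroup estimates.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype={"dimension": str, "subgroup": str})
    except pd.errors.EmptyDataError:
        raise TableParseError(f"{path}: empty file")
    missing = set(_TABLE_COLUMNS) - set(raw.columns)
    if missing:
        raise TableParseError(f"{path}: missing columns {sorted(missing)}")
    if "national" not in raw.columns:
        raw["national"] = 0
    if len(raw) == 0:
        raise TableParseError(f"{path}: no data rows")

    specs = dict(DEFAULT_DIMENSIONS if specs is None else specs)
    national_rows = raw[raw["national"].fillna(0).astype(int) == 1]
    body = raw[raw["national"].fillna(0).astype(int) != 1]

    global_mu = None
    global_pop = None
    per_dim_mu: dict[str, float] = {}
    for idx, r in national_rows.iterrows():
        mu = _parse_float(r["estimate"], idx + 2, "estimate", allow_na=False)
        if str(r["dimension"]) in ("all", "", "nan"):
            global_mu = mu
            pop = _parse_float(r["population"], idx + 2, "population", allow_na=True)
            global_pop = int(pop) if pop is not None else None
        else:
            per_dim_mu[str(r["dimension"])] = mu

    tables: dict[str, DisaggregatedTable] = {}
    for dim, grp in body.groupby("dimension", sort=False):
        spec = specs.get(dim)
        if spec is None:
            spec = DimensionSpec(dim, "unordered")
        rows = []
        pops = []
        for idx, r in grp.iterrows():
            row_no = idx + 2  # header is line 1
            est = _parse_float(r["estimate"], row_no, "estimate", allow_na=True)
            lo = _parse_float(r["ci_low"], row_no, "ci_low", allow_na=True)
            hi = _parse_float(r["ci_high"], row_no, "ci_high", allow_na=True)
            pop = _parse_float(r["population"], row_no, "population", allow_na=False)
            if est is not None and est < 0:
                raise TableParseError(f"row {row_no}: negative estimate {est}")
            pops.append(pop)
            rows.append(
                SubgroupEstimate(
                    dim, str(r["subgroup"]), est, lo, hi, int(pop), 0.0,
                    na_reason=None if est is not None else "missing in source",
                )
            )
        total = sum(pops)
        for row, pop in zip(rows, pops):
            row.population_share = pop / total if total else 0.0
        if spec.subgroup_order is not None:
            labels = {r.subgroup for r in rows}
            missing_subs = set(spec.subgroup_order) - labels
            extra = labels - set(spec.subgroup_order)
            if missing_subs or extra:
                raise TableParseError(
                    f"dimension {dim!r}: subgroups {sorted(labels)} do not match "
                    f"spec order {list(spec.subgroup_order)}"
                )
            for r in rows:
                r.rank_order = spec.subgroup_order.index(r.subgroup) + 1
        mu = per_dim_mu.get(dim, global_mu)
        if mu is None:
            known = [(r.estimate_per_1000, p) for r, p in zip(rows, pops)
                     if r.estimate_per_1000 is not None]
            if not known:
                raise TableParseError(f"dimension {dim!r}: all estimates missing and no national row")
            mu = sum(e * p for e, p in known) / sum(p for _, p in known)
        stated_pop = global_pop
        if stated_pop is not None and abs(total - stated_pop) > 1:
            warnings.warn(
                f"dimension {dim!r}: subgroup populations sum to {int(total)} "
                f"but national row states {stated_pop}",
                stacklevel=2,
            )
        tables[dim] = DisaggregatedTable(
            indicator=indicator,
            dimension=spec,
            rows=rows,
            national_average=mu,
            national_population=stated_pop if stated_pop is not None else int(total),
        )
    return tables


def table_from_csv(
    path, dimension: str | None = None, specs: dict[str, DimensionSpec] | None = None
) -> DisaggregatedTable:
    """Read one dimension's disaggregated table from a CSV."""
    tables = read_tables_csv(path, specs=specs)
    if dimension is None:
        if len(tables) != 1:
            raise TableParseError(
                f"file holds dimensions {sorted(tables)}; pass dimension= to pick one"
            )
        return next(iter(tables.values()))
    if dimension not in tables:
        raise TableParseError(f"dimension {dimension!r} not in file (has {sorted(tables)})")
    return tables[dimension]


def write_table_csv(tables, path) -> None:
    """Write one or several disaggregated tables to a HEAT-style CSV.

    Floats are written in shortest-repr form so a read round-trips to
    bit-identical values.
    """
    if isinstance(tables, DisaggregatedTable):
        tables = {tables.dimension.name: tables}
    records = [
        {
            "indicator": table.indicator,
            "dimension": dim,
            "subgroup": r.subgroup,
            "estimate": r.estimate_per_1000,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "population": r.population,
            "national": 0,
        }
        for dim, table in tables.items()
        for r in table.rows
    ]
    first = next(iter(tables.values()))
    records.append(
        {
            "indicator": first.indicator,
            "dimension": "all",
            "subgroup": "national_average",
            "estimate": first.national_average,
            "ci_low": None,
            "ci_high": None,
            "population": first.national_population,
            "national": 1,
        }
    )
    pd.DataFrame(records).to_csv(path, index=False)


def aggregation_check(births: pd.DataFrame, spec: DimensionSpec, window_months: int = 60):
    """Exact decomposition check for the direct-cohort proportion:
    population-weighted mean of subgroup oracle rates vs overall."""
    values = births[spec.name].astype(str)
    overall = cohort_imr_oracle(births, window_months)
    parts = []
    for sub in values.unique():
        sel = births.loc[(values == sub).to_numpy()]
        w = sel.loc[
            _window_mask(sel, window_months)
            & ((sel["interview_cmc"] - sel["dob_cmc"]) >= 12)
        ]["weight"].sum()
        parts.append((cohort_imr_oracle(sel, window_months), w))
    combined = sum(r * w for r, w in parts) / sum(w for _, w in parts)
    return overall, combined
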