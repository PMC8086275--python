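"""Inequality summary measures over a disaggregated table.

Four measures used in health-inequality monitoring, computed on the
per-1000 scale of the indicator:

* **Difference** ``D = mu_dis − mu_adv``: the gap between the two
  extreme ordered subgroups (poorest vs richest, no-education vs
  secondary+, rural vs urban, male vs female).  Zero under equality;
  positive when the adverse outcome is concentrated among the
  disadvantaged.
* **Ratio** ``R = mu_dis / mu_adv``: the same comparison on the
  relative scale; one under equality.
* **PAR / PAF**: population attributable risk ``PAR = mu_ref − mu``
  where ``mu`` is the national average and the reference subgroup is
  the best-performing (lowest-estimate, for an adverse indicator) one;
  ``PAF = 100 · PAR / mu`` is the percentage of the national rate that
  would be removed if every subgroup matched the reference.  Both are
  ≤ 0 for adverse indicators.
* **ACI** (absolute concentration index): the population-weighted
  gradient across all ordered subgroups.  With subgroup population
  shares ``p_j`` ordered disadvantaged → advantaged, midpoint ranks
  ``x_j = c_{j−1} + p_j/2`` (``c`` the cumulative share), and subgroup
  estimates ``mu_j``,

      ACI = Σ_j p_j · mu_j · (2 x_j − 1) = 2 · cov_w(mu, x).

  Zero under equality (since Σ p_j x_j = 1/2); negative when the
  adverse outcome concentrates among the disadvantaged.

Confidence intervals: D uses a Wald interval from the subgroup standard
errors; R a delta-method interval on the log scale; PAR/PAF/ACI a
parametric simulation that redraws subgroup estimates from normal
distributions implied by their printed CIs (reference subgroup
re-selected per draw for PAR/PAF).  When raw birth records are
available a cluster bootstrap is offered for every measure instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .disaggregate import DimensionSpec, DisaggregatedTable, SubgroupEstimate, disaggregate
from .errors import UndefinedMeasureError, UnsupportedMeasureError

__all__ = [
    "SummaryResult",
    "difference",
    "ratio",
    "par",
    "paf",
    "aci",
    "measure_ci",
    "run_all",
    "InequalityAnalysis",
    "InequalityResults",
    "MEASURES_BY_KIND",
]

_Z = float(stats.norm.ppf(0.975))

#: Which measures apply to which dimension kind (gradient measures need
#: a full ordering; pairwise measures need at least the two extremes).
MEASURES_BY_KIND = {
    "ordered": ("ACI", "D", "PAF", "R"),
    "binary": ("D", "PAF", "R"),
    "unordered": (),
}


@dataclass
class SummaryResult:
    """One inequality measure for one dimension."""

    dimension: str
    measure: str  # D | R | PAR | PAF | ACI
    estimate: float
    scale: str  # absolute | relative
    ci_low: float | None = None
    ci_high: float | None = None
    reference_subgroup: str | None = None
    comparison_subgroup: str | None = None
    note: str | None = None


def _extremes(table: DisaggregatedTable) -> tuple[SubgroupEstimate, SubgroupEstimate]:
    spec = table.dimension
    if spec.kind not in ("ordered", "binary"):
        raise UnsupportedMeasureError(
            f"pairwise measures need an ordered or binary dimension; "
            f"{spec.name!r} is {spec.kind}"
        )
    rows = table.ordered_rows()
    dis, adv = rows[0], rows[-1]
    for row in (dis, adv):
        if row.estimate_per_1000 is None:
            raise UndefinedMeasureError(
                f"{spec.name}/{row.subgroup}: estimate NA ({row.na_reason})"
            )
    return dis, adv


def difference(table: DisaggregatedTable) -> SummaryResult:
    """Absolute gap between the extreme ordered subgroups, per 1000."""
    dis, adv = _extremes(table)
    return SummaryResult(
        dimension=table.dimension.name,
        measure="D",
        estimate=dis.estimate_per_1000 - adv.estimate_per_1000,
        scale="absolute",
        comparison_subgroup=dis.subgroup,
        reference_subgroup=adv.subgroup,
    )


def ratio(table: DisaggregatedTable) -> SummaryResult:
    """Relative gap between the extreme ordered subgroups."""
    dis, adv = _extremes(table)
    if adv.estimate_per_1000 == 0:
        raise UndefinedMeasureError(
            f"{table.dimension.name}/{adv.subgroup}: zero estimate in denominator"
        )
    return SummaryResult(
        dimension=table.dimension.name,
        measure="R",
        estimate=dis.estimate_per_1000 / adv.estimate_per_1000,
        scale="relative",
        comparison_subgroup=dis.subgroup,
        reference_subgroup=adv.subgroup,
    )


def _reference_row(table: DisaggregatedTable) -> SubgroupEstimate:
    known = [r for r in table.rows if r.estimate_per_1000 is not None]
    if not known:
        raise UndefinedMeasureError(f"{table.dimension.name}: all subgroup estimates NA")
    if table.dimension.adverse_indicator:
        return min(known, key=lambda r: r.estimate_per_1000)
    return max(known, key=lambda r: r.estimate_per_1000)


def par(table: DisaggregatedTable) -> SummaryResult:
    """Population attributable risk: reference estimate minus µ."""
    if table.national_average <= 0:
        raise UndefinedMeasureError("national average must be positive for PAR/PAF")
    ref = _reference_row(table)
    return SummaryResult(
        dimension=table.dimension.name,
        measure="PAR",
        estimate=ref.estimate_per_1000 - table.national_average,
        scale="absolute",
        reference_subgroup=ref.subgroup,
    )


def paf(table: DisaggregatedTable) -> SummaryResult:
    """Population attributable fraction: 100 · PAR / µ (percent)."""
    base = par(table)
    return SummaryResult(
        dimension=base.dimension,
        measure="PAF",
        estimate=100.0 * base.estimate / table.national_average,
        scale="relative",
        reference_subgroup=base.reference_subgroup,
    )


def midpoint_ranks(populations) -> tuple[np.ndarray, np.ndarray]:
    """Population shares and midpoint cumulative-share ranks.

    Computed in exact rational arithmetic before conversion to float, so
    Σ p_j x_j = 1/2 holds exactly and reversing the subgroup order
    negates the rank weights 2x_j − 1 exactly.
    """
    shares, ranks, _ = _rational_ranks(populations)
    return (
        np.array([float(s) for s in shares]),
        np.array([float(x) for x in ranks]),
    )


def _rational_ranks(populations):
    fracs = [Fraction(p) for p in populations]
    total = sum(fracs)
    if any(f <= 0 for f in fracs) or total <= 0:
        raise UndefinedMeasureError("non-positive populations")
    shares = [f / total for f in fracs]
    cum = Fraction(0)
    ranks = []
    for s in shares:
        ranks.append(cum + s / 2)
        cum += s
    # p_j (2 x_j − 1): exactly antisymmetric under order reversal
    weights = [s * (2 * x - 1) for s, x in zip(shares, ranks)]
    return shares, ranks, weights


def _shares_and_ranks(table: DisaggregatedTable, use_weighted_shares: bool):
    rows = table.ordered_rows()
    est = []
    for r in rows:
        if r.estimate_per_1000 is None:
            raise UndefinedMeasureError(
                f"{table.dimension.name}/{r.subgroup}: estimate NA ({r.na_reason})"
            )
        est.append(r.estimate_per_1000)
    if use_weighted_shares:
        pops = [r.weighted_population for r in rows]
        if any(p is None for p in pops):
            raise UndefinedMeasureError(
                f"{table.dimension.name}: weighted populations unavailable"
            )
    else:
        pops = [r.population for r in rows]
    p, x = midpoint_ranks(pops)
    return np.asarray(est, dtype=float), p, x


def aci(table: DisaggregatedTable, use_weighted_shares: bool = False) -> SummaryResult:
    """Absolute concentration index across the ordered subgroups."""
    if table.dimension.kind != "ordered":
        raise UnsupportedMeasureError(
            f"ACI needs an ordered dimension; {table.dimension.name!r} is "
            f"{table.dimension.kind}"
        )
    rows = table.ordered_rows()
    est = []
    for r in rows:
        if r.estimate_per_1000 is None:
            raise UndefinedMeasureError(
                f"{table.dimension.name}/{r.subgroup}: estimate NA ({r.na_reason})"
            )
        est.append(r.estimate_per_1000)
    pops = [r.weighted_population for r in rows] if use_weighted_shares else [r.population for r in rows]
    if use_weighted_shares and any(p is None for p in pops):
        raise UndefinedMeasureError(f"{table.dimension.name}: weighted populations unavailable")
    _, _, weights = _rational_ranks(pops)
    if all(e == est[0] for e in est):
        value = 0.0  # exact null: Σ p_j x_j = 1/2 makes the index vanish
    else:
        # Rank weights are exact rationals (antisymmetric under order
        # reversal) and fsum is correctly rounded, so reversing the
        # subgroup order negates the index bit-for-bit.
        value = math.fsum(float(w) * e for w, e in zip(weights, est))
    return SummaryResult(
        dimension=table.dimension.name,
        measure="ACI",
        estimate=value,
        scale="absolute",
    )


_MEASURE_FUNCS = {"D": difference, "R": ratio, "PAR": par, "PAF": paf, "ACI": aci}


# ---------------------------------------------------------------------------
# Confidence intervals

def _se_from_ci(row: SubgroupEstimate) -> float:
    if row.ci_low is None or row.ci_high is None:
        raise UndefinedMeasureError(
            f"{row.dimension}/{row.subgroup}: no CI to derive a standard error from"
        )
    return (row.ci_high - row.ci_low) / (2 * _Z)


def _parametric_ci(
    table: DisaggregatedTable,
    measure: str,
    n_draws: int,
    seed: int | None,
    alpha: float,
) -> tuple[float, float]:
    """Redraw subgroup estimates from N(mu_j, SE_j) and recompute."""
    rows = [r for r in table.rows if r.estimate_per_1000 is not None]
    if measure in ("D", "R", "ACI"):
        rows = [r for r in table.ordered_rows()]
    mus = np.array([r.estimate_per_1000 for r in rows], dtype=float)
    ses = np.array([_se_from_ci(r) for r in rows], dtype=float)
    rng = np.random.default_rng(seed)
    draws = rng.normal(mus, ses, size=(n_draws, len(rows)))

    if measure == "D":
        vals = draws[:, 0] - draws[:, -1]
    elif measure == "R":
        denom = draws[:, -1]
        vals = np.where(denom != 0, draws[:, 0] / denom, np.nan)
    elif measure == "ACI":
        pops = np.array([r.population for r in rows], dtype=float)
        p = pops / pops.sum()
        x = np.cumsum(p) - p / 2
        vals = draws @ (p * (2 * x - 1))
    elif measure in ("PAR", "PAF"):
        mu = table.national_average
        ref = draws.min(axis=1) if table.dimension.adverse_indicator else draws.max(axis=1)
        vals = ref - mu
        if measure == "PAF":
            vals = 100.0 * vals / mu
    else:
        raise ValueError(f"unknown measure {measure!r}")
    vals = vals[np.isfinite(vals)]
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def measure_ci(
    table: DisaggregatedTable,
    measure: str,
    method: str = "parametric",
    n_draws: int = 2000,
    seed: int | None = None,
    alpha: float = 0.05,
    births: pd.DataFrame | None = None,
    window_months: int = 60,
    min_n: int = 200,
) -> tuple[float, float]:
    """95% CI bounds for a summary measure.

    ``method="parametric"`` works from the subgroup CIs in the table:
    closed-form Wald for D, log-scale delta method for R, and normal
    parametric simulation for PAR/PAF/ACI.  ``method="bootstrap"``
    resamples survey clusters from ``births`` and re-runs the whole
    disaggregation per replicate.
    """
    if measure not in _MEASURE_FUNCS:
        raise ValueError(f"unknown measure {measure!r}")
    if method == "parametric":
        if measure == "D":
            dis, adv = _extremes(table)
            se = float(np.hypot(_se_from_ci(dis), _se_from_ci(adv)))
            d = dis.estimate_per_1000 - adv.estimate_per_1000
            return d - _Z * se, d + _Z * se
        if measure == "R":
            dis, adv = _extremes(table)
            if dis.estimate_per_1000 <= 0 or adv.estimate_per_1000 <= 0:
                raise UndefinedMeasureError("log-scale CI needs positive estimates")
            se_log = float(
                np.hypot(
                    _se_from_ci(dis) / dis.estimate_per_1000,
                    _se_from_ci(adv) / adv.estimate_per_1000,
                )
            )
            r = dis.estimate_per_1000 / adv.estimate_per_1000
            return float(r * np.exp(-_Z * se_log)), float(r * np.exp(_Z * se_log))
        return _parametric_ci(table, measure, n_draws, seed, alpha)
    if method == "bootstrap":
        if births is None:
            raise UndefinedMeasureError("cluster bootstrap needs raw birth records")
        return _bootstrap_ci(
            births, table.dimension, measure, n_draws, seed, alpha, window_months, min_n
        )
    raise ValueError(f"unknown CI method {method!r}")


def _bootstrap_ci(
    births, spec: DimensionSpec, measure, n_boot, seed, alpha, window_months, min_n
):
    rng = np.random.default_rng(seed)
    clusters = births["cluster_id"].unique()
    groups = {c: g for c, g in births.groupby("cluster_id")}
    vals = []
    for _ in range(n_boot):
        take = rng.choice(clusters, size=len(clusters), replace=True)
        sample = pd.concat([groups[c] for c in take], ignore_index=True)
        try:
            t = disaggregate(sample, spec, window_months, min_n=min_n)
            vals.append(_MEASURE_FUNCS[measure](t).estimate)
        except (UndefinedMeasureError, UnsupportedMeasureError):
            continue
    if not vals:
        raise UndefinedMeasureError(f"{measure}: no defined bootstrap replicate")
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Batch driver and model/results wrappers

def run_all(
    tables: Mapping[str, DisaggregatedTable] | Iterable[DisaggregatedTable],
    measures: Sequence[str] | None = None,
    ci: str | None = "parametric",
    n_draws: int = 2000,
    seed: int | None = None,
    births: pd.DataFrame | None = None,
) -> tuple[list[SummaryResult], list[str]]:
    """Compute every applicable measure for every dimension.

    Gradient measures (ACI) run only on ordered dimensions; pairwise
    measures (D, R) and PAF also need an ordering or a binary split, so
    unordered dimensions (region) are skipped with a recorded reason, as
    are measures undefined because of NA subgroups.  Returns the results
    and the list of skip/failure notes.
    """
    if not isinstance(tables, Mapping):
        tables = {t.dimension.name: t for t in tables}
    results: list[SummaryResult] = []
    notes: list[str] = []
    for dim, table in tables.items():
        kind = table.dimension.kind
        applicable = MEASURES_BY_KIND[kind]
        if measures is not None:
            applicable = tuple(m for m in applicable if m in measures)
        if not applicable:
            notes.append(f"{dim}: no summary measure for {kind} dimension")
            continue
        for i, m in enumerate(applicable):
            try:
                res = _MEASURE_FUNCS[m](table)
            except (UndefinedMeasureError, UnsupportedMeasureError) as exc:
                notes.append(f"{dim}/{m}: {exc}")
                continue
            if ci is not None and ci != "none":
                try:
                    res.ci_low, res.ci_high = measure_ci(
                        table, m, method=ci, n_draws=n_draws,
                        seed=None if seed is None else seed + 31 * i,
                        births=births,
                    )
                except UndefinedMeasureError as exc:
                    res.note = f"CI unavailable: {exc}"
            results.append(res)
    return results, notes


class InequalityAnalysis:
    """Inequality model over one or several disaggregated tables.

    Parameters
    ----------
    tables : a :class:`DisaggregatedTable` or a mapping of them keyed by
        dimension name (the usual case: wealth, education, residence,
        sex, region).
    births : optional raw birth records backing the tables, enabling
        cluster-bootstrap CIs.

    ``fit()`` computes every applicable measure and returns an
    :class:`InequalityResults`.
    """

    def __init__(self, tables, births: pd.DataFrame | None = None):
        if isinstance(tables, DisaggregatedTable):
            tables = {tables.dimension.name: tables}
        self.tables: dict[str, DisaggregatedTable] = dict(tables)
        self.births = births

    @classmethod
    def from_births(
        cls,
        births: pd.DataFrame,
        dimensions: Sequence[str] | None = None,
        specs: Mapping[str, DimensionSpec] | None = None,
        window_months: int = 60,
        min_n: int = 200,
    ) -> "InequalityAnalysis":
        """Build the model straight from birth records by disaggregating
        each requested stratifier first."""
        from .disaggregate import DEFAULT_DIMENSIONS

        spec_map = dict(DEFAULT_DIMENSIONS if specs is None else specs)
        dims = list(spec_map) if dimensions is None else list(dimensions)
        tables = {
            d: disaggregate(births, spec_map[d], window_months, min_n=min_n)
            for d in dims
        }
        return cls(tables, births=births)

    def fit(
        self,
        measures: Sequence[str] | None = None,
        ci: str | None = "parametric",
        n_draws: int = 2000,
        seed: int | None = None,
    ) -> "InequalityResults":
        results, notes = run_all(
            self.tables, measures=measures, ci=ci, n_draws=n_draws,
            seed=seed, births=self.births,
        )
        return InequalityResults(model=self, results=results, notes=notes)


@dataclass
class InequalityResults:
    """Fitted summary measures with notes on anything skipped."""

    model: InequalityAnalysis
    results: list[SummaryResult]
    notes: list[str]

    def __getitem__(self, key: tuple[str, str]) -> SummaryResult:
        dim, measure = key
        for r in self.results:
            if r.dimension == dim and r.measure == measure:
                return r
        raise KeyError(key)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dimension": r.dimension,
                "measure": r.measure,
                "estimate": r.estimate,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "scale": r.scale,
                "reference_subgroup": r.reference_subgroup,
                "comparison_subgroup": r.comparison_subgroup,
                "note": r.note,
            }
            for r in self.results
        )

    def summary(self) -> str:
        lines = [
            "Inequality summary measures",
            "=" * 58,
            f"{'dimension':<18}{'measure':<9}{'estimate':>10}  95% CI",
            "-" * 58,
        ]
        for r in self.results:
            ci = (
                f"({r.ci_low:.2f}, {r.ci_high:.2f})"
                if r.ci_low is not None and r.ci_high is not None
                else ""
            )
            lines.append(
                f"{r.dimension:<18}{r.measure:<9}{r.estimate:>10.2f}  {ci}"
            )
        for n in self.notes:
            lines.append(f"note: {n}")
        return "\n".join(lines)
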