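"""Synthetic DHS-style full birth histories with known infant mortality.

Emulates a simplified Birth Recode (BR) file: one row per live birth in
the five years before a household survey, with date of birth and (if the
child died) age at death in completed months, a cluster label, a
normalised sampling weight, and the mother's equity stratifiers (wealth
quintile, education, residence, region) plus the child's sex.

The mortality model is a piecewise-constant hazard over the four
standard DHS age segments of infancy — [0,1), [1,3), [3,6) and [6,12)
months.  Each subgroup's target infant death probability q(1) is split
across segments on the log-survival scale (``segment_probabilities``),
children are passed through the segments sequentially, and deaths the
child had not yet lived to experience by the interview date are censored
to "alive".  Dates are century-month codes (CMC, months since January
1900) and events are placed at month midpoints, so a child born in CMC
``b`` and interviewed in CMC ``v`` has attained exactly ``v - b``
completed months of age.

Because the generator's assumptions are exactly those of the
synthetic-cohort estimator, subgroup q(1) is recoverable in expectation,
which is what the recovery tests downstream rely on.
"""

from __future__ import annotations

import math
from typing import Mapping, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from scipy import stats

from .errors import ConfigError

__all__ = [
    "SyntheticConfig",
    "segment_probabilities",
    "generate_births",
    "BIRTH_COLUMNS",
    "DEFAULT_PREVALENCES",
]

#: Column order of the simplified birth-recode CSV.
BIRTH_COLUMNS = (
    "child_id",
    "cluster_id",
    "weight",
    "dob_cmc",
    "interview_cmc",
    "sex",
    "alive",
    "age_at_death_months",
    "wealth_quintile",
    "education",
    "residence",
    "region",
)

# Marginal subgroup prevalences mirroring the 2013 Yemen DHS analysis
# sample (wealth and region shares follow the published population
# counts; 73% rural, 49% female, 60% of mothers with no schooling).
DEFAULT_PREVALENCES: dict[str, dict[str, float]] = {
    "wealth_quintile": {"1": 0.2304, "2": 0.2165, "3": 0.2002, "4": 0.1855, "5": 0.1674},
    "education": {"none": 0.601, "primary": 0.293, "secondary+": 0.106},
    "residence": {"rural": 0.731, "urban": 0.269},
    "sex": {"male": 0.51, "female": 0.49},
}

# Governorate birth counts from the same survey; normalised to shares.
_REGION_BIRTHS = {
    "Ibb": 3480, "Abyan": 572, "Sanaa City": 2586, "Al-Baidha": 1253,
    "Taiz": 3919, "Al-Jawf": 277, "Hajjah": 2152, "Al-Hodiedah": 4037,
    "Hadramout": 1566, "Dhamar": 2644, "Shabwah": 562, "Sadah": 1046,
    "Sanaa": 1720, "Aden": 776, "Lahj": 777, "Mareb": 237,
    "Al-Mhweit": 1005, "Al-Mhrah": 121, "Amran": 1353, "Aldhalae": 804,
    "Reimah": 847,
}
DEFAULT_PREVALENCES["region"] = {
    k: v / sum(_REGION_BIRTHS.values()) for k, v in _REGION_BIRTHS.items()
}

# Share of the infant log-survival drop per age segment; front-loaded
# toward the neonatal month as in typical DHS schedules.
DEFAULT_SEGMENT_SPLIT = (0.45, 0.20, 0.18, 0.17)

_SEGMENT_BOUNDS = ((0, 1), (1, 3), (3, 6), (6, 12))

TargetQ1 = Union[float, Mapping[str, Mapping[str, float]]]


class SyntheticConfig(BaseModel):
    """Parameters of the synthetic birth-history generator.

    ``target_q1`` is either a single infant death probability applied to
    every birth, or a one-dimension marginal map
    ``{dimension: {subgroup: q1}}`` (e.g. different q(1) by residence).
    ``segment_split`` allocates q(1) across the four infancy age
    segments on the log-survival scale.  ``weight_dispersion`` is the
    coefficient of variation of the gamma-distributed sampling weights
    (0 gives unit weights); weights are normalised to mean 1.
    ``stratifier_correlation`` is a Gaussian-copula correlation linking
    the wealth, education and residence draws (0 = independent), with
    the listed subgroup order defining the disadvantaged-to-advantaged
    direction.
    """

    model_config = ConfigDict(frozen=True)

    n_births: int = Field(ge=1)
    n_clusters: int = Field(default=800, ge=1)
    interview_cmc: int = 1367  # November 2013
    birth_window_months: int = Field(default=60, ge=1)
    subgroup_prevalences: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PREVALENCES.items()}
    )
    target_q1: TargetQ1 = 0.0467
    segment_split: tuple[float, float, float, float] = DEFAULT_SEGMENT_SPLIT
    weight_dispersion: float = Field(default=0.2, ge=0.0)
    stratifier_correlation: float = Field(default=0.0, ge=0.0, lt=1.0)
    seed: int = 0

    @field_validator("subgroup_prevalences")
    @classmethod
    def _prevalences_sum_to_one(cls, v):
        for dim, prev in v.items():
            if not prev:
                raise ValueError(f"subgroup_prevalences[{dim!r}]: empty")
            if any(p < 0 for p in prev.values()):
                raise ValueError(f"subgroup_prevalences[{dim!r}]: negative proportion")
            total = sum(prev.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"subgroup_prevalences[{dim!r}]: proportions sum to {total}, not 1"
                )
        return v

    @field_validator("segment_split")
    @classmethod
    def _split_sums_to_one(cls, v):
        if any(s < 0 for s in v):
            raise ValueError("segment_split: negative share")
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError(f"segment_split: shares sum to {sum(v)}, not 1")
        return v

    @model_validator(mode="after")
    def _check_targets(self):
        if isinstance(self.target_q1, Mapping):
            dims = list(self.target_q1)
            if len(dims) != 1:
                raise ValueError(
                    "target_q1: marginal targets must name exactly one dimension, "
                    f"got {dims}"
                )
            dim = dims[0]
            if dim not in self.subgroup_prevalences:
                raise ValueError(f"target_q1: unknown dimension {dim!r}")
            missing = set(self.subgroup_prevalences[dim]) - set(self.target_q1[dim])
            if missing:
                raise ValueError(f"target_q1: no target for subgroups {sorted(missing)}")
            values = self.target_q1[dim].values()
        else:
            values = [self.target_q1]
        for q in values:
            if not (0.0 <= q < 1.0):
                raise ValueError(f"target_q1: probability {q} outside [0, 1)")
        return self


def segment_probabilities(q1: float, split) -> tuple[float, float, float, float]:
    """Split an infant death probability across the four age segments.

    Returns per-segment conditional death probabilities ``q_a`` such
    that ``1 - prod(1 - q_a) == q1`` exactly, with each segment taking
    the stated share of the total log-survival drop:
    ``q_a = 1 - (1 - q1) ** split_a``.
    """
    split = tuple(float(s) for s in split)
    if len(split) != 4:
        raise ConfigError(f"segment_split: expected 4 shares, got {len(split)}")
    if any(s < 0 for s in split) or abs(sum(split) - 1.0) > 1e-9:
        raise ConfigError("segment_split: shares must be non-negative and sum to 1")
    if not (0.0 <= q1 < 1.0):
        raise ConfigError(f"target_q1: probability {q1} outside [0, 1)")
    if q1 == 0.0:
        return (0.0, 0.0, 0.0, 0.0)
    log_s = math.log1p(-q1)
    return tuple(-math.expm1(log_s * s) for s in split)


def _draw_categories(u: np.ndarray, prevalences: Mapping[str, float]) -> np.ndarray:
    labels = np.array(list(prevalences), dtype=object)
    cum = np.cumsum(np.fromiter(prevalences.values(), dtype=float))
    idx = np.searchsorted(cum, u, side="right")
    return labels[np.minimum(idx, len(labels) - 1)]


def generate_births(config: SyntheticConfig) -> pd.DataFrame:
    """Simulate a simplified birth-recode table.

    Returns a DataFrame with the :data:`BIRTH_COLUMNS` columns, one row
    per live birth, reproducible from ``config.seed`` alone.
    """
    if not isinstance(config, SyntheticConfig):
        config = SyntheticConfig.model_validate(config)
    rng = np.random.default_rng(config.seed)
    n = config.n_births

    age_attained = rng.integers(0, config.birth_window_months, size=n)
    dob = config.interview_cmc - age_attained
    cluster = rng.integers(1, config.n_clusters + 1, size=n)

    cv = config.weight_dispersion
    if cv > 0:
        shape = 1.0 / cv**2
        weight = rng.gamma(shape, 1.0 / shape, size=n)
        weight = weight / weight.mean()
    else:
        weight = np.ones(n)

    # Stratifier draws: wealth/education/residence share a Gaussian
    # copula when stratifier_correlation > 0; sex and region are always
    # independent.  Uniforms are drawn in a fixed dimension order so the
    # stream is stable across configs.
    prev = config.subgroup_prevalences
    rho = config.stratifier_correlation
    linked = [d for d in ("wealth_quintile", "education", "residence") if d in prev]
    uniforms: dict[str, np.ndarray] = {}
    if rho > 0 and len(linked) > 1:
        shared = rng.standard_normal(n)
        for dim in linked:
            z = math.sqrt(rho) * shared + math.sqrt(1 - rho) * rng.standard_normal(n)
            uniforms[dim] = stats.norm.cdf(z)
    else:
        for dim in linked:
            uniforms[dim] = rng.random(n)
    for dim in prev:
        if dim not in uniforms:
            uniforms[dim] = rng.random(n)
    columns = {dim: _draw_categories(uniforms[dim], prev[dim]) for dim in prev}

    # Per-child q(1), then per-segment conditional probabilities.
    if isinstance(config.target_q1, Mapping):
        dim = next(iter(config.target_q1))
        targets = config.target_q1[dim]
        q1 = np.array([targets[s] for s in columns[dim]], dtype=float)
    else:
        q1 = np.full(n, float(config.target_q1))
    with np.errstate(divide="ignore"):
        log_s = np.log1p(-q1)
    split = np.asarray(config.segment_split)
    seg_q = -np.expm1(log_s[:, None] * split[None, :])  # (n, 4)

    # Sequential survival through the segments; a death is placed
    # uniformly on the segment's integer months of age.
    at_risk = np.ones(n, dtype=bool)
    death_month = np.full(n, -1)
    for a, (lo, hi) in enumerate(_SEGMENT_BOUNDS):
        dies = at_risk & (rng.random(n) < seg_q[:, a])
        month = rng.integers(lo, hi, size=n)
        death_month[dies] = month[dies]
        at_risk &= ~dies

    # Censor deaths the child had not yet lived to by the interview.
    observed_death = (death_month >= 0) & (death_month < age_attained)
    age_at_death = pd.array(
        np.where(observed_death, death_month, 0), dtype="Int64"
    )
    age_at_death[~observed_death] = pd.NA

    frame = pd.DataFrame(
        {
            "child_id": np.arange(1, n + 1),
            "cluster_id": cluster,
            "weight": weight,
            "dob_cmc": dob,
            "interview_cmc": np.full(n, config.interview_cmc),
            "sex": columns.get("sex", np.full(n, "female", dtype=object)),
            "alive": ~observed_death,
            "age_at_death_months": age_at_death,
            "wealth_quintile": columns.get("wealth_quintile", np.full(n, "3", dtype=object)),
            "education": columns.get("education", np.full(n, "none", dtype=object)),
            "residence": columns.get("residence", np.full(n, "rural", dtype=object)),
            "region": columns.get("region", np.full(n, "all", dtype=object)),
        },
        columns=list(BIRTH_COLUMNS),
    )
    return frame
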