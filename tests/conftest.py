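import warnings

import numpy as np
import pandas as pd
import pytest

from equimort import (
    DimensionSpec,
    DisaggregatedTable,
    SubgroupEstimate,
    load_yemen_2013_table1,
)
from equimort.simulate import BIRTH_COLUMNS


@pytest.fixture(scope="session")
def yemen_tables():
    """Bundled published disaggregated table (all five dimensions)."""
    with warnings.catch_warnings():
        # the published region counts differ from the stated total
        warnings.simplefilter("ignore", UserWarning)
        return load_yemen_2013_table1()


def make_births(
    n,
    age_months,
    death_ages=(),
    weights=None,
    clusters=None,
    interview_cmc=1367,
    **stratifiers,
):
    """Build a small birth-recode frame by hand.

    ``age_months`` is the age attained at interview (scalar or
    per-child); ``death_ages`` maps child index -> age at death.
    """
    age = np.broadcast_to(np.asarray(age_months), (n,)).astype(int)
    death_ages = dict(death_ages) if not isinstance(death_ages, dict) else death_ages
    alive = np.array([i not in death_ages for i in range(n)])
    aad = pd.array([death_ages.get(i) for i in range(n)], dtype="Int64")
    frame = pd.DataFrame(
        {
            "child_id": np.arange(1, n + 1),
            "cluster_id": clusters if clusters is not None else np.arange(n) % 5 + 1,
            "weight": weights if weights is not None else np.ones(n),
            "dob_cmc": interview_cmc - age,
            "interview_cmc": interview_cmc,
            "sex": stratifiers.get("sex", "female"),
            "alive": alive,
            "age_at_death_months": aad,
            "wealth_quintile": stratifiers.get("wealth_quintile", "3"),
            "education": stratifiers.get("education", "none"),
            "residence": stratifiers.get("residence", "rural"),
            "region": stratifiers.get("region", "all"),
        },
        columns=list(BIRTH_COLUMNS),
    )
    return frame


def make_table(estimates, populations, mu, kind="ordered", name="dim", cis=None):
    """Build a DisaggregatedTable with subgroups s0..s{k-1} ordered
    disadvantaged -> advantaged."""
    labels = [f"s{i}" for i in range(len(estimates))]
    spec = DimensionSpec(name, kind, tuple(labels))
    rows = []
    total = sum(populations)
    for i, (label, est, pop) in enumerate(zip(labels, estimates, populations)):
        lo = hi = None
        if cis is not None:
            lo, hi = cis[i]
        rows.append(
            SubgroupEstimate(
                name, label, est, lo, hi, int(pop), pop / total,
                rank_order=i + 1,
                na_reason=None if est is not None else "missing",
            )
        )
    return DisaggregatedTable("imr", spec, rows, mu)
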