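"""Bundled example data.

``load_yemen_2013_table1`` returns the published disaggregated IMR
table for the 2013 Yemen DHS (estimates per 1000 live births with 95%
CIs, unweighted birth counts, national average 46.73 over 31,743
births), transcribed to the package's canonical subgroup labels
(wealth quintiles "1".."5" poorest → richest; education none / primary
/ secondary+).  Two regions (Mareb, Al-Mhrah) have no published
estimate and are NA.  These are *inputs*: recomputing them would need
the survey microdata, which is not redistributable.
"""

from __future__ import annotations

from importlib import resources

from .disaggregate import DisaggregatedTable, read_tables_csv

__all__ = ["load_yemen_2013_table1", "yemen_2013_table1_path"]


def yemen_2013_table1_path():
    return resources.files("equimort.data") / "yemen_2013_table1.csv"


def load_yemen_2013_table1() -> dict[str, DisaggregatedTable]:
    with resources.as_file(yemen_2013_table1_path()) as p:
        return read_tables_csv(p)
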