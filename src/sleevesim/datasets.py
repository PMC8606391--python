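"""Packaged reference tables.

Two CSV fixtures ship with the package: a basal-volume table (11 bougie
sizes x 5 intragastric pressures, in ml) and an elongation-strain table
(11 sizes x 4 pressures x 5 groupings, mean and SD in percent).

One strain cell (46 Fr, antrum, 22.5 mmHg) is printed as 4.12 although
back-solving the table's own cross-size mean row gives 41.22; the printed
value is almost certainly missing its leading digit.  The fixture stores
the printed value; ``load_table2(corrected=True)`` substitutes the
back-solved one.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

__all__ = ["load_table1", "load_table2", "CORRECTED_CELLS", "fixture_checksums"]

#: (bougie_fr, pressure_mmhg, grouping) -> corrected mean_percent.
CORRECTED_CELLS = {(46, 22.5, "antrum"): 41.22}


def _fixture_path(name: str):
    return resources.files("sleevesim").joinpath("data", name)


def load_table1() -> pd.DataFrame:
    """Basal-volume table: columns (bougie_fr, pressure_mmhg, volume_ml)."""
    with resources.as_file(_fixture_path("table1.csv")) as p:
        return pd.read_csv(p)


def load_table2(corrected: bool = False) -> pd.DataFrame:
    """Elongation-strain table: (bougie_fr, pressure_mmhg, grouping, mean_percent, sd_percent).

    With ``corrected=True`` the internally inconsistent printed cell(s)
    listed in :data:`CORRECTED_CELLS` are replaced by their back-solved
    values.
    """
    with resources.as_file(_fixture_path("table2.csv")) as p:
        df = pd.read_csv(p)
    if corrected:
        for (fr, pressure, grouping), value in CORRECTED_CELLS.items():
            mask = (
                (df["bougie_fr"] == fr)
                & (df["pressure_mmhg"] == pressure)
                & (df["grouping"] == grouping)
            )
            df.loc[mask, "mean_percent"] = value
    return df


def fixture_checksums() -> dict[str, str]:
    """SHA-256 of each packaged fixture, for run logs."""
    out = {}
    for name in ("table1.csv", "table2.csv"):
        with resources.as_file(_fixture_path(name)) as p:
            out[name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out
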