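"""Summary analytics over simulated and tabulated results.

Builds basal-volume and strain-summary tables from simulation results,
computes the cross-size statistics quoted alongside the reference tables
(means over sizes, size ratios, region/layer differences), and handles
the computational pressure-volume band (envelope over bougie sizes) and
its coverage of observation points.

Rounding conventions for the headline statistics mirror how such table
arithmetic is conventionally quoted: size ratios to the nearest integer
or nearest half, layer differences round-half-up to integer percentage
points, region differences optionally truncated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .inflation import GROUPINGS, InflationResult, strain_summary

__all__ = [
    "Band",
    "volume_table",
    "strain_table",
    "mean_over_sizes",
    "size_ratio",
    "group_difference",
    "band_envelope",
    "band_coverage",
]


def volume_table(
    results: Mapping[float, InflationResult], pressures: Sequence[float]
) -> pd.DataFrame:
    """Tabulate basal volumes: one row per (bougie size, pressure), in ml."""
    rows = []
    for fr in sorted(results):
        res = results[fr]
        for p in pressures:
            rows.append((float(fr), float(p), res.volume_at(p)))
    return pd.DataFrame(rows, columns=["bougie_fr", "pressure_mmhg", "volume_ml"])


def strain_table(
    results: Mapping[float, InflationResult],
    pressures: Sequence[float],
    groupings: Sequence[str] = GROUPINGS,
) -> pd.DataFrame:
    """Tabulate grouped strain statistics: (size, pressure, grouping, mean, SD) in percent."""
    rows = []
    for fr in sorted(results):
        res = results[fr]
        for p in pressures:
            for g in groupings:
                s = strain_summary(res, p, g)
                rows.append((float(fr), float(p), g, s.mean_percent, s.sd_percent))
    return pd.DataFrame(
        rows, columns=["bougie_fr", "pressure_mmhg", "grouping", "mean_percent", "sd_percent"]
    )


def mean_over_sizes(
    table: pd.DataFrame, grouping: str, pressure_mmhg: float, n_sizes: int = 11
) -> float:
    """Arithmetic mean over all bougie sizes of a strain-table grouping at one pressure."""
    sel = table[
        (table["grouping"] == grouping)
        & np.isclose(table["pressure_mmhg"], pressure_mmhg, rtol=0, atol=1e-9)
    ]
    if len(sel) != n_sizes:
        raise ValueError(
            f"expected {n_sizes} sizes for ({grouping}, {pressure_mmhg} mmHg), found {len(sel)}"
        )
    return float(sel["mean_percent"].mean())


def _pv_cell(table: pd.DataFrame, pressure_mmhg: float, bougie_fr: float) -> float:
    sel = table[
        (table["bougie_fr"] == bougie_fr)
        & np.isclose(table["pressure_mmhg"], pressure_mmhg, rtol=0, atol=1e-9)
    ]
    if sel.empty:
        raise KeyError(f"no cell for {bougie_fr} Fr at {pressure_mmhg} mmHg")
    return float(sel["volume_ml"].iloc[0])


def size_ratio(
    table: pd.DataFrame,
    pressure_mmhg: float,
    numerator_fr: float,
    denominator_fr: float,
    rounding: str = "none",
) -> float:
    """Ratio of basal volumes between two bougie sizes at one pressure.

    ``rounding``: ``"int"`` (nearest integer), ``"half"`` (nearest 0.5) or
    ``"none"``.
    """
    num = _pv_cell(table, pressure_mmhg, numerator_fr)
    den = _pv_cell(table, pressure_mmhg, denominator_fr)
    ratio = num / den
    if rounding == "int":
        return float(round(ratio))
    if rounding == "half":
        return float(round(ratio * 2.0) / 2.0)
    if rounding == "none":
        return float(ratio)
    raise ValueError(f"unknown rounding {rounding!r}")


def group_difference(
    table: pd.DataFrame,
    pressure_mmhg: float,
    group_a: str,
    group_b: str,
    rounding: str = "none",
) -> float:
    """Cross-size mean strain of ``group_a`` minus ``group_b``, in percentage points.

    ``rounding``: ``"round"`` (half-up to integer), ``"truncate"`` or ``"none"``.
    """
    for g in (group_a, group_b):
        if g not in GROUPINGS:
            raise ValueError(f"unknown grouping {g!r}")
    diff = mean_over_sizes(table, group_a, pressure_mmhg) - mean_over_sizes(
        table, group_b, pressure_mmhg
    )
    if rounding == "round":
        return float(math.floor(diff + 0.5))
    if rounding == "truncate":
        return float(math.trunc(diff))
    if rounding == "none":
        return float(diff)
    raise ValueError(f"unknown rounding {rounding!r}")


@dataclass(frozen=True)
class Band:
    """Pointwise envelope of a family of pressure-volume curves."""

    pressures_mmhg: np.ndarray
    volume_min_ml: np.ndarray
    volume_max_ml: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.volume_min_ml > self.volume_max_ml):
            raise ValueError("band min exceeds band max")

    def edges_at(self, pressure_mmhg) -> tuple[np.ndarray, np.ndarray]:
        """Linearly interpolated (lower, upper) volume edges at arbitrary pressures."""
        p = np.asarray(pressure_mmhg, dtype=float)
        if np.any(p < self.pressures_mmhg[0]) or np.any(p > self.pressures_mmhg[-1]):
            raise ValueError("pressure outside the band's pressure range")
        lo = np.interp(p, self.pressures_mmhg, self.volume_min_ml)
        hi = np.interp(p, self.pressures_mmhg, self.volume_max_ml)
        return lo, hi


def band_envelope(curves: Iterable[tuple[np.ndarray, np.ndarray]]) -> Band:
    """Pointwise min/max over a family of (pressures, volumes) curves on a shared grid."""
    curves = list(curves)
    if len(curves) < 2:
        raise ValueError("need at least two curves to form a band")
    grid = np.asarray(curves[0][0], dtype=float)
    vols = []
    for p, v in curves:
        if not np.allclose(np.asarray(p, dtype=float), grid, rtol=0, atol=1e-9):
            raise ValueError("curves must share a common pressure grid")
        vols.append(np.asarray(v, dtype=float))
    stacked = np.vstack(vols)
    return Band(
        pressures_mmhg=grid,
        volume_min_ml=stacked.min(axis=0),
        volume_max_ml=stacked.max(axis=0),
    )


def band_coverage(band: Band, observations: pd.DataFrame) -> float:
    """Fraction of observation points inside the band (closed interval).

    ``observations`` needs columns ``pressure_mmhg`` and ``volume_ml``;
    band edges are interpolated linearly between grid pressures and
    boundary points count as inside.
    """
    if observations.empty:
        raise ValueError("empty observation set")
    p = observations["pressure_mmhg"].to_numpy(dtype=float)
    v = observations["volume_ml"].to_numpy(dtype=float)
    lo, hi = band.edges_at(p)
    eps = 1e-12 * np.maximum(1.0, np.abs(hi))
    inside = (v >= lo - eps) & (v <= hi + eps)
    return float(inside.mean())
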