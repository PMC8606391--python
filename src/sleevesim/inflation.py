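"""Quasi-static inflation of a sleeve geometry over a pressure schedule.

Each axial station is treated as an independent incompressible plane-strain
ring whose inner stretch is found by inverting the through-wall pressure
integral; an end-fixity attenuation then blends the stretch profile to 1 at
the two pinned junctions.  Outputs are insufflated lumen volumes (delta-V
relative to the unloaded configuration by default) and elongation-strain
samples (lam_theta - 1, in percent) at Gauss points through each layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .constitutive import (
    MaterialStack,
    _gauss,
    pressure_profile,
    pressure_profile_with_derivative,
)
from .geometry import MM3_TO_ML, SleeveGeometry

__all__ = [
    "MMHG_TO_KPA",
    "PressureSchedule",
    "InflationResult",
    "StrainSummary",
    "GROUPINGS",
    "solve_ring",
    "apply_end_fixity",
    "inflate",
    "simulate_volumes",
    "strain_summary",
]

MMHG_TO_KPA = 0.1333224

GROUPINGS = ("whole", "antrum", "corpus", "mucosa", "muscularis")

_LAM_MAX = 5.0
_BISECT_ITER = 80  # iteration cap for the safeguarded Newton; typical solves need < 15


@dataclass(frozen=True)
class PressureSchedule:
    """Ordered target intragastric pressures in mmHg."""

    pressures_mmhg: tuple[float, ...]
    max_mmhg: float = 75.0

    def __post_init__(self) -> None:
        p = np.asarray(self.pressures_mmhg, dtype=float)
        if p.size == 0:
            raise ValueError("schedule must contain at least one pressure")
        if np.any(p < 0):
            raise ValueError("pressures must be non-negative")
        if np.any(np.diff(p) <= 0):
            raise ValueError("pressures must be strictly increasing")
        if p[-1] > self.max_mmhg:
            raise ValueError(f"pressures above {self.max_mmhg} mmHg are outside the modelled range")

    @classmethod
    def table_default(cls) -> "PressureSchedule":
        """The five pressure states reported throughout: 7.5-75 mmHg."""
        return cls((7.5, 15.0, 22.5, 37.5, 75.0))


class SolverError(RuntimeError):
    """Equilibrium could not be bracketed (material too soft for the pressure)."""


def _solve_batch(
    interfaces: np.ndarray, stack: MaterialStack, pressures_kpa: np.ndarray
) -> np.ndarray:
    """Vectorised bisection for the inner stretch of a batch of rings.

    ``interfaces`` has shape (n_rings, n_layers + 1); ``pressures_kpa`` is
    1-D.  Returns stretches of shape (n_pressures, n_rings).  Monotonicity
    of P(lam_inner) makes plain bisection on the fixed bracket [1, 5]
    robust and exactly path-independent across pressure steps.
    """
    pressures_kpa = np.atleast_1d(np.asarray(pressures_kpa, dtype=float))
    if np.any(pressures_kpa < 0):
        raise ValueError("pressure must be non-negative")
    n_rings = interfaces.shape[0]
    target = pressures_kpa[:, None]  # (n_p, 1)
    hi_p = pressure_profile(interfaces, stack, np.full(n_rings, _LAM_MAX))
    if np.any(hi_p[None, :] < target):
        raise SolverError(
            f"pressure {pressures_kpa.max():.3f} kPa not reachable with "
            f"lam_inner <= {_LAM_MAX}; material too soft for the requested pressure"
        )
    lo = np.ones((pressures_kpa.size, n_rings))
    hi = np.full_like(lo, _LAM_MAX)
    x = np.full_like(lo, 1.05)
    # Newton on log P(lam) = log p: P grows near-exponentially in lam, so
    # the log-residual is close to linear and convergence is global; a
    # maintained bracket guards the few steps that leave it.
    for _ in range(_BISECT_ITER):
        P, dP = pressure_profile_with_derivative(interfaces, stack, x)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.log(np.maximum(P, 1e-300)) - np.log(target)
            step = np.where(dP > 0, f * P / np.maximum(dP, 1e-300), np.nan)
        high = f > 0
        hi = np.where(high, x, hi)
        lo = np.where(high, lo, x)
        converged = (np.abs(step) < 1e-14) | (hi - lo < 1e-14)
        if np.all(converged):
            break
        x_new = x - step
        bad = ~np.isfinite(x_new) | (x_new < lo) | (x_new > hi)
        x_new = np.where(bad, 0.5 * (lo + hi), x_new)
        x = np.where(converged, x, x_new)  # freeze solved entries
    lam = np.clip(x, lo, hi)
    lam[pressures_kpa == 0.0] = 1.0
    return lam


def _solve_many(interfaces: np.ndarray, stack: MaterialStack, pressure_kpa: float) -> np.ndarray:
    """Inner stretch for a batch of rings at one pressure (kPa)."""
    return _solve_batch(interfaces, stack, np.asarray([pressure_kpa]))[0]


def solve_ring(interfaces, stack: MaterialStack, pressure_kpa: float) -> float:
    """Inner stretch of a single ring at an inflation pressure (kPa).

    Inverts :func:`sleevesim.constitutive.ring_pressure` by bisection on
    lam_inner in [1, 5]; the residual pressure at the returned stretch is
    below 1e-8 kPa and the stretch is resolved beyond 1e-10.
    """
    interfaces = np.asarray(interfaces, dtype=float)
    return float(_solve_many(interfaces[None, :], stack, pressure_kpa)[0])


def apply_end_fixity(lam: np.ndarray, geometry: SleeveGeometry) -> np.ndarray:
    """Blend a stretch profile to 1 at the two pinned junctions.

    The attenuation factor is a squared-exponential decay in the distance
    from each end, with characteristic length equal to the deformed inner
    radius at that end's terminal station: the reach of the pinning
    constraint scales with the junction's own size, not with the far-field
    tube radius.  Stations beyond five characteristic lengths from both
    ends change by less than 1e-6 relative.
    """
    lam = np.asarray(lam, dtype=float)
    z = geometry.stations_mm
    if lam.shape[-1] != len(z):
        raise ValueError("stretch profile length must match the station count")
    ell0 = lam[..., 0] * geometry.inner_radius_mm[0]
    ell1 = lam[..., -1] * geometry.inner_radius_mm[-1]
    d0 = (z - z[0]) / ell0[..., None]
    d1 = (z[-1] - z) / ell1[..., None]
    g = -np.expm1(-(d0**2)) * -np.expm1(-(d1**2))
    return 1.0 + (lam - 1.0) * g


@dataclass(frozen=True)
class StrainSummary:
    """Volume-weighted mean +/- SD elongation strain for one grouping."""

    grouping: str
    mean_percent: float
    sd_percent: float


@dataclass(frozen=True)
class InflationResult:
    """Equilibrium states of one geometry over a pressure schedule."""

    geometry: SleeveGeometry
    pressures_mmhg: np.ndarray
    volumes_ml: np.ndarray
    inner_stretch: np.ndarray  # (n_pressures, n_stations), after end fixity
    samples: pd.DataFrame  # tidy: pressure_mmhg, z_mm, region, layer, R_mm, lambda_theta, strain_percent, weight
    volume_convention: Literal["delta", "total"] = "delta"

    def volume_at(self, pressure_mmhg: float) -> float:
        i = _pressure_index(self.pressures_mmhg, pressure_mmhg)
        return float(self.volumes_ml[i])

    def to_csv(self, path) -> None:
        self.samples.to_csv(path, index=False)


def _pressure_index(pressures: np.ndarray, p: float) -> int:
    hits = np.nonzero(np.isclose(pressures, p, rtol=0, atol=1e-9))[0]
    if hits.size == 0:
        raise KeyError(f"pressure {p} mmHg not in result schedule {list(pressures)}")
    return int(hits[0])


def _lumen_volume(geometry: SleeveGeometry, r_inner_def: np.ndarray) -> float:
    return float(np.trapezoid(np.pi * r_inner_def**2, geometry.stations_mm) * MM3_TO_ML)


def simulate_volumes(
    geometry: SleeveGeometry,
    stack: MaterialStack,
    pressures_mmhg: Iterable[float],
    *,
    end_fixity: bool = True,
    volume_convention: Literal["delta", "total"] = "delta",
) -> np.ndarray:
    """Lumen volumes (ml) at each pressure, skipping strain-field assembly.

    This is the fast path used by calibration and the synthetic-data
    generators; :func:`inflate` returns the same volumes plus strain fields.
    """
    interfaces = geometry.layer_interfaces_mm
    # Stations sharing a reference radius share the ring solution.
    r_key = np.round(geometry.inner_radius_mm, 12)
    uniq, first_idx, inv = np.unique(r_key, return_index=True, return_inverse=True)
    uniq_interfaces = interfaces[first_idx]

    v_ref = _lumen_volume(geometry, geometry.inner_radius_mm)
    pressures = np.asarray(list(pressures_mmhg), dtype=float)
    lam_u = _solve_batch(uniq_interfaces, stack, pressures * MMHG_TO_KPA)
    lam = lam_u[:, inv]  # (n_p, n_stations)
    if end_fixity:
        lam = apply_end_fixity(lam, geometry)
    r_def = lam * geometry.inner_radius_mm
    v = np.trapezoid(np.pi * r_def**2, geometry.stations_mm, axis=-1) * MM3_TO_ML
    return v - v_ref if volume_convention == "delta" else v


def inflate(
    geometry: SleeveGeometry,
    stack: MaterialStack,
    schedule: PressureSchedule | Iterable[float],
    *,
    end_fixity: bool = True,
    volume_convention: Literal["delta", "total"] = "delta",
    gauss_per_layer: int = 4,
) -> InflationResult:
    """Solve the full inflation problem over a pressure schedule.

    For each pressure: per-station ring equilibrium, end-fixity
    attenuation, deformed radii from the incompressible mapping, lumen
    volume, and elongation-strain samples at ``gauss_per_layer`` Gauss
    points through each layer at every station.  Strain-sample weights are
    reference shell volumes (2 pi R w dR dz), used by the grouped
    statistics.
    """
    if not isinstance(schedule, PressureSchedule):
        schedule = PressureSchedule(tuple(float(p) for p in schedule), max_mmhg=np.inf)
    pressures = np.asarray(schedule.pressures_mmhg, dtype=float)
    interfaces = geometry.layer_interfaces_mm
    R_i = interfaces[:, 0]
    v_ref = _lumen_volume(geometry, R_i)
    nodes, gl_weights = _gauss(gauss_per_layer)

    volumes = np.empty(pressures.size)
    stretches = np.empty((pressures.size, geometry.n_stations))
    frames: list[pd.DataFrame] = []
    for i, p_mmhg in enumerate(pressures):
        try:
            lam = _solve_many(interfaces, stack, p_mmhg * MMHG_TO_KPA)
        except SolverError as err:
            raise SolverError(f"at {p_mmhg} mmHg: {err}") from err
        if end_fixity:
            lam = apply_end_fixity(lam, geometry)
        stretches[i] = lam
        r_def = lam * R_i
        v = _lumen_volume(geometry, r_def)
        volumes[i] = v - v_ref if volume_convention == "delta" else v

        ri_def_sq = r_def**2
        for j, layer in enumerate(geometry.layer_names):
            R_a, R_b = interfaces[:, j], interfaces[:, j + 1]
            half = 0.5 * (R_b - R_a)
            mid = 0.5 * (R_b + R_a)
            R = mid[:, None] + half[:, None] * nodes  # (n_stations, gauss)
            lam_R = np.sqrt(ri_def_sq[:, None] + R**2 - R_i[:, None] ** 2) / R
            w = 2.0 * np.pi * R * gl_weights * half[:, None] * geometry.spacing_mm
            frames.append(
                pd.DataFrame(
                    {
                        "pressure_mmhg": p_mmhg,
                        "z_mm": np.repeat(geometry.stations_mm, gauss_per_layer),
                        "region": np.repeat(geometry.region_labels, gauss_per_layer),
                        "layer": layer,
                        "R_mm": R.ravel(),
                        "lambda_theta": lam_R.ravel(),
                        "strain_percent": (lam_R.ravel() - 1.0) * 100.0,
                        "weight": w.ravel(),
                    }
                )
            )
    samples = pd.concat(frames, ignore_index=True)
    return InflationResult(
        geometry=geometry,
        pressures_mmhg=pressures,
        volumes_ml=volumes,
        inner_stretch=stretches,
        samples=samples,
        volume_convention=volume_convention,
    )


def strain_summary(result: InflationResult, pressure_mmhg: float, grouping: str) -> StrainSummary:
    """Reference-volume-weighted mean and SD of elongation strain for one group.

    Groupings: ``whole`` (all samples), ``antrum``/``corpus`` (by axial
    region) and ``mucosa``/``muscularis`` (by wall layer).
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}; expected one of {GROUPINGS}")
    df = result.samples
    df = df[np.isclose(df["pressure_mmhg"], pressure_mmhg, rtol=0, atol=1e-9)]
    if df.empty:
        raise KeyError(f"pressure {pressure_mmhg} mmHg not present in result")
    if grouping in ("antrum", "corpus"):
        df = df[df["region"] == grouping]
    elif grouping in ("mucosa", "muscularis"):
        df = df[df["layer"] == grouping]
    w = df["weight"].to_numpy()
    x = df["strain_percent"].to_numpy()
    mean = float(np.average(x, weights=w))
    sd = float(np.sqrt(np.average((x - mean) ** 2, weights=w)))
    return StrainSummary(grouping=grouping, mean_percent=mean, sd_percent=sd)
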