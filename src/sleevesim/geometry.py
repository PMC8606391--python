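"""Parametric sleeved-stomach geometry.

After a sleeve gastrectomy the residual stomach is, to first order, a
narrow tube whose luminal calibre is set by the bougie used to guide the
staple line.  This module builds an axisymmetric, axially discretised
two-layer tube (mucosa-submucosa inside, muscularis outside) with an
antrum/corpus region partition, a configurable antral flare and a smooth
radius reduction toward the two fixed junctions (gastroesophageal end at
z = 0, pyloric end at z = length).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BougieSpec",
    "LayerSpec",
    "SleeveGeometry",
    "LAYER_NAMES",
    "default_layers",
    "fr_to_diameter",
    "build_sleeve",
    "reference_lumen_volume",
]

#: Ordered wall layers, lumen outward.
LAYER_NAMES = ("mucosa", "muscularis")

MM3_TO_ML = 1e-3


def fr_to_diameter(size_fr: float) -> float:
    """Convert a catheter calibre in French units to a diameter in mm.

    The French scale is exact: 1 Fr = 1/3 mm of diameter.

    Raises
    ------
    ValueError
        If ``size_fr`` is not strictly positive.
    """
    if size_fr <= 0:
        raise ValueError(f"bougie calibre must be positive, got {size_fr} Fr")
    return size_fr / 3.0


@dataclass(frozen=True)
class BougieSpec:
    """Bougie calibre and the luminal geometry it imposes on the sleeve.

    Parameters
    ----------
    size_fr
        Calibre in French units; clinically used sizes span 27-54 Fr.
    length_mm
        Greater-curvature length of the sleeve, default 150 mm.
    """

    size_fr: float
    length_mm: float = 150.0
    inner_diameter_mm: float = field(init=False)

    def __post_init__(self) -> None:
        if not (27.0 <= self.size_fr <= 54.0):
            raise ValueError(
                f"bougie calibre {self.size_fr} Fr outside the modelled 27-54 Fr range"
            )
        if self.length_mm <= 0:
            raise ValueError("sleeve length must be positive")
        object.__setattr__(self, "inner_diameter_mm", fr_to_diameter(self.size_fr))

    @property
    def inner_radius_mm(self) -> float:
        return self.inner_diameter_mm / 2.0


@dataclass(frozen=True)
class LayerSpec:
    """Reference thickness of one gastric wall layer."""

    name: str
    thickness_mm: float

    def __post_init__(self) -> None:
        if self.name not in LAYER_NAMES:
            raise ValueError(f"unknown layer {self.name!r}; expected one of {LAYER_NAMES}")
        if self.thickness_mm <= 0:
            raise ValueError("layer thickness must be positive")


def default_layers() -> list[LayerSpec]:
    """Default wall build-up: 1.0 mm mucosa-submucosa + 1.5 mm muscularis."""
    return [LayerSpec("mucosa", 1.0), LayerSpec("muscularis", 1.5)]


@dataclass(frozen=True)
class SleeveGeometry:
    """Axially discretised two-layer sleeve.

    ``layer_interfaces_mm`` has one row per station and ``n_layers + 1``
    columns: lumen surface, mucosa/muscularis interface, outer surface.
    Region labels partition the axis into a proximal corpus block and a
    distal antrum block.
    """

    stations_mm: np.ndarray
    inner_radius_mm: np.ndarray
    layer_interfaces_mm: np.ndarray
    region_labels: np.ndarray
    layer_names: tuple[str, ...]
    flare: float
    end_taper_length_mm: float
    spacing_mm: float

    def __post_init__(self) -> None:
        n = len(self.stations_mm)
        if self.layer_interfaces_mm.shape != (n, len(self.layer_names) + 1):
            raise ValueError("layer interface table has the wrong shape")
        if np.any(np.diff(self.layer_interfaces_mm, axis=1) <= 0):
            raise ValueError("geometric inversion: interface radii must increase lumen->exterior")
        interior = slice(1, -1)
        if np.any(self.inner_radius_mm[interior] <= 0):
            raise ValueError("inner radius must be positive at interior stations")

    @property
    def n_stations(self) -> int:
        return len(self.stations_mm)

    @property
    def outer_radius_mm(self) -> np.ndarray:
        return self.layer_interfaces_mm[:, -1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z_mm": self.stations_mm,
                "r_inner_mm": self.inner_radius_mm,
                "r_mucosa_outer_mm": self.layer_interfaces_mm[:, 1],
                "r_outer_mm": self.layer_interfaces_mm[:, 2],
                "region": self.region_labels,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _cosine_step(x: np.ndarray) -> np.ndarray:
    """Smooth 0->1 step on [0, 1] with zero slope at both ends."""
    x = np.clip(x, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * x))


def build_sleeve(
    bougie: BougieSpec,
    layers: Sequence[LayerSpec] | None = None,
    *,
    flare: float = 1.3,
    antrum_length_mm: float = 50.0,
    end_taper_length_mm: float = 10.0,
    junction_radius_mm: float = 3.0,
    spacing_mm: float = 2.0,
    blend_length_mm: float = 20.0,
) -> SleeveGeometry:
    """Build the axisymmetric sleeve profile for one bougie calibre.

    The corpus (proximal) block carries the bougie radius; the antrum
    (distal) block carries ``flare`` times that radius, joined by a cosine
    blend of width ``blend_length_mm`` centred on the region boundary.
    Over ``end_taper_length_mm`` at each end the radius decays smoothly to
    ``junction_radius_mm``, standing in for the fixed gastroesophageal and
    pyloric junctions.  z runs from the gastroesophageal junction (z = 0)
    to the pylorus (z = length).
    """
    layers = list(layers) if layers is not None else default_layers()
    if [la.name for la in layers] != list(LAYER_NAMES):
        raise ValueError(f"layers must be {LAYER_NAMES} in lumen->exterior order")
    if flare < 1.0:
        raise ValueError("flare must be >= 1")
    if not (0.0 < antrum_length_mm < bougie.length_mm):
        raise ValueError("antrum length must lie inside the sleeve length")
    if not (0.0 <= end_taper_length_mm <= bougie.length_mm / 4.0):
        raise ValueError("end taper must be between 0 and a quarter of the sleeve length")

    length = bougie.length_mm
    z = np.arange(0.0, length + 0.5 * spacing_mm, spacing_mm)
    r_b = bougie.inner_radius_mm

    # Corpus->antrum flare, cosine-blended across the region boundary.
    z_boundary = length - antrum_length_mm
    if blend_length_mm > 0:
        w = _cosine_step((z - (z_boundary - blend_length_mm / 2.0)) / blend_length_mm)
    else:
        w = (z > z_boundary).astype(float)
    r = r_b * (1.0 + (flare - 1.0) * w)

    # Junction tapers: decay to the junction radius over the taper length.
    if end_taper_length_mm > 0:
        t0 = _cosine_step(z / end_taper_length_mm)
        t1 = _cosine_step((length - z) / end_taper_length_mm)
        r = junction_radius_mm + (r - junction_radius_mm) * t0 * t1

    interfaces = np.empty((len(z), len(layers) + 1))
    interfaces[:, 0] = r
    for j, layer in enumerate(layers):
        interfaces[:, j + 1] = interfaces[:, j] + layer.thickness_mm

    labels = np.where(z > z_boundary, "antrum", "corpus")
    return SleeveGeometry(
        stations_mm=z,
        inner_radius_mm=r,
        layer_interfaces_mm=interfaces,
        region_labels=labels,
        layer_names=tuple(la.name for la in layers),
        flare=flare,
        end_taper_length_mm=end_taper_length_mm,
        spacing_mm=spacing_mm,
    )


def reference_lumen_volume(geometry: SleeveGeometry) -> float:
    """Unloaded luminal volume in ml (trapezoid rule on pi r(z)^2)."""
    r = geometry.inner_radius_mm
    return float(np.trapezoid(np.pi * r**2, geometry.stations_mm) * MM3_TO_ML)


def geometry_from_csv(path: str | Path) -> pd.DataFrame:
    """Read a geometry profile previously written by :meth:`SleeveGeometry.to_csv`."""
    return pd.read_csv(path)
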