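"""Synthetic-data generators.

Two kinds of inputs are needed to exercise the pipeline end to end without
external data: in-vivo-style pressure-volume observation points with
inter-subject geometric scatter, and noisy calibration tables produced
from known material parameters for parameter-recovery audits.

Noise is multiplicative lognormal, parametrised by a coefficient of
variation (volumes are positive and right-skewed):  the noise factor is
exp(sigma * Z) with sigma^2 = ln(1 + cv^2), so E[noisy] = clean *
exp(sigma^2 / 2).  Inter-subject variability enters through sleeve length
(the dominant anatomical difference between patients sleeved over the
same bougie); optional material jitter can be layered on top.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constitutive import DEFAULT_FLARE, DEFAULT_STACK, MaterialStack
from .geometry import BougieSpec, build_sleeve
from .inflation import simulate_volumes

__all__ = ["ObservationSet", "gen_pv_observations", "gen_calibration_dataset"]

#: Shortest anatomically plausible sleeve (truncation bound for length draws).
MIN_LENGTH_MM = 100.0


def _noise_sigma(noise_cv: float) -> float:
    return float(np.sqrt(np.log1p(noise_cv**2)))


@dataclass(frozen=True)
class ObservationSet:
    """Synthetic in-vivo-style pressure-volume observation points.

    ``metadata`` records every generator argument (including the seed), so
    the set can be regenerated bit-for-bit.
    """

    points: pd.DataFrame  # columns: subject, pressure_mmhg, volume_ml
    metadata: dict = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.points.to_csv(path, index=False)
        path.with_suffix(".json").write_text(json.dumps(self.metadata, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ObservationSet":
        path = Path(path)
        meta_path = path.with_suffix(".json")
        metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(points=pd.read_csv(path), metadata=metadata)


def gen_pv_observations(
    n: int,
    *,
    bougie_fr: float = 50.0,
    length_mean_mm: float = 150.0,
    length_sd_mm: float = 15.0,
    noise_cv: float = 0.1,
    stack: MaterialStack = DEFAULT_STACK,
    pressures: Sequence[float] = (7.5, 15.0, 22.5, 37.5, 75.0),
    seed: int = 0,
    flare: float = DEFAULT_FLARE,
) -> ObservationSet:
    """Simulate per-subject pressure-volume observations for one bougie size.

    Each subject's sleeve length is drawn from a normal distribution
    truncated below at 100 mm; the subject's deterministic P-V curve is
    then sampled at the requested pressures and multiplicative lognormal
    measurement noise with the given coefficient of variation is applied.
    """
    if n < 1:
        raise ValueError("need at least one subject")
    if noise_cv < 0 or length_sd_mm < 0:
        raise ValueError("noise_cv and length_sd_mm must be non-negative")
    if length_sd_mm > 0 and length_mean_mm - 3.0 * length_sd_mm < MIN_LENGTH_MM:
        warnings.warn(
            "length distribution truncates within 3 SD of the mean; "
            "draws will be noticeably skewed",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    if length_sd_mm > 0:
        a = (MIN_LENGTH_MM - length_mean_mm) / length_sd_mm
        lengths = stats.truncnorm.rvs(
            a, np.inf, loc=length_mean_mm, scale=length_sd_mm, size=n, random_state=rng
        )
    else:
        lengths = np.full(n, length_mean_mm)
    sigma = _noise_sigma(noise_cv)

    rows = []
    for subject, length in enumerate(lengths):
        geom = build_sleeve(BougieSpec(bougie_fr, length_mm=float(length)), flare=flare)
        volumes = simulate_volumes(geom, stack, pressures)
        if sigma > 0:
            volumes = volumes * np.exp(sigma * rng.standard_normal(volumes.size))
        for p, v in zip(pressures, volumes):
            rows.append((subject, float(p), float(v), float(length)))
    points = pd.DataFrame(rows, columns=["subject", "pressure_mmhg", "volume_ml", "length_mm"])
    metadata = {
        "n": n,
        "bougie_fr": bougie_fr,
        "length_mean_mm": length_mean_mm,
        "length_sd_mm": length_sd_mm,
        "noise_cv": noise_cv,
        "pressures": list(map(float, pressures)),
        "seed": seed,
        "flare": flare,
        "stack": {
            layer.layer_name: {"c_kpa": layer.c_kpa, "a_dimless": layer.a_dimless}
            for layer in stack.layers
        },
    }
    return ObservationSet(points=points, metadata=metadata)


def gen_calibration_dataset(
    true_stack: MaterialStack,
    sizes: Iterable[float] = (27, 30, 34, 36, 38, 40, 42, 46, 48, 50, 54),
    pressures: Sequence[float] = (7.5, 15.0, 22.5, 37.5, 75.0),
    noise_cv: float = 0.0,
    seed: int = 0,
    *,
    flare: float = DEFAULT_FLARE,
    length_mm: float = 150.0,
) -> pd.DataFrame:
    """Forward-simulate a pressure-volume table from known materials.

    Returns a table with columns (bougie_fr, pressure_mmhg, volume_ml);
    with ``noise_cv`` = 0 it is the exact forward simulation, otherwise
    each cell carries independent multiplicative lognormal noise.
    """
    sizes = list(sizes)
    if not sizes:
        raise ValueError("need at least one bougie size")
    rng = np.random.default_rng(seed)
    sigma = _noise_sigma(noise_cv)
    rows = []
    for fr in sizes:
        geom = build_sleeve(BougieSpec(fr, length_mm=length_mm), flare=flare)
        volumes = simulate_volumes(geom, true_stack, pressures)
        if sigma > 0:
            volumes = volumes * np.exp(sigma * rng.standard_normal(volumes.size))
        for p, v in zip(pressures, volumes):
            rows.append((float(fr), float(p), float(v)))
    return pd.DataFrame(rows, columns=["bougie_fr", "pressure_mmhg", "volume_ml"])
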