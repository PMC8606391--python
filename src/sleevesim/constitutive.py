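"""Hyperelastic description of the layered gastric wall.

Each layer is modelled as an incompressible, plane-strain Fung-type
exponential solid.  With circumferential stretch lam (axial stretch fixed
at 1 by the pinned junctions, radial stretch 1/lam by incompressibility)
the strain energy per unit reference volume is

    W(lam) = (c / 2) * (exp(a * (lam**2 + lam**-2 - 2)) - 1)   [kPa]

where c sets the low-strain stiffness scale and a the exponential
strain-stiffening rate.  The inflation pressure of a finite-thickness
two-layer ring follows from the equilibrium integral

    P = int_{r_i}^{r_o} (sigma_theta - sigma_r) / r dr

evaluated with the incompressible mapping r(R)^2 = r_i^2 + R^2 - R_i^2
and a fixed-order Gauss-Legendre rule per layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "LayerMaterial",
    "MaterialStack",
    "DEFAULT_STACK",
    "DEFAULT_FLARE",
    "reduced_energy",
    "stress_difference",
    "ring_pressure",
]

# exp() argument cap; far above any physical state, keeps the bracketing
# root solve finite when a trial stretch is deep in the stiffened regime.
_EXP_CAP = 500.0


@dataclass(frozen=True)
class LayerMaterial:
    """Fung-exponential parameters of one wall layer."""

    layer_name: str
    c_kpa: float
    a_dimless: float

    def __post_init__(self) -> None:
        if self.c_kpa <= 0 or self.a_dimless <= 0:
            raise ValueError("material parameters c and a must be positive")


@dataclass(frozen=True)
class MaterialStack:
    """One material per wall layer, lumen outward."""

    mucosa: LayerMaterial
    muscularis: LayerMaterial

    def __post_init__(self) -> None:
        if self.mucosa.layer_name != "mucosa" or self.muscularis.layer_name != "muscularis":
            raise ValueError("stack layer names must match the geometry layer names")

    @property
    def layers(self) -> tuple[LayerMaterial, LayerMaterial]:
        return (self.mucosa, self.muscularis)


def reduced_energy(material: LayerMaterial, lam):
    """Strain-energy density W(lam) in kPa; W(1) = 0, W(lam) = W(1/lam)."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    q = material.a_dimless * (lam**2 + lam**-2 - 2.0)
    out = 0.5 * material.c_kpa * np.expm1(np.minimum(q, _EXP_CAP))
    return out.item() if out.ndim == 0 else out


def stress_difference(material: LayerMaterial, lam):
    """Cauchy stress difference sigma_theta - sigma_r = lam * dW/dlam, in kPa."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    q = material.a_dimless * (lam**2 + lam**-2 - 2.0)
    out = (
        material.c_kpa
        * material.a_dimless
        * (lam**2 - lam**-2)
        * np.exp(np.minimum(q, _EXP_CAP))
    )
    return out.item() if out.ndim == 0 else out


@lru_cache(maxsize=8)
def _gauss(order: int) -> tuple[np.ndarray, np.ndarray]:
    return np.polynomial.legendre.leggauss(order)


def _stretch_at(R, R_inner, lam_inner):
    """Circumferential stretch at reference radius R for inner stretch lam_inner."""
    r_sq = (lam_inner * R_inner) ** 2 + R**2 - R_inner**2
    return np.sqrt(r_sq) / R


def pressure_profile(
    interfaces: np.ndarray,
    stack: MaterialStack,
    lam_inner: np.ndarray,
    order: int = 16,
) -> np.ndarray:
    """Vectorised inflation pressure (kPa) for a batch of rings.

    ``interfaces`` has shape (..., n_layers + 1); ``lam_inner`` broadcasts
    against its leading dimensions.  Each layer's contribution to the
    through-wall pressure integral is evaluated with an ``order``-point
    Gauss-Legendre rule in the reference radial coordinate:

        P = sum_layers int (sigma_theta - sigma_r) * R / r(R)^2 dR
    """
    interfaces = np.asarray(interfaces, dtype=float)
    lam_inner = np.asarray(lam_inner, dtype=float)
    nodes, weights = _gauss(order)
    R_i = interfaces[..., 0]
    ri_def_sq = (lam_inner * R_i) ** 2

    P = np.zeros(np.broadcast_shapes(lam_inner.shape, R_i.shape))
    for j, material in enumerate(stack.layers):
        R_a, R_b = interfaces[..., j], interfaces[..., j + 1]
        half = 0.5 * (R_b - R_a)
        mid = 0.5 * (R_b + R_a)
        # R: (..., order)
        R = mid[..., None] + half[..., None] * nodes
        r_sq = ri_def_sq[..., None] + R**2 - R_i[..., None] ** 2
        lam = np.sqrt(r_sq) / R
        q = material.a_dimless * (lam**2 + lam**-2 - 2.0)
        sdiff = (
            material.c_kpa
            * material.a_dimless
            * (lam**2 - lam**-2)
            * np.exp(np.minimum(q, _EXP_CAP))
        )
        P += half * np.einsum("...k,k->...", sdiff * R / r_sq, weights)
    return P


def pressure_profile_with_derivative(
    interfaces: np.ndarray,
    stack: MaterialStack,
    lam_inner: np.ndarray,
    order: int = 16,
) -> tuple[np.ndarray, np.ndarray]:
    """Inflation pressure and its derivative dP/dlam_inner, vectorised.

    Shares one pass over the Gauss points with :func:`pressure_profile`;
    the derivative is analytic (the through-wall stretch depends on
    lam_inner only through the deformed lumen radius), which lets the
    equilibrium solver take Newton steps instead of pure bisection.
    """
    interfaces = np.asarray(interfaces, dtype=float)
    lam_inner = np.asarray(lam_inner, dtype=float)
    nodes, weights = _gauss(order)
    R_i = interfaces[..., 0]
    ri_def_sq = (lam_inner * R_i) ** 2

    shape = np.broadcast_shapes(lam_inner.shape, R_i.shape)
    P = np.zeros(shape)
    dP_du = np.zeros(shape)  # u = (lam_inner * R_i)**2
    for j, material in enumerate(stack.layers):
        c, a = material.c_kpa, material.a_dimless
        R_a, R_b = interfaces[..., j], interfaces[..., j + 1]
        half = 0.5 * (R_b - R_a)
        mid = 0.5 * (R_b + R_a)
        R = mid[..., None] + half[..., None] * nodes
        r_sq = ri_def_sq[..., None] + R**2 - R_i[..., None] ** 2
        lam = np.sqrt(r_sq) / R
        q = a * (lam**2 + lam**-2 - 2.0)
        e = np.exp(np.minimum(q, _EXP_CAP))
        s = c * a * (lam**2 - lam**-2) * e
        # ds/dlam, with dq/dlam folded in (zero where the exp cap is active)
        ds = c * a * e * (
            (2.0 * lam + 2.0 * lam**-3)
            + (lam**2 - lam**-2) * np.where(q < _EXP_CAP, a * (2.0 * lam - 2.0 * lam**-3), 0.0)
        )
        # d/du of the integrand s(lam) R / r^2 at fixed R:
        #   dlam/du = 1 / (2 lam R^2),  d(r^-2)/du = -r^-4
        d_int = ds / (2.0 * lam * R) / r_sq - s * R / r_sq**2
        P += half * np.einsum("...k,k->...", s * R / r_sq, weights)
        dP_du += half * np.einsum("...k,k->...", d_int, weights)
    dP = dP_du * 2.0 * lam_inner * R_i**2
    return P, dP


def ring_pressure(
    interfaces,
    stack: MaterialStack,
    lam_inner: float,
    order: int = 16,
) -> float:
    """Inflation pressure (kPa) of one two-layer ring at inner stretch ``lam_inner``.

    ``interfaces`` is the triple of reference radii (lumen surface,
    mucosa/muscularis interface, outer surface) in mm.  Only the inflation
    regime ``lam_inner >= 1`` is supported.
    """
    interfaces = np.asarray(interfaces, dtype=float)
    if interfaces.shape != (len(stack.layers) + 1,):
        raise ValueError("expected one reference radius per layer interface")
    if np.any(np.diff(interfaces) <= 0):
        raise ValueError("interface radii must increase lumen->exterior")
    if lam_inner < 1.0:
        raise ValueError("deflation (lam_inner < 1) is not supported")
    return float(pressure_profile(interfaces, stack, np.asarray(lam_inner), order=order))


# Default operating point: wall materials and antral flare jointly frozen
# from a seeded calibration of the two-layer model against the packaged
# pressure-volume table (see calibration module and docs/methods.md).
DEFAULT_STACK = MaterialStack(
    mucosa=LayerMaterial("mucosa", c_kpa=4.2982, a_dimless=1.25271),
    muscularis=LayerMaterial("muscularis", c_kpa=18.04878, a_dimless=1.24328),
)
DEFAULT_FLARE = 1.8
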