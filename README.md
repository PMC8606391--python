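# sleevesim

Reduced-order biomechanics of the sleeved stomach after laparoscopic
sleeve gastrectomy (LSG).

LSG leaves a narrow gastric tube whose calibre is fixed by the bougie
used during stapling (27–54 Fr; 1 Fr = 1/3 mm of diameter). Two surgical
quantities drive outcome discussions: the **basal volume** associated with
a given intragastric pressure, and the **elongation strain** of the wall,
a proxy for the mechanoreceptor stimulation behind satiety. `sleevesim`
computes both for a family of parametric sleeve geometries, for surgeons
and bioengineers who want desk-scale, fully reproducible estimates of how
bougie calibre shapes the post-surgical mechanics.

## Model

The sleeve is an axisymmetric, axially discretised tube (150 mm greater
curvature, stations every 2 mm) with two wall layers — mucosa–submucosa
(1.0 mm) inside, muscularis (1.5 mm) outside — a flared antrum and tapered
junction ends. Each layer is an incompressible plane-strain Fung solid
with strain energy

    W(λ) = (c/2) · (exp(a·(λ² + λ⁻² − 2)) − 1)        [kPa]

where λ is the circumferential stretch (axial stretch is 1: the sleeve is
pinned at the gastroesophageal and pyloric junctions). Each station is an
independent thick-walled ring whose inflation pressure is the equilibrium
integral

    P(λᵢ) = ∫ (σ_θ − σ_r) / r dr,   σ_θ − σ_r = λ dW/dλ,

evaluated with the incompressible map r(R)² = rᵢ² + R² − Rᵢ² and 16-point
Gauss–Legendre quadrature per layer. Inverting P(λᵢ) per station,
attenuating the stretch toward the pinned ends and integrating πr² along
the axis gives the insufflated volume ΔV(P); strains are sampled at Gauss
points through each layer and summarised (volume-weighted mean ± SD) for
the whole model, by region (antrum/corpus) and by layer.

The free parameters (c, a per layer, plus the antral flare) are
calibrated by seeded multi-start nonlinear least squares on log-volumes
against a packaged 11-size × 5-pressure reference table; the calibrated
values ship as `DEFAULT_STACK` / `DEFAULT_FLARE`.

## Worked example

```python
from sleevesim import (BougieSpec, DEFAULT_FLARE, DEFAULT_STACK,
                       PressureSchedule, build_sleeve, inflate, strain_summary)

geometry = build_sleeve(BougieSpec(40), flare=DEFAULT_FLARE)
result = inflate(geometry, DEFAULT_STACK, PressureSchedule.table_default())
for p, v in zip(result.pressures_mmhg, result.volumes_ml):
    print(f"{p:5.1f} mmHg -> {v:6.2f} ml")
print(strain_summary(result, 37.5, "whole"))
```

prints

```
  7.5 mmHg ->   7.84 ml
 15.0 mmHg ->  17.92 ml
 22.5 mmHg ->  27.87 ml
 37.5 mmHg ->  43.85 ml
 75.0 mmHg ->  67.86 ml
StrainSummary(grouping='whole', mean_percent=39.18..., sd_percent=10.64...)
```

i.e. a 40 Fr sleeve needs ~28 ml of insufflation to reach 22.5 mmHg, and
at 37.5 mmHg its wall is elongated by 39 % ± 11 % on average — with the
mucosa and the antrum leading the muscularis and the corpus, the ordering
expected from Laplace's law. The scripts in `examples/` walk through each
capability (geometry, inflation, calibration, band coverage, parameter
recovery) with one short narrative apiece; a thin CLI (`sleevesim
simulate|calibrate|table-stats|band|synth|recover`) wraps the same
functions for shell use.

## Limitations

The geometry is a parametric axisymmetric tube, not a patient-specific
organ; the wall model is elastic and isotropic in the shell plane
(no viscoelasticity, fibre families, motility or bolus contact); volumes
follow the insufflated (ΔV) convention. See `docs/methods.md` for the
full account, including where the two-layer parameters stop being
identifiable from pressure–volume data alone.
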