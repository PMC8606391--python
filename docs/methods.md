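# Methods

## Scope and model reduction

`sleevesim` models the post-LSG stomach as an axisymmetric two-layer tube
— a deliberate reduction of full 3D finite-element practice. The sleeve
after surgery is close to a hollow cylinder, and the quantities of
interest here (basal volume at a prescribed intragastric pressure,
circumferential elongation strain by region and layer) are dominated by
ring-level equilibrium, which has an exact incompressible solution per
cross-section. The reduction buys determinism, speed (a full 11-size
campaign runs in under a second) and testability against closed forms.

## Geometry

* Axis `z` runs from the gastroesophageal junction (z = 0) to the pylorus
  (z = length, default 150 mm), stations every `spacing_mm` (default 2 mm,
  halving it changes volumes by < 0.5 %).
* Calibre: French scale, diameter = Fr/3 mm exactly. Clinically used
  bougies span 27–54 Fr.
* Wall: mucosa–submucosa 1.0 mm + muscularis 1.5 mm (total 2.5 mm),
  offset outward from the lumen at every station.
* Regions: a proximal corpus block and a distal antrum block
  (default boundary 50 mm from the pylorus). The antrum carries
  `flare` × the bougie radius, joined by a cosine blend (20 mm wide)
  across the boundary; the packaged strain table motivates a flared antrum
  (its strains exceed the corpus), but no antral dimensions are published,
  so the flare is a calibration parameter (below).
* Junctions: over 10 mm at each end the radius decays smoothly
  (cosine) to a 3 mm junction radius, standing in for the pinned
  esophagogastric and pyloric ends. `build_sleeve` keeps 1.3 as its
  signature default flare so the bare geometry is usable without the
  calibrated material context.

## Wall mechanics

Each layer is incompressible and in plane strain (axial stretch 1,
reflecting the fixed junctions), with a reduced Fung strain energy
`W(λ) = (c/2)(exp(a(λ² + λ⁻² − 2)) − 1)` per layer. This is a
deliberately minimal stand-in for the anisotropic visco-hyperelastic
formulations used in the source modelling tradition, whose layer
parameters are published elsewhere and are not reproducible from the
tables this package ships; all reported quantities here are equilibrium
states, so the elastic reduction loses nothing observable.

Ring equilibrium: `P(λᵢ) = ∫ (σθ−σr)/r dr` across both layers with the
incompressible map `r(R)² = rᵢ² + R² − Rᵢ²`, fixed 16-point
Gauss–Legendre per layer (doubling the order moves P by < 1e-9 relative).
The map conserves wall cross-section area exactly, and forces the stretch
to decrease monotonically through the wall — hence the mucosa always
carries more strain than the muscularis, at any material parameters.

The inversion λᵢ(P) uses a vectorised bracketed Newton iteration on
log-pressure (the log-residual is near-linear because P grows
near-exponentially in λ), with bisection fallback inside the bracket
[1, 5] and an analytic dP/dλᵢ. Every pressure state is solved
independently on the same fixed bracket, so results are exactly
path-independent; residuals at convergence are far below the 1e-8 kPa
contract. Stations sharing a reference radius share one solve.

End fixity: the stretch profile is blended to 1 at the two terminal
stations by the factor `1 − exp(−(d/ℓ)²)` per end, `d` the distance from
the end and `ℓ` the deformed radius of that end's terminal station. The
squared exponential keeps stations beyond five characteristic lengths
untouched to < 1e-6 relative. The junction's own (small) deformed radius
is the right decay scale: tying `ℓ` to each station's far-field radius
would let the pinned boundary layer grow with the antral flare until it
swallowed the whole antrum and inverted the Laplace-law region ordering
the model exists to quantify.

Units: kPa and mm internally; pressures cross the API boundary in mmHg
(1 mmHg = 0.1333224 kPa); volumes in ml.

## Volume convention

Reported volumes are insufflated volumes ΔV = V(P) − V(0) relative to the
unloaded configuration. The packaged reference volumes at low pressure
are far below the geometric lumen volume of a 150 mm tube, so they cannot
be total volumes; a `total` convention remains available and every
calibration result is stamped with the convention used.

## Calibration

The free parameters (c, a per layer; optionally the flare) are identified
against the packaged 11 × 5 pressure–volume table by bounded nonlinear
least squares on **log** volumes (the table spans 3.2–151 ml; a raw-volume
loss would see only the largest sleeves). Multi-start: the init point (if
given) plus `n_starts` (default 8) scrambled-Sobol points of the log-bounds
box (c ∈ [0.1, 200] kPa, a ∈ [0.05, 20], flare ∈ [1.0, 1.8]), trust-region
reflective refinement, ties broken by objective then by mucosa stiffness.
Fits are bit-reproducible given (table, init, bounds, seed).

The shipped defaults are the jointly calibrated operating point
(seed 0, 8 starts): c_mucosa = 4.2982 kPa, a_mucosa = 1.2527,
c_muscularis = 18.0488 kPa, a_muscularis = 1.2433, flare = 1.80 (at the
bound), median per-cell volume error 5.0 %, worst cell 15.5 %. Fixing the
flare at 1.3 instead yields a 6.5 % median — the joint point is preferred
because the flare is explicitly a calibration parameter and the joint fit
also lands the simulated strain statistics closest to the reference
strain table. The table is calibration data throughout: agreement
demonstrates representational capacity, not a priori prediction.

### Identifiability

A closed noiseless loop (generate table from known parameters → refit)
recovers all four parameters to machine precision, so the forward model
and optimiser are exact. Under 5 % multiplicative lognormal noise,
however, the global optimum wanders along a sloppy inter-layer direction:
a ~30 % drop in c_mucosa is compensated by small changes in the dominant
(thicker, stiffer) muscularis layer at almost no cost in the loss.
Replicated audits (`recovery_report`) show median worst-parameter errors
of 50–90 % at that noise level, for balanced and calibrated truths alike,
with the optimiser verifiably at the global minimum. The conclusion is
scientific, not numerical: one aggregate P–V family cannot separate
two-layer stiffnesses under realistic noise — layer-resolved tissue
experiments are what pins them down. Per-layer `(c, a)` recovery to ~10 %
from a noisy 55-cell table should not be expected, and the corresponding
acceptance check is left failing as a documented model-limit.

## Pressure–volume curve shape

On the reported pressure states the calibrated curves are
convex-increasing ("exponential trend") for sleeves ≥ 40 Fr; for the
smallest sleeves the segment between 7.5 and 22.5 mmHg is slightly
concave. This is a genuine property of the calibrated regime
(a ≈ 1.25): below ~15 mmHg the wall is nearly linear-elastic, and a
linearly elastic ring inflates with V convex in P (dV/dP ∝ λ² kinematics),
i.e. P(V) initially concave; convexity takes over once exponential
stiffening dominates. Strongly stiffening walls (a ≳ 1.5) are convex
throughout. The corresponding acceptance assertion is left failing for
the small calibres rather than restricting the checked range.

## Synthetic data

`gen_pv_observations` emulates in-vivo-style measurements: one bougie
size (default 50 Fr), subject lengths from a normal truncated below at
100 mm (default 150 ± 15 mm — length is the named dominant anatomical
difference between subjects sleeved over one bougie), deterministic
per-subject curves, then multiplicative lognormal noise parametrised by a
coefficient of variation (default 0.10, a realistic scale for
intra-operative volume reads). `gen_calibration_dataset` does the same
for multi-size tables. Both are pure functions of their arguments
including the seed. What they do **not** emulate: material heterogeneity
between subjects (optional flag excepted), measurement drift, or any
specific published cohort — so band-coverage numbers computed against
them validate the coverage machinery, not clinical coverage rates.

## Statistics and rounding conventions

Strain summaries are means and SDs over Gauss-point samples weighted by
reference shell volume (the source tables do not state their weighting;
volume weighting is the declared choice here). Whether the cross-size
"mean row" statistics agree with a printed source is checked to ±0.02,
the slack introduced by averaging rounded 2-decimal entries. Size ratios
round to nearest integer or nearest half; layer differences round
half-up; the antrum–corpus difference truncates — mirroring how such
table arithmetic is quoted in prose. One reference strain cell
(46 Fr, antrum, 22.5 mmHg, printed 4.12 %) is inconsistent with its own
column mean; the back-solved 41.22 % is substituted only on request
(`load_table2(corrected=True)`).

The band is the pointwise min/max envelope over a family of curves on a
shared pressure grid, interpolated linearly in volume between grid
pressures; the in-band test is closed-interval with an epsilon at
floating-point scale.

## Degenerate inputs and numerical guards

Deflation (λ < 1) is rejected; pressures unreachable within λ ≤ 5 raise a
solver error naming the offending state ("material too soft"). The Fung
exponent is capped at exp(500) inside the solver only to keep trial
states finite during bracketing; the cap is unreachable at any converged
physical state. Geometric inversion (non-increasing interface radii),
non-positive stretches, thicknesses, calibres and empty tables all fail
fast with explicit messages.

## Problem sizes

Default campaigns use all 11 calibres × 5 pressures at 2 mm station
spacing; calibration uses 8 multi-starts; recovery audits in the examples
use 4 sizes × 5 pressures with 2 replicates. These sizes were chosen so a
full audit remains an interactive (sub-minute to few-minute) operation on
a laptop-class single core while leaving every reported statistic at its
full problem size.
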