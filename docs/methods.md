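# Methods

`osteofrac` simulates crack growth through cortical bone microstructure
with a 2D plane-strain AT1 phase-field model, and wraps that solver in the
two-stage design-of-experiments workflow used to identify tissue-level
toughness parameters from bending experiments: a six-factor screening on a
single-osteon cell, then a four-factor response-surface stage on a
single-edge notched bending (SENB) beam with an embedded microstructure
window, closed by a grid calibration of the matrix and cement-line
toughness against an observed (peak force, tortuosity, J_Ic) triple.

All quantities use the mm-N-MPa system: lengths mm, forces N, stresses and
energy densities MPa, toughness G_c in N/mm, stress intensity in
N/mm^(3/2).

## Phase-field model

The composite has three isotropic linear-elastic tissue classes — matrix,
osteon, cement line — each with Young's modulus E, Poisson's ratio nu
(0.3 everywhere) and critical energy release rate G_c.  Damage
d in [0, 1] regularises the crack with the first-order (AT1) crack
density, giving the regularised potential per unit thickness

    Pi_l = ∫ { [(1-d)^2 + k] psi0(eps) + (3 G_c / 8 l) (d + l^2 |∇d|^2) } dA,

with residual stiffness k = 1e-7 and regularisation length l (band width
about 4 l).  The Amor hydrostatic–deviatoric split supplies the damage
driving force:

    psi+ = (alpha/2) kappa' tr(eps)^2 + mu |dev eps|^2,   alpha = [tr eps > 0],

with kappa' = lambda + mu the plane-strain 2D bulk modulus.  The scheme is
hybrid: equilibrium degrades the full isotropic stiffness g(d) C while
only psi+ drives damage.  Irreversibility comes from the history field
H(x, t) = max over time of psi+, clamped from below at the AT1 elastic
threshold H_min = 3 G_c / (16 l), which is exactly the driving force at
which the homogeneous damage solution first leaves zero; the clamp keeps
the linear damage problem from returning negative damage.

Two consequences of the history-field formulation are worth knowing:

* the damage profile around a fully formed crack carries exponential
  tails d ~ exp(-r / (sqrt(2) l)) rather than the compactly supported
  optimal AT1 profile (the latter belongs to the variational-inequality
  treatment of irreversibility);
* the AT1 surface energy accumulated by an *unstable* crack jump exceeds
  G_c per unit advance, because the jump overdrives the history field and
  widens the band.  The energy-release outcome used throughout the study
  is therefore the accumulated strain-energy drop divided by the
  projected crack advance, which reproduces the regularised toughness
  G_c (1 + 3h/(8 l)) to a few percent on the stable-growth benchmark.

AT1 gives an elastic stage and hence an effective strength
sigma_c = sqrt(3 E G_c / (8 l)) (use E/(1-nu^2) for a plane-strain bar
free to contract laterally); the ductile-to-brittle transition flaw size
a_c = E G_c / (pi sigma_c^2) = 8 l / (3 pi) follows identically.

## Discretisation and solver

Bilinear quadrilaterals with 2x2 Gauss quadrature for displacement and
damage; H lives at the quadrature points; h <= l/2 wherever the crack may
run.  Notches are geometric slits (duplicated node seams); Haversian
canals are holes (free surfaces); tissue regions share nodes.

Each displacement-controlled step is solved by alternating minimisation:
linear elasticity at frozen damage, then the linear AT1 damage problem at
frozen history, iterating until the damage fixed-point residual
(max nodal change < 1e-4) and the relative energy change (< 1e-6) both
pass, with at most 200 sweeps and up to 4 step halvings on failure.
Two accelerations preserve the converged states exactly: Aitken
relaxation of the damage update (the fixed point is unchanged), and lazy
stiffness refactorisation — intermediate sweeps may reuse a factorisation
while damage has drifted < 0.05, but convergence is only accepted after a
confirming sweep with a fresh factorisation, and the recorded force comes
from a final exact solve.  Because the hybrid scheme is not variational
and the history field ratchets within a step, the per-sweep energy is
only approximately non-increasing (observed upticks < 0.5% near
instabilities); each evolving step still descends overall.

Load schedules follow the study protocol: a coarse step until the first
drop in load (force below 0.99 of its running maximum), then a refined
step; runs stop when the specimen is severed (force below 5% of peak with
a propagating crack) or the crack has crossed a set fraction of the
ligament.  Everything is deterministic; two identical runs produce
bit-identical histories.

## Geometries

*Screening cell*: 400 um square, central osteon (outer radius 75 um,
canal 25 um) with a cement annulus, edge notch 80 um at mid-height,
loaded by a prescribed vertical displacement of the top face with the
bottom face vertically constrained (one corner pinned horizontally).

*SENB beam*: span L = 4 h between a pin and a roller at the lower
corners, downward displacement at top mid-span, vertical slit notch at
x = 0, origin at the notch mouth with y up the ligament.  Phase field is
active only inside a circular/elliptic window ahead of the notch; outside
it the material is linear elastic with matrix properties; the mesh is
fine in a vertical corridor above the notch and coarsens geometrically
away from it.  The experimental support description is statically
indeterminate as printed; the standard determinate three-point-bend set
(pin + vertical roller) is used.

## Outcomes

* **Peak force**: maximum of the force history, truncated before the step
  at which any fully damaged point (d >= 0.95) first lies on a canal wall
  — the model over-predicts re-initiation strength inside canals because
  of the small l.  If the crack reaches the canal within a single
  unstable advance, the energy-release window includes that jump.
* **Energy release per advance**: accumulated strain-energy drop /
  projected horizontal advance, same truncation.
* **Crack path and tortuosity**: the damage field is sampled on a uniform
  grid at the fine-mesh resolution, thresholded at d > 0.01, and
  skeletonised.  Skeleton spurs shorter than the damage-band width
  (4 l / h pixels) are pruned by endpoint erosion plus geodesic
  reconstruction, and the path length is the longest geodesic path
  resampled as a polyline with 4-pixel vertex spacing — per-pixel chain
  codes overestimate oblique digital lines by up to ~8%, which the coarse
  resampling removes (straight, 45-degree and sinusoid fixtures are
  recovered within 1%).  Tortuosity is path length over projected extent:
  horizontal normalisation for the screening cell, vertical for SENB
  (restricted to the first 25% of the initially intact ligament, the
  validity region of the bend-test standard).  sqrt(2)-weighted chain
  length and half-perimeter estimators remain available as utilities.
* **Toughness**: K_i = P_i L / (t h^{3/2}) f(a_i/h) with the standard
  span-equals-4-heights bend factor (asserted at run time); a_i is the
  notch depth plus the furthest extent of d >= 0.95 along the ligament,
  made non-decreasing.  K_c is taken at the force maximum before the
  first crack jump exceeding 10 l per step (defaulting to the peak-force
  step), and the simulated initiation toughness converts as
  J_Ic = K_c^2 (1 - nu^2) / E (the simulated response is linear elastic
  up to unstable fracture; the experimental 0.2 mm-extension value is
  reported alongside when reached).  J-K pairs satisfy the identity to
  machine precision.

## Design-of-experiments stages

Factors are coded on three levels, value = baseline (1 + code x half
range), around the baseline set E_mat = E_cem = 15 GPa, E_ost = 13.5 GPa,
G_c,mat = 0.35, G_c,ost = 0.5, G_c,cem = 0.1 N/mm.

* **Screening**: all six parameters at +/-20%, classical six-factor
  Box-Behnken (three-factor +/-1 blocks, 48 edge runs) plus six centre
  repeats = 54 rows.  Outcomes per run: peak force, tortuosity
  (horizontal), energy release.  Type-II ANOVA with main effects only;
  a factor's importance is its share TSS = SS_factor / SS_total.
* **Response surface**: E_cem, G_c,mat, G_c,ost, G_c,cem at +/-50%,
  four-factor Box-Behnken (24 edge runs) plus three centre repeats = 27
  rows on one SENB microstructure.  ANOVA with pairwise interactions;
  linear OLS surfaces in (G_c,mat, G_c,cem) with 95% confidence bands.
* **Calibration**: cost(theta) = sum over outcomes of
  |RS(theta) - y_obs| / y_obs on a regular grid (default step 0.01 N/mm)
  across the explored ranges; ties break towards the baseline.  The
  surfaces are linear, so grid search is exact to its resolution.
* Centre repeats of the deterministic forward model are identical, so
  duplicate parameter points are evaluated once and reused.

## Synthetic data

The generator stands in for the experimental inputs.

* **Microstructures**: random sequential adsorption of circular osteons
  (normal outer-radius distribution, canal radius one third of the outer
  radius, 5 um cement annuli included in the overlap exclusion) into a
  circular/elliptic window until a target osteonal area fraction —
  whole-disc area over window area, targeting the 40-70% occupancy of
  cortical bone — is reached or the packing jams; jammed packings return
  partially filled layouts flagged by their achieved fraction.
  Containment is either strict (whole osteons inside the window) or
  canal-only, which lets lamellae straddle the window boundary the way
  traced embedded-cell windows do.  Deterministic per seed.
* **Pseudo-experiments**: the forward model at known "true" parameters
  plus independent lognormal observation noise (median-preserving,
  positivity-respecting) with a stated coefficient of variation, default
  0.05 — within the scatter bending experiments show.  The truth is
  stored beside the observations for recovery tests.
* **Crack images**: rasterised bands of known analytic tortuosity
  (straight, 45-degree staircase, quarter sine by quadrature, arc).

What the generator does **not** emulate: real osteon morphometrics
(ellipticity, drift, size-shape correlations), sub-lamellar texture that
makes real cracks jagged, and uCT image noise.  Passing recovery tests
therefore show the calibration machinery is sound, not that real bone
obeys a linear response surface.

## Problem sizes

The reference resolution (1.25 um elements, l = 2.5 um = half the cement
thickness, 40k-400k elements, step 5e-5 mm) is what the builders produce
at full density, and single runs at h = 2.5 um / l = 5 um are exercised
by the crack-deflection experiment.  Batch stages run at documented
desk-scale conditions chosen so a full design completes in minutes on one
CPU:

* screening: the same cell with the cement line thickened to 15 um so it
  stays two elements wide at h = 7.5 um, l = 15 um; ~2.5k elements,
  54 runs in ~3 minutes;
* response surface: a quarter-scale SENB beam (h = 0.8 mm, span 3.2 mm,
  a0/h = 0.425 as in the reference specimen) with a 0.22 mm window of
  scaled osteons (mean radius 55 um, cement 16 um) at h = 8 um, l = 16 um;
  ~4k elements, 27 runs plus the pseudo-experiment in ~6 minutes.

## Known limitations

* At desk scale the regularisation length spans the whole cement line,
  so interface channelling is smeared: cracks that the reference
  resolution would deflect can penetrate.  The screening consequently
  reproduces the dominant toughness/stiffness sensitivity structure of
  peak force and energy release, but under-weights the cement-line and
  osteon toughness shares of tortuosity, which at reference resolution
  are carried by deflection events.
* At normal incidence (the screening cell, where the crack meets the
  osteon equator head-on) the cement line deflects the crack only below
  an interface-to-bulk toughness ratio of roughly 0.25 — at
  G_c,cem/G_c,mat = 0.05/0.36 the damage path wraps the annulus and
  arrests, while 0.14/0.36 penetrates.  Deflection at the calibrated
  ratio occurs for oblique incidence, as in SENB microstructures.
* The model is linear elastic and brittle: the force-CMOD response is
  linear to the peak, crack growth after the peak is fast, and rising
  R-curve behaviour of real bone is outside its scope.
* Nucleation from the geometric slit overshoots the LEFM onset force by
  tens of percent at finite l (a known property of geometric notches in
  phase-field models), which also overdrives the first crack jump.
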