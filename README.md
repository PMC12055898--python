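# osteofrac

Phase-field simulation of crack growth in cortical bone microstructure,
with design-of-experiments identification of tissue toughness.

Cortical bone is a composite of interstitial matrix, osteons and the thin
(~5 um) cement lines that wrap them.  Whether a propagating crack cuts
straight through an osteon or deflects along its cement line controls how
tough the bone is — and the toughness of the cement line itself cannot be
measured directly.  `osteofrac` is for researchers in bone fracture
mechanics who want to (a) simulate microstructural crack growth with a
brittle AT1 phase-field model and (b) infer the unmeasurable tissue
parameters by comparing simulated single-edge notched bending (SENB)
outcomes against experimental ones.

The model minimises the regularised fracture energy

    Pi_l = ∫ [ ((1-d)^2 + k) psi0 + (3 G_c / 8 l)(d + l^2 |∇d|^2) ] dA

over displacement u and damage d, with the Amor hydrostatic-deviatoric
split driving damage (tension only), a hybrid equilibrium degradation,
and history-field irreversibility with the AT1 threshold 3 G_c/(16 l).
The regularisation length l doubles as a strength parameter through
sigma_c = sqrt(3 E G_c / (8 l)).  On top of the solver sit:

* structured graded meshes of the two canonical geometries (single-osteon
  cell; SENB beam with an embedded microstructure window),
* a synthetic-microstructure generator (random sequential packing of
  osteons with cement annuli) and pseudo-experiment generator,
* post-processing into peak force, energy release per crack advance,
  skeleton-based crack tortuosity, and K/J fracture toughness with
  R-curves,
* Box-Behnken screening (six factors, 54 runs) with Type-II ANOVA
  variance shares, linear response surfaces, and grid calibration of
  (G_c,mat, G_c,cem) by normalised absolute error.

See `docs/methods.md` for the model, estimators, and the desk-scale
problem sizes the batch stages run at.

## Worked example

Simulate the notched single-osteon cell at baseline tissue parameters
(E_mat = E_cem = 15 GPa, E_ost = 13.5 GPa, G_c = 0.35/0.5/0.1 N/mm for
matrix/osteon/cement line):

```bash
osteofrac simulate --outdir out/sim --scale desk
# peak force 65.748 N, final crack 0.400 mm
```

The cell is loaded in vertical tension; the crack starts at the 80 um
notch, crosses the cement line and osteon, re-initiates past the
Haversian canal and severs the 0.4 mm specimen — `final crack 0.400 mm`
means a fully traversed ligament.  The peak force is reported with the
canal-truncation rule (force history considered only until the crack
enters the canal).  `out/sim/history.csv` holds the per-step force, CMOD,
energies and crack length; `final_fields.vtk` the damage field.

Run the screening stage and read off which parameters matter:

```bash
osteofrac screen --outdir out/screen
# peak_force: top factors ['Gc_mat', 'E_mat']
# tortuosity: top factors ['E_ost', 'Gc_cem']
# energy_release: top factors ['Gc_mat', 'E_mat']
```

`out/screen/anova_peak_force.csv` lists each factor's variance share
(TSS): matrix toughness dominates peak force (~0.57 of the variance at
desk scale) and energy release (~0.49), with the matrix modulus second —
the same dominant structure the reference-resolution study reports.

A full calibration round trip (response surfaces on a synthetic SENB
microstructure, then grid calibration against an observed triple) is in
`osteofrac respsurf` + `osteofrac calibrate`; programmatically, the
closed loop recovers a noise-free pseudo-experiment generated at
(G_c,mat, G_c,cem) = (0.36, 0.14) N/mm to within the 0.01 N/mm grid step.

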