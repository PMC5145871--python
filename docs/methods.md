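# Methods

## The physical problem

When a synaptic vesicle docks at the presynaptic membrane, the two
bilayers are pulled to within a few nanometres of each other.  Both
membranes carry anionic lipid (POPS, PIP2) and are neutralized by
potassium in the surrounding aqueous compartments.  Squeezing the
counterion-rich gap between the membranes redistributes charge relative
to the membranes' own charge, and the resulting electrostatic imbalance
appears as a transmembrane voltage across each bilayer.  If the
membranes come close enough, this voltage reaches the electroporation
range (of order 1 V across a ~4 nm slab) and a transient hydrophilic
pore can open without any externally applied field.  memvolt implements
the electrostatic model of that mechanism and the analysis pipeline
around it, with a synthetic data generator standing in for atomistic
simulation output.

## Five-layer slab model

The contact zone is idealized as five planar slabs along the membrane
normal Z (bottom to top): interstitial fluid R3 (thickness H_L),
presynaptic membrane Rm2 (H_m), inter-membrane cytosol R2 (D), vesicle
membrane Rm1 (H_m), vesicle lumen R1 (H_L).  Z = 0 is the mid-plane of
R2.  Each slab carries a uniform volume charge density ρ (e/nm³);
neutrality requires

    ρ1·H_L + ρ3·H_L + ρ2·D + ρm1·H_m + ρm2·H_m = 0 .

The potential obeys the 1-D Poisson equation φ'' = −ρ/(ε_r ε0) with a
single relative dielectric constant ε_r (default 3, an experimental
value for the nanoscale lipid/water stack; explicit water polarization
is deliberately absorbed into ε_r).  With piecewise-constant ρ, φ is
piecewise quadratic and the voltage across each membrane has the
closed form implemented in `layered_model.transmembrane_voltages`; for
a mirror-symmetric stack (ρ1 = ρ3, ρm1 = ρm2 = ρm),

    ΔV = −(1/(2 ε_r ε0)) (ρm H_m + ρ2 D) H_m ,

affine in D at fixed ρ2.  The membrane charge density comes from the
lipid composition: ρm = leaflets · Σ f_s q_s / (a_L H_m) with POPS −1 e,
PIP2 −5 e, neutral lipids 0 e, and area per lipid a_L = 0.65 nm²
(typical fluid-phase value; configurable — the source system does not
fix it).

### Boundary condition and sign convention

The literature prescription integrates φ from the symmetry axis with
φ(0) = 0.  For an arbitrary (asymmetric) neutral stack that
prescription is ambiguous about the integration constant of the field;
memvolt fixes the gauge physically — zero field outside the neutral
stack — and shifts φ(0) = 0.  For mirror-symmetric stacks the two
prescriptions coincide.  In this gauge the closed-form ΔV expressions
equal φ(outer face) − φ(inner face) of each membrane exactly, which is
the sign convention used throughout (only |ΔV| is physically compared
anywhere; the sign convention is internal bookkeeping).

### Charge-closure policies for distance scans

What happens to the aqueous charge when D changes is a modelling
choice, exposed as an explicit enum:

* `FIXED_RHO2` — ρ2 held constant, ρ1 = ρ3 re-neutralize.  ΔV(D) is
  then exactly affine with slope −ρ2 H_m/(2 ε_r ε0); useful as an
  analytic reference.
* `FIXED_COUNTER_CHARGE` (default) — the total counterion charge per
  area is conserved and spread uniformly over R1 ∪ R2 ∪ R3
  (ρ1 = ρ2 = ρ3 = Q/(2H_L + D)), matching a closed simulation box in
  which ion number is constant as the membranes approach.  ΔV(D) is
  then rational in D; for the symmetric stack
  ΔV ∝ (2H_L − D)/(2H_L + D), i.e. the voltage vanishes at wide
  separations and grows steeply on close approach.

Note that a literal reading of "fixed ρ2·D with ρ1, ρ3 fixed" would
make ΔV independent of D (Eq-4 algebra depends on ρ2·D only) and no
critical distance would exist; the uniform-redistribution reading above
is the one consistent with a constant-ion-number box.

### Critical distance

`critical_distance` returns the D at which |ΔV(D)| crosses the critical
poration voltage *downward* with increasing D: pores form at every
separation at or below it.  Under the default closure |ΔV| is V-shaped
(it passes through zero where the gap charge balances the membrane
charge, at D = 2H_L for the symmetric stack) and can rise again at
large D; those upward crossings are artifacts of the closure and are
never returned.  Policy (i) is inverted in closed form; policy (ii) by
scanning a 1025-point grid over the bracket (default [0.5, 10] nm) and
Brent refinement to 1e−9 nm.

## Numeric (Tieleman-style) voltage route

`poisson1d` mirrors what one does with simulation output: bin particle
charges over the membrane plane into ρ(Z) (default 0.1 nm bins spanning
the box), integrate twice (zero field at the lower box edge, φ = 0 at
the symmetry axis), and read ΔV off the membrane faces.  The double
integration treats each bin as uniform, so φ at the bin edges is exact
for the binned representation; the only error versus the continuum
model is the binning itself.  Membrane faces come either from declared
geometry (exact) or, for unlabeled particle input, from gap-clustering
the headgroup Z positions (clusters separated by > 1 nm; two clusters =
two volumetric slabs, four = paired face sheets).  The cluster extent
of a uniformly filled slab coincides with the half-maximum crossing of
its binned density to within the sampling resolution.

## Synthetic generator: the stated world

`synthetic_membrane` builds pseudo-particle realizations of a
LayerStack, not molecular structures:

* **Headgroup charge** is spread uniformly through each membrane slab
  (default), which makes the binned profile an unbiased sample of the
  model density.  A δ-sheet variant (two charged planes per membrane at
  the faces) is available; it integrates to the identical ΔV in the
  continuum limit but acquires a first-order bin-width bias
  (~ε_r⁻¹·K·σ_face·h/4 ≈ 0.03 V at h = 0.1 nm) when a face sheet sits
  on a bin edge, which is why it is not the default.
* **Ions** are +1 e potassium, placed uniformly at random with integer
  counts rounded from the target region charges; a single declared
  CHARGE_PAD particle absorbs the sub-elementary rounding residual so
  every build is exactly neutral.  Chloride is omitted (potassium-only
  neutralization); with the default geometry and 15% POPS the resulting
  concentration is ≈ 0.13 mol/L, inside the 0.04–0.15 mol/L range the
  emulated simulations report.  `ion_concentration` reports, it never
  asserts.
* **Water** is represented by zero-charge occupancy markers on a
  jittered lattice at 33.4 nm⁻³ (1 g/cm³ number density), used only by
  the pore detector.  Dielectric screening enters solely through ε_r.
* **Pores** are planted as cylinders of occupancy markers spanning each
  membrane slab, on a 0.1 nm fill grid, with radius following a
  schedule r(t): zero before t_open, then one of three templates
  mirroring the reseal-fast / reseal-slow / dilate tension regimes
  (linear close-out within ~8 ns; linear shrink to 50% at the 20 ns
  window; 5%/ns monotone growth).
* Default geometry: H_m = H_L = 4 nm (the emulated ~20 nm box with five
  layers; exact slab thicknesses are a declared choice, not an inferred
  one), box cross-section 23 × 23 nm², all config-overridable.
* Determinism: one `numpy` Generator seeded per build; identical
  arguments give bit-identical output.

What a green test on this generator establishes: that the analysis
stages are correct on inputs whose ground truth is known exactly.  What
it does not establish: anything about real lipid packing, water
orientation polarization, pore nucleation kinetics, or force-field
physics — frozen pseudo-particles do not diffuse, planted pores follow
a prescribed schedule rather than membrane mechanics.

## Pore metrics

Detection grids the membrane plane at 0.2 nm cells; a column is "open"
if every Z sub-bin (cell-size thick) across the membrane slab contains
at least one water marker, and open cells are merged by 4-connectivity
with periodic wrap (scipy labelling plus a union-find stitch across the
boundaries).  Pore size is reported as the equivalent circular diameter
2√(area/π) — the emulated observable is "pores of 1–2 nm diameter" with
no defined measure, so the area-equivalent is declared here.  The size
histogram is fitted with an unconstrained Gaussian (least squares on
the counts, moment-based start); fewer than 10 observations yields a
histogram with the fit flagged unavailable, and degenerate histograms
fall back to sample moments.

`classify_fate` labels a (t, diameter) series within a 20 ns window:
RESEAL_FAST if the diameter reaches zero; DILATE if the final diameter
exceeds the initial by ≥ 25% and the least-squares slope over the last
third is non-negative within 0.01 nm/ns (both thresholds configurable —
the emulated regimes are qualitative); everything else still open is
RESEAL_SLOW.  A slow-resealing pore is by definition still open at the
window end, so it carries no close time (fast reseals do).

## Tension and scans

Lateral tension is Γ = L_Z (P_Z − P_Lat) with the SI-derived conversion
1 bar·nm = 0.1 pN/nm.  `distance_scan` steps D from 6 nm down in 0.5 nm
steps (the emulated protocol), marks poration where |ΔV| ≥ ΔV_critical,
and reports D_critical as the largest porating grid point.  In
trajectory mode the opening time is generated by an explicit stub —
t_open = window · (ΔV_critical/|ΔV|)², so exactly-critical voltage
opens at the window edge and stronger voltage opens earlier — and then
measured back by detection; this is a threshold rule for exercising the
pipeline, not a kinetic model.  `composition_scan` repeats the
critical-distance inversion over a POPS ladder and reports whether
D_critical is monotone non-decreasing in the POPS fraction.

## Numerical choices

* Units: {e, nm, V, ns}; Poisson coupling e/(ε0·nm) ≈ 18.0951 V·nm from
  CODATA constants.
* Neutrality tolerance 1e−9 e/nm² (surface) and 1e−9 e (total);
  non-neutral stacks warn rather than fail in the closed forms.
* Binning default 0.1 nm; detector cell 0.2 nm with sub-bin thickness
  equal to the cell; critical-distance bracket [0.5, 10] nm, Brent
  tolerance 1e−9 nm.
* D = 0 (membranes in contact) is a legal degenerate stack (R2 of zero
  thickness); zero-charge stacks give identically zero potential.

## Known limitations

* No Boltzmann redistribution of ions (fixed uniform ρ per layer), no
  image charges, no dielectric contrast between slabs, planar geometry
  only.
* The numeric route's accuracy on particle input is limited by the
  placement noise of the generator (~0.08 V std at a 23 × 23 nm box for
  the default system) — real simulation profiles would instead carry
  thermal averaging noise.
* Trajectory-mode formation times are only meaningful for supplied or
  synthetic trajectories; the package cannot and does not predict
  poration kinetics.
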