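# memvolt

Electrostatics of close membrane–membrane contact: the transmembrane
voltage generated when two charged lipid bilayers approach each other,
and the transient fusion pores that voltage can open.

When a synaptic vesicle is pulled against the presynaptic membrane,
the counterion-rich aqueous gap between the two anionic bilayers is
squeezed, and a voltage develops across each membrane.  Below a
critical separation that voltage reaches the electroporation range and
a 1–2 nm transient pore can form without any applied field.  memvolt
provides, for modellers and simulators of membrane fusion:

* **`layered_model`** — a closed-form five-layer slab model
  (lumen / vesicle membrane / gap / presynaptic membrane / interstitial
  fluid).  With uniform charge density per slab the potential solves
  φ'' = −ρ/(ε_r ε0) piecewise; for a mirror-symmetric stack

      ΔV = −(1/(2 ε_r ε0)) (ρ_m H_m + ρ₂ D) H_m ,

  so the voltage grows as the inter-membrane distance D shrinks.
  Includes composition → membrane charge (POPS −1 e, PIP2 −5 e),
  voltage–distance scans under explicit charge-closure policies, and
  critical-distance inversion |ΔV(D)| = ΔV_critical.
* **`poisson1d`** — the numeric route used on simulation output: bin
  particle charges into ρ(Z), double-integrate the 1-D Poisson
  equation, read ΔV off the membrane faces.
* **`synthetic_membrane`** — a deterministic, exactly-neutral generator
  of two-bilayer pseudo-particle systems and trajectories with planted
  pores (reseal-fast / reseal-slow / dilate schedules), so every
  analysis stage is testable against known ground truth.
* **`pore_metrics`** — water-continuity pore detection on a periodic
  grid, equivalent-diameter statistics with Gaussian fitting, formation
  times, and fate classification under membrane tension.
* **`drivers`** — lateral tension Γ = L_Z (P_Z − P_Lat), the
  distance/composition scan pipelines, and the `memvolt` CLI.

See `docs/methods.md` for the model, its assumptions and all defaults.

## Worked example

```python
import numpy as np
import memvolt as mv

# 20:45:20:15 Chol:DOPC:POPE:POPS membranes, 4 nm apart
comp = mv.standard_composition(0.15)
stack = mv.build_stack_params(comp, D=4.0)
print(mv.transmembrane_voltages(stack)[0])   # 1.8559105812785397  (V)

# how close must the membranes get for a 1 V poration threshold?
print(mv.critical_distance(stack, 1.0))      # 5.5638469073631605  (nm)

# numeric route on a generated 23 x 23 nm particle box
conf = mv.build_configuration(stack, box_xy=23.0, seed=1)
prof = mv.bin_charge_density(conf, 0.1)
bounds = mv.locate_membranes(conf)
pot = mv.integrate_potential(prof, eps_r=3.0, reference_z=bounds.midplane)
print(mv.measure_voltage(pot, bounds))       # (1.8206..., 1.9214...)  (V)
```

The closed form says a 15% POPS contact at 4 nm separation carries
about 1.86 V across each bilayer — inside the electroporation range —
and that a 1 V threshold is crossed once the membranes are closer than
about 5.6 nm.  The numeric pipeline on a finite particle realization
reproduces the analytic voltage to within its placement counting noise
(std ≈ 0.08 V at this box size; the deviations above are 0.04 and
0.07 V).

Pore analysis on a synthetic trajectory:

```python
traj = mv.build_trajectory(stack, box_xy=8.0, schedule=mv.named_schedule("DILATE"), seed=2)
b = mv.locate_membranes(traj.frames[0])
print(mv.pore_formation_time(traj, b))       # 2.0  (ns)
rec = mv.detect_pores(traj.frames[10], b)
print(rec.diameters(membrane=1))             # [1.7625846]  (nm)
```

Command line (same functionality, YAML-configurable):

```sh
memvolt generate --seed 1 --out-dir out/
memvolt voltage  --seed 1 --out-dir out/
memvolt scan-distance --dv-critical 1.0 --out-dir out/
memvolt tension --lz 20 --pz 10.3 --plat 0    # gamma = 20.6 pN/nm
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the whole pipeline from scratch under the given seed — the
distance protocol (6 → 2 nm in 0.5 nm steps), the critical-distance
inversion and POPS-ladder composition scan, the particle-box numeric
voltage against the closed form, pore detection/sizing/fate on the
three tension-regime trajectories, and the tension identity — writing
the results JSON to `--out` and a human-readable pipeline summary next
to it.
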