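# memgrad

Toolkit for studying **lateral sorting of transmembrane peptides by
hydrophobic mismatch** in membranes that carry a thickness gradient.

Cellular membranes differ in thickness between organelles, and a
transmembrane helix whose hydrophobic stretch does not match the local
bilayer thickness pays an energetic penalty — it can relieve the
mismatch by tilting, by deforming the membrane, or by diffusing
laterally toward a better-matching region. A membrane built as a
thickness *gradient* turns this into a measurable sorting experiment:
the mismatch force becomes position-dependent, and peptide position,
tilt and kinetics report directly on the underlying energetics.

`memgrad` provides the full desk-scale analysis stack for such
experiments, testable end to end without a molecular-dynamics engine:

- **blueprint** — construct gradient-membrane blueprints: ordered
  single-lipid patches along x, flat-bottom positional restraints
  (zero force inside an interval, harmonic walls outside), overlap
  optimization against a target linear gradient, expected thickness
  profiles, and a GROMACS-style restraint text dialect.
- **surrogate** — synthetic-data engine: replica ensembles of the
  peptide centre of mass under overdamped mean-reverting
  (Ornstein–Uhlenbeck) dynamics, dx = −(x − x_eq)/τ dt + √(2D) dW,
  optionally with a harmonic umbrella bias; and bead-level membrane
  frames (phosphate markers at ±d(x)/2 plus noise) with an embedded
  rigid helical rod of prescribed tilt/azimuth statistics.
- **thickness** — local thickness as the interleaflet phosphate
  distance: 1D profiles d(x), linear-region fits, 2D peptide-centred
  maps, and thickness-perturbation extraction at the peptide.
- **orientation** — tilt θ (principal axis vs membrane normal, folded
  to [0°, 90°]), azimuth φ, projected length l_proj = l_TM cos θ,
  signed mismatch l_mis = l_proj − d, lateral density profiles,
  equilibrium statistics, and a one-sample Kolmogorov–Smirnov test of
  azimuth uniformity.
- **kinetics** — exponential relaxation fits
  x(t) = x0 − A(1 − e^(−t/τ)) to ensemble-mean sorting paths, and
  diffusion coefficients from origin-averaged mean-squared
  displacements.
- **free_energy** — Boltzmann inversion of densities, 1D potentials of
  mean force from umbrella windows via WHAM, per-window tilt free
  energies ΔF(θ) = −k_BT ln(P(θ)/P(θ0)), additive 2D surfaces
  ΔF(d, θ) ≈ ΔF(d) + ΔF(θ), and extraction of thermally accessible
  (d, θ) regions at 1/2/5/10 k_BT.

Units: lengths in nm, times in ns, energies in kJ/mol; free energies
are reported in multiples of k_BT (default temperature 300 K).

## Worked example

```python
import memgrad as mg

# 1. Blueprint: four lipids spanning 3.34-4.95 nm in a 40 nm box,
#    overlap width chosen to make the central region most linear.
lipids = [mg.LipidSpec("DYPC", 3.34), mg.LipidSpec("DOPC", 3.88),
          mg.LipidSpec("DGPC", 4.41), mg.LipidSpec("DNPC", 4.95)]
target = mg.ThicknessTarget(slope=0.077, linear_region=(8.0, 32.0))
layout = mg.optimize_overlap(lipids, 40.0, target,
                             candidate_overlaps=[2.0, 4.0, 6.0, 8.0])
profile = mg.predict_thickness_profile(layout, bin_width=0.5)
fit = mg.fit_linear_region(profile, region=(8.0, 32.0))

# 2. Sorting kinetics: 100 replicas relaxing from an 8 nm offset.
params = mg.SortingModelParams(x_eq=20.0, tau=2800.0, diffusion=0.02,
                               x0=28.0, n_steps=1000, dt=28.0,
                               n_replicas=100, seed=1)
ens = mg.simulate_sorting_ensemble(params)
rfit = mg.fit_relaxation(ens.times, ens.mean_path())

# 3. Mismatch geometry of a 29-leucine peptide tilted by 23 degrees
#    in a 5.1 nm-thick membrane region.
l_tm = mg.hydrophobic_length(29)
l_proj, l_mis = mg.projected_length_and_mismatch(l_tm, theta_deg=23.0,
                                                 local_d=5.1)
```

This prints (via the obvious format strings):

```
overlap chosen: 8.0 nm
idealized gradient: slope 0.042 nm/nm, R2 = 0.974
fitted tau: 2.18 us, R2 = 0.90
Leu29: l_TM = 4.35 nm, l_proj = 4.0 nm, l_mis = -1.1 nm
```

The overlap optimizer prefers the widest candidate because wider lipid
mixing zones smooth the staircase of pure-patch thicknesses into a
straighter ramp. The relaxation fit recovers the sorting time constant
from a noisy ensemble mean: with 100 replicas and a stationary
positional variance of D·τ = 56 nm², the fitted τ scatters by tens of
percent around the 2.8 μs ground truth (see `docs/methods.md` for the
noise budget). The 29-leucine peptide (hydrophobic length
29 × 0.15 = 4.35 nm) tilted at 23° projects to 4.0 nm along the
membrane normal, leaving a mismatch of −1.1 nm with its preferred
5.1 nm environment — the peptide sits in membrane slightly thicker
than itself, consistent with the rest of the polyleucine series
(bundled as `memgrad.reference.POLYLEUCINE_SERIES`).

A command-line interface mirrors these workflows:

```sh
memgrad build-membrane --config membrane.yaml \
    --out-layout layout.json --out-restraints posres.itp
memgrad simulate-sorting --tau 2800 --diffusion 0.02 --x-eq 20 --x0 28 \
    --steps 1000 --replicas 100 --seed 1 --out ens.npz
memgrad fit-relaxation --in ens.npz
memgrad make-fixture --profile profile.csv --ltm 4.35 --out traj.csv
memgrad thickness-profile --traj traj.csv --bin 0.5 --region 8 32 --out d.csv
memgrad pmf --windows windows/ --grid 0.1 --out pmf.csv
```

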