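# Methods

This note documents the models, estimators and numerical choices
behind `memgrad`, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Gradient-membrane blueprint

A thickness gradient is encoded as an ordered tiling of the box along
the gradient axis x with patches of single-lipid membranes, each
characterised by the thickness of its pure bilayer. Adjacent patches
share a mixing (overlap) region of configurable width. The expected
thickness model is piecewise linear: each pure interval sits exactly at
its lipid's reference thickness and the profile interpolates linearly
in x across each overlap. This matches the smooth, monotone profiles
such constructions produce in practice, at the price of ignoring the
real mixing thermodynamics inside the overlap (ideal-mixing linearity
is an idealization).

Restraints are layered flat-bottom walls along x: zero potential for
|x − x_c| ≤ r and ½k(|x − x_c| − r)² outside, with k defaulting to
1000 kJ·mol⁻¹·nm⁻², a value stiff enough to confine a lipid to its
patch on the nm scale while keeping forces moderate. The zero-force
half-width of each lipid's restraint covers its pure interval plus both
overlaps. The serialization dialect (`memgrad-flat-bottom-x/1`) is a
GROMACS-style include-topology text block, stable byte-for-byte across
runs.

Overlap optimization is a grid search over a user-supplied candidate
list of uniform overlap widths; the objective is the maximum absolute
deviation of the expected profile from its own best-fit line over the
stated linear region, with ties broken toward smaller overlap. The
criterion and the search space are deliberately explicit and small:
the design space (one scalar) does not warrant a continuous optimizer.
Note that the idealized piecewise-linear model spreads the full
anchor-to-anchor thickness span over most of the box, so its best-fit
slope over a central window (≈0.042 nm/nm for anchors 3.34–4.95 nm in
a 40 nm box) is shallower than slopes realized by actual
coarse-grained bilayers, where boundary effects steepen the profile.
The slope of a *measured* profile is therefore always taken from
`thickness.fit_linear_region`, never from the blueprint.

Conventions: x is the gradient axis, z the membrane normal, intervals
half-open [lo, hi), lengths nm, energies kJ/mol, k_BT at 300 K by
default.

## Surrogate sorting dynamics

Peptide sorting is modelled as an overdamped mean-reverting
(Ornstein–Uhlenbeck) process for the centre of mass along the
gradient,

    dx = −(x − x_eq)/τ dt + √(2D) dW,

which is the stochastic idealization of a lateral force proportional
to hydrophobic mismatch in a viscous medium. τ is the sorting
relaxation time (default ground truth 2800 ns, the fitted value of the
reference relaxation experiment) and D the lateral diffusion
coefficient, exposed as a free parameter because published estimates
span 0.015–0.027 nm²/ns without per-peptide attribution.

Integration is Euler–Maruyama with fixed dt (default τ/100); the
error is O(dt/τ) and the accuracy contract is explicit: dt ≥ τ raises,
dt ≥ τ/10 warns. The implied harmonic well has stiffness
κ = k_BT/(Dτ); an umbrella bias ½k_b(x − x_c)² adds the drift
−(k_b D/k_BT)(x − x_c), i.e. the mobility is fixed by
fluctuation–dissipation as D/k_BT so biased runs have a well-defined
temperature (300 K default). Stationary mean and variance (x_eq, Dτ)
and the biased-run minimum of the combined quadratic are used as
closed-form oracles in the tests.

### Noise budget of the relaxation experiment

With the reference parameters (τ = 2800 ns, D = 0.02 nm²/ns) the
stationary positional variance is Dτ = 56 nm². An ensemble mean over
N = 100 replicas therefore carries noise of sd ≈ 0.75 nm whose
correlation time equals τ itself; over a 10τ observation window this
leaves only a handful of independent noise degrees of freedom against
a signal amplitude of 8 nm. Consequently the fitted τ scatters by
roughly ±35% from realization to realization and the coefficient of
determination of the mean-path fit plateaus near
R² ≈ Var(signal)/(Var(signal) + Dτ/N·0.9) ≈ 0.85–0.95. Tighter
recovery requires either more replicas (R² > 0.99 needs N ≳ 1600) or a
smaller D; the parameter-recovery test in the suite uses
D = 0.002 nm²/ns for that reason, while the acceptance experiment
deliberately keeps the reference conditions and reports what they
yield.

## Bead-level fixture generator

`synthesize_membrane_trajectory` renders phosphate-marker beads of two
leaflets at z = ±d(x)/2 with isotropic Gaussian positional noise in z
and lateral (x, y) positions redrawn uniformly every frame. Redrawing
emulates fast lateral lipid mixing and guarantees homogeneous bin
coverage; it does *not* emulate lipid packing, area-per-lipid
constraints, undulations, or lateral correlations of real bilayers.
Passing tests on these fixtures therefore validate the estimators
(binning, leaflet averaging, undefined-bin propagation, geometry
recovery), not the physics of any particular force field.

The peptide is a rigid rod: backbone beads spaced 0.3 nm spanning the
hydrophobic length l_TM, plus one terminal anchor bead 0.3 nm beyond
each end, centred at the bilayer midplane. Tilt and azimuth are drawn
independently per frame from user-supplied samplers (constant, uniform
azimuth, or Boltzmann tilt sampling p(θ) ∝ sin θ·e^(−F(θ)/k_BT) via
inverse-CDF on a 2001-point grid); there is no orientational
autocorrelation because all analyses here consume marginal
distributions only. A Gaussian thickness perturbation of configurable
depth and width can be welded onto the profile around the peptide to
validate perturbation-map extraction; depth −0.5 nm and +0.1 nm mirror
the magnitudes of peptide-induced thinning/thickening such analyses
are meant to resolve.

## Thickness estimation

Thickness is the interleaflet phosphate distance: per x-bin (1D) or
per peptide-centred (x, y) cell (2D), d = mean(z_upper) −
mean(z_lower), pooled over frames. Leaflet-mean differencing is robust
at coarse-grained bead densities and avoids nearest-neighbour pairing
artefacts. Defaults: bin width 0.5 nm, 2D cell 0.5 nm, min_count 10
per leaflet — enough to resolve a ~0.08 nm/nm gradient with sub-0.05 nm
error at typical bead densities. Bins failing min_count are NaN and
stay NaN; nothing is imputed. y is wrapped to the minimum image before
binning; x is not wrapped inside the linear region. The perturbation
field subtracts the reference profile evaluated at the absolute x of
each cell with the same per-frame count weights as the thickness
estimate; the value "at the peptide" averages the central 3×3 cells
(the neighbourhood size is configurable since averaging trades bias
against variance — a 3×3 block underestimates a σ = 1 nm Gaussian
dimple by ~15%, a σ = 2 nm one by ~5%).

## Orientation observables

The peptide axis is the principal (largest-variance) direction of the
backbone beads, sign-folded so its component along the membrane normal
is non-negative; tilt is then automatically in [0°, 90°] and invariant
under head–tail reflection. Azimuth is measured from the gradient axis
and is undefined (NaN, flagged) for an untilted rod. The principal
axis is preferred over the termini vector for robustness to bead
noise.

Mismatch sign convention: l_mis = l_proj − d, negative when the
peptide is shorter than its local membrane. The opposite convention
(d − l_proj) is selectable by flag; the default is chosen so that the
sign agrees with the tabulated reference series bundled in
`memgrad.reference`, whose printed mismatches are negative. Local
thickness at the peptide uses the central-neighbourhood estimate
(beads within 0.75 nm of the COM in x and y), not the global profile.

Tilt histograms are raw marginal densities without the sin θ Jacobian
division, matching how such distributions are usually presented; the
Jacobian-corrected option is available where the isotropic entropic
factor should be removed. Equilibrium statistics default to the last
half of the frames, the conventional equilibrated-window choice.

The azimuth uniformity check is a one-sample Kolmogorov–Smirnov test
of φ/360 against U[0, 1); its type-I error calibration (rejection rate
≈ α over ≥1000 null replicates) is part of the acceptance suite.

## Kinetics

The relaxation fit x(t) = x0 − A(1 − e^(−t/τ)) uses Levenberg–
Marquardt-style least squares with an analytic Jacobian, tolerances
1e-12, initialised at x0 = first point, A = first − last, τ = time to
cover half the displacement. A > 0 means relaxation toward smaller x
and the plateau is x(∞) = x0 − A; the fit is symmetric for both
approach directions. R² is computed on the ensemble-mean curve.
Non-convergence raises a flagged error carrying the initial guess —
never silent defaults. Time-rescaling equivariance (τ scales exactly
with the time axis) is asserted in the tests.

MSD-based diffusion uses overlapping time origins with the maximum lag
capped at 10% of the trajectory to bound origin-correlation bias;
D = slope/(2·dimensionality) by OLS over a configurable lag window
(short lags are preferred since MSD noise grows with lag). Wrapped
coordinates (jumps > box/2) are rejected with advice to unwrap.

## Free energies

All profiles and surfaces are in k_BT units with their minimum (or the
modal tilt bin) pinned to exactly zero; zero-count bins are NaN.

The 1D PMF estimator is standard binned WHAM: self-consistent
iteration of p_j ∝ Σᵢnᵢⱼ / ΣᵢNᵢfᵢcᵢⱼ and fᵢ⁻¹ = Σⱼcᵢⱼp_j to a
tolerance of 1e-8 on the per-window free-energy constants (max 10⁵
iterations, non-convergence flagged with diagnostics). A single
unbiased window reduces exactly to Boltzmann inversion. Windows whose
histograms share no occupied bins are rejected with the disconnected
groups listed; adjacent-window overlap below 5% warns. The
implementation is validated two ways: against a plain-loop fixed-point
oracle on a two-window/three-bin toy at machine precision, and against
the analytic quadratic well of biased surrogate ensembles (max
deviation < 0.2 k_BT over the well-sampled range).

The position-to-thickness mapping is the linear fit of the measured
profile over the linear region; window positions enter d-space through
it. The 2D surface is the additive composition ΔF(d, θ) = ΔF(d) +
ΔF(θ | nearest window), re-referenced to zero and masked above 10 k_BT
(the minimum itself is never masked). Additivity neglects d–θ
correlation within a window and is labelled an approximation.

Accessible regions per threshold are the 4-connected components of the
sublevel set {ΔF ≤ n·k_BT}, each projected onto the d and θ axes at
bin-edge resolution with overlapping projections merged; disjoint
minima therefore yield multiple intervals, and regions nest across
thresholds by construction. The quadratic closed form (1 k_BT interval
width 2√(2k_BT/κ)) anchors the tests.

## Problem sizes

Test and acceptance computations are sized for a single CPU: bead
fixtures of 200–800 lipids per leaflet over 5–60 frames, OU ensembles
of 10–200 replicas and 10³–3×10⁴ steps, umbrella sets of 3–5 windows
with ~4×10⁵ samples each, and 10³ null replicates for the KS
calibration. These sizes keep Monte-Carlo error comfortably inside
each stated tolerance except where the noise budget above says
otherwise.

## Known limitations

- The blueprint's expected profile is an idealization; it does not
  model mixing thermodynamics, boundary effects at the periodic seam,
  or the small repulsive bias mixing zones can exert on solutes.
- The surrogate has no position-dependent D, no orientational
  dynamics, and a strictly harmonic mismatch force; real mismatch
  forces saturate far from equilibrium.
- The fixture generator's ideal-gas lipid placement cannot test
  estimator behaviour under correlated lateral structure.
- 2D WHAM over (x, θ) jointly is out of scope; the additive surface is
  the supported route, with its stated approximation.
- Uncertainty quantification is limited to fit covariances; no
  bootstrap machinery is included.
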