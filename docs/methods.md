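# Methods

## Model summary

The simulator couples a two-dimensional Cellular Potts model (CPM) of
endothelial cells to three scalar fields: a static VEGF gradient, a
diffusible MMP concentration, and a non-diffusing ECM density. One
Monte Carlo step (MCS) is N = X·Y copy attempts; each attempt picks a
uniform random target site and a uniform random source among its 20
first- to fourth-order neighbors (the wide source neighborhood improves
lattice isotropy), computes the total energy change, and accepts with
the Boltzmann rule P = exp(−ΔH/M) for ΔH ≥ 0, P = 1 otherwise. Between
MCSs the fields advance by 15 forward-Euler substeps with the σ grid
held fixed (first-order operator splitting).

Geometry: the dish is X×Y sites with a one-site frozen frame; a frozen
wall band of thickness 2 sits at rows Y_gap..Y_gap+1 with a centered
opening of X_gap sites; 125 cells of exactly 50 sites tile the vessel
region below the wall, packed against its underside; the tumor is a
planar VEGF source beyond the top edge. The initial ECM is 0.9 outside
the vessel, 0.5 inside, with a half-disc of radius X_gap in front of
the opening ramping linearly from 0.5 to 0.9.

## Parameters

All defaults follow the unitless reference set; the field rates are
interpreted physically (see Numerics):

| symbol | default | meaning |
|---|---|---|
| J_CC, J_CM, J_border | 40, 25, 25 | adhesion energy per bond: cell–cell, cell–medium, cell–frozen |
| λ_A, λ_L | 25, 25 | area / length constraint strengths |
| A_T, L_T | 50, 15 sites | nominal target area and rod-equivalent length |
| M | 100 | intrinsic membrane motility (Boltzmann scale) |
| χ | 5000 | chemotaxis strength |
| Γ, s | 300, 7.0 | haptotaxis strength and saturation |
| η, μ, ρ | 200, 0.5, 0.2 | haptokinesis strength, optimal ECM density, Gaussian width |
| ε_EM | 3×10⁻³ /(conc·s) | MMP-dependent ECM degradation constant |
| α_MV, ε_M | 8×10⁻⁵, 1×10⁻³ /s | MMP secretion and decay rates |
| D_M, D_V | 1×10⁻¹⁴, 6×10⁻¹¹ m²/s | MMP and VEGF diffusion coefficients |
| ε_V | 1×10⁻³ /s | VEGF decay rate |
| c_E,init, c_V(0) | 0.9, 0.87 | initial ECM outside the vessel; VEGF at the tumor edge |
| c_M,max | 1 | MMP secretion cap (Heaviside gate) |
| ρ_min | 0.73 | ECM-contact threshold for division |
| X, Y, Y_gap, X_gap | 250, 350, 30, 25 | dish width/height, wall offset, gap width |
| MCS_tot | 40 000 | run length |

Presets `A`–`F` switch the model components on incrementally
(chemotaxis, haptokinesis, matrix, proteolysis, proliferation,
haptotaxis); `F` is aliased `fig3F`.

## Numerics and unit scheme

The lattice spacing is Δx = 2 µm per site (a 500 µm dish across 250
sites) and each Euler substep is Δt = 1 s, so diffusion coefficients in
m²/s convert to site²/substep by dividing by Δx². This gives the VEGF
decay length λ = √(D_V/ε_V) ≈ 122.5 sites (a dish-scale gradient) and
D_M ≈ 2.5×10⁻³ site²/substep, comfortably inside the explicit-scheme
stability bound D·Δt/Δx² ≤ 1/4, which `SimConfig.validate` enforces
together with ε_M Δt < 1 and ε_EM c_M,max Δt < 1 (these also guarantee
ECM nonnegativity and monotone decay). A literal lattice-unit reading
of the two diffusion coefficients remains selectable
(`units="lattice"`); under it MMP diffusion is effectively zero and
matrix degradation becomes strictly contact-mediated (MMP footprints
left where membranes flickered). VEGF is never solved numerically in
production: the 1D closed form c_V(0)·e^(−d/λ) is exact for the
steady state on a semi-infinite strip, and a relaxation solver in the
test suite confirms it to 10⁻³ relative.

The MMP boundary condition is zero-value (Dirichlet) on the lattice
edge; ECM has no transport term and needs none. Secretion uses H(0)=0:
a site exactly at c_M,max receives nothing that substep, which prevents
cap overshoot beyond one substep's secretion. MMPs are secreted only on
cell-covered sites (σ ≥ 1, not merely σ ≠ 0, so frozen wall sites never
secrete) and decay only on medium sites, as the field equations' δ
gates prescribe; ECM under a cell is frozen at the value it had when
covered, and motility terms referencing a cell-covered site read that
retained value.

## Implementation choices

* **Adhesion adjacency.** Bonds in H (and the perimeter pairs of the
  division rule) run over the 8-neighborhood (order ≤ 2, diagonals
  included), matching the membrane-bond picture of the model; only copy
  *sources* use the 20-site neighborhood. Using 20-site adhesion is
  available via `adhesion_order=4` but multiplies interface costs
  ~2.5-fold and freezes the tissue at the reference energies.
* **Connectivity.** A copy that would remove a site from a cell is
  allowed only when the cell's membership around the target's cyclic
  8-neighbor ring forms a single arc (exactly two transitions): this
  forbids local splits and hole punching in O(1). Because sources can
  be two sites away, the mirrored hazard exists on the gaining side; a
  gained site must touch its new cell in the 8-neighborhood, otherwise
  cells shed disconnected satellites and disintegrate (observed before
  the check existed). Cells may not lose their last site.
* **Frozen sites.** The lattice frame and the wall are a frozen
  sentinel; copies into or out of them are rejected outright, which
  realizes the "high border energy" deterministically. Their remaining
  adhesion bonds carry J_border (default J_CM: adhesively neutral
  against medium).
* **Length estimator.** L = √(12 λ_max/A) with λ_max the larger
  inertia-tensor eigenvalue, maintained incrementally from centroid and
  second-moment sums; a single-site cell has L = 1 by convention. The
  estimator is exact for rods in the continuum limit.
* **Division axis.** The plane direction is the inertia-tensor
  eigenvector d = (I₁₂, λ_b − I₁₁) of the larger eigenvalue λ_b; that
  algebraic form vanishes identically when the long axis lies along x₂,
  in which case the complementary form (λ_b − I₂₂, I₁₂) is used; an
  isotropic tensor draws a uniformly random direction. Sites strictly
  on the positive side of the plane through the centroid become the
  daughter; on-plane sites stay with the parent; orphan fragments are
  reassigned to the opposite daughter, and a split that cannot be made
  connected is aborted.
* **Proliferation eligibility.** Only cells outside the parent vessel
  and clear of a quiescent band of one nominal cell length (15 sites)
  above the wall may divide. The cell's topmost site is the reference
  point by default (`eligibility_reference="tip"`); the stricter
  centroid reading is available, but under it ignition essentially
  never occurs because migration-driven buds saturate below the
  threshold. Eligibility and contact ratios are evaluated on a snapshot
  at the start of each sweep (every 5 MCS); divisions apply in
  ascending index order; target regrowth (+2 area, +0.6 length per
  sweep) is capped at the nominal A_T, L_T — unbounded targets would
  contradict the fixed nominal cell size — so a fresh daughter regrows
  in 13 sweeps (65 MCS).
* **Initial tiling.** Full bands of 10×5-site rectangles packed
  downward from the wall, with any remainder laid as 25×2-site
  rectangles below them: every cell is exactly 50 sites for any dish
  width that fits, and the monolayer touches the wall so cells reach
  the opening while the matrix in front of it is still intermediate.
* **Determinism.** One `numpy.random.Generator` per replicate drives
  every stochastic choice (site/neighbor/acceptance draws, division
  draws, random axes). The compiled kernel and the pure-Python
  reference path consume the identical stream and produce bit-identical
  trajectories — the reference path is the oracle for the kernel.
  Sweep cells derive their seeds as
  `SeedSequence([base_seed, value_index, replicate])`, so any cell is
  reproducible in isolation.

## Reduced-scale protocol

Qualitative regime checks run on a 100×140-site dish with 45 cells
(the same cell size, wall offset and gap; dish width scaled 2/5 so that
full bands tile the vessel exactly) for 5000 MCS with 5 replicates per
arm. This emulates the full 250×350 / 40 000-MCS study conditions at
roughly 1/40 of the cost; because the tumor edge is nearer, VEGF levels
and gradients near the wall are several-fold higher than at full scale,
so the reduced runs compress the early sprouting phase rather than
subsample the full trajectory. Full-scale runs are supported unchanged.

## What the tests do and do not show

The unit and property tests verify every energy term, field update and
bookkeeping rule against independent oracles (full-Hamiltonian
recomputation, relaxation solvers, from-scratch recounts, brute-force
hull scans, closed-form acceptance statistics), and the regime tests
verify: constant cell count when division is disabled (ρ_min = 1), no
sprout outgrowth on sparse matrix (c_E,init = 0.3), and larger sprouts
under faster proteolysis (ε_EM 5×10⁻³ vs 1×10⁻³).

Known limitation: at the reference energies the simulated sprouts are
surface-tension-dominated buds one to two cell lengths tall, both at
reduced and full scale; the strongly branched, dish-spanning trees that
this model class is known for arise only when proliferation feeds thin,
high-ECM-contact tips, a regime this parameterization does not reach.
Consequently the compactness *orderings* across haptokinesis and
haptotaxis arms (η = 0 vs 200, Γ = 1500 vs 0) are not reproduced — in
the bud regime those couplings spread the emerging cluster rather than
branch an elongated sprout, inverting the expected ranking — and the
corresponding regime assertions fail. The synthetic initial condition
is idealized in the usual ways: a homogeneous single-component matrix
with no fiber orientation or mechanics, one cell type without
tip/stalk identity, and a planar steady-state VEGF source; passing
tests therefore validate the model's stated rules and their numerics,
not quantitative agreement with any particular in vitro system.
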