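# angiosprout

A hybrid Cellular Potts / reaction–diffusion simulator of
extracellular-matrix-guided endothelial sprouting — the early phase of
angiogenesis in which endothelial cells leave a parent vessel through a
gap in its wall and invade the surrounding matrix toward a VEGF-secreting
tumor.

It is written for computational biologists who want a small, fully
tested, scriptable implementation of this model class: every energy
term, field update and division rule is an ordinary Python function with
an oracle test, and the hot loops are compiled with numba so that
reduced-scale experiments run in seconds on one core.

## The model

Cells are connected patches of lattice sites sharing an index σ on an
X×Y grid (σ = 0 is the medium, which carries the ECM density field).
Membrane dynamics are Metropolis-style index copies driven by the
effective energy

    H = Σ_bonds J(τ,τ′)(1 − δ(σ,σ′)) + Σ_cells [ λ_A (A − A_T)² + λ_L (L − L_T)² ]

with adhesion energies J_CC = 40 (cell–cell) and J_CM = 25 (cell–matrix),
so the surface tension γ_CM = J_CM − J_CC/2 = 5 > 0 keeps cells mutually
adherent; A and L are a cell's area and rod-equivalent length
(L = √(12 λ_max/A) from the inertia tensor) with targets A_T = 50 and
L_T = 15 sites. A proposed copy of a neighbor's index onto a site is
accepted with Boltzmann probability

    P(ΔH) = exp(−ΔH/M)  if ΔH ≥ 0,   1  if ΔH < 0,      M = 100,

where ΔH adds three guidance terms to the core energy difference, all
acting only on extensions into the medium:

* chemotaxis  −χ (c_V(x) − c_V(x′)) up a static VEGF gradient
  c_V = c_V(0) e^(−d/λ), λ = √(D_V/ε_V), from the tumor edge at the top;
* haptotaxis  −Γ (f(c_E(x)) − f(c_E(x′))), f(c) = c/(1+sc), up the ECM
  gradient with saturation;
* haptokinesis  −η (−1 + N(c_E; μ=0.5, ρ=0.2)/N_max-normalised reverse
  Gaussian), making membranes most active at intermediate ECM density.

Cells secrete diffusible matrix metalloproteinases (MMPs) in proportion
to local VEGF (capped at c_M,max = 1), and MMPs degrade the ECM on
exposed medium sites; both fields advance by forward Euler with a
five-point Laplacian, 15 substeps per Monte Carlo step, operator-split
against the lattice dynamics. Cells whose ECM-contact fraction ρ_i
exceeds ρ_min = 0.73 divide perpendicular to their long axis once they
sit a cell length above the vessel wall, daughters inheriting half the
parent's targets and regrowing them by 2 sites (area) and 0.6 sites
(length) every 5 MCS.

Sprout morphology is quantified on the largest connected cell cluster:
**compactness** (cluster area over rasterized convex-hull area, 1 =
unbranched), **height** (highest site above the dish bottom) and
**size** (number of cells in the cluster).

## Worked example

A reduced-scale dish (100×140 sites, 45 cells, all other parameters at
the reference values) for 2000 MCS:

```bash
angiosprout run --scaled --seed 7 --mcs 2000 --out results/demo
```

prints per-1000-MCS progress

```
mcs=1000 compactness=0.754 height=41.0 size=45 n_cells=45
mcs=2000 compactness=0.701 height=47.0 size=45 n_cells=45
```

and writes `metrics.csv`, whose first rows are

```
mcs,compactness,height,size,n_cells,replicate,seed,param,value
0,,29.0,45,45,0,7,,
100,0.3902439024390244,34.0,45,45,0,7,,
200,0.4,36.0,45,45,0,7,,
```

Read: the monolayer starts at height 29 (just under the wall at rows
30–31); by 2000 MCS cells have crossed the gap and the nascent sprout
tip stands 16 sites above the wall; compactness of the emerged cluster
rises from 0.39 (a few scattered protrusions) toward 0.70 (a coherent
bud); the cell count is still 45 because no cell has yet both escaped
contact inhibition and cleared the quiescent zone. Initial compactness
is empty because no cell site lies above the wall. The run also writes
PNG snapshots of the labeled cell raster and an `.npz` dump of the final
σ grid and all three fields.

The same protocol is scriptable:

```python
import angiosprout as ap

res = ap.run_simulation(ap.scaled_config(), seed=7)
print(res.metrics.tail(1))

sweep = ap.run_sweep(ap.SweepSpec(parameter="eta", values=[0, 200],
                                  replicates=5), ap.scaled_config())
print(ap.aggregate_replicates(sweep).tail())
```

Full-scale runs (250×350 sites, 125 cells, 40 000 MCS) use
`ap.SimConfig()` unchanged; the six incremental model-component presets
(`A` … `F`, alias `fig3F`) are available via `--preset` or
`ap.preset_config`.

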