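# landscaper

Reconstruction and mining of 2D-projected protein energy landscapes from
discrete, energy-evaluated conformational samples.

## The problem

Sample-based explorations of a protein's conformational space (stochastic
optimization over principal-component coordinates, with each sampled
conformation scored by a molecular-mechanics force field) yield tens of
thousands of scattered points `(PC1, PC2, E)` over an invisible, rugged
energy surface. The scientific objects of interest are not the raw samples
but the **local structures** of the underlying landscape: the basins
(connected low-energy regions corresponding to thermodynamically stable and
semi-stable states), the saddle points that join adjacent basins and set the
barriers for state-to-state interconversion, and the hierarchical
organization of basins within basins. Comparing these structures between a
protein's healthy and mutated variants — and correlating quantitative
landscape descriptors with measured biochemical activities — links mutations
to mechanism.

`landscaper` implements this analysis for 2D-projected samples:

1. **Smoothing** — the domain boundary is the alpha-convex shape of the
   sample cloud; a regular grid at spacing δ₁ is laid over it, and a smooth
   surface is estimated everywhere by Nadaraya–Watson kernel regression

   ê(x) = Σᵢ K(‖x − xᵢ‖/h) eᵢ / Σᵢ K(‖x − xᵢ‖/h),

   with Gaussian, Epanechnikov, Tricube and bounded-support Gaussian kernels
   (the bounded kernel admits only samples within radius h, located through
   a kd-tree proximity index). For the Gaussian family the estimator's
   gradient and Hessian are evaluated in closed form.

2. **Basin-driven reconstruction (BDR)** — recursive descent of the energy
   level c by steps δ₂, watching the connected components of the sublevel
   set L(c) = {x : ê(x) ≤ c}. A component that splits becomes two basins;
   a working-definition saddle is placed at the midpoint of the shortest
   segment between the boundary polygons of neighboring basins (vertex
   distance ≤ d_th). A jump test (m·δ₂ at a time, reverting when a split
   was skipped) and small-basin pruning (< n₀ grid points) keep the cost
   concentrated in the low-energy detail region (c ≤ c_min + c₀).

3. **Saddle-driven reconstruction (SDR)** — Newton descent from every grid
   point harvests all local minima (duplicates merged by leader clustering
   at radius ε); from each minimum, the four reduced-gradient curves (the
   zero set of one gradient component, tangent orthogonal to the matching
   Hessian column, in both orientations) are followed by predictor–corrector
   or combined steps of length p until they exit the grid, collecting every
   point that passes the saddle test (‖∇ê‖ < ε_g, Hessian eigenvalues of
   opposite signs). Each saddle's two attached basin boundaries are then
   traced as closed contours at the saddle energy, seeded by a jitter along
   the Hessian's softest eigenvector.

4. **Descriptor mining** — a reconstructed landscape is summarized by 10
   descriptors: the PC-space distance d(State, Saddle) and barrier
   dE(State, Saddle) = E(Saddle) − E(State) for each of 5 tracked reference
   states against the On↔Off saddle. Descriptor vectors across variants are
   screened against per-variant biochemical parameter tables by Pearson
   correlation (|r| ≥ 0.5, sign retained).

A synthetic module provides analytic Gaussian-mixture landscapes with
exactly known minima, saddles and barriers — the oracle for every
correctness study — plus samplers emulating the statistical structure of
real sampling runs (non-uniform Boltzmann-like density, energy noise).

## Worked example

```python
import numpy as np
from landscaper import (EnergyLandscape, ReferenceState, RunConfig,
                        SamplingModel, draw_samples, extract_descriptors, fixture)

land = fixture("two_well_symmetric")            # analytic ground truth
samples = draw_samples(land, SamplingModel(n=5000, seed=7), "demo")

fit = EnergyLandscape(samples, RunConfig()).fit()
print(fit.summary())
bdr = fit.reconstruct("bdr")
print(bdr.summary())
```

prints

```
Energy landscape fit
================================================
variant:            demo
samples:            5000
kernel / bandwidth: gaussian / h=0.7
alpha / delta1:     0.15 / 0.1
domain area:        332.3661
grid points (S_max): 33249
energy range:       c_min=-8.5385  c_max=2.9489

Hierarchy (bdr) for variant 'demo'
  basins: 3 (2 leaves)
  saddles: 1
  basin   0 parent=None birth_level= 2.9489 n_grid= 33249 deepest=( 7.100, 0.000) E=-8.5385
  basin   1 parent=   0 birth_level=-1.8511 n_grid=  8905 deepest=( 7.100, 0.000) E=-8.5385
  basin   2 parent=   0 birth_level=-1.8511 n_grid=  8766 deepest=(-7.100, 0.000) E=-8.4926
  saddle (-0.050, 0.100) E=-1.8038 [bdr_midpoint] joins 1<->2
```

The two leaf basins' deepest points sit at (±7.1, 0), within one grid
spacing of the analytic well centers (±7.17, 0), and the midpoint saddle
lies next to the analytic saddle at the origin. Placing reference states at
the analytic minima and extracting descriptors gives
`dE(On,Saddle) = 7.122` against an analytic barrier of `7.170` (−0.7%);
the saddle-driven method run on the same fit
(`fit.reconstruct("sdr")`) recovers 2 minima, 1 critical-point saddle at
(−0.04, 0.30) with opposite-sign Hessian eigenvalues, and two traced basin
boundaries each enclosing one minimum.

The same pipeline is available from the shell:

```sh
landscaper synth --fixture two_well_symmetric --n 5000 --seed 7 \
    --out samples.csv --truth truth.json
landscaper reconstruct-bdr --samples samples.csv --out hierarchy.json
landscaper reconstruct-sdr --samples samples.csv --out hierarchy_sdr.json \
    --minima-csv minima.csv --saddles-csv saddles.csv
landscaper descriptors --hierarchy hierarchy.json --states states.csv --out desc.csv
landscaper correlate --descriptors desc.csv --parameters params.csv --out report.csv
landscaper compare --samples samples.csv --out concordance.csv
```

Every run writes a `*.manifest.json` (config snapshot, input hashes,
timings) sufficient to re-execute it exactly.

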