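# modulrate

Craniofacial **modularity, integration, evolutionary rates and evolvability**
from 2-D landmark data on a time-calibrated phylogeny.

Vertebrate skulls are classically partitioned into two partially decoupled
regions — the **face** and the **braincase**. Whether these regions evolve as
independent modules or as one integrated unit shapes how each can respond to
selection: strong integration spreads the effect of selection across the
whole skull, while modularity lets the face and braincase diversify at
different rates. `modulrate` implements the complete comparative toolkit for
asking these questions from lateral-view landmark configurations (e.g.
cleared-and-stained fish neurocrania or carnivoran skull photographs) and an
ultrametric phylogeny:

- **Generalized Procrustes analysis (GPA)** — removes position, scale and
  orientation; species means, tangent-space coordinates, shape PCA, and
  phylomorphospace projection with maximum-likelihood ancestral states under
  Brownian motion (BM).
- **Phylogenetic modularity** — the covariance ratio
  `CR = ‖S₁₂‖F / √(‖S₁₁°‖F · ‖S₂₂°‖F)` on the evolutionary (GLS-transformed)
  covariance matrix, tested by permuting whole landmarks across modules;
  a CR small relative to the permutation distribution signals modularity.
- **Phylogenetic integration** — two-block partial least squares on the
  evolutionary cross-covariance; `r-PLS ∈ [0, 1]` reads as 0 = fully
  modular, 1 = fully integrated, tested by permuting one block across the
  tips of the tree.
- **Module rates** — the net BM rate `σ²_mult = tr(UᵀU)/(n·k)` per landmark
  per My for each module, with the face:braincase rate ratio tested against
  a simulated null of equal rates that preserves the observed evolutionary
  correlation structure; per-clade rate tables with pairwise tests.
- **Random-skewers evolvability** — phylogenetically corrected P-matrices
  per module probed with random unit selection gradients via the
  multivariate breeder's equation `Δz = Pβ`, summarizing evolvability
  `e = βᵀPβ`, respondability `r = ‖Pβ‖`, conditional evolvability
  `c = (βᵀP⁻β)⁻¹`, autonomy `a = c/e`, and constraints (alignment of the
  response with the line of least resistance). All products are evaluated
  in the positive eigenspace of P, so `c ≤ e ≤ r` and `a ∈ (0, 1]` hold
  even for the rank-deficient matrices Procrustes data produce.
- **A synthetic-study generator** — species-mean configurations evolved by
  multivariate BM on a pure-birth tree with separately controllable
  per-module rates, between-module correlation and digitizing noise, so the
  whole pipeline can be calibrated against known truth without any specimen
  data.

Inputs are plain text: TPS landmark files (tpsDig2 dialect), Newick/NEXUS
trees with branch lengths in time units, and a two-column CSV mapping
landmarks to modules.

## Worked example

Simulate a strongly integrated 60-species study (between-module evolutionary
correlation ρ = 0.9), superimpose it, and run every statistic:

```python
from modulrate import (SimulationSpec, simulate_bm_shapes, gpa, cr_test,
                       phylo_pls, compare_module_rates, evolutionary_pmatrix,
                       draw_skewers, skewer_indices)

spec = SimulationSpec(n_species=60, rho=0.9, seed=11)   # integrated skulls
study = simulate_bm_shapes(spec)
aligned = gpa(study.dataset)

mod = cr_test(aligned, study.tree, study.modules, n_perm=9999, seed=1)
pls = phylo_pls(aligned, study.tree, study.modules, n_perm=9999, seed=2)
rr = compare_module_rates(aligned, study.tree, study.modules, n_sim=999, seed=3)
P = evolutionary_pmatrix(aligned, study.tree, study.modules, "face")
sk = skewer_indices(P, draw_skewers(P.dim, 1000, seed=4))
```

which prints (formatted):

```
CR = 1.777  (p = 0.881, 252 permutations, exact)
r-PLS = 0.939  (p = 0.0001)
sigma2 face = 2.98e-08, braincase = 3.18e-08, ratio = 0.94 (p = 0.099)
face: max evolvability = 2.65e-08, max autonomy = 0.924
```

Read: no modularity is detected (CR is *large* relative to its permutation
distribution, p = 0.881 — with 10 landmarks the 252 distinct assignments are
enumerated exactly), the blocks are strongly integrated (r-PLS = 0.939 at
the smallest achievable permutation p), the modules evolve at
statistically indistinguishable rates (ratio 0.94), and the face P-matrix
admits skewers with autonomy up to 0.92 despite the integration. Rates are
per landmark per unit branch length in squared Procrustes units — tiny
numbers, because unit-centroid-size shapes are dimensionless and the
simulated deviations are a fraction of a percent of configuration size.

The same analyses are exposed as a CLI (`modulrate validate / gpa /
phylomorphospace / modularity / integration / rates / skewers / simulate /
run`); `modulrate run --config analysis.yaml` executes the full pipeline
into `report.json`, `table1_rates.csv`, `table2_evolvability.csv` and
diagnostic SVG plots, with one master seed driving named substreams per
stage.

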