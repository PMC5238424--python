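# Methods

This note records the models, estimators, numerical choices and known
limitations behind `modulrate`, in the spirit of a statistical methods
appendix. Everything stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from elsewhere.

## Geometry: superimposition and tangent space

Landmark configurations (p ≥ 3 two-dimensional landmarks per specimen) are
superimposed by **partial generalized Procrustes analysis**: each
configuration is centered, scaled to unit centroid size, and rotated to the
running consensus by the orthogonal rotation from the SVD of the
cross-product matrix, with a determinant correction so reflections are
never introduced (mirror-image anatomies are not homologous). Scale is
fixed at unit centroid size; no post-hoc cosine rescaling is applied. The
consensus is re-estimated and re-normalized each iteration until its
root-mean-square displacement falls below `tol = 1e-10` (at most
`max_iter = 100` iterations; non-convergence is a warning, not an error).

Multiple conspecific specimens are averaged **after** superimposition (then
re-projected to unit centroid size): averaging raw digitized coordinates
would conflate orientation with shape. Downstream statistics consume
species means orthogonally projected onto the **tangent plane** at the
consensus, flattened in `(x1, y1, …, xp, yp)` order so each module's
columns are contiguous. At the deviation scales the generator enforces
(below), tangent-space distortion is far below test tolerances, but the
projection is applied unconditionally so the choice is fixed.

Shape PCA is the eigendecomposition of the covariance of centered
tangent-space species means. Only PC1–PC2 are used for phylomorphospace
plotting; every test statistic operates on the full coordinates, because
rate, CR and PLS statistics on a 2-dimensional summary would discard most
of the covariance structure they are meant to measure. Ancestral states
for the phylomorphospace are estimated on the scores; by linearity of GLS
estimates this is identical to reconstructing full shapes and projecting
(asserted in the tests).

## Brownian-motion machinery

All comparative statistics share one transform. For a rooted tree with
branch lengths in time units, `C[i,j]` is the branch length shared by tips
i and j; `C = LLᵀ` (Cholesky), `T = L⁻¹`, and the GLS root weights are
`w = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹`. The transform `U = T(Y − 1wᵀY)` yields rows that
are uncorrelated under BM, and `UᵀU` equals the evolutionary
sums-of-squares-and-cross-products matrix — the same quantity
phylogenetically independent contrasts estimate (cross-checked against a
separate pruning-algorithm implementation). Polytomies are accepted as-is.
A covariance matrix with condition number above 1e12 (typically caused by
zero-length terminal branches) is a hard error naming the offending tips;
silent ridge regularization of comparative statistics is deliberately not
offered.

Ancestral states are the BM maximum-likelihood estimates, computed in
closed form as `a + C_anc,tips C⁻¹ (Y − 1a)`; they coincide with
branch-length-weighted squared-change parsimony (verified against direct
numerical minimization).

## Modularity: the covariance ratio

With `S = UᵀU/(n−1)` partitioned by module,
`CR = ‖S₁₂‖F / √(‖S₁₁°‖F · ‖S₂₂°‖F)`, where `°` zeroes the variance
diagonal and — by default — also the x/y covariances of the same landmark,
since within-landmark covariance reflects digitizing geometry rather than
biological covariation between landmarks (the exclusion is configurable
for sensitivity analysis). Significance is one-tailed on the low side:
whole landmarks (x and y moving together) are reassigned to pseudo-modules
of the observed sizes, with the add-one rule
`p = (#{CR_perm ≤ CR_obs} + 1)/(n_perm + 1)`, so p is never exactly zero.
When the requested permutation count exceeds the number of distinct
assignments `C(p, k)` (always the case at the default 9999 permutations
for 10 landmarks, where `C(10,5) = 252`), the full enumeration is used and
flagged in the result.

## Integration: phylogenetic two-block PLS

`r`-PLS is the correlation of the first pair of singular-vector scores of
the evolutionary cross-block `S₁₂ = U₁ᵀU₂/(n−1)`. Because the first
singular value is non-negative, `r ∈ [0, 1]` without sign conventions. The
permutation null shuffles the species rows of block 2 on the *original*
species means and re-applies the GLS transform each iteration (upper-tail,
add-one rule). On a star phylogeny the procedure reduces exactly to
ordinary two-block PLS on centered species means.

A caution on the algebraic identity `r = 1` when one block is a linear
image of the other: under the covariance-maximizing definition of PLS this
holds exactly if and only if the mapped singular vector is an eigenvector
of the block-1 covariance — guaranteed for orthogonal (optionally
uniformly scaled) maps, but not for arbitrary invertible maps, for which
r is slightly below 1. The exactness test therefore uses an orthogonal
map.

## Module rates and the equal-rates null

The net rate of a k-landmark module is `σ²_mult = tr(UᵀU)/(n·k)` on the
module's transformed columns: mean squared evolutionary change per
landmark per unit time. Per-landmark (not per-coordinate) normalization
keeps modules of unequal landmark counts comparable; for 2-D data the
ratio is unaffected by the choice. The face:braincase ratio is tested
against `n_sim = 999` (configurable) BM simulations on the same tree with
a **common** per-landmark rate (the pooled observed rate) and the observed
evolutionary correlation structure rescaled to a common diagonal —
integration inflates the sampling variance of the ratio and therefore
belongs in the null. A singular correlation matrix (expected: GPA leaves
the full shape space rank-deficient) is eigenvalue-clipped to the nearest
positive-definite matrix with a warning. The default statistic is the
two-sided `max(ratio, 1/ratio)`; a one-sided upper-tail option reproduces
the convention of reporting the proportion of simulated ratios at or above
the observed one, for when the direction is specified a priori rather
than observed post hoc.

Per-clade rates use the same machinery on each clade's induced subtree
(clades with fewer than 3 species are excluded with a warning;
non-monophyletic clades are flagged). Pairwise clade contrasts per module
are tested against a single-rate null simulated once on the full tree with
clade rates recomputed per simulated dataset.

## P-matrices and random skewers

A module's P-matrix is `UᵀU/(n−1)` on its transformed columns — the
evolutionary covariance, equivalent to the covariance of independent
contrasts. (Reconstructing node-to-node changes and taking their
covariance is an algebraically different estimator; the GLS/contrasts form
is used because it is the one with known sampling theory. This is the one
place where the upstream literature's procedure is ambiguous.)

Selection gradients are drawn with independent standard-normal coordinates
and normalized to unit length (uniform on the sphere); without the
normalization, evolvability and respondability scale arbitrarily. Each β
is projected into the **positive eigenspace** of P (eigenvalues above
1e-10 of the largest) and renormalized there; all products, including the
inverse in conditional evolvability, are evaluated in that eigenspace.
This contract guarantees the Hansen–Houle ordering `c ≤ e ≤ r` (equality
exactly at eigenvectors of P) and `a = c/e ∈ (0, 1]`. Naive inversion of
near-singular shape P-matrices produces negative conditional
evolvabilities and autonomies — numbers that are impossible under the
theory and that the eigenspace contract excludes by construction.
Constraints are reported as |cos| of the angle between the response `Pβ`
and P's leading eigenvector, so the index is direction-free in [0, 1].
Summaries report mean, minimum and maximum per index; maxima are the
headline values because a module's capacity to respond is set by its best
directions. Shape coordinates are deliberately **not** corrected for
allometry: size-related shape variation is a candidate line of least
resistance and removing it would hide exactly the structure the skewers
probe.

## The synthetic-study generator

`SimulationSpec` defines a study: a pure-birth tree rescaled to unit
height (or a star tree), a skull-like base configuration (face landmarks
on an anterior elliptical arc, braincase landmarks on a posterior arc, in
image-pixel units), and species means evolved by multivariate BM around
the base form, with per-specimen Gaussian digitizing noise optionally
added. Defaults: 40 species, 10 landmarks in 5+5 modules, equal
per-landmark rates 0.01 per unit height, zero between-module correlation,
zero within-module correlation, one specimen per species, no noise — the
neutral equal-rates, no-integration world against which the tests'
departures (rate ratio 2.0, ρ = 0.99, within-module correlation 0.7) are
imposed one at a time.

Two structural choices matter:

1. **Within-module correlation is carried by shape patterns orthogonal to
   the similarity group** (translations, rotation and scaling of the base
   form). Plain equicorrelation makes a module's common factor a rigid
   translation; superimposition removes the global part of such factors
   and converts the remainder into between-module anti-correlation, so an
   "integration dial" implemented that way is erased — or worse,
   inverted — by GPA before any statistic sees it. The `uniform` cross
   mode (one equicorrelated regime across all coordinates) is the
   exception, kept deliberately exchangeable for calibration.
2. **Deviations are simulated in flattened coordinate space and capped at
   5% of the base form's landmark spread** (enforced with an error), which
   keeps Procrustes alignment in its locally linear regime and the
   tangent-space approximation exact to within test tolerances.

What the generator does *not* emulate: measurement error correlated across
landmarks, allometric size variation, sexual dimorphism or ontogenetic
series, fossil (non-ultrametric) sampling, and selection regimes beyond
neutral BM. Passing calibration on these synthetic studies therefore
demonstrates that the estimators recover the structure they target under
their own model assumptions — not that real skull data satisfy those
assumptions.

## Calibration experiments and their conditions

`modulrate.validation` (used by both the test suite and
`scripts/acceptance.py`) runs, at the stated problem sizes:

- **Rate-ratio recovery** — 20 replicate studies, 50 tips, 5+5 landmarks,
  true face:braincase per-landmark rate ratio 2.0 (0.02 vs 0.01); the
  median estimated ratio through the full TPS → GPA → GLS path is expected
  in [1.7, 2.3]. The median sits slightly below 2 (≈1.8–1.95 across
  seeds): alignment removes four degrees of freedom from the whole
  configuration and takes marginally more variance from the faster module.
- **Equal-rates type-I error** — 200 replicates, 40 tips, 199 null
  simulations each; rejection at α = 0.05 expected within the binomial
  95% band [0.02, 0.09].
- **CR power and size** — power: 50 replicates, 100 tips on a star tree,
  within-module correlation 0.7, zero cross-covariance, through the full
  pipeline. Size: 200 replicates of a single equicorrelated covariance
  regime imposed **directly on shape-space species means**. The size
  calibration must be constructed at the shape level because
  superimposing any actual landmark geometry induces landmark-specific
  covariance (a property of shape data, not a defect of the test), which
  breaks the exchangeability that a type-I calibration presupposes.
- **PLS null uniformity** — 50 replicates, 100 tips, two blocks with
  block-diagonal evolutionary covariance imposed directly in shape space
  (superimposition always couples the two blocks of one configuration, so
  exact independence likewise only exists at the shape level); mean
  permutation p expected in [0.3, 0.7].
- **Skewer identities** — exact unit indices for the identity matrix;
  (e, r, c, a) = (2, 2, 2, 1) for `diag(2,1)` probed along its leading
  axis; mean evolvability within three Monte-Carlo standard errors of
  `tr(P)/d`; Hansen–Houle bounds on random PSD matrices.
- **Oracle equivalences** — Procrustes distance vs a 1e-5-radian rotation
  grid search; ancestral states vs direct numerical weighted-squared-change
  minimization; evolutionary covariance vs a contrasts pruning oracle;
  CR vs element-wise formula evaluation.

These sizes keep the whole suite under a minute of compute while leaving
each check's expected band far wider than its Monte-Carlo noise.

## Numerical conventions

- p-values: add-one numerator and denominator everywhere; never 0.
- One master seed per analysis; named, fixed substreams per stage, so
  disabling one stage cannot change another's draws.
- Taxon matching is exact after trimming whitespace and normalizing
  spaces/underscores; no fuzzy matching (silent fuzzy matches corrupt
  comparative datasets). Landmark indices are 1-based in files and
  messages, 0-based internally.
- TPS input is the tpsDig2 dialect (`LM=`, coordinate rows, `ID=`,
  optional `IMAGE=`/`SCALE=`); `SCALE` is applied multiplicatively; 3-D
  (`LM3=`) input is rejected — the pipeline is strictly 2-D lateral-view.
  Conspecific specimens are encoded as `species__k` identifiers.

## Known limitations

- Only two-module hypotheses; finer partitions (six-module skull schemes)
  are out of scope.
- Brownian motion only — no Ornstein–Uhlenbeck or early-burst rate models.
- No semilandmarks, no bilateral-symmetry decomposition, no allometric
  regression (by design, see above).
- Trees are inputs; divergence-time inference is out of scope.
- The rate ratio carries the mild alignment-induced attenuation noted
  above; at the study sizes used it is well inside the acceptance band,
  but it grows as module variance shares become extreme.
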