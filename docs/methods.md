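# Methods

This document records the model assumptions, parameter choices, numerical
methods, and known limitations of `rootmorph`. The package has two halves: a
mechanistic simulation of activator patterning on a growing cell network
(a model of how tooth-root number and shape are set at the epithelial
diaphragm), and association statistics linking EDAR 370V/A genotype to
dichotomized dental traits, with a synthetic cohort generator standing in
for the original (undeposited) individual-level records.

## 1. Cell network and mechanics

The tissue is a two-dimensional vertex model: a planar subdivision whose
faces are cells, edges are walls, and vertices are wall meeting points.

Assumptions and conventions:

- Cell polygons are simple and counter-clockwise; signed (shoelace) area
  must stay positive. `CellNetwork.validate()` checks polygon simplicity,
  wall adjacency (every wall borders 1 or 2 cells), and the Euler relation
  `V - E + (C + 1) = 2` for a disk-like tissue.
- **Elastic walls.** Each wall pulls its endpoints together (or pushes
  apart) with force `k_S (l - l_0)` along the wall; rest length `l_0 = 0.3`,
  stiffness `k_S = 1`.
- **Turgor pressure.** Each cell of area `V` pushes both endpoints of each
  of its walls outward, perpendicular to the wall, with magnitude
  `k_P / V` (`k_P = 1`), independent of wall length. The outward direction
  is derived exactly from the cell's counter-clockwise cycle (the directed
  edge rotated by −90°), not from a centroid heuristic, which matters for
  very thin cells.
- **Overdamped dynamics.** Vertices move as `du/dt = k_T F` (`k_T = 0.5`),
  integrated by forward Euler with step `relax_dt = 0.05` until the largest
  per-step displacement falls below `relax_tol = 1e-4` (or an iteration cap
  is reached; non-convergence is recorded, not an error).

Two numerical safeguards, both consequences of the explicit scheme:

- **Rigid-mode projection.** Because the pressure on a wall is independent
  of its length, the boundary pressure generically sums to a non-zero net
  force *and* net torque on the whole tissue. These rigid translation and
  rotation modes change no length or area — they are zero modes of the
  energy — but they would move vertices forever and prevent the stopping
  rule from ever being met. The relaxation kernel projects both modes out
  of the force field at every step; `CellNetwork.rigid_drift_forces()`
  exposes the projected component so "mechanical equilibrium" can be
  stated as `vertex_force - rigid_drift ≈ 0`.
- **Displacement cap and area backtracking.** Per-step displacements are
  rescaled so none exceeds `relax_max_step = 0.05`, and any trial step that
  would make a cell's signed area non-positive is halved (up to 60 times)
  before being applied. The true overdamped dynamics cannot invert a cell
  (pressure diverges as `V → 0`); only the discrete step can, and the
  backtracking removes exactly that artifact. Steps limited by either
  mechanism never count as converged.

**Initial tissue.** `initial_network(n, seed)` tiles the unit disk with the
Voronoi cells of `n` uniformly drawn points (minimum spacing `0.3/√n`).
Each point is reflected across the disk boundary, and a far ghost ring is
added, so every boundary wall is a genuine Voronoi ridge and shared
vertices are exactly consistent. Four Lloyd iterations (moving each point
to its cell centroid and re-tessellating) regularize the tiling so no
sliver cells reach the mechanical relaxation. Region vertex cycles are
recovered by sorting vertices by angle around the generating point
(Voronoi cells are convex; the library does not guarantee region vertex
order).

**Division.** The largest cell (ties broken toward the smallest cell id)
divides along a line through its area centroid at a uniformly random
orientation in `[0, π)`. The cut must cross the cell boundary exactly
twice and may not pass within `1e-9` of an existing vertex; otherwise the
angle is redrawn (up to 100 times). Both daughters receive the two new
vertices; the neighbouring cell sharing a cut wall has the new vertex
inserted into its cycle, so the subdivision stays watertight.

## 2. Reaction–diffusion on the cell network

Each cell `i` carries an activator `u_i` and inhibitor `v_i`:

```
du_i/dt = φ(ε + α_s u_i − β v_i) − (α_d + ψ_i) u_i + D_u Σ_j (u_j − u_i)
dv_i/dt = γ u_i − δ v_i             + D_v Σ_j (v_j − v_i)
```

with the sum over wall-sharing neighbours (the unweighted graph
Laplacian), `φ` clamped to `[0, α_d·u_max]` (which bounds `u` in
`[0, u_max]`), and `ψ_i = α_m` in marginal (boundary) cells, else 0.
Defaults: `α_d = β = γ = δ = ε = 1`, `α_s = 1.8`, `α_m = 1`. The
homogeneous interior equilibrium is

```
u_0 = δε / (βγ − (α_s − α_d)δ),    v_0 = γε / (βγ − (α_s − α_d)δ)
```

(`u_0 = 5` at the defaults). Integration is forward Euler, `dt = 0.02`,
for `T_d = 50` time units (2500 steps) per growth cycle. Daughter cells
inherit the mother's concentrations unchanged.

### Diffusion calibration

The diffusion pair is **`(D_u, D_v) = (0.1, 2.0)`**, a deliberate
calibration rather than a published constant. Linearizing around
`(u_0, v_0)` and restricting to a Laplacian eigenmode `λ ≥ 0` gives the
2×2 Jacobian `[[α_s − α_d − D_u λ, −β], [γ, −δ − D_v λ]]`, whose
determinant is the dispersion polynomial

```
h(λ) = D_u D_v λ² − (D_v(α_s − α_d) − D_u δ) λ + det J,   det J = 0.2
```

at the kinetic defaults. A Turing instability requires `h(λ) < 0` for
some `λ` in the spectrum, which needs roughly `D_v / D_u ≳ 5`; pairs with
ratio ≤ 2 keep `h > 0` for *every* `λ` (minimum `+0.155`), so the
homogeneous state is stable and no pattern can form — confirmed both by
the eigenvalue oracle in the test suite and by full simulations, which
then produce only a smooth boundary-driven gradient from the `α_m` term.
On the other side, the explicit Euler step bounds `D_v λ_max dt < 2`;
cell-adjacency graphs grown by this pipeline have `λ_max ≈ 9–12`, capping
`D_v ≲ 8` at `dt = 0.02`. The pair (0.1, 2.0) sits inside this window
(unstable band `λ ∈ (0.14, 7.4)`), places the fastest-growing wavelength
at a few cell diameters, and empirically reproduces the expected
qualitative regimes at reduced scale: region count decreasing in `α_s`,
increasing in `γ`, polarity flipping with the saturation level, and a
single C-shaped or compact region at the high-`α_s` corner. The choice
was frozen before the acceptance tests were written.

### Pattern taxonomy

After growth, the activator field is binarized at the mid-range threshold
`(min + max)/2`; a field whose range is below `5% of u_0` is homogeneous
("none"). The minority phase **by total cell area** defines the polarity:
minority-HIGH is "spotted", minority-LOW "reverse-spotted" (exact ties
break toward HIGH). Connected components of the minority phase on the
adjacency graph are the candidate root regions. Each region's
circularity is `4πA/P²` with `P` the total length of walls having exactly
one adjacent cell inside the region; its angular extent is the smallest
arc (about the tissue centroid) containing all member-cell centroids.
Labels: `1`–`4` for 1–4 compact regions (all circularity ≥ 0.4); `C` for a
single elongated region (circularity < 0.4) spanning ≥ 120°; `other`
otherwise. The thresholds 0.4 and 120° are package choices, fixed before
the acceptance tests.

## 3. Association statistics

- **Dichotomization.** Left/right root-shape code pairs map to two classes
  per tooth exactly as published (e.g. LM2: `2|C, C|C → C`, `2|2 → 2`);
  when sides differ, the case goes to the class listing that pair — the
  less common phenotype. Unlisted pairs and missing teeth are excluded;
  unknown codes are errors.
- **Exact test.** `fisher_exact_rxc` enumerates all r×c tables with the
  observed margins (Freeman–Halton) and sums the probabilities of tables
  no more probable than the observed one (tolerance 1e-12). This is
  exact, unlike Monte-Carlo approximations, and is required to reproduce
  printed values such as UP1's P = 0.010 (a Monte-Carlo run gives ≈0.012).
  The 2×2 special case is cross-checked against the hypergeometric closed
  form in tests.
- **Rank correlation.** `spearman_from_table` computes tied-rank Spearman
  directly from a count table: mid-ranks from the margins, then a weighted
  Pearson correlation; P from the t approximation. It agrees with
  expansion + `scipy.stats.spearmanr` to machine precision.
- **Logistic regression.** Newton-fitted maximum likelihood (statsmodels)
  with intercept; Wald χ² `(coef/se)²`, P from 1-df χ². Genotype is coded
  by 370A dosage (VV/VA/AA = 0/1/2), sex male = 0 / female = 1, region
  0–4. Quasi-complete separation (|coef| > 15 or non-finite SE) is
  flagged; a singular-Hessian fit falls back to BFGS so coefficients are
  still reported.

## 4. Synthetic cohort generator

Individual-level records of the genotyped cohort were never deposited, so
`synthetic_cohort` draws cohorts with the same statistical structure:
multinomial genotypes at the printed frequencies, uniform integer ages
20–69, the printed female fraction, uniform region 0–4, per-tooth
dichotomized phenotypes from a logistic model whose default effect sizes
are the published log odds ratios (UP1, LM1, LM2; zero effects for UP2 and
UM2, which showed no association), and intercepts calibrated so the
expected marginal prevalence of each modelled class matches the published
counts at the mean covariates. Side pairs are synthesized consistently
with the drawn class; 5% of listed-discordant classes get a discordant
left/right pair to exercise the less-common-side rule. Crown traits are
Bernoulli with a genotype link only for UI1 shoveling (log-OR 1.5 per
allele, a package choice of the right order for the strong published
genotype–shoveling correlation).

**Scope.** The generator reproduces marginal genotype frequencies,
marginal phenotype prevalences, and the configured genotype effects. It
does **not** model the published inter-trait correlations (e.g. UP1–UP2
roots) beyond those induced by the shared genotype, age patterns other
than uniform, or missing teeth.

**Known inconsistencies in the published summary data** (full analysis in
the development decision log):

- The printed genotype counts (25 VV, 120 VA, 112 AA) sum to 257, not the
  stated 255 (the printed 9.0% for VV implies 23). The generator
  normalizes the printed counts to probabilities.
- The printed genotype–LM2-root Spearman (−0.2327) is inconsistent with
  the printed LM2 count table, which yields −0.2416 by a correct tied-rank
  computation (verified against an independent oracle; UP1 and LM1
  reproduce to 4 decimals including P values). The corresponding
  acceptance assertion states the printed value and fails honestly.
- The printed diffusion pair (0.25, 0.5) cannot produce any pattern (see
  §2); the package uses the calibrated pair (0.1, 2.0).

## 5. Reduced-scale acceptance substitutes

Full-scale pattern-regime reproduction (1000 cells × 20 replicates × a
parameter grid) costs hours on one CPU. The acceptance tests use reduced
scale: 250-cell tissues, 10 replicates per condition for the polarity
flip, 8 per grid point for the monotone region-count trends. At this
scale both properties hold with margin (10/10 polarity majorities;
strictly monotone mean region counts along both parameter axes). The
single full-scale check kept in the suite is the exact final cell count
(10 → 1000 in 990 cycles), which is also what `scripts/acceptance.py`
recomputes.

## 6. Reproducibility

All stochastic entry points take explicit integer seeds (`numpy`
`default_rng`); replicate `k` of a batch uses `base_seed + k`. CLI outputs
are byte-for-byte reproducible for a fixed config and seed. Inner loops
(relaxation, RD integration) are `numba` kernels; pure-`numpy` reference
implementations of each live in the test suite and agree to ≤1e-13 per
step.
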