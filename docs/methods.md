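# Methods

## The model

`metafoci` models the peak-activation coordinates ("foci", MNI mm)
reported by neuroimaging studies of one category as a three-level
hierarchical cluster point process on a brain mask B:

* **Level 3 — population centers.** For each category, latent population
  centers follow a homogeneous Poisson process on B with rate `eta`
  (centers per mm³).  Centers mark locations where studies of that
  category consistently activate.
* **Level 2 — per-study structure.** For each study, every population
  center spawns `Poisson(mu_cent)` attached points, scattered
  isotropically `N(center, sigma_study² I)` and truncated to B.  Each
  attached point is a *study activation center* with probability
  `q_study`, otherwise a *singly reported focus*.  Uniform background
  study centers and singly reported foci arrive at per-study rates
  `nu_bg_center` and `nu_bg_single`.
* **Level 1 — reported foci.** Each study center emits
  `1 + Poisson(mu_multi)` multiply reported foci, scattered
  `N(study center, sigma_foci² I)`.  Only the union of foci is observed;
  whether a focus is singly or multiply reported, its cluster, and all
  parent links are latent (the literature rarely reports them).

Densities are written in Janossy form.  Level-2 streams are marked
Poisson processes; a study-center cluster of size m contributes
`Poisson(m−1; mu_multi) · m! · Π N(focus; center, sigma_foci²)`.

**Background parameterization.** The uniform background is
parameterized by per-study *rates* rather than mixture probabilities.
Rates keep the likelihood well defined when the center configuration is
empty (probabilities tied to the attached streams would put zero mass on
any data at K = 0, freezing the birth–death moves) and are
Gamma-conjugate.  The implied marginal background probabilities given K
are exposed as derived quantities.

**Mask truncation.** Simulation truncates every Gaussian draw to B by
rejection.  Densities use a normalizing-mass correction: the mass of
`N(c, sigma² I)` on B is obtained by smoothing the mask indicator with a
Gaussian kernel on its own grid (grid quadrature), cached per 0.5 mm of
kernel width, and interpolated at c with edge clamping.  The level-1
(`sigma_foci`) kernels are left uncorrected — study centers live well
inside the mask and `sigma_foci` is small, so the omitted factor is a
fraction of a percent; this is the one deliberate approximation in the
density.

## Priors

Weakly informative at MNI brain scale, all overridable:
`eta ~ Gamma(1, |B|)` (about one expected center a priori);
`sigma²_study, sigma²_foci ~ Inv-Gamma(3, 200)` mm² (prior mean 10 mm);
`mu_cent, mu_multi ~ Gamma(2, 1)`; background rates `~ Gamma(1, 0.5)`;
`q_study ~ Beta(1, 1)`.

## Posterior simulation

Each category is fitted independently by Metropolis-within-Gibbs:

1. **Marks and memberships.** Sequential Gibbs over every focus with the
   existing study-center locations instantiated and the location of a
   newly created cluster integrated out in closed form (conjugate
   Gaussian algebra, as in collapsed mixture samplers).  Options per
   focus: singly reported (parents marginalized into one Poisson-mixture
   intensity), join an existing cluster, or open a singleton cluster.
2. **Cluster refresh.** Each cluster's parent is resampled with its
   location collapsed, then the location is drawn from its Gaussian full
   conditional.
3. **Globals.** Parent labels are drawn as auxiliary variables
   (exact conditionals), then all global parameters are updated by
   conjugacy.  The `sigma_study` draw is Metropolis-corrected for the
   truncation masses; a supplementary random-walk move on
   `log sigma²_study` keeps it mobile when the mass tilt makes the
   conjugate independence proposal sticky.
4. **Center locations.** Random-walk Metropolis (4 mm default) with the
   level-2 parent labels marginalized analytically.
5. **Dimension moves.** Discrete-time birth–death Metropolis–Hastings
   (uniform birth location on B, uniform death choice), again with
   parents marginalized — without that marginalization a birth pays
   `exp(−n_studies · mu_cent)` before any point can re-attach and K
   never mixes.  Two flavours alternate: *plain* (fixed `mu_cent`;
   births succeed only near unexplained data, spurious centers die) and
   *rescaled* (`mu_cent` jointly scaled by K/(K±1); a reversible jump
   with a deterministic mapping that preserves the total attachment
   rate K·`mu_cent`).  The rescaled flavour is needed because the
   offspring rate is shared across centers: once `mu_cent` has adapted
   to the current K, plain moves reject in both directions even when
   the posterior prefers a different K.

Parent labels are not part of the chain state: the state is (globals,
centers, marks, memberships, cluster locations), and parents are
re-drawn each sweep where conjugacy needs them, which keeps every move
a valid update of the marginal chain.

**Initialization.** Latent clusters are seeded by single-linkage
grouping of each study's foci at twice the initial `sigma_foci` (an
all-singles start triggers a `q_study → 0` feedback that suppresses
cluster formation for a long transient).  The center count starts from
a data-scaled estimate (mean foci per study divided by the expected
foci per center, discounted 30% for anticipated clutter) with K-means
centroids; a prior draw of K (typically 1) reliably starts the chain in
a broad single-center mode that the birth moves cannot leave.

**Chain lengths.** The desk-scale default is 6,000 iterations with
1,000 burn-in (5,000 retained); reference-scale analyses retain 10,000.
The experiments in the test suite and acceptance script use shorter
chains (400–900 retained states) chosen so each experiment completes in
minutes; recovery and classification results were insensitive to
doubling these lengths.

## Classification

The posterior predictive of category e for new foci F averages the
study density over e's retained states.  The study density collapses
the latent structure: foci are scored as an inhomogeneous Poisson
process whose intensity mixes the `sigma_study` kernel (singly
reported), the `sqrt(sigma_study² + sigma_foci²)` convolution kernel
scaled by `(1 + mu_multi)` (multiply reported), and the uniform
background.  This drops the within-cluster dependence of multiply
reported foci; it is fast, deterministic per state, and identical
across categories, so classification comparisons are on equal footing.
With flat class priors, posteriors are normalized by log-sum-exp and
ties break to the lexicographically smallest label (flagged).

**Leave-one-study-out CV.** Models are fitted once on the full
database.  For a held-out study, the other categories' predictive terms
need no correction (they never saw the study).  The held-out category's
term is importance-reweighted with self-normalized weights
`w_t ∝ 1/pi(F_k | lambda_t)` (clipped at the 99.9th percentile), with
an exact warm-started refit fallback when the weight effective sample
size drops below a floor (default 20).  One caveat is documented and
measured: because the weights use the collapsed study density while the
posterior was sampled under the exact cluster likelihood, the IS
estimate of the held-out term carries a small systematic deficit
(about 1–3 nats in our experiments; Pareto-smoothed weights do not
remove it, and a control with `q_study → 0`, where the collapsed
density is exact, eliminates it).  The deficit is immaterial when
categories are genuinely separated — IS and exact-refit LOOCV agree on
9/10+ of studies there — but is decisive in label-exchangeable designs
where every comparison is a tie; `refit_all=True` switches the held-out
term to short warm-started exact refits and is used for the
chance-level experiment.

Performance metrics are one-vs-rest sensitivity/specificity/PPV/NPV
from the confusion matrix; *mean balanced accuracy* is the mean of the
per-category sensitivities.

## Intensity maps, signatures, tests, networks

* **Intensity map**: posterior mean over states of the level-2
  intensity at each inside-voxel center times the voxel volume, so
  values are expected centers per voxel and the map sums to the
  posterior mean expected center count (K·`mu_cent` + background).  The
  reported quadrature bound accumulates the per-center kernel-mass grid
  error and, by the triangle inequality, always covers the discrepancy
  between the voxel sum and the analytic count.  The conventional
  display threshold for rendered maps is 0.001 per voxel.
* **Region matrices**: entry [t, r] is the mean per-voxel expected
  count over region r's voxels under state t.  Only relative
  comparisons across regions/categories are interpreted.  Signatures
  are exact column means.
* **Profile-difference test**: for categories i, j with mean difference
  profile, count iterations whose per-region signs disagree with the
  mean profile by `sum_r |sign(M_i − M_j) − sign(mean diff)| ≥ R` and
  report `P = min(1, (2^R / T) · count)`; the `2^R` factor accounts for
  the quadrant the mean difference occupies, and sign(0) counts as 0.
  P is capped at 1 (the raw expression can exceed it).  The test runs
  on any region subset, with R the subset size; pairwise tests over
  categories are Benjamini–Hochberg FDR-controlled at q < .05 across
  the C(C−1)/2 pairs.
* **Co-activation**: Pearson correlations of region columns across
  retained states.  The max-statistic permutation threshold permutes
  each column's rows independently (1,000 replicates, 95th percentile
  of the maximum off-diagonal correlation by default), controlling
  matrix-wise FWER; the most stringent per-category threshold is
  applied to all categories.  Permutations are per category.  Graphs
  keep positive supra-threshold correlations as edges (an `absolute`
  flag admits |r|) with distance 2 − r; betweenness centrality is
  weighted-shortest-path, normalized by (N−1)(N−2)/2; grouped global
  efficiency averages 1/d over pairs (within-group: unordered pairs;
  between-group: cross pairs) with unreachable pairs contributing 0,
  so values lie in [0, 1] — 0 for disjoint systems, 1 for a complete
  r = 1 graph.  Averaging 1/d (rather than inverting the mean path
  length) is what makes the disjoint-system value well defined.
* **NNMF**: alternating least squares with exact nonnegative
  least-squares half-steps (so the squared Frobenius error is
  non-increasing within every run), best of 20 seeded restarts, k = 2
  by default for the two canonical activation profiles.

## Synthetic data

The generator is the model itself: a box mask of 40×48×40 voxels at
2 mm (a scaled-down MNI extent), a box-tiled toy atlas with groups
cycling over six cerebral zones, true centers on a separation-spaced
grid, and studies drawn by forward simulation.  Defaults: 5 categories
× 20 studies, 3 centers per category, `sigma_study` 8 mm, `sigma_foci`
4 mm, `mu_cent` 2, `mu_multi` 2, `q_study` 0.5, and a 30% uniform
clutter fraction (reporting practices inject substantial noise into
real foci databases); background rates are derived from the clutter
fraction.  `separation = 0` makes all categories share one center set —
the label-exchangeable null for chance-level experiments; the separated
classification scenario uses 2 centers per category at 6-sigma spacing
with `sigma_study` 6 mm so five disjoint center sets fit in the toy
mask.

What the toy data do **not** emulate: anatomically realistic masks and
parcellations, anisotropic or spatially varying scatter, covariate
structure (induction method, stimulus type), between-study sample-size
differences, and Talairach/MNI conversion error.  Passing tests
therefore demonstrate correctness of the algorithms under the model's
own assumptions, not performance on real meta-analytic databases.

## Numerical choices and limitations

* Rounding world→voxel is half-away-from-zero; foci outside the mask
  are kept, logged, and explained by the background component.
* Truncation masses are clamped to [1e−6, 1]; interpolation clamps edge
  coordinates onto the grid (an unclamped lookup makes boundary centers
  look spuriously good, which the chain will exploit).
* Label switching of centers is ignored: every reported functional (K,
  intensity maps, region intensities) is permutation-invariant.
* The collapsed predictive ignores within-cluster dependence (see the
  LOOCV caveat above).
* Exchangeability ties in classification are resolved
  lexicographically and flagged, so results are deterministic.
* K is only weakly identified when centers nearly coincide (splitting
  one center's rate across duplicates barely changes the likelihood);
  the Gamma priors on `eta` and `mu_cent` plus the paired plain/rescaled
  moves resolve this in practice, but posteriors for K should be read
  with that near-degeneracy in mind on small masks.
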