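# Methods

## Scope and model

`phylofd` implements the statistical core of a biodiversity–ecosystem
functioning (B-EF) analysis for forest plots: richness-independent
diversity indices per plot, phylogenetic-signal estimation per trait, and
adjusted-R² variance partitioning of productivity between functional and
phylogenetic diversity. Phylogeny inference, plot selection and
allometric biomass estimation are out of scope: the package starts from a
rooted ultrametric chronogram (newick), a species × trait table (CSV) and
a plot × species basal-area matrix (CSV).

All matrix quantities derive from the chronogram. With branch lengths in
relative time and tree depth T, the Brownian-motion covariance matrix V
has V[i,j] equal to the shared root-to-MRCA time of tips i and j, so for
an ultrametric tree V[i,j] = T − d(i,j)/2 with d the patristic distance.
Both identities are enforced as tested invariants. Non-ultrametric trees
are accepted with a warning for distance/covariance computations (V is
still well defined from shared path lengths) but rejected by the λ
estimator, whose interpretation assumes a chronogram.

## Diversity indices

* **FDis** — abundance-weighted mean Euclidean distance of species to the
  abundance-weighted centroid in standardized trait space. Traits are
  z-scored (sample SD) over the full species pool, not per plot, so plot
  values share one scale. The dissimilarity is standardized-Euclidean by
  design choice: all participating traits are continuous, for which the
  common Gower alternative is near-equivalent; the choice is recorded
  here rather than asserted as canonical. Default FDis traits are maximum
  height, wood density and log seed mass; shade tolerance is excluded
  from index computation (it is an aggregate life-history score, not an
  elementary functional trait), and leaf N enters as a CWM
  (functional-identity) term instead.
* **PSV** — for the n present species with phylogenetic correlation
  submatrix C: (n·tr C − ΣC)/(n(n−1)) = 1 − mean off-diagonal
  correlation. Presence is basal area > 0; abundances do not enter, and
  the suite verifies abundance-invariance.
* **Monoculture convention** — single-species plots take FDis = PSV = 0.
  There is no spread to measure; the convention is applied identically in
  both indices so monocultures anchor the diversity gradient rather than
  being dropped.

Species labels must match exactly (case-sensitive) across tree, traits
and community; any mismatch is a hard error listing the offenders, since
silent dropping would bias every downstream index.

## Pagel's λ

The trait vector is modelled as N(z₀·1, σ²·V(λ)) with
V(λ) = λV + (1−λ)T·I. For fixed λ, ẑ₀ and σ̂² have closed GLS/ML forms, so
λ is found by 1-D maximization of the profile likelihood over
[ε, 1], ε = 10⁻⁷ (the lower bound that also appears as the floor of
bootstrap CIs for signal-free traits). λ > 1 is excluded: on an
ultrametric tree it can violate positive semidefiniteness.

Because V(λ) is a convex combination of V and T·I, it shares V's
eigenvectors; one symmetric eigendecomposition per tree makes each
profile evaluation O(n). The maximizer uses a 21-point grid scan followed
by bounded scalar refinement in the bracketing interval, with both
endpoints checked — profile likelihoods for λ can be flat or mildly
multimodal on small trees. Convergence tolerance is 10⁻⁸ on λ. The dense
Cholesky likelihood (`bm_loglik`) is retained as an independent path and
cross-checked against the eigendecomposition route in the tests.

**Confidence intervals** are percentile intervals from a parametric
bootstrap: simulate traits from the fitted (λ̂, σ̂², ẑ₀), refit, take the
2.5%/97.5% quantiles; 1000 simulations by default. A replicate that fails
to refit is retried once on a fresh draw, then dropped with a warning
(with the bounded profile optimizer this is a safeguard, not an expected
path). A likelihood-ratio test against λ = 0 is deliberately not the
headline output; the CI is.

## Moran's I correlogram

Moran's I is computed per phylogenetic distance class with binary,
non-row-standardized weights (1 for species pairs whose patristic
distance falls in the class), following classic phylogenetic-correlogram
practice. Expectation under no autocorrelation is −1/(n−1). Significance
defaults to a two-sided permutation test (999 shuffles of trait values
across tips, +1 convention, so the floor p is 0.001); the classic normal
approximation is available as `method="normal"`.

Distance classes default to **eight equal-width bins** over (0, max
patristic distance]. Equal width is the default because deeply split
pools (e.g. angiosperms vs gymnosperms) leave genuine gaps in the
distance distribution, and empty classes — reported as "no comparison
possible" rather than silently merged — are themselves informative.
Equal-frequency binning is provided as an option; because tree distances
arrive in tie blocks (all pairs sharing an MRCA are equidistant), its
cuts are placed between tie blocks at the achievable cumulative count
nearest each quantile target, and requested classes may collapse (with a
warning) when a tie block spans several targets.

## Variance partitioning

The two-block partition regresses log productivity on {FDis}, {PSV} and
their union, converts R² to adjusted R² (Ezekiel), and reports the four
Venn fractions. By default the partition is unconditioned — environmental
covariates appear only in the full multiple-regression model
(`fit_productivity_model`), which also reports per-term Freedman–Lane
p-values conditional on all other terms. Negative adjusted fractions are
reported as-is; clipping would break the additive identities
(a+b+c = R²ₐ(joint), a+b+c+d = 1, both enforced to 10⁻¹²). If the two
blocks are collinear (e.g. duplicated predictors), the union model is fit
by projection onto its column space and adjusted by rank, so the
identities still hold.

The Freedman–Lane test permutes residuals of the reduced model,
reconstructs pseudo-responses, and compares partial F values; the
statistic is partial F because the permutation scheme fixes the reduced
model and partial F is the standard, approximately pivotal choice for a
block increment. p = (1 + #{F* ≥ F})/(1 + n_perm), so 999 permutations
give a 0.001 floor. The shared fraction has no test: it is not a model
contrast.

## Synthetic data generator

The generator emulates a boreal/temperate forest-inventory study system:

* **Tree** — Yule (pure birth) with exactly n tips (default 61, birth
  rate 1); pure birth suffices because every downstream quantity depends
  only on the chronogram, not the diversification model. A two-clade
  variant (basal split spanning 90% of depth, Yule crowns in the
  remaining 10%) emulates a deep taxonomic divide and is what produces
  empty correlogram classes and negative large-distance autocorrelation.
* **Traits** — multivariate normal draws with covariance σ²·V(λ) per
  trait. Default λ values (maxH 0.0176, Wd 0.7929, Sm 0.2281, N 0.6503,
  shade tolerance 0.8230) mirror estimates reported for such species
  pools, so the default bundle spans the weak-to-strong signal range;
  σ² and root states are set to give realistic trait scales (heights in
  m, wood density in g/cm³, leaf N in mg/g).
* **Communities** — per plot, richness ~ Poisson(3) truncated to [1, 10]
  (monocultures always possible, echoing inventory plots of 1–10
  species), species sampled uniformly without replacement, basal areas
  log-normal(0, 0.75) m²/ha.
* **Covariates and response** — organic-horizon depth log-normal(2, 0.5)
  cm, mean annual temperature N(2.5, 2.0) °C, total basal area from the
  community matrix; log productivity = 0.2 + 0.35·FDis + 0.15·PSV +
  0.02·CWM_N + 0.015·total_ba − 0.02·org_depth + 0.06·temp + N(0, 0.35²).
  Coefficients were chosen once to make every term detectable at
  inventory-like effect sizes while keeping FDis the dominant diversity
  term, which reproduces the qualitative FD-over-PD asymmetry in the
  partition.

One master seed drives everything; per-stage child streams are spawned
from it so each stage regenerates independently and bundle files are
byte-identical across reruns.

What the generator does **not** emulate: spatial autocorrelation among
plots, climate gradients structuring community composition (species are
sampled uniformly), non-random trait–abundance covariance, measurement
error in traits, and phylogenetic uncertainty. Passing tests therefore
demonstrate correctness of the estimators under their own model
assumptions — not robustness to the violations real inventories contain.

## Problem sizes in the test and acceptance runs

Recovery and calibration checks use sizes chosen to make sampling error
small relative to the tolerance while keeping the default run quick:
λ recovery uses 100 replicates of 200-tip trees per condition (the suite)
and 30 per condition (the acceptance script); bootstrap coverage 50
replicates × 200 draws; permutation-test size 500 null datasets of 100
observations × 999 permutations; correlogram detection 50 replicates of
61-tip two-clade trees. The end-to-end synthetic run uses the default
61-species, 500-plot bundle.

## Known limitations

* λ̂ at interior truth values is mildly downward-biased on small trees
  (visible as ~0.43–0.46 mean at λ = 0.5 with 200 tips); this is a
  property of the ML estimator, not the implementation, and stays well
  inside the 0.1 recovery tolerance.
* Percentile bootstrap CIs for λ can slightly undercover near the
  boundaries of [0, 1]; observed coverage at λ = 0.5 sits around 85–95%.
* The equal-frequency scheme cannot balance counts on trees whose tie
  blocks are large (e.g. a basal split contributing hundreds of
  equidistant pairs).
* PSV ∈ [0, 1] is guaranteed only for ultrametric correlation matrices;
  non-ultrametric input is the caller's responsibility after the warning.
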