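# Methods

This note documents the models and procedures implemented in `phylomorph`,
the assumptions they make, the defaults and why, and what the synthetic
benchmark does and does not establish.

## Shape representation and superimposition

The atomic observation is a configuration of k landmarks in d dimensions
(d = 2 or 3), in physical length units after the digitizer's pixel/voxel
scale. Missing landmarks are a hard error by design: structures absent in
part of the sample should be excluded from the landmark scheme, not imputed,
and a −999-style sentinel is treated as data corruption.

Generalized Procrustes Analysis removes position, orientation and scale:
configurations are centred, fixed to **unit centroid size** (centroid size
CS — the root summed squared landmark distance to the centroid — is kept as
the size variable), and iteratively rotated to the running consensus until
the consensus moves by less than `tol` (default 1e−10 Frobenius). The
alternating rotate/average scheme makes the Procrustes residual sum
non-increasing by construction, which the tests verify. Reflections are
disallowed by default: consistently digitized specimens never need one, and
an improvement under reflection indicates a digitization error. Degenerate
rotation optima are resolved deterministically by the standard
smallest-singular-pair determinant correction.

After convergence the whole configuration set is rotated so the consensus
lies along its principal axes with deterministic signs. This gives a
canonical output frame: tangent coordinates are then invariant (to ~1e−9)
under arbitrary similarity transforms of the *input* configurations, which
would otherwise leak into the result through the arbitrary initial
reference.

Aligned shapes are projected **orthogonally** onto the tangent space at the
consensus (the component along the consensus direction is removed, then
coordinates are centred across specimens). Orthogonal rather than
stereographic projection is the common default of the field's tools and
keeps the projection linear, which several downstream identities rely on
(e.g. ancestral estimation commutes with PCA projection). Euclidean
distances in tangent space agree with Procrustes distances to first order;
the tests check < 2% relative discrepancy below distance 0.1.

Species means are taken **after** a single joint superimposition of all
specimens (all life stages together), so embryos, adults and species means
share one coordinate frame; tangent coordinates average arithmetically,
centroid sizes on the log scale.

## Morphospace and allometry

The morphospace is the eigendecomposition of the specimen covariance of
tangent coordinates. Axis polarities carry no information; each eigenvector
is oriented so its largest-magnitude loading is positive, making runs
reproducible. Axis-retention for classification and multivariate tests uses
the smallest leading set with > 90% cumulative variance (logged,
configurable).

Allometry is the multivariate regression of tangent shape on log CS. With a
phylogeny, the slope is estimated by regression through the origin of
**phylogenetically independent contrasts** of shape on contrasts of size;
the explained fraction is predicted SS over total SS in contrast space (the
species-space fraction is also reported, since the two differ and either
may be meant when a single number is quoted). Residual shapes are formed in
species space as centred shape minus log-size times the contrast slope;
because contrasts are linear in tip values, re-estimating allometry on
these residuals gives exactly zero, which the tests assert.

Significance is a permutation test against total independence of size and
shape. The permuted unit is the **size contrast row**, not the raw tip
value: under Brownian size evolution the standardized size contrasts are
iid and hence exchangeable, whereas shuffling sizes across tips destroys
the phylogenetic covariance of size and produces a badly inflated null
(shuffled-tip size contrasts become heteroscedastic in exactly the pattern
of the non-phylogenetic component of shape contrasts; in our experiments
this cost essentially all power at a planted 6% effect). The contrast-row
permutation is calibrated under the null (verified by simulation) and uses
the (b+1)/(m+1) convention, so p > 0 always; the default is 10,000
permutations. The caveat — exchangeability presumes Brownian-like size
evolution — is inherent to contrast-based permutation and documented here.

The regression score is the projection of centred shapes onto the
unit-normalized slope vector; its simple regression on log size reproduces
the multivariate explained fraction exactly (an identity the tests check
numerically).

## Thin-plate splines

TPS interpolation uses kernel U(r) = r² log r² in 2D and U(r) = −r in 3D —
the sign conventions under which the kernel system restricted to the
affine-orthogonal subspace is positive semidefinite, so the bending energy
(trace of WᵀKW) is ≥ 0 and vanishes exactly for affine targets. The mapping
interpolates the landmarks exactly; collinear (2D) or coplanar (3D) source
sets are rejected via a rank check. Ancestral-shape visualization warps the
landmarks of the species nearest a reconstructed node onto the estimated
ancestral configuration and carries probe points (outlines, grids) along.

## Tree machinery

Trees are rooted with branch lengths in time units; absent lengths default
to 1 with a warning so topology-only hypotheses can be run. Fossil tips are
ordinary tips at their sampled ages (non-ultrametric trees are fully
supported), and alternative topological hypotheses are alternative input
trees, not internal surgery. Polytomies are resolved deterministically with
zero-length insertions; weighted operations add an epsilon of 1e−8 × tree
depth where a division by branch length would be singular.

Ancestral states use squared-change parsimony: minimize Σ (change)²/w over
branches with w = 1 (unweighted) or w = branch length (weighted), solved
exactly through the tree's weighted Laplacian. The weighted solution equals
the joint maximum-likelihood states under Brownian motion; the acceptance
suite verifies this against an independent re-rooted-GLS oracle to 1e−8.
Ancestral centroid sizes are reconstructed on the log scale and
exponentiated for reporting. Because estimation is linear, ancestors of PC
scores equal the PCA projection of ancestors — the phylomorphospace is
therefore consistent whichever order is used.

Phylogenetic signal is the multivariate generalized K: the ratio of the
among-tip mean squared error to the mean squared error under the Brownian
covariance (both about the phylogenetic mean), scaled by its Brownian
expectation so E[K] = 1 under BM. The permutation null shuffles whole
multivariate tip rows (preserving trait covariance); defaults to 999
permutations. Simulation shows mean K within [0.9, 1.1] under BM on a
64-tip tree and uniform null p-values.

Brownian simulation draws independent increments per branch with covariance
branch length × rate. For simulation-based nulls on a fixed tree, a
vectorized tip-only sampler precomputes the root-to-tip branch incidence so
each replicate is one matrix product. The evolutionary rate matrix is the
standard contrast-based estimator UᵀU/(n−1).

## Convergence measures

For focal taxa suspected of convergence, Dtip is their current phenotypic
distance and Dmax the maximum distance between any pair of nodes along
their two lineages back to the focal MRCA, with internal nodes taken from
the weighted squared-change reconstruction. C1 = (Dmax−Dtip)/Dmax is the
proportion of past divergence subsequently closed; C2 the absolute amount;
C3 and C4 normalize C2 by the summed per-branch evolution along the focal
lineages and across the whole focal clade respectively. With more than two
focal taxa, pairwise values are aggregated by the mean (min/max available);
the aggregation rule is a documented convention since multi-taxon sets do
not define it uniquely. Dmax is found by exhaustive enumeration over node
pairs; ties in its location cannot affect the value. Significance compares
the observed measures with 1000 Brownian simulations at the contrast-
estimated rate matrix, with ancestral states re-estimated inside every
replicate — the statistic is a function of reconstructed histories, so the
null must reconstruct too.

## Ecology inference

Habitat takes five states (aquatic, terrestrial, leaf_litter, fossorial,
arboreal). Association between habitat and shape scores is tested by MANOVA
(Wilks' lambda with Rao's F approximation, implemented directly and
cross-checked against statsmodels) and by a phylogenetic MANOVA whose null
distribution is the same statistic on Brownian-simulated data with labels
held fixed — this is the construction that distinguishes genuine
habitat–shape association from clade-structured lookalikes, and the tests
exercise exactly that contrast. Per-axis ANOVAs are followed by permutation
tests on pairwise class mean distances with Holm correction (a conservative
default, chosen because no particular post hoc procedure is canonical
here).

Ancestral ecologies are predicted from reconstructed ancestral scores with
a Gaussian equal-covariance linear discriminant model: class means, pooled
within-class covariance (ridge-regularized by 1e−6·trace/m when its
condition number exceeds 1e10; singleton classes are permitted and simply
contribute no scatter, which keeps leave-one-out folds fittable), priors
proportional to class frequencies by default (uniform available — the
common library default when none is stated). Posteriors are computed with
a log-sum-exp and sum to one to machine precision; the implementation is
cross-checked against scikit-learn's LDA posteriors. Validation is
leave-one-out cross-validation on the extant species; predictions are run
on both allometry-uncorrected and -corrected bases.

## Ontogeny and heterochrony

Each species contributes a two-point trajectory from a fixed late embryonic
stage (stage 10) to the adult, within the common superimposition; other
anchor stages are accepted but flagged non-comparable. Group trajectories
run between group mean shapes; path length is the norm, angles come from
the arc-cosine of normalized dot products, and significance permutes
species across groups (exhaustive enumeration available for toy groups, and
verified against it).

Heterochrony regression fits per-group multivariate shape-on-log-size
regressions. Slope magnitudes are **bias-corrected** (E‖b̂‖² exceeds ‖b‖² by
the summed coefficient variances, and the bias differs between groups with
different size spreads); inference on the magnitude difference uses
residual-randomization permutation under the reduced common-slope model.
The global mode classifier is a set of auditable gates, each emitted in an
evidence table:

* *steeper*: one-sided permutation p ≤ α **and** corrected magnitude ratio
  > 1.25 (significance plus a material effect);
* *extends*: descendant maximum log size exceeding the ancestor's by > 0.3
  of the ancestor's log-size span (relative, because the difference of two
  group maxima is noisy), or a significantly **and** substantially (> 0.2
  log units) longer descendant development;
* *shifted*: intercept displacement along the common slope direction > 3
  residual SDs;
* *truncated*: descendant adult mean projecting strictly inside the
  ancestor's ontogenetic segment with a clearly smaller size maximum.

Classification: truncated (and not steeper) → paedomorphic pattern; steeper
without longer duration or size extension → acceleration; shifted without
steeper slopes or extension → predisplacement; extension without steeper
slopes → hypermorphosis; otherwise none. A steeper slope with equal or
*shorter* development is still acceleration — only a longer duration argues
for hypermorphosis instead. Truncation requires statistically
indistinguishable slopes because it is defined along a *shared* trajectory.
α defaults to 0.05; all thresholds are keyword arguments. On strongly
planted scenarios the classifier is ≥ 95% correct per mode over 200
simulations (verified in the acceptance suite; residual errors are the
irreducible false-positive rates of the gates' significance tests).
Development durations are compared on the log scale (they are positive and
right-skewed).

## The synthetic benchmark

`simulate_study` generates: a Yule tree rescaled to depth 1; tip shapes as
isotropic Brownian displacements in the tangent space of a 20-point 2D
skull-outline template (simulating directly in tangent space avoids nuisance
transforms; a jitter option re-embeds configurations with random rotations
and translations so superimposition is actually exercised); clade-structured
habitat regimes with fixed shift vectors (orthonormalized, norm 0.12; the
fossorial shift, norm 0.18, is planted independently in one "snake"-nested
and one "lizard"-nested clade to create true convergence); log centroid
size as scalar BM (SD 0.35) around log size 3; an allometric component
along a random tangent direction scaled so the planted explained fraction
is ~6% in contrast space (measured against the realized non-allometric
variation, so the target holds in expectation); and isotropic
non-phylogenetic noise at 50% of the Brownian SD (real datasets carry
measurement and intraspecific noise; this also keeps K below its pure-BM
expectation, as observed in real skull data). Embryo/adult pairs follow
per-clade linear ontogenies along a common direction with the snake slope
doubled and lognormal durations drawn from the same distribution in both
clades — the acceleration configuration. All magnitudes were chosen once as
plausible Procrustes-scale values and are recorded in `SyntheticScenario`;
the truth (node states, regimes, planted vectors) is always emitted.

What passing recovery tests shows: the estimators recover planted effects
of realistic size at realistic n under the model they assume. What it does
not show: robustness to model violations real skulls bring — non-Brownian
evolution, correlated measurement error, digitization bias between views,
unbalanced and non-random taxon sampling, or regime shifts that are
gradual (OU-like) rather than fixed vectors. The generator's fixed-vector
shifts were chosen for analytic transparency; convergence power against
OU-style attraction will differ.

## Problem sizes and defaults

Default permutation/simulation counts: 10,000 (allometry), 999 (K,
heterochrony, trajectory), 1000 (convergence and phylogenetic MANOVA
nulls). The benchmark study uses 300 species, 20 2D landmarks, 5 habitat
classes; calibration experiments in the test suite use 50–200 replicates
at 32–128 tips, sizes at which the simulation-based checks are stable
while the whole suite stays inside a routine desktop run.

## Known limitations

No sliding semilandmarks, missing-landmark estimation, or bilateral
symmetry decomposition; no between-group or phylogenetic PCA; no
Ornstein–Uhlenbeck model fitting or rate-shift inference; the convergence
module implements the distance-based C1–C4 only (no frequency-based C5 or
Wheatsheaf index); ecology prediction is shape→habitat discriminant
analysis, not a habitat-evolution model; 2D and 3D datasets are analysed
independently, with no landmark transfer between them. The synthetic
template is 2D; all analysis modules accept 3D data.
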