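# Methods

This note documents the models, conventions and design choices behind the
package, in the order of the analysis chain.

## Receptor atlas

Tracer maps for the same receptor are combined by z-scoring each map
across regions, averaging with weights proportional to study sample size,
and re-z-scoring; absolute binding values from different studies are not
commensurate, and every downstream computation consumes z-scores anyway.
A warning is raised if two maps for the same receptor correlate below 0.5.
All z-scores use the sample standard deviation (ddof = 1); this makes
test expectations exact and is asserted (mean 0, sd 1 within 1e-9) by the
`ReceptorAtlas` container.

**Receptor similarity** is the Pearson correlation between two regions'
receptor fingerprints (rows of the z-scored matrix). A region with a
zero-variance fingerprint is an error, never silently dropped. The
similarity matrix is symmetrized, clipped to [−1, 1] and has unit
diagonal. Similarity is invariant to any per-receptor affine rescaling
applied before assembly, and equivariant under region permutation (both
property-tested).

**Distance decay** fits sim = a·exp(−b·d) + c on upper-triangle pairs by
nonlinear least squares with b bounded at 0, initialized from a
log-linear regression of the min-shifted similarity (shift ε = 1e-3).
The three-parameter form with offset is used because an exponential
decay to a non-zero baseline is the empirically typical shape.

**Principal gradient**: PC1 scores of the column-centered matrix via SVD.
The SVD sign ambiguity is fixed by requiring the sum of the PC1 loadings
to be positive. Variance-explained fractions are s²ₖ/Σs².

**Age regression** (sensitivity analysis): for each region separately,
the p receptor densities are regressed on the p source-study mean ages
(OLS with intercept) and replaced by residuals; columns are then
re-z-scored. Residuals are exactly orthogonal to the age vector per
region. Note that in-sample OLS removes a 2-degree-of-freedom projection
per region, so even age-independent data lose ≈ 2/p of each fingerprint's
variance; with 19 receptors the residuals correlate ≈ 0.95 with the
originals, not arbitrarily close to 1.

## Null models

**Spin ensembles.** One rotation, uniform on SO(3)
(`scipy.spatial.transform.Rotation.random`), is drawn per repetition and
applied to the left hemisphere's spherical coordinates; the right
hemisphere receives the mirror conjugate M·R·M (M = diag(−1, 1, 1)), the
standard choice that keeps rotations hemisphere-symmetric. Each original
parcel takes the value of the nearest rotated parcel of its own
hemisphere (ties to the lowest index); if the rotated medial-wall marker
is nearest, the next-nearest actual parcel is used. Assignments are
nearest-neighbour reassignments, not permutations — duplicates are
expected and preserved. The identity rotation reproduces the input
exactly (tested). P-values use (1 + k)/(1 + N), never zero, with the
two-tailed variant comparing absolute deviations from the null mean.

For datasets without full cortical coverage the spin test is
inapplicable; a plain label permutation is the appropriate fallback and
`label_contrast_test` accepts any externally generated assignment matrix
for that purpose.

**Rewired connectomes.** Edges are binned by Euclidean length into
equal-count bins (default 10; equal-count avoids sparse long-distance
bins). Within a bin, random edge pairs (a,b), (c,d) are swapped to
(a,d), (c,b). A swap is accepted only if it creates no self-loop or
duplicate edge **and both new edges fall in the same length bin** — the
last condition is this package's strictness choice: plain within-bin
swapping only approximately preserves the length distribution, whereas
the accepted-swap rule makes density, binary degree sequence and per-bin
edge counts exact invariants, asserted per null. Weights travel with
their edges. Swap attempts default to 10× the edge count; with the
bin-stay rejection this relocates roughly a quarter of edges per null,
which the calibration tests show is sufficient mixing. Bins with fewer
than two edges are skipped with a log notice.

**FDR**: Benjamini–Hochberg step-up (statsmodels), default q = 0.05.

## Structure–function coupling

Communicability of the weighted structural connectome is
exp(S^(−1/2) A S^(−1/2)) with S the diagonal strength matrix — the
strength-normalized form, since plain exp(A) diverges with weight scale.
Per region i, FC[i, j≠i] is regressed on communicability[i, j≠i]
(intercept always included; the diagonal is a structural zero, not
data); coupling is the adjusted R² with n−1 observations and one
predictor. The receptor-informed model adds similarity[i, j≠i]; its
one-sided p-value is the fraction of null augmented adjusted R² (from
spun similarity rows) at or above the observed, per the convention of
testing the augmented model's fit rather than ΔR². Near-collinear second
predictors (determinant below 1e-12 of its scale) fall back to the
base-model fit, so a duplicated predictor can never appear to add
variance. Shortest-path length and Euclidean distance are available as
alternative structural predictors behind the same interface.

## Multilinear models, dominance, distance CV

OLS with intercept; adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1).
Rank-deficient designs are an error that names the collinear columns.
Spin significance refits the model on spun targets (spinning y rather
than X: equivalent for model fit under row reassignment, and cheaper)
and is one-sided on adjusted R², with batch BH-FDR across maps.

**Dominance analysis** enumerates the R² of all 2^p − 1 submodels from a
single precomputed (p × p) cross-product matrix of the centered data,
solving all same-size subsets in one batched call; p = 19 takes about
1.5 s at n = 100. Total dominance of predictor i averages, over subset
sizes k = 0..p−1, the mean incremental R² of adding i to same-size
subsets without i. The sum of total dominances equals the **unadjusted**
full-model R² exactly — this identity is asserted in the result
constructor. The common phrasing that dominance parts sum to the
adjusted R² is loose: the identity only holds for R², so percent
contributions are emitted under both normalizations (`percent`, which
sums to 100, and `percent_adj`, normalized by adjusted R² for
comparability across models of different fit). Optional class
aggregation reports mean percent per receptor class.

**Distance-dependent CV**: each region serves once as source; the
⌈0.75·n⌉ regions nearest the source (source included — including it
keeps the split a clean 75/25 partition) train the model, the rest test
it. The out-of-sample statistic is the Pearson correlation between
predicted and observed test values (not R²). The optional null repeats
the whole procedure on spun targets and compares the mean test
correlation one-sided.

## PLS correlation

SVD of the cross-covariance XᵀY/(n − 1) of the two z-scored blocks
(covariance and correlation coincide for standardized columns). Latent
variable k carries orthonormal weights, a singular value sₖ, and
covariance explained s²ₖ/Σs²ₖ. Scores are data projections; loadings are
Pearson correlations between original columns and scores. The sign of
each LV is fixed so its receptor score correlates positively with the
regional mean receptor density. Significance spins the receptor block's
rows and compares singular values one-sided — no Procrustes alignment of
null singular vectors, since only the singular value is tested.
Distance CV fits the decomposition on training rows (test rows are
centered by training means before projection — the standard choice) and
records the train/test LV1 score correlations; only LV1 is propagated to
scores and loadings by default.

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
validated; its defaults are fixed and recorded as ground truth.

- **Geometry.** Each hemisphere is a quasi-uniform Fibonacci lattice on
  its own full sphere of radius 70 mm (the scale of surface-based
  spherical projections of one hemisphere), centers at x = ±70 mm,
  touching at the origin; the right hemisphere mirrors the left; a small
  seeded angular jitter (sd 0.08 rad about the x axis, independent per
  hemisphere) breaks lattice regularity. Full-sphere coverage per
  hemisphere matters: if parcels covered only a half-sphere cap, random
  rotations would strand many parcels far from any rotated parcel,
  nearest-parcel reassignment would duplicate heavily, and the spin test
  would lose calibration. With this geometry the empirical type-I error
  of the spin test at α = 0.05 is ≈ 0.05–0.06 and within-hemisphere
  spatial autocorrelation of spun maps matches the original within a few
  percent (the cross-hemisphere component is scrambled by construction —
  rotations are hemisphere-separate; that is inherent to the method, so
  preservation is measured within hemispheres).
- **Fields.** Spatially autocorrelated maps are draws from a zero-mean
  Gaussian field with covariance σ²·exp(−d/λ) over centroid distances,
  λ = 20 mm by default; the covariance is symmetrized and jittered by
  1e-10·trace/n on the diagonal before Cholesky factorization.
- **Receptor atlas.** p receptor maps are random mixtures of k latent
  fields plus independent noise, z-scored per receptor; the planted
  gradient (leading left singular vector of the noiseless mixture),
  latent maps and mixing weights are recorded. Gradient-recovery
  conditions use k = 1, noise sd 0.2. Dominance-recovery conditions use
  k = p and noise sd 4.0 — receptors then share a weak low-rank gradient
  (mean pairwise |r| ≈ 0.12) but are mostly receptor-specific, because
  with near-collinear receptors a planted "active set" is not
  identifiable by any importance decomposition.
- **Connectomes.** SC edges are drawn without replacement with
  probability ∝ exp(−d/30 mm) (Gumbel top-k) until the target density;
  weights uniform on (0.1, 1], strictly positive as required by the
  strength normalization. FC is planted as
  z(communicability) + β·z(similarity) + symmetric Gaussian noise, where
  z standardizes off-diagonal entries, so β is the known receptor
  contribution the augmentation analysis must recover. A disconnected SC
  is a logged warning, not an error.
- **Target maps.** Weighted sums of a declared active receptor subset
  plus Gaussian noise scaled to a requested signal-to-noise ratio.
  Active weights have random sign and magnitude uniform on [0.5, 1.5] —
  bounded away from zero, since an "active" receptor with a
  near-zero weight is de facto inactive and no method could rank it.
- **Paired term matrix.** Each term is latent_corr·(±u) plus
  √(1 − latent_corr²) × independent spatially autocorrelated noise,
  where u is the atlas's z-scored PC1; columns re-z-scored. latent_corr
  = 1 yields a rank-one cross-covariance; latent_corr = 0 yields
  independent blocks.
- **Seeding.** Every generator is bit-identical under its seed;
  `spawn_seeds` fans a global seed into independent substreams.

What the generator does **not** emulate: cortical folding and geodesic
distances, laminar structure, realistic receptor covariance (real
receptor maps share broad gradients far more strongly than the
dominance-recovery condition assumes), subcortex, hemispheric asymmetry,
measurement artifacts of PET/MRI/MEG, and connectome weight
distributions beyond uniform. Passing tests therefore demonstrate that
the machinery is correct and calibrated under its stated assumptions,
not that real-data effect sizes will match.

## Problem sizes and numerics

Validation runs use 100 regions, 19 receptors, 500–1000 permutations,
100 rewired nulls, and 20–500 repetitions per calibration — sizes at
which each stage finishes in seconds to a couple of minutes on one CPU
while keeping Monte-Carlo error well inside the asserted bands.
Degenerate inputs (zero-variance columns or fingerprints, isolated
nodes, constant distances, singleton classes, empty active sets,
rank-deficient designs) raise informative errors rather than propagate
NaNs; the few deliberate NaN outputs (zero-variance loading columns,
zero-variance coupling predictors) are documented flags. Text output is
written with 12 significant digits so write-then-read round trips are
stable to 1e-12.

## Known limitations

- The spin test at parcel resolution is only approximately exchangeable;
  its small residual miscalibration (empirically ≲ 1 percentage point at
  α = 0.05 under these conditions) is a property of the method class.
- Length-binned rewiring with the exact bin-stay rule mixes more slowly
  than unconstrained swapping; very sparse or very small bins limit
  randomization (skipped bins are logged).
- Full-subset dominance is exponential in p and guarded at p ≤ 20.
- The PLS distance-CV null repeats the full CV per permutation and is
  the slowest path in the package; its default permutation count (1000)
  can be lowered for exploratory runs.
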