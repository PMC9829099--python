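# Methods

## The representational model

A region's condition-by-condition similarity structure is modeled as a
linear mixture of idealized components. For participant *i* and cell *c* of
the vectorized 6 × 6 condition similarity matrix (21 upper-triangle cells,
Fisher-z units),

    y_ic = β₀ + Σₖ βₖ · POI_k[c] + ε_ic,

where each POI is a prespecified {−1, 0, +1} matrix describing perfect
coding of one information type. The model is deliberately coarse — binary
rather than graded similarity — which keeps each β interpretable as the mean
Fisher-z similarity difference attributable to that component. POI
regressors are used unscaled and uncentered for the same reason.

Participants' 21-cell vectors are stacked into one regression (`n = 21·N`
observations) rather than fitted per participant and averaged. This is the
convention the hold-out degrees of freedom pin down: a 7-participant
hold-out yields a denominator df of 7·21 − 2 = 145 in the validation
regression, which is only consistent with stacking.

## From voxels to similarity

1. Per trial, a voxel-wise vector of regression coefficients (one β map per
   trial event; 36 events in the default design).
2. Pairwise Pearson correlation across voxels between all trial vectors
   (plain Pearson, no prewhitening, no spatial smoothing assumed upstream).
3. Fisher z-transform at the trial level, clamped at |r| = 1 − 1e−7
   (z ≈ 8.4) so degenerate perfectly-correlated pairs stay finite.
4. Condensation to 6 × 6: within-condition cells average the 30 ordered
   same-condition pairs excluding the self-pair diagonal (identical to the
   mean of the 15 unordered pairs); between-condition cells average the full
   36-pair cross block. Values remain on the z scale throughout; averaging
   is not back-transformed to r, since downstream modeling is linear in z.
5. Vectorization: row-major upper triangle including the diagonal. The
   diagonal (within-condition similarity) is retained as data, not forced to
   a constant, because several POIs (e.g. face identity) live on it.

Rows with non-finite values or zero variance are rejected rather than
imputed — silent imputation would change the similarity structure being
modeled.

## The POI library

Under the canonical condition order [P+1, P+2, P−, B+1, B+2, B−] the groups
are: P+ = pressure-paired, B+ = brush-paired, PT = {B+1, B+2, P−} (positive
relative to task context), NT = {P+1, P+2, B−}, Hi = P+ ∪ B+ (touch
stimulated), Lo = {P−, B−}. The 13 base POIs are ET (within-task), nST
(within Hi), ST (within P+, B+, Lo separately), AB and AP (single hedonic
touch types), TV (P+/B+ as opposite poles), PE and NE (contextual valence),
AV (PT/NT as opposite poles; no zero cells), Sa (Hi/Lo as opposite poles; no
zero cells), FS (face identity; diagonal only), VE (the rare unpaired
outcome; within Lo including the cross-task cell), and TA (same-task
*different*-condition cells only — the diagonal is excluded because
within-condition averaging removes temporally adjacent pairs). Two
lateralized variants, rST and lST, group one hedonic touch type against all
remaining conditions as generic scanner touch, mirroring ST's grouping
logic; the inclusive reading (the opposite task's CS− belongs to the generic
group) is adopted. "AC" is accepted as an alias for AB.

Diagonal cells are included in a POI's support wherever its verbal
definition covers same-condition pairs, i.e. for every base POI except TA.
Libraries reject duplicate matrices, since two identical regressors make
every containing model rank deficient.

## Model search

BIC is computed in the Gaussian-likelihood form `n·ln(RSS/n) + p·ln(n)` with
p counting regressors, intercept, and the error variance. Only BIC
*differences* enter any decision, so any affine-consistent variant gives
identical selections. RSS is floored at 1e−12 to keep zero-noise fixtures
finite.

The greedy best-first search starts from the intercept-only baseline and
must beat it by ΔBIC > 2 before any POI is accepted — on null data the
selected set is empty. At each level, every remaining POI is fitted in
combination with the path's accepted set; the best candidate is accepted if
it improves the parent path's BIC by more than `delta_accept` (2), and every
other candidate within `delta_equiv` (2) of the level's best that also
passes the acceptance rule spawns an alternate path. Branching applies at
every level, including the first. Improvement is always tested against the
parent path's BIC, not the previous level's best candidate. Paths
terminating in an already-seen POI set are deduplicated by default and the
number of completed paths is reported as the n-path. Exact BIC ties (within
1e−9) resolve by library order for determinism. Rank-deficient candidate
sets (e.g. {PE, NE, AV}, which are collinear with the intercept) are skipped
with a dedicated error type when fitted directly.

Exhaustive best-subset enumeration is provided (`best_subset_search`) as a
verification oracle, not as the default: at 13 POIs it is ~8000 fits and
feasible, but the greedy search is the method under study.

## Cross-validation

Each Monte Carlo iteration draws `n_rs` participants uniformly without
replacement (defaults RS = 60, HO = 7 of a 67-participant cohort, 1000
iterations; iterations are independent and the whole procedure is a pure
function of the seed). The search runs on the RS stack; the selected POIs'
refitted weights build one group-level reconstructed vector, which is tiled
per hold-out participant and fitted with an intercept to the stacked
hold-out cells (simple regression: R², F(1, 21·n_ho − 2), p, slope).

Summaries report each POI's identification proportion, the chance threshold
mean(|selected set|)/|library|, mean weights only for POIs identified above
that threshold, mean n-path, and mean hold-out statistics. The across-ROI
n-path comparison is a fixed-effects one-way ANOVA on raw per-iteration
n-path values plus all pairwise two-sample t tests with Bonferroni
adjustment min(1, p·n_pairs); all-constant input returns F = 0, p = 1 rather
than NaN.

## Synthetic data

The similarity-level generator draws each participant's 21-cell vector as
the target mixture plus iid Gaussian cell noise — exactly the model the
decomposition assumes, so it tests the machinery, not robustness to model
misspecification. Defaults (67 participants, weights nST = 0.12, ET = 0.06,
intercept 0.05, noise SD 0.02) emulate a realistic cohort: the weight
magnitudes and hold-out R² they produce are of the order seen for dominant
somatosensory components in group RSA data.

The voxel-level generator expands the condition-level target to a 36 × 36
trial matrix via the trial-to-condition map, repairs it to the nearest
positive semidefinite matrix by clipping negative eigenvalues at zero (the
deviation introduced is reported on the dataset so tests can bound it), and
draws each voxel's trial profile independently from
N(0, shared_var·PSD + noise_var·I). Profiles are mean-zero, so the Pearson
similarity of the resulting patterns approximates the normalized target
covariance. What the generator does **not** emulate: temporal
autocorrelation, scanner drift, spatially correlated noise, hemodynamic
convolution, participant heterogeneity in weights. Passing recovery tests
therefore demonstrates correctness of the estimator under its own
assumptions, not performance on real fMRI noise.

## Problem sizes and numerical choices

Tests and the acceptance script run the search at N = 60–67 participants
(its natural scale), cross-validation at 100 iterations rather than 1000
(summary definitions are unchanged; 100 Bernoulli trials bound an
identification-proportion estimate to within ~5 points), and the
brute-force cross-check over all 2¹³ subsets once. Law-of-large-numbers
checks use N = 5000 participants with a 3σ/√N band; the voxel covariance
convergence check uses 20 000 voxels with a 0.05 max-abs band.

## Known limitations

- The standard library is design-specific; other designs get the generic
  `build_poi` constructor only.
- No random-effects inference on β across participants; the stacked fit
  treats cells as exchangeable observations.
- Greedy search can miss the global best subset on adversarial data; the
  equivalency branching mitigates but does not eliminate this.
- NIfTI ingestion assumes mask and data share a voxel grid; no resampling.
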