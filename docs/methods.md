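# Methods

This note documents the statistical procedures implemented in `fconn`,
the choices made where the underlying methodology is genuinely open, and
what the synthetic benchmarks do and do not establish.

## Connectivity construction

Per-subject connectivity is the Pearson correlation matrix of the
parcel-averaged BOLD series, computed on the raw averaged series: no
detrending, band-pass filtering, nuisance regression or scrubbing is
applied between parcellation and correlation.  This is deliberate and
prominent — users whose preprocessing conventions differ should filter
upstream.  A constant region series is a hard error naming the region;
silent NaNs would contaminate every downstream stage.  Region order is
ascending atlas index everywhere; all vectors and matrices share it.

The packaged region table (`fconn/data/aal3_synthetic.csv`) lists the 166
regions of the AAL3 parcellation in standard consecutive order.  Its MNI
centroid columns are synthetic placeholders, suitable for exercising the
export formats and the optional distance-based adjacency mode, not for
anatomical localisation; the load-bearing content is the ordering, which
defines the cluster test's neighbourhood structure.

## Weighted network measures

Node strength, eigenvector centrality and the weighted clustering
coefficient are computed on a weight matrix derived from the correlations
by a *weight policy*.  The default policy takes absolute values, because
the clustering coefficient's triple product and the Perron–Frobenius
argument that makes the leading eigenvector nonnegative and unique both
presuppose nonnegative weights; a `positive_only` policy (negatives
zeroed) and a `raw` policy (for sensitivity analyses; clustering refuses
it when negatives are present) are available, and the policy used is
recorded in every result.  The diagonal is always zeroed first —
otherwise every strength would be inflated by exactly the unit
self-correlation.

Numerical conventions worth knowing:

* The clustering coefficient's double sum over ordered neighbour pairs
  equals `diag(W³)` once the diagonal is zero; nodes with total weight
  `l_i ≤ 1` (nonpositive denominator) are assigned 0.
* Centrality is the unit-norm leading eigenvector with global sign fixed
  so its entries sum nonnegative.  A leading eigenvalue with multiplicity
  > 1 within 1e-10 (relative) is an error, never a silent tie-break —
  it arises only on structured matrices (e.g. disconnected identical
  components), not on empirical correlation matrices.
* Network means are arithmetic means over nodes.  The per-node sums are
  recoverable by multiplying by N.

## Edge-wise inference

Each upper-triangle edge is modelled as
`edge ~ intercept + covariates + group`, where the covariates are
dummy-coded diagnosis subgroups (e.g. the MDD/bipolar split within the
patient group).  Dummy columns are pruned greedily to keep the design
full rank — the full set of patient subtype dummies sums to the group
indicator and would otherwise make the contrast inestimable.  The
group-contrast t gets a permutation p-value by Freedman–Lane residual
permutation: residuals of the reduced (no-group) model are permuted,
added back to the reduced fit, and the full-model t recomputed; the
p-value is the add-one estimator `(1 + #{|t*| ≥ |t|}) / (1 + n_perm)`,
so p ≥ 1/(n_perm + 1) always.  Benjamini–Hochberg FDR is applied across
all edges and the mask thresholded at the chosen alpha.  Defaults are the
study-scale parameters (alpha 1e-4, 100,000 permutations); suites and
examples use desk scales (500–5,000 permutations), which matters because
the attainable BH-adjusted minimum is `n_edges/(n_perm + 1)` — at small
permutation counts the FDR step is conservative by construction.

The test is two-sided by default; a one-sided (controls > patients)
alternative is available since published tables in this literature often
report only that direction.

Demographics helpers follow the conventions that reproduce standard
cohort tables: Pearson chi-square without continuity correction (verified
against published 2×2 statistics to three decimals), the asymptotic
two-sample Kolmogorov–Smirnov test, and a one-sample KS normality check
with plug-in mean/SD.  Plug-in parameters (not Lilliefors-corrected
critical values) make that last test conservative about rejecting
normality; it is a screening device, not a calibrated test.

## Cluster-based permutation test

Per node, a pooled-variance two-sample t; nodes with |t| above the
two-sided critical value at the cluster-forming alpha (default 0.05) are
segmented into maximal sign-homogeneous runs of *consecutive atlas
indices*.  This 1-D reading of "anatomical neighbourhood" matches how
atlas orderings place anatomically adjacent regions at adjacent indices,
and published node clusters in this literature are exactly such
consecutive blocks.  The cluster statistic is the mass (sum of member t);
the null is the maximum |mass| over group-label permutations with the
same clustering rule, pooled over both signs — so the reported p-values
control family-wise error across positive (controls higher) and negative
(patients higher) clusters jointly.  Mass was chosen over size or max-t
as the statistic; it rewards both extent and effect strength.  An
optional adjacency-matrix mode (e.g. MNI centroid distance threshold)
replaces runs by connected components for atlases without a meaningful
index order.

A deliberate regression test documents that the ordering semantics are
real: scrambling the node order destroys detection of planted contiguous
effects.

## Specific networks

For each sign, the network keeps the union of that sign's significant
cluster nodes and the FDR-significant edges with both endpoints inside
the set.  Hubs are ranked by within-network degree with atlas-index
tie-break — an explicit operationalisation of the qualitative "main hub"
language common in this literature.  BrainNet Viewer export writes
`.node` files (x, y, z, colour = sign code, size = degree, label) and
dense symmetric `.edge` matrices; both parse back losslessly.

## Classification

LDA with the pooled within-class covariance inverted by pseudo-inverse
("pseudolinear"): with class means μ_k, priors π_k and pooled covariance
S, scores are `x'S⁺μ_k − ½μ_k'S⁺μ_k + log π_k` and posteriors their
softmax.  The pseudo-inverse is realised through the economy SVD of the
within-class centred data matrix, so fitting is O(n²p) and rank-deficient
feature sets (p ≫ n, duplicated columns) are handled exactly; predictions
are invariant to column duplication, and on well-conditioned data the
model matches scikit-learn's SVD-based LDA.

Cross-validation is repeated stratified k-fold (k = 10 by default) with
fold assignment reshuffled per repeat from a seeded stream.  "Repeated"
is the reading adopted for a repeated nested-CV protocol when the
classifier has no hyperparameters to tune in an inner loop.  Accuracy is
summarised as mean ± SD *across repeats*; sensitivity, specificity and
precision come from the confusion matrix pooled over all out-of-fold
predictions with "depression" as the positive class (a documented
convention, configurable in principle); the ROC pools out-of-fold
discriminant scores across folds and repeats rather than averaging
per-fold curves.  Priors default to empirical class proportions.

The `significant_fc` variant carries a leakage hazard: selecting the edge
mask from the full sample before cross-validating biases accuracy upward.
By default the pipeline recomputes the mask inside each training fold (at
a reduced permutation count); a `sig_fc_fixed_mask` flag instead fixes
the whole-sample mask, reproducing the simpler design some studies use,
with the caveat that its accuracy is optimistic.  When a training fold
yields no significant edges, the selector falls back to the top 1 % of
edges by permutation p so the variant stays defined.

## Synthetic cohorts

The generator emulates the study conditions the pipeline targets: 166
regions, 192 timepoints (TR 2 s), 49 controls vs 41 patients with an
internal 35/6 MDD/bipolar patient split.  Baseline dependence is a
rank-4 factor model whose first factor has uniformly positive loadings
(0.4–0.8) plus region-specific noise, rescaled to a correlation matrix —
this yields the positive-dominant, moderate correlation level typical of
parcel-averaged BOLD.  Group effects are planted on disjoint contiguous
blocks: within a *hypo* block patient correlations are scaled by
`1 − δ`; within a *hyper* block moved to `min(1, r(1+δ))`; the result is
projected to the nearest PSD correlation matrix (eigenvalue clipping,
diagonal rescale).  Defaults plant two hypo blocks (occipital-like, atlas
47–54, and vermis-like, 109–113, δ = 0.6) and one hyper block
(orbitofrontal-like, 21–28, δ = 0.5), mirroring the direction and
location of the group contrasts this analysis is designed to detect.

Between-subject variability comes from a Wishart perturbation of the
group correlation (500 degrees of freedom by default, giving entrywise
subject-to-subject SD ≈ 0.05); temporal structure is AR(1) smoothing
(coefficient 0.3) of Gaussian innovations, parameterised so the
stationary cross-sectional covariance equals the subject covariance
exactly.  Per-subject streams spawn from a single `SeedSequence`, so a
cohort is bit-reproducible from its spec.

What the generator does *not* model: haemodynamic convolution, voxel
noise, motion and physiological artefacts, non-Gaussian tails, and any
empirically calibrated between-subject variance (no per-subject variance
statistics exist to calibrate against — the Wishart dof is set only to
make the permutation tests non-degenerate).  Passing tests therefore
establish the correctness and calibration of the *procedures* (type-I
error, power against planted effects, chance-level classification,
determinism), not the empirical effect sizes or accuracies attainable on
real scans, which additionally reflect preprocessing and physiology this
generator does not imitate.  A known behaviour worth noting: because all
subjects share one factor structure, edge-wise t-statistics are
positively correlated across edges, so cohort-level summaries of null
t-fields fluctuate more than edge-count heuristics suggest.

## Benchmark problem sizes

The test suites run at desk scale, chosen once: permutation tests at
10–30 nodes with 300–5,000 permutations, cluster type-I calibration over
400 null replicates (30 nodes, 20+20 subjects, 2,000 permutations),
power checks over 100 replicates, classification suites at 2–100 CV
repeats, and the chance-level benchmark on a 90-subject null cohort with
24-region strength features and 100 repeats of 10-fold CV.  The
single-planted-edge FDR benchmark uses 10 nodes with 5,000 permutations
because the attainable BH minimum `n_edges/(n_perm+1)` must fall below
the 0.01 threshold for the recovery question to be well-posed.
Study-scale defaults remain on the library and CLI surfaces.
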