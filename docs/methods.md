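# Methods

This note documents the models, defaults and numerical choices behind
`omicsfuse`, and what the synthetic-data tests do and do not demonstrate.

## The classification protocol

All predictive models are developed inside a fixed protocol on a
train/test (TR/TS) split. The training split undergoes a repeated
stratified cross-validation (default 10 repeats × 5 folds = 50 splits).
Within each split:

1. features are ranked on the split's training part only — by absolute
   linear-SVM weight or random-forest Gini importance ("native" to the
   classifier) or by the classifier-independent one-way ANOVA F score
   ("kbest");
2. the classifier is retrained on the top *k* features for every grid
   point *k* ∈ {5, 10, 25, 50, 75, 100, 500, 1000, 5000, 10000, NF}
   (points above the feature count NF are dropped, NF itself is appended);
3. the Matthews correlation coefficient (MCC) is recorded on the held-out
   fold.

The 50 rankings are merged by the Borda count (each feature earns
`L − position` points per list with 1-based positions; score totals are
position-based, so heterogeneous score scales cannot bias the merge). The
signature size is the grid point with the best mean CV MCC; ties go to the
smaller *k*, favoring compact signatures. The final model is retrained on
the full training split restricted to the signature and evaluated once on
the test split.

Classifier defaults: linear SVM with C = 1; random forest with 500 trees.
Neither is tuned inside the protocol; both are exposed in the
configuration and recorded in run manifests. The rarer class is treated as
"positive" for the confusion table; MCC is invariant to this choice.

**Interval on the CV estimate.** The mean CV MCC is reported with a
2.5–97.5 percentile bootstrap interval over the 50 split values (1000
seeded resamples). The interval construction is a repository convention
and is labeled as such in outputs.

**Random-label check.** Rerunning the protocol on permuted training
labels (class counts preserved) yields a null distribution of best-CV-MCC
values. Because the selected value is a maximum over grid points it is
slightly optimistic even under the null; the check asserts that the null
distribution sits near zero and that the true-label score lies outside its
95% range, not that the null mean is exactly zero.

## Preprocessing

Features containing any missing value are removed from the whole layer
before splitting (missingness is a property of the assay, not of the
split). The near-zero-variance filter is then fitted on the training rows
only and applied to both sides: a feature is dropped when the ratio of its
most common value's count to the second most common value's count exceeds
19 (= 95/5) **and** the percentage of distinct values is at most 10;
constant features are always dropped. These are the conventional defaults
of this filter as implemented in caret's `nearZeroVar`, and the test suite
cross-checks the flags against that implementation through `Rscript`.
Filtering happens per layer, before juxtaposition.

## Integration strategies

*juxt* concatenates two layers column-wise, aligned by sample id. Feature
ids are prefixed with their layer tag, so layer membership survives
concatenation; this is what makes the mixedness statistic computable.

*Similarity Network Fusion.* Each layer's training samples become a
patient-similarity network: squared Euclidean distances are passed through
a scaled exponential kernel whose bandwidth for a pair (i, j) is
`μ · (m_i + m_j + d²_ij)/3`, with `m_i` the mean squared distance of
sample i to its k nearest neighbors (defaults k = 20 capped at n−1,
μ = 0.5, the cited method's recommended ranges). Identical samples (zero
distance and possibly zero bandwidth) get similarity 1. Fusion runs t = 20
cross-diffusion steps: each layer's full row-normalized similarity P
(off-diagonal mass 1/2 per row, diagonal fixed at 1/2) is updated as
`S · P_other · Sᵀ` with S the row-stochastic k-NN kernel, renormalized and
symmetrized; the fused network is the average of the two diffused
matrices. With t = 0 the fusion degenerates to the average of the
normalized inputs. On an exactly block-structured network whose k-NN
neighborhood covers each block, the update is an exact fixed point — the
property the fusion tests exploit; on generic networks diffusion moves the
matrix slightly away from its input while sharpening structure shared by
both layers.

*rSNF ranking.* The fused network is clustered by normalized spectral
clustering (symmetric normalized Laplacian, k smallest eigenvectors,
row-normalized, K-means); the cluster count is either given or chosen in
2–5 by the eigen-gap heuristic. Each feature of the juxtaposed training
matrix is then scored by the normalized mutual information between the
fused partition and the partition induced by that feature alone (a
one-dimensional affinity built with the same kernel, spectrally clustered
at the same k). The exact ranking rule behind "fused-network clustering"
is not pinned down by its originating description; NMI-against-the-fused-
partition is this package's documented interpretation, isolated in a
single function so it can be swapped. Per-feature clustering replaces
histogram binning for continuous features.

*INF.* The protocol runs once on the juxtaposed matrix with an ordinary
ranking and once with the rSNF ordering supplied as a fixed external
ranking (computed once on the full training split; the protocol then only
evaluates grid points, no Borda step). The two signatures are intersected;
if the intersection has at least 5 features the protocol runs a third time
restricted to it (grid truncated at the intersection size), otherwise the
run is recorded as `failed_small_intersection` — a status, not an
exception. Structurally `|INF| ≤ min(|juxt|, |rSNF|)`.

**Evaluation.** ΔMCC = max(MCC of juxt, rSNF, INF) − max(MCC of the two
single layers), computed identically in CV and validation; a failed INF
run simply drops out of the first maximum. Prop50 is the percentage of an
integrated feature set contributed by its minority layer (0–50). Two
similarity scenarios compare INF against another approach: scenario 1 when
MCC (or the signature size) is equal; scenario 2 when the MCC difference
is within 0.1 in magnitude. Equality on floats uses a 1e−9 tolerance.
Feature-set-size distributions are compared with the two-sided Wilcoxon
rank-sum test (exact null for tie-free samples up to n = 25 per group,
normal approximation with tie correction otherwise).

## Autoencoder branch

A mirrored fully-connected autoencoder is trained on the min-max-scaled
(training-fitted scaler, range (0,1) or (−1,1)) juxtaposed training
matrix: encoder depths 1–3, decoder mirrored, activations per weight layer
from {tanh, softsign, relu}, ADADELTA (ρ = 0.95, ε = 1e−6) on the
mean-squared-error objective, batch size 71 (capped at n), 2500 epochs by
default, optional L1 activity penalty on the bottleneck. The default
architecture is the two-layer layout with activations softsign, softsign,
softsign, relu and (0,1) scaling — the winner of the architecture grid on
(final loss, test cosine distance). Penalties of 1e−6 and above tend to
destabilize training; a diverging run aborts with a diagnostic (inside the
grid search it is caught, flagged and ranked last).

Open architectural details are fixed as follows: the bottleneck defaults
to 1% of the input features (ceiling, at least 2) for depths 1–2 and to 64
for depth 3; hidden widths between input and bottleneck are geometric
interpolations, recorded in the spec manifest. Reconstruction quality is
the per-sample mean cosine distance between the scaled original and its
reconstruction (0 = perfect, bounded by 2; zero-norm rows are skipped with
a warning; a flattened-matrix variant exists behind a flag).

## Survival screening and stratification

Each bottleneck meta-feature (standardized by default; the flag is
recorded) is fitted in a univariate Cox proportional-hazards model. The
solver is a Newton iteration on the partial likelihood, vectorized over
meta-features, with the Breslow convention for tied event times and steps
clipped to ±5 to survive monotone-likelihood columns (non-convergence is
flagged). The reported p-value is the score test at β = 0 — identical to
the two-sample log-rank test for a binary covariate, which is the sense in
which the screen is a "log-rank" screen. The test suite cross-checks
coefficients against lifelines (tie-free) and against R
`coxph(ties="breslow")` (tied), and the score p against the log-rank test.
Benjamini–Hochberg adjustment runs across the bottleneck; adjusted
p < 0.05 selects the significant set.

K-means (50 restarts, seeded) clusters patients on the selected
meta-features for k = 2…6; the k with the best mean Euclidean Silhouette
wins. Groups are named G1, G2, … by decreasing size with centroid
coordinates breaking ties, so naming is independent of sample order.
TR and TS are clustered independently, and TS group names are aligned to
TR by nearest centroids. Kaplan–Meier curves (product-limit estimator via
lifelines) and the log-rank test compare the groups, and the G1/G2 labels
can be fed back to the classification protocol as a derived endpoint.

## Synthetic data

The generator draws the latent class (balanced) and the latent survival
group first, then builds each layer from blocks: class-informative
features (`effect_size · (±1/2) +` noise with a configurable shared-noise
correlation), survival-informative features (same construction on the
survival latent), pure noise, and injected near-zero-variance columns.
Inter-layer redundancy copies the first `overlap_informative` informative
features of layer 1 into layer 2 with fresh noise. Survival times are
exponential with a group-dependent hazard (ratio as designed); censoring
is independent exponential with its rate solved by bisection to hit the
designed censoring fraction. Missing values are injected one cell per
affected feature. The TR/TS split is stratified on the class label.
Defaults (145 samples, 500 features per layer, 20 informative with 10
overlapping, effect 1.5 sd, two survival groups at hazard ratio 3 with 30%
censoring) mirror the matched two-platform cohort scale the toolkit
targets.

What the generator does not emulate: count-distributed RNA-Seq data
(inputs are modeled as already log-scale continuous), segment-level
copy-number structure, batch effects, and non-proportional hazards.
Passing tests therefore demonstrate correctness of the algorithms and of
the leakage discipline under the stated statistical model, not performance
on any real cohort.

## Test and reporting problem sizes

The test suite exercises the protocol at desk scale: the recovery fixture
uses 100 samples × 200 features per layer with 10 planted features at a
2-sd shift, the fusion fixtures use 30–45 samples, and the end-to-end
autoencoder chain uses 150 samples × 60 features per layer over 20 seeded
replicates. The recovery fixture plants *independent* informative features
(no shared noise): with redundant planted features a 5-feature subset is
genuinely optimal and the protocol's compactness preference correctly
selects it, which would measure the tie-break, not recovery. The
acceptance script runs the same two scenarios (integration at n = 100,
autoencoder branch at n = 300 so the TR-only screen has stable power) with
every random stream derived from the single `--seed` argument via hashed
stage seeds, so adding a stage never shifts another stage's stream.

## Known limitations

- Fusion is implemented for exactly two layers (pairs are the unit of
  integration throughout).
- The rSNF score is one documented interpretation of ranking by
  fused-network clustering; alternatives (e.g. Laplacian scores) would
  slot into the same interface.
- The Cox screen is univariate by design; no multivariate adjustment,
  time-varying covariates or competing risks.
- The autoencoder is CPU-oriented; at tens of thousands of features the
  stated defaults are computationally demanding, and the 1% bottleneck
  fraction rather than any fixed unit count governs the architecture.
- Endpoints are binary; multi-class MCC is out of scope.
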