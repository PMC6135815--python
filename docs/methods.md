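# Methods

This note documents the statistical procedures the package implements,
the tunable parameters that matter, what the synthetic-cohort generator
does and does not emulate, and the numerical choices made where the
design was genuinely open.

## Responder stratification from app ratings

Raw ratings are 0–10 VAS values with server timestamps, nominally two
per day. Cleaning applies one rule: scanning in time order, an entry
arriving within 30 minutes of the previously retained candidate
*replaces* it, so a chain of closely spaced entries collapses to its
final member — the subject's last word on their pain at that moment.
Nothing else is altered: missed ratings are left as gaps, never
interpolated or resampled, so the temporal structure of the series is
intact. Period labels come from the six visit dates: entry at time t
belongs to the half-open interval [V_k, V_{k+1}); entries outside
[V_1, V_6) are dropped with a logged count.

The stratification test compares baseline ratings with each treatment
period's ratings using the pooled-variance two-sample t. The null is
built by randomly re-assigning the pooled ratings to the two periods
(default 10,000 resamples); the two-sided Monte-Carlo p uses the
(b+1)/(n_perm+1) correction, with ties counting as exceeding —
both choices keep the estimate conservative and bounded away from 0.
A subject is a Responder iff at least one treatment period has p below
the cutoff (default 0.05) **and** a treatment mean below the baseline
mean; a significant *increase* in pain never qualifies. Because a
subject has two chances (T1, T2) at a two-sided level with a direction
gate, the per-subject null responder rate is ≈ 1 − (1 − α/2)² ≈ 4.9%
at α = 0.05, which the type-I calibration test verifies empirically
(≤ 5% plus Monte-Carlo error on 200 stationary null subjects).
Whether the original analysis used pooled or Welch t is not
determinable; pooled is the default, Welch is available via
`welch=True`. Per-subject permutation seeds derive from a stable hash
of the subject id, so results never depend on subject order.

The magnitude of response is the larger of the two drops
mean(BL) − mean(last week of T_k), where "last week" means the final 7
calendar days of the period, all retained entries included; %analgesia
divides by the baseline mean. Note that taking the maximum of two noisy
period estimates biases the measured %analgesia of labelled responders
upward by a few points relative to the generative plateau; this is a
property of the estimand, not an implementation artifact.

## Questionnaire screen

Subscales are scored generically: if more than 20% of a subscale's items
are missing the subscale is not scored; otherwise missing items take the
mean of the answered items *within that subscale* before aggregation.
Normalisation is leakage-safe by construction: z-scoring statistics are
fit on a designated training set and applied unchanged to held-out
subjects. The univariate screen first drops subjects beyond 3 SD on
magnitude (single pass — mean and SD are computed once, never
re-iterated after exclusion), then per subscale runs a two-sample t
between responder groups (the group test is configurable; the original
report does not name it) and a Pearson correlation with %analgesia.
Significance is Bonferroni-corrected at α/m with m = 37 by default —
the published correction count — even though 38 subscales exist; both
are exposed.

## Network statistics

Connectivity is the Pearson correlation of ROI-averaged time courses
(272 nodes in the full parcellation: 264 parcels plus 8 added limbic
ROIs); constant-signal nodes raise an error naming the node. Fisher
z = atanh(r) is applied off-diagonal with the diagonal set to 0; |r| = 1
is clipped to 1 − 1e-7 with a warning. Restricting to a node mask keeps
the induced submatrix; the 122 nodes of interest give 122·121/2 = 7381
edges.

Consensus communities: Louvain is run `reps_per_subject` times (default
100) on every subject's network; the agreement matrix records, for each
node pair, the fraction of all partitions co-assigning them (63 subjects
× 100 repetitions = 6300 partitions at study scale). Final modules are
the connected components of the agreement graph thresholded at 0.5 —
connected components are the simplest deterministic reading of
"thresholding", and singleton components are allowed and logged.
The Louvain resolution parameter defaults to 1.0 and is exposed. The
Louvain implementation (networkx `louvain_communities`) requires
nonnegative weights, so negative correlations are clipped to 0 for
community detection only, with the clip count logged.

The edgewise test computes a pooled two-sample t per edge on Fisher-z
weights, with the *same* label shuffles applied to every edge so that
cross-edge dependence survives into the null. Because each edge's
statistic has the identical null distribution (same group sizes
everywhere), permuted statistics are pooled across edges before
estimating p, giving a resolution of 1/(n_perm · n_edges):
p = (#{pooled |t_perm| ≥ |t_obs|} + 1)/(n_perm·m + 1). This matters:
per-edge counting floors p at 1/n_perm, and across 7381 edges
Benjamini–Hochberg then either has no power at all (with the add-one
correction, min q ≈ m/n_perm ≫ 0.05 even at 5000 permutations) or
spuriously zeroes out null edges (without it, ~m/n_perm edges hit p = 0
by chance). The pooled estimator was verified empirically: 0 false
flags across null repetitions and full detection of a planted
0.3-z edge at 40 subjects/group. `pooled=False` restores per-edge
counting with the add-one correction, the estimator that matches each
edge's own exhaustively enumerated (conditional) permutation p at small
n — the pooled and per-edge p differ by a few percent there because
they estimate the unconditional and conditional null respectively.
FDR control is Benjamini–Hochberg (not BY); q is reported clamped to
q ≥ p.

Subcortical asymmetry is (NAc_R + AMY_R + HIP_R)/(NAc_L + AMY_L + HIP_L);
1 = perfect symmetry. Group contrasts adjust for peripheral gray matter
volume, age and sex by OLS residualisation before the test.

## Prediction

Both learners sit inside the same nested leave-one-out scheme: the outer
loop holds out one subject; everything learned — feature scaling
(z-scores from training-fold statistics only), selected features,
hyperparameters, weights — comes from the remaining n−1. The inner loop
is 10-fold, stratified by class for classification and by outcome
quantile for regression, seeded and deterministic.

- SVM: RBF kernel; box constraint C and kernel coefficient γ each tuned
  over 7 log-spaced points in [1e-3, 1e3] (the original report gives no
  grid; this is a standard default, fixed in config). The first minimum
  of inner error wins ties.
- LASSO: features pass a robust-regression screen first — per feature, a
  simple regression of outcome on feature by IRLS with Tukey bisquare
  weights (tuning constant 4.685, MAD scale), keeping slope p < 0.001.
  The IRLS is vectorised across features (thousands of edges per fold);
  its slopes agree with statsmodels RLM, which serves as the reference
  implementation in the tests. The slope's standard error uses the
  weighted-least-squares formula with the robust scale and a t(n−2)
  reference — adequate for screening, not for exact inference. λ is then
  tuned by inner 10-fold CV over 100 log-spaced values below the
  training λ_max, minimum mean error (not 1-SE). A fold whose screen
  returns nothing predicts the training mean, logged.

Accuracy, sensitivity and specificity carry exact Clopper–Pearson
(beta-quantile) 95% intervals. The accuracy null repeats the entire
nested procedure on randomly scrambled labels (default 1000 draws);
z = (acc − mean_null)/sd_null with significance at z > 1.96. Consensus
weights average each feature's fitted weight over all outer folds
(never-selected = 0) and record selection frequency; features above the
reporting threshold (default 0.84, i.e. ≥ 37 of 43 folds) are flagged.

One caveat documented deliberately: on pure-noise data the out-of-fold
prediction–outcome correlation is close to −1, not 0, because folds
that shrink every weight predict the training mean, and under
leave-one-out the training mean is perfectly anti-correlated with the
held-out value. Negative r therefore means "no skill"; claims of skill
require r to exceed the scrambled-label null, which is how the tests
and the null calibration frame it.

Cross-model comparison reports the Pearson correlation between two
prediction vectors and a joint two-predictor OLS of the actual outcome
on both (each coefficient's t and p, joint R²); differences between
correlations across independent groups use Fisher r-to-z:
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)).

## Blinding

Decoy labelings are uniform random permutations of the real label
vector, so class counts are preserved exactly (cell scrambling rather
than Bernoulli relabeling — this keeps group-size-dependent power
identical across codes). The real code's position among the three is
randomized and sealed with a SHA-256 checksum over codes, index and
seed; `reveal` verifies the checksum and is idempotent. The seal is
procedural, not cryptographic.

## Synthetic cohorts

The generator emulates the trial design: 43 PTx / 20 NoTx subjects,
period lengths BL = 14 d, T1 = 14 d, W1 = 7 d, T2 = 14 d, W2 = 7 d,
ratings at 9:00/21:00 jittered ±2 h, 10% missingness, ratings truncated
to [0, 10] after noise. Responders follow a step trajectory: baseline
mean (6.10 ± 1.2 between subjects) dropping by the subject's %analgesia
(33 ± 8% across responders) from one day after each treatment start,
with full retention through washouts (the reported analgesia is
constant across treatment and washout periods). NoTx responders carry
the same improvement — the no-treatment arm's 20% response rate models
real natural-history change, not type-I error — while non-responders
have no systematic change at all. Within-subject noise is white by
default (the within-subject autocorrelation of real app ratings is
unknown); an AR(1) coefficient is exposed.

Questionnaire subscales use a Gaussian copula on the subjects' true
%analgesia: a planted subscale with correlation ρ is
ρ·z + √(1−ρ²)·ε on the standardised analgesia. Connectivity matrices
are empirical correlations of multivariate-normal pseudo time series
(default 150 samples) drawn from a group-level population correlation:
a latent-factor base (5 factors + diagonal noise, normalised), planted
edges offset in Fisher-z space for responders (non-persistent edges
only at the pre-treatment visit), then an eigenvalue-clipping
nearest-correlation projection. Every subject matrix is therefore
symmetric, unit-diagonal and positive semi-definite by construction,
with realistic sampling variability. Volumes get a multiplicative
rightward shift (default ratio offset 0.05) in responders, with
age/sex/peripheral-GM covariates.

What the generator does **not** emulate: image-space data, head motion,
physiological noise, non-stationary rating drift, item-level
questionnaire structure, missing-not-at-random patterns, or the
empirical covariance of real subscales. Passing tests therefore show
that the *procedures* behave correctly under known truth — calibration,
power, leakage-freedom, parameter recovery — not that any particular
effect exists in real patients.

`study_conditions()` bundles the reported design and effect magnitudes
into one parameter set: six subscales correlated 0.45–0.60 with
analgesia, and three group-dependent edges (one stronger in responders,
two weaker, one of those transient), all among the 122 network nodes.

## Problem sizes

Default problem sizes in the tests and the acceptance script are chosen
to keep full runs in the minutes range on a single CPU: stratification
at the published 10,000 resamples; the edgewise screen at the published
5,000 permutations on the full 7381 edges for single runs, 400–500 for
repeated power/FDR simulations; Louvain consensus at the full 6300
partitions on small block networks; the scrambled-label accuracy null at
25 draws with a reduced grid in the acceptance script (the library
default remains 1000). Where a simulation is repeated, Monte-Carlo error
bounds in the assertions account for the repetition count.

## Degenerate inputs and tie-breaks

Zero-variance pooled ratings give p = 1 by convention; zero pooled SD
makes the effect size undefined (error); constant subscales are flagged
untestable; constant ROI signals raise with the node named; |r| = 1 is
clipped before atanh; zero-SD outlier screening keeps everything;
SVM inner-grid ties resolve to the first minimum in grid order;
empty LASSO selections predict the training mean; a tampered blinding
key fails its checksum.
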