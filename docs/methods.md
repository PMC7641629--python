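# Methods

## Connectivity features

Each subject contributes a T×P table of region time series. Features are
the Fisher-z Pearson correlations z_ij = atanh(r_ij) of all region pairs,
flattened in row-major upper-triangle order (1,2), (1,3), …, (1,P),
(2,3), … into a length-E vector, E = P(P−1)/2. Conventions: correlations
are clamped to |r| ≤ 0.999999 before atanh so degenerate (collinear)
pairs stay finite; the diagonal is stored as zero and never enters the
feature set; a constant region is a hard error rather than a silent NaN.
Region ids are 1-based in all reports, 0-based internally; the edge
order is fixed and round-trips losslessly with the matrix form.

Subjects whose mean framewise displacement exceeds 0.2 mm are excluded
before any analysis. The boundary is kept (strictly "greater than"
discards), since motion thresholds of this form are conventionally
stated as exceedances.

## mRMR with the mutual-information quotient

Selection scores candidates by relevance over redundancy:

    score(f) = I(f; c) / mean_{s ∈ S} I(f; s)

with I the plug-in mutual information (natural log) on discretised
features and S the already-selected set. The first feature is the pure
relevance maximiser and its recorded score *is* I(f; c); a redundancy
term does not exist yet, and dividing by a machine-epsilon guard would
make the first score meaningless. The denominator uses the mean over S
(classical MIQ); a sum variant is configurable and only rescales scores
within a step, not the ranking at that step. A 1e-12 floor guards the
zero-redundancy case. All ties break to the lowest feature index, making
rankings fully deterministic.

Continuous edges are discretised per feature into three bins cut at
mean ± 0.5 sd (equal-frequency binning with n ≥ 2 bins is available).
Three coarse bins are the standard compromise for mRMR on continuous
data: enough resolution to register a group shift, few enough cells that
the plug-in estimate is stable at n ≈ 100 subjects.

**How many features?** The importance-score trajectory is cut
immediately before its largest relative single-step drop ("elbow").
Because the step-1 score lives on the relevance scale while later scores
are quotients, drops are only compared from step 2 onward. A
`drop_ratio` alternative (first step falling below a fixed fraction of
its predecessor) is available. The cut never returns 0 and never exceeds
the ranking length; an all-equal trajectory keeps everything and warns.

**Low-importance control.** The negative control uses the n edges with
the lowest single-feature relevance I(f; c). This is a deterministic,
linear-time proxy for the bottom of a full greedy ranking, which is not
meaningfully defined (greedy mRMR orders the top; running it to the
bottom of a 35k-edge list is quadratic and its tail order is dominated
by the redundancy denominator, not by importance).

## Nested cross-validation

Outer loop: stratified 10-fold partition of subjects (stratification is
necessary with unequal group sizes, otherwise inner splits can lose a
class). Within each outer training fold: mRMR ranking + drop cut, then
an inner stratified 10-fold grid search over the soft margin C
(2⁻⁵ … 2¹⁵ by powers of four) and the RBF kernel scale s
(√p × {¼, ½, 1, 2, 4}, gamma = 1/(2s²)), maximising inner accuracy with
ties to the smallest C then smallest s. Edges are z-scored with
training-fold statistics before the kernel (an RBF kernel is scale
sensitive; test folds reuse the training parameters). The underlying
quadratic-program solver is scikit-learn's SVC, treated as an
interchangeable engine with a behavioural contract (separable data →
zero training error at large C); decision scores are signed margins.

Nothing derived from a test fold enters selection, scaling or tuning;
the test suite asserts this by corrupting test-fold rows and checking
the fold's selections and hyperparameters are bit-identical.

The whole procedure is repeated over random outer partitions (default
100; the demo uses 5). Per repetition, metrics are fold-averaged
(mean ± sd); across repetitions mean ± sd are reported. The "optimal"
repetition — highest mean test accuracy, ties to higher AUC then earlier
seed — supplies the fold-wise selections for the consensus report:
edges selected in ≥ 9 of 10 outer folds, annotated with region/network
labels and the sign of the patient-minus-control mean z. Sensitivity is
defined on the patient class; AUC is the tie-averaged Mann–Whitney
statistic of the decision scores.

## Inter-subject similarity

Similarity between two subjects is the cosine distance
d = 1 − u·v/(‖u‖‖v‖) of their edge vectors on a feature subset; lower
distance = higher similarity, and all comparisons are stated on
distances. Within-group and between-group pair means are contrasted
with a two-sample t-test on the pooled pair distances (simple and
matching the conventional reporting style), with a subject-label
permutation test offered because pair distances sharing a subject are
not independent — the t-test's p is therefore approximate and the
permutation p is the conservative choice. The panel computes the same
contrast on all edges, on the mRMR subset computed from the complete
groups (no train/test split — this is a descriptive analysis, not an
accuracy claim), and on equal-sized random and lowest-relevance subsets.

## Confound screen

Consensus-edge values are screened against covariates: Pearson
correlation for continuous covariates (illness duration, symptom
scores within the patient group; mean FD across everyone), pooled-variance
t-tests for binary ones (medication flags within patients; sex across
everyone). Welch's test is a flag; the pooled default back-computes
published summary rows more closely. Benjamini–Hochberg FDR is applied
per covariate family across features (the natural family here: one
question per covariate). A summary-statistics t-test mode accepts
(mean, sd, n) per group so published demographic rows can be checked
without raw data. The two-proportion z-test is the pooled form, whose
z² equals the uncorrected chi-square on the 2×2 table.

## Synthetic cohort generator

The generator emulates the minimal structure the analysis assumes —
linear correlation features, group mean shifts, subject heterogeneity —
and nothing more.

* **Baseline.** A block correlation matrix over 8 networks: 0.3 within,
  0.1 between network. Subjects draw T i.i.d. Gaussian rows from their
  correlation matrix (Cholesky transform).
* **Shared signature.** In patients, a sparse planted edge set is
  shifted by ±effect_size (sign per edge, recorded as ground truth).
* **Heterogeneity.** When a subtype fraction is set, a second, disjoint
  edge set carries per-subject loadings w·het_effect with |w| ~
  |N(1, 0.4)| and sign fixed by subtype, so the two patient subtypes
  deviate in opposite directions around the control baseline. Disjoint
  *per-subtype* signature sets were considered and rejected: with them,
  every patient–control pair also differs on the subtype edges, so the
  between-group distance always exceeds the within-patient mixture and
  the characteristic before/after-selection similarity reversal cannot
  occur. Opposite-signed deviations on one set place controls between
  the subtypes, which produces it. Defaults (40 edges, effect 0.3) give
  the pre-selection pattern a clear margin at desk scale.
* **Subject jitter.** Off-diagonal N(0, σ_s²) noise on the latent matrix
  per subject, σ_s = 0.05 by default.
* **PD repair.** Any perturbed matrix is made strictly positive definite
  by eigenvalue clipping at 1e-6 and rescaling to unit diagonal —
  deterministic, and sign-preserving for small planted shifts.
* **Covariates.** Age ~ Normal and mean FD ~ Gamma with group-specific
  moments matching a typical two-group study (patients 37.2 ± 12.2 y,
  FD 0.090 ± 0.036 mm; controls 35.7 ± 8.9 y, 0.085 ± 0.038 mm); illness
  duration, YMRS, MADRS and three medication Bernoulli flags for
  patients; sex balanced by default with configurable group imbalance.
* **Reproducibility.** One integer seed drives everything through
  spawned generator streams; identical specs give byte-identical
  cohorts.

What the generator does **not** model: autocorrelated/hemodynamic noise,
motion artefacts beyond a scalar FD covariate, non-Gaussian marginals,
site/scanner effects, or realistic network topology beyond the block
baseline. Passing tests therefore demonstrate that the machinery
recovers planted linear-correlation structure without leakage — not
that comparable accuracy would be reached on real clinical data.

## Problem sizes and numerical choices

Library defaults mirror the full study design (268 regions → 35,778
edges, 192+173 subjects, T=192, 10/10 folds, 100 repetitions). Tests,
demo and the acceptance script run the pipeline at desk scale — 60
regions (1,770 edges), 40–60 subjects per group, T=150, 5 repetitions,
a compact hyperparameter grid (C ∈ 2^{−3,1,5,9,13}, s/√p ∈ {½, 1, 2},
5 inner folds) and max_k=30 — the package's chosen sizes for fast,
deterministic validation; the full grid and scale remain available
through configuration. At desk scale the drop rule keeps only a few
edges per fold (the planted signal is strong and concentrated), so the
consensus report is read at a fold-majority threshold in the examples
while the pipeline default stays at 9 of 10.

Degenerate inputs are errors, not silences: constant regions, missing
FD, zero vectors in cosine distance, single-class folds, empty score
trajectories. Known limitations: the plug-in MI estimator is biased
upward at very small n (shared by all discretisation-based mRMR
implementations); the t-test on pair distances ignores pair dependence
(permutation alternative provided); the elbow cut is scale-dependent —
on weak, diffuse signals it keeps more features and its variance across
folds grows.
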