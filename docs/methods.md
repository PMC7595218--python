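# Methods

`cnvstrat` re-implements a deep-phenotyping analysis of unilateral choroidal
neovascularization (CNV): unsupervised discovery of two patient classes —
conventional AMD-type disease (older patients, thin choroid, soft drusen) and
pachychoroid neovasculopathy (PNV)-type disease (younger patients, thick
choroid, choroidal vascular hyperpermeability) — followed by a 7-parameter
logistic score that separates the classes, cutoff-based predictive-value
diagnostics, and regression of post-treatment visual-acuity change on the
score. Because the underlying clinical cohort is not publicly deposited, the
package ships a synthetic-cohort generator that reproduces the published
per-class summary statistics, and every stage is validated against it.

## Unsupervised stage

The baseline table holds 61 features per patient (continuous ocular
measurements in native units — micrometres, millimetres, logMAR — and binary
imaging/history flags). The pipeline is:

1. **Standardization** — each column is z-scored with its own mean and sample
   (n−1) standard deviation. Constant columns map to zero and are flagged
   rather than dropped, so matrix shapes stay aligned with the schema.
2. **PCA** — SVD of the centered matrix; loadings are the variance-ordered
   eigenvectors of the sample covariance. Rank is truncated where an
   eigenvalue falls below 1e−10 × the largest, so exact linear dependencies
   (e.g. a redundant encoding) drop out naturally; the retained count is
   reported, not hard-coded.
3. **Gap statistic** — for k = 1..k_max (default 10), the within-cluster
   dispersion W_k = Σ_r D_r/(2 n_r), with D_r the sum of pairwise squared
   Euclidean distances inside cluster r. This equals the within-cluster sum
   of squares about centroids, which is how it is computed; an unsquared
   ("plain") pairwise variant is available behind a flag. gap(k) =
   E*[log W_k] − log W_k, with the expectation estimated from B (default 100)
   reference datasets drawn uniformly over the bounding box of the data in
   PCA-rotated coordinates (an axis-aligned box is available). The reported
   error is s_k = sd(log W*_k)·√(1+1/B). Selection rules: `firstSEmax`
   (default) takes the smallest k whose gap is within one s of the first
   local maximum of the gap curve; `tibshirani2001` takes the smallest k with
   gap(k) ≥ gap(k+1) − s_{k+1}.
4. **k-means** — Lloyd iterations from k-means++ starts, best of n_restarts
   (default 25 for the final clustering) by inertia, convergence at relative
   inertia change < 1e−6 or 300 iterations; an empty cluster is re-seeded at
   the point farthest from its assigned centroid. The final clustering runs
   on *all* retained principal-component scores (variance-weighted, i.e. the
   raw scores of standardized features), at the gap-chosen k.
5. **Semantic labeling** — with k = 2 the cluster with the strictly larger
   mean fellow-eye subfoveal choroidal thickness (SFCT) is PNV-type; a tie
   raises an error rather than guessing.

A numerical point that matters: the data and reference dispersion curves
must be optimized equally hard. If the reference datasets get fewer k-means
restarts than the data, the reference curve carries a larger suboptimality
bias that grows with k, which inflates gap(k) at large k and can erase the
local maximum at the true k. Both curves therefore default to the same
restart count inside the gap computation (10); this was confirmed against
R's `cluster::clusGap` on identical inputs. The final clustering still uses
25 restarts.

Cluster comparison tables use the two-sided Wilcoxon rank-sum test for
continuous features and Fisher's exact test for binary features, matching
the source analysis.

## The CNV score

The score is a linear log-odds rule over seven predictors with fixed unit
scalings:

    score = −7.04 + 0.16·(age/10) + 0.52·sex + 1.99·CVH
            − 0.34·(RT_affected/100) + 1.37·(SFCT_affected/100)
            + 1.24·(SFCT_fellow/100) − 1.68·typeA_drusen

with sex coded male = 0 / female = 1, thicknesses in μm, and the binary
flags 0/1. Positive scores indicate PNV-type disease; the logistic transform
1/(1+e^(−score)) gives the class probability, and classification defaults to
threshold 0 (probability 0.5) — the canonical logistic decision point, since
the source does not state the threshold behind its reported accuracy.

The published constants are 2-decimal roundings of a fitted model. The
package reproduces the published high-score worked example to 3 decimals
(7.656) and the low-score example to within 0.05 (−7.978 printed vs −8.022
recomputed), the residual being exactly the double-rounding of the weights.

Score derivation on new data: an unstratified 3:1 train/validation split
(validation size = ⌈n/4⌉, so 537 → 402/135), maximum-likelihood logistic
regression (statsmodels Newton/IRLS) on the unit-scaled predictors, Wald
standard errors, 95% CIs with z = 1.959964, no regularization. Perfect
separation and collinear designs raise typed errors instead of returning
unusable fits. Weights are the coefficients rounded to a configurable number
of decimals (default 2, matching the published convention).

Evaluation: confusion counts at the threshold (PNV = positive class), ROC by
sweeping all observed scores, AUC by the trapezoid rule (equal to
Mann–Whitney concordance, which the tests assert). The predictive-value bin
table uses half-open bins on the published cutoffs (−3.610, −1.966, 0.697,
2.629; the printed "−1.967" lower bound of the third bin is treated as the
same boundary) and reports each bin's majority-direction predictive value —
AMD-type for bins centred below zero, PNV-type above — as percent to one
decimal, with empty bins undefined rather than zero.

## Outcome association

Follow-up logMAR at months 3 and 12 is completed by last observation carried
forward: any earlier post-baseline observation (scheduled or not) can be
carried; patients with no post-baseline visit are excluded, not imputed from
baseline. The change from baseline (negative = improvement) is regressed on
the score by OLS, optionally adjusting for age (raw years), sex (0/1) and
baseline logMAR, with t-based two-sided p-values. A negative score
coefficient reproduces the direction of the clinical finding: higher
(more PNV-like) scores predict greater visual-acuity improvement.

## Synthetic cohort generator

The generator draws a two-class mixture whose parameters are transcribed
from the published per-cluster summary table: 289 AMD-type and 248 PNV-type
patients; per-class means/SDs for age, logMAR, axial lengths, retinal
thickness and both SFCTs; per-class prevalences (count/class size) for sex,
CSC history, CVH, polypoidal lesions, pachyvessels, reduced tessellation,
pseudodrusen and drusen types A/B/C. Features without published per-class
parameters (fellow-eye logMAR, lesion size, smoking, other history flags,
and 33 auxiliary features padding the schema to 61) use neutral
distributions *shared across classes*, so class recovery cannot lean on
unpublished parameters.

Continuous features are truncated Gaussians in native units (rows violating
physiologic bounds are redrawn, preserving within-row correlation; e.g.
thicknesses cannot go negative). The affected/fellow SFCT pair is correlated
within class at r = 0.8, reflecting the near-identical per-class thickness
of the two eyes in the published table; this makes the pooled SFCT
distribution bimodal in both eyes, as observed clinically. All other
features are independent within class.

Follow-up simulation: visits at months 0/3/12; logMAR change drawn from a
class-specific Gaussian (defaults: AMD-type −0.02 at month 3 and −0.03 at
month 12; PNV-type −0.12 and −0.10; SD 0.20; 10% per-visit dropout). The
class means were chosen once so that, combined with the typical
between-class score separation, the implied per-score-unit slope is of the
order of the published outcome coefficient (≈ −0.01/score unit); the SD is a
realistic short-term logMAR variability under anti-VEGF treatment.

What the generator does *not* emulate: measurement error and grading
disagreement, correlations among most features (only the SFCT pair is
correlated), non-Gaussian skew of thickness distributions, treatment-regimen
dynamics, and any structure in the 33 auxiliary features. Passing recovery
tests therefore show that the pipeline machinery is correct under the
published marginal structure, not that the clinical result replicates.

## What the synthetic conditions can and cannot reach

Under the transcribed parameters the two classes are separated by ≈ 3.1
standardized units along the class-mean direction, so even a supervised
linear classifier with oracle labels tops out near 95–96% accuracy, and
unsupervised k-means recovery ranges ≈ 92–97% across cohort draws (≥ 95% on
the default cohort, which the tests assert). Likewise the gap statistic
selects k = 2 in 18 of 20 seeded cohort replicates; occasional selections of
a neighbouring k are Monte-Carlo flips of a gap curve whose local maxima
differ by less than one reference standard error. Cohort-scale published
numbers (validation accuracy 0.91, AUC 0.939, outcome slope −0.012, cluster
sizes 289/248, the score range) depend on the real data and are checked only
as synthetic analogues or sign/direction properties.

## Sizes and defaults used by the test suite

The full-size checks run on n = 537 cohorts with B = 100 reference datasets
and k = 1..10 (≈ 12 s per replicate with the compiled k-means core);
integration tests of the orchestration layer use reduced budgets (B = 25,
k_max = 5) since the full-size behaviour is covered once. Logistic-recovery
checks use 50 replicates at n = 5000; OLS and dispersion identities use
small random instances against brute-force oracles.
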