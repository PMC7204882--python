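# Methods

This note documents the statistical model behind `traceorigin`, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions a maintainer should know.

## Preprocessing

Bone concentrations are divided element-wise by the bird's Ca
concentration. Apatite (the mineral phase) exchanges cations readily
while collagen does not, and the mineral fraction grows with age, so
raw per-mass concentrations confound origin signal with ossification
state; the Ca ratio cancels this. Ratios are then z-scored per element.
The z-scoring statistics (mean, SD with the n−1 denominator) are part of
the trained library: birds of unknown origin are projected with the
*training* statistics, because the juvenile library defines the reference
frame. A pooled mode (z-scoring juveniles and problem birds together) is
available via `RunConfig.problem_zscore_mode="pooled"` and is used for
the all-birds clustering, where the tree mixes both groups. Missing or
below-detection values are rejected rather than imputed.

## MANOVA

One-way MANOVA across capture sites on the 20 standardized ratios.
Wilks' Λ = det(W)/det(W+B) is computed from log-determinants for
stability; significance uses Rao's F transform

    m = N − 1 − (p+k)/2,
    t = sqrt((p²(k−1)² − 4) / (p² + (k−1)² − 5))   (t = 1 if the denominator ≤ 0),
    df₁ = p(k−1),  df₂ = m·t − df₁/2 + 1,
    F = ((1 − Λ^{1/t})/Λ^{1/t}) · (df₂/df₁).

For the study design (p=20, k=10, N=105) this yields df = (180, 645.230).
A 1000-replicate null simulation (p=5, k=3, n=20/group) in the test suite
checks the empirical type-I error is 0.05 ± 0.02.

## Stepwise canonical discriminant analysis

Selection is greedy forward with backward removal. A candidate's partial
F to enter, with q variables already in the model, is

    F = ((N − k − q)/(k − 1)) · (1 − Λ_p)/Λ_p,   Λ_p = Λ(S∪{x})/Λ(S),

gated at F ≥ 3.84; among admissible candidates the one that most improves
the model criterion enters. Two criteria are provided: minimal model
Wilks' Λ, and maximal smallest pairwise Mahalanobis D² between group
centroids (the classical choice when many correlated variables compete,
and the default). After each entry, any included variable whose partial
F falls below 2.71 is removed (smallest first). Ties are broken by panel
order; collinear candidates that make the within-scatter singular are
skipped with a warning. The 3.84/2.71 gates are the conventional
defaults of the commercial implementations this workflow descends from.

Canonical functions come from the symmetric generalized eigenproblem
B·a = λ·W·a, with coefficients scaled so each score has pooled
within-group variance 1 (then squared Euclidean distance to a centroid in
score space *is* Mahalanobis D²) and signed so the largest-magnitude
coefficient of each function is positive. Functions with λ > 1 are
marked retained (at least one always is); all are reported, together with
canonical correlations, variance shares, residual Wilks Λ and Bartlett
χ² tests.

Classification is nearest-centroid in the retained canonical space with
equal priors (trapping effort, not abundance, set the sample sizes);
ties go to the first site in library order. Leave-one-out
cross-validation refits the canonical functions without each bird while
holding the selected variable set fixed, mirroring the "cross-validation"
of the original software lineage; nested re-selection per fold would give
a more honest error estimate but a different (and not comparable)
statistic. Press's Q = (N − nK)²/(N(K−1)) on the cross-validated correct
count tests whether classification beats chance (χ², 1 df).

## Origin assignment and immigrant detection

A problem bird's canonical scores f_j are divided by each site centroid:
ρ_{s,j} = f_j / c_{s,j}, so a bird at a centroid scores exactly 1
everywhere. Closeness to site s is the Euclidean distance of ρ_s from
the all-ones vector, and the bird is assigned to the argmin site.

Two numerical guards matter. First, centroid components smaller than
0.5 in magnitude are treated as undefined cells and dropped from that
site's closeness: canonical scores have within-group SD 1, so a centroid
closer to zero than half an SD is statistically indistinguishable from
zero and the ratio to it is noise amplification. Second, a Mahalanobis
variant (`method="mahalanobis"`) is provided because the ratio metric
down-weights deviations at sites with large-magnitude centroids and
inflates them at sites near zero; the two methods agree ≥95 % for birds
within 1 SD of a centroid, but for per-site contribution tables the
Mahalanobis closeness is the more reliable choice. This is a genuine
limitation of the centroid-ratio reading, documented rather than patched.

Immigrant/unassigned flagging: a bird whose smallest canonical-space D²
to any centroid exceeds the χ² quantile at 1−α (df = retained functions,
α = 0.05 by default) is deemed too far from every sampled source. For
*new* birds the within-score variance exceeds 1 (coefficient overfitting
at p_sel ≈ 10–14, N = 105, k = 10; empirically 1.3–1.7), so the cut
flags roughly 10–15 % of genuinely local problem birds rather than α.
Training birds are not affected (their score variance is exactly 1).
Users wanting a stricter cut can lower α; the default keeps the rule
simple and transparent.

## Clustering and multiscale-bootstrap support

Agglomeration exposes `ward.D` (Ward's Lance–Williams coefficients
applied to unsquared dissimilarities, the classic convention), `ward.D2`
and `average`, over Euclidean or correlation (1 − Pearson r) distances.
Internally scipy's implementation is used; `ward.D` is obtained exactly
by running the squared-convention algorithm on √d and squaring the
heights (a monotone transform, so merge order is unchanged); tests
verify equivalence against a naive Lance–Williams recomputation. Trees
can be cut at a height or into exactly k clusters, and exported to
Newick (ultrametric convention: node elevation = merge height / 2).

Clade support follows the multiscale bootstrap: for ten scales
r ∈ {0.5, …, 1.4}, B resamples of round(r·20) element columns are drawn
with replacement, reclustered, and each original clade's bootstrap
probability BP(r) recorded. BP values of 0/1 are clamped to 1/(2B),
1 − 1/(2B) (continuity correction) before the probit transform
ψ(r) = Φ⁻¹(1 − BP(r)), which is fitted as ψ(r) ≈ √r·v + c/√r by weighted
least squares with delta-method binomial weights; AU = 1 − Φ(v − c).
Clades seen in every replicate at every scale get AU = BP = 1; clades
never seen get AU = 0; both are flagged as saturated. Resampling
columns (elements) rather than rows is deliberate: the units of
bootstrap uncertainty are the measured variables, matching the
convention of the R package this procedure originates from. B defaults
to 1000 (tests and the acceptance script use 120–400 for speed; with 20
features the BP resolution, not B, is the limiting factor).

## Synthetic data generator

The generator emulates the study conditions: 10 sites named after the
real valley towns with juvenile sample sizes (20, 10, 10, 9, 9, 18, 10,
8, 6, 5) (n = 105), and 118 fall problem birds. Site mean vectors live
in log-ratio space on a one-dimensional "valley axis": site s has mean
base + δ·(t_s·u + j_s), where t_s is its position along the axis (spaced
like the real inter-site road distances, 0–190 km scaled to [0, 1]), u a
fixed unit direction in 20-element space, and j_s a small site-specific
off-axis jitter. Birds are exp(N(μ_s, σ²I)) ratios (concentrations are
positive and right-skewed) multiplied by a lognormal per-bird Ca
(mean 2.65·10⁵ µg/g, CV 0.10 — bone is ~26 % Ca).

Defaults δ = 10, jitter = 0.10, σ_within = 0.3 were calibrated once so
the synthetic library reproduces the *magnitude* of discrimination
reported for real starling bone data — LOO accuracy in the 65–88 % range
across seeds (real data: 79 %), roughly 9–15 elements selected (real:
10), 3–5 canonical functions with λ > 1 (real: 4) — with
misclassification concentrated among axis-neighbouring sites, as in the
field. δ = 0 collapses all sites to one distribution (chance-level
classification), and accuracy rises monotonically with δ.

Immigrants are drawn from virtual unsampled sites on the same geographic
gradient, displaced 10 pooled SDs beyond a sampled axis endpoint (each
with its own off-axis jitter). A uniformly random displacement direction
in the full 20-dimensional element space would be almost orthogonal to
the discriminant subspace — invisible to any assignment method and
chemically implausible, since unsampled sources vary along the same
element gradients the sampled ones do. When δ = 0 there is no gradient
and the displacement direction is uniform.

What the generator does **not** emulate: instrument noise and drift,
detection limits, element-element covariance structure beyond the shared
diagonal, temporal (year-to-year) signature change, age-related residual
variation in problem birds, and non-normal within-site heterogeneity.
Passing tests therefore demonstrate correctness and calibration of the
*procedure* under its own assumptions, not field-data performance.

## Numerical and design choices

- Determinism: all randomness flows from one integer seed; generator
  sub-streams are derived (seed, stream-id) pairs, and the bootstrap uses
  its own seeded generator. Identical config + seed ⇒ identical run
  report, byte for byte.
- Degenerate inputs: singular within-scatter raises; constant ratio
  columns raise at scaling; zero-variance rows raise under the
  correlation metric; a group reduced below 2 members during LOO is kept
  with its single row (with a warning).
- Eigen-decomposition uses the symmetric generalized solver (`eigh` with
  the within-scatter as the metric), which is stabler than forming W⁻¹B.
- Serialization is a single JSON document with row-major matrices and
  label arrays; floats round-trip at full precision.
- Problem sizes in tests: null calibration uses 1000 replicates at
  p=5/k=3/n=60; bootstrap tests use B = 120–200 with ≤ 15 features;
  LOO-heavy checks use the 105-bird design directly. These sizes give
  stable statistics at interactive runtimes.

## Known limitations

- The centroid-ratio closeness is scale-distorted (see above); per-site
  contribution tables should prefer the Mahalanobis method.
- The χ² immigrant cut is anti-conservative for new birds because
  canonical coefficients overfit at these sample sizes; a
  cross-validated or F-corrected threshold would be better calibrated
  but is not part of the classical workflow reproduced here.
- Stepwise selection inherits all the known instabilities of greedy
  subset selection; the exhaustive-oracle tests cover only small
  instances.
- With 20 features, column-bootstrap BP values are coarse; AU values for
  weakly supported clades carry substantial fitting noise.
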