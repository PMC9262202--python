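# Methods

## Model

The classifier seeks a hyperplane H = {x : aᵗx = b} separating two weighted
point sets X (n₁ × p) and Y (n₂ × p). Strict separation is encoded with a
unit margin: aᵗxᵢ ≥ b + 1 and aᵗyⱼ ≤ b − 1. The unit margin is not a
restriction — any strictly separating (c, d) can be rescaled into this form —
it simply fixes the scale of (a, b), which are otherwise determined only up
to a common positive multiple.

When the margin system is inconsistent, the fit minimises the separation
error f(a, b): the weighted sum of per-point violations max(b + 1 − aᵗxᵢ, 0)
and max(aᵗyⱼ − b + 1, 0). f is convex and piecewise linear; introducing one
slack variable per point turns its minimisation into a linear program with
p + 1 + n₁ + n₂ variables and n₁ + n₂ inequality rows. We deliberately do
not implement an LP algorithm: the problem is handed to HiGHS through
`scipy.optimize.linprog`, and the package's own contribution is the
formulation, the surrounding guarantees, and their verification.

Three structural facts shape the implementation:

* **Feasibility bound.** a = 0, b ∈ [−1, 1], u = (b+1)𝟙, v = (1−b)𝟙 is
  always feasible with objective exactly 2 (weights sum to one per group),
  so 0 ≤ v(P) ≤ 2 on every dataset. This is why the constructor renormalises
  raw weights to sum to one within each group.
* **Separability certificate.** v(P) = 0 exactly when the groups are
  strictly separable, and then the optimal (a, b) satisfies every margin
  constraint. `check_separability` applies this with an absolute tolerance
  (default 1e-8) because LP solvers return floating-point optima.
* **Existence of a discriminant.** If v(P) > 0 and the weighted centroids
  x̄ = Σmᵢxᵢ and ȳ = Σwⱼyⱼ differ, some optimal solution has a ≠ 0. The
  converse failure mode — the solver returning the useless a = 0 point — is
  handled explicitly, below.

### Degenerate optima

When the primary solve returns ‖a‖ ≤ tol, the fit first compares the
weighted centroids. If they coincide, no discriminant hyperplane is
guaranteed and a `DegenerateDataError` tells the user to inspect their data
(this is the documented failure on e.g. two groups that are mirror-symmetric
about the same centre). If the centroids differ, an a ≠ 0 optimum exists but
the solver happened to return another point of the optimal face; the fit
then (1) re-solves with the dual simplex to obtain a vertex solution, and if
that is still degenerate (2) solves a secondary LP maximising aᵗ(x̄ − ȳ)
over the optimal face (the original constraints plus objective ≤ v(P) + tol,
with aᵗ(x̄ − ȳ) capped at 1 to keep the face search bounded). Only if both
steps fail does the fit raise a solver error — correctness over convenience:
a silent a = 0 "hyperplane" would classify every point identically.

### Prediction

New points are assigned to the first group when aᵗx ≥ b and to the second
otherwise. The exact tie aᵗx = b is a measure-zero event; it goes to the
first (positive) group, a deterministic documented convention. No feature
standardisation happens inside the core fit: the LP is covariant under
positive scaling and invariant under translation (both property-tested), so
silent rescaling would only surprise users.

## PCA reduction for p ≫ n

With more variables than samples any two groups are linearly separable, so
the raw fit drives the training error to zero while generalising poorly. The
package fits the decomposition X = 1μᵗ + TPᵗ + E on the **pooled training
rows of both groups** — unsupervised, and never on prediction-time rows, so
no test information leaks into the subspace — and runs the LP on the scores
T. Prediction projects new points with the training μ and loadings first.

Numerical choices: the decomposition is computed by SVD of the centred
matrix (stable for p ≫ n; equivalence with the covariance
eigen-decomposition is asserted in tests against both a dense eigensolver
and scikit-learn); loadings get a deterministic sign (largest-magnitude
entry positive) so serialised models are reproducible; columns are always
centred and optionally unit-variance scaled (off by default — the
decomposition centres but does not scale). The component count q is either
given directly or chosen as the smallest count whose cumulative explained
variance reaches `var_threshold`; the default threshold is 0.9, a
conventional choice exposed as a parameter. In pairwise multi-group fits the
reduction is refit per pair on that pair's pooled rows, maximising pairwise
contrast.

## More than two groups

k groups are handled one-vs-one: all k(k−1)/2 pairwise hyperplanes are
fitted, each on only that pair's rows with equal within-group weights (or
user weights). A point receives one vote per pairwise model; the label with
most votes wins. Vote ties are broken by the larger sum of winning signed
margins (aᵗx − b)/‖a‖ over the tied labels' comparisons, then by label
order — the rule is deterministic and label-permutation invariant up to that
final documented tie-break. One-vs-rest fitting is intentionally out of
scope.

## Evaluation protocol

`confusion_stats` reports sensitivity tp/(tp+fn) on a designated positive
class, specificity tn/(tn+fp), and the overall error (fp+fn)/n.
`cross_validate` repeats, `n_reps` times: draw `n_test_per_group` rows per
group uniformly without replacement (stratified), fit on the remainder
(PCA refit per repetition on training rows only), record the test error.
Repetition-level RNG streams are spawned from the master seed
(`numpy.random.SeedSequence`), so any single repetition can be reproduced
independently. The interval around the mean error is a normal approximation
mean ± z·sd/√n clipped to [0, 1] — a deliberately simple, swappable choice;
with a single repetition it degenerates to a zero-width interval. Test-set
size is parameterised per group rather than in total.

## Synthetic data

The generators produce the three regimes the method is designed for, as
pure functions of a `GeneratorSpec` (the seed fully determines the output):

* `separable_lowdim` — two p = 2 Gaussian clusters, n = 20 per group,
  centroid distance 10 noise-sd units: strict separability with a wide
  margin, the regime where v(P) = 0 is expected.
* `overlapping_lowdim` — the same geometry at distance 2σ, n = 50 per
  group: visible overlap, Bayes error Φ(−1) ≈ 0.16.
* `unbalanced` — 10,000 samples with a 0.3% minority ("case") at distance
  3σ: per-class Bayes accuracy ≈ Φ(1.5) ≈ 0.93, so a well-balanced boundary
  detects most cases while an accuracy maximiser predicts "control"
  everywhere. These defaults are the package's standing study conditions for
  the unbalanced regime.
* `highdim_latent` — n = 30 per group, p = 500: scores on 4 latent factors
  (the groups shifted ±effect/2 on factor 1, default effect 3), mapped
  through a random Gaussian loading matrix (scale 1) plus independent unit
  noise. With these defaults roughly 80% of the variance is structured,
  emulating log-normalised expression data where the biology lives in a few
  components. Count-specific features of sequencing data (discreteness,
  mean–variance coupling) are deliberately not emulated: the classifier
  consumes normalised values, so a Gaussian latent-factor model on the
  log scale is the appropriate idealisation.

Multi-group data places k centroids on a regular simplex with all pairwise
distances equal to the requested effect size (requires p ≥ k − 1).

What passing tests on these generators shows — and does not. They verify the
optimisation, the guarantees, weighting behaviour and the PCA mechanism
under known ground truth. They do not establish performance on real data
with heavy tails, batch effects, count noise or label errors; the Gaussian
design is chosen precisely because its Bayes behaviour is known in closed
form.

## Problem sizes and numerical choices

Defaults: `tol = 1e-8` for both the "a is zero" and "v(P) is zero"
decisions; weights validated to sum to one within 1e-10 after
renormalisation. The test suite's heavier studies use 20 seeds × 10,000
samples for the unbalanced regime and 100 train/test repetitions at
n = 60, p = 500 for the overfitting study — sizes at which every
conclusion they assert is already stable across seeds.

## Known limitations

* The discriminant is linear; no kernels, soft-margin cost parameters or
  regularisation paths.
* Missing values are rejected, not imputed.
* The one-vs-one voting rule is a standard completion of pairwise fitting;
  other combination rules (e.g. margin-weighted voting throughout) are
  plausible and would change predictions only in contested regions.
* The CV confidence interval is a normal approximation; for very small
  repetition counts a bootstrap or exact binomial interval would be wider.
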