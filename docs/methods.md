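# Methods

## Model and procedure

`froghop` selects a compact gene subset for a binary classification task in
two phases.

**Filter phase (Relief).** Features are min–max rescaled to [0, 1] using
statistics from the rows being weighted (training rows only, in any
cross-validated context). Relief then performs a full deterministic pass
over the samples in a seed-shuffled order (m = n, sampling without
replacement): for each sample the single nearest hit and nearest miss are
found by Euclidean distance over *all* features (ties broken toward the
lowest sample index), and each feature accumulates
`diff(R, M) − diff(R, H)`, where `diff` is the absolute normalized
difference for continuous features and a 0/1 indicator for features flagged
discrete. The accumulated sums are divided by m once at the end — this is
algebraically identical to the textbook incremental update but makes the
result independent of visit order in floating point, which also makes it
exactly testable against a scalar-loop oracle.

**Wrapper phase (discrete SFLA with IWSSr refinement).** Each frog is a
duplicate-free feature subset. Initial frogs draw their size uniformly from
`init_frac_range × n_features` (clamped to `init_size_clamp`) and their
members by weighted sampling without replacement with probability
proportional to the shifted Relief weight `w′ = w − min(w) + 1e-6`; the
shift gives every feature a nonzero selection probability while preserving
the ordering. Every frog — at initialization, after every leap, and for the
random-replacement stage — is refined by IWSSr over *its own* features
ranked by symmetrical uncertainty: the scan accepts only strict fitness
improvements, preferring (on score ties among improving variants) fewer
features, then replacement over addition, then the earliest replacement
position. This bias produces compact subsets and makes the scan fully
deterministic given the evaluator's values.

The population loop deals the fitness-sorted population round-robin into
memplexes, samples submemplexes with the rank-probability law
`P_j = 2(n+1−j)/(n(n+1))` (sequential draws, renormalizing after each), and
improves the submemplex's worst frog in three gated stages: leap toward the
memplex best, leap toward the global best, then a fresh random frog; the
original frog survives unless a stage strictly improves on it. Leaps resize
by `S_b` (truncated toward zero, one uniform draw per leap, magnitude capped
at `s_max`), add features the guide frog has and the worst frog lacks
(high-weight favored), or remove the worst frog's own features (low-weight
favored, never emptying the frog). The best frog ever seen is tracked
elitistically (replaced only by strictly higher fitness, or equal fitness
with a smaller subset), so the best-fitness trace is non-decreasing by
construction.

**Fitness.** The balanced rate `(sensitivity + specificity)/2` of a
linear-kernel SVM (C = 1) under stratified internal CV on the training rows,
pooled over folds. Balanced rate rather than accuracy protects against the
unbalanced class counts typical of tumor cohorts. Fold assignment is fixed
per search, and subset evaluations are memoized by order-insensitive key, so
fitness is a pure deterministic function of the subset. An absent class's
term is defined as 0.

**External protocol.** Repeated stratified k-fold (default 10 repeats of
10-fold). Within each training split the entire pipeline — normalization
statistics, Relief weights, SU discretizer edges, the SFLA search — is
re-fitted from scratch; the held-out fold only ever meets the final trained
classifier. Confusion counts are pooled per repeat, metrics averaged over
repeats, and the subset size averaged over all splits (sizes differ across
splits; the modal subset is reported for interpretability).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `sfla_p` / `sfla_m` / `sfla_n` | 100 / 10 / 10 | population dealt into memplexes (`p = m·n`) |
| `sfla_q` | 4 | submemplex size |
| `it_max` / `it_mem` | 40 / 10 | outer iterations / submemplex rounds per memplex |
| `s_max` | 5 | max features changed per leap |
| `init_frac_range` | (0.25%, 2.5%) | initial frog size as a fraction of features, clamped to [2, 100] |
| `su_bins` | 10 | equal-frequency bins for SU discretization |
| `inner_cv_folds` | 5 | internal fitness CV folds |
| `svm_kernel`, `svm_c` | linear, 1.0 | wrapper classifier |
| `relief_m` | n_samples | Relief iterations (full pass) |

The population-shape defaults are the published configuration of this
search; the classifier, discretization and initialization settings are this
package's own choices (the underlying method statement specifies only "a
support vector machine" and "a random percentage of the features"), exposed
in `SFLAConfig` and the YAML config.

A single seed feeds named substreams (Relief order, evaluator folds,
initialization, submemplex sampling, leaps) via `SeedSequence.spawn`, so two
runs with the same seed produce byte-identical results and component tests
are independently reproducible.

## Synthetic data

The generator emulates two-class expression cohorts: labels drawn to a fixed
class balance (default 35% positive, n = 60); informative genes are
class-conditional Gaussians with a positive-class mean shift of
`effect_size` (default 2.0) within-class SDs; redundant genes are a randomly
chosen informative parent plus Gaussian noise (default SD 0.1, i.e. nearly
clones — the regime in which redundancy removal is testable); the remaining
genes are class-independent standard Gaussians; columns are then shuffled.
A `heavy_tailed` flag exponentiates the matrix for log-normal marginals
mimicking microarray skew.

What the generator does **not** model: probe-level artifacts, batch
effects, gene–gene correlation structure beyond parent–copy pairs, and
heteroscedastic noise. Passing recovery tests therefore show that the
search machinery finds planted independent-Gaussian signal; they do not
certify performance on real cohorts with correlated backgrounds.

`score_recovery` reports recall/precision strictly over the planted
informative columns plus the count of redundant genes selected together
with their parent. Because a redundant gene is a near-clone of its parent,
the package also provides `signal_recall`, which credits a selected copy to
its parent; this is the scientifically meaningful "did we find the signal"
number when clones are present.

## Numerical choices

- Min–max normalization: constant features map to 0; out-of-range test
  values clip to [0, 1].
- Eq-style SU uses the standard denominator `H(F) + H(C)` (the form with a
  difference in the denominator is degenerate for informative features and
  contradicts the [0, 1] codomain); the value is clipped to [0, 1] against
  ~1e-16 float residue. Equal-frequency bin edges are deduplicated, so
  low-cardinality features collapse to fewer bins.
- Rankings break ties deterministically: SU descending, then Relief
  descending, then feature index ascending. The "worst frog" is the lowest
  fitness, ties to the larger subset then the later position.
- `int(·)` in the leap-size rule truncates toward zero; `rand` is drawn
  once per leap.
- Degenerate inputs: removal leaps never empty a frog; a leap with nothing
  to add returns the frog unchanged (keeping its cached fitness); an
  internal CV fold count exceeding the minority class size is reduced to it.

## Known limitations

- **Fitness saturation on small cohorts.** With tens of training samples an
  internal-CV balanced rate of 1.0 is reachable with 2–4 informative
  features, and because both IWSSr and the frog-improvement stages require
  *strict* improvement, subsets stop growing there. Consequently the
  selected signature is compact (the method's goal) but recovers only a
  subset of all planted signal genes, and occasionally an internally
  perfect-scoring subset includes an overfit noise gene. The package's
  reduced recovery experiment (60 samples, 500 genes, 5 informative,
  seeds 1–5) measures mean strict informative recall 0.08 and
  parent-credited signal recall 0.40 at held-out balanced rate ≈ 0.91; runs
  frequently select redundant near-clones *instead of* their parents, which
  strict recall scores as zero even though the held-out balanced rate is
  1.0.
- **Single-neighbor Relief variance.** With k = 1 and hundreds of noise
  dimensions, nearest-neighbor distances concentrate and a planted gene's
  weight can drop out of the top decile for some data draws (2 of 5
  reference seeds), especially when an outlier inflates its min–max range.
  ReliefF-style k-neighbor averaging would reduce this but is deliberately
  out of scope.
- Only binary tasks are supported; multi-class labels are rejected.
- Test sizes used in the suite are scaled down (population 20, 10
  iterations, 3-fold internal CV for end-to-end runs; 10-feature instances
  for exhaustive wrapper enumeration), chosen so each experiment still
  exercises every stage of the search.
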