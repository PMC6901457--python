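# froghop

Hybrid filter–wrapper gene selection for binary-class, high-dimensional
expression matrices: **Relief** weighting (filter phase) followed by a
**discrete shuffled frog leaping** search over feature subsets whose frogs
are refined by the **IWSSr** incremental wrapper (wrapper phase), with a
linear-SVM balanced-rate fitness.

## Who this is for

Tumor/normal microarray and bulk expression cohorts typically have thousands
of genes and only tens of samples, so classifiers overfit badly unless the
gene set is cut down to a handful of relevant, non-redundant markers.
`froghop` is for analysts who want a compact, high-accuracy gene signature
from such a matrix, plus a leakage-free cross-validated estimate of its
quality.

## The method

1. **Filter — Relief.** Each gene gets a weight from a full pass over the
   (min–max normalized) samples: for each sample *R* find its nearest hit
   *H* (same class) and nearest miss *M* (other class) by Euclidean
   distance, and update
   `W[A] ← W[A] − diff(A, R, H)/m + diff(A, R, M)/m`.
   Genes that separate the classes while agreeing within a class accumulate
   positive weight.

2. **Wrapper — SFLA + IWSSr.** A population of `sfla_p` "frogs" (feature
   subsets, sampled with probability proportional to shifted Relief weight)
   is dealt round-robin by fitness rank into `sfla_m` memplexes. In each
   memplex, submemplexes of `sfla_q` frogs are drawn with rank probabilities
   `P_j = 2(sfla_n + 1 − j) / (sfla_n (sfla_n + 1))`,
   and the worst frog of the submemplex leaps toward the memplex best (then
   the global best, then a fresh random frog — each gated by strict fitness
   improvement). A leap resizes the frog by
   `S_b = min(int(rand·(SP_b − SP_w)), S_max)` (mirrored for shrinking),
   adding high-weight genes from the guide frog or dropping its own
   low-weight genes. Every new frog is re-refined by **IWSSr**: scan its
   genes in descending symmetrical-uncertainty (SU) order, trying both
   *replacing* each current member and *appending* the scanned gene, keeping
   strict improvements only — this is what removes redundant genes.

3. **Fitness and evaluation.** Fitness is the balanced rate
   `F = (TP/(TP+FN) + TN/(TN+FP)) / 2`
   of an internal stratified-CV linear SVM on training rows.  External
   quality comes from a repeated stratified k-fold protocol (default 10×10)
   in which weighting, normalization statistics and the entire search are
   re-fitted per training split.

## Worked example

Generate a synthetic 60 × 500 cohort (5 informative genes, 10 redundant
noisy copies, 35% positive class) and run a reduced search:

```sh
froghop synth --seed 7 --out cohort.csv --truth truth.json
froghop run --data cohort.csv --label-col class --config config.yaml --seed 7 --out out
```

with `config.yaml`:

```yaml
sfla_p: 20
sfla_m: 4
sfla_n: 5
sfla_q: 3
it_max: 10
it_mem: 3
inner_cv_folds: 3
```

Output (stderr log):

```
INFO running SFLA-IWSSr on 60 samples x 500 features (seed 7)
INFO best fitness 0.9524 with 3 features (1601 evaluations)
```

`out/selected_features.tsv` lists the signature — here `g223`, `g277`,
`g337` — and `out/trace.tsv` records the convergence:

```
iteration  mean_fitness  best_fitness  best_size  evals
0          0.662         0.810         4          401
1          0.728         0.905         3          498
...
9          0.797         0.952         3          1601
```

The best internal balanced rate climbs from 0.81 to 0.95 while the subset
stays at 3 genes.  Against the generator's ground truth, `g223` is a
planted informative gene and `g277` is a redundant copy of informative gene
`g67` — the search found the signal twice over, via the copy in one case —
while the mean population fitness rises quickly then flattens, the expected
convergence shape for this search.

Other entry points: `froghop weights` (Relief + SU table), `froghop iwssr`
(standalone wrapper over the top-SU genes), `froghop protocol`
(repeated-CV evaluation report).  The library mirrors the CLI:
`froghop.run`, `froghop.run_protocol`, `froghop.generate`, …

## Limitations

On very small cohorts the internal-CV fitness saturates, so subsets stop
growing after a few genes and near-identical redundant copies can stand in
for their parent genes; see `docs/methods.md` for the full discussion.
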