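"""Discrete shuffled frog leaping over feature subsets.

Each frog is a feature subset; its fitness is the internal-CV balanced rate
of a linear SVM trained on those features.  One outer iteration: sort the
population by fitness, deal it round-robin into memplexes, and within each
memplex repeatedly (a) sample a submemplex with rank-biased probabilities

    P_j = 2 (n + 1 - j) / (n (n + 1)),   j = 1..n,

(b) improve its worst frog (IWF): leap toward the memplex best, then toward
the global best, then fall back to a fresh random frog, each stage gated by
strict fitness improvement.  A leap resizes the worst frog by

    S_b = min(int(rand * (SP_b - SP_w)), S_max)   if SP_b > SP_w
        = max(int(rand * (SP_b - SP_w)), -S_max)  otherwise,

adding Relief-weight-favored features from the guide frog (or removing
low-weight features), after which the frog is re-refined by IWSSr over its
own features.  After all memplexes finish, the frogs are shuffled back
together and the process repeats for ``it_max`` iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data_io import ExpressionDataset, minmax_normalize
from .evaluation import ClassifierConfig
from .filter_weights import FeatureWeights, compute_feature_weights
from .wrapper_iwssr import SubsetEvaluator, iwssr, rank_features


@dataclass
class Frog:
    """A candidate solution: an ordered, duplicate-free feature subset."""

    features: tuple[int, ...]
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.features = tuple(int(j) for j in self.features)
        if len(self.features) == 0:
            raise ValueError("a frog must hold at least one feature")
        if len(set(self.features)) != len(self.features):
            raise ValueError("frog features must be duplicate-free")

    @property
    def size(self) -> int:
        return len(self.features)


@dataclass
class SFLAConfig:
    """All search hyperparameters.

    Defaults follow the published configuration: population 100 split into
    10 memplexes of 10, submemplexes of 4, 40 outer iterations with 10
    submemplex rounds each, and leap length capped at 5 features.
    """

    sfla_p: int = 100
    sfla_m: int = 10
    sfla_n: int = 10
    sfla_q: int = 4
    it_max: int = 40
    it_mem: int = 10
    s_max: int = 5
    #: fraction of n_features drawn for an initial frog, before clamping
    init_frac_range: tuple[float, float] = (0.0025, 0.025)
    #: hard clamp on initial frog size (features)
    init_size_clamp: tuple[int, int] = (2, 100)
    relief_m: int | None = None
    su_bins: int = 10
    inner_cv_folds: int = 5
    svm_kernel: str = "linear"
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"
    max_subset_size: int | None = None
    max_evals: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.sfla_p != self.sfla_m * self.sfla_n:
            raise ValueError("sfla_p must equal sfla_m * sfla_n")
        if not 1 <= self.sfla_q <= self.sfla_n:
            raise ValueError("sfla_q must lie in 1..sfla_n")
        if self.s_max < 1:
            raise ValueError("s_max must be at least 1")
        lo, hi = self.init_frac_range
        if not 0 < lo <= hi <= 1:
            raise ValueError("init_frac_range must satisfy 0 < low <= high <= 1")
        if self.it_max < 0 or self.it_mem < 1:
            raise ValueError("it_max must be >= 0 and it_mem >= 1")
        if self.su_bins < 2:
            raise ValueError("su_bins must be at least 2")
        if self.inner_cv_folds < 2:
            raise ValueError("inner_cv_folds must be at least 2")

    def with_seed(self, seed: int) -> "SFLAConfig":
        return replace(self, seed=seed)

    def classifier(self) -> ClassifierConfig:
        return ClassifierConfig(kernel=self.svm_kernel, C=self.svm_c, gamma=self.svm_gamma)


@dataclass
class TraceRow:
    iteration: int
    mean_fitness: float
    best_fitness: float
    best_size: int
    evals: int


@dataclass
class SelectionResult:
    best_frog: Frog
    trace: list[TraceRow]
    evals: int
    config: SFLAConfig
    seed: int
    truncated: bool = False

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return {
            "best_features": list(self.best_frog.features),
            "best_fitness": self.best_frog.fitness,
            "trace": [asdict(t) for t in self.trace],
            "evals": self.evals,
            "seed": self.seed,
            "truncated": self.truncated,
            "config": asdict(self.config),
        }


# ---------------------------------------------------------------------------
# population mechanics
# ---------------------------------------------------------------------------

def submemplex_probability(j: int, sfla_n: int) -> float:
    """Probability of picking the rank-j frog (1-based) into the submemplex."""
    if not 1 <= j <= sfla_n:
        raise ValueError(f"rank j={j} out of 1..{sfla_n}")
    return 2.0 * (sfla_n + 1 - j) / (sfla_n * (sfla_n + 1))


def _fitness_sort_key(item: tuple[int, Frog]):
    i, frog = item
    return (-frog.fitness, frog.size, i)


def sort_by_fitness(frogs: list[Frog]) -> list[Frog]:
    """Descending fitness; ties prefer the smaller subset, then earlier position."""
    return [f for _, f in sorted(enumerate(frogs), key=_fitness_sort_key)]


def partition_memplexes(population: list[Frog], config: SFLAConfig) -> list[list[Frog]]:
    """Round-robin deal of the fitness-sorted population into sfla_m memplexes."""
    if len(population) != config.sfla_p:
        raise ValueError("population size must equal sfla_p")
    if any(f.fitness is None for f in population):
        raise RuntimeError("all frogs must be evaluated before partitioning")
    ranked = sort_by_fitness(population)
    memplexes: list[list[Frog]] = [[] for _ in range(config.sfla_m)]
    for rank, frog in enumerate(ranked):
        memplexes[rank % config.sfla_m].append(frog)
    return memplexes

def sample_submemplex(memplex: list[Frog], sfla_q: int, rng: np.random.Generator) -> list[Frog]:
    """Draw sfla_q distinct frogs with rank-biased probabilities.

    The memplex must be sorted by descending fitness; probabilities are
    renormalized after each draw.  The sample is returned sorted by
    descending fitness.
    """
    n = len(memplex)
    if not 1 <= sfla_q <= n:
        raise ValueError("sfla_q must lie in 1..len(memplex)")
    probs = np.array([submemplex_probability(j, n) for j in range(1, n + 1)])
    remaining = list(range(n))
    picked: list[int] = []
    for _ in range(sfla_q):
        p = probs[remaining]
        p = p / p.sum()
        choice = remaining[int(rng.choice(len(remaining), p=p))]
        picked.append(choice)
        remaining.remove(choice)
    picked.sort()  # memplex is fitness-sorted, so index order = fitness order
    return [memplex[i] for i in picked]


def worst_of(frogs: list[Frog]) -> Frog:
    """Lowest fitness; ties prefer the larger subset, then the later position."""
    return min(
        enumerate(frogs), key=lambda item: (item[1].fitness, -item[1].size, -item[0])
    )[1]


# ---------------------------------------------------------------------------
# leaps
# ---------------------------------------------------------------------------

def leap_size(sp_b: int, sp_w: int, s_max: int, rng: np.random.Generator) -> int:
    """Signed number of features to add (+) or remove (-), capped at s_max.

    ``int(.)`` truncates toward zero; one uniform draw per leap.
    """
    if sp_b < 1 or sp_w < 1:
        raise ValueError("frog sizes must be at least 1")
    rand = float(rng.random())
    d = sp_b - sp_w
    if d > 0:
        return min(int(rand * d), s_max)
    return max(int(rand * d), -s_max)


def _weighted_draw(
    pool: list[int], weights: np.ndarray, k: int, rng: np.random.Generator
) -> list[int]:
    """k distinct indices from pool, probability proportional to weights[pool]."""
    pool = list(pool)
    out: list[int] = []
    for _ in range(min(k, len(pool))):
        w = weights[pool]
        p = w / w.sum()
        i = int(rng.choice(len(pool), p=p))
        out.append(pool.pop(i))
    return out


def leap_features(
    worst: Frog,
    better: Frog,
    s_b: int,
    weights: FeatureWeights,
    rng: np.random.Generator,
) -> Frog:
    """Edit the worst frog toward the better frog by |s_b| features.

    Positive s_b adds features the worst frog lacks, sampled from the better
    frog with high-weight features favored; negative s_b removes the worst
    frog's own features with LOW-weight features favored, never emptying it.
    An unchanged frog keeps its cached fitness.
    """
    w = weights.sampling_weights
    feats = list(worst.features)
    if s_b > 0:
        pool = [j for j in better.features if j not in worst.features]
        feats = feats + _weighted_draw(pool, w, s_b, rng)
    elif s_b < 0:
        k = min(-s_b, len(feats) - 1)  # keep at least one feature
        inv = 1.0 / w
        for j in _weighted_draw(feats, inv, k, rng):
            feats.remove(j)
    if tuple(feats) == worst.features:
        return Frog(worst.features, worst.fitness)
    return Frog(tuple(feats), None)


# ---------------------------------------------------------------------------
# search context and worst-frog improvement
# ---------------------------------------------------------------------------

@dataclass
class SearchContext:
    """Everything the improvement loop needs: weights, config, RNG substreams
    and the memoized evaluator-backed refinement function."""

    weights: FeatureWeights
    config: SFLAConfig
    evaluator: SubsetEvaluator
    rng_init: np.random.Generator
    rng_sub: np.random.Generator
    rng_leap: np.random.Generator
    n_features: int = 0

    def refine(self, features) -> Frog:
        """Rank the frog's own features by SU and run IWSSr over them."""
        ranked = rank_features(features, self.weights)
        result = iwssr(ranked, self.evaluator, self.config.max_subset_size)
        return Frog(result.subset, result.score)

    def random_frog(self) -> Frog:
        """Weighted random frog, IWSSr-refined (used for init and IWF stage 3)."""
        p = self.n_features
        lo_f, hi_f = self.config.init_frac_range
        lo_c, hi_c = self.config.init_size_clamp
        lo = min(max(1, int(round(lo_f * p)), lo_c), p)
        hi = max(lo, min(int(round(hi_f * p)), hi_c, p))
        size = int(self.rng_init.integers(lo, hi + 1))
        feats = _weighted_draw(list(range(p)), self.weights.sampling_weights, size, self.rng_init)
        return self.refine(feats)


def improve_worst_frog(
    worst: Frog, memplex_best: Frog, global_best: Frog, context: SearchContext
) -> Frog:
    """IWF: leap toward the memplex best, then the global best, else try a
    random frog; each stage returns immediately on strict improvement, and
    the original frog survives if all three fail."""
    for guide in (memplex_best, global_best):
        s_b = leap_size(guide.size, worst.size, context.config.s_max, context.rng_leap)
        moved = leap_features(worst, guide, s_b, context.weights, context.rng_leap)
        refined = context.refine(moved.features)
        if refined.fitness > worst.fitness:
            return refined
    fresh = context.random_frog()
    if fresh.fitness > worst.fitness:
        return fresh
    return worst


def init_population(context: SearchContext) -> list[Frog]:
    """sfla_p random frogs, each IWSSr-refined and evaluated."""
    return [context.random_frog() for _ in range(context.config.sfla_p)]


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def make_context(data: ExpressionDataset, config: SFLAConfig) -> SearchContext:
    """Normalize, weight and wire up the evaluator for a training dataset."""
    config.validate()
    norm = minmax_normalize(data)
    ss = np.random.SeedSequence(config.seed)
    s_relief, s_eval, s_init, s_sub, s_leap = ss.spawn(5)
    weights = compute_feature_weights(
        norm,
        m=config.relief_m,
        bins=config.su_bins,
        seed=int(s_relief.generate_state(1)[0] % (2**31 - 1)),
    )
    evaluator = SubsetEvaluator(
        norm.values,
        norm.labels,
        n_folds=config.inner_cv_folds,
        clf_config=config.classifier(),
        seed=int(s_eval.generate_state(1)[0] % (2**31 - 1)),
    )
    return SearchContext(
        weights=weights,
        config=config,
        evaluator=evaluator,
        rng_init=np.random.default_rng(s_init),
        rng_sub=np.random.default_rng(s_sub),
        rng_leap=np.random.default_rng(s_leap),
        n_features=data.n_features,
    )


def _better(a: Frog, b: Frog) -> bool:
    """Strictly better fitness, or equal fitness with a smaller subset."""
    return a.fitness > b.fitness or (a.fitness == b.fitness and a.size < b.size)


def run(data: ExpressionDataset, config: SFLAConfig) -> SelectionResult:
    """Full hybrid search on a training dataset (caller holds out test rows)."""
    context = make_context(data, config)
    cfg = config
    population = init_population(context)
    best = max(population, key=lambda f: (f.fitness, -f.size))
    trace: list[TraceRow] = []
    truncated = False

    def budget_hit() -> bool:
        return cfg.max_evals is not None and context.evaluator.n_evals >= cfg.max_evals

    for it in range(cfg.it_max):
        if budget_hit():
            truncated = True
            break
        memplexes = partition_memplexes(population, cfg)
        for memplex in memplexes:
            for _ in range(cfg.it_mem):
                if budget_hit():
                    truncated = True
                    break
                memplex.sort(key=lambda f: (-f.fitness, f.size))
                sub = sample_submemplex(memplex, cfg.sfla_q, context.rng_sub)
                worst = worst_of(sub)
                improved = improve_worst_frog(worst, memplex[0], best, context)
                if improved is not worst:
                    slot = next(i for i, f in enumerate(memplex) if f is worst)
                    memplex[slot] = improved
                    if _better(improved, best):
                        best = improved
            if truncated:
                break
        population = [f for mem in memplexes for f in mem]
        trace.append(
            TraceRow(
                iteration=it,
                mean_fitness=float(np.mean([f.fitness for f in population])),
                best_fitness=best.fitness,
                best_size=best.size,
                evals=context.evaluator.n_evals,
            )
        )
        if truncated:
            break
    return SelectionResult(
        best_frog=best,
        trace=trace,
        evals=context.evaluator.n_evals,
        config=cfg,
        seed=cfg.seed,
        truncated=truncated,
    )
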