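"""IWSSr: incremental wrapper subset selection with replacement.

Features are scanned in descending SU order.  The subset S starts as the
top-ranked feature; for each later feature f the algorithm first tries
swapping f for each current member of S (the "replacement" phase — this is
how redundancy with already-selected features is detected), then tries
appending f.  The best strictly-improving variant, if any, becomes the new S.

The fitness oracle is an internal stratified-CV SVM whose score is the
balanced rate; evaluations are memoized by (order-insensitive) subset so the
frog-refinement loop never retrains on a subset it has already scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .evaluation import ClassifierConfig, ConfusionCounts, fitness
from .filter_weights import FeatureWeights


@dataclass
class SubsetEvaluation:
    """Outcome of one IWSSr scan: the ordered subset, its score, evaluations used."""

    subset: tuple[int, ...]
    score: float
    n_evals: int

    def __post_init__(self) -> None:
        if len(self.subset) == 0:
            raise ValueError("subset must be non-empty")
        if len(set(self.subset)) != len(self.subset):
            raise ValueError("subset must be duplicate-free")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


class SubsetEvaluator:
    """Memoized internal-CV fitness oracle over a fixed training matrix.

    Score of a subset = balanced rate of the pooled confusion counts over a
    stratified k-fold CV of the training rows, using a linear-kernel SVM by
    default.  Fold assignment is fixed at construction, so scores are a pure
    deterministic function of the subset.
    """

    def __init__(
        self,
        values: np.ndarray,
        labels: np.ndarray,
        n_folds: int = 5,
        clf_config: ClassifierConfig | None = None,
        seed: int = 0,
    ) -> None:
        self.values = np.asarray(values, dtype=float)
        self.labels = np.asarray(labels)
        self.clf_config = clf_config or ClassifierConfig()
        min_class = int(min((self.labels == 1).sum(), (self.labels == -1).sum()))
        self.n_folds = max(2, min(n_folds, min_class))
        splitter = StratifiedKFold(n_splits=self.n_folds, shuffle=True, random_state=seed % (2**32 - 1))
        self._splits = [
            (np.asarray(tr), np.asarray(te)) for tr, te in splitter.split(self.values, self.labels)
        ]
        self._cache: dict[frozenset[int], float] = {}
        #: distinct subsets actually scored (cache misses)
        self.n_evals = 0

    def __call__(self, subset) -> float:
        key = frozenset(int(j) for j in subset)
        if not key:
            raise ValueError("cannot evaluate an empty subset")
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        cols = self.values[:, sorted(key)]
        counts = ConfusionCounts()
        for train_rows, test_rows in self._splits:
            clf = self.clf_config.build()
            clf.fit(cols[train_rows], self.labels[train_rows])
            counts.add_predictions(self.labels[test_rows], clf.predict(cols[test_rows]))
        score = fitness(counts)
        self._cache[key] = score
        self.n_evals += 1
        return score


def rank_features(candidates, weights: FeatureWeights) -> list[int]:
    """Sort candidates by descending SU; ties by descending Relief, then index."""
    candidates = [int(j) for j in candidates]
    if not candidates:
        raise ValueError("candidates must be non-empty")
    return sorted(candidates, key=lambda j: (-weights.su[j], -weights.relief[j], j))


def iwssr(
    candidates: list[int],
    evaluator,
    max_subset_size: int | None = None,
) -> SubsetEvaluation:
    """Incremental wrapper subset selection with replacement over ranked candidates.

    Acceptance requires a STRICT score improvement; among improving variants
    of equal score the one with fewer features wins (replacement beats
    addition), then the earliest replacement position.  The accepted-score
    sequence is therefore strictly increasing and the best-so-far score
    non-decreasing over the scan.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    if len(set(candidates)) != len(candidates):
        raise ValueError("candidates must be duplicate-free")
    calls = 0

    def score_of(subset: list[int]) -> float:
        nonlocal calls
        calls += 1
        return evaluator(subset)

    s = [int(candidates[0])]
    best = score_of(s)
    for f in candidates[1:]:
        f = int(f)
        # phase 1: swap f for each current member, earliest position preferred
        variants: list[tuple[int, int, list[int]]] = [
            (0, i, s[:i] + [f] + s[i + 1:]) for i in range(len(s))
        ]
        # phase 2: append f (unless capped)
        if max_subset_size is None or len(s) < max_subset_size:
            variants.append((1, len(s), s + [f]))
        chosen: tuple[float, int, int, int, list[int]] | None = None
        for phase, pos, variant in variants:
            sc = score_of(variant)
            if sc <= best:
                continue
            key = (-sc, len(variant), phase, pos)
            if chosen is None or key < chosen[:4]:
                chosen = (*key, variant)
        if chosen is not None:
            s = chosen[4]
            best = -chosen[0]
    return SubsetEvaluation(subset=tuple(s), score=best, n_evals=calls)
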