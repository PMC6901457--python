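"""Filter-phase feature weighting: Relief relevance and symmetrical uncertainty.

Relief weights a feature by how much its values differ between each sampled
instance's nearest miss (closest other-class sample) and nearest hit (closest
same-class sample): informative features differ across the class boundary and
agree within it, so they accumulate positive weight; noise features average
to zero.  SU (symmetrical uncertainty) is normalized mutual information
between a discretized feature and the class label,

    SU(F, C) = 2 * (H(F) - H(F|C)) / (H(F) + H(C))  in [0, 1],

used to rank features inside the wrapper.  Continuous features are
discretized with equal-frequency bins fitted on training rows only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import entropy as _scipy_entropy

from .data_io import ExpressionDataset

#: shift added to Relief weights before using them as a sampling measure,
#: so every feature keeps a nonzero selection probability
WEIGHT_SHIFT_EPS = 1e-6


@dataclass
class FeatureWeights:
    """Per-feature Relief weights and SU scores, aligned to dataset feature order."""

    relief: np.ndarray
    su: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.relief = np.asarray(self.relief, dtype=float)
        self.su = np.asarray(self.su, dtype=float)
        if self.relief.shape != self.su.shape or self.relief.ndim != 1:
            raise ValueError("relief and su must be 1-D vectors of equal length")
        if ((self.su < 0) | (self.su > 1)).any():
            raise ValueError("su scores must lie in [0, 1]")

    @property
    def n_features(self) -> int:
        return self.relief.size

    @property
    def order_relief(self) -> np.ndarray:
        """Feature indices by descending Relief weight; ties by ascending index."""
        p = self.n_features
        return np.lexsort((np.arange(p), -self.relief))

    @property
    def order_su(self) -> np.ndarray:
        """Feature indices by descending SU, ties by descending Relief, then index."""
        p = self.n_features
        return np.lexsort((np.arange(p), -self.relief, -self.su))

    @property
    def sampling_weights(self) -> np.ndarray:
        """Nonnegative sampling measure: w' = w - min(w) + eps."""
        return self.relief - self.relief.min() + WEIGHT_SHIFT_EPS


@dataclass
class DiscretizationRule:
    """Equal-frequency discretization fitted on training rows.

    ``edges[j]`` holds the strictly increasing interior bin boundaries of
    feature ``j``; values beyond the edges clamp to the end bins, constant
    features collapse to a single bin.
    """

    bins: int
    edges: list[np.ndarray]
    method: str = "equal_frequency"

    def transform(self, values: np.ndarray, feature_index: int) -> np.ndarray:
        return np.searchsorted(self.edges[feature_index], values, side="right")


# ---------------------------------------------------------------------------
# Relief
# ---------------------------------------------------------------------------

def diff(feature_index: int, a: int, b: int, data: ExpressionDataset) -> float:
    """Per-feature sample difference on the normalized [0,1] scale.

    Discrete features score 1 when the values differ and 0 when equal;
    continuous features score the absolute difference.
    """
    va, vb = data.values[a, feature_index], data.values[b, feature_index]
    if data.discrete_mask is not None and data.discrete_mask[feature_index]:
        return 0.0 if va == vb else 1.0
    return abs(float(va) - float(vb))


def _diff_vectors(data: ExpressionDataset, a: int, b: int) -> np.ndarray:
    d = np.abs(data.values[a] - data.values[b])
    if data.discrete_mask is not None and data.discrete_mask.any():
        m = data.discrete_mask
        d[m] = (data.values[a, m] != data.values[b, m]).astype(float)
    return d


def relief_weights(
    data: ExpressionDataset, m: int | None = None, seed: int = 0
) -> np.ndarray:
    """Relief relevance weights (single nearest hit/miss).

    For each of ``m`` sampled instances R the nearest hit H (same class) and
    nearest miss M (other class) are found by Euclidean distance over all
    features, and every feature accumulates diff(R,M) - diff(R,H).  The sums
    are divided by ``m`` once at the end (algebraically identical to the
    incremental update, but order-independent in floating point).

    ``m`` defaults to ``n_samples``; for m <= n the pass visits each sample
    at most once, in a seed-shuffled order (sampling without replacement).
    Expects min-max normalized values for continuous features.
    """
    n, p = data.values.shape
    if min(data.class_counts) < 2:
        raise ValueError("Relief needs at least 2 samples per class (no nearest hit otherwise)")
    if m is None:
        m = n
    if m < 1:
        raise ValueError("m must be positive")
    rng = np.random.default_rng(seed)
    if m <= n:
        visit = rng.permutation(n)[:m]
    else:
        visit = np.concatenate([rng.permutation(n), rng.integers(0, n, size=m - n)])

    # pairwise squared Euclidean distances; ties resolved to the lowest index
    sq = np.sum((data.values[:, None, :] - data.values[None, :, :]) ** 2, axis=2)
    same = data.labels[:, None] == data.labels[None, :]
    np.fill_diagonal(same, False)

    sum_hit = np.zeros(p)
    sum_miss = np.zeros(p)
    big = np.inf
    for r in visit:
        hit_d = np.where(same[r], sq[r], big)
        hit_d[r] = big
        miss_d = np.where(~same[r], sq[r], big)
        miss_d[r] = big
        h = int(np.argmin(hit_d))
        mi = int(np.argmin(miss_d))
        sum_hit += _diff_vectors(data, r, h)
        sum_miss += _diff_vectors(data, r, mi)
    return (sum_miss - sum_hit) / float(m)


# ---------------------------------------------------------------------------
# discretization + entropy + SU
# ---------------------------------------------------------------------------

def fit_discretizer(
    data: ExpressionDataset, rows: np.ndarray | None = None, bins: int = 10
) -> DiscretizationRule:
    """Equal-frequency bin edges per feature, learned from ``rows`` only."""
    if bins < 2:
        raise ValueError("bins must be at least 2")
    if rows is None:
        rows = np.arange(data.n_samples)
    rows = np.asarray(rows, dtype=int)
    if rows.size == 0:
        raise ValueError("rows must be non-empty")
    qs = np.arange(1, bins) / bins
    edges: list[np.ndarray] = []
    for j in range(data.n_features):
        col = data.values[rows, j]
        e = np.unique(np.quantile(col, qs))
        # drop edges at or beyond the extremes that would create empty end bins
        e = e[(e > col.min()) & (e <= col.max())] if e.size else e
        edges.append(e)
    return DiscretizationRule(bins=bins, edges=edges)


def entropy(symbols: np.ndarray) -> float:
    """Shannon entropy in bits of the observed symbol frequencies."""
    symbols = np.asarray(symbols)
    if symbols.size == 0:
        raise ValueError("entropy of an empty vector is undefined")
    _, counts = np.unique(symbols, return_counts=True)
    return float(_scipy_entropy(counts, base=2))


def symmetrical_uncertainty(x: np.ndarray, y: np.ndarray) -> float:
    """SU between two discrete vectors: 2*(H(X) - H(X|Y)) / (H(X) + H(Y))."""
    x = np.asarray(x)
    y = np.asarray(y)
    h_x = entropy(x)
    h_y = entropy(y)
    denom = h_x + h_y
    if denom == 0.0:
        return 0.0
    classes, counts = np.unique(y, return_counts=True)
    h_x_given_y = 0.0
    n = y.size
    for cls, cnt in zip(classes, counts):
        h_x_given_y += (cnt / n) * entropy(x[y == cls])
    return float(np.clip(2.0 * (h_x - h_x_given_y) / denom, 0.0, 1.0))


def su(feature_index: int, data: ExpressionDataset, rule: DiscretizationRule) -> float:
    """SU between a (discretized) feature and the class label, in [0, 1]."""
    codes = rule.transform(data.values[:, feature_index], feature_index)
    return symmetrical_uncertainty(codes, data.labels)


def compute_feature_weights(
    data: ExpressionDataset,
    m: int | None = None,
    bins: int = 10,
    seed: int = 0,
) -> FeatureWeights:
    """Relief + SU weights for every feature (call on training rows only)."""
    w = relief_weights(data, m=m, seed=seed)
    rule = fit_discretizer(data, bins=bins)
    scores = np.array([su(j, data, rule) for j in range(data.n_features)])
    return FeatureWeights(relief=w, su=scores, feature_names=list(data.feature_names))
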