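"""Microarray-like synthetic datasets with known ground truth.

Emulates the shape of two-class tumor cohorts: thousands of features over
tens of samples, unbalanced classes, a handful of informative genes
(class-conditional Gaussian mean shift), redundant genes that are noisy
copies of informative ones, and the rest pure noise.  Column positions are
shuffled so structure never correlates with index order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionDataset


@dataclass
class FixtureSpec:
    """Generator settings.

    ``effect_size`` is the positive-class mean shift of informative genes in
    units of the within-class SD; ``redundant_noise_sd`` is the SD of the
    noise added to a redundant gene's informative parent.
    """

    n_samples: int = 60
    n_features: int = 500
    n_informative: int = 5
    n_redundant: int = 10
    class_balance: float = 0.35
    effect_size: float = 2.0
    redundant_noise_sd: float = 0.1
    heavy_tailed: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_informative + self.n_redundant > self.n_features:
            raise ValueError("n_informative + n_redundant must not exceed n_features")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie strictly between 0 and 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.redundant_noise_sd < 0:
            raise ValueError("redundant_noise_sd must be non-negative")
        n_pos = round(self.class_balance * self.n_samples)
        if min(n_pos, self.n_samples - n_pos) < 2:
            raise ValueError("class_balance leaves a class with fewer than 2 samples")


@dataclass
class GroundTruth:
    informative: tuple[int, ...]
    redundant: tuple[int, ...]
    noise: tuple[int, ...]
    #: redundant feature index -> informative parent index
    parents: dict[int, int]


@dataclass
class RecoveryScore:
    recall: float
    precision: float
    redundancy_count: int


def generate(spec: FixtureSpec) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw one dataset; deterministic for a fixed ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_features
    n_pos = int(round(spec.class_balance * n))
    labels = np.full(n, -1, dtype=np.int8)
    labels[rng.permutation(n)[:n_pos]] = 1

    n_inf, n_red = spec.n_informative, spec.n_redundant
    n_noise = p - n_inf - n_red
    informative = rng.normal(0.0, 1.0, size=(n, n_inf))
    informative[labels == 1] += spec.effect_size
    parents_local = rng.integers(0, n_inf, size=n_red) if n_red else np.array([], dtype=int)
    redundant = informative[:, parents_local] + rng.normal(
        0.0, spec.redundant_noise_sd, size=(n, n_red)
    )
    noise = rng.normal(0.0, 1.0, size=(n, n_noise))
    values = np.concatenate([informative, redundant, noise], axis=1)
    if spec.heavy_tailed:
        values = np.exp(values)  # log-normal marginals, mimics microarray skew

    perm = rng.permutation(p)  # column j of output = block column perm[j]... invert below
    inv = np.empty(p, dtype=int)
    inv[perm] = np.arange(p)
    values = values[:, perm]
    # block index b lands at output column inv[b]
    inf_idx = tuple(int(inv[j]) for j in range(n_inf))
    red_idx = tuple(int(inv[n_inf + j]) for j in range(n_red))
    noise_idx = tuple(int(inv[n_inf + n_red + j]) for j in range(n_noise))
    parents = {
        int(inv[n_inf + j]): int(inv[parents_local[j]]) for j in range(n_red)
    }
    width = len(str(p))
    data = ExpressionDataset(
        values=values,
        labels=labels,
        feature_names=[f"g{j:0{width}d}" for j in range(p)],
        sample_ids=[f"s{i:03d}" for i in range(n)],
        positive_label="case",
        negative_label="control",
    )
    truth = GroundTruth(
        informative=inf_idx, redundant=red_idx, noise=noise_idx, parents=parents
    )
    return data, truth


def score_recovery(selected, truth: GroundTruth) -> RecoveryScore:
    """Recall/precision over informative features and redundant-with-parent count.

    Recall is strict: only the planted informative columns themselves count.
    A selected redundant copy contributes nothing here even though it carries
    its parent's signal; see :func:`signal_recall` for the credited variant.
    """
    sel = {int(j) for j in selected}
    inf = set(truth.informative)
    recall = len(sel & inf) / len(inf) if inf else 0.0
    precision = len(sel & inf) / len(sel) if sel else 0.0
    redundancy = sum(1 for j in sel & set(truth.redundant) if truth.parents[j] in sel)
    return RecoveryScore(recall=recall, precision=precision, redundancy_count=redundancy)


def signal_recall(selected, truth: GroundTruth) -> float:
    """Fraction of informative genes recovered directly OR through a redundant copy.

    A redundant feature is a noisy clone of its informative parent, so
    selecting the copy recovers the same biological signal; this metric
    credits it to the parent.
    """
    sel = {int(j) for j in selected}
    recovered = (sel & set(truth.informative)) | {
        truth.parents[j] for j in sel & set(truth.redundant)
    }
    return len(recovered) / len(truth.informative) if truth.informative else 0.0
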