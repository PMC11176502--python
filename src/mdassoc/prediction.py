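"""Pair feature assembly and the random-forest association scorer.

A candidate microbe-drug pair is represented by the concatenation of the
two refined embeddings, [z_m(i) || z_d(j)].  Known associations are the
positives; negatives are drawn uniformly from the unknown (zero) cells
of the association matrix, by default at a 1:1 ratio.  The classifier
is a bootstrap ensemble of decision trees; the association score of a
pair is the fraction of trees voting for the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import NotFittedError
from sklearn.utils.validation import check_is_fitted

from .graph_data import AssociationMatrix

__all__ = [
    "ForestConfig",
    "PairSample",
    "assemble_pairs",
    "stack_samples",
    "sample_negatives",
    "train_forest",
    "score_pairs",
    "rank_candidates",
]


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest hyperparameters; 100 trees is the tuned default."""

    n_estimators: int = 100
    seed: int = 0
    max_depth: int | None = None

    def __post_init__(self):
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")


@dataclass
class PairSample:
    microbe_index: int
    drug_index: int
    label: int
    features: np.ndarray


def assemble_pairs(
    zm: np.ndarray,
    zd: np.ndarray,
    associations: AssociationMatrix,
    negatives: list[tuple[int, int]],
) -> list[PairSample]:
    """One positive sample per association, one negative per given pair.

    Features are [zm_i || zd_j].  A negative that coincides with a known
    positive is an error (it would poison the labels).
    """
    zm = np.asarray(zm, dtype=np.float64)
    zd = np.asarray(zd, dtype=np.float64)
    if zm.shape[0] != associations.n_microbes or zd.shape[0] != associations.n_drugs:
        raise ValueError("embeddings are not row-aligned with the association ids")
    samples = []
    for i, j in associations.pairs():
        samples.append(PairSample(i, j, 1, np.concatenate([zm[i], zd[j]])))
    for i, j in negatives:
        if associations.values[i, j] == 1:
            raise ValueError(f"negative pair ({i},{j}) is a known positive")
        samples.append(PairSample(i, j, 0, np.concatenate([zm[i], zd[j]])))
    return samples


def stack_samples(samples: list[PairSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into an (X, y) pair for the classifier."""
    x = np.stack([s.features for s in samples])
    y = np.array([s.label for s in samples])
    return x, y


def sample_negatives(
    associations: AssociationMatrix,
    ratio: float = 1.0,
    seed: int = 0,
    exclude: set[tuple[int, int]] | frozenset = frozenset(),
) -> list[tuple[int, int]]:
    """Uniform sample (without replacement) of unknown pairs.

    ``exclude`` removes held-out test pairs from the candidate pool so a
    fold's test negatives never appear in training.  The sample size is
    round(ratio x number of positives).
    """
    zeros_i, zeros_j = np.nonzero(associations.values == 0)
    pool = [(int(i), int(j)) for i, j in zip(zeros_i, zeros_j) if (int(i), int(j)) not in exclude]
    count = int(round(ratio * associations.n_associations))
    if count > len(pool):
        raise ValueError(f"requested {count} negatives but only {len(pool)} unknown pairs exist")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=count, replace=False)
    return [pool[k] for k in idx]


def train_forest(samples: list[PairSample], config: ForestConfig) -> RandomForestClassifier:
    """Fit the bootstrap tree ensemble on labeled pair samples."""
    x, y = stack_samples(samples)
    if len(np.unique(y)) < 2:
        raise ValueError("training samples must contain both classes")
    model = RandomForestClassifier(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        random_state=config.seed,
        n_jobs=1,
    )
    model.fit(x, y)
    return model


def score_pairs(model: RandomForestClassifier, samples: list[PairSample]) -> np.ndarray:
    """Association score per pair: fraction of trees voting positive."""
    try:
        check_is_fitted(model)
    except NotFittedError as err:
        raise ValueError("model must be fitted before scoring") from err
    x, _ = stack_samples(samples)
    votes = np.stack([tree.predict(x) for tree in model.estimators_])
    return votes.mean(axis=0)


def rank_candidates(
    model: RandomForestClassifier,
    zm: np.ndarray,
    zd: np.ndarray,
    associations: AssociationMatrix,
    drug_id: str,
    k: int = 10,
) -> list[tuple[str, float]]:
    """Top-k candidate microbes for a drug, by descending vote share.

    Known positives are excluded; ties break lexicographically by
    microbe id so the ranking is deterministic.
    """
    if drug_id not in associations.drug_ids:
        raise KeyError(f"unknown drug id {drug_id!r}")
    j = associations.drug_ids.index(drug_id)
    candidates = [
        PairSample(i, j, 0, np.concatenate([np.asarray(zm[i]), np.asarray(zd[j])]))
        for i in range(associations.n_microbes)
        if associations.values[i, j] == 0
    ]
    if not candidates:
        return []
    scores = score_pairs(model, candidates)
    ranked = sorted(
        zip((associations.microbe_ids[s.microbe_index] for s in candidates), scores),
        key=lambda item: (-item[1], item[0]),
    )
    return [(mid, float(sc)) for mid, sc in ranked[:k]]
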