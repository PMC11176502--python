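"""Cross-validation, confusion metrics and ROC/PR evaluation.

Known associations are split into k folds (5 by default, 10 supported).
Every training structure — GIP kernels, fused similarity graphs,
encoder, attention refinement and the forest — is rebuilt per fold from
the training positives only, so held-out labels never leak into the
model.  Each fold is tested on its held-out positives plus an
equal-size seeded sample of unknown pairs; Acc/Pre/R/F1 use a 0.5 score
threshold, AUC is computed from the ROC threshold sweep (equivalently
the Mann-Whitney concordance probability with ties counted 1/2) and
AUPR is the average-precision step integral.  Fold metrics are averaged
arithmetically; the reported curves come from the pooled test scores.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skm

from . import gat, mgavae, prediction, similarity
from .graph_data import AssociationMatrix

__all__ = [
    "FoldPlan",
    "PipelineConfig",
    "MetricsReport",
    "stage_seed",
    "make_folds",
    "confusion_metrics",
    "roc_auc",
    "pr_auc",
    "cross_validate",
]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out from one global seed."""
    return (zlib.crc32(stage.encode("utf-8")) ^ (global_seed & 0x7FFFFFFF)) % (2**31)


@dataclass
class FoldPlan:
    """Partition of the positive pairs into k test folds."""

    k: int
    assignments: dict[tuple[int, int], int]
    seed: int

    def test_pairs(self, fold: int) -> list[tuple[int, int]]:
        return sorted(p for p, f in self.assignments.items() if f == fold)


@dataclass
class PipelineConfig:
    """Everything a cross-validation run needs besides the data.

    ``embedding`` selects the representation fed to the forest:
    "learned" is the full pipeline (VGAE + optional attention), and
    "profiles" is the degenerate baseline that feeds raw association
    profiles straight to the forest.
    """

    window: int = 5
    microbe_threshold: float = 0.8
    drug_threshold: float = 0.7
    gamma_prime: float = 1.0
    encoder: mgavae.EncoderConfig = field(default_factory=mgavae.EncoderConfig)
    attention: gat.AttentionConfig = field(default_factory=gat.AttentionConfig)
    forest: prediction.ForestConfig = field(default_factory=prediction.ForestConfig)
    negative_ratio: float = 1.0
    use_attention: bool = True
    embedding: str = "learned"
    score_threshold: float = 0.5


@dataclass
class MetricsReport:
    """Per-fold and aggregate cross-validation metrics."""

    fold_metrics: list[dict]
    mean: dict
    std: dict
    roc_points: np.ndarray  # pooled (fpr, tpr) columns
    pr_points: np.ndarray  # pooled (recall, precision) columns
    k: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "fold_metrics": self.fold_metrics,
            "mean": self.mean,
            "std": self.std,
        }


def make_folds(associations: AssociationMatrix, k: int, seed: int) -> FoldPlan:
    """Shuffle the positive pairs and split them as evenly as possible."""
    if k < 2:
        raise ValueError("k must be >= 2")
    pairs = associations.pairs()
    if len(pairs) < k:
        raise ValueError(f"cannot make {k} folds from {len(pairs)} positives")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    assignments = {pairs[idx]: int(pos % k) for pos, idx in enumerate(order)}
    return FoldPlan(k=k, assignments=assignments, seed=seed)


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> tuple[float, float, float, float]:
    """(Acc, Pre, R, F1) from confusion counts; zero denominators give 0 + warning."""
    counts = (tp, tn, fp, fn)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("confusion counts are all zero")
    acc = (tp + tn) / total
    pre = _safe_ratio(tp, tp + fp, "precision")
    rec = _safe_ratio(tp, tp + fn, "recall")
    f1 = _safe_ratio(2 * pre * rec, pre + rec, "F1")
    return acc, pre, rec, f1


def _safe_ratio(num, den, name):
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting 0", stacklevel=3)
        return 0.0
    return num / den


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC curve (fpr, tpr columns) and its area.

    Requires both classes.  The trapezoidal area over the threshold
    sweep equals the probability that a random positive outscores a
    random negative, ties counting one half.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both positive and negative labels")
    fpr, tpr, _ = _skm.roc_curve(labels, scores)
    return np.column_stack([fpr, tpr]), float(_skm.auc(fpr, tpr))


def pr_auc(scores, labels) -> tuple[np.ndarray, float]:
    """Precision-recall curve (recall, precision columns) and average precision."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if np.sum(labels == 1) == 0:
        raise ValueError("PR curve needs at least one positive label")
    precision, recall, _ = _skm.precision_recall_curve(labels, scores)
    return np.column_stack([recall[::-1], precision[::-1]]), float(
        _skm.average_precision_score(labels, scores)
    )


# ---------------------------------------------------------------------------
# per-fold pipeline


def _fold_embeddings(train_assoc, mss, dss, config, fold_seed):
    """Representations for one fold, built from training labels only."""
    if config.embedding == "profiles":
        zm = train_assoc.values.astype(np.float64)
        zd = train_assoc.values.T.astype(np.float64)
        return zm, zd
    if config.embedding != "learned":
        raise ValueError(f"unknown embedding mode {config.embedding!r}")
    mg, dg, _, _ = similarity.build_entity_graphs(
        train_assoc,
        mss,
        dss,
        window=config.window,
        microbe_threshold=config.microbe_threshold,
        drug_threshold=config.drug_threshold,
        gamma_prime=config.gamma_prime,
    )
    enc_m = _with_seed(config.encoder, stage_seed(fold_seed, "vgae-microbe"))
    enc_d = _with_seed(config.encoder, stage_seed(fold_seed, "vgae-drug"))
    _, emb_m, _ = mgavae.train(mg, enc_m)
    _, emb_d, _ = mgavae.train(dg, enc_d)
    zm, zd = emb_m.mu, emb_d.mu
    if config.use_attention:
        att = _with_seed(config.attention, stage_seed(fold_seed, "gat"))
        zm, zd, _ = gat.refine_embeddings(zm, zd, train_assoc, att)
    return zm, zd


def _with_seed(cfg, seed):
    from dataclasses import replace

    return replace(cfg, seed=seed)


def cross_validate(
    associations: AssociationMatrix,
    microbe_similarity: similarity.SimilarityMatrix,
    drug_similarity: similarity.SimilarityMatrix,
    *,
    k: int = 5,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> MetricsReport:
    """k-fold cross-validation of the full pipeline (or a config variant)."""
    config = config or PipelineConfig()
    plan = make_folds(associations, k, stage_seed(seed, "folds"))
    fold_rows: list[dict] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []

    for fold in range(k):
        test_pos = plan.test_pairs(fold)
        train_values = associations.values.copy()
        for i, j in test_pos:
            train_values[i, j] = 0
        train_assoc = AssociationMatrix(
            train_values, list(associations.microbe_ids), list(associations.drug_ids)
        )

        # test negatives: unknown pairs of the FULL matrix, equal count
        test_neg = prediction.sample_negatives(
            associations,
            ratio=len(test_pos) / max(associations.n_associations, 1),
            seed=stage_seed(seed, f"test-neg-{fold}"),
        )
        test_pair_set = set(test_pos) | set(test_neg)

        zm, zd = _fold_embeddings(
            train_assoc, microbe_similarity, drug_similarity, config, stage_seed(seed, f"fold-{fold}")
        )

        train_neg = prediction.sample_negatives(
            train_assoc,
            ratio=config.negative_ratio,
            seed=stage_seed(seed, f"train-neg-{fold}"),
            exclude=test_pair_set,
        )
        train_samples = prediction.assemble_pairs(zm, zd, train_assoc, train_neg)
        # leakage guard: no test pair may appear among the training samples
        train_pair_set = {(s.microbe_index, s.drug_index) for s in train_samples}
        assert not (train_pair_set & test_pair_set), "test pairs leaked into training samples"
        assert not (set(test_pos) & set(train_assoc.pairs())), "test positives left in training labels"

        forest_cfg = _with_seed(config.forest, stage_seed(seed, f"forest-{fold}"))
        model = prediction.train_forest(train_samples, forest_cfg)

        test_samples = [
            prediction.PairSample(i, j, 1, np.concatenate([zm[i], zd[j]])) for i, j in test_pos
        ] + [
            prediction.PairSample(i, j, 0, np.concatenate([zm[i], zd[j]])) for i, j in test_neg
        ]
        scores = prediction.score_pairs(model, test_samples)
        labels = np.array([s.label for s in test_samples])

        predicted = scores >= config.score_threshold
        tp = int(np.sum(predicted & (labels == 1)))
        tn = int(np.sum(~predicted & (labels == 0)))
        fp = int(np.sum(predicted & (labels == 0)))
        fn = int(np.sum(~predicted & (labels == 1)))
        acc, pre, rec, f1 = confusion_metrics(tp, tn, fp, fn)
        _, auc_val = roc_auc(scores, labels)
        _, aupr_val = pr_auc(scores, labels)
        fold_rows.append(
            {
                "fold": fold,
                "tp": tp,
                "tn": tn,
                "fp": fp,
                "fn": fn,
                "acc": acc,
                "precision": pre,
                "recall": rec,
                "f1": f1,
                "auc": auc_val,
                "aupr": aupr_val,
            }
        )
        pooled_scores.append(scores)
        pooled_labels.append(labels)

    keys = ("acc", "precision", "recall", "f1", "auc", "aupr")
    mean = {key: float(np.mean([r[key] for r in fold_rows])) for key in keys}
    std = {key: float(np.std([r[key] for r in fold_rows])) for key in keys}
    scores_all = np.concatenate(pooled_scores)
    labels_all = np.concatenate(pooled_labels)
    roc_points, _ = roc_auc(scores_all, labels_all)
    pr_points, _ = pr_auc(scores_all, labels_all)
    return MetricsReport(
        fold_metrics=fold_rows,
        mean=mean,
        std=std,
        roc_points=roc_points,
        pr_points=pr_points,
        k=k,
        seed=seed,
    )
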