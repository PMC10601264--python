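"""Training loop, cross-validated evaluation, attention export.

Bags are trained one graph at a time with gradient accumulation over small
batches (default 8 bags), a step-decayed learning rate, and the checkpoint
with the best validation weighted-F1 retained.  Evaluation reports
accuracy, precision, recall, weighted F1 and ROC-AUC; attention export
ranks a bag's instances by their pooling scores (tile coordinates when the
bag came from a slide).
"""

from __future__ import annotations

import copy
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

from . import nn
from .data import Bag, CVSplit, MILDataset, Standardizer, split_cv
from .vgae import MILGNN, ModelConfig, mil_objective
from .wsi import Tile

__all__ = [
    "TrainConfig",
    "MetricsReport",
    "AttentionReport",
    "TrainedModel",
    "lr_schedule",
    "train",
    "evaluate",
    "metrics_from_predictions",
    "cross_validate",
    "CVReport",
    "export_attention",
]


@dataclass
class TrainConfig:
    """Optimization settings (defaults: batch 8, 150 epochs, 1e-3 → 1e-5
    step-decayed at epochs 30 and 100)."""

    batch_bags: int = 8
    epochs: int = 150
    lr_init: float = 1e-3
    lr_final: float = 1e-5
    lr_steps: tuple[int, ...] = (30, 100)
    optimizer: str = "adam"
    lambda_vgae: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.lr_final > self.lr_init:
            raise ValueError("lr_final must be <= lr_init")
        steps = tuple(self.lr_steps)
        if any(b <= a for a, b in zip(steps, steps[1:])):
            raise ValueError("lr_steps must be strictly increasing")
        if steps and steps[-1] >= self.epochs:
            raise ValueError("lr_steps must all be < epochs")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.lambda_vgae < 0:
            raise ValueError("lambda_vgae must be >= 0")
        self.lr_steps = steps


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Step decay: geometric levels from lr_init to lr_final at lr_steps."""
    n_levels = len(config.lr_steps) + 1
    levels = np.geomspace(config.lr_init, config.lr_final, n_levels)
    return float(levels[bisect_right(config.lr_steps, epoch)])


@dataclass
class MetricsReport:
    """Split-level metrics plus the confusion counts they derive from.

    ``roc_auc`` is None when the split contains a single class (AUC is
    undefined there); ``degenerate`` flags any 0/0 metric reported as 0.
    Per-bag scores are retained so every metric is recomputable.
    """

    accuracy: float
    precision: float
    recall: float
    f1_weighted: float
    roc_auc: float | None
    confusion: tuple[int, int, int, int]  # (TP, FP, FN, TN)
    degenerate: list[str] = field(default_factory=list)
    scores: dict[str, float] = field(default_factory=dict)
    labels: dict[str, int] = field(default_factory=dict)


def metrics_from_predictions(y_true, y_score, y_pred=None,
                             ids=None) -> MetricsReport:
    """Compute the full metric panel from per-bag scores.

    accuracy = (TP+TN)/(TP+FP+FN+TN), precision = TP/(TP+FP),
    recall = TP/(TP+FN), F1 = 2PR/(P+R) weighted across classes;
    precision/recall/F1 are 0 (and flagged) when their denominator is 0.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_score = np.asarray(y_score, dtype=float)
    if y_pred is None:
        y_pred = (y_score >= 0.5).astype(int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    degenerate = []
    if tp + fp == 0:
        degenerate.append("precision")
    if tp + fn == 0:
        degenerate.append("recall")
    if len(np.unique(y_true)) < 2:
        auc = None
    else:
        auc = float(roc_auc_score(y_true, y_score))
    ids = list(ids) if ids is not None else [str(i) for i in range(len(y_true))]
    return MetricsReport(
        accuracy=float(accuracy_score(y_true, y_pred)),
        precision=float(precision_score(y_true, y_pred, zero_division=0)),
        recall=float(recall_score(y_true, y_pred, zero_division=0)),
        f1_weighted=float(f1_score(y_true, y_pred, average="weighted",
                                   zero_division=0)),
        roc_auc=auc,
        confusion=(tp, fp, fn, tn),
        degenerate=degenerate,
        scores={i: float(s) for i, s in zip(ids, y_score)},
        labels={i: int(t) for i, t in zip(ids, y_true)},
    )


@dataclass
class TrainedModel:
    """A fitted classifier plus the preprocessing fit on its train split."""

    model: MILGNN
    standardizer: Standardizer
    model_config: ModelConfig
    train_config: TrainConfig

    def score_bag(self, bag: Bag) -> float:
        return self.model.predict_score(self.standardizer.transform(bag.instances))

    def attention(self, bag: Bag) -> np.ndarray:
        return self.model.attention_scores(
            self.standardizer.transform(bag.instances))


def train(dataset: MILDataset, split: CVSplit,
          model_config: ModelConfig | None = None,
          train_config: TrainConfig | None = None,
          ) -> tuple[TrainedModel, list[dict]]:
    """Train end-to-end on one split; keep the best-validation-F1 weights.

    Fully reproducible from ``train_config.seed``.  Returns the trained
    model and a per-epoch history (losses, learning rate, validation
    metrics).
    """
    tc = train_config or TrainConfig()
    mc = model_config or ModelConfig(feature_dim=dataset.feature_dim)
    if mc.feature_dim != dataset.feature_dim:
        raise ValueError("model feature_dim does not match dataset")
    by_id = {b.bag_id: b for b in dataset}
    missing = [i for i in split.train_ids + split.val_ids + split.test_ids
               if i not in by_id]
    if missing:
        raise KeyError(f"split references unknown bag ids: {missing[:3]}")
    train_bags = [by_id[i] for i in split.train_ids]
    val_bags = [by_id[i] for i in split.val_ids]
    if not train_bags:
        raise ValueError("empty train split")
    std = Standardizer().fit(train_bags)
    model = MILGNN(mc, seed=tc.seed)
    params = model.parameters()
    opt_cls = nn.Adam if tc.optimizer == "adam" else nn.SGD
    opt = opt_cls(params, lr=tc.lr_init)
    rng = np.random.default_rng(tc.seed + 1)
    history: list[dict] = []
    best_f1, best_state = -1.0, None
    for epoch in range(tc.epochs):
        opt.lr = lr_schedule(epoch, tc)
        order = rng.permutation(len(train_bags))
        totals = {"loss": 0.0, "ce": 0.0, "neg_elbo": 0.0}
        opt.zero_grad()
        in_batch = 0
        for pos, idx in enumerate(order):
            bag = train_bags[idx]
            X = std.transform(bag.instances)
            out = model.forward(X, training=True, rng=rng)
            loss = mil_objective(out.logit, bag.label, out.neg_elbo,
                                 tc.lambda_vgae)
            loss.backward()
            in_batch += 1
            totals["loss"] += loss.item()
            totals["neg_elbo"] += out.neg_elbo.item()
            totals["ce"] += loss.item() - tc.lambda_vgae * out.neg_elbo.item()
            if in_batch == tc.batch_bags or pos == len(order) - 1:
                for p in params:  # average accumulated gradients
                    if p.grad is not None:
                        p.grad /= in_batch
                opt.step()
                opt.zero_grad()
                in_batch = 0
        record = {"epoch": epoch, "lr": opt.lr,
                  **{k: v / len(train_bags) for k, v in totals.items()}}
        if val_bags:
            scores = [model.predict_score(std.transform(b.instances))
                      for b in val_bags]
            val_report = metrics_from_predictions(
                [b.label for b in val_bags], scores,
                ids=[b.bag_id for b in val_bags])
            record["val_accuracy"] = val_report.accuracy
            record["val_f1_weighted"] = val_report.f1_weighted
            if val_report.f1_weighted > best_f1:
                best_f1 = val_report.f1_weighted
                best_state = copy.deepcopy(model.state_dict())
        history.append(record)
    if best_state is not None:
        model.load_state_dict(best_state)
    model.trained_ = True
    return TrainedModel(model=model, standardizer=std, model_config=mc,
                        train_config=tc), history


def evaluate(trained: TrainedModel, dataset: MILDataset,
             ids: list[str]) -> MetricsReport:
    """Score the listed bags and compute the metric panel."""
    by_id = {b.bag_id: b for b in dataset}
    bags = [by_id[i] for i in ids]  # KeyError surfaces missing ids
    scores = [trained.score_bag(b) for b in bags]
    return metrics_from_predictions([b.label for b in bags], scores, ids=ids)


@dataclass
class CVReport:
    folds: list[MetricsReport]
    mean: dict[str, float]
    sd: dict[str, float]


def cross_validate(dataset: MILDataset, folds: int = 10,
                   model_config: ModelConfig | None = None,
                   train_config: TrainConfig | None = None,
                   fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
                   seed: int | None = None) -> CVReport:
    """Repeated stratified shuffle-split evaluation (train+evaluate per fold)."""
    tc = train_config or TrainConfig()
    split_seed = tc.seed if seed is None else seed
    splits = split_cv(dataset, folds=folds, fractions=fractions, seed=split_seed)
    reports = []
    for split in splits:
        fold_tc = _replace_seed(tc, split.fold_index)
        trained, _ = train(dataset, split, model_config, fold_tc)
        reports.append(evaluate(trained, dataset, split.test_ids))
    keys = ("accuracy", "precision", "recall", "f1_weighted", "roc_auc")
    mean, sd = {}, {}
    for k in keys:
        vals = [getattr(r, k) for r in reports if getattr(r, k) is not None]
        mean[k] = float(np.mean(vals)) if vals else float("nan")
        sd[k] = float(np.std(vals)) if vals else float("nan")
    return CVReport(folds=reports, mean=mean, sd=sd)


def _replace_seed(tc: TrainConfig, offset: int) -> TrainConfig:
    cfg = copy.deepcopy(tc)
    cfg.seed = tc.seed + offset
    return cfg


@dataclass
class AttentionReport:
    """Per-instance attention scores with a descending ranking."""

    bag_id: str
    scores: np.ndarray  # (n,), sums to 1
    ranking: np.ndarray  # instance indices, best first
    top_k: np.ndarray  # first top_k of the ranking
    coordinates: list[tuple[int, int]] | None = None  # (x0, y0) per instance


def export_attention(trained: TrainedModel, bag: Bag, top_k: int | None = None,
                     tiles: list[Tile] | None = None) -> AttentionReport:
    """Rank a bag's instances by attention score (highest = most relied on)."""
    if not trained.model.trained_:
        raise RuntimeError("model has not been trained")
    scores = trained.attention(bag)
    n = scores.size
    top_k = n if top_k is None else top_k
    if top_k > n:
        raise ValueError(f"top_k={top_k} exceeds bag size {n}")
    ranking = np.argsort(-scores, kind="stable")
    coords = None
    if tiles is not None:
        if len(tiles) != n:
            raise ValueError("tiles must align with bag instances")
        coords = [(t.x0, t.y0) for t in tiles]
    return AttentionReport(bag_id=bag.bag_id, scores=scores, ranking=ranking,
                           top_k=ranking[:top_k], coordinates=coords)
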