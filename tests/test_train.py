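"""Training loop, schedule, metrics, cross-validation, attention export."""

import numpy as np
import pytest

from graphmil import (
    ModelConfig,
    SyntheticConfig,
    TrainConfig,
    cross_validate,
    evaluate,
    export_attention,
    generate_bags,
    lr_schedule,
    metrics_from_predictions,
    split_cv,
    train,
)


def small_train_config(**kw):
    defaults = dict(epochs=3, lr_steps=(1, 2), batch_bags=4, seed=0)
    defaults.update(kw)
    return TrainConfig(**defaults)


@pytest.fixture(scope="module")
def trained_small():
    ds = generate_bags(SyntheticConfig(n_bags=24, bag_size_range=(4, 8), seed=6))
    split = split_cv(ds, folds=2, seed=0)[0]
    mc = ModelConfig(feature_dim=16, mlp_hidden=16, aug_dim=16, enc_hidden=8,
                     latent_dim=6, attention_hidden=8, n_kernels=2)
    trained, history = train(ds, split, mc, small_train_config())
    return ds, split, trained, history


# ----------------------------------------------------------------------
# Learning-rate schedule
# ----------------------------------------------------------------------

def test_schedule_steps_through_decades():
    cfg = TrainConfig(epochs=150, lr_steps=(30, 100))
    assert lr_schedule(0, cfg) == pytest.approx(1e-3)
    assert lr_schedule(29, cfg) == pytest.approx(1e-3)
    assert lr_schedule(30, cfg) == pytest.approx(1e-4)
    assert lr_schedule(99, cfg) == pytest.approx(1e-4)
    assert lr_schedule(100, cfg) == pytest.approx(1e-5)
    assert lr_schedule(149, cfg) == pytest.approx(1e-5)


def test_schedule_is_nonincreasing_with_correct_endpoints():
    cfg = TrainConfig(epochs=50, lr_steps=(10, 20, 35), lr_init=1e-2,
                      lr_final=1e-5)
    lrs = [lr_schedule(e, cfg) for e in range(cfg.epochs)]
    assert lrs[0] == pytest.approx(cfg.lr_init)
    assert lrs[-1] == pytest.approx(cfg.lr_final)
    assert all(b <= a + 1e-15 for a, b in zip(lrs, lrs[1:]))


def test_invalid_schedules_rejected():
    with pytest.raises(ValueError):
        TrainConfig(epochs=10, lr_steps=(3, 3))
    with pytest.raises(ValueError):
        TrainConfig(epochs=10, lr_steps=(5, 12))
    with pytest.raises(ValueError):
        TrainConfig(lr_init=1e-5, lr_final=1e-3)


# ----------------------------------------------------------------------
# Metrics
# ----------------------------------------------------------------------

def test_confusion_fixture_metrics():
    """TP=3, FP=1, FN=2, TN=4 gives accuracy 0.7, precision 0.75,
    recall 0.6, binary F1 = 2PR/(P+R) = 2/3."""
    y_true = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
    y_pred = [1, 1, 1, 0, 0, 1, 0, 0, 0, 0]
    rep = metrics_from_predictions(y_true, np.array(y_pred, dtype=float),
                                   y_pred=y_pred)
    assert rep.confusion == (3, 1, 2, 4)
    assert rep.accuracy == pytest.approx(0.7)
    assert rep.precision == pytest.approx(0.75)
    assert rep.recall == pytest.approx(0.6)
    p, r = 0.75, 0.6
    f1_pos = 2 * p * r / (p + r)
    assert f1_pos == pytest.approx(2 / 3, abs=1e-4)


def test_perfect_predictions_score_one():
    y = [0, 1, 0, 1]
    rep = metrics_from_predictions(y, np.array(y, dtype=float))
    assert (rep.accuracy, rep.precision, rep.recall, rep.f1_weighted,
            rep.roc_auc) == (1.0, 1.0, 1.0, 1.0, 1.0)


def test_perfectly_ordered_scores_give_unit_auc(rng):
    y = np.array([0] * 10 + [1] * 10)
    scores = np.concatenate([rng.uniform(0, 0.4, 10), rng.uniform(0.6, 1, 10)])
    assert metrics_from_predictions(y, scores).roc_auc == 1.0


def test_auc_equals_pairwise_comparison_oracle(rng):
    """ROC-AUC is the normalized Mann-Whitney U: the fraction of
    (positive, negative) pairs ranked correctly, ties counting half."""
    for _ in range(10):
        n = int(rng.integers(10, 50))
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            continue
        scores = np.round(rng.uniform(0, 1, n), 2)  # induce some ties
        pos, neg = scores[y == 1], scores[y == 0]
        wins = (pos[:, None] > neg[None, :]).sum()
        ties = (pos[:, None] == neg[None, :]).sum()
        oracle = (wins + 0.5 * ties) / (len(pos) * len(neg))
        assert metrics_from_predictions(y, scores).roc_auc == pytest.approx(oracle)


def test_single_class_auc_is_undefined_marker():
    rep = metrics_from_predictions([1, 1, 1], [0.2, 0.8, 0.6])
    assert rep.roc_auc is None
    assert rep.accuracy is not None


def test_zero_division_metrics_flagged():
    rep = metrics_from_predictions([0, 0, 1], [0.1, 0.2, 0.3])  # no predicted pos
    assert rep.precision == 0.0
    assert "precision" in rep.degenerate


def test_accuracy_bounded_by_classwise_recalls(rng):
    """accuracy = prevalence-weighted mean of class recalls, hence lies
    between the min and max class recall (direct-count oracle)."""
    for _ in range(20):
        n = int(rng.integers(10, 60))
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            continue
        pred = rng.integers(0, 2, n)
        rep = metrics_from_predictions(y, pred.astype(float), y_pred=pred)
        rec_pos = (pred[y == 1] == 1).mean()
        rec_neg = (pred[y == 0] == 0).mean()
        assert min(rec_pos, rec_neg) - 1e-12 <= rep.accuracy <= max(
            rec_pos, rec_neg) + 1e-12


# ----------------------------------------------------------------------
# Training
# ----------------------------------------------------------------------

def test_history_has_one_record_per_epoch(trained_small):
    _, _, _, history = trained_small
    assert len(history) == 3
    assert [h["epoch"] for h in history] == [0, 1, 2]
    assert {"loss", "ce", "neg_elbo", "lr", "val_f1_weighted"} <= history[0].keys()


def test_training_is_reproducible_from_seed():
    ds = generate_bags(SyntheticConfig(n_bags=16, bag_size_range=(4, 6), seed=2))
    split = split_cv(ds, folds=2, seed=0)[0]
    mc = ModelConfig(feature_dim=16, mlp_hidden=8, aug_dim=8, enc_hidden=6,
                     latent_dim=4, attention_hidden=4, n_kernels=2)
    _, h1 = train(ds, split, mc, small_train_config(epochs=2, lr_steps=(1,)))
    _, h2 = train(ds, split, mc, small_train_config(epochs=2, lr_steps=(1,)))
    assert h1 == h2


def test_empty_train_split_raises(trained_small):
    ds, split, _, _ = trained_small
    from graphmil.data import CVSplit

    empty = CVSplit(fold_index=0, train_ids=[], val_ids=split.val_ids,
                    test_ids=split.test_ids)
    with pytest.raises(ValueError, match="empty train"):
        train(ds, empty, ModelConfig(feature_dim=16), small_train_config())


def test_evaluate_covers_requested_ids(trained_small):
    ds, split, trained, _ = trained_small
    rep = evaluate(trained, ds, split.test_ids)
    assert sum(rep.confusion) == len(split.test_ids)
    assert set(rep.scores) == set(split.test_ids)


# ----------------------------------------------------------------------
# Cross-validation
# ----------------------------------------------------------------------

def test_cross_validation_aggregates_folds():
    ds = generate_bags(SyntheticConfig(n_bags=20, bag_size_range=(4, 6), seed=9))
    mc = ModelConfig(feature_dim=16, mlp_hidden=8, aug_dim=8, enc_hidden=6,
                     latent_dim=4, attention_hidden=4, n_kernels=2)
    report = cross_validate(ds, folds=2, model_config=mc,
                            train_config=small_train_config(epochs=2,
                                                            lr_steps=(1,)))
    assert len(report.folds) == 2
    accs = [r.accuracy for r in report.folds]
    assert min(accs) <= report.mean["accuracy"] <= max(accs)


# ----------------------------------------------------------------------
# Attention export
# ----------------------------------------------------------------------

def test_attention_report_contracts(trained_small):
    ds, split, trained, _ = trained_small
    bag = ds.get(split.test_ids[0])
    rep = export_attention(trained, bag, top_k=bag.n_instances)
    assert rep.scores.shape == (bag.n_instances,)
    assert rep.scores.sum() == pytest.approx(1.0)
    assert sorted(rep.ranking) == list(range(bag.n_instances))
    assert len(rep.top_k) == bag.n_instances
    with pytest.raises(ValueError):
        export_attention(trained, bag, top_k=bag.n_instances + 1)


def test_attention_carries_tile_coordinates(trained_small):
    from graphmil import Tile

    ds, split, trained, _ = trained_small
    bag = ds.get(split.test_ids[0])
    tiles = [Tile(512 * i, 0, 512) for i in range(bag.n_instances)]
    rep = export_attention(trained, bag, top_k=3, tiles=tiles)
    assert rep.coordinates[1] == (512, 0)


def test_untrained_model_cannot_export(trained_small):
    ds, split, trained, _ = trained_small
    trained.model.trained_ = False
    try:
        with pytest.raises(RuntimeError, match="trained"):
            export_attention(trained, ds.get(split.test_ids[0]))
    finally:
        trained.model.trained_ = True
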