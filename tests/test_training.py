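"""Training loop determinism, metric identities, and the comparison harness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from callernet.audio import ValidationError
from callernet.models import YamNet1dConfig, build_yamnet_1d
from callernet.nn import Adam, softmax_cross_entropy
from callernet.training import (
    ArrayDataset, ComparisonSpec, EvalReport, TrainConfig, clips_to_dataset,
    evaluate, report_from_predictions, run_comparison, synthetic_split_clips,
    train,
)

CLASSES = ("roar", "rumble", "trumpet")


def _tiny_model(seed=0):
    return build_yamnet_1d(YamNet1dConfig(
        stem_channels=8, blocks=((16, 2), (32, 2)), depthwise_kernel=5), seed=seed)


def _tiny_data(seed=0, n=24, length=2048):
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 3
    # three distinguishable tones
    t = np.arange(length) / 4000.0
    x = np.stack([np.sin(2 * np.pi * (100 + 400 * c) * t) + 0.05 * rng.standard_normal(length)
                  for c in y]).astype(np.float32)
    return ArrayDataset(x, y, CLASSES)


def test_training_is_deterministic_per_seed():
    results = []
    for _ in range(2):
        model = _tiny_model(seed=5)
        res = train(model, _tiny_data(0), _tiny_data(1, n=9),
                    TrainConfig(learning_rate=1e-3, train_batch=8, epochs=3, seed=5))
        results.append(res)
    assert results[0].curves.train_loss == results[1].curves.train_loss
    assert results[0].curves.val_accuracy == results[1].curves.val_accuracy


def test_single_batch_overfit():
    model = _tiny_model(seed=1)
    data = _tiny_data(2, n=8)
    opt = Adam(model.parameters(), lr=2e-3)
    model.train()
    first = None
    for _ in range(200):
        logits = model.forward_logits(data.x)
        loss, g = softmax_cross_entropy(logits, data.y)
        first = first if first is not None else loss
        opt.zero_grad()
        model.backward(g)
        opt.step()
    assert loss < 0.1 * first


def test_curves_length_and_best_checkpoint():
    model = _tiny_model(seed=2)
    res = train(model, _tiny_data(0), _tiny_data(1, n=9),
                TrainConfig(learning_rate=1e-3, train_batch=8, epochs=4, seed=2))
    assert len(res.curves.val_accuracy) == 4
    assert res.best_val_accuracy >= max(res.curves.val_accuracy) - 1e-9


def test_nonfinite_loss_aborts_with_diagnostics():
    model = _tiny_model(seed=3)
    # a diverged weight state must abort with lr/epoch/batch context
    model.parameters()[-1].data[...] = np.nan
    with pytest.raises(RuntimeError, match="epoch=1"):
        train(model, _tiny_data(0, n=8), _tiny_data(1, n=6),
              TrainConfig(learning_rate=1e-3, epochs=1, seed=0))


# --- metrics ----------------------------------------------------------------

def test_perfect_predictions_give_diagonal_matrix():
    y = np.array([0, 1, 2, 1, 0])
    rep = report_from_predictions(y, y, CLASSES)
    assert np.trace(rep.confusion_matrix) == 5
    assert rep.overall_accuracy == 1.0
    assert all(v == 1.0 for v in rep.f1.values())


def test_two_thirds_accuracy_example():
    rep = report_from_predictions(np.array([0, 0, 2]), np.array([0, 2, 2]), CLASSES)
    assert rep.overall_accuracy == pytest.approx(2 / 3)


def test_precision_recall_hand_arithmetic():
    # confusion matrix [[5,1,0],[0,6,2],[1,0,3]] (rows = true class)
    y_true = np.repeat([0, 1, 2], [6, 8, 4])
    y_pred = np.concatenate([
        [0] * 5 + [1], [1] * 6 + [2] * 2, [0] + [2] * 3])
    rep = report_from_predictions(y_true, y_pred, CLASSES)
    assert rep.confusion_matrix.tolist() == [[5, 1, 0], [0, 6, 2], [1, 0, 3]]
    assert rep.precision[CLASSES[0]] == pytest.approx(5 / 6)
    assert rep.precision[CLASSES[1]] == pytest.approx(6 / 7)
    assert rep.precision[CLASSES[2]] == pytest.approx(3 / 5)
    assert rep.recall[CLASSES[0]] == pytest.approx(5 / 6)
    assert rep.recall[CLASSES[1]] == pytest.approx(6 / 8)
    assert rep.recall[CLASSES[2]] == pytest.approx(3 / 4)
    assert rep.per_class_accuracy == rep.recall


def test_empty_test_set_rejected():
    with pytest.raises(ValidationError):
        report_from_predictions(np.array([]), np.array([]), CLASSES)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 2), st.integers(0, 2)), min_size=1, max_size=60))
def test_confusion_matrix_identities(pairs):
    y_true = np.array([a for a, _ in pairs])
    y_pred = np.array([b for _, b in pairs])
    rep = report_from_predictions(y_true, y_pred, CLASSES)
    cm = rep.confusion_matrix
    assert (cm >= 0).all()
    assert cm.sum(axis=1).tolist() == [int((y_true == i).sum()) for i in range(3)]
    assert rep.overall_accuracy == pytest.approx(np.trace(cm) / len(pairs))
    macro_f1 = np.mean(list(rep.f1.values()))
    assert 0.0 <= macro_f1 <= 1.0


# --- comparison harness -----------------------------------------------------

@pytest.fixture(scope="module")
def tiny_comparison():
    spec = ComparisonSpec(
        pipelines=("raw",), models=("yamnet", "rawnet"),
        regimes=("none", "approach1"), seeds=(0,),
        clips_per_class=6, duration_s=1.0, sample_rate=4000,
        epochs=2, train_batch=8, learning_rate=1e-3)
    return spec, run_comparison(spec)


def test_comparison_grid_cardinality(tiny_comparison):
    _, (table, artifacts) = tiny_comparison
    assert len(table) == 4  # 2 models x 2 regimes x 1 seed
    assert set(table["regime"]) == {"none", "approach1"}
    assert len(artifacts) == 4


def test_comparison_rerun_is_identical(tiny_comparison):
    spec, (table, _) = tiny_comparison
    table2, _ = run_comparison(spec)
    assert table.drop(columns=["run_id"]).equals(table2.drop(columns=["run_id"]))


def test_approach1_balances_training_counts(tiny_comparison):
    _, (table, artifacts) = tiny_comparison
    for run_id in table["run_id"]:
        counts = artifacts[run_id]["train_counts"]
        if ":approach1:" in run_id:
            assert len(set(counts.values())) == 1  # balanced classes
        else:
            assert counts == {"roar": 4, "rumble": 4, "trumpet": 4}


def test_no_test_clip_leaks_into_training():
    splits = synthetic_split_clips(10, 0.5, 4000, seed=0)
    train_ids = {id(c) for c in splits["train"]} | {id(c) for c in splits["val"]}
    assert all(id(c) not in train_ids for c in splits["test"])
    sig = lambda c: c.samples.tobytes()
    train_sigs = {sig(c) for c in splits["train"]} | {sig(c) for c in splits["val"]}
    assert all(sig(c) not in train_sigs for c in splits["test"])


def test_unknown_model_rejected():
    with pytest.raises(ValidationError):
        ComparisonSpec(models=("transformer",)).validate()


def test_clips_to_dataset_labels(small_call_clips):
    data = clips_to_dataset(small_call_clips)
    assert len(data) == len(small_call_clips)
    assert set(np.unique(data.y)) == {0, 1, 2}
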