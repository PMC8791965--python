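"""Training protocol: losses, schedule determinism, checkpointing, and the
fine-tuning rules."""

import numpy as np
import pytest

from tests.conftest import plane_arrays
from gestage import FinetuneConfig, PhantomConfig, TrainConfig, \
    generate_cohort, load_checkpoint, mse_loss, save_checkpoint, total_loss
from gestage.estimators import DualBranchAgeRegressor
from gestage.evaluation import mae_days
from gestage.model import BackboneSpec, build_model
from gestage.training import finetune, predict_dataset, train


@pytest.fixture(scope="module")
def tiny_dataset():
    subs = generate_cohort(PhantomConfig(), 60, seed=21)
    return plane_arrays(subs)


def test_mse_examples_and_loop_oracle():
    assert mse_loss([210.0, 224.0], [210.0, 224.0]) == 0.0
    assert mse_loss((210.0, 224.0), (217.0, 217.0)) == pytest.approx(49.0)
    rng = np.random.default_rng(0)
    a, b = rng.normal(size=30), rng.normal(size=30)
    assert mse_loss(a, b) == pytest.approx(
        sum((x - z) ** 2 for x, z in zip(a, b)) / 30, abs=1e-9)
    with pytest.raises(ValueError):
        mse_loss([], [])


def test_total_loss_examples():
    one_plane = {"axial": {"y_true": [210.0], "y_global": [217.0],
                           "y_local": [203.0]}}
    assert total_loss(one_plane) == pytest.approx(49.0 + 49.0)
    perfect = {p: {"y_true": [210.0], "y_global": [210.0],
                   "y_local": [210.0]} for p in ("axial", "coronal")}
    assert total_loss(perfect) == 0.0
    # zero local weight reduces to the global-only comparator objective
    assert total_loss(one_plane, loss_weights=(1.0, 0.0)) == pytest.approx(49.0)
    global_only = {"axial": {"y_true": [210.0], "y_global": [217.0],
                             "y_local": None}}
    assert total_loss(global_only) == pytest.approx(49.0)


def test_train_config_validation_and_paper_defaults():
    config = TrainConfig()
    assert (config.learning_rate, config.batch_size, config.iterations) == \
        (1e-4, 50, 2000)
    with pytest.raises(ValueError):
        TrainConfig(iterations=0)
    with pytest.raises(ValueError):
        TrainConfig(loss_weights=(0.0, 0.0))
    with pytest.raises(ValueError):
        TrainConfig(optimizer="sgd")


def test_training_beats_constant_mean_predictor(tiny_dataset):
    x, y = tiny_dataset
    model = build_model(BackboneSpec(), seed=0)
    config = TrainConfig.desk(iterations=120, seed=0)
    history = train(model, (x[:45], y[:45]), (x[45:], y[45:]), config)
    baseline = mae_days(y[45:], np.full(15, y[:45].mean()))
    assert history["best_mae"] < baseline
    assert len(history["loss"]) == 120


def test_training_is_deterministic(tiny_dataset):
    x, y = tiny_dataset
    curves = []
    for _ in range(2):
        model = build_model(BackboneSpec(), seed=3)
        history = train(model, (x[:40], y[:40]), (x[40:], y[40:]),
                        TrainConfig.desk(iterations=25, seed=3))
        curves.append(history["loss"])
    assert curves[0] == curves[1]


def test_training_divergence_aborts_with_diagnostics(tiny_dataset):
    x, y = tiny_dataset
    model = build_model(BackboneSpec(), seed=1)
    # absurd learning rate drives the loss non-finite within a few steps
    config = TrainConfig.desk(learning_rate=1e12, iterations=60,
                              eval_every=60, seed=1)
    with pytest.raises(RuntimeError, match="diverged"):
        train(model, (x[:40], y[:40]), (x[40:], y[40:]), config)


def test_checkpoint_round_trip_preserves_predictions(tiny_dataset, tmp_path):
    x, y = tiny_dataset
    model = build_model(BackboneSpec(), seed=2)
    train(model, (x[:40], y[:40]), (x[40:], y[40:]),
          TrainConfig.desk(iterations=30, seed=2))
    before = predict_dataset(model, x[40:])
    path = tmp_path / "ckpt.npz"
    save_checkpoint(model, path, extra_meta={"note": "test"})
    models, extra = load_checkpoint(path)
    assert extra == {"note": "test"}
    after = predict_dataset(models["single"], x[40:])
    assert np.allclose(before, after, atol=1e-6)


def test_finetune_zero_epochs_is_a_no_op(tiny_dataset):
    x, y = tiny_dataset
    est = DualBranchAgeRegressor(iterations=40, random_state=0).fit(x, y)
    report = est.finetune(x[:20], y[:20],
                          config=FinetuneConfig.desk(max_epochs=0, seed=0))
    assert report["epochs_run"] == 0
    assert report["finetuned"]["mae"] == pytest.approx(
        report["zero_shot"]["mae"], abs=1e-9)


def test_finetune_small_set_selects_reduced_learning_rate(tiny_dataset):
    x, y = tiny_dataset
    model = build_model(BackboneSpec(), seed=4)
    train(model, (x[:40], y[:40]), (x[40:], y[40:]),
          TrainConfig.desk(iterations=20, seed=4))
    config = FinetuneConfig.desk(max_epochs=1, seed=0)
    # 25 external subjects -> floor(0.2*25) = 5 adaptation samples
    report = finetune(model, (x[:25], y[:25]), config=config)
    assert report["n_adapt"] == 5
    assert report["learning_rate"] == config.small_set_learning_rate
    # a larger site uses the standard fine-tuning rate
    model2 = build_model(BackboneSpec(), seed=4)
    train(model2, (x[:40], y[:40]), (x[40:], y[40:]),
          TrainConfig.desk(iterations=20, seed=4))
    report2 = finetune(model2, (x, y), config=config)
    assert report2["n_adapt"] == 12
    assert report2["learning_rate"] == config.learning_rate


def test_finetune_config_validation():
    with pytest.raises(ValueError):
        FinetuneConfig(adapt_fraction=0.0)
    defaults = FinetuneConfig()
    assert defaults.learning_rate == 1e-5
    assert defaults.small_set_learning_rate == 1e-6
    assert defaults.batch_size == 5
    assert defaults.early_stop_epochs == 5


def test_global_only_training_ignores_local_weight(tiny_dataset):
    """With the local loss weight at zero and attention disabled, the
    objective is the global branch's MSE alone: the loss curves of a dual
    model with w_local=0 and a global-only model coincide."""
    x, y = tiny_dataset
    curves = {}
    for mode, weights in (("dual", (1.0, 0.0)), ("global_only", (1.0, 1.0))):
        model = build_model(BackboneSpec(), mode=mode,
                            gradient_through_mask=False, seed=5)
        history = train(model, (x[:40], y[:40]), (x[40:], y[40:]),
                        TrainConfig.desk(iterations=15, seed=5,
                                         loss_weights=weights))
        curves[mode] = history["loss"]
    assert np.allclose(curves["dual"], curves["global_only"], rtol=1e-6)
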