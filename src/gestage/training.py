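"""Optimization protocol: joint global+local MSE, validation-tracked
checkpointing, and the small-sample fine-tuning procedure for new sites.

The published schedule (Adam, learning rate 1e-4, batch 50, 2000 optimizer
steps) is the default ``TrainConfig``; ``TrainConfig.desk()`` is a separate
preset for desk-scale experiments on the tiny backbone. Per-branch MSE
losses are summed (over planes, for multi-plane training); the fused
branch average carries no loss term of its own by default, with a flag for
ablation. Fine-tuning re-optimizes a trained model on a small adaptation
fraction of a new site's data with a reduced learning rate (and a further
reduced one when five or fewer samples are available), early-stopping when
the adaptation loss stops improving.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .evaluation import mae_days, r2_score
from .model import AttentionSettings, BackboneSpec, DualBranchModel
from .nn import Adam, Tensor

__all__ = ["TrainConfig", "FinetuneConfig", "mse_loss", "total_loss",
           "train", "finetune", "predict_dataset", "save_checkpoint",
           "load_checkpoint"]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 50
    iterations: int = 2000
    optimizer: str = "adam"
    loss_weights: tuple[float, float] = (1.0, 1.0)  # (w_global, w_local)
    fused_loss_weight: float = 0.0
    eval_every: int = 50
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.iterations) <= 0:
            raise ValueError("rate, batch size and iterations must be positive")
        if any(w < 0 for w in self.loss_weights) or sum(self.loss_weights) == 0:
            raise ValueError("loss weights must be >= 0 and not both zero")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")

    @classmethod
    def desk(cls, **overrides) -> "TrainConfig":
        """Desk-scale preset: tiny backbone, small images, a few hundred
        steps on one CPU."""
        base = dict(learning_rate=1e-2, batch_size=25, iterations=300,
                    eval_every=50)
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class FinetuneConfig:
    learning_rate: float = 1e-5
    small_set_learning_rate: float = 1e-6
    small_set_threshold: int = 5     # adapt sets this small use the lower rate
    batch_size: int = 5
    early_stop_epochs: int = 5
    adapt_fraction: float = 0.20
    max_epochs: int = 50
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.adapt_fraction < 1.0:
            raise ValueError("adapt_fraction must lie in (0, 1)")

    @classmethod
    def desk(cls, **overrides) -> "FinetuneConfig":
        base = dict(learning_rate=1e-3, small_set_learning_rate=1e-4,
                    max_epochs=30)
        base.update(overrides)
        return cls(**base)


def mse_loss(y_true, y_pred) -> float:
    """Mean squared error between true and predicted ages (days^2)."""
    y_true = np.asarray(y_true, dtype=np.float64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.float64).ravel()
    if y_true.size == 0:
        raise ValueError("empty batch")
    if y_true.shape != y_pred.shape:
        raise ValueError("batch length mismatch")
    return float(np.mean((y_true - y_pred) ** 2))


def total_loss(batch: dict, loss_weights: tuple[float, float] = (1.0, 1.0)
               ) -> float:
    """Plane-summed training objective.

    ``batch`` maps plane -> {"y_true", "y_global", "y_local" (optional)};
    the result is sum over planes of w_g*MSE(y, y_g) + w_l*MSE(y, y_l),
    with the local term dropped in global-only batches.
    """
    w_g, w_l = loss_weights
    out = 0.0
    for plane_batch in batch.values():
        y = plane_batch["y_true"]
        out += w_g * mse_loss(y, plane_batch["y_global"])
        if plane_batch.get("y_local") is not None and w_l > 0:
            out += w_l * mse_loss(y, plane_batch["y_local"])
    return out


def _as_plane_dict(models, data):
    """Normalize (model, (X, y)) and ({plane: model}, ({plane: X}, y))."""
    x, y = data
    if isinstance(models, DualBranchModel):
        return {"single": models}, {"single": np.asarray(x, dtype=np.float32)}, \
            np.asarray(y, dtype=np.float64)
    return dict(models), {p: np.asarray(x[p], dtype=np.float32) for p in models}, \
        np.asarray(y, dtype=np.float64)


def predict_dataset(models, x, batch_size: int = 64) -> np.ndarray:
    """Fused prediction, averaged over planes for multi-plane input."""
    if isinstance(models, DualBranchModel):
        models, x = {"single": models}, {"single": x}
    per_plane = []
    for plane, model in models.items():
        arr = np.asarray(x[plane], dtype=np.float32)
        preds = [model.predict_batch(arr[i:i + batch_size])["y_pred"]
                 for i in range(0, arr.shape[0], batch_size)]
        per_plane.append(np.concatenate(preds))
    return np.mean(per_plane, axis=0)


def _batch_loss_tensor(model, xb, yb, config: TrainConfig) -> Tensor:
    out = model.forward(Tensor(xb))
    target = Tensor(yb.astype(np.float32))
    w_g, w_l = config.loss_weights
    loss = ((out["y_global"] - target) ** 2).mean() * w_g
    if out["y_local"] is not None and w_l > 0:
        loss = loss + ((out["y_local"] - target) ** 2).mean() * w_l
    if config.fused_loss_weight > 0:
        loss = loss + (((out["y_pred"] - target) ** 2).mean()
                       * config.fused_loss_weight)
    return loss


def train(models, train_set, val_set, config: TrainConfig | None = None
          ) -> dict:
    """Optimize one model (or a plane-keyed dict of models under the summed
    multi-plane loss), tracking the best-on-validation checkpoint.

    Returns a history dict with per-step losses, periodic validation
    R²/MAE, and the step of the restored best checkpoint. Deterministic
    given the config seed.
    """
    config = config or TrainConfig()
    models_d, x_train, y_train = _as_plane_dict(models, train_set)
    _, x_val, y_val = _as_plane_dict(
        models if isinstance(models, DualBranchModel) else models_d, val_set)
    if y_train.size == 0 or y_val.size == 0:
        raise ValueError("training and validation sets must be non-empty")

    loc, scale = float(y_train.mean()), float(max(y_train.std(), 1e-6))
    for model in models_d.values():
        model.set_calibration(loc, scale)
        model.train(True)

    params = [p for m in models_d.values() for p in m.parameters()]
    opt = Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    n = y_train.size
    batch = min(config.batch_size, n)

    history = {"loss": [], "val": [], "best_step": None, "best_mae": np.inf}
    best_states = None

    def validate(step):
        for m in models_d.values():
            m.train(False)
        preds = predict_dataset(models_d, x_val)
        for m in models_d.values():
            m.train(True)
        mae = mae_days(y_val, preds)
        rec = {"step": step, "mae": mae,
               "r2": r2_score(y_val, preds) if np.ptp(y_val) > 0 else np.nan}
        history["val"].append(rec)
        return mae

    for step in range(1, config.iterations + 1):
        idx = rng.choice(n, size=batch, replace=False)
        loss = None
        for plane, model in models_d.items():
            pl = _batch_loss_tensor(model, x_train[plane][idx],
                                    y_train[idx], config)
            loss = pl if loss is None else loss + pl
        value = float(loss.data)
        if not np.isfinite(value):
            raise RuntimeError(
                f"training diverged at step {step}: loss={value} "
                f"(lr={config.learning_rate}, batch={batch})")
        opt.zero_grad()
        loss.backward()
        opt.step()
        history["loss"].append(value)
        if step % config.eval_every == 0 or step == config.iterations:
            mae = validate(step)
            if mae < history["best_mae"]:
                history["best_mae"] = mae
                history["best_step"] = step
                best_states = {p: m.state_dict()
                               for p, m in models_d.items()}

    if best_states is not None:
        for plane, model in models_d.items():
            model.load_state_dict(best_states[plane])
    for model in models_d.values():
        model.train(False)
    return history


def finetune(models, external_set, config: FinetuneConfig | None = None,
             subject_ids=None) -> dict:
    """Adapt a trained model to a domain-shifted site.

    Splits the external cohort into an adaptation fraction and a held-out
    test set, re-optimizes on the adaptation set with the reduced learning
    rate (further reduced when the adaptation set has at most
    ``small_set_threshold`` samples), early-stopping when the adaptation
    loss has not improved for ``early_stop_epochs`` epochs, and reports
    zero-shot versus fine-tuned R²/MAE on the held-out subjects.
    """
    from .preprocessing import finetune_split

    config = config or FinetuneConfig()
    models_d, x_ext, y_ext = _as_plane_dict(models, external_set)
    n = y_ext.size
    ids = list(subject_ids) if subject_ids is not None \
        else [str(i) for i in range(n)]
    adapt_ids, test_ids = finetune_split(ids, fraction=config.adapt_fraction,
                                         seed=config.seed)
    pos = {s: i for i, s in enumerate(ids)}
    adapt_idx = np.array([pos[s] for s in adapt_ids])
    test_idx = np.array([pos[s] for s in test_ids])

    x_test = {p: x[test_idx] for p, x in x_ext.items()}
    y_test = y_ext[test_idx]
    zero_preds = predict_dataset(models_d, x_test)
    report = {"zero_shot": {"mae": mae_days(y_test, zero_preds),
                            "r2": r2_score(y_test, zero_preds)},
              "n_adapt": int(adapt_idx.size), "n_test": int(test_idx.size)}

    lr = (config.small_set_learning_rate
          if adapt_idx.size <= config.small_set_threshold
          else config.learning_rate)
    report["learning_rate"] = lr
    step_config = TrainConfig(learning_rate=lr, batch_size=config.batch_size,
                              iterations=1, seed=config.seed)

    params = [p for m in models_d.values() for p in m.parameters()]
    opt = Adam(params, lr=lr)
    rng = np.random.default_rng(config.seed)
    best_loss = np.inf
    best_states = {p: m.state_dict() for p, m in models_d.items()}
    stale = 0
    epochs_run = 0
    for model in models_d.values():
        model.train(True)
    for epoch in range(config.max_epochs):
        order = rng.permutation(adapt_idx.size)
        epoch_losses = []
        for start in range(0, adapt_idx.size, config.batch_size):
            sel = adapt_idx[order[start:start + config.batch_size]]
            loss = None
            for plane, model in models_d.items():
                pl = _batch_loss_tensor(model, x_ext[plane][sel],
                                        y_ext[sel], step_config)
                loss = pl if loss is None else loss + pl
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        epochs_run = epoch + 1
        epoch_loss = float(np.mean(epoch_losses))
        if epoch_loss < best_loss - 1e-12:
            best_loss = epoch_loss
            best_states = {p: m.state_dict() for p, m in models_d.items()}
            stale = 0
        else:
            stale += 1
            if stale >= config.early_stop_epochs:
                break
    for plane, model in models_d.items():
        model.load_state_dict(best_states[plane])
        model.train(False)

    tuned_preds = predict_dataset(models_d, x_test)
    report["finetuned"] = {"mae": mae_days(y_test, tuned_preds),
                           "r2": r2_score(y_test, tuned_preds)}
    report["delta_mae"] = report["finetuned"]["mae"] - report["zero_shot"]["mae"]
    report["epochs_run"] = epochs_run
    return report


# -- checkpoint round-trip -------------------------------------------------

def save_checkpoint(models, path, extra_meta: dict | None = None) -> None:
    """Serialize one model or a plane-keyed dict of models to an .npz file
    together with the configuration needed to rebuild them."""
    if isinstance(models, DualBranchModel):
        models = {"single": models}
    arrays = {}
    meta: dict = {"planes": {}, "extra": extra_meta or {}}
    for plane, model in models.items():
        meta["planes"][plane] = {
            "spec": asdict(model.spec), "mode": model.mode,
            "attention": asdict(model.attention),
            "gradient_through_mask": model.gradient_through_mask}
        for key, value in model.state_dict().items():
            arrays[f"{plane}::{key}"] = value
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[dict[str, DualBranchModel], dict]:
    """Rebuild the models stored by :func:`save_checkpoint`."""
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode("utf-8"))
        models = {}
        for plane, info in meta["planes"].items():
            spec_info = dict(info["spec"])
            spec_info["weights"] = None
            spec = BackboneSpec(**spec_info)
            model = DualBranchModel(
                spec, mode=info["mode"],
                attention=AttentionSettings(**{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in info["attention"].items()}),
                gradient_through_mask=info["gradient_through_mask"])
            prefix = plane + "::"
            state = {k[len(prefix):]: archive[k] for k in archive.files
                     if k.startswith(prefix)}
            model.load_state_dict(state)
            model.train(False)
            models[plane] = model
    return models, meta["extra"]
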