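"""scikit-learn style estimators wrapping the dual-branch network.

``DualBranchAgeRegressor`` fits one plane; ``MultiPlaneAgeRegressor`` fits
one network per anatomical plane under the summed loss and averages their
fused predictions. Both follow the sklearn contract (``get_params`` /
``set_params``, fitted attributes with trailing underscores, ``score`` =
R²) so they compose with pipelines and model selection; the functional
interfaces in :mod:`gestage.training` and :mod:`gestage.model` are what
these classes drive underneath.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import train_test_split

from .model import AttentionSettings, BackboneSpec, build_model
from .training import FinetuneConfig, TrainConfig, finetune, predict_dataset, train

__all__ = ["DualBranchAgeRegressor", "MultiPlaneAgeRegressor"]


def _check_images(X, n_slices: int) -> np.ndarray:
    X = np.asarray(X, dtype=np.float32)
    if X.ndim != 4:
        raise ValueError("X must be (n_samples, n_slices, height, width)")
    if X.shape[1] != n_slices:
        raise ValueError(f"X has {X.shape[1]} slices per sample; the "
                         f"estimator was configured for {n_slices}")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    return X


class DualBranchAgeRegressor(RegressorMixin, BaseEstimator):
    """Attention-guided dual-branch convolutional age regressor (one plane).

    Parameters mirror the training protocol: a residual backbone family,
    the slice count of the input slab, the dual/global-only mode, the
    attention settings (normalization percentile and Gaussian center
    prior), and the Adam schedule. Defaults are the desk-scale preset;
    paper-scale values (ResNet-50, lr 1e-4, batch 50, 2000 iterations)
    are available by parameter.

    Attributes set by fit: ``model_`` (the network, best-on-validation
    checkpoint restored), ``history_`` (loss curve and validation R²/MAE).
    """

    def __init__(self, backbone: str = "tiny", n_slices: int = 3,
                 image_size: int = 64, mode: str = "dual", pool: str = "avg",
                 attention_percentile: float = 100.0,
                 attention_sigma_fraction: float = 0.25,
                 gradient_through_mask: bool = True,
                 learning_rate: float = 1e-2, batch_size: int = 25,
                 iterations: int = 300,
                 loss_weights: tuple[float, float] = (1.0, 1.0),
                 eval_every: int = 50, validation_fraction: float = 0.125,
                 random_state: int = 0):
        self.backbone = backbone
        self.n_slices = n_slices
        self.image_size = image_size
        self.mode = mode
        self.pool = pool
        self.attention_percentile = attention_percentile
        self.attention_sigma_fraction = attention_sigma_fraction
        self.gradient_through_mask = gradient_through_mask
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.iterations = iterations
        self.loss_weights = loss_weights
        self.eval_every = eval_every
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _build(self):
        spec = BackboneSpec(family=self.backbone, in_channels=self.n_slices,
                            input_size=self.image_size, pool=self.pool)
        attention = AttentionSettings(
            percentile=self.attention_percentile,
            sigma_fraction=self.attention_sigma_fraction)
        return build_model(spec, mode=self.mode, attention=attention,
                           gradient_through_mask=self.gradient_through_mask,
                           seed=self.random_state)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(learning_rate=self.learning_rate,
                           batch_size=self.batch_size,
                           iterations=self.iterations,
                           loss_weights=tuple(self.loss_weights),
                           eval_every=self.eval_every,
                           seed=self.random_state)

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y, validation_data=None):
        X = _check_images(X, self.n_slices)
        y = np.asarray(y, dtype=np.float64).ravel()
        if y.size != X.shape[0]:
            raise ValueError("X and y length mismatch")
        if validation_data is None:
            X_tr, X_val, y_tr, y_val = train_test_split(
                X, y, test_size=self.validation_fraction,
                random_state=self.random_state)
        else:
            X_tr, y_tr = X, y
            X_val = _check_images(validation_data[0], self.n_slices)
            y_val = np.asarray(validation_data[1], dtype=np.float64).ravel()
        self.model_ = self._build()
        self.history_ = train(self.model_, (X_tr, y_tr), (X_val, y_val),
                              self._train_config())
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        X = _check_images(X, self.n_slices)
        return predict_dataset(self.model_, X)

    def predict_components(self, X) -> dict[str, np.ndarray]:
        """Per-branch (global/local) and fused predictions, in days."""
        self._check_fitted()
        X = _check_images(X, self.n_slices)
        out = {}
        for start in range(0, X.shape[0], 64):
            chunk = self.model_.predict_batch(X[start:start + 64])
            for key, val in chunk.items():
                out.setdefault(key, []).append(val)
        return {k: np.concatenate(v) for k, v in out.items()}

    def attention_maps(self, X) -> np.ndarray:
        """Gaussian-weighted attention heatmaps at input resolution."""
        self._check_fitted()
        if self.mode != "dual":
            raise ValueError("attention maps exist only in dual mode")
        return self.predict_components(X)["heatmap"]

    def finetune(self, X, y, config: FinetuneConfig | None = None,
                 subject_ids=None) -> dict:
        """Site adaptation on an external cohort; returns the before/after
        comparison report and updates ``model_`` in place."""
        self._check_fitted()
        X = _check_images(X, self.n_slices)
        y = np.asarray(y, dtype=np.float64).ravel()
        return finetune(self.model_, (X, y), config=config,
                        subject_ids=subject_ids)

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted; call fit first")


class MultiPlaneAgeRegressor(RegressorMixin, BaseEstimator):
    """Multi-plane ensemble: one dual-branch network per plane trained
    under the summed loss, fused predictions averaged across planes.

    ``X`` is a mapping plane-name -> (n_samples, n_slices, height, width)
    with a shared sample order; any subset of planes may be supplied at
    prediction time.
    """

    def __init__(self, planes: tuple[str, ...] = ("axial", "coronal",
                                                  "sagittal"),
                 backbone: str = "tiny", n_slices: int = 3,
                 image_size: int = 64, mode: str = "dual", pool: str = "avg",
                 attention_percentile: float = 100.0,
                 attention_sigma_fraction: float = 0.25,
                 gradient_through_mask: bool = True,
                 learning_rate: float = 1e-2, batch_size: int = 25,
                 iterations: int = 300,
                 loss_weights: tuple[float, float] = (1.0, 1.0),
                 eval_every: int = 50, validation_fraction: float = 0.125,
                 random_state: int = 0):
        self.planes = planes
        self.backbone = backbone
        self.n_slices = n_slices
        self.image_size = image_size
        self.mode = mode
        self.pool = pool
        self.attention_percentile = attention_percentile
        self.attention_sigma_fraction = attention_sigma_fraction
        self.gradient_through_mask = gradient_through_mask
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.iterations = iterations
        self.loss_weights = loss_weights
        self.eval_every = eval_every
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _check_planes(self, X) -> dict[str, np.ndarray]:
        if not isinstance(X, dict):
            raise ValueError("multi-plane X must be a dict plane -> array")
        checked = {}
        sizes = set()
        for plane in X:
            if plane not in self.planes:
                continue
            checked[plane] = _check_images(X[plane], self.n_slices)
            sizes.add(checked[plane].shape[0])
        if not checked:
            raise ValueError(f"no usable plane among {tuple(X)}; "
                             f"expected a subset of {self.planes}")
        if len(sizes) != 1:
            raise ValueError("planes carry different sample counts")
        return checked

    def fit(self, X, y, validation_data=None):
        X = self._check_planes(X)
        if set(X) != set(self.planes):
            raise ValueError(f"fit requires all planes {self.planes}")
        y = np.asarray(y, dtype=np.float64).ravel()
        n = y.size
        if validation_data is None:
            idx_tr, idx_val = train_test_split(
                np.arange(n), test_size=self.validation_fraction,
                random_state=self.random_state)
            X_tr = {p: X[p][idx_tr] for p in X}
            X_val = {p: X[p][idx_val] for p in X}
            y_tr, y_val = y[idx_tr], y[idx_val]
        else:
            X_tr, y_tr = X, y
            X_val = self._check_planes(validation_data[0])
            y_val = np.asarray(validation_data[1], dtype=np.float64).ravel()

        proto = DualBranchAgeRegressor(**{k: v for k, v in
                                          self.get_params().items()
                                          if k != "planes"})
        spec = BackboneSpec(family=self.backbone, in_channels=self.n_slices,
                            input_size=self.image_size, pool=self.pool)
        attention = AttentionSettings(
            percentile=self.attention_percentile,
            sigma_fraction=self.attention_sigma_fraction)
        self.models_ = {}
        for i, plane in enumerate(self.planes):
            # distinct init per plane, reproducible from random_state
            self.models_[plane] = build_model(
                spec, mode=self.mode, attention=attention,
                gradient_through_mask=self.gradient_through_mask,
                seed=self.random_state * 1000 + i)
        config = proto._train_config()
        self.history_ = train(self.models_, (X_tr, y_tr), (X_val, y_val),
                              config)
        return self

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        X = self._check_planes(X)
        models = {p: self.models_[p] for p in X}
        return predict_dataset(models, X)

    def predict_per_plane(self, X) -> dict[str, np.ndarray]:
        self._check_fitted()
        X = self._check_planes(X)
        return {p: predict_dataset(self.models_[p], X[p]) for p in X}

    def attention_maps(self, X) -> dict[str, np.ndarray]:
        self._check_fitted()
        X = self._check_planes(X)
        out = {}
        for plane, arr in X.items():
            model = self.models_[plane]
            maps = [model.predict_batch(arr[i:i + 64])["heatmap"]
                    for i in range(0, arr.shape[0], 64)]
            out[plane] = np.concatenate(maps)
        return out

    def finetune(self, X, y, config: FinetuneConfig | None = None,
                 subject_ids=None) -> dict:
        self._check_fitted()
        X = self._check_planes(X)
        if set(X) != set(self.models_):
            raise ValueError("fine-tuning requires all fitted planes")
        y = np.asarray(y, dtype=np.float64).ravel()
        return finetune(self.models_, (X, y), config=config,
                        subject_ids=subject_ids)

    def _check_fitted(self):
        if not hasattr(self, "models_"):
            raise AttributeError("estimator is not fitted; call fit first")
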