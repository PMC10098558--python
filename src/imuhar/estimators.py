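"""scikit-learn style estimators wrapping the end-to-end pipeline.

:class:`MovementClassifier` is the neural system (sensor encoder + temporal
model trained jointly); :class:`BaselineMovementClassifier` is the
hand-crafted-feature linear ECOC-SVM reference.  Both take the windowed
frame tensor (n_frames, 24, 120) as X and integer frame labels as y, follow
the fit/predict/predict_proba contract, and compose with sklearn model
selection (``get_params``/``set_params``/``clone``).

Because consecutive frames of one recording form the temporal context, an
optional ``recording_ids`` array (one id per frame) tells ``fit`` and
``predict_proba`` where recordings begin and end; without it the whole
input is treated as a single recording.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .augmentation import AugmentationConfig
from .baseline_features import extract_features, fit_baseline_classifier
from .encoders import EncoderSpec
from .signal_io import N_CHANNELS
from .synthetic_data import Recording
from .temporal_models import TemporalSpec
from .train_eval import (
    TrainConfig,
    confusion_matrix,
    evaluate_system,
    train_system,
    uwaf,
)


def _check_frames(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 3 or X.shape[1] != N_CHANNELS:
        raise ValueError(f"X must be (n_frames, {N_CHANNELS}, frame_len); got {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    return X


def _group_recordings(X, y, recording_ids) -> list[Recording]:
    if recording_ids is None:
        return [Recording(recording_id="rec000", frames=X, labels=y)]
    recording_ids = np.asarray(recording_ids)
    if len(recording_ids) != len(X):
        raise ValueError("recording_ids must align with frames")
    recs = []
    for rid in pd_unique(recording_ids):
        mask = recording_ids == rid
        recs.append(Recording(recording_id=str(rid), frames=X[mask], labels=y[mask]))
    return recs


def pd_unique(values: np.ndarray) -> np.ndarray:
    """Unique values in order of first appearance."""
    _, idx = np.unique(values, return_index=True)
    return values[np.sort(idx)]


class MovementClassifier(BaseEstimator, ClassifierMixin):
    """End-to-end neural movement classifier.

    Parameters
    ----------
    encoder, temporal : str
        Architecture kinds (see :mod:`imuhar.encoders` and
        :mod:`imuhar.temporal_models`).
    bottleneck_dim : int
        Width of the per-frame bottleneck representation.
    per_sensor_dim : int or None
        Features per sensor for the sensor-independent encoder
        (bottleneck_dim becomes 4x this when set).
    augmentation : AugmentationConfig, sequence of keys, or None
        Training-time augmentation (e.g. ``["dr1", "drs"]``).
    learning_rate, max_epochs, patience, batch_frames, val_fraction
        Training protocol knobs (see :class:`imuhar.train_eval.TrainConfig`).
    random_state : int
        Seed for initialization, augmentation and minibatch order.

    Attributes
    ----------
    model_ : MovementNet
        The trained encoder + temporal network.
    classes_ : ndarray
        Class labels in training order.
    history_ : dict
        Per-epoch train/validation losses, best epoch, epochs run.
    n_parameters_ : int
        Trainable parameter count of the fitted model.
    """

    def __init__(
        self,
        encoder: str = "conv2d_si",
        temporal: str = "wavenet",
        bottleneck_dim: int = 160,
        per_sensor_dim: int | None = None,
        wavenet_channels: int = 64,
        augmentation=None,
        learning_rate: float = 1e-3,
        max_epochs: int = 250,
        patience: int = 30,
        batch_frames: int = 100,
        val_fraction: float = 0.2,
        random_state: int = 0,
    ):
        self.encoder = encoder
        self.temporal = temporal
        self.bottleneck_dim = bottleneck_dim
        self.per_sensor_dim = per_sensor_dim
        self.wavenet_channels = wavenet_channels
        self.augmentation = augmentation
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_frames = batch_frames
        self.val_fraction = val_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _aug_config(self) -> AugmentationConfig:
        if self.augmentation is None:
            return AugmentationConfig.none()
        if isinstance(self.augmentation, AugmentationConfig):
            return self.augmentation
        return AugmentationConfig.from_keys(list(self.augmentation))

    def _specs(self, n_classes: int) -> tuple[EncoderSpec, TemporalSpec]:
        e_spec = EncoderSpec(
            kind=self.encoder,
            bottleneck_dim=self.bottleneck_dim,
            per_sensor_dim=self.per_sensor_dim if self.encoder == "conv2d_si" else None,
        )
        t_spec = TemporalSpec(
            kind=self.temporal,
            input_dim=e_spec.bottleneck_dim,
            n_classes=n_classes,
            wavenet_channels=self.wavenet_channels,
        )
        return e_spec, t_spec

    def fit(self, X, y, recording_ids=None):
        X = _check_frames(X)
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        lut = {c: i for i, c in enumerate(self.classes_)}
        y_idx = np.array([lut[v] for v in y], dtype=int)
        e_spec, t_spec = self._specs(len(self.classes_))
        cfg = TrainConfig(
            lr=self.learning_rate,
            batch_frames=self.batch_frames,
            max_epochs=self.max_epochs,
            patience=self.patience,
            val_fraction=self.val_fraction,
            seed=self.random_state,
        )
        dataset = _group_recordings(X, y_idx, recording_ids)
        self.model_, self.history_ = train_system(
            e_spec, t_spec, dataset, self._aug_config(), cfg
        )
        self.encoder_spec_, self.temporal_spec_ = e_spec, t_spec
        self.n_parameters_ = self.model_.n_parameters()
        return self

    def predict_proba(self, X, recording_ids=None) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = _check_frames(X)
        if recording_ids is None:
            return self.model_.predict_proba(X, block_len=self.batch_frames)
        recording_ids = np.asarray(recording_ids)
        out = np.empty((len(X), len(self.classes_)))
        for rid in pd_unique(recording_ids):
            mask = recording_ids == rid
            out[mask] = self.model_.predict_proba(X[mask], block_len=self.batch_frames)
        return out

    def predict(self, X, recording_ids=None) -> np.ndarray:
        proba = self.predict_proba(X, recording_ids)
        return self.classes_[proba.argmax(axis=1)]

    def uwaf_score(self, X, y, recording_ids=None) -> float:
        """Unweighted average F1 of predictions on (X, y)."""
        pred = self.predict(X, recording_ids)
        lut = {c: i for i, c in enumerate(self.classes_)}
        conf = confusion_matrix(
            [lut[v] for v in np.asarray(y)], [lut[v] for v in pred], len(self.classes_)
        )
        return uwaf(conf)


class BaselineMovementClassifier(BaseEstimator, ClassifierMixin):
    """336-feature linear ECOC-SVM baseline (frame-wise; no temporal
    context).  X is the same (n_frames, 24, 120) tensor; features and the
    global standardization are fitted internally."""

    def __init__(self, fs: float = 52.0, random_state: int = 0):
        self.fs = fs
        self.random_state = random_state

    def fit(self, X, y):
        X = _check_frames(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        features = extract_features(X, self.fs)
        self.pipeline_ = fit_baseline_classifier(features, y, self.random_state)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict(extract_features(_check_frames(X), self.fs))

    def uwaf_score(self, X, y) -> float:
        pred = self.predict(X)
        lut = {c: i for i, c in enumerate(self.classes_)}
        conf = confusion_matrix(
            [lut[v] for v in np.asarray(y)], [lut[v] for v in pred], len(self.classes_)
        )
        return uwaf(conf)
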