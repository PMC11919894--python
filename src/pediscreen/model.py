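"""The multimodal convolutional classifier of overall ECG abnormality.

A 21-weight-layer VGG-style network reads the 2 x 12 x 400 spectral tensor
through separate amplitude and phase stems plus an age/sex vector, and
outputs the probability that the ECG contains any guideline abnormality.
Training follows 5-fold cross-validation with folds split at the patient
level; within each fold the epoch with the lowest validation loss is
checkpointed, and the five fold models form an ensemble whose prediction
is the mean of the five sigmoid outputs.

Two scale presets are provided. ``paper`` keeps the published training
recipe (batch 32, Adam, binary cross-entropy, learning rate 1e-7, 100
epochs) at full width; ``desk`` shrinks widths (multiplier 1/16) and uses
learning rate 1e-3 for 5 epochs so a full train/evaluate cycle runs on a
single CPU core in minutes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .io import ECGRecord
from .nnet import Adam, SpectralConvNet, bce_with_logits
from .preprocess import SpectralTensorizer


@dataclass
class ArchitectureConfig:
    """Widths and wiring of the network; 21 weight layers by default."""

    stem_width: int = 32
    block_widths: tuple[int, ...] = (64, 128, 256, 512, 512)
    block_sizes: tuple[int, ...] = (2, 3, 3, 3, 3)
    dense_widths: tuple[int, ...] = (128, 32)
    dropout: float = 0.2
    width_multiplier: float = 1.0
    grad_cam_conv_index: int = 12
    n_freq_bins: int = 400
    n_leads: int = 12
    meta_dim: int = 2

    @property
    def n_conv_layers(self) -> int:
        return 2 * 2 + sum(self.block_sizes)          # both stems + trunk

    @property
    def n_weight_layers(self) -> int:
        return 2 * 2 + sum(self.block_sizes) + len(self.dense_widths) + 1

    def validate(self) -> "ArchitectureConfig":
        # grad-CAM indexing counts the amplitude stem then the trunk
        if not (1 <= self.grad_cam_conv_index <= 2 + sum(self.block_sizes)):
            raise ValueError(
                f"grad_cam_conv_index {self.grad_cam_conv_index} exceeds the "
                f"{2 + sum(self.block_sizes)} indexable conv layers")
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")
        return self

    def scaled_widths(self) -> dict:
        m = self.width_multiplier
        return {
            "stem_width": max(1, int(round(self.stem_width * m))),
            "block_widths": tuple(max(1, int(round(w * m))) for w in self.block_widths),
        }


@dataclass
class TrainConfig:
    """Published recipe by default; use presets for runnable scales."""

    batch_size: int = 32
    learning_rate: float = 1.0e-7
    epochs: int = 100
    k_folds: int = 5
    seed: int = 0
    scale_preset: str = "paper"

    def validate(self) -> "TrainConfig":
        if self.k_folds < 2:
            raise ValueError("k_folds must be at least 2")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        return self


def preset(name: str, seed: int = 0) -> tuple[ArchitectureConfig, TrainConfig]:
    """Named (architecture, training) configuration pairs."""
    if name == "paper":
        return ArchitectureConfig(), TrainConfig(seed=seed, scale_preset="paper")
    if name == "desk":
        arch = ArchitectureConfig(width_multiplier=1.0 / 16.0, dropout=0.1)
        train = TrainConfig(learning_rate=1.0e-3, epochs=4, seed=seed,
                            scale_preset="desk")
        return arch, train
    raise ValueError(f"unknown preset {name!r}")


def build_model(arch: ArchitectureConfig, seed: int) -> SpectralConvNet:
    """Instantiate the network with deterministic seeded initialization."""
    arch.validate()
    widths = arch.scaled_widths()
    return SpectralConvNet(
        stem_width=widths["stem_width"],
        block_widths=widths["block_widths"],
        block_sizes=arch.block_sizes,
        dense_widths=arch.dense_widths,
        dropout=arch.dropout,
        input_shape=(arch.n_leads, arch.n_freq_bins),
        meta_dim=arch.meta_dim,
        seed=seed,
    )


@dataclass
class FoldResult:
    fold_index: int
    weights: list
    train_losses: list[float]
    val_losses: list[float]
    selected_epoch: int          # 0-based epoch attaining min validation loss
    val_patient_ids: list[str]


#: Floor added to the amplitude spectrum before taking log10.
AMP_LOG_EPS = 1e-6


def normalize_inputs(X: np.ndarray, norm: dict) -> tuple[np.ndarray, np.ndarray]:
    """Model-side input scaling: standardized log-amplitude, phase / pi.

    The tensor contract keeps amplitude in mV; the network sees
    ``(log10(amp + eps) - mean) / std`` with statistics estimated on the
    training group and carried with the ensemble.
    """
    amp = np.log10(X[:, 0] + AMP_LOG_EPS)
    amp = (amp - norm["amp_mean"]) / norm["amp_std"]
    phase = X[:, 1] / np.pi
    return amp.astype(np.float32), phase.astype(np.float32)


def fit_norm(X: np.ndarray) -> dict:
    amp = np.log10(X[:, 0] + AMP_LOG_EPS)
    return {"amp_mean": float(amp.mean()), "amp_std": float(amp.std() + 1e-12)}


@dataclass
class Ensemble:
    folds: list[FoldResult]
    arch: ArchitectureConfig
    train_cfg: TrainConfig
    fingerprint: dict = field(default_factory=dict)
    norm: dict = field(default_factory=dict)
    _models: Optional[list[SpectralConvNet]] = None

    def models(self) -> list[SpectralConvNet]:
        if self._models is None:
            ms = []
            for fr in self.folds:
                m = build_model(self.arch, seed=0)
                m.set_weights(fr.weights)
                ms.append(m)
            self._models = ms
        return self._models

    def save(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for fr in self.folds:
            for i, w in enumerate(fr.weights):
                arrays[f"fold{fr.fold_index}_w{i}"] = w
        meta = {
            "arch": asdict(self.arch),
            "train_cfg": asdict(self.train_cfg),
            "fingerprint": self.fingerprint,
            "norm": self.norm,
            "folds": [{
                "fold_index": fr.fold_index,
                "train_losses": fr.train_losses,
                "val_losses": fr.val_losses,
                "selected_epoch": fr.selected_epoch,
                "val_patient_ids": fr.val_patient_ids,
                "n_weights": len(fr.weights),
            } for fr in self.folds],
        }
        np.savez(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
        return path.with_suffix(".npz")

    @classmethod
    def load(cls, path) -> "Ensemble":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        arrays = np.load(path.with_suffix(".npz"))
        folds = []
        for fm in meta["folds"]:
            weights = [arrays[f"fold{fm['fold_index']}_w{i}"]
                       for i in range(fm["n_weights"])]
            folds.append(FoldResult(
                fold_index=fm["fold_index"], weights=weights,
                train_losses=fm["train_losses"], val_losses=fm["val_losses"],
                selected_epoch=fm["selected_epoch"],
                val_patient_ids=fm["val_patient_ids"]))
        arch = ArchitectureConfig(**{k: tuple(v) if isinstance(v, list) else v
                                     for k, v in meta["arch"].items()})
        return cls(folds=folds, arch=arch,
                   train_cfg=TrainConfig(**meta["train_cfg"]),
                   fingerprint=meta["fingerprint"],
                   norm=meta.get("norm", {}))


def _patient_folds(patient_ids: Sequence[str], k: int, rng: np.random.Generator
                   ) -> list[np.ndarray]:
    """Partition record indices into k folds by whole patients."""
    patient_ids = np.asarray(patient_ids)
    unique = sorted(set(patient_ids.tolist()))
    order = rng.permutation(len(unique))
    chunks = np.array_split(order, k)
    folds = []
    for chunk in chunks:
        members = {unique[i] for i in chunk}
        folds.append(np.flatnonzero(np.isin(patient_ids, sorted(members))))
    return folds


def train_cv(
    X: np.ndarray,
    meta: np.ndarray,
    y: np.ndarray,
    patient_ids: Sequence[str],
    train_cfg: TrainConfig,
    arch: ArchitectureConfig,
    verbose: bool = False,
) -> Ensemble:
    """Train the five-fold ensemble on tensorized training-group records.

    ``X`` is (N, 2, 12, F) float32, ``meta`` (N, 2), ``y`` boolean/0-1.
    Folds are split at the patient level; each fold trains for
    ``train_cfg.epochs`` epochs and checkpoints the epoch with the lowest
    validation loss. Deterministic given ``train_cfg.seed`` under
    single-threaded execution.
    """
    train_cfg.validate()
    arch.validate()
    X = np.asarray(X, dtype=np.float32)
    meta = np.asarray(meta, dtype=np.float32)
    y = np.asarray(y, dtype=np.float64).ravel()
    if len(X) != len(y) or len(meta) != len(y):
        raise ValueError("X, meta and y must have equal lengths")

    master = np.random.default_rng(train_cfg.seed)
    fold_rng = np.random.default_rng(int(master.integers(2**31 - 1)))
    folds = _patient_folds(patient_ids, train_cfg.k_folds, fold_rng)
    norm = fit_norm(X)
    Xa, Xp = normalize_inputs(X, norm)

    results = []
    for fi, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(y)), val_idx)
        for name, idx in (("training", train_idx), ("validation", val_idx)):
            if len(np.unique(y[idx])) < 2:
                raise ValueError(
                    f"fold {fi}: {name} subset contains a single class; "
                    "supply a larger or better mixed cohort")
        init_seed = int(master.integers(2**31 - 1))
        shuffle_rng = np.random.default_rng(int(master.integers(2**31 - 1)))
        drop_rng = np.random.default_rng(int(master.integers(2**31 - 1)))
        model = build_model(arch, seed=init_seed)
        opt = Adam(model.layers, lr=train_cfg.learning_rate)
        best_val, best_weights, best_epoch = np.inf, model.get_weights(), -1
        train_losses, val_losses = [], []
        for epoch in range(train_cfg.epochs):
            order = shuffle_rng.permutation(train_idx)
            batch_losses = []
            for s in range(0, len(order), train_cfg.batch_size):
                b = order[s:s + train_cfg.batch_size]
                z = model.forward(Xa[b], Xp[b], meta[b], train=True, rng=drop_rng)
                loss, dz = bce_with_logits(z, y[b])
                model.backward(dz)
                opt.step()
                batch_losses.append(loss)
            train_losses.append(float(np.mean(batch_losses)))
            zv = []
            for s in range(0, len(val_idx), 256):
                b = val_idx[s:s + 256]
                zv.append(model.forward(Xa[b], Xp[b], meta[b], train=False))
            vloss, _ = bce_with_logits(np.concatenate(zv), y[val_idx])
            val_losses.append(vloss)
            if vloss < best_val:
                best_val, best_epoch = vloss, epoch
                best_weights = model.get_weights()
            if verbose:
                print(f"fold {fi} epoch {epoch}: train {train_losses[-1]:.4f} "
                      f"val {vloss:.4f}")
        results.append(FoldResult(
            fold_index=fi, weights=best_weights,
            train_losses=train_losses, val_losses=val_losses,
            selected_epoch=best_epoch,
            val_patient_ids=sorted({patient_ids[i] for i in val_idx})))
    fingerprint = {"input_shape": [2, int(X.shape[2]), int(X.shape[3])],
                   "meta_dim": int(meta.shape[1])}
    return Ensemble(folds=results, arch=arch, train_cfg=train_cfg,
                    fingerprint=fingerprint, norm=norm)


def predict(ensemble: Ensemble, X: np.ndarray, meta: np.ndarray) -> np.ndarray:
    """Mean of the five fold models' sigmoid outputs, per record."""
    X = np.asarray(X, dtype=np.float32)
    meta = np.asarray(meta, dtype=np.float32)
    fp = ensemble.fingerprint
    if fp and list(X.shape[1:]) != fp["input_shape"]:
        raise ValueError(
            f"tensor shape {list(X.shape[1:])} does not match the ensemble "
            f"fingerprint {fp['input_shape']}")
    Xa, Xp = normalize_inputs(X, ensemble.norm) if ensemble.norm else (X[:, 0], X[:, 1])
    probs = [m.predict_proba(Xa, Xp, meta) for m in ensemble.models()]
    return np.mean(probs, axis=0)


class ECGAbnormalityClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn style front end over the spectral CNN ensemble.

    ``fit`` accepts a sequence of :class:`~pediscreen.io.ECGRecord` (records
    are tensorized internally and patient ids taken from them) or a
    pre-tensorized (N, 2, 12, 400) array with ``meta`` and ``groups``
    passed explicitly. ``predict_proba`` returns the ensemble mean
    probability of abnormality.
    """

    def __init__(self, preset: str = "desk", epochs: Optional[int] = None,
                 learning_rate: Optional[float] = None, k_folds: int = 5,
                 batch_size: int = 32, width_multiplier: Optional[float] = None,
                 dropout: Optional[float] = None, grad_cam_conv_index: int = 12,
                 random_state: int = 0):
        self.preset = preset
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.k_folds = k_folds
        self.batch_size = batch_size
        self.width_multiplier = width_multiplier
        self.dropout = dropout
        self.grad_cam_conv_index = grad_cam_conv_index
        self.random_state = random_state

    def _configs(self) -> tuple[ArchitectureConfig, TrainConfig]:
        arch, train = preset(self.preset, seed=self.random_state)
        if self.epochs is not None:
            train.epochs = self.epochs
        if self.learning_rate is not None:
            train.learning_rate = self.learning_rate
        train.k_folds = self.k_folds
        train.batch_size = self.batch_size
        if self.width_multiplier is not None:
            arch.width_multiplier = self.width_multiplier
        if self.dropout is not None:
            arch.dropout = self.dropout
        arch.grad_cam_conv_index = self.grad_cam_conv_index
        return arch.validate(), train.validate()

    def _prepare(self, X, meta, groups):
        if len(X) and isinstance(X[0], ECGRecord):
            tensorizer = getattr(self, "tensorizer_", None) or SpectralTensorizer()
            tensors = tensorizer.fit(X).transform(X)
            meta = tensorizer.transform_meta(X)
            groups = [r.patient_id for r in X]
            self.tensorizer_ = tensorizer
            return tensors, meta, groups
        X = np.asarray(X, dtype=np.float32)
        if meta is None:
            raise ValueError("meta (age/sex matrix) is required for array input")
        if groups is None:
            groups = [str(i) for i in range(len(X))]
        return X, np.asarray(meta, dtype=np.float32), groups

    def fit(self, X, y, meta=None, groups=None) -> "ECGAbnormalityClassifier":
        arch, train = self._configs()
        Xt, meta, groups = self._prepare(X, meta, groups)
        y = np.asarray(y).astype(bool)
        self.classes_ = np.array([False, True])
        self.ensemble_ = train_cv(Xt, meta, y, groups, train, arch)
        self.n_features_in_ = int(np.prod(Xt.shape[1:]))
        return self

    def _check_fitted(self):
        if not hasattr(self, "ensemble_"):
            raise RuntimeError("classifier is not fitted")

    def decision_function(self, X, meta=None) -> np.ndarray:
        self._check_fitted()
        if len(X) and isinstance(X[0], ECGRecord):
            Xt = self.tensorizer_.transform(X)
            meta = self.tensorizer_.transform_meta(X)
        else:
            Xt = np.asarray(X, dtype=np.float32)
        return predict(self.ensemble_, Xt, meta)

    def predict_proba(self, X, meta=None) -> np.ndarray:
        p = self.decision_function(X, meta)
        return np.column_stack([1.0 - p, p])

    def predict(self, X, meta=None, threshold: float = 0.5) -> np.ndarray:
        return self.decision_function(X, meta) >= threshold
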