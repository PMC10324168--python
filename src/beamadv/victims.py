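"""Victim seizure-detection classifiers in scikit-learn estimator form.

Two families share the training and attack interfaces and differ only in
input: BEAM-related models consume T x 4-channel 22x22 topographic-map slices,
EEG-related models consume T x 1-channel 22x256 raw-signal slices.  Each
family comes in four architectures (``maxpool``, ``temporal_conv``, ``lstm``,
``mixed_lstm``) named after the temporal head that aggregates the per-slice
convolutional features.

Training optimizes cross-entropy with Adam (lr 1e-3, betas 0.9/0.999) and is
deterministic given ``seed``.  ``loss_gradient`` exposes the input gradient of
the loss, the quantity the white-box attacks build on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .net import Adam, VictimNet

__all__ = ["ArchitectureSpec", "TrainConfig", "VictimClassifier", "TrainingDivergedError"]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class ArchitectureSpec:
    """Victim architecture: input family plus temporal head."""

    name: str = "maxpool"  # maxpool | temporal_conv | lstm | mixed_lstm
    input_kind: str = "beam"  # beam | eeg
    fc_width: int = 512
    lstm_hidden: int = 128
    tconv_out: int = 64
    tconv_kernel: int = 3

    def slice_shape(self, n_bands: int = 4, grid: tuple[int, int] = (22, 22),
                    n_channels: int = 22, n_samples: int = 256) -> tuple[int, int, int]:
        if self.input_kind == "beam":
            return (n_bands, *grid)
        return (1, n_channels, n_samples)


@dataclass
class TrainConfig:
    """Optimisation settings; dropout/L2 default on only for the eeg mixed_lstm."""

    learning_rate: float = 1e-3
    adam_betas: tuple[float, float] = (0.9, 0.999)
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0
    dropout_p: float = 0.5
    l2: float = 1e-4
    early_stop_patience: int = 3
    validation_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")


class VictimClassifier(ClassifierMixin, BaseEstimator):
    """Seizure/background classifier over BEAM or raw-EEG sample tensors.

    Parameters
    ----------
    architecture : str
        Temporal head: ``maxpool``, ``temporal_conv``, ``lstm`` or ``mixed_lstm``.
    input_kind : str
        ``beam`` expects X of shape (N, T, B, H, W); ``eeg`` expects
        (N, T, C, S) raw EEG samples.
    regularize : bool or None
        Apply dropout + L2.  ``None`` (default) enables it only for the
        eeg-input mixed_lstm combination, the one prone to overfitting.

    Attributes
    ----------
    net_ : the fitted network.
    classes_ : class labels.
    history_ : dict of per-epoch train/validation loss and accuracy curves.
    """

    def __init__(
        self,
        architecture: str = "maxpool",
        input_kind: str = "beam",
        epochs: int = 30,
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        seed: int = 0,
        fc_width: int = 512,
        lstm_hidden: int = 128,
        regularize: bool | None = None,
        dropout_p: float = 0.5,
        l2: float = 1e-4,
        early_stop_patience: int = 3,
        validation_fraction: float = 0.15,
        dtype: str = "float32",
    ):
        self.architecture = architecture
        self.input_kind = input_kind
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.seed = seed
        self.fc_width = fc_width
        self.lstm_hidden = lstm_hidden
        self.regularize = regularize
        self.dropout_p = dropout_p
        self.l2 = l2
        self.early_stop_patience = early_stop_patience
        self.validation_fraction = validation_fraction
        self.dtype = dtype

    # ------------------------------------------------------------------
    def _regularized(self) -> bool:
        if self.regularize is None:
            return self.architecture == "mixed_lstm" and self.input_kind == "eeg"
        return bool(self.regularize)

    def _coerce(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if self.input_kind == "eeg" and X.ndim == 4:  # (N, T, C, S) -> add channel axis
            X = X[:, :, None, :, :]
        if X.ndim != 5:
            raise ValueError(f"expected a 5-axis batch after coercion, got shape {X.shape}")
        return X

    def _build_net(self, slice_shape: tuple[int, int, int], n_slices: int) -> VictimNet:
        return VictimNet(
            input_kind=self.input_kind,
            head=self.architecture,
            slice_shape=slice_shape,
            n_slices=n_slices,
            fc_width=self.fc_width,
            lstm_hidden=self.lstm_hidden,
            dropout=self.dropout_p if self._regularized() else 0.0,
            seed=self.seed,
            dtype=np.dtype(self.dtype).type,
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "VictimClassifier":
        X = self._coerce(X)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError("victim models are binary classifiers")
        n = len(X)
        rng = np.random.default_rng(self.seed)
        net = self._build_net(X.shape[2:], X.shape[1])
        opt = Adam(net.params, net.grads, lr=self.learning_rate,
                   l2=self.l2 if self._regularized() else 0.0)

        perm = rng.permutation(n)
        n_val = int(round(self.validation_fraction * n))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        history: dict[str, list[float]] = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
        best_val, best_state, patience = np.inf, None, 0
        from .net.layers import cross_entropy_with_grad

        for _ in range(self.epochs):
            order = rng.permutation(tr_idx)
            losses, correct = [], 0
            for start in range(0, len(order), self.batch_size):
                idx = order[start : start + self.batch_size]
                logits = net.forward(X[idx], train=True)
                loss, dlogits = cross_entropy_with_grad(logits, y_idx[idx])
                if not np.isfinite(loss):
                    raise TrainingDivergedError("training loss is not finite")
                net.zero_grad()
                net.backward(dlogits)
                opt.step()
                losses.append(loss)
                correct += int((logits.argmax(axis=1) == y_idx[idx]).sum())
            history["train_loss"].append(float(np.mean(losses)))
            history["train_acc"].append(correct / len(order))
            if n_val:
                vl, va = self._eval(net, X[val_idx], y_idx[val_idx])
                history["val_loss"].append(vl)
                history["val_acc"].append(va)
                if vl < best_val - 1e-5:
                    best_val, patience = vl, 0
                    best_state = {k: v.copy() for k, v in net.state_dict().items()}
                else:
                    patience += 1
                    if patience >= self.early_stop_patience:
                        break
        if best_state is not None:
            net.load_state_dict(best_state)
        self.net_ = net
        self.history_ = history
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    @staticmethod
    def _eval(net: VictimNet, X: np.ndarray, y_idx: np.ndarray, batch: int = 64) -> tuple[float, float]:
        from .net.layers import cross_entropy_with_grad

        losses, correct = [], 0
        for s in range(0, len(X), batch):
            logits = net.forward(X[s : s + batch])
            loss, _ = cross_entropy_with_grad(logits, y_idx[s : s + batch])
            losses.append(loss * len(logits))
            correct += int((logits.argmax(axis=1) == y_idx[s : s + batch]).sum())
        return float(np.sum(losses) / len(X)), correct / len(X)

    # ------------------------------------------------------------------
    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = self._coerce(np.atleast_1d(X))
        out = []
        for s in range(0, len(X), 64):
            out.append(self.net_.predict_proba(X[s : s + 64]))
        return np.concatenate(out)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def loss_gradient(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Gradient of the cross-entropy loss at the input, shaped like X."""
        Xc = self._coerce(X)
        y_idx = np.searchsorted(self.classes_, np.asarray(y))
        _, grad = self.net_.loss_and_input_grad(Xc, y_idx)
        return grad.reshape(np.asarray(X).shape)

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write weights (.npz) and estimator parameters (.json sidecar)."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.net_.state_dict(),
                 classes=self.classes_)
        meta = {"params": self.get_params(), "history": self.history_,
                "slice_shape": list(self.net_.slice_shape), "n_slices": self.net_.n_slices}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "VictimClassifier":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        est = cls(**meta["params"])
        with np.load(path.with_suffix(".npz")) as data:
            est.classes_ = data["classes"]
            net = est._build_net(tuple(meta["slice_shape"]), meta["n_slices"])
            net.load_state_dict({k: data[k] for k in data.files if k.startswith("p")})
        est.net_ = net
        est.history_ = meta["history"]
        return est
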