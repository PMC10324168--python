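"""Shared fixtures: geometry, small synthetic data, and a quickly trained victim."""

from __future__ import annotations

import numpy as np
import pytest

import beamadv as ba


@pytest.fixture(scope="session")
def montage():
    return ba.build_montage()


@pytest.fixture(scope="session")
def grid(montage):
    return ba.build_grid(montage, 22, 22)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small, strongly separable synthetic set for fast functional tests."""
    X, y = ba.generate_dataset(ba.SyntheticConfig(n_per_class=24, seed=7, seizure_amp=2.5))
    return X, y


@pytest.fixture(scope="session")
def tiny_beam_victim(montage, grid, tiny_dataset):
    """A beam-input maxpool victim trained briefly on the tiny dataset."""
    X, y = tiny_dataset
    beams = ba.BeamTransformer(montage, grid).transform(X)
    clf = ba.VictimClassifier(architecture="maxpool", input_kind="beam",
                              epochs=4, seed=0, fc_width=64, validation_fraction=0.0)
    clf.fit(beams[:32], y[:32])
    return clf, beams, X, y


class LinearBeamStub:
    """Analytic linear-logistic 'victim' over flattened BEAM tensors.

    logit difference = w . x; provides exact gradients and probabilities, so
    attack algebra can be checked against closed forms.
    """

    input_kind = "beam"

    def __init__(self, w: np.ndarray, classes=(0, 1)):
        self.w = np.asarray(w, dtype=float)
        self.classes_ = np.asarray(classes)

    def _score(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X.reshape(X.shape[0], -1) @ self.w.ravel()

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        s = np.clip(self._score(X), -700.0, 700.0)
        p1 = 1.0 / (1.0 + np.exp(-s))
        return np.stack([1 - p1, p1], axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[(self._score(X) > 0).astype(int)]

    def loss(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        p = self.predict_proba(X)
        return -np.log(np.clip(p[np.arange(len(p)), np.searchsorted(self.classes_, y)], 1e-300, None))

    def loss_gradient(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        p1 = self.predict_proba(X)[:, 1]
        yi = np.searchsorted(self.classes_, np.asarray(y))
        coef = (p1 - yi)[:, None]  # d(-log p_y)/d score
        return (coef * self.w.ravel()[None, :]).reshape(X.shape)


@pytest.fixture()
def linear_stub_factory():
    return LinearBeamStub
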