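"""Gradient-based perturbation generators on BEAM (or raw EEG) tensors.

All generators maximize the victim's cross-entropy at the true label within an
L-infinity ball of radius epsilon.  FGSM is the default; the iterative
variants (I-FGSM, MI-FGSM, PGD) follow their standard definitions with
per-step projection onto the epsilon ball.  The registry is pluggable so
further generators can be added without touching the attack pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from ..victims import VictimClassifier

__all__ = ["PerturbationConfig", "gen_perturbation", "register_method", "METHODS"]


@dataclass
class PerturbationConfig:
    """Settings for the perturbation generator (epsilon is the L-inf budget)."""

    epsilon: float = 0.3
    method: str = "fgsm"
    iterations: int = 10
    step: float | None = None  # default epsilon / iterations
    momentum: float = 1.0      # MI-FGSM decay factor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def _fgsm(model: VictimClassifier, X: np.ndarray, y: np.ndarray, cfg: PerturbationConfig) -> np.ndarray:
    return cfg.epsilon * np.sign(model.loss_gradient(X, y))


def _iterative(model, X, y, cfg, *, momentum: bool, random_start: bool) -> np.ndarray:
    step = cfg.step if cfg.step is not None else cfg.epsilon / cfg.iterations
    rng = np.random.default_rng(cfg.seed)
    eta = (
        rng.uniform(-cfg.epsilon, cfg.epsilon, size=np.shape(X))
        if random_start and cfg.epsilon > 0
        else np.zeros(np.shape(X))
    )
    g_acc = np.zeros(np.shape(X))
    for _ in range(cfg.iterations):
        grad = model.loss_gradient(np.asarray(X) + eta, y)
        if momentum:
            norm = np.abs(grad).mean(axis=tuple(range(1, grad.ndim)), keepdims=True)
            g_acc = cfg.momentum * g_acc + grad / np.maximum(norm, 1e-12)
            grad = g_acc
        eta = np.clip(eta + step * np.sign(grad), -cfg.epsilon, cfg.epsilon)
    return eta


METHODS: dict[str, Callable] = {
    "fgsm": _fgsm,
    "ifgsm": lambda m, X, y, c: _iterative(m, X, y, c, momentum=False, random_start=False),
    "mifgsm": lambda m, X, y, c: _iterative(m, X, y, c, momentum=True, random_start=False),
    "pgd": lambda m, X, y, c: _iterative(m, X, y, c, momentum=False, random_start=True),
}


def register_method(name: str, fn: Callable) -> None:
    """Add a perturbation generator to the registry."""
    METHODS[name] = fn


def gen_perturbation(
    model: VictimClassifier, X: np.ndarray, y: np.ndarray, config: PerturbationConfig
) -> np.ndarray:
    """Perturbation eta with ||eta||_inf <= epsilon, shaped like X."""
    try:
        fn = METHODS[config.method]
    except KeyError:
        raise KeyError(f"unknown perturbation method {config.method!r}; known: {sorted(METHODS)}") from None
    if config.epsilon == 0:
        return np.zeros(np.shape(X))
    return fn(model, X, y, config)
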