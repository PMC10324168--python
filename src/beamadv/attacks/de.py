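"""Sparse BEAM attack: differential evolution over (slice, electrode, band) genes.

Each individual carries N genes; a gene is an integer vector
``(t, c, v_1..v_B)`` encoding a perturbation of the B rhythm powers at time
slice t and electrode c.  Power perturbations are integers in
``[-round(eps * r * delta), round(eps * r * delta)]`` and are divided by the
amplification factor ``r`` when applied (``delta`` widens the range to C when
perturbation overflow is on).  Classic DE/rand/1/bin evolves the population:
donor = X_r1 + F * (X_r2 - X_r3), rounded and redrawn uniformly on range
violations; uniform crossover at rate CR; greedy selection on fitness
``1 - max-class probability`` of the victim on BEAMs built from P + eta.
Evolution stops as soon as any individual flips the victim's label away from
the true class.

Perturbation overflow redistributes the summed excess above eps (over all
slices, bands and electrodes) equally across electrodes, signed like the
dense-attack perturbation on the same sample, then clips to the eps ball —
trading a little dense distortion for a much higher flip rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from ..beams import build_beams, sample_perturbation
from ..montage import GridSpec, Montage
from ..rhythms import DEFAULT_BANDS, decompose_sample
from ..victims import VictimClassifier
from .gpbeam import AdversarialResult, _rmse, impose_on_frequency, reconstruct_eeg

__all__ = [
    "DEConfig", "init_population", "individual_to_eta", "fitness_population",
    "evolve_step", "apply_overflow", "GPBEAMDEAttack", "attack_gpbeam_de",
]


@dataclass
class DEConfig:
    """Differential-evolution attack settings."""

    NP: int = 40              # population size
    N: int = 5                # genes per individual
    F: float = 0.5            # mutation scaling factor, [0, 2]
    CR: float = 0.6           # crossover probability
    r: float = 100.0          # integer amplification of power perturbations
    epsilon: float = 0.3
    overflow: bool = True
    overflow_in_fitness: bool = True
    max_generations: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.F <= 2.0:
            raise ValueError("F must be in [0, 2]")
        if not 0.0 <= self.CR <= 1.0:
            raise ValueError("CR must be in [0, 1]")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if self.r * self.epsilon < 1:
            raise ValueError("r * epsilon must be >= 1 for a non-degenerate integer grid")

    def delta(self, C: int) -> int:
        return C if self.overflow else 1

    def v_max(self, C: int) -> int:
        return int(round(self.epsilon * self.r * self.delta(C)))


def _ranges(config: DEConfig, T: int, B: int, C: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-column (low, high) inclusive bounds of a gene array (..., N, 2 + B)."""
    vmax = config.v_max(C)
    low = np.array([0, 0] + [-vmax] * B)
    high = np.array([T - 1, C - 1] + [vmax] * B)
    return low, high


def init_population(config: DEConfig, T: int = 5, B: int = 4, C: int = 22,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Uniform random integer population, shape (NP, N, 2 + B)."""
    rng = rng or np.random.default_rng(config.seed)
    low, high = _ranges(config, T, B, C)
    return rng.integers(low, high + 1, size=(config.NP, config.N, 2 + B))


def individual_to_eta(ind: np.ndarray, config: DEConfig, T: int = 5, B: int = 4, C: int = 22) -> np.ndarray:
    """Sparse rhythm-power perturbation eta' (T, B, C) from one individual.

    All entries are zero except the rows named by genes (value v / r); genes
    hitting the same (t, c) pair overwrite earlier ones (last wins).
    """
    eta = np.zeros((T, B, C))
    for gene in np.asarray(ind).reshape(-1, 2 + B):
        t, c = int(gene[0]), int(gene[1])
        eta[t, :, c] = gene[2:] / config.r
    return eta


def apply_overflow(eta_prime: np.ndarray, eta_gpbeam: np.ndarray, epsilon: float, C: int) -> np.ndarray:
    """Redistribute the total excess above epsilon across all electrodes.

    The summed excess (over every slice, band, electrode) is divided by C,
    signed per-entry like the dense-attack perturbation ``eta_gpbeam``, added
    everywhere, and the result clipped to [-epsilon, epsilon].
    """
    eta_prime = np.asarray(eta_prime, dtype=float)
    over = np.abs(eta_prime) - epsilon
    excess = float(np.sum(np.where(over > 0, over, 0.0)))
    spread = (excess / C) * np.sign(np.asarray(eta_gpbeam, dtype=float))
    return np.clip(spread + eta_prime, -epsilon, epsilon)


def _valid_int(X: np.ndarray, low: np.ndarray, high: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Round to integers; redraw uniformly within range on violation."""
    V = np.rint(X).astype(int)
    bad = (V < low) | (V > high)
    if bad.any():
        V[bad] = rng.integers(np.broadcast_to(low, V.shape)[bad],
                              np.broadcast_to(high, V.shape)[bad] + 1)
    return V


def fitness_population(
    pop: np.ndarray,
    model_beam: VictimClassifier,
    P: np.ndarray,
    montage: Montage,
    grid: GridSpec,
    config: DEConfig,
    eta_sign: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fitness (1 - max-class probability) and predictions for a population.

    BEAMs for every candidate are interpolated in one vectorized call and the
    victim is evaluated as one batch.
    """
    T, B, C = P.shape
    etas = np.stack([individual_to_eta(ind, config, T, B, C) for ind in pop])
    if config.overflow and config.overflow_in_fitness:
        if eta_sign is None:
            raise ValueError("overflow requires the dense-attack sign template")
        etas = np.stack([apply_overflow(e, eta_sign, config.epsilon, C) for e in etas])
    beams = build_beams(P[None] + etas, montage, grid)
    proba = model_beam.predict_proba(beams)
    return 1.0 - proba.max(axis=1), proba.argmax(axis=1)


def evolve_step(
    pop: np.ndarray,
    fit: np.ndarray,
    fitness_fn,
    config: DEConfig,
    T: int, B: int, C: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One DE/rand/1/bin generation with greedy selection.

    Returns (population, fitness, predictions of the evaluated offspring).
    """
    NP = len(pop)
    if NP < 4:
        raise ValueError("population size must be >= 4 for three distinct donors")
    low, high = _ranges(config, T, B, C)
    donors = np.empty_like(pop)
    for i in range(NP):
        r1, r2, r3 = rng.choice([j for j in range(NP) if j != i], size=3, replace=False)
        donors[i] = _valid_int(pop[r1] + config.F * (pop[r2] - pop[r3]), low, high, rng)
    if config.CR > 0:
        cross = rng.random(pop.shape) <= config.CR
    else:
        cross = np.zeros(pop.shape, dtype=bool)
    trial = np.where(cross, donors, pop)
    fit_u, pred_u = fitness_fn(trial)
    better = fit_u > fit
    new_pop = np.where(better[:, None, None], trial, pop)
    new_fit = np.where(better, fit_u, fit)
    return new_pop, new_fit, pred_u


class GPBEAMDEAttack:
    """Sparse DE attack bound to a beam-input victim and head geometry."""

    def __init__(
        self,
        victim: VictimClassifier,
        montage: Montage,
        grid: GridSpec,
        config: DEConfig | None = None,
        sample_rate: float = 256.0,
        bands: Mapping[str, tuple[float, float]] = DEFAULT_BANDS,
        level: int = 8,
    ):
        if victim.input_kind != "beam":
            raise ValueError("GPBEAM-DE attacks a beam-input victim")
        self.victim = victim
        self.montage, self.grid = montage, grid
        self.config = config or DEConfig()
        self.sample_rate, self.bands, self.level = sample_rate, bands, level

    def attack(self, sample: np.ndarray, y_true: int) -> AdversarialResult:
        cfg = self.config
        sample = np.asarray(sample, dtype=float)
        dec = decompose_sample(sample, self.sample_rate, level=self.level, bands=self.bands)
        P = dec.powers
        T, B, C = P.shape
        beam_raw = build_beams(P, self.montage, self.grid)
        pred_before = int(self.victim.predict(beam_raw[None])[0])

        # sign template from the dense attack on the same sample
        eta_sign = None
        if cfg.overflow:
            eta_beam = self.victim.loss_gradient(beam_raw[None], np.array([y_true]))[0]
            eta_sign = sample_perturbation(cfg.epsilon * np.sign(eta_beam), self.montage, self.grid)

        rng = np.random.default_rng(cfg.seed)

        def fit_fn(p):
            return fitness_population(p, self.victim, P, self.montage, self.grid, cfg, eta_sign)

        trace = []
        if pred_before != y_true:  # clean sample already misclassified
            eta = np.zeros((T, B, C))
            return self._emit(sample, dec, P, beam_raw, eta, y_true, pred_before,
                              pred_before, generations=0, trace=trace)

        pop = init_population(cfg, T, B, C, rng)
        fit, pred = fit_fn(pop)
        generations = 0
        winner = None
        if (pred != y_true).any():
            winner = pop[np.flatnonzero(pred != y_true)[np.argmax(fit[pred != y_true])]]
        while winner is None and generations < cfg.max_generations:
            pop, fit, pred_u = evolve_step(pop, fit, fit_fn, cfg, T, B, C, rng)
            generations += 1
            trace.append(float(fit.max()))
            flipped = pred_u != y_true
            if flipped.any():
                winner = pop[np.flatnonzero(flipped)[np.argmax(fit[flipped])]]
        if winner is None:  # exhausted: report the fittest candidate, unsuccessful
            winner = pop[int(np.argmax(fit))]

        eta = individual_to_eta(winner, cfg, T, B, C)
        if cfg.overflow:
            eta = apply_overflow(eta, eta_sign, cfg.epsilon, C)
        beam_pert = build_beams(P + eta, self.montage, self.grid)
        pred_after_beam = int(self.victim.predict(beam_pert[None])[0])
        return self._emit(sample, dec, P, beam_raw, eta, y_true, pred_before,
                          pred_after_beam, generations, trace)

    def _emit(self, sample, dec, P, beam_raw, eta, y_true, pred_before, pred_after,
              generations, trace) -> AdversarialResult:
        D = impose_on_frequency(dec.freq, eta)
        adv = reconstruct_eeg(sample, D, self.sample_rate, self.level, self.bands)
        beam_pert = build_beams(P + eta, self.montage, self.grid)
        return AdversarialResult(
            adversarial_eeg=adv,
            eta_beam=None,
            eta_p=eta,
            y_true=int(y_true),
            pred_before=pred_before,
            pred_after=pred_after,
            dl_b=_rmse(beam_pert, beam_raw),
            dl_e=_rmse(adv, sample),
            generations=generations,
            extras={"fitness_trace": trace},
        )

    def attack_many(self, X: np.ndarray, y: np.ndarray) -> list[AdversarialResult]:
        results = []
        for i, (x, t) in enumerate(zip(np.asarray(X), np.asarray(y))):
            sub = replace(self.config, seed=int(np.random.SeedSequence([self.config.seed, i]).generate_state(1)[0] % (2**31)))
            results.append(GPBEAMDEAttack(self.victim, self.montage, self.grid, sub,
                                          self.sample_rate, self.bands, self.level).attack(x, int(t)))
        return results


def attack_gpbeam_de(
    model_beam: VictimClassifier,
    sample: np.ndarray,
    y_true: int,
    config: DEConfig,
    montage: Montage,
    grid: GridSpec,
    **kw,
) -> AdversarialResult:
    """One-shot functional form of :class:`GPBEAMDEAttack`."""
    return GPBEAMDEAttack(model_beam, montage, grid, config, **kw).attack(sample, y_true)
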