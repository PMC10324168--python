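"""Dense BEAM-space attack: perturb topographic maps, carry the perturbation back to EEG.

The pipeline has three stages.  (1) The raw sample is decomposed into rhythms
and rendered as BEAMs.  (2) A gradient perturbation of the BEAM tensor is
generated against the victim and resampled at the electrode positions, giving
a rhythm-power perturbation eta_P.  (3) eta_P is imposed on the frequency-
domain rhythms — each spectral bin absorbs a share of the power change
proportional to its squared real/imaginary magnitudes — and the perturbed
rhythms are spliced back into the raw signal's wavelet-packet decomposition,
yielding a time-domain adversarial sample whose out-of-band content is
untouched.

The modified variant additionally attacks an EEG-input victim directly and
uses that adversarial signal as the carrier for stage (3), making the output
aggressive to both model families at the same distortion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ..beams import build_beams, sample_perturbation
from ..montage import GridSpec, Montage
from ..rhythms import DEFAULT_BANDS, band_leaf_indices, haar_packet, haar_packet_inverse
from ..victims import VictimClassifier
from .gradient import PerturbationConfig, gen_perturbation

__all__ = [
    "AdversarialResult",
    "impose_on_frequency",
    "reconstruct_eeg",
    "gen_beam_perturbation",
    "GPBEAMAttack",
    "attack_gpbeam",
    "attack_modified",
]


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.asarray(a, float) - np.asarray(b, float)) ** 2)))


@dataclass
class AdversarialResult:
    """Outcome of one attack on one sample."""

    adversarial_eeg: np.ndarray          # (T, C, S)
    eta_beam: np.ndarray | None          # (T, B, H, W)
    eta_p: np.ndarray                    # (T, B, C)
    y_true: int
    pred_before: int
    pred_after: int
    dl_b: float
    dl_e: float
    generations: int | None = None       # DE only
    extras: dict = field(default_factory=dict)

    @property
    def success(self) -> bool:
        return self.pred_after != self.y_true

    @property
    def label_changed(self) -> bool:
        """Success relative to the clean prediction instead of the true label."""
        return self.pred_after != self.pred_before


def impose_on_frequency(F: np.ndarray, eta_p: np.ndarray) -> np.ndarray:
    """Add a rhythm-power perturbation to frequency-domain rhythms.

    ``F`` has shape (..., C, S) complex; ``eta_p`` broadcasts over the bin axis
    (shape (..., C)).  Working on the magnitudes of the real and imaginary
    components, each bin receives ``sign(eta) * eta**2`` split proportionally
    to the components' squared magnitudes; magnitudes are clamped at zero and
    the original component signs are restored.  Bins with both components zero
    are left unchanged, and eta_p = 0 is the exact identity.
    """
    F = np.asarray(F, dtype=complex)
    eta = np.asarray(eta_p, dtype=float)[..., None]
    fr, fi = F.real, F.imag
    m_r, m_i = np.abs(fr), np.abs(fi)
    denom = m_r**2 + m_i**2
    safe = np.where(denom > 0, denom, 1.0)
    add = np.sign(eta) * eta**2
    new_r = np.clip(m_r + add * m_r**2 / safe, 0.0, None)
    new_i = np.clip(m_i + add * m_i**2 / safe, 0.0, None)
    zero = denom == 0
    new_r = np.where(zero, m_r, new_r)
    new_i = np.where(zero, m_i, new_i)
    return np.sign(fr) * new_r + 1j * np.sign(fi) * new_i


def reconstruct_eeg(
    raw: np.ndarray,
    D: np.ndarray,
    sample_rate: float = 256.0,
    level: int = 8,
    bands: Mapping[str, tuple[float, float]] = DEFAULT_BANDS,
    imag_tol: float = 1e-8,
) -> np.ndarray:
    """Rebuild a time-domain sample from perturbed frequency rhythms.

    Each band of ``D`` (shape (T, B, C, S)) is inverse-DFT'd, wavelet-packet
    decomposed, and its in-band leaves spliced into the raw sample's
    decomposition; leaves outside every band come from ``raw`` (T, C, S).
    """
    raw = np.asarray(raw, dtype=float)
    rhythms = np.fft.ifft(np.asarray(D, dtype=complex), axis=-1)
    resid = np.abs(rhythms.imag).max()
    if resid > imag_tol:
        raise ValueError(f"perturbed rhythms are not real: imaginary residue {resid:.3e}")
    leaves = haar_packet(raw, level)               # (T, C, 2**level, S/2**level)
    adv_leaves = haar_packet(rhythms.real, level)  # (T, B, C, 2**level, ...)
    band_names = list(bands)
    for bi, b in enumerate(band_names):
        idx = band_leaf_indices(b, sample_rate, level, bands)
        leaves[..., idx, :] = adv_leaves[..., bi, :, :, :][..., idx, :]
    return haar_packet_inverse(leaves, level)


def gen_beam_perturbation(
    model_beam: VictimClassifier,
    beam: np.ndarray,
    y_true: int,
    config: PerturbationConfig,
) -> np.ndarray:
    """Perturbation of one BEAM tensor (T, B, H, W) against a beam-input victim."""
    if model_beam.input_kind != "beam":
        raise ValueError("gen_beam_perturbation requires a beam-input victim")
    return gen_perturbation(model_beam, np.asarray(beam)[None], np.array([y_true]), config)[0]


class GPBEAMAttack:
    """Configured dense attack bound to a beam-input victim and a head geometry."""

    def __init__(
        self,
        victim: VictimClassifier,
        montage: Montage,
        grid: GridSpec,
        config: PerturbationConfig | None = None,
        sample_rate: float = 256.0,
        bands: Mapping[str, tuple[float, float]] = DEFAULT_BANDS,
        level: int = 8,
    ):
        if victim.input_kind != "beam":
            raise ValueError("GPBEAM attacks a beam-input victim")
        self.victim = victim
        self.montage, self.grid = montage, grid
        self.config = config or PerturbationConfig()
        self.sample_rate, self.bands, self.level = sample_rate, bands, level

    # -- pipeline pieces ------------------------------------------------
    def _beams_of(self, sample: np.ndarray) -> np.ndarray:
        from ..rhythms import decompose_sample

        P = decompose_sample(sample, self.sample_rate, level=self.level, bands=self.bands).powers
        return build_beams(P, self.montage, self.grid)

    def perturb(self, sample: np.ndarray, y_true: int, carrier: np.ndarray | None = None
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Run the three stages; returns (adversarial EEG, eta_beam, eta_p).

        ``carrier`` (default: the raw sample) receives the imposed rhythm
        perturbation — the hook the modified dual-target variant uses.
        """
        from ..rhythms import decompose_sample

        sample = np.asarray(sample, dtype=float)
        dec = decompose_sample(sample, self.sample_rate, level=self.level, bands=self.bands)
        beam = build_beams(dec.powers, self.montage, self.grid)
        eta_beam = gen_beam_perturbation(self.victim, beam, y_true, self.config)
        eta_p = sample_perturbation(eta_beam, self.montage, self.grid)
        if carrier is None:
            F = dec.freq
            base = sample
        else:
            base = np.asarray(carrier, dtype=float)
            F = decompose_sample(base, self.sample_rate, level=self.level, bands=self.bands).freq
        D = impose_on_frequency(F, eta_p)
        adv = reconstruct_eeg(base, D, self.sample_rate, self.level, self.bands)
        return adv, eta_beam, eta_p

    def attack(self, sample: np.ndarray, y_true: int) -> AdversarialResult:
        sample = np.asarray(sample, dtype=float)
        beam_raw = self._beams_of(sample)
        adv, eta_beam, eta_p = self.perturb(sample, y_true)
        beam_adv = self._beams_of(adv)
        pred_before = int(self.victim.predict(beam_raw[None])[0])
        pred_after = int(self.victim.predict(beam_adv[None])[0])
        return AdversarialResult(
            adversarial_eeg=adv,
            eta_beam=eta_beam,
            eta_p=eta_p,
            y_true=int(y_true),
            pred_before=pred_before,
            pred_after=pred_after,
            dl_b=_rmse(beam_raw + eta_beam, beam_raw),
            dl_e=_rmse(adv, sample),
        )

    def attack_many(self, X: np.ndarray, y: np.ndarray) -> list[AdversarialResult]:
        return [self.attack(x, int(t)) for x, t in zip(np.asarray(X), np.asarray(y))]


def attack_gpbeam(
    model_beam: VictimClassifier,
    sample: np.ndarray,
    y_true: int,
    config: PerturbationConfig,
    montage: Montage,
    grid: GridSpec,
    **kw,
) -> AdversarialResult:
    """One-shot functional form of :class:`GPBEAMAttack`."""
    return GPBEAMAttack(model_beam, montage, grid, config, **kw).attack(sample, y_true)


def attack_modified(
    model_beam: VictimClassifier,
    model_eeg: VictimClassifier,
    sample: np.ndarray,
    y_true: int,
    eps_b: float,
    eps_e: float,
    config: PerturbationConfig | None = None,
    montage: Montage | None = None,
    grid: GridSpec | None = None,
    recompute_on_adv: bool = False,
    **kw,
) -> AdversarialResult:
    """Dual-target attack: FGSM in EEG space supplies the carrier signal.

    An adversarial EEG sample (FGSM at ``eps_e`` against the eeg-input victim)
    replaces the raw sample as the carrier into which the BEAM-space
    rhythm-power perturbation (at ``eps_b``) is imposed.  With
    ``recompute_on_adv`` the BEAMs/eta_P are computed from the carrier instead
    of the raw sample.
    """
    if model_eeg.input_kind != "eeg":
        raise ValueError("attack_modified needs an eeg-input victim for the carrier")
    sample = np.asarray(sample, dtype=float)
    cfg = config or PerturbationConfig()
    cfg = PerturbationConfig(epsilon=eps_b, method=cfg.method, iterations=cfg.iterations,
                             step=cfg.step, momentum=cfg.momentum, seed=cfg.seed)
    e_adv = sample + eps_e * np.sign(model_eeg.loss_gradient(sample[None], np.array([y_true]))[0])
    atk = GPBEAMAttack(model_beam, montage, grid, cfg, **kw)
    source = e_adv if recompute_on_adv else sample
    dec_beam_raw = atk._beams_of(sample)
    adv, eta_beam, eta_p = atk.perturb(source, y_true, carrier=e_adv)
    beam_adv = atk._beams_of(adv)
    return AdversarialResult(
        adversarial_eeg=adv,
        eta_beam=eta_beam,
        eta_p=eta_p,
        y_true=int(y_true),
        pred_before=int(model_beam.predict(dec_beam_raw[None])[0]),
        pred_after=int(model_beam.predict(beam_adv[None])[0]),
        dl_b=_rmse(dec_beam_raw + eta_beam, dec_beam_raw),
        dl_e=_rmse(adv, sample),
        extras={"eps_b": eps_b, "eps_e": eps_e,
                "pred_after_eeg": int(model_eeg.predict(adv[None])[0]),
                "pred_before_eeg": int(model_eeg.predict(sample[None])[0])},
    )
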