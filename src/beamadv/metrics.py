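"""Attack evaluation: success rate, distortion, accuracy, baselines, transfer.

SR = R/S counts label flips; distortion DL is the mean over samples of the
per-sample root-mean-square difference (computed on BEAM tensors for DL_B, raw
EEG for DL_E); Acc = A/S is plain classification accuracy.  Success is counted
against the true label by default; the clean-prediction-relative count is
always recorded alongside, since published tables do not always say which
convention they use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .attacks.gpbeam import AdversarialResult
from .beams import BeamTransformer
from .montage import GridSpec, Montage
from .victims import VictimClassifier

__all__ = [
    "EvalReport", "success_rate", "distortion", "accuracy",
    "evaluate_results", "gaussian_baseline", "transfer_eval",
]


@dataclass
class EvalReport:
    """Aggregate attack metrics over a sample set."""

    sr: float
    acc: float
    dl_b: float
    dl_e: float
    n_samples: int
    sr_vs_clean: float = float("nan")  # flips counted against the clean prediction
    records: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.sr <= 1.0 and 0.0 <= self.acc <= 1.0):
            raise ValueError("sr and acc must lie in [0, 1]")
        if self.dl_b < 0 or self.dl_e < 0:
            raise ValueError("distortions must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def success_rate(flips: Sequence[bool]) -> float:
    """Fraction of attacks that changed the predicted label (R / S)."""
    flips = np.asarray(flips, dtype=bool)
    if flips.size == 0:
        raise ValueError("success_rate needs at least one sample")
    return float(flips.mean())


def accuracy(preds: Sequence[int], labels: Sequence[int]) -> float:
    """Fraction of correct predictions (A / S)."""
    preds, labels = np.asarray(preds), np.asarray(labels)
    if preds.size == 0:
        raise ValueError("accuracy needs at least one sample")
    if preds.shape != labels.shape:
        raise ValueError("preds and labels must align")
    return float((preds == labels).mean())


def distortion(adv: np.ndarray, raw: np.ndarray) -> float:
    """Mean over samples of the per-sample RMSE between adv and raw."""
    adv, raw = np.asarray(adv, float), np.asarray(raw, float)
    if adv.shape != raw.shape:
        raise ValueError("shape mismatch")
    diff = (adv - raw).reshape(adv.shape[0], -1)
    return float(np.sqrt(np.mean(diff**2, axis=1)).mean())


def evaluate_results(results: Sequence[AdversarialResult]) -> EvalReport:
    """Aggregate a list of per-sample attack results."""
    if not results:
        raise ValueError("no results to evaluate")
    recs = [
        {
            "y_true": r.y_true, "pred_before": r.pred_before, "pred_after": r.pred_after,
            "success": r.success, "label_changed": r.label_changed,
            "dl_b": r.dl_b, "dl_e": r.dl_e,
            "generations": r.generations,
        }
        for r in results
    ]
    return EvalReport(
        sr=success_rate([r.success for r in results]),
        acc=accuracy([r.pred_after for r in results], [r.y_true for r in results]),
        dl_b=float(np.mean([r.dl_b for r in results])),
        dl_e=float(np.mean([r.dl_e for r in results])),
        n_samples=len(results),
        sr_vs_clean=success_rate([r.label_changed for r in results]),
        records=recs,
    )


def gaussian_baseline(
    beams: np.ndarray,
    y: np.ndarray,
    victim: VictimClassifier,
    sigma: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, EvalReport]:
    """Additive N(0, sigma) noise on BEAM tensors, evaluated through the victim.

    The reported DL_B is the empirical RMSE of the noise field, not sigma.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    beams = np.asarray(beams, float)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=beams.shape) if sigma > 0 else np.zeros_like(beams)
    perturbed = beams + noise
    pred_before = victim.predict(beams)
    pred_after = victim.predict(perturbed)
    y = np.asarray(y)
    report = EvalReport(
        sr=success_rate(pred_after != y),
        acc=accuracy(pred_after, y),
        dl_b=distortion(perturbed, beams),
        dl_e=0.0,
        n_samples=len(y),
        sr_vs_clean=success_rate(pred_after != pred_before),
        records=[{"y_true": int(t), "pred_before": int(b), "pred_after": int(a)}
                 for t, b, a in zip(y, pred_before, pred_after)],
    )
    return perturbed, report


def transfer_eval(
    adversarial_eeg: np.ndarray,
    raw_eeg: np.ndarray,
    y: np.ndarray,
    targets: dict[str, VictimClassifier],
    montage: Montage,
    grid: GridSpec,
    sample_rate: float = 256.0,
) -> pd.DataFrame:
    """Apply EEG adversarial samples to target victims through their own pipelines.

    Beam-input targets see the BEAMs recomputed from the adversarial EEG;
    eeg-input targets see the raw adversarial EEG.  SR counts flips of each
    target's own clean prediction; SR versus the true label and Acc are also
    reported.  Returns one row per named target.
    """
    adversarial_eeg = np.asarray(adversarial_eeg, float)
    raw_eeg = np.asarray(raw_eeg, float)
    y = np.asarray(y)
    bt = BeamTransformer(montage, grid, sample_rate)
    cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def inputs_for(kind: str) -> tuple[np.ndarray, np.ndarray]:
        if kind not in cache:
            if kind == "beam":
                cache[kind] = (bt.transform(adversarial_eeg), bt.transform(raw_eeg))
            else:
                cache[kind] = (adversarial_eeg, raw_eeg)
        return cache[kind]

    rows = []
    for name, victim in targets.items():
        adv_in, raw_in = inputs_for(victim.input_kind)
        pred_after = victim.predict(adv_in)
        pred_before = victim.predict(raw_in)
        rows.append({
            "target": name,
            "input_kind": victim.input_kind,
            "acc": accuracy(pred_after, y),
            "sr": success_rate(pred_after != pred_before),
            "sr_vs_true": success_rate(pred_after != y),
            "clean_acc": accuracy(pred_before, y),
            "n": len(y),
        })
    return pd.DataFrame(rows).set_index("target")
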