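"""Synthetic seizure/background EEG, segmentation rules, and an optional EDF reader.

The generator emulates the structure the attack pipeline assumes: 22-channel
scalp EEG at 256 Hz in trials of five 1-second slices.  Background activity is
1/f noise plus a 10 Hz alpha rhythm on every channel; the seizure class adds a
high-amplitude 3 Hz spike-wave complex (fundamental plus decaying harmonics) on
a focal subset of electrodes, mimicking the generalized spike-and-wave
discharges of absence-type seizures.  Every sample is z-scored per channel, so
classes differ in spectral content and topography, not in gross amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .montage import Montage, build_montage, load_channel_mapping

__all__ = ["SyntheticConfig", "generate_dataset", "segment_recording", "read_edf", "is_bad_window"]


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic two-class EEG task.

    The seizure class combines a focal spike-wave discharge (the strong,
    clinically obvious feature, with trial-to-trial amplitude variability) and
    a diffuse low-amplitude delta-band elevation over the whole scalp (many
    weak distributed correlates, as in generalized slowing).  The variability
    makes weak-discharge trials genuinely hard, holding a well-trained
    classifier below ceiling, while the diffuse component means its decision
    aggregates many small spectral features across electrodes.
    """

    n_per_class: int = 100
    T: int = 5
    C: int = 22
    S: int = 256
    fs: float = 256.0
    seed: int = 0
    seizure_freq: float = 3.0      # Hz, spike-wave fundamental (delta band)
    seizure_amp: float = 1.1       # median focal amplitude vs unit background
    seizure_amp_sigma: float = 0.45  # lognormal spread of the focal amplitude
    n_harmonics: int = 4
    diffuse_amp: float = 0.35      # scalp-wide delta elevation amplitude
    noise_exponent: float = 1.0    # 1/f^a background spectrum
    alpha_freq: float = 10.0
    alpha_amp: float = 0.5
    alpha_amp_sigma: float = 0.3   # lognormal spread of the alpha amplitude
    spatial_focus: tuple[str, ...] = ("F7", "T7", "P7", "FT9")

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.fs != self.S:
            raise ValueError("slices are 1 s long: fs must equal S")


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], n: int, exponent: float) -> np.ndarray:
    """1/f^exponent noise along a final axis of length n, unit variance."""
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    spec = (rng.standard_normal(shape + (len(freqs),)) + 1j * rng.standard_normal(shape + (len(freqs),))) * scale
    x = np.fft.irfft(spec, n=n, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _band_noise(rng: np.random.Generator, shape: tuple[int, ...], n: int,
                lo: float, hi: float, fs: float) -> np.ndarray:
    """Gaussian noise band-limited to [lo, hi] Hz, unit variance per row."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = ((freqs >= lo) & (freqs <= hi)).astype(float)
    spec = (rng.standard_normal(shape + (len(freqs),)) + 1j * rng.standard_normal(shape + (len(freqs),))) * mask
    x = np.fft.irfft(spec, n=n, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def generate_dataset(
    config: SyntheticConfig | None = None,
    montage: Montage | None = None,
    **overrides,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate a balanced, shuffled, per-channel z-scored two-class dataset.

    Returns
    -------
    X : (2 * n_per_class, T, C, S) float array
    y : (2 * n_per_class,) int array; 0 = background, 1 = seizure
    """
    cfg = config or SyntheticConfig(**overrides)
    if config is not None and overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    montage = montage or build_montage()
    if montage.n_channels != cfg.C:
        raise ValueError("montage channel count does not match config C")
    focus = np.array([montage.index(ch) for ch in cfg.spatial_focus])
    rng = np.random.default_rng(cfg.seed)
    n_total = 2 * cfg.n_per_class
    L = cfg.T * cfg.S
    t = np.arange(L) / cfg.fs

    X = _pink_noise(rng, (n_total, cfg.C), L, cfg.noise_exponent)
    # alpha rhythm: random phase per channel, lognormal amplitude per trial
    phases = rng.uniform(0, 2 * np.pi, size=(n_total, cfg.C, 1))
    a_amp = cfg.alpha_amp * rng.lognormal(0.0, cfg.alpha_amp_sigma, size=(n_total, 1, 1))
    X += a_amp * np.sin(2 * np.pi * cfg.alpha_freq * t + phases)

    y = np.zeros(n_total, dtype=int)
    y[cfg.n_per_class :] = 1
    n_sz = cfg.n_per_class
    # focal spike-wave: fundamental + decaying harmonics, continuous phase,
    # lognormal trial amplitude and per-channel weight jitter
    sz_phase = rng.uniform(0, 2 * np.pi, size=(n_sz, 1, 1))
    wave = sum(
        (1.0 / k) * np.sin(2 * np.pi * k * cfg.seizure_freq * t + k * sz_phase)
        for k in range(1, cfg.n_harmonics + 1)
    )
    amp = cfg.seizure_amp * rng.lognormal(0.0, cfg.seizure_amp_sigma, size=(n_sz, 1, 1))
    weights = rng.uniform(0.5, 1.0, size=(n_sz, len(focus), 1))
    X[n_sz:, focus, :] += amp * weights * wave
    # diffuse scalp-wide delta elevation (generalized slowing), jittered per channel
    diffuse = _band_noise(rng, (n_sz, cfg.C), L, 0.5, 4.0, cfg.fs)
    X[n_sz:] += cfg.diffuse_amp * rng.uniform(0.5, 1.5, size=(n_sz, cfg.C, 1)) * diffuse

    X -= X.mean(axis=-1, keepdims=True)
    X /= X.std(axis=-1, keepdims=True)
    X = X.reshape(n_total, cfg.C, cfg.T, cfg.S).transpose(0, 2, 1, 3)  # (N, T, C, S)

    order = rng.permutation(n_total)
    return X[order], y[order]


def is_bad_window(window: np.ndarray, flat_std: float = 1e-7, amp_limit: float = 15.0) -> bool:
    """Simple artefact screen for unit-normalized data.

    A window is bad if any channel is flat (std < ``flat_std``) or any sample
    exceeds ``amp_limit`` standard deviations.
    """
    w = np.asarray(window)
    return bool((w.std(axis=-1) < flat_std).any() or (np.abs(w) > amp_limit).any())


def segment_recording(
    recording: np.ndarray,
    seizure_intervals: Sequence[tuple[float, float]],
    fs: float = 256.0,
    window_s: float = 5.0,
    seizure_stride_s: float = 3.0,
    background_stride_s: float = 5.0,
    n_slices: int = 5,
    balance: bool = True,
    reject: bool = False,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cut a continuous recording into labeled (T, C, S) trials.

    Seizure windows start every ``seizure_stride_s`` (5 s windows sharing 2 s)
    inside each seizure interval; background windows tile the complement
    non-overlapping.  With ``balance`` the background class is subsampled to
    the seizure count.
    """
    rec = np.asarray(recording, dtype=float)
    if rec.ndim != 2:
        raise ValueError("recording must be channels x samples")
    n_samp = rec.shape[1]
    win = int(round(window_s * fs))
    if n_samp < win:
        raise ValueError("recording shorter than one window")
    S = win // n_slices

    def cut(start_samp: int) -> np.ndarray:
        w = rec[:, start_samp : start_samp + win]  # (C, win)
        return w.reshape(rec.shape[0], n_slices, S).transpose(1, 0, 2)

    in_seizure = np.zeros(n_samp, dtype=bool)
    for s, e in seizure_intervals:
        in_seizure[int(round(s * fs)) : int(round(e * fs))] = True

    seiz, bg = [], []
    for s, e in seizure_intervals:
        start, stride = int(round(s * fs)), int(round(seizure_stride_s * fs))
        while start + win <= int(round(e * fs)):
            seiz.append(cut(start))
            start += stride
    stride_bg = int(round(background_stride_s * fs))
    start = 0
    while start + win <= n_samp:
        if not in_seizure[start : start + win].any():
            bg.append(cut(start))
        start += stride_bg

    if reject:
        seiz = [w for w in seiz if not is_bad_window(w)]
        bg = [w for w in bg if not is_bad_window(w)]
    rng = np.random.default_rng(seed)
    if balance and len(bg) > len(seiz):
        bg = [bg[i] for i in sorted(rng.choice(len(bg), size=len(seiz), replace=False))]
    X = np.stack(seiz + bg) if (seiz or bg) else np.empty((0, n_slices, rec.shape[0], S))
    y = np.array([1] * len(seiz) + [0] * len(bg), dtype=int)
    return X, y


def read_edf(
    path: str,
    montage_mapping: dict[str, str] | None = None,
    expected_fs: float = 256.0,
) -> tuple[np.ndarray, list[str], list[tuple[float, float, str]]]:
    """Read an EDF recording, map channels to 10-20 labels, unit-normalize.

    Returns (data (C, n_samples), mapped labels, annotations).  Requires the
    optional ``mne`` dependency.
    """
    import mne  # optional dependency

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if abs(raw.info["sfreq"] - expected_fs) > 1e-6:
        raise ValueError(f"expected sampling rate {expected_fs} Hz, file has {raw.info['sfreq']}")
    mapping = montage_mapping or load_channel_mapping()
    missing = [ch for ch in mapping if ch not in raw.ch_names]
    if missing:
        raise KeyError(f"mapping channels absent from file: {missing}")
    data = np.stack([raw.get_data(picks=[ch])[0] for ch in mapping])
    std = data.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    data = (data - data.mean(axis=1, keepdims=True)) / std
    annot = [(float(a["onset"]), float(a["duration"]), str(a["description"])) for a in raw.annotations]
    return data, list(mapping.values()), annot
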