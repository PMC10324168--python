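"""Wavelet-packet rhythm extraction and rhythm power.

Each 1-second, 256-sample slice of each electrode is decomposed with a full
wavelet-packet tree (db1/Haar, 8 levels), whose leaves tile the 0..fs/2 axis in
uniform bins of fs/2**(level+1) Hz.  Zeroing every leaf outside a rhythm band
and inverting the transform yields the time-domain rhythm; its unnormalized DFT
is the frequency-domain rhythm, and the mean absolute value of that spectrum is
the rhythm power.  The orthonormal filter convention is used throughout so the
transform conserves energy exactly.

Leaves are kept in frequency (sequency) order: the tree's natural order
interleaves frequencies in Gray-code fashion, and band selection is only
meaningful after the Gray-code permutation ``natural_index = f ^ (f >> 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pywt

__all__ = [
    "DEFAULT_BANDS",
    "WPTCoefficients",
    "wpt_decompose",
    "wpt_reconstruct",
    "band_leaf_indices",
    "filter_band",
    "extract_time_rhythm",
    "fft_rhythm",
    "rhythm_power",
    "decompose_sample",
    "rhythm_powers",
    "reconstruct_slice",
    "haar_packet",
    "haar_packet_inverse",
    "Decomposition",
]

#: Canonical EEG rhythm bands, Hz, half-open intervals.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

_SQRT2 = np.sqrt(2.0)


def _check_bands(bands: Mapping[str, tuple[float, float]]) -> None:
    items = sorted(bands.items(), key=lambda kv: kv[1][0])
    for (na, (la, ha)), (nb, (lb, hb)) in zip(items, items[1:]):
        if ha > lb:
            raise ValueError(f"bands {na!r} and {nb!r} overlap")


def _gray_permutation(level: int) -> np.ndarray:
    f = np.arange(2**level)
    return f ^ (f >> 1)  # natural-order index of the f-th frequency-ordered leaf


def haar_packet(x: np.ndarray, level: int) -> np.ndarray:
    """Full orthonormal Haar wavelet-packet transform along the last axis.

    Returns leaves in frequency order, shaped ``(..., 2**level, S / 2**level)``.
    Vectorized over all leading axes.
    """
    x = np.asarray(x, dtype=np.float64)
    S = x.shape[-1]
    if S % (2**level):
        raise ValueError(f"signal length {S} not divisible by 2**{level}")
    out = x.reshape(x.shape[:-1] + (1, S))
    for _ in range(level):
        a = (out[..., ::2] + out[..., 1::2]) / _SQRT2
        d = (out[..., ::2] - out[..., 1::2]) / _SQRT2
        out = np.stack([a, d], axis=-2).reshape(
            out.shape[:-2] + (out.shape[-2] * 2, out.shape[-1] // 2)
        )
    return out[..., _gray_permutation(level), :]


def haar_packet_inverse(leaves: np.ndarray, level: int) -> np.ndarray:
    """Inverse of :func:`haar_packet`; accepts frequency-ordered leaves."""
    leaves = np.asarray(leaves, dtype=np.float64)
    inv = np.empty_like(_gray_permutation(level))
    inv[_gray_permutation(level)] = np.arange(2**level)
    out = leaves[..., inv, :]
    for _ in range(level):
        half = out.reshape(out.shape[:-2] + (out.shape[-2] // 2, 2, out.shape[-1]))
        a, d = half[..., 0, :], half[..., 1, :]
        rec = np.empty(a.shape[:-1] + (2 * a.shape[-1],), dtype=out.dtype)
        rec[..., ::2] = (a + d) / _SQRT2
        rec[..., 1::2] = (a - d) / _SQRT2
        out = rec.reshape(out.shape[:-2] + (out.shape[-2] // 2, 2 * out.shape[-1]))
    return out[..., 0, :]


@dataclass
class WPTCoefficients:
    """Frequency-ordered wavelet-packet leaves of one slice of one electrode."""

    leaves: np.ndarray  # (2**level, S / 2**level)
    wavelet: str = "db1"
    level: int = 8

    @property
    def n_samples(self) -> int:
        return self.leaves.shape[0] * self.leaves.shape[1]

    def copy(self) -> "WPTCoefficients":
        return WPTCoefficients(self.leaves.copy(), self.wavelet, self.level)


def wpt_decompose(signal: np.ndarray, wavelet: str = "db1", level: int = 8) -> WPTCoefficients:
    """Decompose a slice into full wavelet-packet leaf coefficients.

    db1 takes a closed-form vectorized path; other wavelets go through
    PyWavelets (periodization mode, so the transform stays orthonormal).
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 1:
        raise ValueError("wpt_decompose expects a 1-D slice")
    if signal.size % (2**level):
        raise ValueError(f"signal length {signal.size} not divisible by 2**{level}")
    if wavelet in ("db1", "haar"):
        return WPTCoefficients(haar_packet(signal, level), wavelet, level)
    wp = pywt.WaveletPacket(signal, wavelet, mode="periodization", maxlevel=level)
    nodes = wp.get_level(level, order="freq")
    return WPTCoefficients(np.stack([n.data for n in nodes]), wavelet, level)


def wpt_reconstruct(coeffs: WPTCoefficients) -> np.ndarray:
    """Invert :func:`wpt_decompose`."""
    if coeffs.wavelet in ("db1", "haar"):
        return haar_packet_inverse(coeffs.leaves, coeffs.level)
    wp = pywt.WaveletPacket(None, coeffs.wavelet, mode="periodization", maxlevel=coeffs.level)
    paths = [n.path for n in pywt.WaveletPacket(
        np.zeros(coeffs.n_samples), coeffs.wavelet, mode="periodization",
        maxlevel=coeffs.level).get_level(coeffs.level, order="freq")]
    for path, leaf in zip(paths, coeffs.leaves):
        wp[path] = leaf
    return wp.reconstruct(update=False)[: coeffs.n_samples]


def band_leaf_indices(
    band: str,
    sample_rate: float = 256.0,
    level: int = 8,
    bands: Mapping[str, tuple[float, float]] = DEFAULT_BANDS,
) -> np.ndarray:
    """Frequency-ordered leaf indices whose nominal interval intersects the band.

    Leaf ``k`` nominally covers ``[k*w, (k+1)*w)`` with ``w = fs / 2**(level+1)``.
    With the default bands and level the band edges are multiples of ``w``
    (0.5 Hz), so distinct bands select disjoint leaf sets and the DC leaf
    belongs to none.
    """
    _check_bands(bands)
    try:
        lo, hi = bands[band]
    except KeyError:
        raise KeyError(f"unknown band {band!r}; known: {sorted(bands)}") from None
    w = sample_rate / 2 ** (level + 1)
    k = np.arange(2**level)
    return k[(k * w < hi) & ((k + 1) * w > lo)]


def filter_band(
    coeffs: WPTCoefficients,
    band: str,
    sample_rate: float = 256.0,
    bands: Mapping[str, tuple[float, float]] = DEFAULT_BANDS,
) -> WPTCoefficients:
    """Zero every leaf outside the band (idempotent)."""
    idx = band_leaf_indices(band, sample_rate, coeffs.level, bands)
    out = np.zeros_like(coeffs.leaves)
    out[idx] = coeffs.leaves[idx]
    return WPTCoefficients(out, coeffs.wavelet, coeffs.level)


def extract_time_rhythm(
    slice_: np.ndarray,
    band: str,
    sample_rate: float = 256.0,
    wavelet: str = "db1",
    level: int = 8,
    bands: Mapping[str, tuple[float, float]] = DEFAULT_BANDS,
) -> np.ndarray:
    """Time-domain rhythm of one slice: IWPT of the band-filtered leaves."""
    return wpt_reconstruct(filter_band(wpt_decompose(slice_, wavelet, level), band, sample_rate, bands))


def fft_rhythm(rhythm: np.ndarray) -> np.ndarray:
    """Unnormalized forward DFT of a time-domain rhythm (last axis)."""
    return np.fft.fft(np.asarray(rhythm), axis=-1)


def rhythm_power(spectrum: np.ndarray) -> np.ndarray:
    """Mean absolute value of the spectrum (last axis); the rhythm power."""
    spectrum = np.asarray(spectrum)
    if spectrum.shape[-1] == 0:
        raise ValueError("empty spectrum")
    return np.mean(np.abs(spectrum), axis=-1)


class Decomposition(NamedTuple):
    """All products of the slice-wise rhythm pipeline for one or more samples."""

    coeffs: np.ndarray   # (..., T, C, 2**level, S/2**level) frequency-ordered leaves
    rhythms: np.ndarray  # (..., T, B, C, S) time-domain rhythms
    freq: np.ndarray     # (..., T, B, C, S) complex frequency-domain rhythms
    powers: np.ndarray   # (..., T, B, C) rhythm power array P


def decompose_sample(
    sample: np.ndarray,
    sample_rate: float = 256.0,
    wavelet: str = "db1",
    level: int = 8,
    bands: Mapping[str, tuple[float, float]] = DEFAULT_BANDS,
) -> Decomposition:
    """Run the full rhythm pipeline on a T x C x S sample (leading axes allowed).

    Only the db1 fast path is vectorized; other wavelets fall back to per-slice
    PyWavelets transforms.
    """
    sample = np.asarray(sample, dtype=np.float64)
    if sample.ndim < 2:
        raise ValueError("sample must be at least T x S")
    _check_bands(bands)
    band_names = list(bands)
    if wavelet in ("db1", "haar"):
        coeffs = haar_packet(sample, level)
        rhythms = []
        for b in band_names:
            idx = band_leaf_indices(b, sample_rate, level, bands)
            kept = np.zeros_like(coeffs)
            kept[..., idx, :] = coeffs[..., idx, :]
            rhythms.append(haar_packet_inverse(kept, level))
        rhythms = np.stack(rhythms, axis=-3)  # (..., T, B, C, S)
    else:
        flat = sample.reshape(-1, sample.shape[-1])
        coeffs = np.stack([wpt_decompose(s, wavelet, level).leaves for s in flat])
        coeffs = coeffs.reshape(sample.shape[:-1] + coeffs.shape[1:])
        rhythms = np.stack(
            [
                np.stack([extract_time_rhythm(s, b, sample_rate, wavelet, level, bands) for s in flat])
                .reshape(sample.shape)
                for b in band_names
            ],
            axis=-3,
        )
    freq = fft_rhythm(rhythms)
    powers = rhythm_power(freq)
    return Decomposition(coeffs=coeffs, rhythms=rhythms, freq=freq, powers=powers)


def rhythm_powers(
    samples: np.ndarray,
    sample_rate: float = 256.0,
    level: int = 8,
    bands: Mapping[str, tuple[float, float]] = DEFAULT_BANDS,
    chunk: int = 64,
) -> np.ndarray:
    """Rhythm power arrays (..., T, B, C) for a batch, without keeping rhythms.

    Memory-bounded variant of :func:`decompose_sample` (db1 only) for whole
    datasets: processes ``chunk`` samples at a time.
    """
    samples = np.asarray(samples, dtype=np.float64)
    if samples.ndim == 3:
        return decompose_sample(samples, sample_rate, level=level, bands=bands).powers
    out = []
    for i in range(0, samples.shape[0], chunk):
        out.append(decompose_sample(samples[i : i + chunk], sample_rate, level=level, bands=bands).powers)
    return np.concatenate(out, axis=0)


def reconstruct_slice(
    original: np.ndarray,
    band_coeffs: Mapping[str, WPTCoefficients | np.ndarray],
    sample_rate: float = 256.0,
    wavelet: str = "db1",
    level: int = 8,
    bands: Mapping[str, tuple[float, float]] = DEFAULT_BANDS,
) -> np.ndarray:
    """Splice per-band leaf coefficients into a slice's decomposition and invert.

    Leaves outside every band's index set come from ``original``; leaves inside
    band ``b`` come from ``band_coeffs[b]``.
    """
    base = wpt_decompose(np.asarray(original, dtype=np.float64), wavelet, level)
    leaves = base.leaves.copy()
    for b, repl in band_coeffs.items():
        idx = band_leaf_indices(b, sample_rate, level, bands)
        repl_leaves = repl.leaves if isinstance(repl, WPTCoefficients) else np.asarray(repl)
        leaves[idx] = repl_leaves[idx]
    return wpt_reconstruct(WPTCoefficients(leaves, wavelet, level))
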