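"""Wavelet-packet transform, band filtering, rhythm power."""

import numpy as np
import pytest
import pywt
from hypothesis import given, settings
from hypothesis import strategies as st

import beamadv.rhythms as rh

FS = 256.0
T_AXIS = np.arange(256) / 256.0


class TestWPT:
    def test_haar_constant_closed_form(self):
        """Level-8 db1 of an all-ones 256-sample slice: approximation leaf 16, rest 0."""
        c = rh.wpt_decompose(np.ones(256))
        assert c.leaves.shape == (256, 1)
        assert abs(c.leaves[0, 0] - 16.0) < 1e-12
        assert np.abs(c.leaves[1:]).max() == 0.0

    def test_zero_signal_all_zero_leaves(self):
        assert np.all(rh.wpt_decompose(np.zeros(256)).leaves == 0.0)

    def test_energy_conservation(self):
        x = np.random.default_rng(3).standard_normal(256)
        c = rh.wpt_decompose(x)
        assert abs((c.leaves**2).sum() - (x**2).sum()) < 1e-8 * (x**2).sum()

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_perfect_reconstruction(self, seed):
        x = np.random.default_rng(seed).standard_normal(256)
        back = rh.wpt_reconstruct(rh.wpt_decompose(x))
        assert np.abs(back - x).max() < 1e-10

    def test_matches_pywavelets_frequency_order(self):
        """The vectorized Haar path agrees with PyWavelets leaf-for-leaf."""
        x = np.random.default_rng(5).standard_normal(256)
        wp = pywt.WaveletPacket(x, "db1", mode="periodization", maxlevel=8)
        ref = np.stack([n.data for n in wp.get_level(8, order="freq")])
        np.testing.assert_allclose(rh.wpt_decompose(x).leaves, ref, atol=1e-12)

    def test_other_wavelet_round_trip(self):
        x = np.random.default_rng(6).standard_normal(256)
        back = rh.wpt_reconstruct(rh.wpt_decompose(x, wavelet="db2", level=4))
        np.testing.assert_allclose(back, x, atol=1e-8)

    def test_indivisible_length_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            rh.wpt_decompose(np.zeros(250))


class TestBandMapping:
    @pytest.mark.parametrize(
        "band, expected",
        [("delta", range(1, 8)), ("theta", range(8, 16)),
         ("alpha", range(16, 26)), ("beta", range(26, 60))],
    )
    def test_leaf_indices(self, band, expected):
        assert rh.band_leaf_indices(band).tolist() == list(expected)

    def test_bands_disjoint_and_skip_dc(self):
        all_idx = np.concatenate([rh.band_leaf_indices(b) for b in rh.DEFAULT_BANDS])
        assert len(all_idx) == len(set(all_idx))
        assert 0 not in all_idx

    def test_unknown_band_rejected(self):
        with pytest.raises(KeyError, match="gamma"):
            rh.band_leaf_indices("gamma")

    def test_filter_idempotent_and_partition(self):
        x = np.random.default_rng(7).standard_normal(256)
        c = rh.wpt_decompose(x)
        alpha = rh.filter_band(c, "alpha")
        np.testing.assert_array_equal(rh.filter_band(alpha, "alpha").leaves, alpha.leaves)
        # four bands + out-of-band complement reproduce the decomposition
        total = sum(rh.filter_band(c, b).leaves for b in rh.DEFAULT_BANDS)
        in_band = np.concatenate([rh.band_leaf_indices(b) for b in rh.DEFAULT_BANDS])
        complement = np.setdiff1d(np.arange(256), in_band)
        total[complement] += c.leaves[complement]
        np.testing.assert_allclose(total, c.leaves, atol=1e-12)

    def test_filter_zero_is_zero(self):
        z = rh.wpt_decompose(np.zeros(256))
        assert np.all(rh.filter_band(z, "delta").leaves == 0.0)


class TestRhythmExtraction:
    @pytest.mark.parametrize("freq, band", [(2, "delta"), (6, "theta"), (10, "alpha"), (20, "beta")])
    def test_matching_band_dominates_with_db1(self, freq, band):
        """db1 leaves leak across bands, but the matching band always wins."""
        x = np.sin(2 * np.pi * freq * T_AXIS)
        fracs = {b: (rh.extract_time_rhythm(x, b) ** 2).sum() / (x**2).sum()
                 for b in rh.DEFAULT_BANDS}
        assert max(fracs, key=fracs.get) == band

    @pytest.mark.parametrize("freq, band", [(2, "delta"), (6, "theta"), (10, "alpha"), (20, "beta")])
    def test_sharper_wavelet_localizes_90_percent(self, freq, band):
        """With a long filter the same leaf mapping concentrates >= 90% energy,
        isolating db1's leakage to the wavelet, not the band bookkeeping."""
        x = np.sin(2 * np.pi * freq * T_AXIS)
        r = rh.extract_time_rhythm(x, band, wavelet="db16", level=8)
        assert (r**2).sum() / (x**2).sum() >= 0.9

    def test_rhythms_plus_remainder_reproduce_slice(self):
        x = np.random.default_rng(8).standard_normal(256)
        c = rh.wpt_decompose(x)
        in_band = np.concatenate([rh.band_leaf_indices(b) for b in rh.DEFAULT_BANDS])
        complement = np.setdiff1d(np.arange(256), in_band)
        kept = c.copy()
        kept.leaves[in_band] = 0.0
        remainder = rh.wpt_reconstruct(kept)
        total = remainder + sum(rh.extract_time_rhythm(x, b) for b in rh.DEFAULT_BANDS)
        np.testing.assert_allclose(total, x, atol=1e-8)

    def test_zero_slice_zero_rhythm(self):
        assert np.all(rh.extract_time_rhythm(np.zeros(256), "alpha") == 0.0)


class TestSpectrumAndPower:
    def test_fft_basics(self):
        assert np.all(rh.fft_rhythm(np.zeros(256)) == 0.0)
        spec = rh.fft_rhythm(np.full(256, 3.0))
        assert abs(abs(spec[0]) - 256 * 3.0) < 1e-9 and np.abs(spec[1:]).max() < 1e-9
        x = np.random.default_rng(9).standard_normal(256)
        np.testing.assert_allclose(np.fft.ifft(rh.fft_rhythm(x)).real, x, atol=1e-10)

    def test_power_examples(self):
        assert rh.rhythm_power(np.zeros(256, complex)) == 0.0
        assert abs(rh.rhythm_power(np.full(256, 2.0 + 0.0j)) - 2.0) < 1e-12
        # on-bin unit sinusoid: two bins of magnitude S/2 -> mean |F| = 1
        spec = rh.fft_rhythm(np.sin(2 * np.pi * 10 * T_AXIS))
        assert abs(rh.rhythm_power(spec) - 1.0) < 1e-9

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rh.rhythm_power(np.empty(0, complex))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_power_is_1_lipschitz_in_mean_abs_metric(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal(64) + 1j * rng.standard_normal(64)
        b = rng.standard_normal(64) + 1j * rng.standard_normal(64)
        assert abs(rh.rhythm_power(a) - rh.rhythm_power(b)) <= np.mean(np.abs(a - b)) + 1e-12


class TestSamplePipeline:
    def test_paper_shapes(self):
        x = np.random.default_rng(10).standard_normal((5, 22, 256))
        dec = rh.decompose_sample(x)
        assert dec.powers.shape == (5, 4, 22)
        assert dec.rhythms.shape == (5, 4, 22, 256)
        assert dec.freq.shape == (5, 4, 22, 256)
        assert dec.coeffs.shape == (5, 22, 256, 1)
        assert (dec.powers >= 0).all()

    def test_zero_sample_zero_powers(self):
        assert np.all(rh.decompose_sample(np.zeros((5, 22, 256))).powers == 0.0)

    def test_batched_powers_match_per_sample(self):
        X = np.random.default_rng(11).standard_normal((7, 5, 22, 256))
        batch = rh.rhythm_powers(X, chunk=3)
        single = np.stack([rh.decompose_sample(x).powers for x in X])
        np.testing.assert_allclose(batch, single, atol=1e-12)


class TestReconstructSlice:
    def test_identity_replacement(self):
        x = np.random.default_rng(12).standard_normal(256)
        c = rh.wpt_decompose(x)
        out = rh.reconstruct_slice(x, {b: c for b in rh.DEFAULT_BANDS})
        np.testing.assert_allclose(out, x, atol=1e-6)

    def test_zero_bands_equal_signal_minus_rhythms(self):
        """Zeroing every in-band leaf removes exactly the four extracted rhythms."""
        x = np.random.default_rng(13).standard_normal(256)
        zeros = rh.WPTCoefficients(np.zeros((256, 1)))
        out = rh.reconstruct_slice(x, {b: zeros for b in rh.DEFAULT_BANDS})
        expected = x - sum(rh.extract_time_rhythm(x, b) for b in rh.DEFAULT_BANDS)
        np.testing.assert_allclose(out, expected, atol=1e-8)

    def test_only_in_band_leaves_affected(self):
        x = np.random.default_rng(14).standard_normal(256)
        repl = rh.WPTCoefficients(np.random.default_rng(15).standard_normal((256, 1)))
        out_leaves = rh.wpt_decompose(rh.reconstruct_slice(x, {"alpha": repl})).leaves
        orig = rh.wpt_decompose(x).leaves
        idx = rh.band_leaf_indices("alpha")
        outside = np.setdiff1d(np.arange(256), idx)
        np.testing.assert_allclose(out_leaves[outside], orig[outside], atol=1e-10)
        np.testing.assert_allclose(out_leaves[idx], repl.leaves[idx], atol=1e-10)
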