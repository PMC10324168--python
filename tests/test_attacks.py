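"""Attack algebra: perturbation generators, frequency imposition, reconstruction, DE."""

import numpy as np
import pytest

import beamadv as ba
from beamadv.attacks.de import (
    DEConfig, apply_overflow, evolve_step, fitness_population, individual_to_eta,
    init_population,
)
from beamadv.attacks.gradient import PerturbationConfig, gen_perturbation


class TestPerturbationGenerators:
    def test_zero_epsilon_gives_zero(self, linear_stub_factory):
        stub = linear_stub_factory(np.ones((5, 4, 22, 22)))
        X = np.zeros((2, 5, 4, 22, 22))
        eta = gen_perturbation(stub, X, np.array([0, 0]), PerturbationConfig(epsilon=0.0))
        assert np.all(eta == 0.0)

    def test_fgsm_elements_in_sign_set(self, linear_stub_factory):
        rng = np.random.default_rng(0)
        stub = linear_stub_factory(rng.standard_normal((5, 4, 22, 22)))
        X = rng.standard_normal((3, 5, 4, 22, 22))
        eta = gen_perturbation(stub, X, np.array([0, 1, 0]), PerturbationConfig(epsilon=0.3))
        assert set(np.round(np.unique(eta), 12)) <= {-0.3, 0.0, 0.3}

    def test_fgsm_increases_loss_on_linear_logistic_victim(self, linear_stub_factory):
        rng = np.random.default_rng(1)
        stub = linear_stub_factory(rng.standard_normal((5, 4, 22, 22)))
        X = 0.1 * rng.standard_normal((4, 5, 4, 22, 22))
        y = np.array([0, 1, 0, 1])
        eta = gen_perturbation(stub, X, y, PerturbationConfig(epsilon=0.3))
        assert (stub.loss(X + eta, y) > stub.loss(X, y)).all()

    @pytest.mark.parametrize("method", ["ifgsm", "mifgsm", "pgd"])
    def test_iterative_methods_respect_ball_and_raise_loss(self, method, linear_stub_factory):
        rng = np.random.default_rng(2)
        stub = linear_stub_factory(rng.standard_normal((5, 4, 22, 22)))
        X = 0.1 * rng.standard_normal((2, 5, 4, 22, 22))
        y = np.array([0, 1])
        eta = gen_perturbation(stub, X, y, PerturbationConfig(epsilon=0.2, method=method, iterations=5))
        assert np.abs(eta).max() <= 0.2 + 1e-12
        assert (stub.loss(X + eta, y) > stub.loss(X, y)).all()

    def test_unknown_method_and_bad_epsilon_rejected(self):
        with pytest.raises(KeyError, match="cw"):
            gen_perturbation(None, np.zeros(1), np.zeros(1), PerturbationConfig(epsilon=0.1, method="cw"))
        with pytest.raises(ValueError, match="epsilon"):
            PerturbationConfig(epsilon=-0.1)


class TestImposeOnFrequency:
    def test_hand_derived_single_bin_values(self):
        """F = 3+4i with eta = +/-1: shares 9/25 and 16/25 of the unit change."""
        up = ba.impose_on_frequency(np.array([3.0 + 4.0j]), np.array(1.0))
        np.testing.assert_allclose([up.real[0], up.imag[0]], [3.36, 4.64], atol=1e-12)
        down = ba.impose_on_frequency(np.array([3.0 + 4.0j]), np.array(-1.0))
        np.testing.assert_allclose([down.real[0], down.imag[0]], [2.64, 3.36], atol=1e-12)

    def test_zero_eta_is_exact_identity(self):
        rng = np.random.default_rng(3)
        F = rng.standard_normal((5, 4, 22, 16)) + 1j * rng.standard_normal((5, 4, 22, 16))
        D = ba.impose_on_frequency(F, np.zeros((5, 4, 22)))
        np.testing.assert_array_equal(D, F)

    def test_zero_bins_left_unchanged(self):
        F = np.array([0.0 + 0.0j, 1.0 + 0.0j])
        D = ba.impose_on_frequency(F, np.array(2.0))
        assert D[0] == 0.0 + 0.0j
        assert D[1].real > 1.0

    def test_negative_eta_clamps_magnitudes_at_zero(self):
        D = ba.impose_on_frequency(np.array([0.1 + 0.0j]), np.array(-5.0))
        assert D[0] == 0.0 + 0.0j

    def test_preserves_conjugate_symmetry(self):
        x = np.random.default_rng(4).standard_normal(64)
        F = np.fft.fft(x)
        D = ba.impose_on_frequency(F[None, :], np.array([0.7]))[0]
        np.testing.assert_allclose(D[1:], np.conj(D[1:][::-1]), atol=1e-12)


class TestReconstructEEG:
    def test_unperturbed_round_trip_is_identity(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((5, 22, 256))
        dec = ba.decompose_sample(x)
        back = ba.reconstruct_eeg(x, dec.freq)
        assert np.abs(back - x).max() < 1e-6

    def test_output_shape_and_realness(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((5, 22, 256))
        dec = ba.decompose_sample(x)
        D = ba.impose_on_frequency(dec.freq, rng.normal(0, 0.3, (5, 4, 22)))
        adv = ba.reconstruct_eeg(x, D)
        assert adv.shape == (5, 22, 256)
        assert np.isrealobj(adv)

    def test_non_symmetric_spectrum_rejected(self):
        x = np.random.default_rng(7).standard_normal((1, 2, 256))
        D = np.zeros((1, 4, 2, 256), complex)
        D[..., 3] = 1j  # breaks conjugate symmetry -> complex rhythm
        with pytest.raises(ValueError, match="imaginary"):
            ba.reconstruct_eeg(x, D)


class TestGPBEAMPipeline:
    def test_zero_epsilon_returns_input_and_flags_clean_misclassification(
        self, tiny_beam_victim, montage, grid
    ):
        clf, beams, X, y = tiny_beam_victim
        atk = ba.GPBEAMAttack(clf, montage, grid, PerturbationConfig(epsilon=0.0))
        res = atk.attack(X[0], int(y[0]))
        assert np.abs(res.adversarial_eeg - X[0]).max() < 1e-6
        clean_pred = int(clf.predict(beams[:1])[0])
        assert res.success == (clean_pred != y[0])

    def test_fgsm_eta_beam_rmse_equals_epsilon(self, tiny_beam_victim, montage, grid):
        clf, _, X, y = tiny_beam_victim
        atk = ba.GPBEAMAttack(clf, montage, grid, PerturbationConfig(epsilon=0.25))
        res = atk.attack(X[1], int(y[1]))
        if np.all(res.eta_beam != 0.0):  # no zero-gradient elements
            assert abs(res.dl_b - 0.25) < 1e-9
        else:
            assert res.dl_b <= 0.25

    def test_requires_beam_victim(self, montage, grid):
        clf = ba.VictimClassifier(input_kind="eeg")
        with pytest.raises(ValueError, match="beam"):
            ba.GPBEAMAttack(clf, montage, grid)


class TestDEMechanics:
    def test_init_population_ranges_and_determinism(self):
        cfg = ba.DEConfig(NP=50, N=4, epsilon=0.3, overflow=False, seed=9)
        pop = init_population(cfg, T=5, B=4, C=22)
        assert pop.shape == (50, 4, 6)
        assert pop[..., 0].min() >= 0 and pop[..., 0].max() <= 4
        assert pop[..., 1].min() >= 0 and pop[..., 1].max() <= 21
        vmax = cfg.v_max(22)
        assert vmax == 30
        assert np.abs(pop[..., 2:]).max() <= vmax
        np.testing.assert_array_equal(pop, init_population(cfg, T=5, B=4, C=22))

    def test_overflow_widens_value_range_by_c(self):
        on = ba.DEConfig(epsilon=0.3, overflow=True)
        off = ba.DEConfig(epsilon=0.3, overflow=False)
        assert on.v_max(22) == 22 * off.v_max(22)

    def test_individual_to_eta(self):
        cfg = ba.DEConfig(N=1, r=100.0, epsilon=0.3, overflow=False)
        gene = np.array([[2, 5, 10, -10, 0, 10]])
        eta = individual_to_eta(gene, cfg, T=5, B=4, C=22)
        assert np.count_nonzero(eta) == 3
        np.testing.assert_allclose(eta[2, :, 5], [0.1, -0.1, 0.0, 0.1])
        # zero genes -> zero array; duplicate (t, c): last wins
        assert np.all(individual_to_eta(np.empty((0, 6)), cfg) == 0.0)
        dup = np.array([[2, 5, 10, 10, 10, 10], [2, 5, -20, -20, -20, -20]])
        np.testing.assert_allclose(individual_to_eta(dup, cfg)[2, :, 5], -0.2)

    def test_apply_overflow_hand_derived(self):
        eta = np.array([0.18, 0.0, 0.0, 0.0]).reshape(1, 1, 4)
        signs = np.array([1.0, 1.0, -1.0, 1.0]).reshape(1, 1, 4)
        out = apply_overflow(eta, signs, epsilon=0.1, C=4)
        np.testing.assert_allclose(out.ravel(), [0.1, 0.02, -0.02, 0.02], atol=1e-15)

    def test_apply_overflow_identity_without_excess_and_bounded(self):
        rng = np.random.default_rng(10)
        eta = rng.uniform(-0.1, 0.1, (5, 4, 22))
        signs = np.sign(rng.standard_normal((5, 4, 22)))
        np.testing.assert_array_equal(apply_overflow(eta, signs, 0.1, 22), eta)
        big = rng.uniform(-2.2, 2.2, (5, 4, 22))
        assert np.abs(apply_overflow(big, signs, 0.1, 22)).max() <= 0.1 + 1e-15

    def test_fitness_formula_and_range(self, linear_stub_factory, montage, grid):
        cfg = ba.DEConfig(NP=6, N=2, epsilon=0.3, overflow=False, seed=0)
        stub = linear_stub_factory(np.zeros((5, 4, 22, 22)))  # always (0.5, 0.5)
        P = np.random.default_rng(11).uniform(0.5, 2.0, (5, 4, 22))
        pop = init_population(cfg, 5, 4, 22)
        fit, pred = fitness_population(pop, stub, P, montage, grid, cfg)
        np.testing.assert_allclose(fit, 0.5, atol=1e-12)  # 1 - max(0.5, 0.5)
        assert ((fit >= 0) & (fit <= 1)).all()

    def test_evolution_monotone_and_cr_zero_noop(self, linear_stub_factory, montage, grid):
        rng = np.random.default_rng(12)
        stub = linear_stub_factory(rng.standard_normal((5, 4, 22, 22)))
        P = rng.uniform(0.5, 2.0, (5, 4, 22))
        cfg = ba.DEConfig(NP=8, N=2, epsilon=0.3, overflow=False, seed=1)

        def fit_fn(pop):
            return fitness_population(pop, stub, P, montage, grid, cfg)

        pop = init_population(cfg, 5, 4, 22, rng)
        fit, _ = fit_fn(pop)
        low, high = np.array([0, 0, -30, -30, -30, -30]), np.array([4, 21, 30, 30, 30, 30])
        for _ in range(5):
            prev = fit.copy()
            pop, fit, _ = evolve_step(pop, fit, fit_fn, cfg, 5, 4, 22, rng)
            assert (fit >= prev - 1e-15).all()  # greedy selection never loses fitness
            assert pop.dtype.kind == "i"
            assert ((pop >= low) & (pop <= high)).all()

        frozen = ba.DEConfig(NP=8, N=2, epsilon=0.3, overflow=False, CR=0.0, seed=2)
        pop2 = init_population(frozen, 5, 4, 22)
        fit2, _ = fit_fn(pop2)
        new_pop, _, _ = evolve_step(pop2, fit2, fit_fn, frozen, 5, 4, 22, np.random.default_rng(3))
        np.testing.assert_array_equal(new_pop, pop2)

    def test_small_population_rejected(self, linear_stub_factory, montage, grid):
        cfg = ba.DEConfig(NP=3, N=1, epsilon=0.3, overflow=False)
        pop = init_population(cfg, 5, 4, 22)
        with pytest.raises(ValueError, match=">= 4"):
            evolve_step(pop, np.zeros(3), lambda p: (np.zeros(len(p)), np.zeros(len(p))),
                        cfg, 5, 4, 22, np.random.default_rng(0))

    def test_config_validation(self):
        with pytest.raises(ValueError, match="F must"):
            ba.DEConfig(F=2.5)
        with pytest.raises(ValueError, match="CR"):
            ba.DEConfig(CR=1.5)
        with pytest.raises(ValueError, match="non-degenerate"):
            ba.DEConfig(epsilon=0.001, r=100.0)


class TestDEAttackEndToEnd:
    def test_misclassified_clean_sample_succeeds_at_generation_zero(
        self, linear_stub_factory, montage, grid
    ):
        rng = np.random.default_rng(13)
        x = rng.standard_normal((5, 22, 256))
        stub = linear_stub_factory(np.zeros((5, 4, 22, 22)) + 1e-6)  # predicts class 1
        cfg = ba.DEConfig(NP=6, N=2, epsilon=0.3, max_generations=3, seed=0)
        res = ba.attack_gpbeam_de(stub, x, y_true=0, config=cfg, montage=montage, grid=grid)
        assert res.success and res.generations == 0
        assert np.all(res.eta_p == 0.0)
        assert np.abs(res.adversarial_eeg - x).max() < 1e-6

    def test_generation_budget_respected_and_deterministic(self, linear_stub_factory, montage, grid):
        rng = np.random.default_rng(14)
        w = rng.standard_normal((5, 4, 22, 22))
        x = rng.standard_normal((5, 22, 256))
        stub = linear_stub_factory(w)
        y_true = int(stub.predict(ba.build_beams(ba.decompose_sample(x).powers, montage, grid)[None])[0])
        cfg = ba.DEConfig(NP=8, N=2, epsilon=0.2, max_generations=4, seed=21)
        res1 = ba.attack_gpbeam_de(stub, x, y_true, cfg, montage, grid)
        res2 = ba.attack_gpbeam_de(stub, x, y_true, cfg, montage, grid)
        assert res1.generations <= 4
        np.testing.assert_array_equal(res1.eta_p, res2.eta_p)
        assert np.abs(res1.eta_p).max() <= 0.2 + 1e-12  # overflow keeps the ball


class TestModifiedAttack:
    def test_eps_e_zero_matches_plain_gpbeam(self, tiny_beam_victim, montage, grid):
        clf, _, X, y = tiny_beam_victim
        eeg_clf = _quick_eeg_victim(X, y)
        plain = ba.GPBEAMAttack(clf, montage, grid, PerturbationConfig(epsilon=0.2)).attack(X[0], int(y[0]))
        mod = ba.attack_modified(clf, eeg_clf, X[0], int(y[0]), eps_b=0.2, eps_e=0.0,
                                 montage=montage, grid=grid)
        np.testing.assert_allclose(mod.adversarial_eeg, plain.adversarial_eeg, atol=1e-6)

    def test_eps_b_zero_matches_pure_eeg_fgsm(self, tiny_beam_victim, montage, grid):
        clf, _, X, y = tiny_beam_victim
        eeg_clf = _quick_eeg_victim(X, y)
        mod = ba.attack_modified(clf, eeg_clf, X[0], int(y[0]), eps_b=0.0, eps_e=0.05,
                                 montage=montage, grid=grid)
        e_adv = X[0] + 0.05 * np.sign(eeg_clf.loss_gradient(X[:1], y[:1])[0])
        np.testing.assert_allclose(mod.adversarial_eeg, e_adv, atol=1e-6)

    def test_model_kind_mismatch_rejected(self, tiny_beam_victim, montage, grid):
        clf, _, X, y = tiny_beam_victim
        with pytest.raises(ValueError, match="eeg-input"):
            ba.attack_modified(clf, clf, X[0], int(y[0]), 0.1, 0.1, montage=montage, grid=grid)


_EEG_CACHE = {}


def _quick_eeg_victim(X, y):
    if "clf" not in _EEG_CACHE:
        clf = ba.VictimClassifier(architecture="maxpool", input_kind="eeg",
                                  epochs=1, seed=0, fc_width=32, validation_fraction=0.0)
        clf.fit(X[:12], y[:12])
        _EEG_CACHE["clf"] = clf
    return _EEG_CACHE["clf"]
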