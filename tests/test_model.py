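import numpy as np
import pytest

from fourfold.model import (
    FitConfig,
    SfsMixtureModel,
    _profile_alpha,
    fit_model,
    fit_model_alpha,
    joint_negloglik,
    multinomial_loglik,
    simulate_spectrum,
)
from fourfold.sfs import (
    ModelParams,
    SelectionCategory,
    SelectionMixture,
    mixture_spectrum,
)
from fourfold.spectra import ObservedSpectrum

THETA = 0.0132
N = 130
MP = ModelParams(THETA, N)
STRONG = SelectionMixture.three_class(0.0, 0.226, -1.0, -283.0)
NEUTRAL = SelectionMixture.neutral()

FAST = FitConfig(restarts=4, seed=0)


def spec(counts, n=4):
    return ObservedSpectrum(n=n, counts=np.array(counts, dtype=np.int64))


class TestMultinomialLoglik:
    def test_three_class_hand_value(self):
        ll = multinomial_loglik(spec([8, 1, 1]), np.array([0.8, 0.1, 0.1]))
        assert ll == pytest.approx(8 * np.log(0.8) + 2 * np.log(0.1))
        assert ll == pytest.approx(-6.39, abs=5e-3)

    def test_label_permutation_invariance(self):
        k = np.array([5, 2, 3])
        g = np.array([0.5, 0.2, 0.3])
        perm = [2, 0, 1]
        assert multinomial_loglik(spec(k), g) == multinomial_loglik(
            spec(k[perm]), g[perm]
        )

    def test_zero_probability_with_counts_is_minus_inf(self):
        assert multinomial_loglik(spec([5, 2, 3]), np.array([0.8, 0.0, 0.2])) == -np.inf

    def test_empirical_frequencies_maximise_over_expectations(self):
        # entropy argument: for fixed counts k the loglik is maximal at
        # g = k/L; any perturbation of g (renormalised) decreases it
        k = np.array([900, 60, 40])
        g = k / k.sum()
        base = multinomial_loglik(spec(k), g)
        rng = np.random.default_rng(1)
        for _ in range(20):
            gg = g * (1 + 0.1 * rng.normal(size=3))
            gg = np.abs(gg) / np.abs(gg).sum()
            assert multinomial_loglik(spec(k), gg) < base

    def test_counts_linearity(self):
        g1 = np.array([0.9, 0.06, 0.04])
        g2 = np.array([0.85, 0.1, 0.05])
        k = np.array([880, 70, 50])
        d1 = multinomial_loglik(spec(k), g1) - multinomial_loglik(spec(k), g2)
        d2 = multinomial_loglik(spec(2 * k), g1) - multinomial_loglik(spec(2 * k), g2)
        assert d2 == pytest.approx(2 * d1, rel=1e-12)


class TestJointNegLoglik:
    def test_alpha_of_ones_is_bitwise_identical(self):
        test = simulate_spectrum(MP, STRONG, None, 100_000, seed=3)
        ref = simulate_spectrum(MP, NEUTRAL, None, 100_000, seed=4)
        base = joint_negloglik(MP, STRONG, None, test, ref)
        ones = joint_negloglik(MP, STRONG, np.ones(N // 2 + 1), test, ref)
        assert base == ones

    def test_invalid_model_point_returns_inf(self):
        test = simulate_spectrum(MP, NEUTRAL, None, 1000, seed=0)
        bad = ModelParams(0.5, N)  # segregating mass > 1
        assert joint_negloglik(bad, NEUTRAL, None, test, test) == np.inf

    def test_doubling_counts_doubles_likelihood_differences(self):
        test = simulate_spectrum(MP, STRONG, None, 50_000, noise="none")
        ref = simulate_spectrum(MP, NEUTRAL, None, 50_000, noise="none")
        test2 = ObservedSpectrum(n=N, counts=2 * test.counts)
        ref2 = ObservedSpectrum(n=N, counts=2 * ref.counts)
        p1 = ModelParams(0.0132, N)
        p2 = ModelParams(0.0150, N)
        d1 = joint_negloglik(p2, NEUTRAL, None, test, ref) - joint_negloglik(
            p1, NEUTRAL, None, test, ref
        )
        d2 = joint_negloglik(p2, NEUTRAL, None, test2, ref2) - joint_negloglik(
            p1, NEUTRAL, None, test2, ref2
        )
        assert d2 == pytest.approx(2 * d1, rel=1e-9)


class TestSimulateSpectrum:
    def test_deterministic_counts_track_neutral_shape(self):
        s = simulate_spectrum(MP, NEUTRAL, None, 10**6, noise="none")
        expected = mixture_spectrum(MP, NEUTRAL).proportions * 10**6
        # polymorphic classes are rounded; the zero class absorbs the residual
        assert np.max(np.abs(s.counts[1:] - expected[1:])) <= 0.5
        assert s.counts[0] == 10**6 - s.counts[1:].sum()
        assert s.L == 10**6

    def test_multinomial_frequencies_within_4_se(self):
        L = 10**6
        s = simulate_spectrum(MP, STRONG, None, L, seed=11)
        p = mixture_spectrum(MP, STRONG).proportions
        se = np.sqrt(p * (1 - p) / L)
        ok = np.abs(s.counts / L - p) <= 4 * se + 1e-12
        assert ok.all()

    def test_mutation_deficit_class_only_adds_monomorphics(self):
        mix = SelectionMixture(
            (
                SelectionCategory("neutral", 0.0, 0.0),
                SelectionCategory("mutation_deficit", 1.0, 0.0),
            )
        )
        s = simulate_spectrum(MP, mix, None, 1000, seed=1)
        assert s.counts[0] == 1000 and s.m == 0

    def test_seed_reproducibility(self):
        a = simulate_spectrum(MP, STRONG, None, 10000, seed=42)
        b = simulate_spectrum(MP, STRONG, None, 10000, seed=42)
        assert (a.counts == b.counts).all()


class TestFit:
    def test_noiseless_self_consistency(self):
        truth = SelectionMixture.three_class(0.0, 0.2, -1.0, -300.0)
        mp = ModelParams(0.01, N)
        test = simulate_spectrum(mp, truth, None, 860_000, noise="none")
        ref = simulate_spectrum(mp, NEUTRAL, None, 860_000, noise="none")
        res = SfsMixtureModel(test, ref, FAST).fit()
        assert res.converged
        assert abs(res.f_strong - 0.2) < 0.005
        assert abs(res.gamma_strong + 300) / 300 < 0.05
        assert res.theta == pytest.approx(0.01, rel=0.01)

    def test_identical_neutral_spectra_find_no_selection(self):
        both = simulate_spectrum(MP, NEUTRAL, None, 400_000, noise="none")
        res = SfsMixtureModel(both, both, FAST).fit()
        assert res.missing_polymorphism < 0.005
        assert res.f_weak < 0.005

    def test_mismatched_depths_rejected(self):
        a = simulate_spectrum(MP, NEUTRAL, None, 1000, seed=0)
        b = simulate_spectrum(ModelParams(THETA, 60), NEUTRAL, None, 1000, seed=0)
        with pytest.raises(ValueError, match="depth"):
            SfsMixtureModel(a, b)

    def test_fit_is_deterministic(self):
        test = simulate_spectrum(MP, STRONG, None, 200_000, seed=5)
        ref = simulate_spectrum(MP, NEUTRAL, None, 200_000, seed=6)
        r1 = SfsMixtureModel(test, ref, FAST).fit()
        r2 = SfsMixtureModel(test, ref, FAST).fit()
        assert r1.theta == r2.theta and r1.gamma_strong == r2.gamma_strong
        assert r1.loglik == r2.loglik

    def test_summary_and_serialisation(self):
        test = simulate_spectrum(MP, STRONG, None, 100_000, seed=5)
        ref = simulate_spectrum(MP, NEUTRAL, None, 100_000, seed=6)
        res = SfsMixtureModel(test, ref, FitConfig(restarts=2)).fit()
        text = res.summary()
        assert "theta" in text and "gamma_strong" in text
        assert "missing_polymorphism" in res.to_text()
        p_t, p_r = res.expected_spectra()
        assert p_t.sum() == pytest.approx(1.0) and p_r.sum() == pytest.approx(1.0)


class TestAlphaModel:
    def test_profile_alpha_increases_joint_likelihood(self):
        test = simulate_spectrum(MP, STRONG, None, 300_000, seed=21)
        ref = simulate_spectrum(MP, NEUTRAL, None, 300_000, seed=22)
        model = SfsMixtureModel(test, ref)
        z = model._pack(THETA, 0.0, 0.226, -1.0, -283.0)
        nll_plain, _ = model._objective(z, profile_alpha=False)
        nll_alpha, alpha = model._objective(z, profile_alpha=True)
        assert alpha[0] == 1.0
        assert nll_alpha <= nll_plain

    def test_profile_alpha_fixed_point_is_stationary(self):
        rng = np.random.default_rng(0)
        p_t = rng.dirichlet(np.ones(6))
        p_r = rng.dirichlet(np.ones(6))
        k_t = rng.multinomial(5000, p_t)
        k_r = rng.multinomial(5000, p_r)
        alpha = _profile_alpha(p_t, p_r, k_t, k_r)
        # numerical gradient of the profiled objective wrt each free alpha
        def obj(a):
            wt, wr = a * p_t, a * p_r
            return k_t @ np.log(wt / wt.sum()) + k_r @ np.log(wr / wr.sum())

        base = obj(alpha)
        for x in range(1, 6):
            for eps in (1e-5, -1e-5):
                a = alpha.copy()
                a[x] *= 1 + eps
                assert obj(a) <= base + 1e-7

    def test_neutral_data_with_shared_distortion_yields_no_selection(self):
        half = N // 2
        distort = np.ones(half + 1)
        distort[1:] = 1.0 + 0.8 * np.linspace(1, 0, half) ** 2
        test = simulate_spectrum(MP, NEUTRAL, distort, 400_000, seed=31)
        ref = simulate_spectrum(MP, NEUTRAL, distort, 400_000, seed=32)
        res = SfsMixtureModel(test, ref, FitConfig(restarts=4, use_alpha=True)).fit()
        assert res.missing_polymorphism < 0.01
        assert res.alpha is not None and res.alpha[0] == 1.0

    def test_alpha_never_decreases_maximised_loglik(self):
        test = simulate_spectrum(MP, STRONG, None, 200_000, seed=41)
        ref = simulate_spectrum(MP, NEUTRAL, None, 200_000, seed=42)
        base = fit_model(test, ref, FAST)
        withalpha = fit_model_alpha(test, ref, FAST)
        assert withalpha.loglik >= base.loglik - 1e-6
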