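"""Menzerath-Altmann law: clouds, fits, mechanism, speech velocity."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

import speechlaws as sl
from speechlaws.menzerath import MALMechanism, MALPoints, mal_curve

from conftest import make_tokens

# printed BG/word time-units parameters used as a worked example throughout
A, B, C = 0.364, -0.227, -6.7e-3


def _points(n, y):
    return MALPoints(
        points=pd.DataFrame({"n": np.asarray(n, float), "y": np.asarray(y, float)}),
        construct="bg", constituent="word", measure="duration",
    )


class TestMALPoints:
    def test_bg_point_is_mean_word_duration(self):
        rows = [
            ("s0", "word", "a", 0.0, 0.2, 0, 0),
            ("s0", "word", "b", 0.2, 0.4, 1, 0),
        ]
        corpus = sl.SegmentedCorpus(make_tokens(rows))
        pts = sl.mal_points(corpus, "bg", "word", "duration")
        assert pts.n.tolist() == [2]
        assert pts.y.tolist() == [pytest.approx(0.3)]

    def test_all_single_word_bgs(self):
        rows = [
            ("s0", "word", f"w{i}", 0.4 * i, 0.2, i, i) for i in range(6)
        ]
        corpus = sl.SegmentedCorpus(make_tokens(rows))
        pts = sl.mal_points(corpus, "bg", "word", "duration")
        assert np.all(pts.n == 1)

    def test_word_phoneme_cloud(self, small_corpus):
        corpus, _ = small_corpus
        pts = sl.mal_points(corpus, "word", "phoneme", "duration")
        assert len(pts) == len(corpus.words)
        assert (pts.y > 0).all()


class TestFitMAL:
    def test_noiseless_recovery_to_four_digits(self):
        n = np.arange(1, 81)
        fit = sl.fit_mal(_points(n, mal_curve(n, A, B, C)))
        assert fit.a == pytest.approx(A, abs=1e-4)
        assert fit.b == pytest.approx(B, abs=1e-4)
        assert fit.c == pytest.approx(C, abs=1e-5)
        assert fit.n_star == pytest.approx(B / C, rel=1e-3)

    def test_constant_cloud_degenerates_to_order_zero(self):
        n = np.arange(1, 41)
        fit = sl.fit_mal(_points(n, np.full(40, 0.25)))
        assert fit.b == pytest.approx(0.0, abs=1e-6)
        assert fit.c == pytest.approx(0.0, abs=1e-6)
        assert fit.r2_means == pytest.approx(0.0, abs=1e-6)

    def test_mechanism_corpus_recovers_kappa_mapping(self):
        """Noisy samples around the exact-variant curve give back
        b ~ kappa2 - 1 and c ~ -ln kappa1."""
        mech = MALMechanism(1.007, 0.77, 0.36, "exact")
        rng = np.random.default_rng(1)
        n = np.repeat(np.arange(1, 61), 30)
        y = sl.closed_form(mech, n) * np.exp(rng.normal(0, 0.15, n.size))
        fit = sl.fit_mal(_points(n, y))
        assert fit.b == pytest.approx(0.77 - 1, abs=0.1)
        assert fit.c == pytest.approx(-np.log(1.007), abs=0.005)

    def test_too_few_sizes(self):
        with pytest.raises(ValueError):
            sl.fit_mal(_points([1, 2, 3], [0.3, 0.25, 0.2]))

    def test_two_regimes_of_the_fitted_curve(self):
        """With b, c < 0 the curve decreases up to n* = b/c and increases
        beyond: the classic reading and its inversion."""
        n = np.arange(1, 81)
        fit = sl.fit_mal(_points(n, mal_curve(n, A, B, C)))
        grid = np.linspace(1, 2 * fit.n_star, 500)
        y = fit.curve(grid)
        dy = np.diff(y)
        assert np.all(dy[grid[:-1] < fit.n_star - 1] < 0)
        assert np.all(dy[grid[:-1] > fit.n_star + 1] > 0)


class TestMechanism:
    def test_order0_constant_constituents(self):
        mech = MALMechanism(1.0, 0.5, 0.2, "order0")
        t, y = sl.mechanism_simulate(mech, 30)
        assert np.allclose(y, 0.2)
        assert np.allclose(t, 0.2 * np.arange(1, 31))

    def test_order1_approaches_restricted_mal(self):
        """y(n) / [t1 n^(k2-1) / Gamma(1+k2)] -> 1."""
        mech = MALMechanism(1.0, 0.7, 0.2, "order1")
        _, y = sl.mechanism_simulate(mech, 2000)
        n = 2000
        limit = 0.2 * n ** (0.7 - 1) / np.exp(gammaln(1.7))
        assert y[-1] / limit == pytest.approx(1.0, abs=0.001)

    def test_exact_variant_telescopes(self):
        mech = MALMechanism(1.0067, 0.773, 0.36, "exact")
        t, _ = sl.mechanism_simulate(mech, 80)
        n = np.arange(1, 81)
        assert np.allclose(t, 0.36 * 1.0067 ** (n - 1) * n**0.773, rtol=1e-12)

    def test_duration_grows_monotonically_when_kappa1_geq_one(self):
        mech = MALMechanism(1.0, 0.3, 0.15, "order2")
        t, _ = sl.mechanism_simulate(mech, 100)
        assert np.all(np.diff(t) > 0)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            MALMechanism(0.9, 0.5, 0.2, "order2")  # kappa1 < 1 unphysical
        with pytest.raises(ValueError):
            MALMechanism(1.0, 1.5, 0.2, "order1")
        with pytest.raises(ValueError):
            sl.mechanism_simulate(MALMechanism(1.0, 0.5, 0.2, "order1"), 1)


class TestClosedForm:
    def test_gamma_identity_against_brute_product(self):
        k2, n = 0.5, 50
        prod = np.prod([1 + k2 / (j - 1) for j in range(2, n + 1)])
        gamma_form = np.exp(gammaln(n + k2) - gammaln(1 + k2) - gammaln(n))
        assert abs(prod - gamma_form) / gamma_form < 1e-12

    def test_order1_closed_form_matches_recursion(self):
        mech = MALMechanism(1.0, 0.6, 0.25, "order1")
        _, y = sl.mechanism_simulate(mech, 100)
        assert np.allclose(y, sl.closed_form(mech, np.arange(1, 101)), rtol=1e-10)

    def test_order2_asymptotic_within_one_percent(self):
        mech = MALMechanism(1.01, 0.8, 0.2, "order2")
        _, y = sl.mechanism_simulate(mech, 100)
        approx = sl.closed_form(mech, np.array([100.0]))[0]
        assert abs(approx - y[-1]) / y[-1] < 0.01

    def test_unit_kappas_reduce_to_constant(self):
        mech = MALMechanism(1.0, 1.0, 0.2, "exact")
        assert np.allclose(sl.closed_form(mech, np.arange(1, 50)), 0.2)


class TestMechanismToMAL:
    def test_kappa1_one_gives_zero_c(self):
        a, b, c = sl.mechanism_to_mal(MALMechanism(1.0, 0.6, 0.2, "exact"))
        assert c == 0.0

    def test_inverts_printed_time_units_row(self):
        """kappa2 = 0.773, kappa1 = 1.0067 map back to (b, c) = (-0.227,
        -6.7e-3), the printed BG/word time-units exponents."""
        _, b, c = sl.mechanism_to_mal(MALMechanism(1.0067, 0.773, 0.36, "exact"))
        assert b == pytest.approx(-0.227, abs=1e-12)
        assert c == pytest.approx(-6.7e-3, abs=1e-4)

    def test_mapping_reproduces_simulation(self):
        mech = MALMechanism(1.005, 0.8, 0.3, "exact")
        a, b, c = sl.mechanism_to_mal(mech)
        n = np.arange(1, 81)
        _, y = sl.mechanism_simulate(mech, 80)
        assert np.allclose(y, mal_curve(n, a, b, c), rtol=1e-12)

    def test_closed_loop_mechanism_fit_identity(self):
        """mechanism -> curve -> MAL fit returns the mapped (a, b, c)."""
        mech = MALMechanism(1.0067, 0.773, 0.36, "exact")
        a, b, c = sl.mechanism_to_mal(mech)
        n = np.arange(1, 81)
        _, y = sl.mechanism_simulate(mech, 80)
        fit = sl.fit_mal(_points(n, y))
        assert fit.a == pytest.approx(a, rel=0.05)
        assert fit.b == pytest.approx(b, rel=0.05)
        assert fit.c == pytest.approx(c, rel=0.05)


class TestSpeechVelocity:
    def _fit(self):
        n = np.arange(1, 81)
        return sl.fit_mal(_points(n, mal_curve(n, A, B, C)))

    def test_optimum_near_34_words(self):
        vel = sl.speech_velocity(self._fit())
        assert vel.n_star == pytest.approx(33.9, abs=0.5)

    def test_max_velocity_near_printed_value(self):
        vel = sl.speech_velocity(self._fit())
        assert vel.v_max == pytest.approx(4.8, rel=0.02)

    def test_typical_bg_is_slower_than_optimum(self):
        """At the typical six-word BG the speaker is below the optimal
        efficiency limit (about 4 words per second)."""
        vel = sl.speech_velocity(self._fit())
        v6 = vel.v_at(6)
        assert v6 < vel.v_max
        assert v6 == pytest.approx(4.0, abs=0.1)

    def test_monotone_velocity_reported_without_optimum(self):
        from speechlaws.menzerath import MALFit

        fit = MALFit(a=0.3, b=-0.2, c=0.0, r2_binned=1.0, r2_means=1.0,
                     n_star=None, v_max=None)
        vel = sl.speech_velocity(fit)
        assert not vel.has_optimum
        assert vel.v_max is None
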