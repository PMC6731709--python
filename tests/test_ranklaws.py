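"""Zipf/Yule rank laws, Herdan growth, size-rank law."""

import numpy as np
import pandas as pd
import pytest

import speechlaws as sl
from speechlaws.ranklaws import rank_table_from_counts
from speechlaws.synthetic import yule_pmf

from conftest import make_tokens


class TestRankFrequency:
    def test_basic_counts(self):
        rt = sl.rank_frequency(["a", "b", "a"])
        assert rt.table["label"].tolist() == ["a", "b"]
        assert rt.table["frequency"].tolist() == [2, 1]

    def test_all_distinct_stable_first_occurrence_order(self):
        rt = sl.rank_frequency(["z", "m", "a"])
        assert rt.table["label"].tolist() == ["z", "m", "a"]
        assert (rt.frequencies == 1).all()

    def test_invariant_under_count_preserving_relabeling(self):
        toks = ["a", "b", "a", "c", "b", "a"]
        swapped = [{"a": "x", "b": "y", "c": "z"}[t] for t in toks]
        f1 = sl.rank_frequency(toks).frequencies
        f2 = sl.rank_frequency(swapped).frequencies
        assert np.array_equal(f1, f2)

    def test_frequencies_nonincreasing_and_sum_to_n(self, small_corpus):
        corpus, _ = small_corpus
        rt = sl.rank_frequency(corpus.words["label"])
        assert np.all(np.diff(rt.frequencies) <= 0)
        assert rt.frequencies.sum() == rt.n_tokens == len(corpus.words)

    def test_empirical_frequencies_track_generating_pmf(self):
        pmf = sl.double_zipf_pmf(200, 0.63, 1.41, 20)
        toks = sl.sample_zipf_double(200, 0.63, 1.41, 20, 50_000, seed=1)
        counts = np.bincount(toks, minlength=201)[1:]
        # multinomial CI per head rank (sorting leaves the head intact)
        for r in range(10):
            se = np.sqrt(50_000 * pmf[r] * (1 - pmf[r]))
            assert abs(counts[r] - 50_000 * pmf[r]) < 4 * se


class TestFitZipf:
    def test_double_law_recovery(self):
        toks = sl.sample_zipf_double(3000, 0.63, 1.41, 49, 100_000, seed=2)
        rt = sl.rank_frequency([f"w{t}" for t in toks])
        fit = sl.fit_zipf(rt)
        assert fit.model == "double"
        assert fit.alpha1 == pytest.approx(0.63, abs=0.05)
        assert fit.alpha2 == pytest.approx(1.41, abs=0.1)
        assert abs(fit.r_star - 49) <= 8

    def test_single_law_exponent_recovered_breakpoint_degenerates(self):
        """On single-exponent data the single-model alpha is recovered and
        the two-segment fit collapses to an extreme-tail artifact: the
        breakpoint lands in the last fifth of ranks and the head exponent
        equals the single fit."""
        p = np.arange(1, 1001.0) ** -1.0
        counts = np.random.default_rng(3).multinomial(100_000, p / p.sum())
        fit = sl.fit_zipf(rank_table_from_counts(counts))
        assert fit.alpha == pytest.approx(1.0, abs=0.02)
        assert fit.alpha1 == pytest.approx(fit.alpha, abs=0.02)
        n_types = (counts > 0).sum()
        assert fit.r_star > 0.8 * n_types

    def test_uniform_frequencies_give_zero_exponent(self):
        counts = np.full(100, 50)
        fit = sl.fit_zipf(rank_table_from_counts(counts))
        assert fit.alpha == pytest.approx(0.0, abs=0.02)

    def test_too_few_types(self):
        with pytest.raises(ValueError):
            sl.fit_zipf(rank_table_from_counts(np.arange(10, 0, -1)))


class TestFitYule:
    def test_power_law_boundary_matches_zipf(self):
        pmf = yule_pmf(100, 0.8, 1.0)
        counts = np.random.default_rng(4).multinomial(100_000, pmf)
        rt = rank_table_from_counts(counts)
        yf = sl.fit_yule(rt)
        zf = sl.fit_zipf(rt)
        assert yf.c > 0.999
        assert yf.b == pytest.approx(zf.alpha, abs=0.05)

    def test_pure_geometric_recovery(self):
        pmf = yule_pmf(64, 0.0, 0.9)
        counts = np.random.default_rng(5).multinomial(100_000, pmf)
        yf = sl.fit_yule(rank_table_from_counts(counts))
        assert yf.b == pytest.approx(0.0, abs=0.05)
        assert yf.c == pytest.approx(0.9, abs=0.005)

    def test_phoneme_like_recovery(self):
        pmf = yule_pmf(64, 0.25, 0.96)
        counts = np.random.default_rng(6).multinomial(200_000, pmf)
        yf = sl.fit_yule(rank_table_from_counts(counts))
        assert yf.b == pytest.approx(0.25, abs=0.1)
        assert yf.c == pytest.approx(0.96, abs=0.01)


class TestHerdan:
    def _corpus_from_labels(self, labels):
        rows = [
            ("s0", "word", lab, 0.2 * i, 0.2, i, 0)
            for i, lab in enumerate(labels)
        ]
        return sl.SegmentedCorpus(make_tokens(rows))

    def test_all_distinct_gives_unit_exponent(self):
        corpus = self._corpus_from_labels([f"w{i}" for i in range(400)])
        fit = sl.herdan_curves(corpus, "tokens", n_permutations=1, seed=0)
        assert fit.exponent == pytest.approx(1.0, abs=1e-9)

    def test_single_type_gives_zero_exponent(self):
        corpus = self._corpus_from_labels(["w"] * 400)
        fit = sl.herdan_curves(corpus, "tokens", n_permutations=1, seed=0)
        assert fit.exponent == pytest.approx(0.0, abs=1e-9)

    def test_token_and_time_exponents_coincide(self, big_corpus):
        """Elapsed time is proportional to token count (law of large
        numbers), so the growth exponent is axis-independent."""
        corpus, _ = big_corpus
        beta = sl.herdan_curves(corpus, "tokens", n_permutations=5, seed=1)
        gamma = sl.herdan_curves(corpus, "time", n_permutations=5, seed=1)
        assert beta.exponent == pytest.approx(gamma.exponent, abs=0.02)
        assert 0 < beta.exponent < 1  # sublinear growth

    def test_permutation_stability(self, small_corpus):
        corpus, _ = small_corpus
        fit = sl.herdan_curves(corpus, "tokens", n_permutations=6, seed=2)
        assert np.std(fit.exponents) < 0.03


class TestSizeRank:
    def test_theta_from_printed_exponents(self):
        """alpha1/lambda = 0.63/20 ~ 0.03 and alpha2/lambda = 1.41/20 ~ 0.07."""
        rt = rank_table_from_counts(np.arange(500, 0, -1))
        sizes = 0.03 * np.log(rt.ranks) + 0.1
        fit = sl.size_rank(rt, sizes, r_star=49, alpha1=0.63, alpha2=1.41, lam=20.0)
        assert fit.theta1 == pytest.approx(0.0315)
        assert fit.theta2 == pytest.approx(0.0705)

    def test_infinite_lambda_flattens_the_law(self):
        rt = rank_table_from_counts(np.arange(100, 0, -1))
        sizes = np.full(100, 0.2)
        fit = sl.size_rank(rt, sizes, r_star=10, alpha1=0.6, alpha2=1.4, lam=1e9)
        pred = fit.predict(rt.ranks)
        assert np.allclose(pred, pred[0], atol=1e-6)

    def test_piecewise_slopes_on_coupled_corpus(self, big_corpus):
        """Binned size vs log-rank bends at the Zipf breakpoint with the
        steeper slope alpha2/lambda in the tail."""
        corpus, _ = big_corpus
        rt = sl.rank_frequency(corpus.words["label"])
        zf = sl.fit_zipf(rt)
        table = sl.build_type_table(corpus, "word")
        bf = sl.fit_brevity(table, "duration", mode="continuous", f_min=5)
        sizes = (
            table.table.set_index("label")["median_duration_s"]
            .reindex(rt.table["label"])
            .to_numpy()
        )
        fit = sl.size_rank(rt, sizes, zf.r_star, zf.alpha1, zf.alpha2, bf.lambda_)
        binned = sl.bin_series(rt.ranks.astype(float), sizes, "log", 25)
        tail = binned.bin_centers > zf.r_star
        tail_slope = np.polyfit(
            np.log(binned.bin_centers[tail]), binned.bin_means[tail], 1
        )[0]
        assert tail_slope == pytest.approx(fit.theta2, rel=0.3)
        assert fit.theta1 < fit.theta2
        assert fit.rmse_binned < 0.3 * sizes.mean()
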