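"""Corpus model: alignment I/O, breath-group segmentation, summaries."""

import io

import numpy as np
import pandas as pd
import pytest

import speechlaws as sl
from speechlaws.corpus import (
    AlignmentFormatError,
    ValidationError,
    character_count,
    segment_breath_groups,
)

from conftest import make_tokens

HEADER = "speaker_id\tlevel\tlabel\tonset_s\tduration_s\tword_id\tbg_id\n"


def _read(body: str, **kw):
    return sl.read_alignment(io.StringIO(HEADER + body), **kw)


class TestReadAlignment:
    def test_minimal_word_with_two_phonemes(self):
        corpus = _read(
            "s0\tword\thi\t0.0\t0.11\t0\t\n"
            "s0\tphoneme\th\t0.0\t0.05\t0\t\n"
            "s0\tphoneme\tiy\t0.05\t0.05\t0\t\n"
        )
        assert len(corpus.words) == 1
        assert len(corpus.phonemes) == 2
        assert len(corpus.bg_table) == 1
        # phoneme durations (0.05 + 0.05) fit inside the 0.11 s word
        assert corpus.words["bg_id"].notna().all()

    def test_negative_duration_names_row(self):
        with pytest.raises(ValidationError, match=r"row 1"):
            _read(
                "s0\tword\thi\t0.0\t0.11\t0\t\n"
                "s0\tphoneme\th\t0.0\t-0.1\t0\t\n"
            )

    def test_missing_column_is_format_error(self):
        bad = "speaker_id\tlevel\tlabel\tonset_s\tduration_s\tword_id\n" \
              "s0\tword\thi\t0.0\t0.11\t0\n"
        with pytest.raises(AlignmentFormatError, match="bg_id"):
            sl.read_alignment(io.StringIO(bad))

    def test_orphan_phoneme_rejected(self):
        with pytest.raises(ValidationError, match="without word_id"):
            _read(
                "s0\tword\thi\t0.0\t0.11\t0\t\n"
                "s0\tphoneme\th\t0.0\t0.05\t\t\n"
            )

    def test_hierarchy_overflow_beyond_tolerance_rejected(self):
        body = (
            "s0\tword\thi\t0.0\t0.08\t0\t\n"
            "s0\tphoneme\th\t0.0\t0.05\t0\t\n"
            "s0\tphoneme\tiy\t0.05\t0.05\t0\t\n"
        )
        with pytest.raises(ValidationError, match="phoneme durations"):
            _read(body)
        # a generous tolerance admits the same file
        assert len(_read(body, tolerance=0.5).words) == 1

    def test_round_trip_is_identity(self, small_corpus):
        corpus, _ = small_corpus
        buf = io.StringIO()
        sl.write_alignment(corpus, buf)
        buf.seek(0)
        back = sl.read_alignment(buf)
        a = corpus.tokens.copy()
        b = back.tokens.copy()
        for col in ("onset_s", "duration_s"):  # 6-decimal wire format
            a[col] = a[col].round(6)
            b[col] = b[col].round(6)
        pd.testing.assert_frame_equal(a, b)


class TestBreathGroups:
    def test_pause_splits_runs(self):
        tokens = make_tokens(
            [
                ("s0", "word", "a", 0.0, 0.2, 0, None),
                ("s0", "word", "b", 0.2, 0.2, 1, None),
                ("s0", "pause", "SIL", 0.4, 0.5, None, None),
                ("s0", "word", "c", 0.9, 0.2, 2, None),
            ]
        )
        out = segment_breath_groups(tokens)
        sizes = out[out["level"] == "word"].groupby("bg_id").size()
        assert sorted(sizes.tolist()) == [1, 2]

    def test_no_pauses_single_bg(self):
        tokens = make_tokens(
            [("s0", "word", f"w{i}", 0.2 * i, 0.2, i, None) for i in range(5)]
        )
        out = segment_breath_groups(tokens)
        assert out[out["level"] == "word"]["bg_id"].nunique() == 1

    def test_empty_sequence(self):
        tokens = make_tokens([])
        assert len(segment_breath_groups(tokens)) == 0

    def test_partition_complete_and_idempotent(self, small_corpus):
        corpus, _ = small_corpus
        once = segment_breath_groups(corpus.tokens)
        words = once[once["level"] == "word"]
        assert words["bg_id"].notna().all()  # every word in exactly one BG
        twice = segment_breath_groups(once)
        # identical partition (ids may renumber, boundaries may not)
        b1 = words["bg_id"].to_numpy()
        b2 = twice[twice["level"] == "word"]["bg_id"].to_numpy()
        assert np.array_equal(b1[1:] != b1[:-1], b2[1:] != b2[:-1])

    def test_bg_sizes_match_generating_geometric(self, big_corpus):
        """Log-frequency of BG size is linear: the memoryless pause process."""
        corpus, truth = big_corpus
        q = truth.spec.pause_prob
        sizes = corpus.bg_table["n_words"].to_numpy()
        counts = np.bincount(sizes)[1:]
        n = np.arange(1, len(counts) + 1)
        keep = counts >= 10
        slope, _ = np.polyfit(n[keep], np.log(counts[keep]), 1)
        assert slope == pytest.approx(np.log(1 - q), abs=0.02)
        fitted = np.polyval(np.polyfit(n[keep], np.log(counts[keep]), 1), n[keep])
        resid = np.log(counts[keep]) - fitted
        r2 = 1 - resid.var() / np.log(counts[keep]).var()
        assert r2 > 0.98


class TestSummary:
    def test_constant_durations_degenerate_stats(self):
        tokens = make_tokens(
            [("s0", "word", f"w{i}", 0.2 * i, 0.2, i, 0) for i in range(20)]
        )
        with pytest.warns(UserWarning, match="absent"):
            s = sl.summarize(sl.SegmentedCorpus(tokens))
        st = s.durations["word"]
        assert st.mean == pytest.approx(0.2)
        assert st.median == pytest.approx(0.2)
        assert st.sd == pytest.approx(0.0, abs=1e-12)
        assert st.mode == pytest.approx(0.2, rel=0.05)

    def test_phonemes_per_word_ratio_from_means(self):
        # mean word 0.24 s over mean phoneme 0.08 s -> ratio 3
        rows = []
        for w in range(4):
            rows.append(("s0", "word", f"w{w}", 0.24 * w, 0.24, w, 0))
            for p in range(3):
                rows.append(
                    ("s0", "phoneme", "x", 0.24 * w + 0.08 * p, 0.08, w, 0)
                )
        s = sl.summarize(sl.SegmentedCorpus(make_tokens(rows)))
        assert s.phonemes_per_word_ratio == pytest.approx(3.0)

    def test_sample_mean_matches_lognormal_expectation(self, independent_corpus):
        corpus, truth = independent_corpus
        mu, sigma = truth.spec.phoneme_duration
        x = corpus.phonemes["duration_s"].to_numpy()
        expected = np.exp(mu + sigma**2 / 2)
        se = x.std() / np.sqrt(x.size)
        assert abs(x.mean() - expected) < 3 * se

    def test_percentiles_invariant_under_permutation(self, small_corpus):
        corpus, _ = small_corpus
        s1 = sl.summarize(corpus)
        shuffled = corpus.tokens.sample(frac=1, random_state=0)
        c2 = sl.SegmentedCorpus(shuffled, bg_table=corpus.bg_table, validate=False)
        s2 = sl.summarize(c2)
        for lvl in s1.durations:
            assert s1.durations[lvl].median == s2.durations[lvl].median
            assert s1.durations[lvl].p10 == s2.durations[lvl].p10
            assert s1.durations[lvl].p90 == s2.durations[lvl].p90

    def test_percentile_ordering(self, small_corpus):
        corpus, _ = small_corpus
        s = sl.summarize(corpus)
        for st in {**s.durations, **s.counts}.values():
            assert st.p10 <= st.median <= st.p90

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValidationError):
            sl.summarize(sl.SegmentedCorpus(make_tokens([])))


def test_character_count_strips_punctuation():
    assert character_count("don't") == 4
    assert character_count("Okay") == 4
    assert character_count("uh-huh") == 5
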