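"""Segmentation, the weighted edit metric, and the vector metric."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

import guessability as g
from guessability.errors import (
    ConfigError,
    UnknownSegmentError,
    ValidationError,
)

ORACLE_INVENTORY = ["p", "a", "s", "n", "i", "ts"]


def brute_force_distance(a, b, table):
    """Exhaustive recursive alignment search; independent of the DP."""
    def rec(i, j):
        if i == len(a) and j == len(b):
            return 0.0
        best = float("inf")
        if i < len(a):
            best = min(best, table.indel_cost(a[i]) + rec(i + 1, j))
        if j < len(b):
            best = min(best, table.indel_cost(b[j]) + rec(i, j + 1))
        if i < len(a) and j < len(b):
            best = min(best, table.substitution_cost(a[i], b[j]) + rec(i + 1, j + 1))
        return best
    return rec(0, 0)


class TestSegmentation:
    def test_single_symbol_segments(self, table):
        assert g.segment_ipa("dɛn", table).segments == ("d", "ɛ", "n")

    def test_longest_match_attaches_length_mark(self, table):
        assert g.segment_ipa("ɦoːkoː", table).segments == ("ɦ", "oː", "k", "oː")

    def test_affricate_is_one_segment(self, table):
        assert g.segment_ipa("tʃas", table).segments == ("tʃ", "a", "s")

    def test_empty_word_rejected(self, table):
        with pytest.raises(ValidationError):
            g.segment_ipa("", table)

    def test_unknown_symbol_named(self, table):
        with pytest.raises(UnknownSegmentError) as exc:
            g.segment_ipa("dqn", table)
        assert "q" in str(exc.value)


class TestEditDistance:
    @pytest.mark.parametrize("a,b,expected", [
        ("dɛn", "dɪn", 0.5),
        ("dɛn", "djɛna", 14.5),
        ("dɛn", "ɦɪ", 11.875),
        ("smjɛr", "ɦoːkoː", 23.5),
    ])
    def test_worked_values(self, table, a, b, expected):
        assert g.feature_edit_distance(a, b, table) == pytest.approx(expected)

    @pytest.mark.parametrize("word", ["dɛn", "smjɛr", "ɦoːkoː", "a"])
    def test_identity(self, table, word):
        assert g.feature_edit_distance(word, word, table) == 0.0

    def test_exhaustive_oracle_short_strings(self, table):
        """DP equals brute-force alignment search on all short string pairs."""
        strings = [
            list(t) for n in (1, 2)
            for t in itertools.product(ORACLE_INVENTORY, repeat=n)
        ]
        for a in strings:
            for b in strings:
                got = g.feature_edit_distance(
                    g.IpaString(tuple(a)), g.IpaString(tuple(b)), table)
                assert got == pytest.approx(brute_force_distance(a, b, table))

    @given(
        a=st.lists(st.sampled_from(ORACLE_INVENTORY), min_size=1, max_size=4),
        b=st.lists(st.sampled_from(ORACLE_INVENTORY), min_size=1, max_size=4),
    )
    def test_oracle_equivalence_random_strings(self, table, a, b):
        ia, ib = g.IpaString(tuple(a)), g.IpaString(tuple(b))
        assert g.feature_edit_distance(ia, ib, table) == pytest.approx(
            brute_force_distance(a, b, table))

    @given(
        a=st.lists(st.sampled_from(ORACLE_INVENTORY), min_size=1, max_size=4),
        b=st.lists(st.sampled_from(ORACLE_INVENTORY), min_size=1, max_size=4),
    )
    def test_symmetry_and_nonnegativity(self, table, a, b):
        ia, ib = g.IpaString(tuple(a)), g.IpaString(tuple(b))
        d1 = g.feature_edit_distance(ia, ib, table)
        d2 = g.feature_edit_distance(ib, ia, table)
        assert d1 == pytest.approx(d2)
        assert d1 >= 0.0


class TestVectorMetric:
    def test_worked_values(self, table):
        den = g.word_feature_vector("dɛn", table)
        assert g.vector_distance(den, g.word_feature_vector("djɛna", table)) \
            == pytest.approx(np.sqrt(37) / 15)
        assert g.vector_distance(den, g.word_feature_vector("ɦɪ", table)) \
            == pytest.approx(7 / 6)

    def test_vector_is_column_means(self, table):
        vec = g.word_feature_vector("dɛn", table)
        ind = np.array([
            [table.class_indicator(f, s) for f in vec.feature_set]
            for s in ("d", "ɛ", "n")
        ])
        assert np.allclose(vec.values, ind.mean(axis=0))

    def test_twelve_features(self, table):
        vec = g.word_feature_vector("dɛn", table)
        assert len(vec.values) == 12

    def test_identity_and_mismatched_sets(self, table):
        v = g.word_feature_vector("voda", table)
        assert g.vector_distance(v, v) == 0.0
        other = g.word_feature_vector("voda", table, feature_set=("nasal", "labial"))
        with pytest.raises(ConfigError):
            g.vector_distance(v, other)

    @given(
        x=st.lists(st.floats(0, 1), min_size=3, max_size=3),
        y=st.lists(st.floats(0, 1), min_size=3, max_size=3),
        z=st.lists(st.floats(0, 1), min_size=3, max_size=3),
    )
    def test_metric_axioms(self, x, y, z):
        fs = ("nasal", "labial", "sibilant")
        vx = g.TwelveFeatureVector(tuple(x), fs)
        vy = g.TwelveFeatureVector(tuple(y), fs)
        vz = g.TwelveFeatureVector(tuple(z), fs)
        dxy = g.vector_distance(vx, vy)
        assert dxy == pytest.approx(g.vector_distance(vy, vx))
        assert dxy >= 0.0
        if tuple(x) == tuple(y):
            assert dxy == 0.0
        if dxy == 0.0:  # squared differences can underflow for denormals
            assert np.allclose(x, y)
        assert dxy <= g.vector_distance(vx, vz) + g.vector_distance(vz, vy) + 1e-9

    def test_aggregation_modes(self, table):
        s = g.word_feature_vector("ssa", table, aggregation="sum")
        m = g.word_feature_vector("ssa", table, aggregation="mean")
        p = g.word_feature_vector("ssa", table, aggregation="presence")
        i = list(s.feature_set).index("sibilant")
        assert s.values[i] == 2.0
        assert m.values[i] == pytest.approx(2 / 3)
        assert p.values[i] == 1.0


class TestDistanceSummary:
    def test_permutation_invariance(self, table, toy_lexicon):
        metric = lambda a, b: g.feature_edit_distance(a, b, table)
        s1 = g.distance_summary(toy_lexicon, metric)
        shuffled = g.StudyLexicon(
            language_pair=toy_lexicon.language_pair,
            records=tuple(reversed(toy_lexicon.records)),
        )
        s2 = g.distance_summary(shuffled, metric)
        assert s1.target_median == pytest.approx(s2.target_median)
        assert s1.median_of_medians == pytest.approx(s2.median_of_medians)

    def test_identical_word_pairs(self, table):
        from conftest import make_word
        words = tuple(
            make_word(f"i{k}", w, w, table=table)
            for k, w in enumerate(["dɛn", "voda", "pɛs", "nɛbɛ"])
        )
        lex = g.StudyLexicon(language_pair="self", records=words)
        s = g.distance_summary(lex, lambda a, b: g.feature_edit_distance(a, b, table))
        assert s.target_median == 0.0
        assert s.median_of_medians > 0.0  # off-target distances are not zero

    def test_degenerate_single_word_lexicon(self, table):
        from conftest import make_word
        words = tuple(make_word(f"d{k}", "dɛn", "dɛn", table=table) for k in range(4))
        lex = g.StudyLexicon(language_pair="degenerate", records=words)
        s = g.distance_summary(lex, lambda a, b: g.feature_edit_distance(a, b, table))
        assert s.target_median == 0.0
        assert s.median_of_medians == 0.0

    def test_empty_lexicon_rejected(self, table):
        lex = g.StudyLexicon(language_pair="x", records=())
        with pytest.raises(ValidationError):
            g.distance_summary(lex, lambda a, b: 0.0)
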