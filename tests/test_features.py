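"""Lexical indices, dictionary counting, composites and the 100-slot vector."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from speechscreen.corpus import CategoryDictionary, Transcript, tokenize
from speechscreen.features import (
    analytic_composite,
    brunet_index,
    category_proportions,
    consecutive_duplicates,
    corrected_ttr,
    disfluency_aggregate,
    extract_feature_table,
    extract_features,
    feature_names,
    honore_index,
    idea_density,
    lexical_counts,
    read_feature_table,
    words_per_sentence,
    write_feature_table,
    LexicalCounts,
)

token_streams = st.lists(
    st.sampled_from("a b c the boy is on stool um know knows it".split()),
    min_size=1,
    max_size=60,
)


def _make_transcript(text):
    tokens, spans = tokenize(text)
    return Transcript("t", text, tokens, spans, "en")


class TestLexicalIndices:
    def test_cttr_hand_values(self):
        assert corrected_ttr(LexicalCounts(8, 8, 8)) == pytest.approx(2.0)
        assert corrected_ttr(LexicalCounts(1, 1, 1)) == pytest.approx(1 / math.sqrt(2))
        counts = lexical_counts(["the", "boy", "is", "on", "the", "stool"])
        assert counts.n_types == 5
        assert corrected_ttr(counts) == pytest.approx(5 / math.sqrt(12))

    def test_brunet_hand_values_and_monotonicity(self):
        assert brunet_index(LexicalCounts(1, 1, 1)) == pytest.approx(1.0)
        w50 = brunet_index(LexicalCounts(100, 50, 0))
        w100 = brunet_index(LexicalCounts(100, 100, 0))
        assert w50 == pytest.approx(100 ** (50**-0.165))
        assert w100 == pytest.approx(100 ** (100**-0.165))
        assert w100 < w50  # richer vocabulary -> lower W

    def test_brunet_decreases_in_types_on_grid(self):
        for n in (20, 100, 400):
            values = [brunet_index(LexicalCounts(n, v, 0)) for v in range(1, n + 1, 7)]
            assert all(a > b for a, b in zip(values, values[1:]))

    def test_honore_hand_values(self):
        counts = lexical_counts(["a", "b", "c", "a"])
        assert (counts.n_types, counts.n_hapax) == (3, 2)
        assert honore_index(counts) == pytest.approx(100 * math.log(4) / (1 - 2 / 3))
        all_same = lexical_counts(["x"] * 5)
        assert honore_index(all_same) == pytest.approx(100 * math.log(5))

    def test_honore_all_hapax_capped(self):
        counts = lexical_counts(["a", "b", "c"])  # V1 == V
        assert honore_index(counts) == pytest.approx(100 * math.log(3) * 2 * 3)

    def test_empty_transcript_rejected(self):
        empty = LexicalCounts(0, 0, 0)
        for fn in (corrected_ttr, brunet_index, honore_index):
            with pytest.raises(ValueError, match="empty"):
                fn(empty)


class TestIdeaDensityAndDuplicates:
    def test_idea_density_hand_count(self):
        tokens = ["the", "boy", "is", "falling", "quickly"]
        tags = ["DET", "NOUN", "VERB", "VERB", "ADV"]
        assert idea_density(tokens, tags) == pytest.approx(0.6)
        assert idea_density(["a", "b"], ["DET", "NOUN"]) == 0.0
        assert idea_density(["a", "b"], ["VERB", "VERB"]) == 1.0

    def test_idea_density_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            idea_density(["a"], ["DET", "NOUN"])

    @pytest.mark.parametrize(
        "tokens, expected",
        [(["the", "the", "boy"], 1), (["a", "a", "a"], 2), ([], 0), (["a", "b", "a"], 0)],
    )
    def test_consecutive_duplicates(self, tokens, expected):
        assert consecutive_duplicates(tokens) == expected


class TestCategoryCounting:
    def test_proportions_hand_values(self):
        d = CategoryDictionary({"filler": ("um", "uh"), "pronoun": ("it", "he")})
        props = category_proportions(["um", "it", "it", "runs"], d)
        assert props["filler"] == pytest.approx(0.25)
        assert props["pronoun"] == pytest.approx(0.50)

    def test_prefix_pattern(self):
        d = CategoryDictionary({"knowing": ("know*",)})
        props = category_proportions(["knows", "knowing", "now"], d)
        assert props["knowing"] == pytest.approx(2 / 3)

    def test_empty_category_and_empty_tokens(self):
        d = CategoryDictionary({"empty": ()})
        assert category_proportions(["a", "b"], d)["empty"] == 0.0
        assert category_proportions([], d)["empty"] == 0.0

    def test_bigram_pattern_counts_one_token(self):
        d = CategoryDictionary({"filler": ("you_know",)})
        props = category_proportions(["you", "know", "the", "boy"], d)
        assert props["filler"] == pytest.approx(0.25)

    @settings(derandomize=True, max_examples=100)
    @given(token_streams)
    def test_matching_equals_naive_scan(self, tokens):
        d = CategoryDictionary(
            {"lit": ("the", "um", "it"), "pre": ("know*", "sto*"), "none": ("zzz",)}
        )
        props = category_proportions(tokens, d)
        for cat, patterns in d.categories.items():
            naive = 0
            for tok in tokens:
                for pat in patterns:
                    if pat.endswith("*"):
                        if tok.startswith(pat[:-1]):
                            naive += 1
                            break
                    elif tok == pat:
                        naive += 1
                        break
            assert props[cat] == pytest.approx(naive / len(tokens))


class TestComposites:
    def test_disfluency_raw_sum(self):
        props = {"nonfluency": 0.02, "filler": 0.01, "assent": 0.03}
        assert disfluency_aggregate(props) == pytest.approx(0.06)
        assert disfluency_aggregate(
            {"nonfluency": 0.0, "filler": 0.0, "assent": 0.0}
        ) == 0.0

    def test_disfluency_missing_category_named(self):
        with pytest.raises(KeyError, match="assent"):
            disfluency_aggregate({"nonfluency": 0.0, "filler": 0.0})

    def test_analytic_composite_arithmetic(self):
        base = {
            c: 0.0
            for c in (
                "article", "preposition", "personal_pronoun", "impersonal_pronoun",
                "auxiliary_verb", "conjunction", "adverb", "negation",
            )
        }
        assert analytic_composite(base) == pytest.approx(30.0)
        positive = dict(base, article=0.10, preposition=0.10)
        assert analytic_composite(positive) == pytest.approx(50.0)
        negative = dict(base, adverb=0.40)
        assert analytic_composite(negative) == 0.0  # clamped

    def test_analytic_composite_missing_input(self):
        with pytest.raises(KeyError, match="negation"):
            analytic_composite({"article": 0.1})

    def test_words_per_sentence(self):
        assert words_per_sentence(_make_transcript("one two three. four five.")) == 2.5
        assert words_per_sentence(_make_transcript("a b c d e f g")) == 7.0
        t = _make_transcript("a b c. a b c d. a b c d e. a b c d.")
        assert words_per_sentence(t) == pytest.approx(4.0)


class TestFeatureVector:
    def test_shape_order_and_determinism(self, dictionary):
        t = _make_transcript("The boy is falling. Um the cookie jar is full.")
        v1 = extract_features(t, dictionary)
        v2 = extract_features(t, dictionary)
        assert len(v1) == 100
        assert list(v1.values) == feature_names(dictionary)
        assert v1.values == v2.values
        for name, value in v1.values.items():
            assert np.isfinite(value)
            if name.startswith("cat_"):
                assert 0.0 <= value <= 1.0
        assert 0.0 <= v1.values["analytic_composite"] <= 100.0

    def test_doubling_transcript_keeps_proportions_lowers_cttr(self, dictionary):
        text = "The boy is falling. Um the cookie jar is full."
        single = extract_features(_make_transcript(text), dictionary)
        double = extract_features(_make_transcript(text + " " + text), dictionary)
        for name in single.values:
            if name.startswith("cat_") or name == "idea_density":
                assert double.values[name] == pytest.approx(single.values[name])
        assert double.values["cttr"] < single.values["cttr"]

    def test_empty_transcript_error_names_participant(self, dictionary):
        t = Transcript("p42", "", (), (), "en")
        with pytest.raises(ValueError, match="p42"):
            extract_features(t, dictionary)

    @settings(derandomize=True, max_examples=100)
    @given(token_streams)
    def test_lexical_indices_match_brute_force(self, tokens):
        """Independent references: direct formulas over Counter-based counts."""
        n = len(tokens)
        freqs = Counter(tokens)
        v = len(freqs)
        v1 = sum(1 for c in freqs.values() if c == 1)
        counts = lexical_counts(tokens)
        assert corrected_ttr(counts) == pytest.approx(v / math.sqrt(2 * n), abs=1e-9)
        assert brunet_index(counts) == pytest.approx(n ** (v**-0.165), abs=1e-9)
        denom = max(1 - v1 / v, 1 / (2 * v))
        assert honore_index(counts) == pytest.approx(
            100 * math.log(n) / denom, abs=1e-9
        )
        assert consecutive_duplicates(tokens) == sum(
            1 for i in range(1, n) if tokens[i] == tokens[i - 1]
        )

    def test_feature_table_zscores_disfluency(self, dictionary):
        texts = [
            "Um uh yeah the boy is falling down now.",
            "The boy is on the stool reaching for the cookie jar.",
            "Uh um er well yeah ok the the jar.",
        ]
        transcripts = [
            Transcript(f"p{i}", txt, *tokenize(txt), "en")
            for i, txt in enumerate(texts)
        ]
        table = extract_feature_table(transcripts, dictionary)
        col = table["disfluency_aggregate"].to_numpy()
        assert col.mean() == pytest.approx(0.0, abs=1e-12)
        assert col.std(ddof=0) == pytest.approx(1.0)
        # zero-variance cohort maps to zeros
        same = [transcripts[0], transcripts[0]]
        table_same = extract_feature_table(
            [Transcript(f"q{i}", t.raw_text, t.tokens, t.sentences, "en")
             for i, t in enumerate(same)],
            dictionary,
        )
        assert (table_same["disfluency_aggregate"] == 0.0).all()

    def test_feature_table_round_trip_bit_exact(self, tmp_path, dictionary):
        texts = ["The boy is falling.", "Um the cookie jar is full up there."]
        transcripts = [
            Transcript(f"p{i}", txt, *tokenize(txt), "en")
            for i, txt in enumerate(texts)
        ]
        table = extract_feature_table(transcripts, dictionary)
        write_feature_table(table, tmp_path / "features.csv")
        back = read_feature_table(tmp_path / "features.csv")
        assert (back.to_numpy() == table.to_numpy()).all()
        assert list(back.columns) == list(table.columns)
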