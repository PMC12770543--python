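"""Interpretable linguistic features for cognitive-impairment screening.

Each participant transcript is summarised as a fixed-order 100-slot feature
vector:

* five lexical-semantic indices — corrected type-token ratio (CTTR,
  :math:`V/\\sqrt{2N}`), Brunet's index (:math:`W = N^{V^{-0.165}}`),
  Honoré's statistic (:math:`R = 100\\ln N / (1 - V_1/V)`), propositional
  idea density, and the count of consecutive duplicate words;
* mean words per sentence;
* an analytic-thinking composite (the Categorical-Dynamic Index);
* a disfluency aggregate (nonfluency + filler + assent rates, z-scored
  across the cohort);
* 92 dictionary-category proportions in dictionary order.

Category proportions and the disfluency/analytic composites use LIWC-style
dictionary counting over lowercase tokens; a token may contribute to several
categories, and prefix patterns (``know*``) match any token sharing the stem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections import Counter
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import CategoryDictionary, Transcript, load_dictionary

__all__ = [
    "LexicalCounts",
    "FeatureVector",
    "lexical_counts",
    "corrected_ttr",
    "brunet_index",
    "honore_index",
    "idea_density",
    "consecutive_duplicates",
    "category_proportions",
    "disfluency_aggregate",
    "analytic_composite",
    "words_per_sentence",
    "rule_based_pos_tags",
    "extract_features",
    "extract_feature_table",
    "feature_names",
    "default_dictionary",
    "write_feature_table",
    "read_feature_table",
]

BRUNET_EXPONENT = 0.165

#: POS tags counted as proposition-bearing for idea density.
PROPOSITION_TAGS = frozenset({"VERB", "ADJ", "ADV", "ADP", "CONJ"})

DISFLUENCY_CATEGORIES = ("nonfluency", "filler", "assent")

#: Categorical-Dynamic Index inputs (percent rates): constant + positives - negatives.
_CDI_POSITIVE = ("article", "preposition")
_CDI_NEGATIVE = (
    "personal_pronoun",
    "impersonal_pronoun",
    "auxiliary_verb",
    "conjunction",
    "adverb",
    "negation",
)

LEXICAL_FEATURES = (
    "cttr",
    "brunet_index",
    "honore_index",
    "idea_density",
    "consecutive_duplicates",
)


@dataclass(frozen=True)
class LexicalCounts:
    """Token, type and hapax counts feeding the lexical diversity indices."""

    n_tokens: int
    n_types: int
    n_hapax: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_hapax <= self.n_types <= self.n_tokens:
            raise ValueError(
                f"require 0 <= V1 <= V <= N, got V1={self.n_hapax}, "
                f"V={self.n_types}, N={self.n_tokens}"
            )


@dataclass(frozen=True)
class FeatureVector:
    """Fixed-order named feature map for one participant."""

    participant_id: str
    values: dict[str, float]
    groups: dict[str, str]

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=float)


def lexical_counts(tokens: Sequence[str]) -> LexicalCounts:
    freqs = Counter(tokens)
    return LexicalCounts(
        n_tokens=len(tokens),
        n_types=len(freqs),
        n_hapax=sum(1 for c in freqs.values() if c == 1),
    )


def corrected_ttr(counts: LexicalCounts) -> float:
    """Carroll's corrected type-token ratio, ``V / sqrt(2N)``."""
    if counts.n_tokens == 0:
        raise ValueError("empty transcript: CTTR undefined for N=0")
    return counts.n_types / math.sqrt(2.0 * counts.n_tokens)


def brunet_index(counts: LexicalCounts) -> float:
    """Brunet's W = ``N ** (V ** -0.165)``; lower means richer vocabulary."""
    if counts.n_tokens == 0 or counts.n_types == 0:
        raise ValueError("empty transcript: Brunet index undefined")
    return counts.n_tokens ** (counts.n_types ** -BRUNET_EXPONENT)


def honore_index(counts: LexicalCounts) -> float:
    """Honoré's R = ``100 ln N / (1 - V1/V)``.

    When every type is a hapax (V1 = V) the denominator is floored at
    ``1/(2V)``, capping R instead of diverging.
    """
    if counts.n_tokens == 0 or counts.n_types == 0:
        raise ValueError("empty transcript: Honore index undefined")
    denom = 1.0 - counts.n_hapax / counts.n_types
    denom = max(denom, 1.0 / (2.0 * counts.n_types))
    return 100.0 * math.log(counts.n_tokens) / denom


def idea_density(tokens: Sequence[str], pos_tags: Sequence[str]) -> float:
    """Proportion of proposition-bearing tokens (verbs, adjectives,
    adverbs, adpositions, conjunctions)."""
    if len(tokens) != len(pos_tags):
        raise ValueError(
            f"tokens ({len(tokens)}) and pos_tags ({len(pos_tags)}) differ in length"
        )
    if not tokens:
        raise ValueError("empty transcript: idea density undefined")
    return sum(1 for t in pos_tags if t in PROPOSITION_TAGS) / len(tokens)


def consecutive_duplicates(tokens: Sequence[str]) -> int:
    """Number of positions where a token repeats its predecessor."""
    return sum(1 for a, b in zip(tokens, tokens[1:]) if a == b)


def words_per_sentence(transcript: Transcript) -> float:
    if transcript.n_sentences == 0:
        raise ValueError(
            f"empty transcript for participant {transcript.participant_id!r}"
        )
    return transcript.n_tokens / transcript.n_sentences


def _match_count(tokens: Sequence[str], patterns: Sequence[str]) -> int:
    """Tokens matched by a pattern list: literals, ``stem*`` prefixes, and
    ``a_b`` bigrams (a bigram match counts one token against N)."""
    literals = set()
    prefixes: list[str] = []
    bigrams: list[tuple[str, str]] = []
    for pat in patterns:
        if "_" in pat:
            first, _, second = pat.partition("_")
            bigrams.append((first, second.rstrip("*")))
        elif pat.endswith("*"):
            prefixes.append(pat[:-1])
        else:
            literals.add(pat)
    count = 0
    for i, tok in enumerate(tokens):
        if tok in literals or any(tok.startswith(p) for p in prefixes):
            count += 1
            continue
        if any(
            tok == first and i + 1 < len(tokens) and tokens[i + 1] == second
            for first, second in bigrams
        ):
            count += 1
    return count


def category_proportions(
    tokens: Sequence[str], dictionary: CategoryDictionary
) -> dict[str, float]:
    """Per-category matched-token proportion; a token may match several
    categories. Empty input yields all-zero proportions."""
    n = len(tokens)
    if n == 0:
        return {name: 0.0 for name in dictionary.category_order}
    return {
        name: _match_count(tokens, dictionary.categories[name]) / n
        for name in dictionary.category_order
    }


def disfluency_aggregate(props: Mapping[str, float]) -> float:
    """Raw disfluency: nonfluency + filler + assent proportions.

    The reported feature is this raw sum z-scored across the cohort
    (see :func:`extract_feature_table`).
    """
    missing = [c for c in DISFLUENCY_CATEGORIES if c not in props]
    if missing:
        raise KeyError(f"missing disfluency categories: {missing}")
    return float(sum(props[c] for c in DISFLUENCY_CATEGORIES))


def analytic_composite(props: Mapping[str, float]) -> float:
    """Categorical-Dynamic Index analytic-thinking score in [0, 100].

    ``30 + article% + preposition% - personal_pronoun% - impersonal_pronoun%
    - auxiliary_verb% - conjunction% - adverb% - negation%`` with category
    rates expressed as percentages, clamped to [0, 100].
    """
    needed = _CDI_POSITIVE + _CDI_NEGATIVE
    missing = [c for c in needed if c not in props]
    if missing:
        raise KeyError(f"missing analytic-composite categories: {missing}")
    score = (
        30.0
        + sum(100.0 * props[c] for c in _CDI_POSITIVE)
        - sum(100.0 * props[c] for c in _CDI_NEGATIVE)
    )
    return min(max(score, 0.0), 100.0)


# ---------------------------------------------------------------------------
# POS tagging
# ---------------------------------------------------------------------------

_TAG_LEXICON: dict[str, str] = {}
for _w in ("a", "an", "the", "this", "that", "these", "those", "each", "every",
           "either", "another", "such", "some", "any", "no"):
    _TAG_LEXICON[_w] = "DET"
for _w in ("in", "on", "at", "of", "to", "from", "with", "by", "for", "over",
           "under", "into", "onto", "about", "through", "between", "behind",
           "beside", "near", "off", "out", "up", "down", "around"):
    _TAG_LEXICON[_w] = "ADP"
for _w in ("and", "but", "or", "nor", "so", "yet", "because", "while",
           "although", "though", "if", "when", "since", "until"):
    _TAG_LEXICON[_w] = "CONJ"
for _w in ("i", "me", "my", "we", "us", "our", "you", "your", "he", "him",
           "his", "she", "her", "they", "them", "their", "it", "its",
           "something", "anything", "nothing", "everything", "who", "what",
           "which"):
    _TAG_LEXICON[_w] = "PRON"
for _w in ("is", "am", "are", "was", "were", "be", "been", "being", "have",
           "has", "had", "do", "does", "did", "will", "would", "can", "could",
           "shall", "should", "may", "might", "must", "go", "goes", "going",
           "went", "get", "gets", "got", "make", "makes", "made", "take",
           "takes", "took", "see", "sees", "saw", "say", "says", "said",
           "know", "knows", "knew", "think", "thinks", "thought", "fell",
           "ran", "came", "stood"):
    _TAG_LEXICON[_w] = "VERB"
for _w in ("very", "really", "just", "there", "then", "now", "here", "quite",
           "too", "also", "again", "always", "never", "often", "maybe",
           "perhaps", "still", "already", "soon", "not"):
    _TAG_LEXICON[_w] = "ADV"
for _w in ("big", "small", "little", "tall", "short", "old", "young", "new",
           "good", "bad", "nice", "pretty", "dirty", "clean", "wet", "open",
           "high", "busy", "full", "empty", "happy", "sad"):
    _TAG_LEXICON[_w] = "ADJ"

_SUFFIX_TAGS = (
    ("ly", "ADV"),
    ("ing", "VERB"),
    ("ed", "VERB"),
    ("ful", "ADJ"),
    ("ous", "ADJ"),
    ("ive", "ADJ"),
    ("able", "ADJ"),
    ("ible", "ADJ"),
)


def rule_based_pos_tags(tokens: Sequence[str]) -> list[str]:
    """Deterministic rule-based tagger: closed-class lexicon lookup, then
    suffix rules, else NOUN. Coarse by design; it exists so idea density is
    computable without an external NLP model, and any tagger with the same
    ``tokens -> tags`` signature can be swapped in."""
    tags = []
    for tok in tokens:
        tag = _TAG_LEXICON.get(tok)
        if tag is None:
            for suffix, stag in _SUFFIX_TAGS:
                if len(tok) > len(suffix) + 2 and tok.endswith(suffix):
                    tag = stag
                    break
        tags.append(tag or "NOUN")
    return tags


# ---------------------------------------------------------------------------
# Feature vector assembly
# ---------------------------------------------------------------------------

def default_dictionary() -> CategoryDictionary:
    """The packaged 92-category stand-in dictionary."""
    with resources.as_file(
        resources.files("speechscreen.data") / "standin_dictionary.txt"
    ) as path:
        return load_dictionary(path)


def feature_names(dictionary: CategoryDictionary) -> list[str]:
    """Canonical 100-name feature order for a 92-category dictionary."""
    return (
        list(LEXICAL_FEATURES)
        + ["words_per_sentence", "analytic_composite", "disfluency_aggregate"]
        + [f"cat_{name}" for name in dictionary.category_order]
    )


def feature_groups(dictionary: CategoryDictionary) -> dict[str, str]:
    groups = {name: "lexical" for name in LEXICAL_FEATURES}
    groups["words_per_sentence"] = "structural"
    groups["analytic_composite"] = "composite"
    groups["disfluency_aggregate"] = "composite"
    for name in dictionary.category_order:
        groups[f"cat_{name}"] = "category"
    return groups


def extract_features(
    transcript: Transcript,
    dictionary: CategoryDictionary,
    tagger: Callable[[Sequence[str]], Sequence[str]] = rule_based_pos_tags,
) -> FeatureVector:
    """Compute the full fixed-order feature vector for one transcript.

    The ``disfluency_aggregate`` slot holds the raw (un-normalised) sum;
    :func:`extract_feature_table` replaces it with the cohort z-score.
    """
    if transcript.n_tokens == 0:
        raise ValueError(
            f"empty transcript for participant {transcript.participant_id!r}"
        )
    counts = lexical_counts(transcript.tokens)
    props = category_proportions(transcript.tokens, dictionary)
    tags = tagger(transcript.tokens)
    values: dict[str, float] = {
        "cttr": corrected_ttr(counts),
        "brunet_index": brunet_index(counts),
        "honore_index": honore_index(counts),
        "idea_density": idea_density(transcript.tokens, tags),
        "consecutive_duplicates": float(consecutive_duplicates(transcript.tokens)),
        "words_per_sentence": words_per_sentence(transcript),
        "analytic_composite": analytic_composite(props),
        "disfluency_aggregate": disfluency_aggregate(props),
    }
    for name in dictionary.category_order:
        values[f"cat_{name}"] = props[name]
    return FeatureVector(
        participant_id=transcript.participant_id,
        values=values,
        groups=feature_groups(dictionary),
    )


def extract_feature_table(
    transcripts: Sequence[Transcript],
    dictionary: CategoryDictionary | None = None,
    tagger: Callable[[Sequence[str]], Sequence[str]] = rule_based_pos_tags,
) -> pd.DataFrame:
    """Feature table for a cohort, participants as rows.

    Applies the cohort-level normalisation of the disfluency aggregate:
    the raw sums are z-scored across participants (zero-variance cohorts
    map to 0).
    """
    if dictionary is None:
        dictionary = default_dictionary()
    vectors = [extract_features(t, dictionary, tagger) for t in transcripts]
    df = pd.DataFrame(
        [v.values for v in vectors],
        index=pd.Index([v.participant_id for v in vectors], name="participant_id"),
        columns=feature_names(dictionary),
    )
    raw = df["disfluency_aggregate"].to_numpy()
    sd = raw.std(ddof=0)
    df["disfluency_aggregate"] = 0.0 if sd == 0 else (raw - raw.mean()) / sd
    return df


def write_feature_table(df: pd.DataFrame, path: Path | str) -> None:
    """Write a feature table to CSV with full float round-trip precision."""
    df.to_csv(path, float_format="%.17g")


def read_feature_table(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, index_col="participant_id", float_precision="round_trip")
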