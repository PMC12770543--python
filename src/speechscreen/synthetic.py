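"""Synthetic picture-description cohorts with controllable group structure.

The study data for speech-based dementia screening (DementiaBank corpora,
in-residence pilot recordings) are access-restricted, so every downstream
stage of this package is exercised on simulated cohorts. Each participant
carries a latent severity ``s`` in [0, 1] (0 = idealised cognitively-normal
extreme). Severity drives, monotonically:

* MMSE, via ``clamp(round(29 - 22 s + eps), 0, 30)``;
* word-category rates — pronouns (personal and impersonal), adverbs,
  nonfluencies, fillers and assent words increase with ``s``; articles,
  prepositions, family and fulfilment words decrease;
* active vocabulary size (shrinks, lowering CTTR and Honoré's index),
  sentence length (shrinks) and the adjacent-duplicate-word probability
  (grows).

These are the effect directions reported for dementia picture-description
speech; the magnitudes are simulation choices, not literature estimates.
``effect_size="none"`` removes all group differences, giving a null cohort
for calibration checks. Sex is sampled independently of severity, so the
generator is demographically fair by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .corpus import CategoryDictionary, ParticipantRecord, Transcript, tokenize
from .features import default_dictionary

__all__ = [
    "CohortConfig",
    "EFFECT_DIRECTIONS",
    "sample_mmse",
    "sample_transcript",
    "generate_cohort",
    "label_from_mmse",
    "MMSE_CUTOFF",
]

MMSE_CUTOFF = 26
SEVERITY_THRESHOLD = 0.35  # diagnosis = ADRD iff s > threshold

_EFFECT_SCALE = {"none": 0.0, "weak": 0.5, "strong": 1.0}

#: Base token-category mixture rates at severity 0 and the per-unit-severity
#: shift applied at effect_size="strong" (halved at "weak", zero at "none").
_BASE_RATES: dict[str, float] = {
    "personal_pronoun": 0.10,
    "impersonal_pronoun": 0.05,
    "article": 0.10,
    "preposition": 0.12,
    "adverb": 0.06,
    "conjunction": 0.06,
    "auxiliary_verb": 0.08,
    "nonfluency": 0.010,
    "filler": 0.015,
    "assent": 0.010,
    "family": 0.025,
    "fulfil": 0.020,
    "common_verb": 0.10,
}
_RATE_SHIFTS: dict[str, float] = {
    "personal_pronoun": +0.050,
    "impersonal_pronoun": +0.050,
    "adverb": +0.040,
    "nonfluency": +0.035,
    "filler": +0.030,
    "assent": +0.020,
    "article": -0.040,
    "preposition": -0.050,
    "family": -0.018,
    "fulfil": -0.015,
}

#: Expected sign of the ADRD-minus-CN difference for each manipulated
#: dictionary category (+1 higher in ADRD, -1 lower).
EFFECT_DIRECTIONS: dict[str, int] = {
    "personal_pronoun": +1,
    "impersonal_pronoun": +1,
    "adverb": +1,
    "nonfluency": +1,
    "filler": +1,
    "assent": +1,
    "family": -1,
    "fulfil": -1,
}

_BASE_WORDS_PER_SENTENCE = 9.0
_WPS_SHIFT = -3.5
_BASE_DUP_PROB = 0.01
_DUP_SHIFT = 0.08
_VOCAB_SHRINK = 0.65

_SYLLABLES = (
    "ba be bi bo bu da de di do du ka ke ki ko ku la le li lo lu "
    "ma me mi mo mu na ne ni no nu pa pe pi po pu ra re ri ro ru "
    "sa se si so su ta te ti to tu va ve vi vo vu za ze zi zo zu"
).split()


@dataclass(frozen=True)
class CohortConfig:
    """Simulation settings; defaults mirror the training-cohort demographics
    the screening study reports (age 68 (6.8) years, 34% male, roughly
    balanced diagnosis groups)."""

    n_participants: int = 100
    adrd_prevalence: float = 0.5
    effect_size: Literal["none", "weak", "strong"] = "strong"
    age_mean: float = 68.0
    age_sd: float = 6.8
    male_fraction: float = 0.34
    mmse_noise_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.adrd_prevalence <= 1.0:
            raise ValueError("adrd_prevalence must be in [0, 1]")
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.effect_size not in _EFFECT_SCALE:
            raise ValueError(f"unknown effect_size {self.effect_size!r}")


def sample_mmse(severity: float, noise_sd: float, rng: np.random.Generator) -> int:
    """MMSE from latent severity: ``clamp(round(29 - 22 s + eps), 0, 30)``."""
    if not 0.0 <= severity <= 1.0:
        raise ValueError(f"severity {severity} outside [0, 1]")
    eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
    return int(np.clip(round(29.0 - 22.0 * severity + eps), 0, 30))


def _category_rates(severity: float, effect: float) -> dict[str, float]:
    rates = dict(_BASE_RATES)
    for cat, shift in _RATE_SHIFTS.items():
        rates[cat] = max(rates[cat] + shift * effect * severity, 0.0)
    return rates


def _build_lexicon(dictionary: CategoryDictionary) -> tuple[dict[str, list[str]], list[str]]:
    """Category word pools plus a general content pool (~1200 words total).

    Pool words come from the dictionary's own single-token patterns (prefix
    stems included as-is); the content pool adds pseudo-words screened to
    match no dictionary pattern, so content words never perturb category
    proportions of the manipulated categories."""
    pools: dict[str, list[str]] = {}
    for cat in _BASE_RATES:
        words = []
        for pat in dictionary.categories[cat]:
            if "_" in pat:
                words.append(pat)  # bigram, emitted as two tokens
            else:
                words.append(pat.rstrip("*"))
        pools[cat] = words

    manipulated = set(_BASE_RATES)
    content: list[str] = []
    seen: set[str] = set()
    for cat in dictionary.category_order:
        if cat in manipulated:
            continue
        for pat in dictionary.categories[cat]:
            if "_" in pat or pat.endswith("*"):
                continue
            if pat not in seen and not _matches_any(pat, dictionary, manipulated):
                seen.add(pat)
                content.append(pat)
    # pad with screened pseudo-words up to ~1200 total
    target = 1200 - sum(len(p) for p in pools.values())
    for a in _SYLLABLES:
        for b in _SYLLABLES:
            if len(content) >= target:
                break
            w = a + b + "n"
            if w not in seen and not _matches_any(w, dictionary, manipulated):
                seen.add(w)
                content.append(w)
        if len(content) >= target:
            break
    return pools, content


def _matches_any(token: str, dictionary: CategoryDictionary, cats: set[str]) -> bool:
    for cat in cats:
        for pat in dictionary.categories[cat]:
            if "_" in pat:
                continue
            if pat.endswith("*"):
                if token.startswith(pat[:-1]):
                    return True
            elif token == pat:
                return True
    return False


_LEXICON_CACHE: dict[int, tuple[dict[str, list[str]], list[str]]] = {}


def _lexicon(dictionary: CategoryDictionary):
    key = id(dictionary)
    if key not in _LEXICON_CACHE:
        _LEXICON_CACHE[key] = _build_lexicon(dictionary)
    return _LEXICON_CACHE[key]


def sample_transcript(
    severity: float,
    effect_size: str,
    rng: np.random.Generator,
    participant_id: str = "sim",
    dictionary: CategoryDictionary | None = None,
) -> Transcript:
    """Draw one synthetic picture-description transcript.

    Tokens are sampled from a severity-dependent mixture over category word
    pools and a general content pool whose active size shrinks with
    severity. Sentence length shrinks and the adjacent-duplicate probability
    grows with severity. ``effect_size="none"`` collapses all participants
    onto the severity-0 distribution.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError(f"severity {severity} outside [0, 1]")
    if dictionary is None:
        dictionary = default_dictionary()
    effect = _EFFECT_SCALE[effect_size]
    pools, content = _lexicon(dictionary)

    rates = _category_rates(severity, effect)
    cats = list(rates)
    probs = np.array([rates[c] for c in cats])
    p_content = max(1.0 - probs.sum(), 0.05)
    probs = np.append(probs, p_content)
    probs /= probs.sum()

    # active content vocabulary shrinks with severity
    k = max(30, int(round(len(content) * (1.0 - _VOCAB_SHRINK * effect * severity))))
    active = list(content)
    rng.shuffle(active)
    active = active[:k]

    wps = max(_BASE_WORDS_PER_SENTENCE + _WPS_SHIFT * effect * severity, 3.0)
    p_dup = _BASE_DUP_PROB + _DUP_SHIFT * effect * severity
    n_sentences = max(int(round(rng.normal(12.0, 2.0))), 4)

    sentences: list[str] = []
    prev: str | None = None
    for _ in range(n_sentences):
        n_words = max(int(rng.poisson(max(wps - 3.0, 0.5))) + 3, 3)
        words: list[str] = []
        while len(words) < n_words:
            if prev is not None and rng.random() < p_dup:
                words.append(prev)
                continue
            ci = rng.choice(len(probs), p=probs)
            if ci == len(cats):
                word = active[rng.integers(len(active))]
            else:
                pool = pools[cats[ci]]
                word = pool[rng.integers(len(pool))]
            if "_" in word:
                parts = word.split("_")
                words.extend(parts)
                prev = parts[-1]
                continue
            words.append(word)
            prev = word
        sentences.append(" ".join(words) + ".")

    raw_text = " ".join(sentences)
    tokens, spans = tokenize(raw_text)
    return Transcript(
        participant_id=participant_id,
        raw_text=raw_text,
        tokens=tokens,
        sentences=spans,
        language="en",
    )


def _sample_severity(is_adrd: bool, rng: np.random.Generator) -> float:
    # CN severities hug 0 (MMSE ~28); ADRD spans mild-to-severe so the
    # cohort MMSE mixture tracks the reported 22.9 (7) training profile.
    if is_adrd:
        return float(SEVERITY_THRESHOLD + (1.0 - SEVERITY_THRESHOLD) * rng.beta(1.0, 2.8))
    return float(SEVERITY_THRESHOLD * rng.beta(1.0, 6.0))


def generate_cohort(
    config: CohortConfig,
    dictionary: CategoryDictionary | None = None,
) -> tuple[list[Transcript], list[ParticipantRecord], pd.DataFrame]:
    """Generate a full cohort: transcripts, metadata records, and the
    generator-truth table (participant_id, severity, label, target rates).

    Diagnosis is ADRD iff severity > 0.35; the train/test split is 70:30,
    stratified by diagnosis. Each participant has an independent RNG stream
    derived from ``(seed, index)`` so cohorts extend without reshuffling.
    """
    if dictionary is None:
        dictionary = default_dictionary()
    n = config.n_participants
    n_adrd = int(round(n * config.adrd_prevalence))
    if 0 < config.adrd_prevalence < 1 and (n_adrd == 0 or n_adrd == n):
        raise ValueError("cohort too small to hold both diagnosis classes")
    label_rng = np.random.default_rng((config.seed, 982451653))
    labels = np.array([True] * n_adrd + [False] * (n - n_adrd))
    label_rng.shuffle(labels)

    # stratified 70:30 split
    split = np.empty(n, dtype=object)
    for lab in (True, False):
        idx = np.flatnonzero(labels == lab)
        label_rng.shuffle(idx)
        n_train = int(round(len(idx) * 0.7))
        split[idx[:n_train]] = "train"
        split[idx[n_train:]] = "test"

    transcripts: list[Transcript] = []
    records: list[ParticipantRecord] = []
    truth_rows: list[dict] = []
    effect = _EFFECT_SCALE[config.effect_size]
    for i in range(n):
        pid = f"p{i:04d}"
        rng = np.random.default_rng((config.seed, i))
        s = _sample_severity(bool(labels[i]), rng)
        mmse = sample_mmse(s, config.mmse_noise_sd, rng)
        age = float(rng.normal(config.age_mean, config.age_sd))
        sex = "male" if rng.random() < config.male_fraction else "female"
        transcript = sample_transcript(
            s, config.effect_size, rng, participant_id=pid, dictionary=dictionary
        )
        transcripts.append(transcript)
        records.append(
            ParticipantRecord(
                participant_id=pid,
                age=round(age, 1),
                sex=sex,
                mmse=mmse,
                diagnosis="ADRD" if labels[i] else "CN",
                split=str(split[i]),
                language="en",
            )
        )
        row = {"participant_id": pid, "severity": s, "diagnosis_adrd": bool(labels[i])}
        for cat, rate in _category_rates(s, effect).items():
            row[f"rate_{cat}"] = rate
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows).set_index("participant_id")
    return transcripts, records, truth


def label_from_mmse(records, cutoff: int = MMSE_CUTOFF) -> np.ndarray:
    """Binary impairment labels from MMSE: impaired iff MMSE <= cutoff."""
    missing = [r.participant_id for r in records if r.mmse is None]
    if missing:
        raise ValueError(f"missing MMSE for participants: {missing}")
    return np.array([r.mmse <= cutoff for r in records], dtype=bool)
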