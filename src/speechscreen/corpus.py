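"""Corpus input/output: transcripts, participant metadata, category dictionaries.

Transcripts are plain UTF-8 text files, one per participant, produced by a
picture-description task. Metadata travels as a CSV with the columns
``participant_id,age,sex,mmse,diagnosis,split,language``. Category
dictionaries use a simple line-oriented format (one category per line,
``name: pattern1, pattern2, ...``) mimicking the mechanics of LIWC-style
word-category dictionaries: patterns are either literal tokens, prefix
patterns ending in ``*``, or token bigrams written with an underscore
(``you_know``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "Transcript",
    "ParticipantRecord",
    "CategoryDictionary",
    "tokenize",
    "read_transcript",
    "read_cohort",
    "write_cohort",
    "load_dictionary",
    "METADATA_COLUMNS",
]

METADATA_COLUMNS = [
    "participant_id",
    "age",
    "sex",
    "mmse",
    "diagnosis",
    "split",
    "language",
]

# A word is a maximal run of letters/digits, optionally joined by internal
# apostrophes ("it's", "don't"). Underscore is a separator, not a word char.
_WORD_RE = re.compile(r"[^\W_]+(?:'[^\W_]+)*")
_SENT_SPLIT_RE = re.compile(r"(?<=[.!?])\s+")


@dataclass(frozen=True)
class Transcript:
    """Tokenized participant speech with sentence boundaries.

    ``sentences`` holds half-open ``(start, stop)`` token-index spans that
    partition ``tokens``.
    """

    participant_id: str
    raw_text: str
    tokens: tuple[str, ...]
    sentences: tuple[tuple[int, int], ...]
    language: str = "en"

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)

    @property
    def n_sentences(self) -> int:
        return len(self.sentences)


@dataclass(frozen=True)
class ParticipantRecord:
    """One row of the cohort metadata table.

    ``mmse`` is an integer in [0, 30] or ``None`` when the score was not
    collected; ``diagnosis`` is ``"CN"``, ``"ADRD"`` or ``None``.
    """

    participant_id: str
    age: float
    sex: str
    mmse: int | None
    diagnosis: str | None
    split: str
    language: str = "en"


@dataclass(frozen=True)
class CategoryDictionary:
    """Ordered word-category dictionary with literal/prefix/bigram patterns."""

    categories: dict[str, tuple[str, ...]]
    category_order: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        order = self.category_order or tuple(self.categories)
        object.__setattr__(self, "category_order", order)
        if set(order) != set(self.categories) or len(order) != len(self.categories):
            raise ValueError("category_order must cover every category exactly once")

    def __len__(self) -> int:
        return len(self.category_order)


def tokenize(raw_text: str) -> tuple[tuple[str, ...], tuple[tuple[int, int], ...]]:
    """Lowercase, punctuation-stripping word tokenizer with sentence spans.

    Sentences are split on ``.``, ``!`` or ``?`` followed by whitespace or
    end of text; text without terminal punctuation is a single sentence.
    Deterministic; empty input yields empty tuples.
    """
    tokens: list[str] = []
    spans: list[tuple[int, int]] = []
    for chunk in _SENT_SPLIT_RE.split(raw_text):
        sent_tokens = _WORD_RE.findall(chunk.lower())
        if not sent_tokens:
            continue
        start = len(tokens)
        tokens.extend(sent_tokens)
        spans.append((start, len(tokens)))
    return tuple(tokens), tuple(spans)


def read_transcript(path: Path | str, participant_id: str, language: str = "en") -> Transcript:
    raw = Path(path).read_text(encoding="utf-8")
    tokens, sentences = tokenize(raw)
    return Transcript(
        participant_id=participant_id,
        raw_text=raw,
        tokens=tokens,
        sentences=sentences,
        language=language,
    )


def _parse_optional_int(value, row_id: str, name: str, lo: int, hi: int) -> int | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or str(value).strip() == "":
        return None
    try:
        out = int(round(float(value)))
    except (TypeError, ValueError) as exc:
        raise ValueError(f"participant {row_id!r}: malformed {name} value {value!r}") from exc
    if not lo <= out <= hi:
        raise ValueError(
            f"participant {row_id!r}: {name}={out} outside [{lo}, {hi}]"
        )
    return out


def read_cohort(
    transcript_dir: Path | str, metadata_path: Path | str
) -> tuple[list[Transcript], list[ParticipantRecord]]:
    """Load a transcript directory with its metadata CSV, order preserved.

    Each metadata row ``participant_id`` must resolve to
    ``<transcript_dir>/<participant_id>.txt``. Missing MMSE or diagnosis
    cells become ``None``, never zero.
    """
    transcript_dir = Path(transcript_dir)
    meta = pd.read_csv(metadata_path, dtype={"participant_id": str})
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata missing required columns: {missing_cols}")
    ids = meta["participant_id"].tolist()
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValueError(f"duplicate participant ids in metadata: {dupes}")

    transcripts: list[Transcript] = []
    records: list[ParticipantRecord] = []
    for row in meta.itertuples(index=False):
        pid = str(row.participant_id)
        path = transcript_dir / f"{pid}.txt"
        if not path.exists():
            raise FileNotFoundError(f"no transcript file for participant {pid!r}: {path}")
        language = str(row.language) if pd.notna(row.language) else "en"
        diagnosis = (
            str(row.diagnosis)
            if pd.notna(row.diagnosis) and str(row.diagnosis).strip()
            else None
        )
        records.append(
            ParticipantRecord(
                participant_id=pid,
                age=float(row.age),
                sex=str(row.sex),
                mmse=_parse_optional_int(row.mmse, pid, "mmse", 0, 30),
                diagnosis=diagnosis,
                split=str(row.split),
                language=language,
            )
        )
        transcripts.append(read_transcript(path, pid, language=language))
    return transcripts, records


def write_cohort(
    transcripts: Sequence[Transcript],
    records: Sequence[ParticipantRecord],
    transcript_dir: Path | str,
    metadata_path: Path | str,
) -> None:
    """Write transcripts and metadata in the format :func:`read_cohort` reads."""
    transcript_dir = Path(transcript_dir)
    transcript_dir.mkdir(parents=True, exist_ok=True)
    for t in transcripts:
        (transcript_dir / f"{t.participant_id}.txt").write_text(
            t.raw_text, encoding="utf-8"
        )
    rows = [
        {
            "participant_id": r.participant_id,
            "age": r.age,
            "sex": r.sex,
            "mmse": "" if r.mmse is None else r.mmse,
            "diagnosis": "" if r.diagnosis is None else r.diagnosis,
            "split": r.split,
            "language": r.language,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(metadata_path, index=False)


def load_dictionary(path: Path | str) -> CategoryDictionary:
    """Parse a category dictionary file.

    Format: one category per line, ``name: pattern1, pattern2, ...``;
    blank lines and ``#`` comments ignored. Patterns are lowercased;
    a trailing ``*`` marks a prefix pattern; ``*`` anywhere else is an
    error; ``_`` joins the two tokens of a bigram pattern.
    """
    categories: dict[str, tuple[str, ...]] = {}
    order: list[str] = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ValueError(f"line {lineno}: expected 'name: patterns', got {line!r}")
        name, _, rest = line.partition(":")
        name = name.strip().lower()
        if not name:
            raise ValueError(f"line {lineno}: empty category name")
        if name in categories:
            raise ValueError(f"line {lineno}: duplicate category {name!r}")
        patterns = []
        for pat in rest.split(","):
            pat = pat.strip().lower()
            if not pat:
                continue
            if "*" in pat[:-1]:
                raise ValueError(
                    f"line {lineno}: pattern {pat!r} has internal '*' (only trailing allowed)"
                )
            patterns.append(pat)
        categories[name] = tuple(patterns)
        order.append(name)
    return CategoryDictionary(categories=categories, category_order=tuple(order))
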