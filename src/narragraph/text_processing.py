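"""Transcript cleaning: tokenization and stop-word removal.

Turns raw UTF-8 narrative text into the ordered lowercase token sequence
consumed by the graph stage.  Tokenization is deliberately minimal --
lowercase, whitespace split, Unicode punctuation stripped from token
boundaries -- so that word identity stays stable for node merging.
No lemmatization or canonical-form conversion is performed.
"""

from __future__ import annotations

import re
import sys
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "Transcript",
    "TokenSequence",
    "StopwordList",
    "EmptyTranscriptError",
    "tokenize",
    "remove_stopwords",
    "load_stopwords",
    "default_stopwords",
    "read_transcript",
    "read_transcript_dir",
]


class EmptyTranscriptError(ValueError):
    """Raised when a transcript contains no tokens after cleaning."""


@dataclass(frozen=True)
class Transcript:
    """Raw narrative text for one subject."""

    subject_id: str
    raw_text: str


@dataclass(frozen=True)
class TokenSequence:
    """Ordered lowercase word tokens for one narrative.

    ``raw_token_count`` is the token count *before* stop-word removal, so
    the raw-verbosity definition of TNW remains available downstream.
    """

    subject_id: str
    tokens: tuple[str, ...]
    raw_token_count: int

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.tokens)


@dataclass(frozen=True)
class StopwordList:
    language_tag: str
    words: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        lowered = frozenset(w.lower() for w in self.words)
        object.__setattr__(self, "words", lowered)

    def __contains__(self, token: str) -> bool:
        return token in self.words


# Strip any Unicode punctuation or symbol character from token boundaries;
# internal hyphens/apostrophes survive because only the edges are trimmed.
def _is_strippable(ch: str) -> bool:
    return unicodedata.category(ch)[0] in ("P", "S")


_STRIP_CHARS = "".join(
    ch for ch in map(chr, range(sys.maxunicode + 1)) if _is_strippable(ch)
)

# En/em dashes are word separators even without surrounding whitespace
# ("Frog—where" is two words); ASCII hyphens stay word-internal.
_DASH_RE = re.compile(r"[–—―−]+")

_NUMERAL_RE = re.compile(r"^\d+([.,]\d+)*$")


def tokenize(transcript: Transcript) -> TokenSequence:
    """Split raw text into cleaned lowercase tokens.

    Lowercases, splits on whitespace (treating dash characters as
    separators), strips leading/trailing punctuation, and drops empty
    fragments.  Numerals are retained at this stage.

    Raises
    ------
    EmptyTranscriptError
        If no tokens survive cleaning.
    """
    text = _DASH_RE.sub(" ", transcript.raw_text.lower())
    tokens = []
    for frag in text.split():
        word = frag.strip(_STRIP_CHARS)
        if word:
            tokens.append(word)
    if not tokens:
        raise EmptyTranscriptError(
            f"transcript {transcript.subject_id!r} is empty after cleaning"
        )
    return TokenSequence(
        subject_id=transcript.subject_id,
        tokens=tuple(tokens),
        raw_token_count=len(tokens),
    )


def remove_stopwords(seq: TokenSequence, stops: StopwordList) -> TokenSequence:
    """Drop stop-words and bare numerals, preserving order.

    ``raw_token_count`` is carried through unchanged.  An empty result is
    legal; downstream stages guard against it.
    """
    kept = tuple(
        t for t in seq.tokens if t not in stops and not _NUMERAL_RE.match(t)
    )
    return TokenSequence(
        subject_id=seq.subject_id,
        tokens=kept,
        raw_token_count=seq.raw_token_count,
    )


def load_stopwords(path: str | Path, language_tag: str = "custom") -> StopwordList:
    """Read a stop-word file: one token per line, ``#`` comments allowed."""
    words = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip().lower()
        if line:
            words.add(line)
    return StopwordList(language_tag=language_tag, words=frozenset(words))


def default_stopwords(language_tag: str = "pt") -> StopwordList:
    """Bundled stop-word list; ``pt`` (default) or ``en``."""
    name = {"pt": "stopwords_pt.txt", "en": "stopwords_en.txt"}.get(language_tag)
    if name is None:
        raise ValueError(f"no bundled stop-word list for {language_tag!r}")
    ref = resources.files("narragraph.data").joinpath(name)
    words = frozenset(
        line.strip().lower()
        for line in ref.read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.startswith("#")
    )
    return StopwordList(language_tag=language_tag, words=words)


def read_transcript(path: str | Path) -> Transcript:
    """Load one transcript file; the filename stem is the subject id."""
    path = Path(path)
    return Transcript(subject_id=path.stem, raw_text=path.read_text(encoding="utf-8"))


def read_transcript_dir(directory: str | Path) -> list[Transcript]:
    """Load every ``*.txt`` transcript in a directory, sorted by subject id."""
    directory = Path(directory)
    return [read_transcript(p) for p in sorted(directory.glob("*.txt"))]
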