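"""Lexical resources: word-frequency tables, translation maps, orthographic similarity.

Frequency tables follow the SUBTLEX convention of occurrences per million
words.  Translation maps are static word-level lookup tables (one most-likely
translation per source word), so the pipeline is reproducible without any
online translation service.  Orthographic similarity is a normalized
edit-distance measure used as a cognateness proxy; the measure is pluggable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import edlib

from .corpus import LANGS

logger = logging.getLogger(__name__)


class TableFormatError(ValueError):
    """Raised for malformed frequency or translation files."""


@dataclass
class FrequencyTable:
    """word -> frequency per million, for one language."""

    language: str
    per_million: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for w, f in self.per_million.items():
            if f <= 0:
                raise ValueError(f"nonpositive frequency for {w!r}: {f}")

    def get(self, word: str) -> float | None:
        return self.per_million.get(word.lower())

    def __contains__(self, word: str) -> bool:
        return word.lower() in self.per_million

    def __len__(self) -> int:
        return len(self.per_million)

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for w, f in self.per_million.items():
                fh.write(f"{w}\t{f:.10g}\n")


def load_frequency_table(path: str | Path, language: str) -> FrequencyTable:
    """Load a two-column TSV ``word<TAB>per-million`` table.

    Keys are lowercased; duplicate words and nonpositive or non-numeric
    frequencies are errors (reported with the line number).
    """
    path = Path(path)
    table: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise TableFormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            word = parts[0].strip().lower()
            try:
                freq = float(parts[1])
            except ValueError as exc:
                raise TableFormatError(f"{path}:{lineno}: non-numeric frequency {parts[1]!r}") from exc
            if freq <= 0:
                raise TableFormatError(f"{path}:{lineno}: nonpositive frequency {freq}")
            if word in table:
                raise TableFormatError(f"{path}:{lineno}: duplicate word {word!r}")
            table[word] = freq
    return FrequencyTable(language=language, per_million=table)


@dataclass
class TranslationMap:
    """Directed word-level translation lookup: (word, source lang) -> translation.

    Values may be multiword phrases; downstream pair construction filters
    those out.
    """

    entries: dict[tuple[str, str], str] = field(default_factory=dict)

    def get(self, word: str, source_lang: str) -> str | None:
        return self.entries.get((word.lower(), source_lang))

    def add(self, word: str, source_lang: str, translation: str) -> None:
        if source_lang not in LANGS:
            raise ValueError(f"source_lang must be one of {LANGS}")
        self.entries[(word.lower(), source_lang)] = translation

    def __len__(self) -> int:
        return len(self.entries)

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for (word, lang), translation in self.entries.items():
                fh.write(f"{word}\t{lang}\t{translation}\n")


def load_translation_map(path: str | Path) -> TranslationMap:
    """Load a three-column TSV ``word<TAB>source_lang<TAB>translation``.

    ``source_lang`` is the abstract tag ``A`` or ``B``.  Later duplicates of
    the same (word, source_lang) key overwrite earlier ones with a warning.
    """
    path = Path(path)
    tmap = TranslationMap()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise TableFormatError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            word, lang, translation = (p.strip() for p in parts)
            if lang not in LANGS:
                raise TableFormatError(f"{path}:{lineno}: unknown source language {lang!r}")
            if (word.lower(), lang) in tmap.entries:
                logger.warning("%s:%d: duplicate translation key %r overwritten", path, lineno, word)
            tmap.add(word, lang, translation)
    return tmap


def log_frequency(f: float) -> float:
    """Base-10 log of a per-million frequency (frequencies are skewed)."""
    if f <= 0:
        raise ValueError(f"frequency must be positive, got {f}")
    return math.log10(f)


def levenshtein_distance(w1: str, w2: str) -> int:
    """Plain edit distance (insertions, deletions, substitutions)."""
    return edlib.align(w1, w2, task="distance")["editDistance"]


def orthographic_similarity(
    w1: str,
    w2: str,
    distance: Callable[[str, str], int] = levenshtein_distance,
) -> float:
    """Normalized orthographic similarity in [0, 1] as a cognateness proxy.

    Defined as ``1 - d(w1, w2) / max(|w1|, |w2|)`` with ``d`` the Levenshtein
    distance by default; symmetric, 1 for identical words, 0 for words with
    nothing in common.  Pass a different ``distance`` to plug in another
    measure.
    """
    if not w1 or not w2:
        raise ValueError("orthographic similarity of an empty string is undefined")
    d = distance(w1, w2)
    return 1.0 - d / max(len(w1), len(w2))
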