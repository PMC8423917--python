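"""Reading, validating, preprocessing and writing language-tagged bilingual corpora.

A corpus is an ordered sequence of utterances; each utterance is an ordered
sequence of tokens carrying a word form and a language tag.  The two languages
of the pair are referred to internally by the abstract tags ``A`` and ``B``;
tokens whose language cannot be determined (shared forms, proper nouns, mixed
morphology) carry the ``AMBIGUOUS`` tag.

Two on-disk dialects are supported:

``tagged``
    UTF-8, one utterance per line, optional leading ``speaker<TAB>`` field,
    then space-separated ``form/TAG`` tokens with ``TAG`` one of ``a``, ``b``,
    ``amb``.  This mirrors transcripts with hand-annotated per-word language
    identity.

``script_detect``
    Plain whitespace-tokenized text; the language of each token is inferred
    from its script.  Only valid for language pairs written in disjoint
    scripts (CJK vs. Latin).
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

logger = logging.getLogger(__name__)

#: Abstract language tags.
LANG_A = "A"
LANG_B = "B"
AMBIGUOUS = "AMBIGUOUS"

LANGS = (LANG_A, LANG_B)

_TAG_TO_LANG = {"a": LANG_A, "b": LANG_B, "amb": AMBIGUOUS}
_LANG_TO_TAG = {v: k for k, v in _TAG_TO_LANG.items()}

#: Default non-word markers stripped during preprocessing.
DEFAULT_MARKERS = frozenset({"<unk>"})


class CorpusFormatError(ValueError):
    """Raised when a corpus file violates the expected dialect."""


class Token(NamedTuple):
    form: str
    lang: str

    def is_unambiguous(self) -> bool:
        return self.lang in LANGS


@dataclass(frozen=True)
class Utterance:
    """One sentence/turn of the conversation."""

    tokens: tuple[Token, ...]
    index: int
    speaker: str | None = None

    def languages(self) -> frozenset[str]:
        """Set of unambiguous language tags present in this utterance."""
        return frozenset(t.lang for t in self.tokens if t.lang in LANGS)

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class Corpus:
    """An ordered bilingual conversation with per-token language tags."""

    utterances: tuple[Utterance, ...]
    lang_a_name: str = "L1"
    lang_b_name: str = "L2"
    source: str = ""

    def __post_init__(self) -> None:
        for i, utt in enumerate(self.utterances):
            if utt.index != i:
                raise ValueError(
                    f"utterance indices must form 0..n-1; got {utt.index} at position {i}"
                )
            for tok in utt.tokens:
                if tok.lang not in (LANG_A, LANG_B, AMBIGUOUS):
                    raise ValueError(f"unknown language tag {tok.lang!r}")

    def __len__(self) -> int:
        return len(self.utterances)

    def __iter__(self) -> Iterator[Utterance]:
        return iter(self.utterances)

    def tokens(self) -> Iterator[Token]:
        for utt in self.utterances:
            yield from utt.tokens

    def n_tokens(self) -> int:
        return sum(len(u) for u in self.utterances)

    def lang_name(self, lang: str) -> str:
        """Human-readable name for an abstract tag."""
        if lang == LANG_A:
            return self.lang_a_name
        if lang == LANG_B:
            return self.lang_b_name
        return "other"

    def vocabulary(self) -> set[tuple[str, str]]:
        """Unique (form, lang) pairs over all tokens."""
        return {(t.form, t.lang) for t in self.tokens()}


# ---------------------------------------------------------------------------
# script detection
# ---------------------------------------------------------------------------

_CJK_RANGES = (
    (0x3400, 0x4DBF),   # CJK extension A
    (0x4E00, 0x9FFF),   # CJK unified
    (0xF900, 0xFAFF),   # compatibility ideographs
    (0x20000, 0x2A6DF),  # extension B
    (0x3040, 0x30FF),   # kana (defensive; not expected in Mandarin data)
)


def _char_class(ch: str) -> str:
    cp = ord(ch)
    for lo, hi in _CJK_RANGES:
        if lo <= cp <= hi:
            return "cjk"
    cat = unicodedata.category(ch)
    if cat.startswith(("P", "M", "Z")) or cat in ("Sk", "Sm", "So", "Sc"):
        return "neutral"
    if cat == "Nd":
        return "digit"
    if cat.startswith("L"):
        name = unicodedata.name(ch, "")
        if name.startswith("LATIN"):
            return "latin"
        return "other"
    return "other"


def detect_language_by_script(form: str, cjk_lang: str = LANG_A) -> str:
    """Infer the language tag of ``form`` from its script.

    All-CJK forms belong to ``cjk_lang``, all-Latin forms to the other
    language; all-digit, mixed-script or otherwise unclassifiable forms are
    ``AMBIGUOUS`` (digits carry no language identity).  Punctuation, marks and
    symbols attached to the form are ignored when deciding.
    """
    if not form:
        raise ValueError("cannot detect language of an empty string")
    if cjk_lang not in LANGS:
        raise ValueError(f"cjk_lang must be one of {LANGS}")
    latin_lang = LANG_B if cjk_lang == LANG_A else LANG_A
    classes = {_char_class(ch) for ch in form}
    classes.discard("neutral")
    if classes == {"cjk"}:
        return cjk_lang
    if classes == {"latin"}:
        return latin_lang
    return AMBIGUOUS


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def read_corpus(
    path: str | Path,
    format: str = "tagged",
    lang_names: tuple[str, str] = ("L1", "L2"),
    cjk_lang: str = LANG_A,
) -> Corpus:
    """Read a corpus file in the ``tagged`` or ``script_detect`` dialect.

    Forms are lowercased on input.  In ``script_detect`` mode ``cjk_lang``
    names the abstract tag that owns the CJK script; the mode is only
    meaningful for script-disjoint pairs, so requesting it with a pair of
    Latin-script language names raises ``CorpusFormatError``.
    """
    path = Path(path)
    if format not in ("tagged", "script_detect"):
        raise ValueError(f"unknown corpus format {format!r}")
    utterances: list[Utterance] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            speaker: str | None = None
            body = line
            if "\t" in line:
                speaker, body = line.split("\t", 1)
                speaker = speaker.strip() or None
            tokens: list[Token] = []
            for raw in body.split():
                if format == "tagged":
                    if "/" not in raw:
                        raise CorpusFormatError(
                            f"{path}:{lineno}: token {raw!r} has no /TAG annotation"
                        )
                    form, tag = raw.rsplit("/", 1)
                    tag = tag.lower()
                    if tag not in _TAG_TO_LANG:
                        raise CorpusFormatError(
                            f"{path}:{lineno}: unknown language tag {tag!r} in {raw!r}"
                        )
                    if not form:
                        raise CorpusFormatError(
                            f"{path}:{lineno}: empty form in token {raw!r}"
                        )
                    tokens.append(Token(form.lower(), _TAG_TO_LANG[tag]))
                else:
                    tokens.append(
                        Token(raw.lower(), detect_language_by_script(raw, cjk_lang))
                    )
            utterances.append(
                Utterance(tokens=tuple(tokens), index=len(utterances), speaker=speaker)
            )
    return Corpus(
        utterances=tuple(utterances),
        lang_a_name=lang_names[0],
        lang_b_name=lang_names[1],
        source=str(path),
    )


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus in the ``tagged`` dialect (inverse of ``read_corpus``)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for utt in corpus.utterances:
            prefix = f"{utt.speaker}\t" if utt.speaker else ""
            body = " ".join(f"{t.form}/{_LANG_TO_TAG[t.lang]}" for t in utt.tokens)
            fh.write(prefix + body + "\n")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _is_punctuation(form: str) -> bool:
    return all(unicodedata.category(ch).startswith("P") for ch in form)


def _strip_edge_punctuation(form: str) -> str:
    start, end = 0, len(form)
    while start < end and unicodedata.category(form[start]).startswith("P"):
        start += 1
    while end > start and unicodedata.category(form[end - 1]).startswith("P"):
        end -= 1
    return form[start:end]


@dataclass
class PreprocessLog:
    """Counts of what preprocessing removed."""

    markers: int = 0
    communicators: int = 0
    punctuation: int = 0
    emptied_utterances: int = 0


def preprocess(
    corpus: Corpus,
    marker_set: Iterable[str] = DEFAULT_MARKERS,
    communicator_set: Iterable[str] = (),
) -> Corpus:
    """Remove non-word markers, discourse communicators and punctuation.

    Forms are lowercased and stripped of leading/trailing punctuation
    characters; tokens reduced to nothing (or consisting entirely of
    punctuation) are dropped, as are tokens in ``marker_set`` or
    ``communicator_set``.  Utterances emptied by filtering are removed and the
    remaining utterances re-indexed.  The operation is idempotent.
    """
    markers = {m.lower() for m in marker_set}
    communicators = {c.lower() for c in communicator_set}
    log = PreprocessLog()
    new_utts: list[Utterance] = []
    for utt in corpus.utterances:
        kept: list[Token] = []
        for tok in utt.tokens:
            form = tok.form.lower()
            if form in markers:
                log.markers += 1
                continue
            stripped = _strip_edge_punctuation(form)
            if not stripped or _is_punctuation(stripped):
                log.punctuation += 1
                continue
            if stripped in markers:
                log.markers += 1
                continue
            if stripped in communicators:
                log.communicators += 1
                continue
            kept.append(Token(stripped, tok.lang))
        if kept:
            new_utts.append(
                Utterance(tokens=tuple(kept), index=len(new_utts), speaker=utt.speaker)
            )
        else:
            log.emptied_utterances += 1
    logger.info(
        "preprocess: removed %d markers, %d communicators, %d punctuation tokens; "
        "dropped %d emptied utterances",
        log.markers,
        log.communicators,
        log.punctuation,
        log.emptied_utterances,
    )
    return replace(corpus, utterances=tuple(new_utts))
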