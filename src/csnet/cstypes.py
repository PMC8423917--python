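"""Classification of code-switching sentence types and extraction of CS words.

Three sentence types are distinguished in bilingual speech: sentences with no
switch (non-CS), sentences mixing unambiguous words of both languages
(intra-sentential CS), and monolingual sentences in a language different from
the immediately preceding sentence (inter-sentential CS).  Only words with an
unambiguous language identity participate in classification — the
conservative rule needed when corpora contain shared or ambiguous forms.

A *CS word* is a word produced in a language different from the immediately
preceding word within the same sentence; its *translation equivalent* (TE) is
the word of the other language that it replaced.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .corpus import LANG_A, LANG_B, LANGS, Corpus

logger = logging.getLogger(__name__)


class CSType(enum.Enum):
    NON_CS = "non_cs"
    INTRA_SENTENTIAL = "intra_sentential"
    INTER_SENTENTIAL = "inter_sentential"


@dataclass(frozen=True)
class SwitchEvent:
    """A token produced in a different language than its predecessor."""

    utterance_index: int
    position: int  # 0-based token index of the CS word, >= 1
    cs_form: str
    cs_lang: str
    prev_form: str
    prev_lang: str

    def __post_init__(self) -> None:
        if self.cs_lang not in LANGS or self.prev_lang not in LANGS:
            raise ValueError("switch events require unambiguous languages")
        if self.cs_lang == self.prev_lang:
            raise ValueError("cs_lang must differ from prev_lang")
        if self.position < 1:
            raise ValueError("position must be >= 1")


@dataclass(frozen=True)
class CSPairRecord:
    """A unique CS word with its single-word translation equivalent."""

    cs_form: str
    cs_lang: str
    te_form: str
    te_lang: str
    direction: str  # "<cs lang name>-<te lang name>"


def classify_cs_types(corpus: Corpus) -> list[CSType]:
    """Label every utterance as non-CS, intra- or inter-sentential CS.

    An utterance is intra-sentential iff it contains at least one unambiguous
    word of each language.  Otherwise it is inter-sentential iff it contains
    an unambiguous word in a language not present among the unambiguous
    languages of the immediately preceding utterance (the first utterance can
    never be inter-sentential).  Everything else — including utterances with
    no unambiguous word at all — is non-CS.
    """
    types: list[CSType] = []
    prev_langs: frozenset[str] | None = None
    for utt in corpus.utterances:
        langs = utt.languages()
        if LANG_A in langs and LANG_B in langs:
            types.append(CSType.INTRA_SENTENTIAL)
        elif prev_langs is not None and (langs - prev_langs):
            types.append(CSType.INTER_SENTENTIAL)
        else:
            types.append(CSType.NON_CS)
        prev_langs = langs
    return types


def count_cs_types(types: Sequence[CSType], corpus: Corpus) -> pd.DataFrame:
    """Tabulate sentence and word-token statistics per CS type.

    Returns one row per CS type with the sentence count, the percentage of
    all sentences, and the percentages of word tokens in each language within
    that type (ambiguous tokens are the implicit remainder).
    """
    if len(corpus) == 0:
        raise ValueError("cannot tabulate an empty corpus")
    if len(types) != len(corpus):
        raise ValueError("types must align with corpus utterances")
    rows = []
    n_utts = len(corpus)
    for cs_type in CSType:
        utts = [u for u, t in zip(corpus.utterances, types) if t is cs_type]
        n_tok = sum(len(u) for u in utts)
        n_a = sum(1 for u in utts for tok in u.tokens if tok.lang == LANG_A)
        n_b = sum(1 for u in utts for tok in u.tokens if tok.lang == LANG_B)
        rows.append(
            {
                "cs_type": cs_type.value,
                "n_sentences": len(utts),
                "pct_sentences": 100.0 * len(utts) / n_utts,
                f"pct_tokens_{corpus.lang_a_name}": (100.0 * n_a / n_tok) if n_tok else 0.0,
                f"pct_tokens_{corpus.lang_b_name}": (100.0 * n_b / n_tok) if n_tok else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("cs_type")


def extract_switch_events(corpus: Corpus) -> list[SwitchEvent]:
    """All within-sentence switch points of the corpus.

    An event occurs at token position *i* iff both token *i* and token *i−1*
    have unambiguous language identities and those identities differ;
    ambiguous tokens neither trigger events nor transmit language context,
    and events never cross utterance boundaries.
    """
    events: list[SwitchEvent] = []
    for utt in corpus.utterances:
        for i in range(1, len(utt.tokens)):
            cur, prev = utt.tokens[i], utt.tokens[i - 1]
            if cur.lang in LANGS and prev.lang in LANGS and cur.lang != prev.lang:
                events.append(
                    SwitchEvent(
                        utterance_index=utt.index,
                        position=i,
                        cs_form=cur.form,
                        cs_lang=cur.lang,
                        prev_form=prev.form,
                        prev_lang=prev.lang,
                    )
                )
    return events


def build_cs_te_pairs(
    events: Sequence[SwitchEvent],
    translations,
    lang_names: tuple[str, str] = ("L1", "L2"),
) -> tuple[dict[str, list[CSPairRecord]], Counter]:
    """Unique CS words with single-word TEs, grouped by switch direction.

    Uniqueness is type-level per (form, language).  CS words whose
    translation is missing from ``translations`` or is a multiword phrase are
    excluded; exclusion counts are returned (``no_translation``,
    ``multiword_te``), never raised.
    """
    name = {LANG_A: lang_names[0], LANG_B: lang_names[1]}
    seen: set[tuple[str, str]] = set()
    exclusions: Counter = Counter()
    pairs: dict[str, list[CSPairRecord]] = {}
    for ev in events:
        key = (ev.cs_form, ev.cs_lang)
        if key in seen:
            continue
        seen.add(key)
        te_lang = LANG_B if ev.cs_lang == LANG_A else LANG_A
        te = translations.get(ev.cs_form, ev.cs_lang)
        direction = f"{name[ev.cs_lang]}-{name[te_lang]}"
        if te is None:
            exclusions["no_translation"] += 1
            continue
        te = te.strip().lower()
        if " " in te or not te:
            exclusions["multiword_te"] += 1
            continue
        pairs.setdefault(direction, []).append(
            CSPairRecord(
                cs_form=ev.cs_form,
                cs_lang=ev.cs_lang,
                te_form=te,
                te_lang=te_lang,
                direction=direction,
            )
        )
    logger.info(
        "build_cs_te_pairs: %s pairs by direction, exclusions %s",
        {d: len(v) for d, v in pairs.items()},
        dict(exclusions),
    )
    return pairs, exclusions
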