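"""Synthetic bilingual code-switching corpora with known ground truth.

The generator emulates the statistical structure of tagged bilingual speech
transcripts: two languages sharing a concept inventory (each concept has one
word form per language, a bijective translation pair), Zipfian concept
frequencies, topic structure that induces language-dominant semantic
communities (each topic has a dominant language that seeds its utterances),
a first-order language chain with stay probability ``p_stay``, a small
proportion of ambiguous-language tokens, and a planted *accessibility*
effect: the probability of switching into the other language at a given
concept is modulated on the log-odds scale by that concept's
target-language clustering propensity (``beta_C``) and log frequency
(``beta_F``).  With ``beta_C`` negative, words that get switched into are
enriched for low clustering propensity — the effect the analysis pipeline
is supposed to recover, at the sign level.

The clustering propensity is a per-(concept, language) score in (0, 1)
rather than a corpus co-occurrence count, because a language-shared proxy
would be identical for a CS word and its translation equivalent and could
never produce a CS-TE contrast.  ``generate_vectors`` builds matched
"pretrained-style" per-language embedding tables in which a low-propensity
word is blended between two topic directions (its neighborhood splits into
two mutually unconnected cliques) while a high-propensity word sits inside
one tight topic clique, so realized network clustering tracks the planted
score.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import AMBIGUOUS, LANG_A, LANG_B, Corpus, Token, Utterance
from .embedding import EmbeddingTable
from .lexicon import FrequencyTable, TranslationMap
from .stats import PairedSample

logger = logging.getLogger(__name__)

_CONSONANTS = "ptkmnsl"
_VOWELS = "aeiou"


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic bilingual corpus.

    ``utterance_length`` is the mean of a shifted-Poisson length law
    (minimum 1 token).  ``topic_language_bias`` is the probability that an
    utterance opens in its topic's dominant language.  ``cognate_rate`` is
    the fraction of concepts whose two forms are orthographic neighbors,
    giving the cognateness analysis a non-constant predictor.
    """

    n_concepts: int = 400
    n_topics: int = 8
    n_function_words: int = 25
    zipf_exponent: float = 1.0
    p_stay: float = 0.8
    dominance_boost: float = 1.5
    p_ambiguous: float = 0.0
    utterance_length: float = 8.0
    n_utterances: int = 2000
    beta_C: float = 0.0
    beta_F: float = 0.0
    topic_language_bias: float = 0.75
    topic_persistence: float = 0.85
    language_affinity: float = 0.8
    freq_jitter_sd: float = 0.3
    cognate_rate: float = 0.25
    lang_a_name: str = "lang-a"
    lang_b_name: str = "lang-b"
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.p_stay,
            self.p_ambiguous,
            self.topic_language_bias,
            self.topic_persistence,
            self.cognate_rate,
            self.language_affinity,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probabilities must lie in [0, 1], got {p}")
        if not self.n_concepts >= self.n_topics >= 1:
            raise ValueError("need n_concepts >= n_topics >= 1")
        if not 0 <= self.n_function_words <= self.n_concepts - 2 * self.n_topics:
            raise ValueError("n_function_words leaves too few topic concepts")
        if self.dominance_boost < 0:
            raise ValueError("dominance_boost must be >= 0")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be positive")
        if self.utterance_length < 1:
            raise ValueError("utterance_length must be >= 1")
        if self.n_utterances < 1:
            raise ValueError("n_utterances must be >= 1")
        if self.freq_jitter_sd < 0:
            raise ValueError("freq_jitter_sd must be >= 0")


def seame_like(**overrides) -> GeneratorConfig:
    """High intra-sentential switching, script-separable pair, no ambiguous tags."""
    base = dict(
        p_stay=0.8,
        p_ambiguous=0.0,
        n_utterances=4000,
        lang_a_name="mandarin",
        lang_b_name="english",
    )
    base.update(overrides)
    return GeneratorConfig(**base)


def miami_like(**overrides) -> GeneratorConfig:
    """Rare switching, hand-tagged pair with ambiguous shared forms."""
    base = dict(
        p_stay=0.97,
        p_ambiguous=0.05,
        topic_language_bias=0.9,
        n_utterances=4000,
        lang_a_name="spanish",
        lang_b_name="english",
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@dataclass
class GoldRecord:
    """Ground truth of a generated corpus.

    ``concepts`` has one row per concept: forms in both languages, topic,
    per-language per-million frequencies, planted clustering propensities
    (``proxy_a``/``proxy_b``), the concept sampling probability, and
    realized token counts.  ``topic_lang`` holds each topic's dominant
    language tag.
    """

    concepts: pd.DataFrame
    topic_lang: np.ndarray
    config: GeneratorConfig

    def form_to_concept(self) -> dict[tuple[str, str], int]:
        out = {}
        for row in self.concepts.itertuples():
            out[(row.form_a, LANG_A)] = row.concept
            out[(row.form_b, LANG_B)] = row.concept
        return out


def _make_form(rng: np.random.Generator, used: set[str]) -> str:
    for _ in range(1000):
        n_syll = int(rng.integers(1, 4))
        form = "".join(
            _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[rng.integers(len(_VOWELS))]
            for _ in range(n_syll)
        )
        if form not in used:
            used.add(form)
            return form
    # pathological collision streak: disambiguate deterministically
    form = form + str(len(used))
    used.add(form)
    return form


def _mutate_form(rng: np.random.Generator, form: str, used: set[str]) -> str:
    alphabet = _CONSONANTS + _VOWELS
    for _ in range(1000):
        chars = list(form)
        pos = int(rng.integers(len(chars)))
        chars[pos] = alphabet[rng.integers(len(alphabet))]
        cand = "".join(chars)
        if cand != form and cand not in used:
            used.add(cand)
            return cand
    return _make_form(rng, used)


def _switch_base_logit(p_stay: float) -> float:
    p_sw = 1.0 - p_stay
    if p_sw <= 0.0:
        return -np.inf
    if p_sw >= 1.0:
        return np.inf
    return math.log(p_sw / (1.0 - p_sw))


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[Corpus, GoldRecord, TranslationMap, dict[str, FrequencyTable]]:
    """Generate a tagged bilingual corpus plus its companion resources.

    Deterministic given ``config.seed``.  Returns the corpus, the gold
    record, a bidirectional word-level translation map, and one per-million
    frequency table per language (theoretical frequencies with independent
    per-language log-normal jitter, so translation pairs differ in
    frequency the way independent norms would).
    """
    rng = np.random.default_rng(config.seed)
    nc, nt = config.n_concepts, config.n_topics

    # word forms (globally unique across both languages)
    used: set[str] = set()
    form_a = [_make_form(rng, used) for _ in range(nc)]
    form_b = []
    for c in range(nc):
        if rng.random() < config.cognate_rate:
            form_b.append(_mutate_form(rng, form_a[c], used))
        else:
            form_b.append(_make_form(rng, used))

    # Zipfian concept probabilities (rank assigned at random); the top
    # ranks are language-specific *function words*, emitted from any topic —
    # they provide the high-frequency within-language glue that makes each
    # language cohere across topics, as closed-class words do in real speech
    ranks = rng.permutation(nc)
    p_concept = (ranks + 1.0) ** -config.zipf_exponent
    p_concept /= p_concept.sum()
    pm = p_concept * 1e6
    is_function = ranks < config.n_function_words

    # topics: skewed sizes over content concepts, alternating dominant language
    topic_probs = (np.arange(nt) + 1.0) ** -0.8
    topic_probs /= topic_probs.sum()
    topic_of = rng.choice(nt, size=nc, p=topic_probs)
    topic_of[is_function] = -1
    # guarantee every topic at least two content concepts
    for t in range(nt):
        while np.sum(topic_of == t) < 2:
            sizes = np.bincount(topic_of[topic_of >= 0], minlength=nt)
            movable = np.nonzero(topic_of == int(np.argmax(sizes)))[0]
            topic_of[movable[int(rng.integers(len(movable)))]] = t
    topic_lang = np.array([LANG_A if t % 2 == 0 else LANG_B for t in range(nt)])
    jitter_a = 10.0 ** rng.normal(0.0, config.freq_jitter_sd, nc)
    jitter_b = 10.0 ** rng.normal(0.0, config.freq_jitter_sd, nc)
    pm_a, pm_b = pm * jitter_a, pm * jitter_b

    # planted per-(concept, language) clustering propensity
    proxy_a = rng.beta(2.0, 2.0, nc)
    proxy_b = rng.beta(2.0, 2.0, nc)

    def _z(v: np.ndarray) -> np.ndarray:
        return (v - v.mean()) / v.std(ddof=1)

    z_proxy = {LANG_A: _z(proxy_a), LANG_B: _z(proxy_b)}
    z_logf = {LANG_A: _z(np.log10(pm_a)), LANG_B: _z(np.log10(pm_b))}
    forms = {LANG_A: form_a, LANG_B: form_b}
    base_logit = _switch_base_logit(config.p_stay)

    # per-concept language affinity: most content words are habitually
    # realized in one language; the other-language form exists (it is the
    # translation equivalent) but is produced far less often
    affinity = rng.choice([LANG_A, LANG_B], size=nc)

    # per-(topic, language) content pools: within-topic Zipf weights skewed
    # toward concepts whose affinity matches the current language
    pools: dict[tuple[int, str], tuple[np.ndarray, np.ndarray]] = {}
    topic_members = []
    for t in range(nt):
        members = np.nonzero(topic_of == t)[0]
        topic_members.append(members)
        for lang in (LANG_A, LANG_B):
            w = p_concept[members] * np.where(
                affinity[members] == lang,
                config.language_affinity,
                1.0 - config.language_affinity,
            )
            pools[(t, lang)] = (members, w / w.sum())
    topic_mass = np.array([p_concept[m].sum() for m in topic_members])
    topic_mass /= topic_mass.sum()
    fn_members = np.nonzero(is_function)[0]
    fn_mass = float(p_concept[fn_members].sum()) if len(fn_members) else 0.0
    fn_weights = (
        p_concept[fn_members] / p_concept[fn_members].sum() if len(fn_members) else None
    )

    counts = {LANG_A: np.zeros(nc, dtype=int), LANG_B: np.zeros(nc, dtype=int)}
    utterances: list[Utterance] = []
    other = {LANG_A: LANG_B, LANG_B: LANG_A}
    t: int | None = None
    matrix = LANG_A
    for _ in range(config.n_utterances):
        # conversations dwell on a topic for several utterances; the matrix
        # language of the dwell is usually the topic's dominant language,
        # and within-utterance switches are pulled back toward it
        if t is None or rng.random() >= config.topic_persistence:
            t = int(rng.choice(nt, p=topic_mass))
            matrix = (
                topic_lang[t]
                if rng.random() < config.topic_language_bias
                else other[topic_lang[t]]
            )
        length = 1 + int(rng.poisson(config.utterance_length - 1.0))
        lang = matrix
        tokens: list[Token] = []
        for i in range(length):
            if fn_weights is not None and rng.random() < fn_mass:
                c = int(rng.choice(fn_members, p=fn_weights))
            else:
                members, weights = pools[(t, lang)]
                c = int(rng.choice(members, p=weights))
            if i > 0:
                target = other[lang]
                logit = base_logit
                if np.isfinite(logit):
                    # switching back toward the topic's dominant (matrix)
                    # language is easier than switching out of it
                    boost = (
                        config.dominance_boost
                        if target == matrix
                        else -config.dominance_boost
                    )
                    logit = (
                        logit
                        + boost
                        + config.beta_C * z_proxy[target][c]
                        + config.beta_F * z_logf[target][c]
                    )
                p_sw = 1.0 / (1.0 + math.exp(-logit)) if np.isfinite(logit) else (
                    0.0 if logit < 0 else 1.0
                )
                if rng.random() < p_sw:
                    lang = target
            counts[lang][c] += 1
            tag = AMBIGUOUS if rng.random() < config.p_ambiguous else lang
            tokens.append(Token(forms[lang][c], tag))
        utterances.append(Utterance(tokens=tuple(tokens), index=len(utterances)))

    corpus = Corpus(
        utterances=tuple(utterances),
        lang_a_name=config.lang_a_name,
        lang_b_name=config.lang_b_name,
        source=f"synthetic(seed={config.seed})",
    )

    tmap = TranslationMap()
    for c in range(nc):
        tmap.add(form_a[c], LANG_A, form_b[c])
        tmap.add(form_b[c], LANG_B, form_a[c])

    freq = {
        LANG_A: FrequencyTable(LANG_A, {form_a[c]: float(pm_a[c]) for c in range(nc)}),
        LANG_B: FrequencyTable(LANG_B, {form_b[c]: float(pm_b[c]) for c in range(nc)}),
    }

    gold = GoldRecord(
        concepts=pd.DataFrame(
            {
                "concept": np.arange(nc),
                "form_a": form_a,
                "form_b": form_b,
                "topic": topic_of,
                "affinity": affinity,
                "p_concept": p_concept,
                "pm_a": pm_a,
                "pm_b": pm_b,
                "proxy_a": proxy_a,
                "proxy_b": proxy_b,
                "count_a": counts[LANG_A],
                "count_b": counts[LANG_B],
            }
        ),
        topic_lang=topic_lang,
        config=config,
    )
    return corpus, gold, tmap, freq


def generate_vectors(
    gold: GoldRecord,
    dim: int = 50,
    seed: int = 0,
    noise: float = 0.25,
    te_align: float = 0.2,
) -> dict[str, EmbeddingTable]:
    """Per-language "pretrained-style" embedding tables matched to the gold record.

    A word with clustering propensity 1 lies on its topic's direction: all
    its strong neighbors are topic-mates that interconnect, so its network
    clustering coefficient is high.  A word with propensity 0 is an even
    blend of its topic direction and a second, unrelated topic direction:
    its neighborhood splits into two groups with no edges between them,
    which is exactly the low-clustering configuration.  Propensities in
    between interpolate the blend.  A small shared concept offset
    (``te_align``) keeps translation pairs similar, and isotropic noise of
    scale ``noise`` roughens everything.  Function words (no topic) get a
    random pseudo-topic per concept.
    """
    rng = np.random.default_rng(seed)
    nt = len(gold.topic_lang)
    nc = len(gold.concepts)
    if nt > dim:
        raise ValueError("need dim >= number of topics")
    # topic directions in simplex configuration: pairwise cosine -1/(nt-1),
    # so cross-topic word pairs land below zero and are pruned as non-edges
    basis = np.zeros((nt, dim))
    basis[np.arange(nt), np.arange(nt)] = 1.0
    mu = basis - basis.mean(axis=0, keepdims=True)
    mu /= np.linalg.norm(mu, axis=1, keepdims=True)
    q, _ = np.linalg.qr(rng.normal(size=(dim, dim)))
    mu = mu @ q  # random rotation for genericity
    delta = rng.normal(size=(nc, dim)) / math.sqrt(dim)

    topics = gold.concepts["topic"].to_numpy().copy()
    pseudo = rng.integers(0, nt, size=nc)
    topics = np.where(topics < 0, pseudo, topics)

    tables = {}
    for lang, form_col, proxy_col in (
        (LANG_A, "form_a", "proxy_a"),
        (LANG_B, "form_b", "proxy_b"),
    ):
        proxies = gold.concepts[proxy_col].to_numpy()
        # secondary topic per (concept, language), never the primary one
        second = rng.integers(0, nt - 1, size=nc) if nt > 1 else topics
        if nt > 1:
            second = np.where(second >= topics, second + 1, second)
        alpha = 0.5 + 0.5 * proxies  # 0.5 = even two-topic blend, 1 = pure
        eps = rng.normal(size=(nc, dim)) / math.sqrt(dim)
        vecs = (
            alpha[:, None] * mu[topics]
            + (1.0 - alpha)[:, None] * mu[second]
            + te_align * delta
            + noise * eps
        )
        tables[lang] = EmbeddingTable(list(gold.concepts[form_col]), vecs)
    return tables


def generate_paired_sample(
    n_items: int,
    delta: float,
    sigma: float,
    seed: int = 0,
    directions: tuple = ("d1", "d2"),
    p_first: float = 0.5,
) -> PairedSample:
    """Paired CS/TE values with a planted mean difference ``delta``.

    TE values are standard normal; CS values add ``delta`` plus
    N(0, sigma^2) noise.  Direction labels split the items in proportion
    ``p_first`` (deterministic sizes).
    """
    if n_items < 2:
        raise ValueError("n_items must be >= 2")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not 0.0 <= p_first <= 1.0:
        raise ValueError("p_first must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    te = rng.normal(0.0, 1.0, n_items)
    cs = te + delta + rng.normal(0.0, sigma, n_items)
    n1 = int(round(n_items * p_first))
    labels = np.array([directions[0]] * n1 + [directions[1]] * (n_items - n1))
    return PairedSample(value_cs=cs, value_te=te, direction=labels)


def write_dataset(
    out_dir: str | Path,
    config: GeneratorConfig,
    vector_dim: int = 50,
) -> dict[str, Path]:
    """Generate a full dataset and write every artifact as text files.

    Writes the tagged corpus, translation map, per-language frequency
    tables and vector files, the gold concept table, and a manifest JSON
    recording the config and seed.  Returns the path of each artifact.
    """
    from .corpus import write_corpus  # local import to avoid cycle at module load

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    corpus, gold, tmap, freq = generate_corpus(config)
    vectors = generate_vectors(gold, dim=vector_dim, seed=config.seed)
    paths = {
        "corpus": out / "corpus.txt",
        "translations": out / "translations.tsv",
        "freq_a": out / "freq_a.tsv",
        "freq_b": out / "freq_b.tsv",
        "vectors_a": out / "vectors_a.txt",
        "vectors_b": out / "vectors_b.txt",
        "gold": out / "gold.tsv",
        "manifest": out / "manifest.json",
    }
    write_corpus(corpus, paths["corpus"])
    tmap.save(paths["translations"])
    freq[LANG_A].save(paths["freq_a"])
    freq[LANG_B].save(paths["freq_b"])
    vectors[LANG_A].save(paths["vectors_a"])
    vectors[LANG_B].save(paths["vectors_b"])
    gold.concepts.to_csv(paths["gold"], sep="\t", index=False)
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump({"config": asdict(config), "vector_dim": vector_dim}, fh, indent=2)
    return paths
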