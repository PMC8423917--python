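"""End-to-end orchestration of the three analyses.

Study 1: community structure of the bilingual lexicon.  Build a weighted
semantic network over all unique words of the selected sentences (all
sentences, or intra-sentential CS sentences only), detect communities, and
summarize the language composition of each community.

Study 2: clustering-coefficient and frequency effects on language choice.
Extract unique CS-word/translation-equivalent pairs per switch direction,
apply the exclusion chain (multiword or missing translations, missing
frequencies, missing vectors), build one semantic network per language over
the retained words, compute each word's weighted clustering coefficient,
z-score it within its language, residualize against log frequency (and
vice versa), and run the mixed ANOVA, per-direction paired t-tests and
sign tests.

Study 3: cognateness.  Label every produced word CS or non-CS (a single
switch use suffices for CS), measure the orthographic similarity to its
translation equivalent, and fit a logistic regression of class on
similarity.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .community import CommunityPartition, community_composition, louvain
from .corpus import LANGS, Corpus
from .cstypes import (
    CSType,
    build_cs_te_pairs,
    classify_cs_types,
    count_cs_types,
    extract_switch_events,
)
from .embedding import EmbeddingConfig, EmbeddingTable, train_sgns
from .lexicon import FrequencyTable, TranslationMap, log_frequency, orthographic_similarity
from .semnet import SemanticNetwork, build_network, clustering_coefficients
from .stats import (
    PairedSample,
    TestResult,
    logistic_fit,
    mixed_anova_2x2,
    paired_t,
    pearson,
    residualize,
    sign_test,
    zscore,
)

logger = logging.getLogger(__name__)


def _jsonable(obj):
    if isinstance(obj, TestResult):
        return obj.to_dict()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# Study 1
# ---------------------------------------------------------------------------


@dataclass
class Study1Report:
    """CS-type table plus community structure of one network variant."""

    cs_type_table: pd.DataFrame
    sentence_filter: str
    n_nodes: int
    n_edges: int
    partition: CommunityPartition
    composition: pd.DataFrame
    Q: float
    seed: int

    def community_purities(self) -> list[float]:
        """Max single-language percentage per community, largest first."""
        return [
            max(row.pct_l1, row.pct_l2) for row in self.composition.itertuples()
        ]

    def to_json(self, path: str | Path | None = None) -> dict:
        payload = {
            "sentence_filter": self.sentence_filter,
            "seed": self.seed,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "Q": self.Q,
            "n_communities": self.partition.n_communities(),
            "cs_type_table": _jsonable(self.cs_type_table.reset_index()),
            "composition": _jsonable(self.composition),
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")
        return payload


def run_study1(
    corpus: Corpus,
    embed_config: EmbeddingConfig | None = None,
    vectors: EmbeddingTable | None = None,
    sentence_filter: str = "all",
    seed: int = 0,
) -> Study1Report:
    """Community analysis of the bilingual lexicon.

    Vectors are trained on the whole (preprocessed) corpus unless a table is
    supplied; the network nodes are the unique (form, tag) pairs of the
    sentences selected by ``sentence_filter`` ("all" or "intra_only"),
    with ambiguous-tagged words reported as "other" in the composition.
    """
    if sentence_filter not in ("all", "intra_only"):
        raise ValueError(f"unknown sentence filter {sentence_filter!r}")
    types = classify_cs_types(corpus)
    table = count_cs_types(types, corpus)
    if vectors is None:
        config = embed_config or EmbeddingConfig(seed=seed)
        vectors = train_sgns(corpus, config)
    if sentence_filter == "intra_only":
        utts = [u for u, t in zip(corpus.utterances, types) if t is CSType.INTRA_SENTENTIAL]
    else:
        utts = list(corpus.utterances)
    words = sorted({(tok.form, tok.lang) for u in utts for tok in u.tokens})
    if len(words) < 2:
        raise ValueError("sentence filter leaves fewer than 2 words")
    net = build_network(words, vectors)
    partition = louvain(net, seed=seed)
    tags = {
        node: (corpus.lang_name(node[1]) if node[1] in LANGS else "other")
        for node in net.graph.nodes
    }
    composition = community_composition(
        partition, tags, l1=corpus.lang_a_name, l2=corpus.lang_b_name
    )
    return Study1Report(
        cs_type_table=table,
        sentence_filter=sentence_filter,
        n_nodes=net.n_nodes(),
        n_edges=net.n_edges(),
        partition=partition,
        composition=composition,
        Q=partition.Q,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Study 2
# ---------------------------------------------------------------------------


@dataclass
class Study2Report:
    """Per-direction paired comparisons of clustering and frequency.

    ``pairs`` is the fully retained pair table with every covariate used by
    the tests, so each reported statistic is recomputable from the report
    itself.  ``filter_log`` records how many candidate pairs each exclusion
    removed.
    """

    pairs: pd.DataFrame
    filter_log: dict
    correlation: TestResult
    anova_cz: dict[str, TestResult]
    anova_logf: dict[str, TestResult]
    paired_cz: dict[str, TestResult]
    paired_logf: dict[str, TestResult]
    sign_cz: dict[str, TestResult]
    sign_logf: dict[str, TestResult]
    networks: dict[str, SemanticNetwork] = field(default_factory=dict)

    def mean_res_cz_diff(self, direction: str) -> float:
        sub = self.pairs[self.pairs["direction"] == direction]
        return float((sub["res_cz_cs"] - sub["res_cz_te"]).mean())

    def to_json(self, path: str | Path | None = None) -> dict:
        payload = {
            "filter_log": _jsonable(self.filter_log),
            "n_pairs": _jsonable(
                self.pairs.groupby("direction").size().to_dict()
            ),
            "correlation": self.correlation.to_dict(),
            "anova_res_cz": _jsonable(self.anova_cz),
            "anova_res_logf": _jsonable(self.anova_logf),
            "paired_t_res_cz": _jsonable(self.paired_cz),
            "paired_t_res_logf": _jsonable(self.paired_logf),
            "sign_res_cz": _jsonable(self.sign_cz),
            "sign_res_logf": _jsonable(self.sign_logf),
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")
        return payload


def _sign_counts(diff: np.ndarray) -> tuple[int, int]:
    lower = int(np.sum(diff < 0))
    higher = int(np.sum(diff > 0))
    return lower, higher


def run_study2(
    corpus: Corpus,
    translations: TranslationMap,
    frequencies: Mapping[str, FrequencyTable],
    vectors: Mapping[str, EmbeddingTable],
) -> Study2Report:
    """Clustering-coefficient and frequency effects on switch direction.

    ``frequencies`` and ``vectors`` map the abstract language tags ``A`` and
    ``B`` to that language's per-million table and embedding table.  See
    module docstring for the full exclusion and residualization chain.
    """
    events = extract_switch_events(corpus)
    lang_names = (corpus.lang_a_name, corpus.lang_b_name)
    pairs_by_dir, exclusions = build_cs_te_pairs(events, translations, lang_names)
    filter_log: dict = {"translation_exclusions": dict(exclusions)}

    records = []
    counts = Counter()
    for direction, pairs in pairs_by_dir.items():
        for rec in pairs:
            f_cs = frequencies[rec.cs_lang].get(rec.cs_form)
            f_te = frequencies[rec.te_lang].get(rec.te_form)
            if f_cs is None or f_te is None:
                counts[f"{direction}:missing_frequency"] += 1
                continue
            if rec.cs_form not in vectors[rec.cs_lang] or rec.te_form not in vectors[rec.te_lang]:
                counts[f"{direction}:missing_vector"] += 1
                continue
            records.append(
                {
                    "direction": direction,
                    "cs_form": rec.cs_form,
                    "cs_lang": rec.cs_lang,
                    "te_form": rec.te_form,
                    "te_lang": rec.te_lang,
                    "logf_cs": log_frequency(f_cs),
                    "logf_te": log_frequency(f_te),
                }
            )
    filter_log["resource_exclusions"] = dict(counts)
    if not records:
        raise ValueError("no CS-TE pairs survive the exclusion filters")
    pairs = pd.DataFrame(records)

    # per-language networks over that language's retained CS words and TEs
    networks: dict[str, SemanticNetwork] = {}
    cz: dict[str, dict[str, float]] = {}
    for lang in LANGS:
        words = sorted(
            set(pairs.loc[pairs["cs_lang"] == lang, "cs_form"])
            | set(pairs.loc[pairs["te_lang"] == lang, "te_form"])
        )
        if len(words) < 2:
            logger.warning("language %s has < 2 retained words; skipped", lang)
            continue
        net = build_network(words, vectors[lang])
        networks[lang] = net
        coeffs = clustering_coefficients(net)
        zvals, _ = zscore(list(coeffs.values()))
        cz[lang] = dict(zip(coeffs.keys(), zvals))

    def _lookup(row, role: str) -> float | None:
        lang, form = row[f"{role}_lang"], row[f"{role}_form"]
        return cz.get(lang, {}).get(form)

    pairs["cz_cs"] = pairs.apply(lambda r: _lookup(r, "cs"), axis=1)
    pairs["cz_te"] = pairs.apply(lambda r: _lookup(r, "te"), axis=1)
    before = len(pairs)
    pairs = pairs.dropna(subset=["cz_cs", "cz_te"]).reset_index(drop=True)
    if before - len(pairs):
        filter_log["resource_exclusions"]["dropped_from_network"] = before - len(pairs)

    # pooled residualization over the unique words involved in retained pairs
    long = pd.concat(
        [
            pairs[["cs_form", "cs_lang", "cz_cs", "logf_cs"]].rename(
                columns={"cs_form": "form", "cs_lang": "lang", "cz_cs": "cz", "logf_cs": "logf"}
            ),
            pairs[["te_form", "te_lang", "cz_te", "logf_te"]].rename(
                columns={"te_form": "form", "te_lang": "lang", "cz_te": "cz", "logf_te": "logf"}
            ),
        ]
    ).drop_duplicates(subset=["form", "lang"])
    correlation = pearson(long["cz"], long["logf"])
    res_cz = residualize(long["cz"].to_numpy(), long["logf"].to_numpy())
    res_logf = residualize(long["logf"].to_numpy(), long["cz"].to_numpy())
    res_cz_map = dict(zip(zip(long["form"], long["lang"]), res_cz))
    res_logf_map = dict(zip(zip(long["form"], long["lang"]), res_logf))
    pairs["res_cz_cs"] = [res_cz_map[(f, l)] for f, l in zip(pairs["cs_form"], pairs["cs_lang"])]
    pairs["res_cz_te"] = [res_cz_map[(f, l)] for f, l in zip(pairs["te_form"], pairs["te_lang"])]
    pairs["res_logf_cs"] = [res_logf_map[(f, l)] for f, l in zip(pairs["cs_form"], pairs["cs_lang"])]
    pairs["res_logf_te"] = [res_logf_map[(f, l)] for f, l in zip(pairs["te_form"], pairs["te_lang"])]

    def _battery(col_cs: str, col_te: str):
        sample = PairedSample(
            pairs[col_cs].to_numpy(), pairs[col_te].to_numpy(), pairs["direction"].to_numpy()
        )
        anova = (
            mixed_anova_2x2(sample) if len(sample.directions()) == 2 else {}
        )
        paired: dict[str, TestResult] = {}
        signs: dict[str, TestResult] = {}
        for d in sample.directions():
            sub = sample.subset(d)
            if len(sub) < 2:
                logger.warning("direction %s has < 2 pairs; tests skipped", d)
                continue
            try:
                paired[d] = paired_t(sub)
            except ValueError as exc:
                logger.warning("paired t skipped for %s: %s", d, exc)
            diff = sub.value_cs - sub.value_te
            lo, hi = _sign_counts(diff)
            if lo + hi > 0:
                signs[d] = sign_test(lo, hi)
        return anova, paired, signs

    anova_cz, paired_cz, sign_cz = _battery("res_cz_cs", "res_cz_te")
    anova_logf, paired_logf, sign_logf = _battery("res_logf_cs", "res_logf_te")

    return Study2Report(
        pairs=pairs,
        filter_log=filter_log,
        correlation=correlation,
        anova_cz=anova_cz,
        anova_logf=anova_logf,
        paired_cz=paired_cz,
        paired_logf=paired_logf,
        sign_cz=sign_cz,
        sign_logf=sign_logf,
        networks=networks,
    )


# ---------------------------------------------------------------------------
# Study 3
# ---------------------------------------------------------------------------


@dataclass
class Study3Report:
    """Cognateness (orthographic-similarity) logistic analysis."""

    words: pd.DataFrame
    result: TestResult
    n_cs: int
    n_non_cs: int
    filter_log: dict

    def to_json(self, path: str | Path | None = None) -> dict:
        payload = {
            "n_cs": self.n_cs,
            "n_non_cs": self.n_non_cs,
            "filter_log": _jsonable(self.filter_log),
            "logistic": self.result.to_dict(),
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")
        return payload


def run_study3(
    corpus: Corpus,
    translations: TranslationMap,
    similarity: Callable[[str, str], float] = orthographic_similarity,
) -> Study3Report:
    """Does cognateness predict whether a word ever gets code-switched?

    Every unambiguous word produced in the corpus is labeled CS (it appears
    as a CS word in at least one switch event) or non-CS; the orthographic
    similarity to its single-word translation equivalent is the predictor of
    a logistic regression on that label.
    """
    produced = sorted(
        {(t.form, t.lang) for t in corpus.tokens() if t.lang in LANGS}
    )
    cs_words = {(e.cs_form, e.cs_lang) for e in extract_switch_events(corpus)}
    counts = Counter()
    rows = []
    for form, lang in produced:
        te = translations.get(form, lang)
        if te is None:
            counts["no_translation"] += 1
            continue
        te = te.strip().lower()
        if " " in te or not te:
            counts["multiword_te"] += 1
            continue
        rows.append(
            {
                "form": form,
                "lang": lang,
                "te": te,
                "similarity": similarity(form, te),
                "is_cs": int((form, lang) in cs_words),
            }
        )
    words = pd.DataFrame(rows)
    if words.empty or words["is_cs"].nunique() < 2:
        raise ValueError("need both CS and non-CS words after filtering")
    result = logistic_fit(words["is_cs"].to_numpy(), words["similarity"].to_numpy())
    return Study3Report(
        words=words,
        result=result,
        n_cs=int(words["is_cs"].sum()),
        n_non_cs=int((1 - words["is_cs"]).sum()),
        filter_log=dict(counts),
    )


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------


def plot_composition(report: Study1Report, path: str | Path) -> None:
    """Stacked bar chart of per-community language composition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    comp = report.composition
    fig, ax = plt.subplots(figsize=(1.5 + len(comp), 4))
    x = np.arange(len(comp))
    bottom = np.zeros(len(comp))
    for col, label in (("pct_l1", "L1"), ("pct_l2", "L2"), ("pct_other", "other")):
        vals = comp[col].to_numpy()
        ax.bar(x, vals, bottom=bottom, label=label)
        bottom += vals
    ax.set_xticks(x)
    ax.set_xticklabels([f"C{c} (n={n})" for c, n in zip(comp["community"], comp["n"])])
    ax.set_ylabel("% of community nodes")
    ax.set_title(f"Community composition (Q={report.Q:.2f})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
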