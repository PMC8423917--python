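import numpy as np
import pytest

from csnet.corpus import AMBIGUOUS, LANG_A, LANG_B, write_corpus
from csnet.cstypes import CSType, classify_cs_types, extract_switch_events
from csnet.stats import paired_t
from csnet.synthetic import (
    GeneratorConfig,
    generate_corpus,
    generate_paired_sample,
    generate_vectors,
    miami_like,
    seame_like,
    write_dataset,
)


class TestGenerateCorpus:
    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        cfg = GeneratorConfig(n_utterances=150, seed=9)
        for name in ("a", "b"):
            corpus, *_ = generate_corpus(cfg)
            write_corpus(corpus, tmp_path / name)
        assert (tmp_path / "a").read_bytes() == (tmp_path / "b").read_bytes()

    def test_stay_probability_one_yields_monolingual_non_cs_corpus(self):
        cfg = GeneratorConfig(
            n_utterances=100,
            n_topics=1,
            n_function_words=5,
            p_stay=1.0,
            p_ambiguous=0.0,
            topic_language_bias=1.0,
            seed=2,
        )
        corpus, *_ = generate_corpus(cfg)
        langs = {t.lang for t in corpus.tokens()}
        assert langs == {LANG_A}
        assert extract_switch_events(corpus) == []
        assert all(t is CSType.NON_CS for t in classify_cs_types(corpus))

    def test_no_ambiguous_tags_when_probability_zero(self):
        corpus, *_ = generate_corpus(GeneratorConfig(n_utterances=200, seed=1))
        assert all(t.lang != AMBIGUOUS for t in corpus.tokens())

    def test_ambiguous_tags_appear_at_requested_rate(self):
        corpus, *_ = generate_corpus(
            GeneratorConfig(n_utterances=500, p_ambiguous=0.1, seed=1)
        )
        frac = sum(t.lang == AMBIGUOUS for t in corpus.tokens()) / corpus.n_tokens()
        assert frac == pytest.approx(0.1, abs=0.02)

    def test_rank_frequency_slope_matches_zipf_exponent(self):
        cfg = GeneratorConfig(n_utterances=6000, seed=5)  # ~50k tokens
        corpus, gold, *_ = generate_corpus(cfg)
        assert corpus.n_tokens() > 40000
        tot = np.sort((gold.concepts["count_a"] + gold.concepts["count_b"]).to_numpy())[::-1]
        tot = tot[tot > 0][:100]
        slope = np.polyfit(np.log10(np.arange(1, len(tot) + 1)), np.log10(tot), 1)[0]
        assert slope == pytest.approx(-cfg.zipf_exponent, abs=0.15)

    def test_translation_map_bijective_over_concepts(self):
        corpus, gold, tmap, _ = generate_corpus(GeneratorConfig(n_utterances=50, seed=0))
        for row in gold.concepts.itertuples():
            assert tmap.get(row.form_a, LANG_A) == row.form_b
            assert tmap.get(row.form_b, LANG_B) == row.form_a
        assert gold.concepts["form_a"].is_unique and gold.concepts["form_b"].is_unique
        assert not (set(gold.concepts["form_a"]) & set(gold.concepts["form_b"]))

    def test_every_emitted_form_is_in_the_gold_record(self):
        corpus, gold, *_ = generate_corpus(GeneratorConfig(n_utterances=100, seed=3))
        known = set(gold.concepts["form_a"]) | set(gold.concepts["form_b"])
        assert {t.form for t in corpus.tokens()} <= known

    def test_intra_rate_monotone_decreasing_in_p_stay(self):
        rates = []
        for p_stay in (0.5, 0.8, 0.95):
            cfg = GeneratorConfig(n_utterances=800, p_stay=p_stay, seed=21)
            corpus, *_ = generate_corpus(cfg)
            types = classify_cs_types(corpus)
            rates.append(sum(t is CSType.INTRA_SENTENTIAL for t in types) / len(types))
        assert rates[0] > rates[1] > rates[2]

    def test_frequency_tables_cover_both_forms_positively(self):
        _, gold, _, freq = generate_corpus(GeneratorConfig(n_utterances=50, seed=0))
        for row in gold.concepts.itertuples():
            assert freq[LANG_A].get(row.form_a) > 0
            assert freq[LANG_B].get(row.form_b) > 0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(p_stay=1.5)
        with pytest.raises(ValueError):
            GeneratorConfig(n_concepts=10, n_topics=40)
        with pytest.raises(ValueError):
            GeneratorConfig(zipf_exponent=0.0)

    def test_presets_contrast_in_switching_rate(self):
        seame, *_ = generate_corpus(seame_like(n_utterances=600, seed=4))
        miami, *_ = generate_corpus(miami_like(n_utterances=600, seed=4))
        rate = lambda c: len(extract_switch_events(c)) / c.n_tokens()
        assert rate(seame) > 3 * rate(miami)


class TestGenerateVectors:
    def test_propensity_correlates_with_network_clustering(self):
        from csnet.semnet import build_network, clustering_coefficients

        cfg = GeneratorConfig(n_utterances=50, seed=7)
        _, gold, _, _ = generate_corpus(cfg)
        vecs = generate_vectors(gold, dim=50, seed=7)
        forms = list(gold.concepts["form_a"])
        net = build_network(forms, vecs[LANG_A])
        coeffs = clustering_coefficients(net)
        c = np.array([coeffs[f] for f in forms])
        r = np.corrcoef(c, gold.concepts["proxy_a"])[0, 1]
        assert r > 0.15

    def test_translation_pairs_more_similar_than_random_pairs(self):
        from csnet.embedding import cosine

        _, gold, _, _ = generate_corpus(GeneratorConfig(n_utterances=50, seed=3))
        vecs = generate_vectors(gold, dim=50, seed=3)
        rng = np.random.default_rng(0)
        rows = gold.concepts.sample(80, random_state=1)
        te_sims = [
            cosine(vecs[LANG_A][r.form_a], vecs[LANG_B][r.form_b])
            for r in rows.itertuples()
        ]
        shuffled = rows["form_b"].sample(frac=1, random_state=2).tolist()
        rand_sims = [
            cosine(vecs[LANG_A][r.form_a], vecs[LANG_B][s])
            for r, s in zip(rows.itertuples(), shuffled)
        ]
        assert np.mean(te_sims) > np.mean(rand_sims)


class TestGeneratePairedSample:
    def test_minimal_sample(self):
        sample = generate_paired_sample(2, delta=0.0, sigma=1.0, seed=0)
        assert len(sample) == 2

    def test_planted_difference_recovered_in_power_simulation(self):
        # with |delta| = 0.5*sigma and n = 200 the paired t is essentially
        # always significant (noncentrality ~ 7)
        rejections = sum(
            paired_t(
                generate_paired_sample(200, delta=-0.5, sigma=1.0, seed=seed)
            ).p
            < 0.05
            for seed in range(500)
        )
        assert rejections >= 475

    def test_direction_proportions(self):
        sample = generate_paired_sample(10, 0.0, 1.0, seed=0, p_first=0.3)
        assert (sample.direction == "d1").sum() == 3

    def test_invalid_args_rejected(self):
        with pytest.raises(ValueError):
            generate_paired_sample(1, 0.0, 1.0)
        with pytest.raises(ValueError):
            generate_paired_sample(10, 0.0, 0.0)


def test_write_dataset_produces_loadable_artifacts(tmp_path):
    from csnet.corpus import read_corpus
    from csnet.embedding import load_vectors
    from csnet.lexicon import load_frequency_table, load_translation_map

    cfg = GeneratorConfig(n_utterances=60, seed=13)
    paths = write_dataset(tmp_path / "ds", cfg, vector_dim=20)
    corpus = read_corpus(paths["corpus"])
    assert len(corpus) > 0
    assert len(load_translation_map(paths["translations"])) == 2 * cfg.n_concepts
    assert len(load_frequency_table(paths["freq_a"], LANG_A)) == cfg.n_concepts
    table = load_vectors(paths["vectors_b"])
    assert table.dim == 20
    import json

    manifest = json.loads(paths["manifest"].read_text())
    assert manifest["config"]["seed"] == 13
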