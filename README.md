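# csnet

Network-science analysis of bilingual code-switching speech.

Bilinguals alternate between languages within conversations and even
within sentences (code-switching, CS).  Two questions about the bilingual
lexicon can be asked directly of such speech: do the two languages occupy
distinct regions of the speaker's semantic network, and do structural
properties of individual words — beyond plain frequency — predict which
language gets chosen at each moment?  `csnet` implements the full analysis
pipeline for both, for researchers in psycholinguistics and cognitive
network science working with language-tagged speech transcripts.

## What it computes

**Semantic networks.** Words are nodes; the edge weight between two words
is the cosine similarity of their embedding vectors (skip-gram vectors
trained from scratch on the corpus, or loaded pretrained vectors).  Pairs
with non-positive cosine are not connected, so weights lie in (0, 1].

**Communities.** Louvain community detection maximizing weighted
modularity

$$Q = \frac{1}{2m}\sum_{uv}\Bigl[W_{uv} - \frac{s_u s_v}{2m}\Bigr]\,\delta(c_u, c_v),$$

followed by the per-community language composition — the direct test of
whether the two languages form separate lexical modules.

**Clustering coefficients.** For each word $u$, the weighted local
clustering coefficient

$$C_u = \frac{2}{\deg(u)(\deg(u)-1)} \sum_{v,w} \bigl(\hat W_{uv}\,\hat W_{uw}\,\hat W_{vw}\bigr)^{1/3}, \qquad \hat W = W / \max(w),$$

a measure of how interconnected a word's semantic neighborhood is.  Words
with low $C_u$ "stick out" of their neighborhood and are hypothesized to
be easier to retrieve — hence more likely to be switched into.

**The paired battery.** Every CS word (a word produced in a different
language than the preceding word) is paired with its translation
equivalent (TE) in the other language.  After z-scoring $C$ within
language, log-transforming per-million frequencies, and residualizing
each variable on the other, the package runs a mixed-design
(split-plot) ANOVA over switching × direction, per-direction paired
t-tests with Cohen's d, and sign tests
$\chi^2 = (a-b)^2/(a+b)$ on lower/higher counts — plus a logistic
regression of ever-being-switched on orthographic similarity to the TE
(cognateness), with Cox–Snell $R^2$.

A synthetic bilingual-corpus generator with known ground truth (Zipfian
frequencies, topic structure, matrix-language dynamics, a planted
accessibility effect on switching) makes every stage testable without
licensed corpora.

## Worked example

```python
from csnet import (
    EmbeddingConfig, seame_like, generate_corpus, generate_vectors,
    run_study1, run_study2,
)
from csnet.corpus import preprocess

cfg = seame_like(n_utterances=2000, beta_C=-1.0, seed=42)
corpus, gold, translations, frequencies = generate_corpus(cfg)
corpus = preprocess(corpus)

s1 = run_study1(corpus, embed_config=EmbeddingConfig(dim=50, epochs=5, seed=42), seed=42)
print(f"communities: {s1.partition.n_communities()}, Q = {s1.Q:.3f}")
print(s1.composition.round(1))

vectors = generate_vectors(gold, dim=50, seed=42)
s2 = run_study2(corpus, translations, frequencies, vectors)
d = s2.pairs["res_cz_cs"] - s2.pairs["res_cz_te"]
print(f"pairs: {len(s2.pairs)}, mean Res C_Z (CS - TE) = {d.mean():.3f}")
```

prints

```
communities: 2, Q = 0.059
   community    n  pct_l1  pct_l2  pct_other
0          0  407    83.8    16.2    0.0
1          1  347    12.1    87.9    0.0
pairs: 371, mean Res C_Z (CS - TE) = -0.165
```

Read: the Louvain partition of the 754-word semantic network found two
communities, each dominated by one language (83.8% and 87.9%) — the two
lexicons largely occupy separate modules, with a modest overlap.  Across
the 371 retained CS–TE pairs, code-switched words have residualized
standardized clustering coefficients 0.165 below their translation
equivalents on average: the planted negative clustering effect on
switching (`beta_C = -1.0`) is recovered with the correct sign after
frequency is controlled for.

The same pipeline runs from the shell:

```bash
csnet simulate --preset seame-like --seed 42 --out-dir data/
csnet report --data-dir data/ --seed 42 --out-dir results/
```

with further subcommands (`preprocess`, `classify`, `embed`, `network`,
`communities`, `cs-stats`, `cognates`) exposing the individual stages for
user-supplied corpora in the tagged one-utterance-per-line dialect.

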