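# Methods

`csnet` analyzes bilingual code-switching (CS) speech as a pair of
interacting lexical networks.  This note describes the models and
procedures the package implements, the choices made where the design was
genuinely open, and what the synthetic data generator does and does not
emulate.

## Corpus model and CS classification

A corpus is an ordered sequence of utterances of language-tagged tokens.
The two languages are abstract tags `A`/`B`; a third tag `AMBIGUOUS` covers
forms assignable to either language (shared forms such as "no", proper
nouns, mixed morphology).  Language tags come either from hand annotation
(the `tagged` file dialect) or, for script-disjoint pairs such as
Mandarin–English, from Unicode script detection: an all-CJK form belongs to
the CJK language, an all-Latin form to the other, and anything mixed,
all-digit, or otherwise unclassifiable is ambiguous.  Punctuation and
combining marks attached to a form are ignored when deciding.

Preprocessing lowercases forms, strips leading/trailing punctuation
characters, and removes non-word markers (e.g. `<unk>`), discourse
communicators (e.g. "eh"), and punctuation-only tokens.  How the original
transcripts tokenized punctuation-attached forms ("job?") is not knowable
from the transcripts themselves; edge-stripping is our convention and may
differ from other pipelines.  Word segmentation for Mandarin is out of
scope: input must be pre-tokenized.

Sentence types follow a conservative rule that only uses unambiguous
tokens: a sentence mixing unambiguous words of both languages is
*intra-sentential* CS; otherwise a sentence containing an unambiguous word
in a language absent from the immediately preceding sentence's unambiguous
languages is *inter-sentential* CS (the first sentence never is); all else
is non-CS.  Two consequences of this reading: a sentence following an
intra-sentential sentence can never be inter-sentential, and a sentence
with no unambiguous words contributes an empty language set as
predecessor.  Sentence order is corpus line order, regardless of speaker.

A *CS word* is a token whose language differs from the immediately
preceding token within the sentence, both unambiguous; ambiguous tokens
neither trigger nor transmit switching context.  CS words are unique at
the type level per (form, language).  Their *translation equivalents*
(TEs) come from a static word→word map supplied as input; entries whose
translation is a multiword phrase are excluded, with counts logged.

## Semantic networks and the weighted clustering coefficient

Word vectors come either from skip-gram with negative sampling trained on
the corpus itself (`embedding.train_sgns`) or from a pretrained vector
file.  The trainer uses the common defaults: dynamic window (uniform
1..window per position), 5 negative samples from the unigram^0.75
distribution, learning rate 0.025 with linear decay, no frequency
subsampling, minimum count 1 so networks can cover the whole vocabulary.
Training is single-threaded and bitwise reproducible given the seed;
updates are applied in scatter-add mini-batches.  Subword (character
n-gram) training is deliberately not implemented — for pretrained subword
vectors only the text-format reader is needed, and scratch training uses
plain skip-gram.

A semantic network connects two words iff the cosine similarity of their
vectors is strictly positive, with the cosine as edge weight.  Zero
cosines are treated as non-edges: exact zero carries no similarity signal,
and the published pruning rule only states that negative cosines are
disconnected.  Degree is defined over retained edges only.

The local clustering coefficient of node *u* is the geometric-mean form
for weighted graphs:

    C_u = 2 / (deg(u)(deg(u)−1)) · Σ_{v,w} (Ŵ_uv Ŵ_uw Ŵ_vw)^{1/3},

where Ŵ = W / max(w) normalizes by the maximum edge weight of the network
and a missing (v,w) edge contributes zero.  Nodes of degree < 2 get
C_u = 0 (the standard convention; the formula is undefined there).  C_u is
invariant under uniform weight rescaling and reduces to the unweighted
closed-triple fraction for equal weights; both properties are tested, and
the implementation is checked against a brute-force triple enumeration and
against networkx's independent implementation.  The full-network variant
computes diag((Ŵ^{1/3})³) by matrix products, so dense networks of a few
thousand nodes stay fast.

## Community detection

Modularity is the weighted Newman–Girvan quantity; Louvain optimizes it
with the usual two phases (greedy local moves, then aggregation), stopping
when a phase improves Q by less than 1e−7.  Node visit order is a seeded
shuffle and ties keep the node in its current community, making runs
deterministic given the seed.  Q is non-decreasing across phases by
construction, and the reported Q is always recomputed from scratch on the
final assignment.  Community ids are relabeled by size descending.  The
resolution parameter is exposed but fixed at 1 for all analyses.  Louvain
is a heuristic: on small random instances it matches exhaustive-search
optima in ≥ 90% of cases (tested), not always.

## The paired CS/TE battery

For each language of a bilingual group, a network is built over that
language's retained CS words and TEs pooled across both switch directions
(pooling maximizes shared context; counts are logged).  The exclusion
chain is: multiword or missing translations → pairs missing a frequency
for either word → pairs missing a vector for either word; every stage logs
its count, and pair counts are non-increasing along the chain.

Clustering coefficients are z-scored within language (reference
distribution = all nodes of that language's network), frequencies are
log10 per-million.  To separate the two effects each variable is
residualized on the other by OLS over the pooled unique words of the group
(the single reported correlation per group implies a pooled regression;
this is the default, documented here as a choice).  The battery is then:

- a split-plot (mixed-design) 2×2 ANOVA with the item (CS–TE pair) as the
  random unit, switching as the within-item factor and direction as the
  between-item factor.  With two within levels the decomposition reduces
  to one-way analyses of item sums and item differences; the interaction F
  equals the squared pooled two-sample t on per-item differences, with
  df (1, N−2).  Group sizes may be unbalanced; sums of squares use
  weighted (Type-I-style) means, and other SS conventions could differ
  slightly for unbalanced data.
- paired t-tests per direction (CS − TE; sample sd, Cohen's d = mean/sd).
- sign tests per direction: χ² = (a−b)²/(a+b) on counts of pairs with the
  CS word lower vs. higher, df 1, no continuity correction — this form
  exactly reproduces all eight published statistics from their printed
  counts, which is its verification.  Ties are excluded before testing.

The cognateness analysis labels every produced unambiguous word CS if it
was *ever* used as a CS word and non-CS otherwise, measures orthographic
similarity to its TE, and fits a logistic regression of the class on
similarity, reporting the slope B, Wald = (B/SE)², and Cox–Snell
R² = 1 − (L0/L1)^{2/n} (Nagelkerke's rescaling also emitted).  Perfect
separation is flagged as non-convergence, never silently ignored.
Orthographic similarity defaults to 1 − d/max(|w1|,|w2|) with Levenshtein
distance d; the cited external similarity measure is not publicly
specified, so normalized Levenshtein is an explicit stand-in and the
distance function is a plug point.

## Synthetic data generator

No open bilingual CS corpus with per-token language tags can ship with the
package, so every stage is exercised on generated data with known ground
truth.  The generator emulates:

- a shared concept inventory: each concept has one syllable-shaped word
  form per language (a bijective translation pair); a configurable
  fraction (`cognate_rate`) of pairs are orthographic neighbors so the
  cognateness analysis has a non-constant predictor;
- Zipfian concept frequencies (`zipf_exponent`, realized rank-frequency
  slope verified at ±0.15); the top `n_function_words` ranks are
  language-specific *function words* emitted from any topic — the
  high-frequency closed-class glue that makes a language cohere across
  topics;
- topic structure: content concepts belong to topics with skewed sizes;
  conversations dwell on a topic (`topic_persistence`); each topic has a
  dominant language and each dwell a *matrix language* (the dominant one
  with probability `topic_language_bias`);
- a first-order language chain: the base probability of switching at each
  token is 1 − `p_stay` on the log-odds scale, shifted by
  `dominance_boost` toward the matrix language (switching back to the
  matrix is easier than leaving it);
- per-concept *language affinity*: concept choice is skewed toward
  concepts habitually realized in the current language, so most content
  words are produced overwhelmingly in one language, as in real bilingual
  speech;
- a small probability `p_ambiguous` of tagging a token ambiguous (the
  token keeps a real word form);
- a planted accessibility effect: each (concept, language) carries a
  clustering-propensity score in (0,1) and the switch log-odds add
  `beta_C`·z(propensity) + `beta_F`·z(log frequency) *of the form in the
  target language*.  The propensity must be language-specific: any proxy
  shared by a concept's two forms would be identical for a CS word and
  its TE and could never generate a CS–TE contrast.

Two presets fix the study conditions.  The high-switching preset
(`seame_like`: p_stay 0.8, boost 1.5, bias 0.75) yields roughly 30%
intra-sentential and 4% inter-sentential sentences with two language
communities of 90–95% purity; the low-switching preset (`miami_like`:
p_stay 0.97, bias 0.9, 5% ambiguous tokens) yields roughly 4–5%
intra-sentential sentences.  These magnitudes echo the contrast between
the two published corpus profiles at the order-of-magnitude level; they
were chosen once, from those profiles, and are not tuned per analysis.

`generate_vectors` builds matched "pretrained-style" per-language tables:
topic directions sit in a simplex configuration (pairwise cosine
−1/(n_topics−1)), so cross-topic word pairs prune away as negative
cosines; a word with propensity 1 lies on its topic direction (all strong
neighbors interconnect — high C_u), a word with propensity 0 is an even
blend of two topic directions (its neighborhood splits into two mutually
unconnected cliques — low C_u).  A small concept offset shared across
languages keeps translation pairs similar.  Realized network clustering
correlates with the planted propensity at r ≈ 0.3 at default sizes, which
is sufficient for sign-level recovery and is all that is claimed.

What the generator does *not* model: syntax, morphology,
matrix-language grammatical constraints, speaker identity, discourse
coherence beyond topic dwells, or any naturalness of word forms.  Passing
tests therefore show that the pipeline recovers the statistical structure
it is designed to measure when that structure is present; they do not
certify behavior on natural speech, where topics are softer, frequency
distributions heavier-tailed, and annotation noisier.

## Numerical choices and problem sizes

All randomness flows from explicit seeds (numpy `default_rng`); repeated
runs are bit-identical.  Z-scores and t-tests use the sample (ddof 1)
standard deviation.  Residualization is ordinary least squares via
`lstsq`; residuals are orthogonal to the predictor to 1e−8.  The logistic
fit is maximum likelihood via statsmodels' Newton optimizer and is tested
against independently coded IRLS steps to 1e−6.  Cosines are clipped to
[−1, 1] against rounding.  Dense cosine computation proceeds in blocks of
512 rows so memory stays linear in block size.

The shipped analyses use corpora of ~30–50k tokens, 400 concepts, 8
topics, and 50-dimensional embeddings trained for 5 epochs — sizes at
which the full pipeline (generation, training, networks, communities, and
the statistical battery) completes in well under a minute per study on one
CPU while leaving all planted effects clearly measurable.  Larger corpora
and dimensions sharpen the community purities and the propensity–C_u
correlation but do not change any qualitative conclusion.

## Known limitations

- The split-plot ANOVA uses weighted means for unbalanced groups; other
  sums-of-squares conventions would give slightly different F values for
  the main effects (the interaction is unaffected).
- Louvain is greedy and single-seed; no consensus clustering across seeds
  is attempted.
- The orthographic-similarity measure is a stand-in (see above).
- Study-2-style networks cover only the retained CS words and TEs of a
  language, not its full lexicon, so z-scored clustering is relative to
  that restricted word set.
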