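import networkx as nx
import numpy as np
import pytest

from csnet.corpus import AMBIGUOUS, LANG_A, LANG_B, Corpus, Token, Utterance
from csnet.semnet import SemanticNetwork


def make_corpus(tagged_utterances, lang_names=("L1", "L2")):
    """Build a Corpus from [[(form, lang), ...], ...] shorthand."""
    utts = tuple(
        Utterance(tokens=tuple(Token(f, l) for f, l in toks), index=i)
        for i, toks in enumerate(tagged_utterances)
    )
    return Corpus(utterances=utts, lang_a_name=lang_names[0], lang_b_name=lang_names[1])


def random_weighted_network(n, p, rng, w_lo=0.1, w_hi=1.0):
    """Erdos-Renyi graph with uniform positive weights, as a SemanticNetwork."""
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(i, j, weight=float(rng.uniform(w_lo, w_hi)))
    return SemanticNetwork(g)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def mixed_corpus():
    """Small bilingual corpus with ambiguous tokens and several switch points."""
    return make_corpus(
        [
            [("hola", LANG_A), ("amigo", LANG_A)],
            [("hola", LANG_A), ("my", LANG_B), ("friend", LANG_B)],
            [("ok", AMBIGUOUS), ("bye", LANG_B)],
            [("nos", LANG_A), ("vemos", LANG_A)],
        ]
    )
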