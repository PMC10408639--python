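"""PMI-weighted term co-occurrence networks.

Terms that appear together in a tweet are linked; raw co-occurrence
frequency over-weights globally frequent terms, so each retained link is
weighted by pointwise mutual information instead:

    PMI(w1, w2) = ln( P(w1 w2) / (P(w1) P(w2)) )

with probabilities estimated per document (binary occurrence per tweet):
P(w) = df(w)/n and P(w1 w2) = codf(w1, w2)/n over n tweets.  PMI is 0
under independence and positive for associated pairs; only positive-PMI
edges enter the network, since modularity over negative weights is
ill-defined.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "VocabStats",
    "CooccurrenceNetwork",
    "NoEdgesError",
    "count_cooccurrence",
    "pmi",
    "build_network",
    "CooccurrenceNetworkBuilder",
    "MIN_RECOMMENDED_NODES",
]

# co-occurrence analysis is considered reliable above this network size
MIN_RECOMMENDED_NODES = 75

Pair = tuple[str, str]


def _key(w1: str, w2: str) -> Pair:
    return (w1, w2) if w1 <= w2 else (w2, w1)


@dataclass
class VocabStats:
    """Document-level occurrence statistics backing the PMI estimates.

    ``n``: number of documents; ``df``: documents containing each term;
    ``codf``: documents containing both terms of an (unordered) pair.
    Occurrence is binary per document — repeated tokens in one tweet
    count once.
    """

    n: int
    df: dict[str, int] = field(default_factory=dict)
    codf: dict[Pair, int] = field(default_factory=dict)

    def codf_get(self, w1: str, w2: str) -> int:
        return self.codf.get(_key(w1, w2), 0)


class NoEdgesError(ValueError):
    """No term pair survived the co-count / positive-PMI thresholds."""


def count_cooccurrence(docs: Sequence) -> VocabStats:
    """Count per-document term occurrences and pairwise co-occurrences.

    ``docs`` is a sequence of token lists or objects with ``.tokens``.
    """
    token_lists = [d if isinstance(d, (list, tuple, set)) else d.tokens for d in docs]
    if not token_lists:
        raise ValueError("cannot count co-occurrence over an empty corpus")
    stats = VocabStats(n=len(token_lists))
    for toks in token_lists:
        uniq = sorted(set(toks))
        for t in uniq:
            stats.df[t] = stats.df.get(t, 0) + 1
        for w1, w2 in combinations(uniq, 2):
            k = (w1, w2)
            stats.codf[k] = stats.codf.get(k, 0) + 1
    return stats


def pmi(w1: str, w2: str, stats: VocabStats) -> float:
    """Pointwise mutual information of a term pair, natural log.

    Returns ``-inf`` when the pair never co-occurs (such an edge is never
    retained).  The log base is behavior-neutral downstream: modularity
    normalizes by total weight, so any base rescales Q's inputs uniformly.
    """
    for w in (w1, w2):
        if stats.df.get(w, 0) <= 0:
            raise KeyError(f"term {w!r} not present in vocabulary statistics")
    co = stats.codf_get(w1, w2)
    if co == 0:
        return float("-inf")
    return math.log(co * stats.n / (stats.df[w1] * stats.df[w2]))


@dataclass
class CooccurrenceNetwork:
    """Weighted undirected term graph (PMI edge weights).

    Backed by a :class:`networkx.Graph`; node attribute ``df`` stores
    document frequency, edge attributes ``count`` (raw co-document count)
    and ``weight`` (PMI).  ``m`` is the sum of all link weights and
    ``degree(i)`` the weighted degree k_i.
    """

    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def isolated_nodes(self) -> list[str]:
        return [v for v in self.graph.nodes if self.graph.degree(v) == 0]

    @property
    def m(self) -> float:
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))

    def degree(self, node: str) -> float:
        return sum(d["weight"] for _, _, d in self.graph.edges(node, data=True))

    def degrees(self) -> dict[str, float]:
        return {v: self.degree(v) for v in self.graph.nodes}

    def edge_weight(self, w1: str, w2: str) -> float:
        return self.graph.edges[w1, w2]["weight"]

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def write_edgelist(self, path) -> None:
        """Three-column weighted edge list: term1, term2, weight."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("term1\tterm2\tweight\n")
            for u, v, d in sorted(self.graph.edges(data=True)):
                fh.write(f"{u}\t{v}\t{d['weight']:.12g}\n")

    @classmethod
    def read_graphml(cls, path) -> "CooccurrenceNetwork":
        return cls(graph=nx.read_graphml(path))


def build_network(
    stats: VocabStats, top_n: int = 150, min_co: int = 2
) -> CooccurrenceNetwork:
    """Build the thresholded PMI network over the top-``top_n`` terms.

    Nodes are the ``top_n`` highest-document-frequency terms (ties broken
    lexicographically); edges are pairs among them with co-document count
    ``>= min_co`` and strictly positive PMI.  Isolated nodes are retained.
    A warning is emitted when the surviving network is at or below
    ``MIN_RECOMMENDED_NODES`` nodes, the floor below which co-occurrence
    analysis is not recommended.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if min_co < 1:
        raise ValueError("min_co must be >= 1")
    if not stats.df:
        raise ValueError("no terms in vocabulary statistics")
    ranked = sorted(stats.df.items(), key=lambda kv: (-kv[1], kv[0]))
    vocab = [t for t, _ in ranked[:top_n]]
    vocab_set = set(vocab)

    g = nx.Graph()
    for t in vocab:
        g.add_node(t, df=stats.df[t])
    for (w1, w2), co in stats.codf.items():
        if co < min_co or w1 not in vocab_set or w2 not in vocab_set:
            continue
        w = pmi(w1, w2, stats)
        if w > 0:
            g.add_edge(w1, w2, count=co, weight=w)
    if g.number_of_edges() == 0:
        raise NoEdgesError(
            "no edges survived thresholds; lower min_co or raise top_n"
        )
    if g.number_of_nodes() <= MIN_RECOMMENDED_NODES:
        warnings.warn(
            f"network has {g.number_of_nodes()} nodes "
            f"(> {MIN_RECOMMENDED_NODES} recommended for co-occurrence analysis)",
            stacklevel=2,
        )
    return CooccurrenceNetwork(graph=g)


class CooccurrenceNetworkBuilder(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer: token documents → PMI network.

    Parameters
    ----------
    top_n : int, default=150
        Vocabulary size — terms ranked by document frequency.
    min_co : int, default=2
        Minimum co-document count for an edge.

    Attributes
    ----------
    stats_ : VocabStats
        Document/co-document frequencies from the fitted corpus.
    network_ : CooccurrenceNetwork
        The thresholded PMI network.
    """

    def __init__(self, top_n: int = 150, min_co: int = 2):
        self.top_n = top_n
        self.min_co = min_co

    def fit(self, X, y=None):
        self.stats_ = count_cooccurrence(X)
        self.network_ = build_network(self.stats_, self.top_n, self.min_co)
        return self

    def transform(self, X=None) -> CooccurrenceNetwork:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "network_")
        return self.network_
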