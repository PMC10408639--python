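"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math
from datetime import datetime, timezone
from itertools import combinations

import networkx as nx
import pytest

from peolc_topics.network import CooccurrenceNetwork
from peolc_topics.synth import CorpusSpec, make_topic_specs

UTC = timezone.utc


def dt(*args):
    return datetime(*args, tzinfo=UTC)


# ---------------------------------------------------------------------------
# Independent oracles (kept free of the implementation paths they check)
# ---------------------------------------------------------------------------


def brute_force_stats(docs):
    """Recount document/co-document frequencies by explicit loops."""
    n = len(docs)
    vocab = sorted({t for d in docs for t in d})
    df = {t: sum(1 for d in docs if t in d) for t in vocab}
    codf = {}
    for w1, w2 in combinations(vocab, 2):
        c = sum(1 for d in docs if w1 in d and w2 in d)
        if c:
            codf[(w1, w2)] = c
    return n, df, codf


def brute_force_pmi(docs, w1, w2):
    """PMI from raw documents: ln of joint over product of marginals."""
    n, df, codf = brute_force_stats(docs)
    key = (w1, w2) if w1 <= w2 else (w2, w1)
    co = codf.get(key, 0)
    if co == 0:
        return float("-inf")
    return math.log((co / n) / ((df[w1] / n) * (df[w2] / n)))


def naive_modularity(graph: nx.Graph, assignment: dict) -> float:
    """Double-loop evaluation of Q over all ordered node pairs."""
    nodes = list(graph.nodes)
    m = sum(d.get("weight", 1.0) for _, _, d in graph.edges(data=True))
    k = {
        v: sum(d.get("weight", 1.0) for _, _, d in graph.edges(v, data=True))
        for v in nodes
    }
    q = 0.0
    for i in nodes:
        for j in nodes:
            # ordered pairs including i=j: A_ii = 0 but the null-model
            # term k_i^2/(2m) still enters via delta(c_i, c_i) = 1
            if i == j:
                a = 0.0
            elif graph.has_edge(i, j):
                a = graph.edges[i, j].get("weight", 1.0)
            else:
                a = 0.0
            if assignment[i] == assignment[j]:
                q += a - k[i] * k[j] / (2.0 * m)
    return q / (2.0 * m)


def all_partitions(items):
    """Enumerate every set partition of ``items`` (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partial in all_partitions(rest):
        for i in range(len(partial)):
            yield partial[:i] + [[first] + partial[i]] + partial[i + 1 :]
        yield [[first]] + partial


def exhaustive_best_modularity(graph: nx.Graph):
    """Maximum Q over all partitions (feasible for <= 8 nodes)."""
    best_q, best_part = -math.inf, None
    for part in all_partitions(list(graph.nodes)):
        assignment = {v: i for i, block in enumerate(part) for v in block}
        q = naive_modularity(graph, assignment)
        if q > best_q:
            best_q, best_part = q, part
    return best_q, best_part


# ---------------------------------------------------------------------------
# Fixture graphs and corpora
# ---------------------------------------------------------------------------


def _weighted_graph(edges):
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return g


@pytest.fixture
def two_triangles():
    """Two disconnected unit-weight triangles; optimal Q = 0.5."""
    edges = [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0),
             ("x", "y", 1.0), ("y", "z", 1.0), ("x", "z", 1.0)]
    return CooccurrenceNetwork(graph=_weighted_graph(edges))


@pytest.fixture
def four_clique():
    g = nx.complete_graph(4)
    relabel = {i: f"n{i}" for i in g.nodes}
    g = nx.relabel_nodes(g, relabel)
    for u, v in g.edges:
        g.edges[u, v]["weight"] = 1.0
    return CooccurrenceNetwork(graph=g)


@pytest.fixture
def single_edge():
    return CooccurrenceNetwork(graph=_weighted_graph([("a", "b", 1.0)]))


@pytest.fixture
def planted_two_community():
    """Two dense 4-cliques joined by one weak bridge (8 nodes)."""
    edges = []
    for block, names in enumerate((list("abcd"), list("wxyz"))):
        for u, v in combinations(names, 2):
            edges.append((u, v, 1.0))
    edges.append(("a", "w", 0.25))
    return CooccurrenceNetwork(graph=_weighted_graph(edges))


@pytest.fixture
def small_corpus_spec():
    """Factory for compact three-topic corpora used across tests."""

    def make(
        k=3,
        n_tweets=600,
        peolc_fraction=0.3,
        overlap=0.0,
        seed=0,
        noise_fraction=0.1,
        topics=None,
    ):
        if topics is None:
            topics = make_topic_specs(k, vocab_size=20, overlap=overlap, seed=seed)
        return CorpusSpec(
            topics=topics,
            n_tweets=n_tweets,
            peolc_fraction=peolc_fraction,
            overlap=overlap,
            countries=(("US", 0.5), ("GB", 0.3), ("CA", 0.2)),
            date_range=(dt(2020, 10, 1), dt(2021, 3, 30)),
            changepoint=dt(2020, 12, 10),
            tokens_per_tweet=(8, 20),
            seed=seed,
            noise_fraction=noise_fraction,
        )

    return make
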