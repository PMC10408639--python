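"""End-to-end topic model: filter → preprocess → PMI network → Louvain.

:class:`PMITopicModel` composes the stage estimators into one
scikit-learn-style model over raw tweet records: it keeps the tweets
passing the PEoLC keyword filter, reduces them to canonical terms,
builds the PMI co-occurrence network over the high-frequency vocabulary,
and detects term communities (topics) by Louvain modularity.  ``predict``
assigns each document to the community holding the plurality of its
tokens, which makes partition purity against planted topic labels
directly computable on synthetic corpora.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .community import LouvainCommunities
from .corpus import TweetRecord, match_peolc
from .network import CooccurrenceNetworkBuilder
from .report import TopicSummary, select_representatives, summarize_topics
from .textprep import TokenizedDoc, TweetPreprocessor

__all__ = ["PMITopicModel", "document_purity"]

UNASSIGNED = -1


class PMITopicModel(BaseEstimator):
    """Topic detection for short-text corpora via PMI networks.

    Parameters
    ----------
    filter_terms : iterable of str, optional
        Keyword filter applied to raw records; ``None`` uses the bundled
        PEoLC list. Pass an empty sequence semantics via
        ``apply_filter=False`` instead.
    apply_filter : bool, default=True
        Whether to keep only records matching the keyword filter.
    normalizer : {"lemma", "stem", "none"}, default="lemma"
    top_n : int, default=150
        Network vocabulary size (terms by document frequency).
    min_co : int, default=2
        Minimum co-document count for an edge.
    seed : int, default=0
        Louvain node-order shuffle seed.
    tolerance : float, default=1e-12
        Louvain minimum modularity gain.
    n_keywords : int, default=10

    Attributes
    ----------
    preprocessor_, builder_, clusterer_ : the fitted stage estimators
    docs_ : list of TokenizedDoc surviving filter + preprocessing
    network_ : CooccurrenceNetwork
    partition_ : CommunityPartition
    summaries_ : list of TopicSummary
    modularity_, n_communities_ : floats/int convenience mirrors
    """

    def __init__(
        self,
        filter_terms: Iterable[str] | None = None,
        apply_filter: bool = True,
        normalizer: str = "lemma",
        top_n: int = 150,
        min_co: int = 2,
        seed: int = 0,
        tolerance: float = 1e-12,
        n_keywords: int = 10,
    ):
        self.filter_terms = filter_terms
        self.apply_filter = apply_filter
        self.normalizer = normalizer
        self.top_n = top_n
        self.min_co = min_co
        self.seed = seed
        self.tolerance = tolerance
        self.n_keywords = n_keywords

    def fit(self, X: Sequence[TweetRecord], y=None):
        records = list(X)
        if self.apply_filter:
            terms = (
                list(self.filter_terms) if self.filter_terms is not None else None
            )
            records = [r for r in records if match_peolc(r.text, terms)]
        if not records:
            raise ValueError("no records survive the keyword filter")
        self.preprocessor_ = TweetPreprocessor(normalizer=self.normalizer).fit(records)
        self.docs_ = [
            d for d in self.preprocessor_.transform_docs(records) if d.tokens
        ]
        self.builder_ = CooccurrenceNetworkBuilder(
            top_n=self.top_n, min_co=self.min_co
        ).fit(self.docs_)
        self.network_ = self.builder_.network_
        self.clusterer_ = LouvainCommunities(
            seed=self.seed, tolerance=self.tolerance
        ).fit(self.network_)
        self.partition_ = self.clusterer_.partition_
        self.modularity_ = self.partition_.modularity
        self.n_communities_ = self.partition_.n_communities
        self.summaries_ = summarize_topics(
            self.network_, self.partition_, k=self.n_keywords
        )
        timestamps = {r.id: r.created_at for r in records}
        for s in self.summaries_:
            s.representatives = select_representatives(
                self.docs_, s, r=3, timestamps=timestamps
            )
        return self

    def predict_docs(self, docs: Sequence[TokenizedDoc]) -> np.ndarray:
        """Community label per document (plurality vote of its tokens).

        Tokens outside the network vocabulary abstain; a document with
        no in-vocabulary token gets ``UNASSIGNED`` (-1).  Vote ties break
        toward the smaller community id.
        """
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "partition_")
        assignment = self.partition_.assignment
        labels = np.empty(len(docs), dtype=int)
        for i, doc in enumerate(docs):
            votes = Counter(
                assignment[t] for t in doc.tokens if t in assignment
            )
            if not votes:
                labels[i] = UNASSIGNED
            else:
                top = max(votes.values())
                labels[i] = min(c for c, v in votes.items() if v == top)
        return labels

    def predict(self, X: Sequence[TweetRecord]) -> np.ndarray:
        """Community label per raw record (after preprocessing)."""
        docs = self.preprocessor_.transform_docs(list(X))
        return self.predict_docs(docs)

    def fit_predict(self, X: Sequence[TweetRecord], y=None) -> np.ndarray:
        """Fit, then label the documents the model was fitted on."""
        self.fit(X)
        return self.predict_docs(self.docs_)


def document_purity(
    labels: Sequence[int],
    truth: Sequence[int],
    ignore_unassigned: bool = False,
) -> float:
    """Purity of a document clustering against planted topic labels.

    purity = (1/N) * sum over detected clusters of the size of the
    cluster's largest intersection with any planted topic.  Documents
    labelled ``UNASSIGNED`` count against purity unless
    ``ignore_unassigned``.
    """
    if len(labels) != len(truth):
        raise ValueError("labels and truth must align")
    pairs = [
        (l, t)
        for l, t in zip(labels, truth)
        if not (ignore_unassigned and l == UNASSIGNED)
    ]
    if not pairs:
        return 0.0
    clusters: dict[int, Counter] = {}
    for l, t in pairs:
        clusters.setdefault(l, Counter())[t] += 1
    correct = sum(
        max(c.values()) if cid != UNASSIGNED else 0
        for cid, c in clusters.items()
    )
    return correct / len(pairs)
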