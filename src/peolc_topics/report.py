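"""Topic summaries from a partitioned co-occurrence network.

Each detected community becomes a :class:`TopicSummary`: its terms ranked
by within-community weighted degree, plus the documents that best cover
the top keywords.  :func:`compare_periods` matches pre- and
post-intervention summaries by keyword-set Jaccard similarity and flags
communities with no adequate match as emergent (post-only) or vanished
(pre-only) — the structural analogue of a topic appearing after a
vaccination program starts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

from .community import CommunityPartition
from .network import CooccurrenceNetwork
from .textprep import TokenizedDoc

__all__ = [
    "TopicSummary",
    "PeriodComparison",
    "rank_keywords",
    "rank_keywords_by_df",
    "select_representatives",
    "compare_periods",
    "summarize_topics",
]


@dataclass
class TopicSummary:
    """One community rendered as a topic: ranked keywords + exemplars."""

    community: int
    keywords: list[tuple[str, float]]
    size: int
    representatives: list[tuple[str, int]] = field(default_factory=list)


@dataclass
class PeriodComparison:
    """Outcome of matching pre-period topics to post-period topics."""

    matched: list[tuple[int, int, float]]  # (pre id, post id, jaccard)
    emergent: list[int]  # post communities with no pre match
    vanished: list[int]  # pre communities with no post match
    threshold: float


def rank_keywords(
    network: CooccurrenceNetwork,
    partition: CommunityPartition,
    community: int,
    k: int = 10,
) -> list[tuple[str, float]]:
    """Top-k community terms by within-community weighted degree.

    A term's score sums its PMI edge weights to same-community
    neighbors; ties break lexicographically.  A singleton community
    yields its lone term with score 0.
    """
    members = [t for t, c in partition.assignment.items() if c == community]
    if not members:
        raise KeyError(f"community {community} not present in partition")
    member_set = set(members)
    scores = {}
    for t in members:
        s = 0.0
        if t in network.graph:
            for _, v, d in network.graph.edges(t, data=True):
                if v in member_set:
                    s += d["weight"]
        scores[t] = s
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def rank_keywords_by_df(
    network: CooccurrenceNetwork,
    partition: CommunityPartition,
    community: int,
    k: int = 10,
) -> list[tuple[str, float]]:
    """Alternative ranking: raw document frequency within the community."""
    members = [t for t, c in partition.assignment.items() if c == community]
    if not members:
        raise KeyError(f"community {community} not present in partition")
    scores = {
        t: float(network.graph.nodes[t].get("df", 0)) if t in network.graph else 0.0
        for t in members
    }
    return sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))[:k]


def summarize_topics(
    network: CooccurrenceNetwork,
    partition: CommunityPartition,
    k: int = 10,
    ranking: str = "degree",
) -> list[TopicSummary]:
    """One TopicSummary per community, ordered by community id."""
    rank_fn = rank_keywords if ranking == "degree" else rank_keywords_by_df
    sizes: dict[int, int] = {}
    for c in partition.assignment.values():
        sizes[c] = sizes.get(c, 0) + 1
    return [
        TopicSummary(
            community=c,
            keywords=rank_fn(network, partition, c, k),
            size=sizes[c],
        )
        for c in sorted(sizes)
    ]


def select_representatives(
    docs: Sequence[TokenizedDoc],
    summary: TopicSummary,
    r: int = 3,
    timestamps: dict[str, object] | None = None,
) -> list[tuple[str, int]]:
    """The r documents covering the most of the topic's top-10 keywords.

    Coverage counts distinct top-10 keywords present in the document;
    ties go to the earlier timestamp when ``timestamps`` (id →
    sortable time) is given, then to the smaller id.  Documents matching
    no keyword are never returned.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    top = {t for t, _ in summary.keywords[:10]}
    scored = []
    for doc in docs:
        hits = len(top.intersection(doc.tokens))
        if hits > 0:
            ts = timestamps.get(doc.id) if timestamps else None
            scored.append((-hits, ts if ts is not None else doc.id, doc.id, hits))
    scored.sort(key=lambda x: (x[0], str(x[1]), x[2]))
    return [(doc_id, hits) for _, _, doc_id, hits in scored[:r]]


def compare_periods(
    pre_summaries: Sequence[TopicSummary],
    post_summaries: Sequence[TopicSummary],
    threshold: float = 0.1,
    top_k: int = 20,
) -> PeriodComparison:
    """Match pre to post communities by top-``top_k`` keyword Jaccard.

    Greedy maximum-similarity matching: the best-scoring remaining
    (pre, post) pair is matched repeatedly; pairs below ``threshold``
    are left unmatched, so each community lands in exactly one of
    matched / emergent (post-only) / vanished (pre-only).
    """
    if not pre_summaries or not post_summaries:
        raise ValueError("both period summary lists must be nonempty")

    def top_set(s: TopicSummary) -> set[str]:
        return {t for t, _ in s.keywords[:top_k]}

    pre_sets = {s.community: top_set(s) for s in pre_summaries}
    post_sets = {s.community: top_set(s) for s in post_summaries}
    candidates = []
    for pc, ps in pre_sets.items():
        for qc, qs in post_sets.items():
            union = ps | qs
            jac = len(ps & qs) / len(union) if union else 0.0
            candidates.append((jac, pc, qc))
    candidates.sort(key=lambda x: (-x[0], x[1], x[2]))

    matched: list[tuple[int, int, float]] = []
    used_pre: set[int] = set()
    used_post: set[int] = set()
    for jac, pc, qc in candidates:
        if jac < threshold:
            break
        if pc in used_pre or qc in used_post:
            continue
        matched.append((pc, qc, jac))
        used_pre.add(pc)
        used_post.add(qc)
    emergent = sorted(set(post_sets) - used_post)
    vanished = sorted(set(pre_sets) - used_pre)
    return PeriodComparison(
        matched=matched, emergent=emergent, vanished=vanished, threshold=threshold
    )


def report_to_json(
    summaries: Sequence[TopicSummary],
    partition: CommunityPartition,
    path=None,
) -> str:
    """Serialize topic summaries (+ run metadata) as JSON."""
    payload = {
        "modularity": partition.modularity,
        "n_communities": partition.n_communities,
        "seed": partition.seed,
        "topics": [
            {
                "community": s.community,
                "size": s.size,
                "keywords": [{"term": t, "score": sc} for t, sc in s.keywords],
                "representatives": [
                    {"id": i, "matches": h} for i, h in s.representatives
                ],
            }
            for s in summaries
        ],
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def report_to_markdown(summaries: Sequence[TopicSummary]) -> str:
    """Markdown table mimicking a topics/keywords/examples layout."""
    lines = ["| Topic | Keywords | Representative tweet ids |",
             "| --- | --- | --- |"]
    for s in summaries:
        kw = ", ".join(t for t, _ in s.keywords)
        reps = ", ".join(i for i, _ in s.representatives) or "—"
        lines.append(f"| community {s.community} (n={s.size}) | {kw} | {reps} |")
    return "\n".join(lines)
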