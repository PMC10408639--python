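"""Synthetic tweet corpora with planted topic structure.

Real PEoLC tweet streams cannot be redistributed, so every downstream
stage is exercised on generated corpora instead: short documents drawn
from K latent topics (term distributions with controllable cross-topic
vocabulary overlap), a configurable fraction carrying a verbatim PEoLC
filter term, profile locations resolvable to US/GB/CA, and timestamps
spanning a date range around a vaccination-program changepoint.

Generated vocabularies avoid substrings of the PEoLC filter terms, so on
synthetic data the keyword filter accepts exactly the tweets that
received an inserted term.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np

from .corpus import TweetRecord, default_filter_terms

__all__ = [
    "TopicSpec",
    "CorpusSpec",
    "SpecValidationError",
    "make_topic_specs",
    "generate",
    "write_corpus_jsonl",
    "write_ground_truth_csv",
    "DEFAULT_LOCATIONS",
]

# gazetteer-resolvable profile strings per country
DEFAULT_LOCATIONS: dict[str, list[str]] = {
    "US": ["Boston, Massachusetts", "Chicago, Illinois", "Austin, Texas",
           "Seattle, WA", "New York, NY", "Denver, Colorado"],
    "GB": ["London, England", "Manchester, UK", "Edinburgh, Scotland",
           "Cardiff, Wales", "Bristol, United Kingdom"],
    "CA": ["Toronto, Ontario", "Vancouver, British Columbia",
           "Montreal, Quebec", "Halifax, Nova Scotia", "Calgary, Alberta"],
}

_NOISE_URLS = ["https://t.co/abc123", "http://example.org/x", "https://news.example.com/story"]
_NOISE_EMOJI = ["\U0001F600", "\U0001F622", "\U00002764", "\U0001F64F"]
_NOISE_STOPWORDS = ["the", "and", "with", "this", "from", "very"]


class SpecValidationError(ValueError):
    """A corpus/topic specification violates an invariant; names the field."""

    def __init__(self, fieldname: str, message: str):
        self.fieldname = fieldname
        super().__init__(f"{fieldname}: {message}")


@dataclass(frozen=True)
class TopicSpec:
    """A latent topic: a vocabulary and a term distribution over it."""

    topic_id: int
    vocabulary: tuple[str, ...]
    term_weights: tuple[float, ...]

    def validate(self) -> None:
        if len(self.vocabulary) < 5:
            raise SpecValidationError("vocabulary", "needs at least 5 terms")
        for t in self.vocabulary:
            if not t or t != t.lower() or " " in t:
                raise SpecValidationError(
                    "vocabulary", f"term {t!r} must be a nonempty lowercase string"
                )
        if len(self.term_weights) != len(self.vocabulary):
            raise SpecValidationError("term_weights", "length mismatch with vocabulary")
        if abs(sum(self.term_weights) - 1.0) > 1e-9:
            raise SpecValidationError("term_weights", "must sum to 1")


@dataclass(frozen=True)
class CorpusSpec:
    """Full recipe for one synthetic corpus.

    ``peolc_fraction`` is the proportion of tweets that receive one
    verbatim PEoLC filter term (the study regime is a tiny minority of a
    large COVID stream); ``overlap`` is the proportion of vocabulary
    shared across topics; ``changepoint`` emulates a vaccination-program
    start date inside ``date_range``.
    """

    topics: tuple[TopicSpec, ...]
    n_tweets: int
    peolc_fraction: float
    overlap: float
    countries: tuple[tuple[str, float], ...]
    date_range: tuple[datetime, datetime]
    changepoint: datetime
    tokens_per_tweet: tuple[int, int]
    seed: int
    noise_fraction: float = 0.1

    def validate(self) -> None:
        if not self.topics:
            raise SpecValidationError("topics", "at least one topic required")
        for t in self.topics:
            t.validate()
        if self.n_tweets < 0:
            raise SpecValidationError("n_tweets", "must be >= 0")
        if not 0.0 <= self.peolc_fraction <= 1.0:
            raise SpecValidationError("peolc_fraction", "must be in [0, 1]")
        if not 0.0 <= self.overlap <= 1.0:
            raise SpecValidationError("overlap", "must be in [0, 1]")
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise SpecValidationError("noise_fraction", "must be in [0, 1]")
        if abs(sum(p for _, p in self.countries) - 1.0) > 1e-9:
            raise SpecValidationError("countries", "probabilities must sum to 1")
        lo, hi = self.tokens_per_tweet
        if lo > hi or lo < 1:
            raise SpecValidationError("tokens_per_tweet", "need 1 <= min <= max")
        start, end = self.date_range
        if start >= end:
            raise SpecValidationError("date_range", "start must precede end")
        if not (start <= self.changepoint <= end):
            raise SpecValidationError("changepoint", "must lie within date_range")


def _pseudo_word(rng: np.random.Generator) -> str:
    consonants = "bdfgjklmnprstvz"
    vowels = "aeiou"
    n_syll = int(rng.integers(2, 4))
    return "".join(
        consonants[rng.integers(len(consonants))] + vowels[rng.integers(len(vowels))]
        for _ in range(n_syll)
    )


def _collides_with_filter(word: str, filter_terms: list[str]) -> bool:
    return any(word in t.lower() or t.lower() in word for t in filter_terms)


def make_topic_specs(
    k: int,
    vocab_size: int = 20,
    overlap: float = 0.0,
    seed: int = 0,
    concentration: float = 5.0,
) -> tuple[TopicSpec, ...]:
    """Build K topics over generated pseudo-words.

    ``overlap`` is the fraction of each topic's vocabulary drawn from a
    pool shared by all topics; the remainder is unique per topic.  Term
    weights are Dirichlet-distributed (symmetric, ``concentration``).
    Generated words never collide (as substrings) with the PEoLC filter
    terms, keeping the keyword filter exact on synthetic corpora.
    """
    rng = np.random.default_rng(seed)
    filter_terms = default_filter_terms()
    n_shared = int(round(overlap * vocab_size))
    n_unique = vocab_size - n_shared

    def draw_words(n: int, taken: set[str]) -> list[str]:
        out: list[str] = []
        while len(out) < n:
            w = _pseudo_word(rng)
            if w in taken or _collides_with_filter(w, filter_terms):
                continue
            taken.add(w)
            out.append(w)
        return out

    taken: set[str] = set()
    shared = draw_words(n_shared, taken)
    specs = []
    for tid in range(k):
        vocab = draw_words(n_unique, taken) + shared
        weights = rng.dirichlet([concentration] * len(vocab))
        specs.append(
            TopicSpec(
                topic_id=tid,
                vocabulary=tuple(vocab),
                term_weights=tuple(float(w) for w in weights),
            )
        )
    return tuple(specs)


def generate(spec: CorpusSpec) -> tuple[list[TweetRecord], dict[str, int]]:
    """Generate the corpus described by ``spec``.

    Returns the tweet records and the ground-truth map tweet id →
    generating topic id.  Fully deterministic given ``spec.seed``: the
    same spec yields byte-identical corpora.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    filter_terms = [t for t in default_filter_terms() if "#" not in t]
    start, end = spec.date_range
    if start.tzinfo is None:
        start = start.replace(tzinfo=timezone.utc)
    if end.tzinfo is None:
        end = end.replace(tzinfo=timezone.utc)
    country_codes = [c for c, _ in spec.countries]
    country_probs = [p for _, p in spec.countries]

    records: list[TweetRecord] = []
    truth: dict[str, int] = {}
    for i in range(spec.n_tweets):
        tid = int(rng.integers(len(spec.topics)))
        topic = spec.topics[tid]
        lo, hi = spec.tokens_per_tweet
        n_tok = int(rng.integers(lo, hi + 1))
        toks = list(
            rng.choice(topic.vocabulary, size=n_tok, p=topic.term_weights)
        )
        if rng.random() < spec.peolc_fraction:
            pos = int(rng.integers(len(toks) + 1))
            toks.insert(pos, filter_terms[int(rng.integers(len(filter_terms)))])
        if rng.random() < spec.noise_fraction:
            toks.append(_NOISE_STOPWORDS[int(rng.integers(len(_NOISE_STOPWORDS)))])
            toks.append(_NOISE_URLS[int(rng.integers(len(_NOISE_URLS)))])
            toks.append(_NOISE_EMOJI[int(rng.integers(len(_NOISE_EMOJI)))])
        text = " ".join(toks)
        ts = start + (end - start) * float(rng.random())
        cc = country_codes[int(rng.choice(len(country_codes), p=country_probs))]
        locs = DEFAULT_LOCATIONS[cc]
        loc = locs[int(rng.integers(len(locs)))]
        rec_id = f"synth{i:07d}"
        records.append(
            TweetRecord(
                id=rec_id,
                text=text,
                created_at=ts.astimezone(timezone.utc),
                user_location=loc,
                country=cc,
                lang="en",
            )
        )
        truth[rec_id] = tid
    return records, truth


def write_corpus_jsonl(records: list[TweetRecord], path) -> None:
    """Write records as Twitter-API-shaped JSON-lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            obj = {
                "id_str": rec.id,
                "full_text": rec.text,
                "created_at": rec.created_at.strftime("%a %b %d %H:%M:%S +0000 %Y"),
                "user": {"location": rec.user_location},
                "lang": rec.lang,
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def write_ground_truth_csv(truth: dict[str, int], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "topic_id"])
        for tid in sorted(truth):
            writer.writerow([tid, truth[tid]])
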