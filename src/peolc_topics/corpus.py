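"""Corpus loading, PEoLC keyword filtering, and geographic/temporal partitioning.

A tweet stream arrives as JSON-lines (one Twitter-API-shaped object per
line).  This module turns it into :class:`TweetRecord` objects, applies the
palliative and end-of-life care (PEoLC) search filter, resolves free-text
profile locations to countries via a small built-in gazetteer, and splits
each country's records into pre- and post-vaccination-program periods.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone, date, time
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources as _ir
from typing import Iterable

__all__ = [
    "TweetRecord",
    "PeriodSplit",
    "LoadDiagnostics",
    "EmptyCorpusError",
    "default_filter_terms",
    "load_tweets",
    "match_peolc",
    "assign_country",
    "partition_by_period",
    "monthly_counts",
    "share",
    "dedupe_texts",
]

# Twitter API v1.1 timestamp, e.g. "Wed Oct 10 20:19:24 +0000 2018"
_TWITTER_TS = "%a %b %d %H:%M:%S %z %Y"


@dataclass(frozen=True)
class TweetRecord:
    """One raw tweet: identity, text, timing and (resolved) location."""

    id: str
    text: str
    created_at: datetime
    user_location: str = ""
    country: str | None = None
    lang: str = "en"


@dataclass
class LoadDiagnostics:
    """Counts of lines excluded while loading a JSONL corpus."""

    n_lines: int = 0
    n_loaded: int = 0
    n_malformed: int = 0
    n_missing_fields: int = 0
    n_bad_date: int = 0
    n_non_english: int = 0


@dataclass
class PeriodSplit:
    """A country's records split at the vaccination-program start date.

    ``pre`` holds records created strictly before 00:00 UTC on
    ``start_date``; ``post`` holds the rest.  Percentages are of the
    country total, half-up rounded.
    """

    country: str
    start_date: date
    pre: list[TweetRecord] = field(default_factory=list)
    post: list[TweetRecord] = field(default_factory=list)

    @property
    def n_pre(self) -> int:
        return len(self.pre)

    @property
    def n_post(self) -> int:
        return len(self.post)

    @property
    def n_total(self) -> int:
        return self.n_pre + self.n_post

    def percentages(self, decimals: int = 2) -> tuple[float, float]:
        if self.n_total == 0:
            return (0.0, 0.0)
        return (
            share(self.n_pre, self.n_total, decimals),
            share(self.n_post, self.n_total, decimals),
        )


class EmptyCorpusError(ValueError):
    """Raised when a JSONL file yields no well-formed tweet records."""


def share(numerator: int, denominator: int, decimals: int = 2) -> float:
    """Percentage ``numerator/denominator*100`` with half-up rounding.

    Half-up (not banker's) rounding matches how corpus shares are
    conventionally printed, e.g. ``share(1739, 4133) == 42.08``.
    """
    if denominator == 0:
        raise ZeroDivisionError("share() with zero denominator")
    q = Decimal(numerator) / Decimal(denominator) * 100
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


def default_filter_terms() -> list[str]:
    """The PEoLC search-filter terms shipped with the package.

    Read verbatim from the bundled plain-text resource (one term per
    line, as published), deduplicated case-insensitively while
    preserving first-seen order.
    """
    text = (
        _ir.files("peolc_topics.resources")
        .joinpath("peolc_filter_terms.txt")
        .read_text(encoding="utf-8")
    )
    seen: set[str] = set()
    out: list[str] = []
    for line in text.splitlines():
        term = line.strip()
        if term and term.lower() not in seen:
            seen.add(term.lower())
            out.append(term)
    return out


def match_peolc(text: str, terms: Iterable[str] | None = None) -> bool:
    """True iff ``text`` contains at least one PEoLC filter term.

    Matching is case-insensitive substring matching on whitespace-collapsed
    text, so multiword terms match across single spaces and hashtag terms
    (``#eol``) match literally.  Substring (rather than token-boundary)
    matching is deliberate: the filter list mixes hashtags, fused forms
    ("pallcare") and phrases, and substring semantics is the most
    conservative reading of such a filter.
    """
    if terms is None:
        terms = default_filter_terms()
    terms = list(terms)
    if not terms:
        raise ValueError("filter term list is empty")
    for t in terms:
        if not t or not t.strip():
            raise ValueError("filter term list contains an empty term")
    haystack = " ".join(text.lower().split())
    return any(t.lower() in haystack for t in terms)


def load_tweets(path) -> tuple[list[TweetRecord], LoadDiagnostics]:
    """Load a JSONL tweet file into records, skipping bad lines.

    Each line must be a JSON object with ``id_str``, ``full_text`` (or
    ``text``), ``created_at`` and ``lang``; ``user.location`` is optional.
    Records that are malformed, missing required fields, or carry an
    unparseable date are skipped and counted in the diagnostics; records
    with ``lang != "en"`` are excluded (the corpus is English-only).

    Raises
    ------
    OSError
        If the file cannot be read.
    EmptyCorpusError
        If no line yields a well-formed record.
    """
    diags = LoadDiagnostics()
    records: list[TweetRecord] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            diags.n_lines += 1
            try:
                obj = json.loads(line)
                if not isinstance(obj, dict):
                    raise ValueError
            except ValueError:
                diags.n_malformed += 1
                continue
            tid = obj.get("id_str") or obj.get("id")
            text = obj.get("full_text") or obj.get("text")
            created = obj.get("created_at")
            lang = obj.get("lang")
            if not tid or text is None or not created or lang is None:
                diags.n_missing_fields += 1
                continue
            try:
                ts = parse_created_at(created)
            except ValueError:
                diags.n_bad_date += 1
                continue
            if lang != "en":
                diags.n_non_english += 1
                continue
            loc = (obj.get("user") or {}).get("location") or ""
            records.append(
                TweetRecord(
                    id=str(tid),
                    text=text,
                    created_at=ts,
                    user_location=loc,
                    country=assign_country(loc),
                    lang=lang,
                )
            )
            diags.n_loaded += 1
    if diags.n_lines > 0 and diags.n_loaded == 0 and diags.n_non_english == 0:
        raise EmptyCorpusError(f"no well-formed tweet lines in {path}")
    if diags.n_lines == 0:
        raise EmptyCorpusError(f"{path} is empty")
    return records, diags


def parse_created_at(value: str) -> datetime:
    """Parse a tweet timestamp (Twitter v1.1 format or ISO-8601) to UTC."""
    try:
        return datetime.strptime(value, _TWITTER_TS).astimezone(timezone.utc)
    except ValueError:
        pass
    dt = datetime.fromisoformat(value.replace("Z", "+00:00"))
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.astimezone(timezone.utc)


# ---------------------------------------------------------------------------
# Gazetteer
# ---------------------------------------------------------------------------

_US_STATES = {
    "alabama": "AL", "alaska": "AK", "arizona": "AZ", "arkansas": "AR",
    "california": "CA", "colorado": "CO", "connecticut": "CT",
    "delaware": "DE", "florida": "FL", "georgia": "GA", "hawaii": "HI",
    "idaho": "ID", "illinois": "IL", "indiana": "IN", "iowa": "IA",
    "kansas": "KS", "kentucky": "KY", "louisiana": "LA", "maine": "ME",
    "maryland": "MD", "massachusetts": "MA", "michigan": "MI",
    "minnesota": "MN", "mississippi": "MS", "missouri": "MO",
    "montana": "MT", "nebraska": "NE", "nevada": "NV",
    "new hampshire": "NH", "new jersey": "NJ", "new mexico": "NM",
    "new york": "NY", "north carolina": "NC", "north dakota": "ND",
    "ohio": "OH", "oklahoma": "OK", "oregon": "OR", "pennsylvania": "PA",
    "rhode island": "RI", "south carolina": "SC", "south dakota": "SD",
    "tennessee": "TN", "texas": "TX", "utah": "UT", "vermont": "VT",
    "virginia": "VA", "washington": "WA", "west virginia": "WV",
    "wisconsin": "WI", "wyoming": "WY",
}

_CA_PROVINCES = {
    "ontario": "ON", "quebec": "QC", "british columbia": "BC",
    "alberta": "AB", "manitoba": "MB", "saskatchewan": "SK",
    "nova scotia": "NS", "new brunswick": "NB",
    "newfoundland": "NL", "newfoundland and labrador": "NL",
    "prince edward island": "PE", "yukon": "YT",
    "northwest territories": "NT", "nunavut": "NU",
}

_UK_NATIONS = ["england", "scotland", "wales", "northern ireland"]

_US_CITIES = [
    "new york city", "nyc", "los angeles", "chicago", "houston", "phoenix",
    "philadelphia", "san antonio", "san diego", "dallas", "san jose",
    "austin", "san francisco", "seattle", "denver", "boston", "nashville",
    "detroit", "portland", "memphis", "las vegas", "baltimore",
    "milwaukee", "albuquerque", "atlanta", "miami", "minneapolis",
    "new orleans", "cleveland", "pittsburgh", "washington dc",
    "washington, d.c.", "brooklyn", "manhattan",
]

_GB_CITIES = [
    "london", "birmingham", "manchester", "glasgow", "liverpool", "leeds",
    "sheffield", "edinburgh", "bristol", "cardiff", "belfast", "leicester",
    "nottingham", "newcastle", "southampton", "oxford", "cambridge",
    "brighton", "york", "aberdeen", "dundee", "swansea",
]

_CA_CITIES = [
    "toronto", "montreal", "vancouver", "calgary", "edmonton", "ottawa",
    "winnipeg", "mississauga", "hamilton", "halifax", "victoria",
    "saskatoon", "regina", "quebec city", "st. john's",
]

_COUNTRY_NAMES = {
    "united states": "US", "united states of america": "US", "usa": "US",
    "america": "US", "u.s.": "US", "u.s.a.": "US",
    "united kingdom": "GB", "uk": "GB", "u.k.": "GB", "britain": "GB",
    "great britain": "GB",
    "canada": "CA",
}


def _build_gazetteer() -> tuple[dict[str, str], dict[str, str]]:
    phrases: dict[str, str] = {}
    phrases.update(_COUNTRY_NAMES)
    for name in _US_STATES:
        phrases[name] = "US"
    for name in _CA_PROVINCES:
        phrases[name] = "CA"
    for name in _UK_NATIONS:
        phrases[name] = "GB"
    for city in _US_CITIES:
        phrases[city] = "US"
    for city in _GB_CITIES:
        phrases[city] = "GB"
    for city in _CA_CITIES:
        phrases[city] = "CA"
    # Uppercase-only abbreviations. US state codes take precedence over
    # clashing ISO country codes ("CA" reads as California, not Canada),
    # keeping "Los Angeles, CA" unambiguous.
    abbrevs: dict[str, str] = {"GB": "GB", "UK": "GB", "CA": "CA", "US": "US",
                               "USA": "US", "CAN": "CA"}
    for code in _CA_PROVINCES.values():
        abbrevs[code] = "CA"
    for code in _US_STATES.values():
        abbrevs[code] = "US"
    return phrases, abbrevs


_PHRASES, _ABBREVS = _build_gazetteer()
# longest phrases first so "new york" wins over "york"
_PHRASE_ORDER = sorted(_PHRASES, key=lambda p: -len(p.split()))


def assign_country(user_location: str) -> str | None:
    """Resolve a free-text profile location to US / GB / CA, or ``None``.

    The gazetteer covers country names and abbreviations, US states,
    Canadian provinces, UK nations and major cities.  A location resolves
    only when all its gazetteer hits agree on one country; conflicting
    hits ("London / New York") and unknown strings yield ``None``.
    """
    if not user_location or not user_location.strip():
        return None
    import re as _re

    cleaned = _re.sub(r"[,/|;()!?]", " ", user_location)
    tokens = cleaned.split()
    lower = [t.lower().strip(".") for t in tokens]
    hits: set[str] = set()

    consumed = [False] * len(lower)
    for phrase in _PHRASE_ORDER:
        words = phrase.replace(",", "").replace(".", "").split()
        L = len(words)
        for i in range(len(lower) - L + 1):
            if any(consumed[i : i + L]):
                continue
            if lower[i : i + L] == words:
                hits.add(_PHRASES[phrase])
                for j in range(i, i + L):
                    consumed[j] = True
    for i, tok in enumerate(tokens):
        if consumed[i]:
            continue
        bare = tok.strip(".,")
        if bare.isupper() and bare in _ABBREVS:
            hits.add(_ABBREVS[bare])
    if len(hits) == 1:
        return hits.pop()
    return None


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------


def partition_by_period(
    records: Iterable[TweetRecord], country: str, start_date: date
) -> PeriodSplit:
    """Split one country's records at 00:00 UTC on ``start_date``.

    The start date itself belongs to "post": a tweet posted on the day a
    vaccination program starts counts as after the start.  Records of
    other countries are excluded; ``|pre| + |post|`` always equals the
    number of input records for ``country``.
    """
    cutoff = datetime.combine(start_date, time.min, tzinfo=timezone.utc)
    split = PeriodSplit(country=country, start_date=start_date)
    for rec in records:
        if rec.country != country:
            continue
        if rec.created_at < cutoff:
            split.pre.append(rec)
        else:
            split.post.append(rec)
    if split.n_total == 0:
        import warnings

        warnings.warn(f"no records for country {country}", stacklevel=2)
    return split


def monthly_counts(
    records: Iterable[TweetRecord],
    countries: Iterable[str] = ("US", "GB", "CA"),
) -> tuple[dict[tuple[int, int], int], dict[tuple[int, int], dict[str, float]]]:
    """Per-month tweet counts and per-country proportions.

    Returns ``(counts, proportions)`` where ``counts[(year, month)]`` is
    the number of records created that month and
    ``proportions[(year, month)]`` maps each reported country code, plus
    ``"other"``, to its fraction of that month (fractions sum to 1).
    """
    countries = list(countries)
    counts: dict[tuple[int, int], int] = {}
    by_country: dict[tuple[int, int], dict[str, int]] = {}
    for rec in records:
        key = (rec.created_at.year, rec.created_at.month)
        counts[key] = counts.get(key, 0) + 1
        cc = rec.country if rec.country in countries else "other"
        month = by_country.setdefault(key, {})
        month[cc] = month.get(cc, 0) + 1
    proportions = {
        key: {cc: n / counts[key] for cc, n in month.items()}
        for key, month in by_country.items()
    }
    return counts, proportions


def dedupe_texts(records: Iterable[TweetRecord]) -> list[TweetRecord]:
    """Drop exact text duplicates, keeping each text's earliest record."""
    ordered = sorted(records, key=lambda r: (r.created_at, r.id))
    seen: set[str] = set()
    out = []
    for rec in ordered:
        if rec.text not in seen:
            seen.add(rec.text)
            out.append(rec)
    return out
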