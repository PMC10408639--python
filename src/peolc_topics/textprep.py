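"""Four-step tweet preprocessing: clean, tokenize, de-stopword, normalize.

The chain reduces raw tweet text to canonical root-form terms suitable for
co-occurrence counting.  The stages run in a fixed order —
``clean_text`` → ``tokenize`` → ``remove_stopwords`` → ``normalize`` —
and the full chain is idempotent.  :class:`TweetPreprocessor` exposes the
chain as a scikit-learn transformer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

__all__ = [
    "TokenizedDoc",
    "clean_text",
    "tokenize",
    "remove_stopwords",
    "normalize",
    "lemmatize_noun",
    "stem_light",
    "preprocess",
    "TweetPreprocessor",
    "DEFAULT_STOPWORDS",
]

DEFAULT_STOPWORDS: frozenset[str] = frozenset(ENGLISH_STOP_WORDS)


@dataclass(frozen=True)
class TokenizedDoc:
    """A tweet reduced to its ordered canonical terms."""

    id: str
    tokens: tuple[str, ...]


_URL_RE = re.compile(r"(?:https?://\S+|www\.\S+|\bt\.co/\S+)", re.IGNORECASE)
# Unicode emoji blocks: misc symbols/pictographs, emoticons, transport,
# supplemental symbols, flags, dingbats, variation selectors, ZWJ.
_EMOJI_RE = re.compile(
    "["
    "\U0001F000-\U0001FAFF"
    "\U00002600-\U000027BF"
    "\U0001F1E6-\U0001F1FF"
    "\U00002190-\U000021FF"
    "\U00002B00-\U00002BFF"
    "\U0000FE00-\U0000FE0F"
    "\U0000200D"
    "\U00002764"
    "]+"
)
_TOKEN_SPLIT_RE = re.compile(r"[^\w]+", re.UNICODE)


def clean_text(text: str) -> str:
    """Strip URLs and emoji; unwrap mentions and hashtags; collapse spaces.

    ``@user`` loses its ``@`` and ``#hashtag`` its ``#`` — the body token
    is kept, since hashtag bodies carry topical vocabulary in this domain
    (e.g. "hpm", "hapc").
    """
    text = _URL_RE.sub(" ", text)
    text = _EMOJI_RE.sub(" ", text)
    text = re.sub(r"[@#](\w)", r"\1", text)
    return " ".join(text.split())


def tokenize(text: str, min_len: int = 2, drop_numeric: bool = True) -> list[str]:
    """Lowercase and split on whitespace/punctuation.

    Tokens shorter than ``min_len`` and purely numeric tokens are dropped
    (alphanumerics like "covid19" survive) to keep the vocabulary
    meaningful for network construction.
    """
    out = []
    for tok in _TOKEN_SPLIT_RE.split(text.lower()):
        if len(tok) < min_len:
            continue
        if drop_numeric and tok.isdigit():
            continue
        out.append(tok)
    return out


def remove_stopwords(
    tokens: Sequence[str], stoplist: Iterable[str] | None = None
) -> list[str]:
    """Order-preserving removal of exact stoplist matches."""
    stops = frozenset(stoplist) if stoplist is not None else DEFAULT_STOPWORDS
    if not stops:
        raise ValueError("stopword list is empty")
    return [t for t in tokens if t not in stops]


# Irregular noun plurals and forms the suffix rules would mangle.
_LEMMA_EXCEPTIONS = {
    "men": "man", "women": "woman", "children": "child", "people": "people",
    "feet": "foot", "teeth": "tooth", "mice": "mouse", "geese": "goose",
    "lives": "life", "wives": "wife", "knives": "knife", "leaves": "leaf",
    "selves": "self", "this": "this", "news": "news", "series": "series",
    "species": "species", "analyses": "analysis", "crises": "crisis",
    "diagnoses": "diagnosis", "data": "data", "media": "media",
}

# Singulars that end in s and must not be clipped.
_S_FINAL_OK = ("ss", "us", "is", "ous")


def lemmatize_noun(token: str) -> str:
    """Noun-default dictionary/rule lemmatizer.

    Maps regular English plurals to their singular (nurses→nurse,
    families→family, churches→church) via an exception table plus suffix
    rules; anything else — including verb forms like "died", which a
    noun-default lemmatizer leaves alone — passes through unchanged.
    """
    if token in _LEMMA_EXCEPTIONS:
        return _LEMMA_EXCEPTIONS[token]
    if len(token) < 4 or not token.endswith("s"):
        return token
    if token.endswith(_S_FINAL_OK):
        return token
    if token.endswith("ies"):
        return token[:-3] + "y"
    if token.endswith(("ches", "shes", "xes", "sses")):
        return token[:-2]
    if token.endswith("ves") and token[:-3] + "f" in _LEMMA_EXCEPTIONS.values():
        return token[:-3] + "f"
    return token[:-1]


def stem_light(token: str) -> str:
    """Light suffix-stripping stemmer (alternative normalizer)."""
    for suffix in ("ingly", "edly", "ing", "ed", "ly", "es", "s"):
        if token.endswith(suffix) and len(token) - len(suffix) >= 3:
            stem = token[: -len(suffix)]
            if suffix in ("ing", "ed") and len(stem) >= 3 and stem[-1] == stem[-2]:
                stem = stem[:-1]  # stopped→stop
            return stem
    return token


_NORMALIZERS = {
    "lemma": lemmatize_noun,
    "stem": stem_light,
    "none": lambda t: t,
}


def normalize(tokens: Sequence[str], method: str = "lemma") -> list[str]:
    """Map each token to its root form; unknown tokens pass through.

    ``method`` selects the normalizer: ``"lemma"`` (noun-default
    lemmatizer, the canonical choice — reported topic keywords are lemmas,
    not stems), ``"stem"`` (light suffix stripper) or ``"none"``.
    """
    try:
        fn = _NORMALIZERS[method]
    except KeyError:
        raise ValueError(
            f"unknown normalizer {method!r}; choose from {sorted(_NORMALIZERS)}"
        ) from None
    return [fn(t) for t in tokens]


def preprocess(
    text: str,
    stoplist: Iterable[str] | None = None,
    normalizer: str = "lemma",
    min_token_len: int = 2,
    drop_numeric: bool = True,
) -> list[str]:
    """Run the full four-step chain on one raw text.

    A lemma that lands on a stopword ("ones" → "one") is filtered after
    normalization, so output never contains active stopwords and the
    chain is idempotent.
    """
    tokens = tokenize(clean_text(text), min_len=min_token_len, drop_numeric=drop_numeric)
    tokens = remove_stopwords(tokens, stoplist)
    return remove_stopwords(normalize(tokens, normalizer), stoplist)


class TweetPreprocessor(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer wrapping the preprocessing chain.

    Parameters
    ----------
    normalizer : {"lemma", "stem", "none"}, default="lemma"
        Root-form normalizer applied after stopword removal.
    stopwords : iterable of str, optional
        Stoplist; defaults to scikit-learn's English list.
    min_token_len : int, default=2
        Tokens shorter than this are dropped at tokenization.
    drop_numeric : bool, default=True
        Drop purely numeric tokens.
    """

    def __init__(
        self,
        normalizer: str = "lemma",
        stopwords: Iterable[str] | None = None,
        min_token_len: int = 2,
        drop_numeric: bool = True,
    ):
        self.normalizer = normalizer
        self.stopwords = stopwords
        self.min_token_len = min_token_len
        self.drop_numeric = drop_numeric

    def fit(self, X, y=None):
        if self.normalizer not in _NORMALIZERS:
            raise ValueError(f"unknown normalizer {self.normalizer!r}")
        self.stopwords_ = (
            frozenset(self.stopwords) if self.stopwords is not None else DEFAULT_STOPWORDS
        )
        return self

    def transform(self, X) -> list[list[str]]:
        """Transform raw texts (or objects with ``.text``) to token lists."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "stopwords_")
        out = []
        for item in X:
            text = item if isinstance(item, str) else item.text
            out.append(
                preprocess(
                    text,
                    stoplist=self.stopwords_,
                    normalizer=self.normalizer,
                    min_token_len=self.min_token_len,
                    drop_numeric=self.drop_numeric,
                )
            )
        return out

    def transform_docs(self, records) -> list[TokenizedDoc]:
        """Transform TweetRecords to :class:`TokenizedDoc` (ids kept)."""
        tokens = self.transform(records)
        return [
            TokenizedDoc(id=rec.id, tokens=tuple(toks))
            for rec, toks in zip(records, tokens)
        ]
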