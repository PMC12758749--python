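"""Post-text preprocessing: cleaning, heat-keyword filtering, stopword
handling, pluggable segmentation and word-frequency ranking.

Cleaning is privacy-first: personally identifying patterns (phone-number-like
11-digit runs, national-ID-like 15/18-digit runs, decimal latitude/longitude
pairs) are stripped with conservative regexes — over-removal is acceptable,
under-removal is not. Platform noise (URLs, user mentions, hashtag markers,
emoji, advertisement-looking Latin fragments) is removed in the same pass.

Segmentation is a contract, not an implementation: any callable mapping a
string to an ordered token list may be injected (e.g. a Chinese segmenter);
the bundled default splits on whitespace, which is what synthetic corpora
use.
"""
from __future__ import annotations

import logging
import re
from collections import Counter
from collections.abc import Callable, Iterable, Sequence
from dataclasses import dataclass, replace

from .records import PostRecord

log = logging.getLogger(__name__)

Segmenter = Callable[[str], list[str]]

#: Default heat-keyword set (English equivalents of the crawl keywords).
DEFAULT_KEYWORDS = frozenset(
    {"high temperature", "hot", "sweating", "heat stroke", "scorching"}
)

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_MENTION_RE = re.compile(r"@[\w一-鿿]+")
_HASHTAG_MARK_RE = re.compile(r"#")
# PII: longest digit runs first so an 18-digit ID is not left as 11+7.
_ID18_RE = re.compile(r"(?<!\d)\d{18}(?!\d)")
_ID15_RE = re.compile(r"(?<!\d)\d{15}(?!\d)")
_PHONE_RE = re.compile(r"(?<!\d)\d{11}(?!\d)")
_LATLONG_RE = re.compile(r"[+-]?\d{1,3}\.\d+\s*,\s*[+-]?\d{1,3}\.\d+")
# Advertisement-looking Latin fragments: unbroken alphanumeric runs of 20+,
# or three or more consecutive ALL-CAPS words (typical spam shouting).
_AD_RUN_RE = re.compile(r"(?<![0-9A-Za-z])[0-9A-Za-z]{20,}(?![0-9A-Za-z])")
_AD_CAPS_RE = re.compile(r"\b[A-Z]{2,}(?:\s+[A-Z]{2,}){2,}\b")
_EMOJI_RE = re.compile(
    "["
    "\U0001f000-\U0001faff"  # symbols, pictographs, emoticons, extended
    "☀-➿"          # misc symbols and dingbats
    "⬀-⯿"
    "︎️"           # variation selectors
    "‍"                 # zero-width joiner
    "]+"
)

_CLEAN_PASSES = (
    _URL_RE,
    _MENTION_RE,
    _HASHTAG_MARK_RE,
    _EMOJI_RE,
    _AD_RUN_RE,
    _AD_CAPS_RE,
    _LATLONG_RE,
    _ID18_RE,
    _ID15_RE,
    _PHONE_RE,
)


def clean_text(raw: str) -> str:
    """Strip platform noise and PII from raw post text.

    Cleaning is total (never raises) and idempotent; removed spans are
    replaced by a space and whitespace is then normalised, so no removal can
    splice two fragments into a new removable pattern.
    """
    text = raw
    for pattern in _CLEAN_PASSES:
        text = pattern.sub(" ", text)
    return " ".join(text.split())


def filter_heat_related(
    post: PostRecord | str, keywords: Iterable[str] = DEFAULT_KEYWORDS
) -> bool:
    """True iff any keyword occurs as a substring of the (cleaned) text.

    Matching is case-folded, so Latin keywords match regardless of case.
    An empty keyword set is an error: it would silently drop every post.
    """
    kws = {k.casefold() for k in keywords if k}
    if not kws:
        raise ValueError("empty keyword set: the filter would drop everything")
    text = (post.raw_text if isinstance(post, PostRecord) else post).casefold()
    return any(k in text for k in kws)


@dataclass(frozen=True)
class StopwordSet:
    """A merged stopword set with the names of its source lists."""

    tokens: frozenset[str]
    provenance: tuple[str, ...]

    def __contains__(self, token: str) -> bool:
        return token in self.tokens


def merge_stopwords(
    lists: Sequence[Iterable[str]],
    corpus: Iterable[str] | None = None,
    provenance: Sequence[str] | None = None,
) -> StopwordSet:
    """Union several stopword lists, optionally pruning unused members.

    When a corpus token stream is supplied, members with zero occurrence in
    it are dropped (removal of archaic list entries that never appear in the
    data). Empty-string members are discarded.
    """
    union: set[str] = set()
    for lst in lists:
        union.update(t for t in lst if t)
    if not union:
        raise ValueError("all stopword lists are empty")
    names = tuple(provenance) if provenance is not None else tuple(
        f"list{i}" for i in range(len(lists))
    )
    if corpus is not None:
        seen = set(corpus)
        union &= seen
    return StopwordSet(tokens=frozenset(union), provenance=names)


def read_stopword_list(path) -> list[str]:
    """Read a plain-text stopword list: one token per line, ``#`` comments
    and blank lines ignored, UTF-8."""
    tokens = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens.append(line)
    return tokens


def detect_platform_markers(
    corpus: Sequence[PostRecord] | Sequence[Sequence[str]],
    df_threshold: float = 0.30,
) -> list[str]:
    """Candidate platform discourse-marker stopwords by document frequency.

    Tokens appearing in more than ``df_threshold`` of documents are returned,
    ranked by document frequency descending (ties lexicographic). This is a
    deliberately simple stand-in for corpus-specific marker extraction: a
    token present in a third of all posts carries no topical signal.
    """
    if not (0.0 < df_threshold <= 1.0):
        raise ValueError(f"df_threshold must be in (0, 1], got {df_threshold}")
    docs = [
        list(d.tokens) if isinstance(d, PostRecord) else list(d) for d in corpus
    ]
    n_docs = len(docs)
    if n_docs == 0:
        return []
    df: Counter[str] = Counter()
    for doc in docs:
        df.update(set(doc))
    hits = [(t, c / n_docs) for t, c in df.items() if c / n_docs > df_threshold]
    hits.sort(key=lambda tc: (-tc[1], tc[0]))
    return [t for t, _ in hits]


def whitespace_segmenter(text: str) -> list[str]:
    """Default segmenter: split on runs of whitespace."""
    return text.split()


def tokenize(
    post: PostRecord,
    segmenter: Segmenter = whitespace_segmenter,
    stopwords: StopwordSet | Iterable[str] | None = None,
) -> PostRecord:
    """Segment a cleaned post and drop stopwords, preserving segmenter order.

    Returns a new record; the input is not mutated. The segmenter may be any
    ``str -> list[str]`` callable (whitespace by default; inject an external
    Chinese segmenter for real microblog text).
    """
    tokens = segmenter(post.raw_text)
    if not isinstance(tokens, list):
        raise TypeError(
            f"segmenter must return a list of tokens, got {type(tokens).__name__}"
        )
    if stopwords is not None:
        sw = stopwords.tokens if isinstance(stopwords, StopwordSet) else set(stopwords)
        tokens = [t for t in tokens if t not in sw]
    return replace(post, tokens=list(tokens))


def word_frequencies(
    corpus: Sequence[PostRecord] | Sequence[Sequence[str]],
    top_k: int,
) -> list[tuple[str, int]]:
    """Top-``top_k`` tokens by corpus count, ties broken lexicographically."""
    if top_k <= 0:
        raise ValueError(f"top_k must be positive, got {top_k}")
    counts: Counter[str] = Counter()
    for doc in corpus:
        counts.update(doc.tokens if isinstance(doc, PostRecord) else doc)
    ranked = sorted(counts.items(), key=lambda tc: (-tc[1], tc[0]))
    return ranked[:top_k]
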