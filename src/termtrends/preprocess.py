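"""Text normalization: symbol mapping, tokenization, filtering, plural rules.

Cleaned abstract text is turned into two parallel lowercase token streams:

* the **matching stream** keeps stop words — it is what multiword terms such
  as "men who have sex with men" are matched against, and what the per-year
  vocabulary size (the TF denominator, "all words") is counted on;
* the **discovery stream** drops stop words — it feeds unigram ranking during
  terminology discovery, where function words are noise.

Numbers, punctuation and diacritic marks are filtered out: digits are
stripped (purely numeric tokens vanish), punctuation splits tokens, and
accented characters are transliterated to their ASCII base letters.  Symbol
conversion (``HIV+`` -> ``hiv positive``) happens on the raw text, before
tokenization would destroy the symbol.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "PreprocessConfig",
    "TokenStream",
    "DEFAULT_STOPWORDS",
    "DEFAULT_SYMBOL_MAP",
    "DEFAULT_PLURAL_EXCEPTIONS",
    "load_config",
    "apply_symbol_map",
    "transliterate",
    "tokenize_and_filter",
    "preprocess_corpus",
    "singularize",
    "pluralize",
]

# Small English function-word list; the matching stream retains these, the
# discovery stream drops them.  Configurable via the YAML config.
DEFAULT_STOPWORDS: frozenset[str] = frozenset(
    """
    the a an and or of in on at to for with by from as is are was were be been
    being that this these those it its he him she her they them his their we
    us our you your i me my not no nor but if then than so such do does did
    done can could may might must will would shall should have has had having
    who whom whose which what when where why how about into onto over under
    up down out off between among through during before after above below
    again further once here there all any both each few more most other some
    only own same too very
    """.split()
)

# Symbol-bearing surface forms replaced before tokenization.  Word-boundary
# delimited and case-insensitive; longest key first.
DEFAULT_SYMBOL_MAP: dict[str, str] = {
    "hiv+": "hiv positive",
    "hiv-": "hiv negative",
}

# Words never singularized: disease/organization acronyms and lexical plurals.
DEFAULT_PLURAL_EXCEPTIONS: frozenset[str] = frozenset(
    {"aids", "sms", "mens", "lens", "news", "series", "species", "measles",
     "herpes", "diabetes", "pertussis", "syphilis"}
)


@dataclass
class PreprocessConfig:
    stopwords: frozenset[str] = DEFAULT_STOPWORDS
    symbol_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SYMBOL_MAP))
    plural_exceptions: frozenset[str] = DEFAULT_PLURAL_EXCEPTIONS

    def __post_init__(self) -> None:
        self.stopwords = frozenset(w.lower() for w in self.stopwords)
        self.plural_exceptions = frozenset(w.lower() for w in self.plural_exceptions)
        # longest key first so "hiv+" style keys win over any shorter overlap
        self.symbol_map = dict(
            sorted(self.symbol_map.items(), key=lambda kv: -len(kv[0]))
        )


DEFAULT_CONFIG = PreprocessConfig()


def load_config(path: str | Path) -> PreprocessConfig:
    """Read a :class:`PreprocessConfig` from a YAML file.

    Recognized keys: ``stopwords`` (list), ``symbol_map`` (mapping),
    ``plural_exceptions`` (list).  Missing keys fall back to the defaults.
    """
    with Path(path).open(encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return PreprocessConfig(
        stopwords=frozenset(data.get("stopwords", DEFAULT_STOPWORDS)),
        symbol_map=dict(data.get("symbol_map", DEFAULT_SYMBOL_MAP)),
        plural_exceptions=frozenset(
            data.get("plural_exceptions", DEFAULT_PLURAL_EXCEPTIONS)
        ),
    )


@dataclass(frozen=True)
class TokenStream:
    """Normalized token streams of one abstract.

    ``sentence_breaks`` holds matching-stream indices *i* such that a sentence
    boundary falls immediately after ``matching_tokens[i]``; n-gram windows
    never span such a boundary.
    """

    abstract_id: str
    year: int
    matching_tokens: tuple[str, ...]
    discovery_tokens: tuple[str, ...]
    sentence_breaks: frozenset[int] = frozenset()


def apply_symbol_map(text: str, config: PreprocessConfig | None = None) -> str:
    """Replace every symbol-map key (word-boundary, case-insensitive) by its phrase."""
    config = config or DEFAULT_CONFIG
    for key, phrase in config.symbol_map.items():
        pattern = re.compile(r"(?<!\w)" + re.escape(key) + r"(?!\w)", re.IGNORECASE)
        text = pattern.sub(phrase, text)
    return text


def transliterate(text: str) -> str:
    """Map accented characters to ASCII base letters (NFKD, combining marks dropped)."""
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch))


_TOKEN_RE = re.compile(r"[a-z0-9]+")
_SENTENCE_PUNCT = re.compile(r"[.!?;]")
_DIGITS = re.compile(r"[0-9]+")


def tokenize_and_filter(
    text: str,
    config: PreprocessConfig | None = None,
    abstract_id: str = "",
    year: int = 0,
) -> TokenStream:
    """Split normalized text into the matching and discovery token streams.

    Assumes the symbol map was already applied.  Splits on non-alphanumeric
    boundaries, lowercases, transliterates diacritics, strips digits (purely
    numeric tokens are dropped), and records sentence-final punctuation
    positions for downstream n-gram windowing.
    """
    config = config or DEFAULT_CONFIG
    lowered = transliterate(text).casefold()
    matching: list[str] = []
    breaks: set[int] = set()
    prev_end = 0
    for m in _TOKEN_RE.finditer(lowered):
        if matching and _SENTENCE_PUNCT.search(lowered, prev_end, m.start()):
            breaks.add(len(matching) - 1)
        token = _DIGITS.sub("", m.group())
        prev_end = m.end()
        if token:
            matching.append(token)
    discovery = tuple(t for t in matching if t not in config.stopwords)
    return TokenStream(
        abstract_id=abstract_id,
        year=year,
        matching_tokens=tuple(matching),
        discovery_tokens=discovery,
        sentence_breaks=frozenset(breaks),
    )


def preprocess_corpus(corpus, config: PreprocessConfig | None = None) -> list[TokenStream]:
    """Symbol-map then tokenize every abstract of an ``AbstractCorpus``."""
    config = config or DEFAULT_CONFIG
    return [
        tokenize_and_filter(
            apply_symbol_map(a.text, config), config, abstract_id=a.id, year=a.year
        )
        for a in corpus
    ]


def singularize(token: str, config: PreprocessConfig | None = None) -> str:
    """Rule-based singular form of a normalized lowercase word.

    ``-ies`` -> ``-y``; ``-ses``/``-xes``/``-ches``/``-shes`` -> drop ``es``;
    otherwise a trailing ``s`` is dropped when the word is longer than three
    characters.  Words in the plural-exception list ("aids", ...) and words
    ending in ``-ss`` are returned unchanged.  Idempotent on its own output.
    """
    config = config or DEFAULT_CONFIG
    if token in config.plural_exceptions or len(token) <= 3 or not token.endswith("s"):
        return token
    if token.endswith("ies") and len(token) > 4:
        return token[:-3] + "y"
    if token.endswith(("ses", "xes", "ches", "shes")):
        return token[:-2]
    if token.endswith("ss"):
        return token
    return token[:-1]


def pluralize(token: str, config: PreprocessConfig | None = None) -> str:
    """Rule-based plural surface form, the inverse direction of :func:`singularize`.

    Used to auto-expand terminology variants so plural occurrences in text
    match without stemming the corpus.  Exception-list words are returned
    unchanged.
    """
    config = config or DEFAULT_CONFIG
    if token in config.plural_exceptions or not token:
        return token
    if token.endswith("y") and len(token) > 1 and token[-2] not in "aeiou":
        return token[:-1] + "ies"
    if token.endswith(("s", "x", "z", "ch", "sh")):
        return token + "es"
    return token + "s"
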