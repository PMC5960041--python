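"""The controlled terminology: validation and exact multiword counting.

A terminology corpus is a set of canonical 1-6 word terms, each with surface
variants (plural forms, symbol-normalized spellings) and single-token
acronyms, grouped into mutually exclusive categories.  Validation enforces
the two structural rules the analysis depends on: every canonical term
belongs to exactly one category, and no surface form resolves to more than
one canonical term — an ambiguous acronym (the classic case being "STI",
shared by "structured treatment interruption" and "sexually transmitted
infection") is rejected outright rather than guessed at.

Counting scans the matching token stream greedily left to right; at each
position the longest matching surface form wins and its tokens are consumed,
so nested terms ("antiretroviral therapy" inside "highly active
antiretroviral therapy") never double-count one text span.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .preprocess import (
    DEFAULT_CONFIG,
    PreprocessConfig,
    TokenStream,
    pluralize,
    tokenize_and_filter,
)

__all__ = [
    "TermEntry",
    "TerminologyCorpus",
    "TermCounts",
    "TerminologyError",
    "load_terminology",
    "save_terminology",
    "default_terminology",
    "count_term_occurrences",
    "aggregate_counts",
]


class TerminologyError(ValueError):
    """Raised when a terminology file violates a structural rule."""


def _norm_phrase(phrase: str) -> tuple[str, ...]:
    # normalize a surface phrase with the same tokenizer the corpus text uses,
    # so hyphenated/cased forms in the file match the token stream
    return tokenize_and_filter(phrase).matching_tokens


@dataclass
class TermEntry:
    """A canonical term with its variant surfaces, acronyms and category."""

    canonical: str
    category: str
    variants: set[str] = field(default_factory=set)
    acronyms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.canonical = " ".join(_norm_phrase(self.canonical))
        if not self.canonical:
            raise TerminologyError("empty canonical term")
        self.variants = {" ".join(_norm_phrase(v)) for v in self.variants} | {
            self.canonical
        }
        if "" in self.variants:
            raise TerminologyError(f"{self.canonical!r}: empty variant")
        self.acronyms = {a.strip().lower() for a in self.acronyms if a.strip()}
        for a in self.acronyms:
            if a.isdigit():
                raise TerminologyError(f"{self.canonical!r}: purely numeric acronym {a!r}")

    def surfaces(
        self, config: PreprocessConfig | None = None, expand_plurals: bool = True
    ) -> set[tuple[str, ...]]:
        """All token-tuple surfaces that resolve to this canonical term.

        With ``expand_plurals`` (the default) each variant also matches with
        its final word pluralized, so "aids patients" counts toward
        "aids patient" without stemming the corpus.
        """
        config = config or DEFAULT_CONFIG
        out: set[tuple[str, ...]] = set()
        for v in self.variants:
            toks = tuple(v.split())
            out.add(toks)
            if expand_plurals and toks:
                plural_last = pluralize(toks[-1], config)
                if plural_last != toks[-1]:
                    out.add(toks[:-1] + (plural_last,))
        out.update((a,) for a in self.acronyms)
        return out


class TerminologyCorpus:
    """A validated set of :class:`TermEntry` with an exact matching table."""

    def __init__(
        self,
        entries: Sequence[TermEntry],
        config: PreprocessConfig | None = None,
        expand_plurals: bool = True,
    ):
        self.entries = list(entries)
        self.config = config or DEFAULT_CONFIG
        self.expand_plurals = expand_plurals
        self._build()

    def _build(self) -> None:
        seen_canonical: dict[str, str] = {}
        table: dict[tuple[str, ...], str] = {}
        owners: dict[tuple[str, ...], str] = {}
        for entry in self.entries:
            if entry.canonical in seen_canonical:
                raise TerminologyError(
                    f"term {entry.canonical!r} appears in two categories: "
                    f"{seen_canonical[entry.canonical]!r} and {entry.category!r}"
                )
            seen_canonical[entry.canonical] = entry.category
            for surface in entry.surfaces(self.config, self.expand_plurals):
                if surface in owners and owners[surface] != entry.canonical:
                    raise TerminologyError(
                        f"surface {' '.join(surface)!r} claimed by both "
                        f"{owners[surface]!r} and {entry.canonical!r}; "
                        "ambiguous forms are not included in the terminology corpus"
                    )
                owners[surface] = entry.canonical
                table[surface] = entry.canonical
        self._table = table
        self._max_len = max((len(s) for s in table), default=0)

    @property
    def categories(self) -> set[str]:
        return {e.category for e in self.entries}

    @property
    def canonicals(self) -> list[str]:
        return [e.canonical for e in self.entries]

    def category_of(self, canonical: str) -> str:
        for e in self.entries:
            if e.canonical == canonical:
                return e.category
        raise KeyError(canonical)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class TermCounts:
    """Exact per-abstract occurrence counts under the longest-match rule."""

    abstract_id: str
    year: int
    counts: dict[str, int]


def count_term_occurrences(
    stream: TokenStream, corpus: TerminologyCorpus
) -> TermCounts:
    """Greedy longest-match scan of one abstract's matching stream.

    Matched tokens are consumed: no overlap and no double counting.  An empty
    terminology yields all-zero counts.
    """
    toks = stream.matching_tokens
    table = corpus._table
    max_len = corpus._max_len
    counts: Counter[str] = Counter()
    i = 0
    n = len(toks)
    while i < n:
        for length in range(min(max_len, n - i), 0, -1):
            canonical = table.get(toks[i : i + length])
            if canonical is not None:
                counts[canonical] += 1
                i += length
                break
        else:
            i += 1
    return TermCounts(abstract_id=stream.abstract_id, year=stream.year, counts=dict(counts))


def aggregate_counts(
    per_abstract: Iterable[TermCounts], terms: Iterable[str] | None = None
) -> pd.DataFrame:
    """Per (term, year) absolute term frequency and abstract-level DF.

    Returns a tidy frame with columns ``term, year, absolute_tf, abstract_df``,
    zero-filled over every (term, year) combination when ``terms`` is given.
    """
    per_abstract = list(per_abstract)
    years = sorted({c.year for c in per_abstract})
    tf: Counter[tuple[str, int]] = Counter()
    df: Counter[tuple[str, int]] = Counter()
    observed: set[str] = set()
    for c in per_abstract:
        for term, k in c.counts.items():
            if k > 0:
                tf[(term, c.year)] += k
                df[(term, c.year)] += 1
                observed.add(term)
    term_list = sorted(observed) if terms is None else list(terms)
    rows = [
        {
            "term": t,
            "year": y,
            "absolute_tf": tf.get((t, y), 0),
            "abstract_df": df.get((t, y), 0),
        }
        for t in term_list
        for y in years
    ]
    return pd.DataFrame(rows, columns=["term", "year", "absolute_tf", "abstract_df"])


def _split_multi(value: str) -> set[str]:
    return {v.strip() for v in value.split("|") if v.strip()}


def load_terminology(
    path: str | Path,
    config: PreprocessConfig | None = None,
    expand_plurals: bool = True,
) -> TerminologyCorpus:
    """Load and validate a terminology file (YAML mapping or CSV table).

    YAML layout: a top-level ``terms`` list of mappings with keys
    ``canonical``, ``category`` and optional ``variants``/``acronyms`` lists.
    CSV layout: columns ``canonical, variants, acronyms, category`` with
    ``|``-separated multi-values.
    """
    path = Path(path)
    entries: list[TermEntry] = []
    if path.suffix.lower() in {".yaml", ".yml"}:
        with path.open(encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        for item in data.get("terms", []):
            entries.append(
                TermEntry(
                    canonical=item["canonical"],
                    category=item["category"],
                    variants=set(item.get("variants") or ()),
                    acronyms=set(item.get("acronyms") or ()),
                )
            )
    else:
        with path.open(newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                entries.append(
                    TermEntry(
                        canonical=row["canonical"],
                        category=row["category"],
                        variants=_split_multi(row.get("variants") or ""),
                        acronyms=_split_multi(row.get("acronyms") or ""),
                    )
                )
    if not entries:
        raise TerminologyError(f"{path}: no terms found")
    return TerminologyCorpus(entries, config=config, expand_plurals=expand_plurals)


def save_terminology(corpus: TerminologyCorpus, path: str | Path) -> None:
    """Write a terminology corpus back out as YAML (round-trips with load)."""
    data = {
        "terms": [
            {
                "canonical": e.canonical,
                "category": e.category,
                "variants": sorted(e.variants - {e.canonical}),
                "acronyms": sorted(e.acronyms),
            }
            for e in corpus.entries
        ]
    }
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def default_terminology(
    config: PreprocessConfig | None = None, expand_plurals: bool = True
) -> TerminologyCorpus:
    """The bundled HIV terminology reconstruction (see data/default_terms.yaml)."""
    ref = resources.files("termtrends.data").joinpath("default_terms.yaml")
    with resources.as_file(ref) as p:
        return load_terminology(p, config=config, expand_plurals=expand_plurals)
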