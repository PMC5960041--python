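"""Terminology discovery: unigram DF ranking and n-gram candidate expansion.

Mirrors the corpus-creation workflow used to build a controlled terminology:
rank the discovery-stream unigrams of each conference year by abstract-level
document frequency, keep those reaching a DF threshold (default 100) in at
least one year, fold in expert include/exclude lists, then expand the
retained *key unigrams* into contiguous 2..max_n word candidates drawn from
the matching stream (so phrases with interior stop words survive).  Candidate
windows never cross abstract boundaries or sentence-final punctuation.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .preprocess import TokenStream

__all__ = [
    "UnigramStats",
    "NgramCandidate",
    "unigram_stats",
    "unigram_stats_by_year",
    "select_key_unigrams",
    "expand_ngrams",
    "candidates_to_frame",
]


@dataclass(frozen=True)
class UnigramStats:
    """Per-year token statistics: total occurrences and abstract-level DF."""

    year: int
    token: str
    absolute_count: int
    abstract_df: int


@dataclass
class NgramCandidate:
    """A 2..n word candidate phrase anchored on a key unigram."""

    surface: str
    seed_unigram: str
    df_by_year: dict[int, int] = field(default_factory=dict)

    @property
    def abstract_df(self) -> int:
        """Maximum abstract-level DF over the years observed."""
        return max(self.df_by_year.values(), default=0)

    @property
    def years_observed(self) -> frozenset[int]:
        return frozenset(self.df_by_year)


def unigram_stats(streams: Sequence[TokenStream], year: int) -> list[UnigramStats]:
    """Exact discovery-stream unigram counts and abstract DFs for one year.

    Raises ``ValueError`` if the year has no abstracts in the corpus.
    """
    year_streams = [s for s in streams if s.year == year]
    if not year_streams:
        raise ValueError(f"year {year} absent from corpus")
    totals: Counter[str] = Counter()
    dfs: Counter[str] = Counter()
    for s in year_streams:
        totals.update(s.discovery_tokens)
        dfs.update(set(s.discovery_tokens))
    return [
        UnigramStats(year=year, token=tok, absolute_count=totals[tok], abstract_df=dfs[tok])
        for tok in sorted(totals)
    ]


def unigram_stats_by_year(streams: Sequence[TokenStream]) -> dict[int, list[UnigramStats]]:
    """:func:`unigram_stats` for every year present, keyed by year."""
    years = sorted({s.year for s in streams})
    return {y: unigram_stats(streams, y) for y in years}


def select_key_unigrams(
    stats: Iterable[UnigramStats],
    threshold: int = 100,
    include: Iterable[str] = (),
    exclude: Iterable[str] = (),
) -> list[str]:
    """Tokens whose abstract DF reaches ``threshold`` in at least one year.

    ``exclude`` removes tokens regardless of DF; ``include`` adds tokens
    regardless of DF (modelling expert judgment, e.g. terms kept below the
    threshold).  Deterministic order: descending maximum DF, then lexicographic.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    max_df: dict[str, int] = defaultdict(int)
    for st in stats:
        max_df[st.token] = max(max_df[st.token], st.abstract_df)
    exclude_set = {w.lower() for w in exclude}
    selected = {t for t, df in max_df.items() if df >= threshold} - exclude_set
    selected |= {w.lower() for w in include}
    return sorted(selected, key=lambda t: (-max_df.get(t, 0), t))


def _segments(stream: TokenStream) -> Iterable[tuple[int, int]]:
    """Half-open [start, stop) sentence segments of the matching stream."""
    start = 0
    for brk in sorted(stream.sentence_breaks):
        yield start, brk + 1
        start = brk + 1
    if start < len(stream.matching_tokens):
        yield start, len(stream.matching_tokens)


def expand_ngrams(
    streams: Sequence[TokenStream],
    key_unigrams: Iterable[str],
    max_n: int = 6,
) -> list[NgramCandidate]:
    """All 2..max_n word windows containing at least one key unigram.

    Windows are taken over the matching stream (stop words retained) within
    sentence segments; per surface, the abstract-level DF is aggregated per
    year.  Empty ``key_unigrams`` yields an empty result.
    """
    if not 2 <= max_n <= 6:
        raise ValueError("max_n must be in 2..6")
    keys = {w.lower() for w in key_unigrams}
    if not keys:
        return []
    # surface -> year -> set of abstract ids
    presence: dict[tuple[str, ...], dict[int, set[str]]] = defaultdict(
        lambda: defaultdict(set)
    )
    seeds: dict[tuple[str, ...], str] = {}
    for stream in streams:
        toks = stream.matching_tokens
        for seg_start, seg_stop in _segments(stream):
            for i in range(seg_start, seg_stop):
                for n in range(2, max_n + 1):
                    if i + n > seg_stop:
                        break
                    window = toks[i : i + n]
                    hit = next((t for t in window if t in keys), None)
                    if hit is None:
                        continue
                    presence[window][stream.year].add(stream.abstract_id)
                    seeds.setdefault(window, hit)
    out = []
    for window in sorted(presence):
        out.append(
            NgramCandidate(
                surface=" ".join(window),
                seed_unigram=seeds[window],
                df_by_year={y: len(ids) for y, ids in sorted(presence[window].items())},
            )
        )
    return out


def candidates_to_frame(
    candidates: Iterable[NgramCandidate], floor: int = 0
) -> pd.DataFrame:
    """Tidy export of candidates: one row per (surface, year).

    ``floor`` suppresses rows whose per-year abstract DF is below the
    reporting floor; the full candidate objects remain available upstream.
    """
    rows = [
        {"surface": c.surface, "seed": c.seed_unigram, "year": y, "abstract_df": df}
        for c in candidates
        for y, df in sorted(c.df_by_year.items())
        if df >= floor
    ]
    return pd.DataFrame(rows, columns=["surface", "seed", "year", "abstract_df"])
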