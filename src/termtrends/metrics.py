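"""Frequency metrics over (term, conference-year) counts.

Conference years act as the documents of a TF-IDF scheme:

* ``TF(T, Y) = absolute_tf(T, Y) / vocabulary_size(Y)`` where the vocabulary
  size is the total count of *all* words (matching stream, stop words
  retained) over all abstracts of year ``Y``;
* ``relTF = TF * 1e6`` — expected occurrences per million words;
* ``DF(T)`` = number of conference years in which ``T`` appears in at least
  one abstract, from 0 to the number of years ``N``;
* ``IDF(T) = log(1 + N / DF(T))``, natural log by default (base 10
  selectable; trend shapes are invariant to the base);
* ``TFIDF(T, Y) = TF(T, Y) * IDF(T)``;
* a trailing 3-point moving average of relTF over *conference occurrences*
  (positions in the conference sequence, not calendar years, since the
  conference spacing is uneven), undefined at the first two positions.

Terms with zero counts in a year still get a metrics row (tf = 0) so trend
lines stay continuous across years.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .preprocess import TokenStream

logger = logging.getLogger(__name__)

__all__ = [
    "YearSummary",
    "MetricsContext",
    "year_summary",
    "term_frequency",
    "year_document_frequency",
    "inverse_document_frequency",
    "tf_idf",
    "moving_average",
    "compute_metrics",
]

METRICS_COLUMNS = [
    "term",
    "category",
    "year",
    "absolute_tf",
    "tf",
    "reltf",
    "abstract_df",
    "year_df",
    "idf",
    "tfidf",
    "reltf_ma3",
]


@dataclass(frozen=True)
class YearSummary:
    """Per-year totals: vocabulary size (all matching-stream words) and abstract count."""

    year: int
    vocabulary_size: int
    n_abstracts: int


@dataclass(frozen=True)
class MetricsContext:
    """The conference-year sequence and the IDF log base."""

    years: tuple[int, ...]
    log_base: Literal["e", "10"] = "e"

    @property
    def n_years(self) -> int:
        return len(self.years)

    def log(self, x: float) -> float:
        return math.log10(x) if self.log_base == "10" else math.log(x)


def year_summary(streams: Sequence[TokenStream]) -> list[YearSummary]:
    """Exact matching-stream token totals per conference year."""
    if not streams:
        raise ValueError("empty corpus")
    years = sorted({s.year for s in streams})
    out = []
    for y in years:
        year_streams = [s for s in streams if s.year == y]
        out.append(
            YearSummary(
                year=y,
                vocabulary_size=sum(len(s.matching_tokens) for s in year_streams),
                n_abstracts=len(year_streams),
            )
        )
    return out


def term_frequency(absolute_tf: int, vocabulary_size: int) -> tuple[float, float]:
    """``(tf, reltf)`` for one term-year: tf = absolute/vocabulary, reltf = tf * 1e6."""
    if vocabulary_size <= 0:
        raise ValueError("vocabulary_size must be positive")
    if not 0 <= absolute_tf <= vocabulary_size:
        raise ValueError("absolute_tf must be in [0, vocabulary_size]")
    tf = absolute_tf / vocabulary_size
    return tf, tf * 1_000_000


def year_document_frequency(abstract_dfs: Sequence[int]) -> int:
    """Number of conference years with at least one abstract containing the term."""
    return int(sum(1 for df in abstract_dfs if df >= 1))


def inverse_document_frequency(df: int, context: MetricsContext) -> float:
    """``log(1 + N/DF)`` in the configured base; requires ``1 <= DF <= N``."""
    if not 1 <= df <= context.n_years:
        raise ValueError(f"df must be in 1..{context.n_years}, got {df}")
    return context.log(1 + context.n_years / df)


def tf_idf(tf: float, idf: float) -> float:
    """The product TF x IDF, exactly."""
    return tf * idf


def moving_average(values: Sequence[float]) -> np.ndarray:
    """Trailing 3-point moving average over conference-sequence positions.

    Positions are conference occurrences in order; the first two positions
    are NaN (undefined).  A series shorter than 3 is all-NaN, with a warning.
    """
    arr = pd.Series(values, dtype=float)
    if len(arr) < 3:
        logger.warning("series of length %d: moving average undefined everywhere", len(arr))
    return arr.rolling(window=3).mean().to_numpy()


def compute_metrics(
    counts: pd.DataFrame,
    summaries: Sequence[YearSummary],
    context: MetricsContext | None = None,
    categories: dict[str, str] | None = None,
) -> pd.DataFrame:
    """The full tidy metrics table, one row per (term, year), zero-filled.

    ``counts`` carries columns ``term, year, absolute_tf, abstract_df`` (as
    produced by ``term_corpus.aggregate_counts``); ``summaries`` the per-year
    vocabulary sizes; ``categories`` an optional term -> category mapping.
    Terms appearing in no year at all get tfidf 0 with a warning (their tf is
    0 everywhere anyway).
    """
    vocab = {s.year: s.vocabulary_size for s in summaries}
    if context is None:
        context = MetricsContext(years=tuple(sorted(vocab)))
    years = list(context.years)
    lookup = {
        (r.term, r.year): (int(r.absolute_tf), int(r.abstract_df))
        for r in counts.itertuples()
    }
    terms = sorted({t for t, _ in lookup})
    rows = []
    for term in terms:
        per_year = [lookup.get((term, y), (0, 0)) for y in years]
        year_df = year_document_frequency([df for _, df in per_year])
        if year_df >= 1:
            idf = inverse_document_frequency(year_df, context)
        else:
            logger.warning("term %r appears in no conference year; tfidf set to 0", term)
            idf = float("nan")
        reltfs = []
        for (abs_tf, abs_df), y in zip(per_year, years):
            tf, reltf = term_frequency(abs_tf, vocab[y])
            reltfs.append(reltf)
            rows.append(
                {
                    "term": term,
                    "category": (categories or {}).get(term, ""),
                    "year": y,
                    "absolute_tf": abs_tf,
                    "tf": tf,
                    "reltf": reltf,
                    "abstract_df": abs_df,
                    "year_df": year_df,
                    "idf": idf,
                    "tfidf": tf_idf(tf, idf) if year_df >= 1 else 0.0,
                }
            )
        ma = moving_average(reltfs) if reltfs else np.array([])
        for offset, val in enumerate(ma):
            rows[len(rows) - len(years) + offset]["reltf_ma3"] = val
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)
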