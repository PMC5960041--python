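"""Analytical data products: trend tables, word-cloud weights, term lifespans.

Visualization proper is deliberately out of scope; this module emits tidy,
plot-ready structures — a zero-filled per-(category, term, year) relTF table
for line graphs, per-(category, year) TF-IDF weight maps for word clouds,
and lifespan summaries (first/last/peak conference year, active spans) for
inception/disappearance questions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["TrendTable", "CloudWeights", "Lifespan",
           "build_trend_table", "wordcloud_weights", "term_lifespan"]


@dataclass(frozen=True)
class CloudWeights:
    """TF-IDF weights of one category in one year; zero-weight terms excluded."""

    year: int
    category: str
    weights: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"year": self.year, "category": self.category, "weights": self.weights},
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(payload + "\n", encoding="utf-8")
        return payload


@dataclass(frozen=True)
class Lifespan:
    """Activity summary of one term across the conference sequence.

    ``first_year``/``last_year`` bound the years whose relTF exceeds the
    activity threshold, ``peak_year`` is the year of maximum relTF (earliest
    on tie), and ``active_spans`` lists maximal runs of consecutive
    *conference occurrences* above threshold.  All fields are None for a term
    that never appears.
    """

    term: str
    first_year: int | None
    last_year: int | None
    peak_year: int | None
    active_spans: tuple[tuple[int, int], ...] = ()


TrendTable = pd.DataFrame  # rows (category, term, year, reltf, reltf_ma3), canonically sorted


def build_trend_table(
    metrics: pd.DataFrame, categories: list[str] | None = None
) -> pd.DataFrame:
    """Zero-filled line-graph table sorted by (category, term, year).

    ``categories`` filters to the named categories; an unknown name raises
    ``KeyError``.  The result is invariant to the input row order.
    """
    table = metrics[["category", "term", "year", "reltf", "reltf_ma3"]].copy()
    if categories:
        known = set(metrics["category"])
        unknown = [c for c in categories if c not in known]
        if unknown:
            raise KeyError(f"unknown categories: {unknown}")
        table = table[table["category"].isin(categories)]
    return table.sort_values(["category", "term", "year"], kind="mergesort").reset_index(
        drop=True
    )


def wordcloud_weights(metrics: pd.DataFrame, category: str, year: int) -> CloudWeights:
    """TF-IDF weights for one category-year; terms with tfidf 0 are excluded."""
    if year not in set(metrics["year"]):
        raise KeyError(f"year {year} absent from metrics")
    sel = metrics[
        (metrics["category"] == category)
        & (metrics["year"] == year)
        & (metrics["tfidf"] > 0)
    ]
    return CloudWeights(
        year=year,
        category=category,
        weights={r.term: float(r.tfidf) for r in sel.itertuples()},
    )


def term_lifespan(
    metrics: pd.DataFrame, term: str, threshold: float = 0.0
) -> Lifespan:
    """First/last/peak activity of ``term``, with relTF > ``threshold`` as "active"."""
    series = metrics[metrics["term"] == term].sort_values("year")
    if series.empty:
        raise KeyError(f"unknown term {term!r}")
    years = series["year"].to_list()
    reltf = series["reltf"].to_list()
    active = [x > threshold for x in reltf]
    if not any(active):
        return Lifespan(term=term, first_year=None, last_year=None, peak_year=None)
    active_years = [y for y, a in zip(years, active) if a]
    peak_idx = max(range(len(reltf)), key=lambda i: (reltf[i], -i))
    spans: list[tuple[int, int]] = []
    start = None
    for i, a in enumerate(active):
        if a and start is None:
            start = i
        elif not a and start is not None:
            spans.append((years[start], years[i - 1]))
            start = None
    if start is not None:
        spans.append((years[start], years[-1]))
    return Lifespan(
        term=term,
        first_year=active_years[0],
        last_year=active_years[-1],
        peak_year=years[peak_idx],
        active_spans=tuple(spans),
    )
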