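"""End-to-end convenience: corpus + terminology -> tidy metrics table."""

from __future__ import annotations

from typing import Literal

import pandas as pd

from .corpus_io import AbstractCorpus, clean_corpus, deduplicate
from .metrics import MetricsContext, compute_metrics, year_summary
from .preprocess import PreprocessConfig, preprocess_corpus
from .term_corpus import TerminologyCorpus, aggregate_counts, count_term_occurrences

__all__ = ["compute_term_metrics"]


def compute_term_metrics(
    corpus: AbstractCorpus,
    terminology: TerminologyCorpus,
    config: PreprocessConfig | None = None,
    log_base: Literal["e", "10"] = "e",
    clean: bool = False,
) -> pd.DataFrame:
    """Run cleaning (optional), preprocessing, counting and metrics in order.

    Returns one row per (term, year) over every canonical term of the
    terminology and every conference year of the corpus, zero-filled.
    """
    if clean:
        corpus = deduplicate(clean_corpus(corpus))
    streams = preprocess_corpus(corpus, config)
    counts = aggregate_counts(
        (count_term_occurrences(s, terminology) for s in streams),
        terms=terminology.canonicals,
    )
    summaries = year_summary(streams)
    context = MetricsContext(years=tuple(s.year for s in summaries), log_base=log_base)
    categories = {e.canonical: e.category for e in terminology.entries}
    return compute_metrics(counts, summaries, context=context, categories=categories)
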