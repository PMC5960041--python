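"""Abstract ingestion, cleaning, deduplication and JSONL persistence.

The raw input is a delimited table with one row per conference abstract
(identifier, conference year, free text).  Ingestion preserves the text
verbatim; :func:`clean_text` then strips markup tags and decodes character
entities without altering or removing any word, and :func:`deduplicate`
collapses exact duplicate submissions within a conference year.  The cleaned
corpus round-trips through a line-delimited JSON store used as the pipeline's
intermediate format.
"""

from __future__ import annotations

import csv
import html
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

logger = logging.getLogger(__name__)

__all__ = [
    "Abstract",
    "AbstractCorpus",
    "CorpusFormatError",
    "read_abstract_table",
    "clean_text",
    "clean_corpus",
    "deduplicate",
    "write_jsonl",
    "read_jsonl",
]


class CorpusFormatError(ValueError):
    """Raised for malformed abstract tables (bad year, duplicate id, empty file)."""


@dataclass(frozen=True)
class Abstract:
    """One conference abstract: opaque unique id, conference year, text."""

    id: str
    year: int
    text: str


@dataclass
class AbstractCorpus:
    """Ordered collection of abstracts plus the distinct conference years present."""

    abstracts: list[Abstract] = field(default_factory=list)

    @property
    def years(self) -> list[int]:
        """Distinct conference years, ascending."""
        return sorted({a.year for a in self.abstracts})

    def __len__(self) -> int:
        return len(self.abstracts)

    def __iter__(self) -> Iterator[Abstract]:
        return iter(self.abstracts)

    def validate(self) -> None:
        ids = [a.id for a in self.abstracts]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise CorpusFormatError(f"duplicate abstract id {dup!r}")


def read_abstract_table(
    path: str | Path,
    id_col: str = "id",
    year_col: str = "year",
    text_col: str = "text",
    delimiter: str = ",",
    quotechar: str = '"',
) -> AbstractCorpus:
    """Parse a delimited abstract table into an :class:`AbstractCorpus`.

    One :class:`Abstract` per well-formed row, row order preserved; no cleaning
    is applied at this stage.  A missing or unparsable year raises a
    :class:`CorpusFormatError` naming the offending row, as do duplicate ids
    and an empty table.
    """
    path = Path(path)
    abstracts: list[Abstract] = []
    seen_ids: set[str] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter, quotechar=quotechar)
        if reader.fieldnames is None:
            raise CorpusFormatError(f"{path}: empty input (no header row)")
        for col in (id_col, year_col, text_col):
            if col not in reader.fieldnames:
                raise CorpusFormatError(
                    f"{path}: required column {col!r} not in header {reader.fieldnames}"
                )
        for rownum, row in enumerate(reader, start=2):  # row 1 is the header
            raw_year = (row.get(year_col) or "").strip()
            try:
                year = int(raw_year)
            except ValueError:
                raise CorpusFormatError(
                    f"{path}: row {rownum}: unparsable year {raw_year!r}"
                ) from None
            aid = (row.get(id_col) or "").strip()
            if not aid:
                raise CorpusFormatError(f"{path}: row {rownum}: empty id")
            if aid in seen_ids:
                raise CorpusFormatError(f"{path}: row {rownum}: duplicate id {aid!r}")
            seen_ids.add(aid)
            abstracts.append(Abstract(id=aid, year=year, text=row.get(text_col) or ""))
    if not abstracts:
        raise CorpusFormatError(f"{path}: empty input (no data rows)")
    return AbstractCorpus(abstracts)


_TAG_RE = re.compile(r"<[^<>]+>")
_ENTITY_RE = re.compile(r"&#?\w+;")


def clean_text(raw: str) -> str:
    """Remove markup tags and decode character entities; collapse whitespace.

    Total on any input.  Entity decoding and tag stripping are iterated to a
    fixed point so doubly-escaped fragments (``&amp;lt;b&amp;gt;``) resolve
    fully.  No word is altered or removed; unknown entities are left verbatim
    and logged.
    """
    text = raw
    for _ in range(5):
        stripped = _TAG_RE.sub(" ", text)
        decoded = html.unescape(stripped)
        if decoded == text:
            break
        text = decoded
    leftover = _ENTITY_RE.findall(text)
    if leftover:
        logger.debug("unresolved character entities left verbatim: %s", sorted(set(leftover)))
    return " ".join(text.split())


def clean_corpus(corpus: AbstractCorpus) -> AbstractCorpus:
    """Apply :func:`clean_text` to every abstract."""
    return AbstractCorpus(
        [Abstract(a.id, a.year, clean_text(a.text)) for a in corpus.abstracts]
    )


def _dedup_key(text: str) -> str:
    return " ".join(text.casefold().split())


def deduplicate(corpus: AbstractCorpus) -> AbstractCorpus:
    """Drop within-year exact duplicates (case-folded, whitespace-collapsed text).

    The first occurrence is retained; cross-year repeats are kept as
    legitimate resubmissions.  Idempotent; the number of removed records is
    logged.
    """
    seen: set[tuple[int, str]] = set()
    kept: list[Abstract] = []
    for a in corpus.abstracts:
        key = (a.year, _dedup_key(a.text))
        if key in seen:
            continue
        seen.add(key)
        kept.append(a)
    removed = len(corpus.abstracts) - len(kept)
    if removed:
        logger.info("deduplicate: removed %d duplicate abstract(s)", removed)
    return AbstractCorpus(kept)


def write_jsonl(corpus: AbstractCorpus, path: str | Path) -> None:
    """Persist the corpus as line-delimited JSON (fields: id, year, text)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for a in corpus.abstracts:
            fh.write(json.dumps({"id": a.id, "year": a.year, "text": a.text}) + "\n")


def read_jsonl(path: str | Path) -> AbstractCorpus:
    """Load a corpus previously written by :func:`write_jsonl`."""
    path = Path(path)
    abstracts = []
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            abstracts.append(Abstract(str(rec["id"]), int(rec["year"]), rec["text"]))
    corpus = AbstractCorpus(abstracts)
    corpus.validate()
    return corpus
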