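"""Synthetic abstract corpora with planted term occurrences.

The real input this pipeline was designed around — tens of thousands of
conference abstracts spanning 16 conference years — is not publicly
distributable, so every stage is exercised against generated corpora whose
statistical structure is known exactly:

* background text is drawn from a Zipf-weighted vocabulary of letter-only
  nonsense words on a reserved prefix, guaranteed disjoint from any planted
  phrase (no accidental matches, so count recovery is exact);
* multiword terms are planted either an exact number of times per year or at
  a Poisson rate per abstract; each occurrence is spliced contiguously at a
  uniformly chosen token boundary of a uniformly chosen abstract;
* the generator returns a :class:`GroundTruth` with the realized counts,
  abstract-presence counts and per-year token totals — the oracle every
  downstream metric is checked against.

The default scale (16 conference years emulating the uneven annual/biennial
spacing of 1989-2014, 200 abstracts per year, ~150 tokens each) keeps a full
pipeline run in seconds; a full-archive scale (tens of thousands of
abstracts) is a matter of raising ``abstracts_per_year``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from string import ascii_lowercase

import numpy as np
import yaml

from .corpus_io import Abstract, AbstractCorpus
from .preprocess import DEFAULT_CONFIG
from .term_corpus import TermEntry, TerminologyCorpus

__all__ = [
    "PlantedTerm",
    "SyntheticSpec",
    "GroundTruth",
    "DEFAULT_YEARS",
    "generate_corpus",
    "synthetic_terminology",
    "table1_scenario",
    "load_spec",
]

# 16 conference occurrences: annual 1989-1994, biennial 1996-2014.
DEFAULT_YEARS: tuple[int, ...] = (
    1989, 1990, 1991, 1992, 1993, 1994,
    1996, 1998, 2000, 2002, 2004, 2006, 2008, 2010, 2012, 2014,
)

_BACKGROUND_PREFIX = "zq"


@dataclass(frozen=True)
class PlantedTerm:
    """A phrase planted at known per-year counts (exact) or Poisson rates.

    Exactly one of ``exact`` (year -> occurrence count) and ``rate`` (mean
    occurrences per abstract, every year) must be given.
    """

    phrase: str
    category: str = "planted"
    exact: dict[int, int] | None = None
    rate: float | None = None

    def __post_init__(self) -> None:
        if (self.exact is None) == (self.rate is None):
            raise ValueError(f"{self.phrase!r}: give exactly one of exact= or rate=")
        if self.exact is not None and any(c < 0 for c in self.exact.values()):
            raise ValueError(f"{self.phrase!r}: exact counts must be >= 0")
        if self.rate is not None and self.rate < 0:
            raise ValueError(f"{self.phrase!r}: rate must be >= 0")
        words = self.phrase.lower().split()
        if not 1 <= len(words) <= 6:
            raise ValueError(f"{self.phrase!r}: phrase must be 1-6 words")

    @property
    def words(self) -> tuple[str, ...]:
        return tuple(self.phrase.lower().split())

    @property
    def canonical(self) -> str:
        return " ".join(self.words)


@dataclass(frozen=True)
class SyntheticSpec:
    years: tuple[int, ...] = DEFAULT_YEARS
    abstracts_per_year: int | dict[int, int] = 200
    mean_abstract_length: int = 150
    background_vocab_size: int = 5000
    zipf_exponent: float = 1.1
    planted_terms: tuple[PlantedTerm, ...] = ()
    seed: int = 0

    def n_abstracts(self, year: int) -> int:
        if isinstance(self.abstracts_per_year, dict):
            return self.abstracts_per_year[year]
        return self.abstracts_per_year

    def validate(self) -> None:
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be > 0")
        background = set(_background_vocab(self.background_vocab_size))
        for t in self.planted_terms:
            clash = set(t.words) & background
            if clash:
                raise ValueError(
                    f"planted phrase {t.phrase!r} shares word(s) {sorted(clash)} "
                    "with the background vocabulary"
                )
            if t.exact is not None:
                unknown = set(t.exact) - set(self.years)
                if unknown:
                    raise ValueError(
                        f"{t.phrase!r}: exact plan names years {sorted(unknown)} "
                        "not in the corpus"
                    )


@dataclass
class GroundTruth:
    """Realized planted structure: the exact oracle for pipeline recovery."""

    planted_counts: dict[tuple[str, int], int] = field(default_factory=dict)
    planted_presence: dict[tuple[str, int], int] = field(default_factory=dict)
    year_tokens: dict[int, int] = field(default_factory=dict)


def _background_vocab(size: int) -> list[str]:
    """Letter-only nonsense words on a reserved prefix, deterministic order."""
    words = []
    for n in (3, 4, 5):
        for combo in product(ascii_lowercase, repeat=n):
            words.append(_BACKGROUND_PREFIX + "".join(combo))
            if len(words) == size:
                return words
    raise ValueError(f"background_vocab_size {size} too large")


def _zipf_weights(size: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, size + 1, dtype=float)
    w = ranks**-exponent
    return w / w.sum()


def generate_corpus(spec: SyntheticSpec) -> tuple[AbstractCorpus, GroundTruth]:
    """Generate a corpus and its ground truth; bit-identical for a given seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    vocab = np.array(_background_vocab(spec.background_vocab_size))
    weights = _zipf_weights(spec.background_vocab_size, spec.zipf_exponent)
    truth = GroundTruth()
    abstracts: list[Abstract] = []
    for year in spec.years:
        m = spec.n_abstracts(year)
        lengths = np.maximum(rng.poisson(spec.mean_abstract_length, size=m), 20)
        bodies = [
            list(vocab[rng.choice(len(vocab), size=ln, p=weights)]) for ln in lengths
        ]
        # plan how many occurrences of each term go into each abstract
        per_abstract: list[list[tuple[str, ...]]] = [[] for _ in range(m)]
        for term in spec.planted_terms:
            if term.exact is not None:
                total = term.exact.get(year, 0)
                targets = rng.integers(0, m, size=total) if total else np.array([], int)
            else:
                draws = rng.poisson(term.rate, size=m)
                targets = np.repeat(np.arange(m), draws)
                total = int(draws.sum())
            for idx in targets:
                per_abstract[int(idx)].append(term.words)
            truth.planted_counts[(term.canonical, year)] = total
            truth.planted_presence[(term.canonical, year)] = int(
                len(set(targets.tolist()))
            )
        year_total = 0
        for i, body in enumerate(bodies):
            # splice phrases at descending background boundaries so each
            # occurrence stays contiguous and none interleaves another
            slots = sorted(
                (int(s) for s in rng.integers(0, len(body) + 1, size=len(per_abstract[i]))),
                reverse=True,
            )
            for slot, phrase in zip(slots, per_abstract[i]):
                body[slot:slot] = list(phrase)
            year_total += len(body)
            abstracts.append(
                Abstract(id=f"{year}-{i:05d}", year=year, text=" ".join(body))
            )
        truth.year_tokens[year] = year_total
    return AbstractCorpus(abstracts), truth


def synthetic_terminology(spec: SyntheticSpec) -> TerminologyCorpus:
    """A terminology corpus whose entries are exactly the planted terms."""
    entries = [
        TermEntry(canonical=t.canonical, category=t.category)
        for t in spec.planted_terms
    ]
    return TerminologyCorpus(entries, config=DEFAULT_CONFIG)


def table1_scenario(seed: int = 0) -> tuple[SyntheticSpec, AbstractCorpus, GroundTruth]:
    """A desk-scale two-year scenario with known absolute-frequency contrasts.

    Year 1989 plants "aids carrier" 7 times against "affected communities"
    once; year 1990 plants them 1 and 2 times.  Within a year the two terms
    share one token pool, so their TF ratio equals the ratio of planted
    absolute frequencies regardless of the pool's size.
    """
    spec = SyntheticSpec(
        years=(1989, 1990),
        abstracts_per_year=25,
        mean_abstract_length=120,
        background_vocab_size=500,
        planted_terms=(
            PlantedTerm("aids carrier", category="living with HIV",
                        exact={1989: 7, 1990: 1}),
            PlantedTerm("affected communities", category="living with HIV",
                        exact={1989: 1, 1990: 2}),
        ),
        seed=seed,
    )
    corpus, truth = generate_corpus(spec)
    return spec, corpus, truth


def load_spec(path) -> SyntheticSpec:
    """Read a :class:`SyntheticSpec` from YAML (keys mirror the dataclass)."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    planted = tuple(
        PlantedTerm(
            phrase=item["phrase"],
            category=item.get("category", "planted"),
            exact={int(y): int(c) for y, c in item["exact"].items()}
            if "exact" in item
            else None,
            rate=item.get("rate"),
        )
        for item in data.get("planted_terms", ())
    )
    spec = SyntheticSpec(
        years=tuple(data.get("years", DEFAULT_YEARS)),
        abstracts_per_year=data.get("abstracts_per_year", 200),
        mean_abstract_length=data.get("mean_abstract_length", 150),
        background_vocab_size=data.get("background_vocab_size", 5000),
        zipf_exponent=data.get("zipf_exponent", 1.1),
        planted_terms=planted,
        seed=int(data.get("seed", 0)),
    )
    spec.validate()
    return spec
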