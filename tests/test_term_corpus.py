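"""Terminology validation and the longest-match counting engine."""

import random
import re
from collections import Counter

import pytest

from termtrends.preprocess import preprocess_corpus, tokenize_and_filter
from termtrends.term_corpus import (
    TermCounts,
    TermEntry,
    TerminologyCorpus,
    TerminologyError,
    aggregate_counts,
    count_term_occurrences,
    default_terminology,
    load_terminology,
    save_terminology,
)

ART = TermEntry(
    canonical="antiretroviral therapy",
    category="antiretroviral therapy",
    acronyms={"art"},
)
HAART = TermEntry(
    canonical="highly active antiretroviral therapy",
    category="antiretroviral therapy",
    acronyms={"haart"},
)


class TestValidation:
    def test_acronym_resolves_to_canonical(self):
        corpus = TerminologyCorpus([ART])
        stream = tokenize_and_filter("ART improved outcomes")
        assert count_term_occurrences(stream, corpus).counts == {
            "antiretroviral therapy": 1
        }

    def test_ambiguous_acronym_rejected_naming_both(self):
        sti1 = TermEntry(
            canonical="structured treatment interruption",
            category="treatment history",
            acronyms={"sti"},
        )
        sti2 = TermEntry(
            canonical="sexually transmitted infection",
            category="prevention",
            acronyms={"sti"},
        )
        with pytest.raises(TerminologyError) as err:
            TerminologyCorpus([sti1, sti2])
        assert "structured treatment interruption" in str(err.value)
        assert "sexually transmitted infection" in str(err.value)

    def test_term_in_two_categories_rejected(self):
        a = TermEntry(canonical="sex worker", category="sex worker")
        b = TermEntry(canonical="sex worker", category="other")
        with pytest.raises(TerminologyError, match="two categories"):
            TerminologyCorpus([a, b])

    def test_numeric_acronym_rejected(self):
        with pytest.raises(TerminologyError, match="numeric"):
            TermEntry(canonical="x", category="c", acronyms={"90"})

    def test_load_save_load_round_trip(self, tmp_path):
        path = tmp_path / "terms.yaml"
        path.write_text(
            "terms:\n"
            "  - canonical: antiretroviral therapy\n"
            "    category: antiretroviral therapy\n"
            "    acronyms: [art]\n"
            "  - canonical: sex worker\n"
            "    category: sex worker\n"
            "    variants: [commercial sex worker]\n",
            encoding="utf-8",
        )
        corpus = load_terminology(path)
        out = tmp_path / "roundtrip.yaml"
        save_terminology(corpus, out)
        again = load_terminology(out)
        assert {e.canonical for e in again.entries} == {e.canonical for e in corpus.entries}
        assert again._table == corpus._table

    def test_csv_format_loads(self, tmp_path):
        path = tmp_path / "terms.csv"
        path.write_text(
            "canonical,variants,acronyms,category\n"
            "antiretroviral therapy,arv therapy,art,antiretroviral therapy\n",
            encoding="utf-8",
        )
        corpus = load_terminology(path)
        assert ("arv", "therapy") in corpus._table

    def test_default_terminology_loads_and_validates(self):
        corpus = default_terminology()
        assert "living with HIV" in corpus.categories
        assert corpus.category_of("men who have sex with men") == "MSM"


class TestCounting:
    def test_longest_match_consumes_nested_term(self):
        corpus = TerminologyCorpus([ART, HAART])
        stream = tokenize_and_filter("highly active antiretroviral therapy")
        counts = count_term_occurrences(stream, corpus).counts
        assert counts == {"highly active antiretroviral therapy": 1}

    def test_symbol_mapped_surface_counts(self):
        corpus = TerminologyCorpus(
            [TermEntry(canonical="hiv positive", category="living with HIV")]
        )
        from termtrends.preprocess import apply_symbol_map

        stream = tokenize_and_filter(apply_symbol_map("HIV+ individuals"))
        assert count_term_occurrences(stream, corpus).counts == {"hiv positive": 1}

    def test_plural_variant_matches(self):
        corpus = TerminologyCorpus(
            [TermEntry(canonical="aids patient", category="living with HIV")]
        )
        stream = tokenize_and_filter("aids patients and aids patient")
        assert count_term_occurrences(stream, corpus).counts == {"aids patient": 2}

    def test_empty_terminology_all_zero(self):
        corpus = TerminologyCorpus([])
        stream = tokenize_and_filter("any words at all")
        assert count_term_occurrences(stream, corpus).counts == {}

    def test_no_double_counting_of_spans(self):
        corpus = TerminologyCorpus([ART, HAART])
        stream = tokenize_and_filter(
            "highly active antiretroviral therapy then antiretroviral therapy"
        )
        counts = count_term_occurrences(stream, corpus).counts
        matched_tokens = 4 * counts.get("highly active antiretroviral therapy", 0)
        matched_tokens += 2 * counts.get("antiretroviral therapy", 0)
        assert matched_tokens <= len(stream.matching_tokens)
        assert counts == {
            "highly active antiretroviral therapy": 1,
            "antiretroviral therapy": 1,
        }

    def test_single_word_terms_equal_token_tallies(self):
        rng = random.Random(3)
        words = ["gay", "homosexual", "filler", "other"]
        text = " ".join(rng.choices(words, k=200))
        corpus = TerminologyCorpus(
            [
                TermEntry(canonical="gay", category="homosexual"),
                TermEntry(canonical="homosexual", category="homosexual"),
            ],
            expand_plurals=False,
        )
        counts = count_term_occurrences(tokenize_and_filter(text), corpus).counts
        naive = Counter(text.split())
        assert counts == {w: naive[w] for w in ("gay", "homosexual") if naive[w]}

    def test_counting_invariant_to_abstract_order(self, corpus_factory):
        rows = [("a", 1990, "gay men"), ("b", 1990, "sex worker outreach"),
                ("c", 1992, "sex workers")]
        term = TerminologyCorpus(
            [TermEntry(canonical="sex worker", category="sex worker"),
             TermEntry(canonical="gay", category="homosexual")]
        )
        fwd = [count_term_occurrences(s, term) for s in
               preprocess_corpus(corpus_factory(rows))]
        rev = [count_term_occurrences(s, term) for s in
               preprocess_corpus(corpus_factory(rows[::-1]))]
        assert aggregate_counts(fwd).equals(aggregate_counts(rev))


class TestAggregateCounts:
    def test_worked_example_totals(self):
        per_abstract = [
            TermCounts("a1", 1, {"aids patient": 5}),
            TermCounts("a2", 1, {"aids patient": 10}),
            TermCounts("a3", 1, {"aids patient": 15}),
        ]
        agg = aggregate_counts(per_abstract)
        row = agg[(agg.term == "aids patient") & (agg.year == 1)].iloc[0]
        assert row.absolute_tf == 30
        assert row.abstract_df == 3

    def test_absent_term_zero_filled(self):
        agg = aggregate_counts(
            [TermCounts("a1", 1990, {"gay": 1})], terms=["gay", "homosexual"]
        )
        row = agg[(agg.term == "homosexual")].iloc[0]
        assert row.absolute_tf == 0 and row.abstract_df == 0

    def test_matches_regex_scan_on_raw_text(self, corpus_factory):
        rng = random.Random(5)
        background = [f"bg{c}" for c in "abcdefgh"]
        rows = []
        for i in range(12):
            toks = []
            for _ in range(rng.randint(10, 60)):
                r = rng.random()
                if r < 0.08:
                    toks += ["sex", "worker"]
                elif r < 0.12:
                    toks.append("prostitute")
                else:
                    toks.append(rng.choice(background))
            rows.append((f"a{i}", 1990 + (i % 2), " ".join(toks)))
        term = TerminologyCorpus(
            [TermEntry(canonical="sex worker", category="sex worker"),
             TermEntry(canonical="prostitute", category="sex worker")],
            expand_plurals=False,
        )
        streams = preprocess_corpus(corpus_factory(rows))
        agg = aggregate_counts(
            [count_term_occurrences(s, term) for s in streams],
            terms=term.canonicals,
        )
        for phrase in ("sex worker", "prostitute"):
            pattern = re.compile(r"(?<!\w)" + phrase.replace(" ", r"\s") + r"(?!\w)")
            for year in (1990, 1991):
                expected = sum(
                    len(pattern.findall(t)) for _, y, t in rows if y == year
                )
                got = agg[(agg.term == phrase) & (agg.year == year)].absolute_tf.iloc[0]
                assert got == expected
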