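# Methods

## Pipeline overview

`termtrends` computes temporal usage trends for a controlled terminology
over a corpus of conference abstracts.  The stages, each a module with a
stable surface:

1. **corpus_io** — parse a delimited abstract table (id, conference year,
   text); strip markup and decode character entities without altering words;
   drop within-year exact duplicates; persist as line-delimited JSON.
2. **preprocess** — symbol normalization, tokenization, filtering.
3. **term_discovery** — rank unigrams by abstract-level document frequency,
   apply a DF threshold plus expert include/exclude lists, expand key
   unigrams into 2..6-word candidate phrases.
4. **term_corpus** — validate the curated terminology (canonical terms,
   variants, acronyms, mutually exclusive categories) and count occurrences
   exactly.
5. **metrics** — TF, relTF, abstract- and year-level DF, IDF, TF-IDF,
   3-point moving average.
6. **trends** — trend tables, word-cloud weights, lifespan summaries.
7. **synthetic_data** — corpora with planted counts, the oracle for all of
   the above.

## Two token streams

Tokenization produces two parallel streams per abstract, both lowercase,
digit-free, diacritic-free (NFKD transliteration), split on non-alphanumeric
boundaries:

- the **matching stream** retains stop words.  Term matching and the
  vocabulary size (the TF denominator, "all words in all abstracts of a
  year") use this stream.  This is load-bearing: multiword terms like
  "men who have sex with men" and "continuum of care" contain function
  words, and a stop-word-filtered stream could never match them.
- the **discovery stream** drops stop words.  Unigram DF ranking uses it,
  since function words would otherwise dominate every ranking.

Counting on the unfiltered stream and discovering on the filtered one keeps
both halves of the workflow consistent; the TF denominator is configurable
to the filtered stream for sensitivity analyses.

Sentence-final punctuation positions are recorded during tokenization and
n-gram candidate windows never cross them (phrases spanning sentences are
artifacts).  Hyphenated forms are split, and terminology surfaces are
normalized through the same tokenizer, so "pre-exposure prophylaxis" and
"pre exposure prophylaxis" match identically.

## Normalization choices

- **Symbol map** (default: `hiv+` → "hiv positive", `hiv-` → "hiv
  negative") is applied to the raw text, word-boundary delimited and
  case-insensitive, *before* tokenization — otherwise punctuation stripping
  would silently delete the symbol.  Longest key wins.
- **Plurals** are handled at match time, not by stemming: each terminology
  variant is auto-expanded with the plural of its final word (rule-based:
  `-y`→`-ies`, sibilant endings→`-es`, else `+s`), so the corpus text is
  never rewritten.  The singularization rules are the inverse branches, with
  an exception list ("aids", "measles", ...) for words whose trailing "s" is
  not a plural.  Both directions are idempotent on their own output.
- **Duplicates** are exact matches of case-folded, whitespace-collapsed text
  *within* one conference year; identical text in different years is a
  legitimate resubmission and kept.  Near-duplicate detection is out of
  scope.
- The default stop-word list is a small English function-word set shipped in
  code; all three normalization inputs (stop words, symbol map, plural
  exceptions) are configurable via a YAML file.

## Counting semantics

The matcher is a greedy left-to-right longest-match scan over the matching
stream with token consumption: at each position the longest surface form in
the terminology wins, its tokens are consumed, and scanning resumes after
them.  Consequences:

- one text span never feeds two trend lines ("highly active antiretroviral
  therapy" does not also count as "antiretroviral therapy");
- counts are non-overlapping and invariant to abstract processing order;
- an acronym only matches where no longer phrase does.

A surface form claimed by two canonical terms is a validation error (the
motivating case is an acronym shared by two phrases, which cannot be
disambiguated without context, so it is excluded outright), as is a
canonical term listed under two categories.

## Frequency metrics

With each conference year as one document of `N` total years:

- `TF(T,Y) = absolute_TF(T,Y) / V(Y)`; `relTF = TF × 10⁶`.
- `DF(T)` counts years where `T` appears in ≥1 abstract; `IDF(T) =
  log(1 + N/DF(T))`, bounded in `[log 2, log(1+N)]` and strictly decreasing
  in DF.  The log base defaults to natural and can be set to 10; the choice
  rescales all IDFs by a constant, so trend *shapes* are base-invariant.
- `TFIDF(T,Y) = TF × IDF` exactly.
- The trailing 3-point moving average of relTF runs over conference
  *occurrences* (the sequence position, not the calendar year, because the
  conference calendar mixes annual and biennial spacing); it is reported as
  missing for the first two positions.
- A term with zero counts in a year still emits a row (tf = 0), keeping
  trend lines continuous.
- A term with `DF = 0` has no defined IDF; its rows carry `tfidf = 0` with a
  warning (its tf is 0 everywhere anyway).

Within a year all terms share the denominator `V(Y)`, so within-year TF
ratios equal absolute-frequency ratios to floating precision — the
denominator-invariant property the acceptance checks rely on.

## Terminology discovery

Unigram selection keeps tokens whose abstract-level DF reaches a threshold
(default 100, matching the common practice of thresholding on "appears in at
least 100 abstracts in some year") in at least one year.  Expert judgment is
modelled as data, not code: an include list adds below-threshold tokens, an
exclude list removes any token, and ordering is deterministic (descending
max DF, then lexicographic).  Candidate expansion enumerates every
contiguous window of 2..`max_n` matching-stream tokens containing a key
unigram, aggregated to per-year abstract DF.  `max_n` defaults to 6 so that
six-word phrases are representable; windows respect sentence boundaries.
No collocation statistics (PMI, log-likelihood) are computed — candidate
vetting is a human step by design.

## Synthetic corpora

The generator emulates the *scale and structure* of a multi-decade
conference abstract dataset, not its language:

- default 16 conference years with annual-then-biennial spacing
  (1989–1994, then every second year to 2014), 200 abstracts/year,
  ~150 tokens/abstract (≈ half a million tokens total — sized so the full
  pipeline runs in seconds; raising `abstracts_per_year` to a few thousand
  reproduces the 10⁵–10⁶ tokens-per-year scale of the real datasets this
  emulates);
- background tokens are drawn from a Zipf-weighted vocabulary (default
  5,000 words, exponent 1.1 — a realistic rank-frequency slope for natural
  text) of letter-only nonsense words on a reserved prefix, guaranteed
  disjoint from planted phrases, so no accidental matches exist and count
  recovery is *exact*, with zero tolerance;
- planted terms carry either an exact per-year count or a Poisson rate per
  abstract; each occurrence is spliced contiguously at a uniformly chosen
  token boundary of a uniformly chosen abstract (splicing at descending
  boundaries prevents one phrase interleaving another);
- the returned ground truth records realized counts, abstract presence and
  per-year token totals, all consistent with the emitted corpus by
  construction.

What passing on synthetic corpora does **not** show: robustness to real
abstract language (word-sense ambiguity, spelling variation, OCR noise,
near-duplicate abstracts), nor anything about which terms a real corpus
would surface.  Those require the real data and human review.  A separate
adversarial fixture plants nested terms with hand-computed longest-match
expectations to exercise the consumption rule.

The bundled `data/default_terms.yaml` is an explicit reconstruction of the
documented HIV terminology categories ("living with HIV", "MSM",
"sex worker", "alcohol and drug use", "older adults", "antiretroviral
therapy", ...); the full curated list behind the original analyses is not
publicly distributed.

## Numerical and degenerate-input choices

- TF requires a positive vocabulary size; a year with no tokens is an error
  rather than a NaN.
- Moving averages on series shorter than 3 are all-missing, with a warning.
- Peak-year ties resolve to the earliest year; surface-length ties in
  matching cannot occur (a surface maps to exactly one canonical term).
- Unknown character entities are left verbatim and logged; entity decoding
  and tag stripping iterate to a fixed point (bounded) to handle
  double-escaped fragments.
- All generator randomness flows through one `numpy` Generator seeded from
  `SyntheticSpec.seed`, making corpora bit-identical across runs.

## Known limitations

- Exact-duplicate removal only; no fuzzy matching or lemmatization; no
  non-Latin scripts.
- The plural rules are deliberately shallow (no irregular plurals beyond the
  exception list).
- Terminology validity on real text (contextual word senses) is a human
  review step outside the package.
- Trend detection is descriptive — no significance testing or changepoint
  detection is provided.
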