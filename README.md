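# termtrends

Temporal terminology-trend analysis of conference abstract corpora.

Health terminology shifts over time — stigmatizing labels fall out of use,
new treatment concepts appear — and those shifts can be measured by counting
a controlled set of multiword terms in a large abstract corpus, year by year.
`termtrends` implements that measurement end to end for corpora organized by
conference year: ingestion and cleaning of raw abstract tables, tokenization
and normalization, data-driven terminology discovery, exact multiword term
counting against a curated terminology with variants and acronyms, frequency
metrics, and plot-ready trend/word-cloud data products.  It is aimed at
text-mining practitioners and health-communication researchers who want the
whole pipeline reproducible and testable rather than spread across
spreadsheet, database and dashboard tools.

## The model

Each conference year `Y` is treated as one document.  For a term `T`:

- **absolute TF**: total occurrences of `T` over all abstracts of year `Y`;
- **TF**: `TF(T,Y) = absolute_TF(T,Y) / V(Y)`, where the *vocabulary size*
  `V(Y)` is the total count of all words in all abstracts of `Y`;
- **relTF**: `TF × 10⁶` — expected occurrences per million words;
- **DF(T)**: the number of conference years (1..N) in which `T` appears in
  at least one abstract;
- **IDF**: `IDF(T) = log(1 + N / DF(T))` (natural log by default);
- **TF-IDF**: `TF(T,Y) × IDF(T)` — the word-cloud weight;
- **moving average**: `MA(t) = (X(t−2) + X(t−1) + X(t)) / 3` over
  *conference occurrences* `t` (the conference spacing is uneven, so `t`
  indexes occurrences, not calendar years), undefined at the first two
  positions.

Term occurrences are counted with a greedy longest-match scan, so a nested
term such as "antiretroviral therapy" inside "highly active antiretroviral
therapy" is never double-counted.  Plural forms, symbol-normalized spellings
("HIV+" → "hiv positive") and unambiguous acronyms ("ART") all resolve to
their canonical term; an acronym claimed by two terms is rejected at
validation time.

Because real conference-abstract datasets of this kind are typically not
redistributable, the package includes a synthetic-corpus generator that
plants terms at known per-year counts (or Poisson rates) inside
Zipf-distributed background text on a reserved word alphabet — every planted
count is recoverable exactly, giving each pipeline stage a zero-tolerance
oracle.

## Worked example

A two-year scenario plants "aids carrier" 7 times and "affected communities"
once in 1989, and 1 and 2 times in 1990, inside ~3,000 background tokens per
year:

```python
from termtrends import compute_term_metrics
from termtrends.synthetic_data import table1_scenario, synthetic_terminology

spec, corpus, truth = table1_scenario(seed=0)
metrics = compute_term_metrics(corpus, synthetic_terminology(spec))
cols = ["term", "year", "absolute_tf", "reltf", "year_df", "idf", "tfidf"]
print(metrics[cols].round(6).to_string(index=False))
```

```
                term  year  absolute_tf       reltf  year_df      idf    tfidf
affected communities  1989            1  327.118090        2 0.693147 0.000227
affected communities  1990            2  665.778961        2 0.693147 0.000461
        aids carrier  1989            7 2289.826627        2 0.693147 0.001587
        aids carrier  1990            1  332.889481        2 0.693147 0.000231
```

Every absolute TF equals its planted count.  Both terms appear in both of
the two years, so `DF = N = 2` and `IDF = log(1 + 2/2) = log 2 ≈ 0.693147`.
Within 1989 the relTF ratio 2289.8 / 327.1 is exactly 7 — the two terms share
one vocabulary-size denominator, so within-year TF ratios equal
absolute-frequency ratios no matter how large the token pool is.

The same pipeline is available from the shell:

```sh
termtrends simulate --seed 1 --out-corpus corpus.jsonl --out-truth truth.json
termtrends metrics  --corpus corpus.jsonl --out metrics.csv
termtrends trends   --metrics metrics.csv --category "sex worker" --out trend.csv
termtrends cloud    --metrics metrics.csv --category "alcohol and drug use" \
                    --year 2014 --out cloud.json
```

`ingest` reads real abstract tables (CSV with configurable column mapping),
`discover` ranks unigrams by abstract-level document frequency and expands
key unigrams into n-gram candidates, and `count` emits raw per-(term, year)
counts.

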