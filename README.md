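# cinemort

Analysis pipeline comparing crowd-sourced on-screen (film) death records
against the US NVSS 2021 leading-cause mortality reference, overall and by
gender.

The pipeline:

1. **Ingest** (`cinemort.corpus`) — parse a MediaWiki-style XML dump (one
   actor per page, one death entry per wiki list item) or a plain entries
   CSV, and filter to film entries (television / video-game entries are
   detected from category tags or keywords and excluded by default).
2. **Cause classification** (`cinemort.causes`) — lowercase, tokenize and
   suffix-stem each free-text death description, then assign one of 13
   cause categories (12 named leading causes + `other`) via a versioned
   stem lexicon (`src/cinemort/data/lexicon.yml`). Ties break by a fixed
   priority order; unmatched descriptions fall back to `other`.
3. **Gender classification** (`cinemort.gender`) — look up the actor's
   first name in a packaged 61k-name dictionary
   (`src/cinemort/data/name_gender.tsv`, six-valued labels), then
   consolidate: `male`/`mostly_male` → man, `female`/`mostly_female` →
   woman, `androgynous`/`unknown` → excluded from gender-stratified
   statistics (but retained in overall cause counts).
4. **Reference** (`cinemort.reference`) — the NVSS 2021 per-cause,
   per-gender counts as a validated packaged fixture
   (`src/cinemort/data/nvss2021.csv`). Internally inconsistent rows are
   flagged, never corrected; gender proportions are always recomputed from
   the women/men counts.
5. **Statistics** (`cinemort.stats`) — within-dataset cause shares and
   representation ratios (film share / reference share), and a per-cause
   one-sample goodness-of-fit chi-square of film gender counts against
   reference gender proportions (two cells, df = 1, no continuity
   correction; causes with fewer than 5 film observations carry no
   statistic). A 2×2 independence mode is available but is *not*
   equivalent when the film sample is large relative to the reference.
6. **Synthetic data** (`cinemort.synth`) — generator for wiki-style dumps
   with planted cause/gender mixtures and exact truth tables, used to test
   every stage without the real dump.
7. **Reporting** (`cinemort.reporting`) — end-to-end orchestration: year
   percentiles, gender tallies, the chi-square battery, share-scatter and
   gender-bar figures, audit CSVs, and a run manifest with stage counts
   and fixture versions.

## CLI

```sh
# generate a synthetic corpus with planted structure
cinemort synth --config synth.yml --out fixtures/

# stage by stage
cinemort ingest --dump fixtures/synthetic_dump.xml --out entries.csv --media film
cinemort classify-cause --entries entries.csv --out causes.csv
cinemort classify-gender --entries entries.csv --out genders.csv
cinemort compare --causes causes.csv --genders genders.csv --out report/

# or the whole pipeline from one config
cinemort run --config run.yml
```

`run.yml` example:

```yaml
dump: fixtures/synthetic_dump.xml
media: [film]
out_dir: report
# lexicon / name_dictionary / reference default to the packaged fixtures
```

`synth.yml` example:

```yaml
n_entries: 1000
cause_mixture: {heart: 0.3, suicide: 0.3, accidents: 0.2, other: 0.2}
gender_mixture_by_cause: {suicide: 0.6}
ambiguous_name_fraction: 0.13
seed: 42
```

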