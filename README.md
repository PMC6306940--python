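# phenosig

Target-level phenotype profiling from adverse-event case reports.

`phenosig` turns FAERS-style spontaneous case reports plus drug→protein
link tables into statistically characterized target–phenotype association
profiles. It covers the full pipeline:

- **`phenosig.model`** — domain types (case reports, a 4-level phenotype
  hierarchy, drug concepts, target links) and plain-text delimited
  readers/writers (`$`-, tab- and comma-delimited dialects).
- **`phenosig.mapping`** — staged normalization of verbatim drug mentions:
  blacklist exclusion, exact synonym match, whole-token part match, then
  bounded edit-distance match (never more than 5 edits), with multi-drug
  phrase splitting and coverage reporting.
- **`phenosig.integrate`** — expansion of mapped drugs to targets, enzymes,
  carriers, transporters, pathways and ATC classes; the clean-target
  filter (targets never listed with any other role); temporal slices and
  declarative cohort selection.
- **`phenosig.signals`** — 2×2 contingency construction with hierarchy
  rollup, PRR `a(c+d)/(c(a+b))`, Fisher's exact test (exact integer
  arithmetic for small tables), Benjamini–Hochberg q-values (Storey π₀
  behind a flag), per-entity profiles, corpus-wide screens, and
  mechanism-stratified (agonist vs antagonist) profiles.
- **`phenosig.cohorts`** — outcome-rate comparison between two cohorts
  ("virtual perturbation experiment"): rates, risk ratio, exact p.
- **`phenosig.benchmark`** — direct case-level target signals contrasted
  with indirect drug-mediated signals for known protein–effect pairs,
  including per-drug PRR spread and recapitulation totals.
- **`phenosig.simulate`** — a deterministic synthetic-world generator
  (vocabularies, dictionary with misspellings, blacklist noise, planted
  protein–reaction effects, protective-outcome cohorts) with full ground
  truth, so every stage is testable offline.

## Command line

All functionality is exposed through one entry point:

```sh
phenosig simulate --seed 1 --n-cases 5000 --planted P0000:R4_0000:5.0 --out data/
phenosig map --cases data/cases.tsv --dictionary data/drug_dictionary.tsv \
    --blacklist data/blacklist.txt --out mapped/
phenosig screen --cases data/cases.tsv --dictionary data/drug_dictionary.tsv \
    --hierarchy data/hierarchy.tsv --links data/target_links.tsv \
    --event-level 4 --min-support 100 --out screen.tsv
phenosig profile ... --entity-id P0000 --out profile.tsv
phenosig compare-cohorts ... --exposed-config exposed.toml --outcome DE --out cmp.tsv
phenosig benchmark ... --pairs pairs.tsv --out bench.tsv
phenosig run --config pipeline.toml
```

Cohort and pipeline configs are flat TOML; every CLI flag overrides its
config key. Signal thresholds default to support ≥ 500 cases,
co-occurrence ≥ 10, PRR ≥ 2 and q < 0.05.

Note on q-values: they are computed within each profile or screen call,
never across calls, so the same pair can carry different q-values in
differently scoped screens.

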