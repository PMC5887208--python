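# adescreen

Stratified adverse-drug-event screening on spontaneous-report data.

For each (drug A, primary-disease stratum B, adverse event C) triple the
package runs two detectors side by side:

* **Association rules** `A ∩ B → C`, scored by *lift*
  (`confidence / support(C)` with the consequent support taken over the whole
  database) and *conviction* (`(1 − support(C)) / (1 − confidence)`, `+inf`
  for exception-free rules). Signal criteria: rule count ≥ 3, lift > 1,
  conviction > 1. Candidate generation is apriori-pruned, and is verified to
  be identical to exhaustive enumeration.
* **Proportional reporting ratio (PRR)** with a Yates-corrected χ² on the
  stratum-restricted 2×2 table. Signal criteria: count ≥ 3, PRR ≥ 2, χ² ≥ 4.

A head-to-head evaluation treats the PRR signal set as the reference and
reports sensitivity / specificity / Youden's index / PPV / NPV, a ROC curve
with trapezoidal AUC over the lift ranking, and an OLS fit of `log10 lift`
against the signal intensity `log10 PRR + log10 χ²`.

A synthetic-data module generates four-table datasets (DEMO / DRUG / REAC /
HIST) with configurable baseline rates and injected `(drug, disease, event)`
relative risks, so the whole pipeline is testable without any external data.

## Input format

Four delimited text tables with a header row and a shared case-id column
(defaults: `case_id`, `drug_name`, `role`, `route`, `event_term`,
`hist_term`; all configurable via `LoadConfig`). DEMO rows are deduplicated
by case id (first occurrence wins); DRUG rows are filtered by a route
allow-list (default `oral`) and optionally by drug role. Strata are named
preferred-term lists, given as YAML (`name: [term, ...]`) or one term per
line in a plain-text file.

## Command line

```sh
# synthesize a dataset (packaged default config: 18,000 reports, 2 strata)
adescreen simulate --seed 7 --out sim/

# screen four tables and evaluate AR against PRR
adescreen screen --demo sim/demo.csv --drug sim/drug.csv \
    --reac sim/reac.csv --hist sim/hist.csv \
    --strata sim/strata.yaml --out run/

# re-evaluate an existing rules table
adescreen evaluate --rules run/rules.csv --out run/

# simulate + screen + evaluate in one deterministic run
adescreen all --seed 7 --out run/
```

Outputs: `rules.csv` (one row per candidate triple with all counts, both
detectors' statistics and boolean signal flags), `evaluation.json`,
per-stratum ROC point and regression scatter CSVs, and a `provenance.json`
with the config hash, seed and row counts.

## Worked example

`adescreen.toy_dataset()` returns this 12-report fixture (all reports carry
history term `H`, defining stratum `K`):

| cases   | drugs | events |
|---------|-------|--------|
| T01–T03 | D1    | E1     |
| T04–T06 | D2    | E2     |
| T07     | –     | E1     |
| T08     | –     | E2     |
| T09     | D3    | E3     |
| T10     | D3    | –      |
| T11     | –     | –      |
| T12     | D4    | E3     |

Both detectors flag exactly `(D1, K, E1)` and `(D2, K, E2)` (lift 3,
conviction ∞, PRR 9, χ² 4.5) and nothing else, so the agreement between the
two methods is perfect (Youden's index 1.0).

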