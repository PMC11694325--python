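# pvdisprop

Disproportionality signal mining and descriptive pharmacovigilance for
FAERS-shaped spontaneous adverse-event reports, built around the study
workflow for tumor adverse events (TAEs) under proton-pump-inhibitor (PPI)
exposure — esomeprazole, lansoprazole, omeprazole, pantoprazole and
rabeprazole.

## Who this is for

Pharmacoepidemiologists and drug-safety analysts who want the complete desk
workflow — report cleaning, MedDRA-style tumor-term classification,
reporting-odds-ratio (ROR) scans, descriptive/time-to-onset analysis and
univariate logistic risk modelling — as tested, reusable code. Because raw
FAERS extracts are large and access-encumbered, the package ships a synthetic
spontaneous-report generator with *planted* association strengths, so every
downstream stage can be validated against known truth before being pointed at
real data.

## The statistic at the core

For a target drug group and an event term, count deduplicated cases into the
2×2 table

|              | event | no event |
|--------------|-------|----------|
| drug group   | a     | c        |
| all others   | b     | d        |

The reporting odds ratio and its Wald 95% confidence interval are

    ROR = (a/c) / (b/d) = (a·d) / (b·c)
    95% CI = exp( ln ROR ± 1.96 · √(1/a + 1/b + 1/c + 1/d) )

A drug–event pair is flagged as a **signal** when the event was reported at
least 3 times under the drug group *and* the lower CI bound exceeds 1. The
interval is symmetric on the log scale, so the point estimate is always the
geometric mean of its bounds. When a cell is zero, a Haldane–Anscombe
correction (+0.5 to all cells) is applied and flagged.

The generator plants associations on exactly this scale: for a pair with
target ROR *R*, exposed-case event odds are *R* times the background odds,
making *R* the estimand of the downstream ROR.

## Worked example

```sh
pvdisprop run --config examples/demo_config.yaml --out runs/demo
```

generates 5,000 synthetic cases (with versioned duplicates, delete-file
members and out-of-range demographics), with two planted associations —
(esomeprazole, Gastric cancer) at ROR 6 and (omeprazole, Renal cell
carcinoma) at ROR 3 — then cleans, classifies, scans and models. It prints
the stage chain:

```json
{
  "generated": 5253,
  "ingest_in": 5253,
  "ingest_out": 4939,
  "classified": 4939,
  "tae_cases": 625,
  "scanned_pairs": 78,
  "signals": 5
}
```

5,253 records collapse to 4,939 analysable cases (253 duplicate versions, 37
delete-file members, 12 invalid ages, 12 invalid weights removed — the exact
counts are in `filter_ledger.json`). The scan output `signals.tsv` ranks the
flagged pairs; both planted pairs are recovered at the top:

```
drug_group    event                 a   b   c    d     ror    ci_low  ci_high  is_signal
esomeprazole  Gastric cancer        34  36  599  4270  6.733  4.181   10.842   True
all PPIs      Gastric cancer        56  14  3053 1816  2.379  1.321   4.286    True
omeprazole    Renal cell carcinoma  12  34  633  4260  2.375  1.223   4.611    True
```

The esomeprazole × Gastric cancer estimate of 6.73 [4.18, 10.84] brackets the
planted value of 6; the two remaining flags are the expected false-positive
traffic of an unadjusted scan at this sample size (the replicate studies
below quantify it). Also written: `table1.tsv` (strata split by fatal
outcome with Wilcoxon/chi-square/Fisher tests), `annual_proportions.tsv`,
`tumor_sites.tsv`, `co_reported_*.tsv`, `km_*.tsv` (Kaplan–Meier event-free
curves with log-rank tests) and `risk_factors.tsv` (univariate logistic odds
ratios for age band, sex, drug group and dose band).

Every stage is also callable as a library function
(`pvdisprop.signals.scan_all`, `pvdisprop.outcomes.summarize_table1`, ...)
or as an individual CLI subcommand (`generate`, `ingest`, `classify`,
`scan`, `describe`, `riskfactors`).

## Layout

```
src/pvdisprop/
  synthetic_faers.py   generator: planted associations, duplicates, invalids
  ingest.py            readers + dedup/exclusion cascade with audit ledger
  meddra.py            toy PT→HLT→HLGT→SOC hierarchy, tumor classification
  signals.py           2×2 tables, ROR + Wald CI, signal criterion, scans
  outcomes.py          Table-1-style summaries, sites, co-AEs, Kaplan–Meier
  riskmodel.py         univariate logistic odds ratios, age/dose bands
  pipeline.py          run_all orchestration + replicate study harnesses
  cli.py               click command group
docs/methods.md        model assumptions, conventions, limitations
```
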