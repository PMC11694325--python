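# Methods

## Scope and model

The package implements spontaneous-report disproportionality analysis for
tumor adverse events (TAEs) under proton-pump-inhibitor exposure. The
analysis unit is the deduplicated *case* (one per CASEID); all 2×2 cells,
descriptive strata and regression rows are case-level, so a case contributes
at most once to any count regardless of how many drugs or reactions it
carries.

The disproportionality statistic is the reporting odds ratio
ROR = (a·d)/(b·c) with the Wald interval
exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)), z = 1.96 by default. The signal
criterion is a ≥ 3 and CI lower bound > 1. Both z and the case threshold are
configuration keys. The comparator for a drug group is every case in the
loaded dataset with no exposure to that group — the only dataset-closed
reading of "all other medications in the database". Zero cells get a
Haldane–Anscombe +0.5 on all four cells (flagged in the output); a "none"
policy returns non-finite estimates flagged rather than raised.

ROR is not an incidence measure and a signal is not causation; the package
deliberately reports cell counts alongside every estimate so denominators
stay visible.

## Exclusion cascade

Order is fixed and audited by a ledger whose stage counts sum exactly to
input minus output: (1) per-CASEID deduplication keeping the latest FDA_DT,
ties to the higher PRIMARYID (records with missing FDA_DT lose any dated
tie); (2) delete-file removal; (3) present age outside [0, 150] years;
(4) present weight above 150 kg; (5) optional suspect-role restriction —
a case is kept only if a study PPI carries a suspect role, the
machine-checkable reading of "excluding events attributable to concomitant
medication"; (6) exact-duplicate collapse: records identical in every field
except PRIMARYID/CASEID/FDA_DT reduce to the lowest CASEID. Missing age or
weight is retained by default (the filters bind only on present values);
`drop_missing_demo` drops them instead. The suspect-role restriction is
opt-in for full pipeline runs because the disproportionality comparator
needs the unexposed background cases.

## MedDRA stand-in

MedDRA is licensed, so a synthetic, reduced hierarchy ships as package data:
47 PTs with one primary PT→HLT→HLGT→SOC path each — 13 tumor terms (all
under the neoplasms SOC, each with an anatomical site) and 34 non-tumor
terms across 11 other SOCs. Term matching is case-insensitive exact match
after whitespace normalization; unknown reaction terms classify as
non-tumor and are counted, never fatal to a run. The tumor set is a
configuration surface (`MedDRAHierarchy.with_tumor_pts`) because real
analyses differ in whether they use a standardized query or a curated list.
The LLT level is omitted: the workflow operates at PT level throughout.
For tumor-site profiles a case with tumor PTs in several sites takes the
site of its alphabetically first matched PT, so site percentages partition
to exactly 100%.

## Synthetic generator

The generator emulates a reporting-system extract, not disease biology. Per
case: one suspect drug drawn from five PPIs plus three non-PPI comparators
(uniform by default); per-PT independent reaction draws at background
probability 0.01; an event date uniform on 2004-01-01..2024-03-31; onset
days log-normal with median 2,556 days and σ = 1.1 (median and quartile
ratio chosen to echo the observed onset profile of PPI tumor reports),
capped at 100 years; receipt 0–180 days after the event. Planted
associations tilt the exposed-case event odds by the target ROR, so the
planted parameter is exactly the estimand. Cases drawing no reaction
receive one uniform non-tumor filler PT (a report cannot exist without a
reaction); this inflates non-tumor background counts slightly and leaves
tumor-pair RORs untouched.

Demographics echo the observed report mix: age ~ N(60, 15²) clipped to
[18, 100] (30% missing), weight ~ N(75, 15²) (40% missing), sex
female/male/missing at 31/37/32%, US-dominated reporter countries, tumor-case
fatality 0.297 (non-tumor 0.05). Data pathologies are injected at
configurable rates: duplicate case versions (5%; same CASEID and content,
later FDA_DT, higher PRIMARYID), delete-file members (0.5%), out-of-range
ages and weights (0.5% each). Daily doses come from a per-drug level/weight
map (default 20/40/80 mg/day at 39/49/12%).

What the generator does **not** emulate: reporting-delay dynamics, multiple
drugs per case (one suspect drug is the default marginal), drug–drug
interactions, correlated reactions within a case, secular reporting trends,
and the real database's much lower tumor-term share. Passing tests therefore
demonstrate that the *machinery* is calibrated and recovers planted
structure — not that any real-data estimate is unbiased.

## Statistical conventions

* Quantiles (median, IQR) use linear interpolation between order statistics.
* Group comparison in stratified summaries: Wilcoxon rank-sum for continuous
  variables; Pearson chi-square for categorical, switching to Fisher exact
  for 2×2 tables with any expected cell < 5 (larger sparse tables keep
  chi-square and carry a low-expected-count note). The choice is recorded
  per variable.
* Time to onset runs from the earliest suspect study-drug therapy start to
  the event date; cases missing either date are excluded and counted. No
  censoring is generated (every tumor case has an event), but the
  Kaplan–Meier machinery (lifelines) supports it; with no censoring the
  product-limit curve equals the empirical survival function. Log-rank
  compares groups; Mann–Whitney (exact for n ≤ 8) compares raw onset days
  for two groups.
* Calendar periods are left-closed five-year bins [2000, 2005), …
* Logistic models are univariate by design, fitted by maximum likelihood
  (statsmodels GLM/binomial, IRLS, tolerance 1e-10), reporting Exp(β) with
  Wald CIs and z-based p-values. For a binary exposure the model is
  saturated and Exp(β) equals (a·d)/(b·c) exactly, which the tests use to
  cross-check the regression against the ROR engine. Levels with a zero
  cell are flagged non-estimable and dropped from the design; missing
  exposures are excluded and counted, never imputed.
* Band conventions: age <65 (reference) / 65–75 inclusive / >75; dose
  ≤20 (Low, reference) / (20, 40] (Medium) / >40 mg/day (High). Raw mg/day
  bands are applied uniformly across drugs even though milligrams are not
  potency-equivalent between PPIs — a deliberate, documented limitation of
  the dose analysis.

## Determinism and problem sizes

A single integer seed drives one numpy Generator through a fixed draw order,
so identical configurations reproduce byte-identical datasets and tabular
outputs; the run manifest records the config hash, seed and per-stage
counts, which must chain exactly. The replicate harnesses use a seed ladder
(base + k). Operating characteristics are measured at 100,000 cases × 50
seeds for planted-effect recovery (targets 2/5/10) and 50,000 cases × 200
seeds for null calibration — sizes at which a replicate costs about a second
and the planted-effect sampling error is a few percent.

Measured at these sizes: recovered medians within 2% of the planted targets
with 100% detection; all-null per-pair false-signal fractions of 2–6%
(mean ≈ 2.5%), and mean per-pair CI coverage of ≈95% — consistent with the
nominal Wald level. Note that with 200 replicates the binomial standard
error on a per-pair coverage estimate is ±1.5 percentage points, so
individual pairs scatter a few points around 95% even when calibration is
exact; per-pair coverage assertions tighter than that scatter will fail by
chance for a correct implementation.

## Known limitations

* The toy hierarchy's paths are plausible but synthetic; SOC-level co-AE
  profiles depend on them.
* The scan applies no multiple-testing adjustment (by design, matching
  standard pharmacovigilance practice); false-signal traffic at scan scale
  is quantified by the null-calibration harness instead.
* Only the ROR family is implemented — no PRR, EBGM or Bayesian shrinkage.
* Univariate models only; no adjustment, interaction or causal machinery.
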