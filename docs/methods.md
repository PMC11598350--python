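# Methods

## Data model and deduplication

A spontaneous-report extract is a set of `$`-delimited tables keyed by
PRIMARYID: DEMO (one row per *report version*), DRUG, REAC, INDI, OUTC
and THER, plus deleted-case lists. A case (CASEID) may be submitted
repeatedly; analysis requires one version per case. The survivor is the
version maximizing (FDA_DT, PRIMARYID):

- FDA_DT must be a valid 8-digit calendar date; blank or unparseable
  values sort below every dated version, on the view that a dated
  submission carries more recent information.
- PRIMARYID comparison is numeric when both values parse as integers,
  lexicographic otherwise — "higher" is an ordinal notion. The two
  regimes never interleave in real extracts.
- Cases on the deleted lists are removed outright.

The rule is idempotent, order-independent and conserving (every version
is survivor, superseded or deleted); all three properties are tested,
the first two with hypothesis. Child rows are joined by the surviving
PRIMARYID only; rows pointing at superseded versions are counted and
dropped. Per-case reaction PT lists are de-duplicated preserving first
occurrence. A case with no reactions is kept but marked non-analyzable.

Absolute report counts from any given public extract depend on which
deleted-list vintages were applied, so the pipeline reports its own flow
counts (versions read / deleted / superseded / cases) in the manifest
rather than promising to match any external tally.

## Cohort definition

A case enters the analysis cohort when **any** of its drugs carries an
indication PT in the configured set (default `{Rheumatoid arthritis}`,
compared case-insensitively). Report-level restriction was chosen over
drug-level indication linkage because it is the more sensitive reading
and the indication of co-medications in the same report is still
rheumatoid-arthritis care.

Exposure attribution uses only the primary-suspect (PS) role. Verbatim
drug strings are normalized (case-fold; dose, salt and formulation
tokens stripped) and matched against a pattern dictionary by
longest-pattern-wins, which is deterministic and lets brand names
(`HUMIRA`) and decorated strings (`METHOTREXATE SODIUM 25MG`) resolve to
canonical ingredients. The bundled dictionary covers the 20 DMARD
ingredients with common brands and is fully user-overridable; drugs with
zero matched reports are reported explicitly rather than silently
dropped. Cases whose PS drug does not match remain in the cohort as
background: the comparator for every index drug is *all other
rheumatoid-arthritis reports in the same period*, including non-DMARD
suspects. If several PS entries map to different ingredients the case
contributes to each ingredient's exposed set (configurable to
first-only); exposed and background are then still disjoint per
ingredient, which is the partition the 2×2 tables need.

## Disproportionality statistics

Counting is report-level: a case counts once in `a` however often a PT
repeats. With `a,b,c,d` as usual and `N = a+b+c+d`:

- `ROR = ad/bc`, 95% Wald bounds `exp(ln ROR ± 1.96·se)`,
  `se = √(1/a+1/b+1/c+1/d)`. Any zero cell leaves the ROR undefined
  (NaN) instead of applying a Haldane-type correction: the ≥3-report
  signal rule makes corrected small-cell RORs irrelevant, and silent
  corrections would alter reported estimates.
- `IC = log2((a+0.5)/(E+0.5))`, `E = (a+b)(a+c)/N` — the shrinkage
  observed-over-expected measure of the Bayesian confidence propagation
  (BCPNN) tradition. Its lower 2.5% credibility bound uses the Norén
  approximation `IC025 = IC − 3.3(a+0.5)^−1/2 − 2(a+0.5)^−3/2`, the
  standard form in FAERS disproportionality work; the screen accepts a
  pluggable IC function should the exact posterior be preferred. The
  correction terms are strictly positive, so `IC025 < IC` always.
- Signal rule: `n ≥ 3 AND ROR025 > 1 AND IC025 > 0`, all strict
  ("exceeded", "greater than"). Undefined bounds never signal.

Both statistics are verified against an independently coded evaluation
on 1,000 random tables to 1e-10 relative error, plus monotonicity and
invariance properties (ROR is scale-invariant, IC deliberately is not).

SMQ-level screening replaces the event indicator by SMQ membership: a
case counts once per SMQ regardless of how many member PTs it carries,
so an SMQ's count is at least the maximum member-PT count. Narrow/broad
scope is not modelled separately; a membership file may encode scope as
distinct group names. With singleton SMQs the SMQ screen reduces exactly
to the PT screen (tested).

## Adjusted reporting odds ratios

The malignancy indicator (any reaction PT in the configured event
universe, pooled — a per-event option exists) is regressed on index-drug
exposure, age in years, sex (F=1, M=0) and four concomitant-medication
flags (methotrexate, tofacitinib, leflunomide, sulfasalazine; a drug
never flags its own exposure). Rows are restricted to cases whose PS
drug is any dictionary DMARD, so the adjusted comparison is within the
DMARD-treated population. Missing age or sex leads to complete-case
exclusion with logged counts — the simplest defensible default given no
stated alternative; unknown sex is treated as missing.

The fit is IRLS (Newton–Raphson on the logistic log-likelihood), written
out rather than delegated so the estimates are reproducible from the
stated algorithm alone: tolerance 1e-8 on the max coefficient change,
at most 100 iterations, step-halving guaranteeing likelihood ascent,
constant covariate columns dropped to keep the design full rank, and
separation flagged when a coefficient diverges (|β| > 30) or fitted
probabilities pin to 0/1 against the observed class. Standard errors
come from the inverse observed information; `adjusted ROR = exp(β_drug)`
with 1.96-based Wald intervals. The implementation is cross-checked in
the tests against an independent maximum-likelihood routine
(statsmodels) and against the closed-form collapsibility identity
(exposure-only model ⇒ exp(β) = ad/bc to 1e-8).

The recovery benchmark simulates 50 replicates of n = 20,000 with a true
conditional odds ratio of 2.5, where standardized age, sex and one
co-medication flag raise both exposure and outcome odds (coefficients
0.6/0.5/0.8 on exposure, 0.5/0.3/0.6 on outcome, chosen once to make the
confounding visible: the crude ROR lands near 3.5). The adjusted mean
estimate is required within 5% of truth with Wald coverage in
[0.90, 0.99]. Note the adjusted estimand is the conditional odds ratio;
even without confounding it differs from the marginal one
(non-collapsibility), which is why crude and adjusted are reported side
by side rather than treated as interchangeable.

## Time to onset and descriptives

Onset is `(event date − earliest therapy start of the PS drug)/365.25`
years. Both dates must be full YYYYMMDD values; partial dates (YYYY,
YYYYMM) are excluded with reason codes rather than imputed, since
inventing a day fabricates precision (mid-point imputation would be a
caller-side preprocessing choice). The anchor is the adverse-event onset
date, not the report receipt date. Negative intervals are excluded as
inconsistent. Candidates are conserved: records + reasoned exclusions =
exposed cases. Quantiles are linear-interpolation (type 7) so medians
and IQRs are bit-for-bit reproducible; groups under 4 records are
flagged low-n.

Age normalization follows the FAERS unit codes: DEC×10, YR×1, MON÷12,
WK÷52.1786, DY÷365.25, HR÷8766; results outside [0, 120] years and
unknown codes are set missing. Percentage shares round half-up to two
decimals. Outcome percentages are reported against two denominators —
reports and outcome entries — because a case may carry several outcome
codes and published outcome percentages in this literature often use an
entry-level denominator without printing it.

## Synthetic data generator

The generator emulates the features the pipeline must survive: duplicate
version clusters (10% of cases by default, 2–3 versions, later versions
with later FDA_DT or, in 20% of clusters, an identical FDA_DT so the
PRIMARYID tie-break is exercised), a deleted-case list (1%), FAERS age
units (YR/DEC/MON mix), 5% unknown sex, ~70% rheumatoid-arthritis
indication with a non-RA remainder, per-field missingness (20% age, 30%
event date, 8% partial event dates, 25% therapy start), brand-name and
dose-decorated verbatim strings, concomitant drug rows, and 1–2 outcome
codes per case.

Drug–event dependence is injected on the **odds scale**: an exposed
case's odds for an associated event are multiplied by RR, making the
reporting odds ratio the natural estimand so recovered RORs are directly
comparable to the generating RR. Default PS marginals give the DMARDs
about 57% of reports with relative volumes mirroring public reporting
shares (methotrexate and adalimumab largest; iguratimod, filgotinib and
peficitinib at zero so zero-count reporting is exercised); event
background rates are 0.2–1%. Onset times are log-normal per class —
median 5 years (σ=0.6 log-years) for csDMARDs, 2 for bDMARDs, 1.2 for
tsDMARDs — echoing the pattern that conventional synthetic agents show
the longest published onset times. Event dates are therapy start plus
onset; receipt dates follow with a 30–300 day lag clipped to the
2019–2023 window. An optional confounding switch tilts both exposure and
event odds by age and sex for exercising the adjusted stage.

Everything derives from one `numpy` generator seeded by the config, and
output files are byte-identical across runs of the same config. What the
generator does **not** emulate: misspelled verbatim text, report-source
(RPSR) content, correlated event co-occurrence, secular reporting
trends, or indication hierarchies beyond the binary RA/other mix — so a
passing recovery benchmark demonstrates estimator and plumbing
correctness under the stated generating model, not robustness to every
real-world pathology of spontaneous data.

The recovery benchmark (`recovery_benchmark_config`) uses 200,000
reports with three injected RR = 5 pairs against 557 null pairs; each
injected pair expects ≳75 exposed-event reports. Required operating
characteristics: every evaluable injected pair flagged, false-signal
rate among null pairs ≤ 2%, every duplicate cluster resolved to its
generated survivor. Observed false-signal rates sit near 1%, consistent
with the joint strictness of the three-condition rule. The benchmark
sizes (200,000 reports; 50×20,000 regression replicates) keep the whole
suite and the acceptance script in the tens of seconds on one CPU while
leaving Monte-Carlo error well inside the tested margins.

## Numerical and interface choices

- 1.96 is used as the 95% normal quantile throughout.
- Dates are carried as integers (YYYYMMDD / YYYYMM / YYYY) with explicit
  precision handling; 8-digit values must be real calendar dates.
- Stage outputs are plain delimited tables and a manifest with SHA-256
  content hashes, echoing pharmacovigilance audit practice; the CLI
  (`signalkit synth | ingest | screen | adjust | tto | describe |
  run-all | heatmap`) is a thin layer over the library.
- Heatmap rendering is presentational only; the delimited tables are the
  contract.

## Known limitations

- Disproportionality measures reporting association, not incidence or
  causation; no multiple-testing correction is applied (none is standard
  for this screening rule), so isolated chance signals are expected.
- The dictionary is pattern-based; genuinely misspelled verbatims fall
  to the background rather than being fuzzily rescued.
- The adjusted model is a pooled-outcome logistic regression; it does
  not address unmeasured confounding, reporting bias, or within-case
  correlation across multiple events.
- SMQ content must be user-supplied; results at SMQ level are only as
  complete as the supplied membership file.
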