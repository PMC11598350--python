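# signalkit

Disproportionality signal detection for spontaneous adverse-event report
databases, built around the question of malignancy risk under
disease-modifying antirheumatic drugs (DMARDs) in rheumatoid arthritis.

Spontaneous reporting systems such as the FDA Adverse Event Reporting
System (FAERS) publish quarterly multi-table extracts (DEMO, DRUG, REAC,
INDI, OUTC, THER plus deleted-case lists). `signalkit` turns such extracts
into screened drug–event safety signals:

1. **Ingestion and deduplication** — report versions sharing a CASEID are
   collapsed to the one with the latest FDA_DT (ties broken by the higher
   PRIMARYID), and cases on the deleted lists are removed.
2. **Cohort restriction** — cases are limited to a target indication
   (default *Rheumatoid arthritis*), and each case is attributed to the
   canonical ingredient of its primary-suspect (PS) drug via a bundled,
   overridable dictionary of 20 DMARDs (csDMARD / bDMARD / tsDMARD) and
   their brand names. Unmatched PS cases stay in the cohort as the
   comparator background.
3. **Disproportionality screen** — for each drug–event 2×2 table
   (`a,b,c,d`; N = a+b+c+d) the package computes

   - reporting odds ratio `ROR = ad/bc` with the ln-scale Wald interval
     `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`;
   - information component `IC = log2((a+0.5)/(E+0.5))` with expected
     count `E = (a+b)(a+c)/N`, and the lower credibility bound
     `IC025 = IC − 3.3(a+0.5)^−1/2 − 2(a+0.5)^−3/2`;
   - the signal rule: **n ≥ 3 reports, ROR025 > 1 and IC025 > 0** (all
     strict).

   The same screen runs at the level of Standardised MedDRA Queries
   (SMQs) once a user-supplied PT→SMQ membership file is given (MedDRA
   content is licensed and therefore never bundled; the nine
   malignancy-related SMQ names ship as the default universe).
4. **Adjusted reporting odds ratios** — a hand-rolled IRLS logistic
   regression of the malignancy indicator on exposure, age, sex and
   concomitant methotrexate/tofacitinib/leflunomide/sulfasalazine yields
   `adjusted ROR = exp(β_drug)` with Wald 95% intervals, reported next to
   the crude ROR.
5. **Time to onset and descriptives** — years from the first full-dated
   therapy start of the suspect drug to the event date (median/IQR,
   type-7 quantiles), plus per-drug shares, sex/age/country/outcome
   tabulations.
6. **Synthetic generator** — `signalkit.synthetic_faers` writes complete
   FAERS-style quarterly tables with known ground truth (injected
   relative reporting rates, duplicate clusters, missingness, class-wise
   onset distributions), so the whole pipeline is testable offline.

## Worked example

Generate a 50,000-report synthetic extract (four drug–event pairs carry
injected relative reporting rates of 3–5) and run the full pipeline:

```python
from pathlib import Path
from signalkit.pipeline import PipelineConfig, run_pipeline
from signalkit.synthetic_faers import SynthConfig

out = run_pipeline(PipelineConfig(
    output_dir=Path("demo_out"),
    synth_config=SynthConfig(seed=1, n_cases=50_000),
    smq_map_path=Path("smq.csv"),   # your pt,smq membership file
))
```

`demo_out/signals_pt.csv` then contains one row per screened pair; the
rows passing the signal rule were:

```
        drug                           event  a  ror  ror025   ic  ic025  signal
  adalimumab               Uterine leiomyoma 45 3.41    2.42 1.44   0.94    True
 baricitinib                   Breast cancer 13 3.31    1.89 1.55   0.61    True
  infliximab                       Leukaemia  8 2.78    1.36 1.28   0.06    True
methotrexate    Lymphoproliferative disorder 55 3.58    2.61 1.46   1.01    True
upadacitinib Squamous cell carcinoma of skin 26 3.60    2.38 1.64   0.99    True
```

All four injected associations are recovered; the infliximab–leukaemia
row is a chance finding of the kind any database-wide screen produces,
which is why signals are screening hypotheses, not causal claims.
`a` is the number of deduplicated reports carrying both the index drug
(as primary suspect) and the event; ROR025/IC025 are the lower interval
bounds entering the signal rule. The run's `manifest.json` logs the flow:
56,510 report versions → 49,475 cases after deduplication (595 deleted,
6,440 superseded) → 33,533 rheumatoid-arthritis cases, 19,203 of them
with a DMARD as primary suspect.

The same directory holds `adjusted.csv` (crude vs covariate-adjusted
ROR per drug), `tto.csv` (e.g. hydroxychloroquine median onset 5.30
years against 1.21 for baricitinib — the generator gives conventional
synthetic DMARDs the longest onset times), the SMQ-level screen and the
descriptive tables.

The same pipeline runs from the shell:

```sh
signalkit synth --seed 1 --n-cases 50000 --out synth/
signalkit run-all --in synth/ --out results/ \
    --events events.txt --smq-map smq.csv --level both
```

For real FAERS quarters, point `--in` at a directory of `$`-delimited
quarterly ASCII tables instead.

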