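"""Time-to-onset and descriptive summaries of the analysis cohort.

Time to onset is the interval from the first therapy start of the
primary-suspect drug to the adverse-event onset date, in years
(365.25-day years).  Both dates must be full YYYYMMDD values: partial
dates (year or year-month) are excluded rather than imputed, and every
exclusion carries a reason code so candidates are conserved.  Quantiles
use linear interpolation (the type-7 convention), making medians and
interquartile ranges reproducible bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    CohortCase,
    OnsetExclusion,
    OnsetRecord,
    date_precision,
    to_date,
)

log = logging.getLogger(__name__)

#: days (or hours) per year conversions for FAERS age-unit codes
_AGE_FACTORS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1786,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

DAYS_PER_YEAR = 365.25


def normalize_age(value: Optional[float], unit_code: Optional[str]) -> Optional[float]:
    """Convert a FAERS (age, unit-code) pair to years; None when unusable.

    Implausible results (< 0 or > 120 years) and unknown unit codes are
    flagged missing rather than propagated.
    """
    if value is None or unit_code is None:
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    if not np.isfinite(v):
        return None
    factor = _AGE_FACTORS.get(str(unit_code).strip().upper())
    if factor is None:
        if str(unit_code).strip().upper() not in ("", "UNK"):
            log.debug("unknown age unit %r", unit_code)
        return None
    years = v * factor
    if years < 0 or years > 120:
        return None
    return years


def compute_onset(case: CohortCase, drug: str) -> OnsetRecord | OnsetExclusion:
    """Time to onset for one case, or an exclusion with a reason code.

    Uses the earliest full-precision start date across the suspect drug's
    therapy episodes and the case's event onset date.
    """
    starts = [
        t.start_dt
        for t in case.therapies
        if t.drug_seq in case.ps_drug_seqs and t.start_dt is not None
    ]
    if not case.ps_drug_seqs or not any(
        t.drug_seq in case.ps_drug_seqs for t in case.therapies
    ):
        return OnsetExclusion(case.caseid, drug, "no_therapy")
    full_starts = [s for s in starts if date_precision(s) == "day"]
    if case.event_dt is None or not starts:
        return OnsetExclusion(case.caseid, drug, "missing_date")
    if date_precision(case.event_dt) != "day" or not full_starts:
        return OnsetExclusion(case.caseid, drug, "partial_date")
    start = min(full_starts)
    days = (to_date(case.event_dt) - to_date(start)).days
    if days < 0:
        return OnsetExclusion(case.caseid, drug, "negative")
    return OnsetRecord(case.caseid, drug, days / DAYS_PER_YEAR)


def collect_onsets(
    cohort: Sequence[CohortCase], drugs: Iterable[str]
) -> tuple[list[OnsetRecord], list[OnsetExclusion]]:
    """Onset records for every (exposed case, drug) candidate pair."""
    records: list[OnsetRecord] = []
    exclusions: list[OnsetExclusion] = []
    for drug in drugs:
        for case in cohort:
            if not case.exposed_to(drug):
                continue
            out = compute_onset(case, drug)
            if isinstance(out, OnsetRecord):
                records.append(out)
            else:
                exclusions.append(out)
    return records, exclusions


def summarize_onset(
    records: Sequence[OnsetRecord], min_n: int = 4
) -> pd.DataFrame:
    """Median, IQR and mean onset years per drug (type-7 quantiles).

    Drugs with fewer than ``min_n`` records are flagged ``low_n`` but
    still summarized; empty groups are simply absent.
    """
    if not records:
        log.warning("no onset records to summarize")
        return pd.DataFrame(
            columns=["drug", "n", "median", "q1", "q3", "mean", "low_n"]
        )
    rows = []
    by_drug: dict[str, list[float]] = {}
    for r in records:
        by_drug.setdefault(r.drug, []).append(r.onset_years)
    for drug in sorted(by_drug):
        vals = np.asarray(by_drug[drug], dtype=float)
        q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])  # linear interp
        rows.append(
            {
                "drug": drug,
                "n": len(vals),
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "mean": float(vals.mean()),
                "low_n": len(vals) < min_n,
            }
        )
    return pd.DataFrame(rows)


def percent_share(count: int, total: int) -> float:
    """100*count/total, rounded half-up to two decimals (19.795 -> 19.80)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    pct = Decimal(count) * 100 / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class DescriptiveSummary:
    """Tabulations of the cohort's exposed reports.

    ``per_drug``/``per_class`` shares use the DMARD-suspect report total as
    denominator.  Outcome percentages are given against both the report
    total and the outcome-entry total (a case may carry several outcome
    codes, so the two denominators differ and both are surfaced).
    """

    n_reports: int
    per_drug: pd.DataFrame
    per_class: pd.DataFrame
    sex: pd.DataFrame
    age: pd.DataFrame
    country: pd.DataFrame
    outcomes: pd.DataFrame


def summarize_descriptives(
    cohort: Sequence[CohortCase], drugs: Optional[Sequence[str]] = None
) -> DescriptiveSummary:
    """Descriptive tables over the DMARD-suspect cases of the cohort."""
    exposed = [c for c in cohort if c.ps_ingredients]
    n_total = len(exposed)

    drug_counts: dict[str, int] = {}
    class_counts: dict[str, int] = {}
    for c in exposed:
        # a multi-PS case contributes to each mapped ingredient
        for ing, cls in zip(c.ps_ingredients, c.ps_classes):
            drug_counts[ing] = drug_counts.get(ing, 0) + 1
            class_counts[cls] = class_counts.get(cls, 0) + 1
    if drugs:
        for d in drugs:  # surface zero-count drugs explicitly
            drug_counts.setdefault(d, 0)

    def share_frame(counts: dict[str, int], key: str) -> pd.DataFrame:
        rows = [
            {key: k, "n": v, "percent": percent_share(v, n_total) if n_total else 0.0}
            for k, v in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ]
        return pd.DataFrame(rows, columns=[key, "n", "percent"])

    per_drug = share_frame(drug_counts, "drug")
    per_class = share_frame(class_counts, "class")

    sex_counts: dict[str, int] = {"F": 0, "M": 0, "UNK": 0}
    ages_by_drug: dict[str, list[float]] = {}
    country_counts: dict[str, int] = {}
    outcome_counts: dict[str, int] = {}
    n_outcome_entries = 0
    for c in exposed:
        sex_counts[c.sex if c.sex in ("F", "M") else "UNK"] += 1
        age = normalize_age(c.age_value, c.age_unit)
        if age is not None:
            for ing in c.ps_ingredients:
                ages_by_drug.setdefault(ing, []).append(age)
            ages_by_drug.setdefault("__all__", []).append(age)
        key = c.country or "UNKNOWN"
        country_counts[key] = country_counts.get(key, 0) + 1
        for oc in c.outcomes:
            outcome_counts[oc] = outcome_counts.get(oc, 0) + 1
            n_outcome_entries += 1

    sex = pd.DataFrame(
        [
            {"sex": k, "n": v, "percent": percent_share(v, n_total) if n_total else 0.0}
            for k, v in sex_counts.items()
        ]
    )
    age_rows = []
    for drug in sorted(ages_by_drug):
        vals = np.asarray(ages_by_drug[drug])
        q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
        age_rows.append(
            {
                "drug": "all" if drug == "__all__" else drug,
                "n": len(vals),
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
            }
        )
    age = pd.DataFrame(age_rows, columns=["drug", "n", "median", "q1", "q3"])
    country = pd.DataFrame(
        [
            {
                "country": k,
                "n": v,
                "percent": percent_share(v, n_total) if n_total else 0.0,
            }
            for k, v in sorted(
                country_counts.items(), key=lambda kv: (-kv[1], kv[0])
            )
        ],
        columns=["country", "n", "percent"],
    )
    outcomes = pd.DataFrame(
        [
            {
                "outcome": k,
                "n": v,
                "percent_of_reports": percent_share(v, n_total)
                if n_total
                else 0.0,
                "percent_of_entries": percent_share(v, n_outcome_entries)
                if n_outcome_entries
                else 0.0,
            }
            for k, v in sorted(
                outcome_counts.items(), key=lambda kv: (-kv[1], kv[0])
            )
        ],
        columns=["outcome", "n", "percent_of_reports", "percent_of_entries"],
    )
    return DescriptiveSummary(
        n_reports=n_total,
        per_drug=per_drug,
        per_class=per_class,
        sex=sex,
        age=age,
        country=country,
        outcomes=outcomes,
    )
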