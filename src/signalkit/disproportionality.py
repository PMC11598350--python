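"""Reporting odds ratio and information component screening.

For a drug-event pair the cohort splits into a 2x2 table

    ==============  ======  =========
    .               event   no event
    index drug        a        b
    other reports     c        d
    ==============  ======  =========

and two disproportionality statistics are computed:

* ROR = (a d)/(b c) with the ln-scale Wald 95% interval
  exp(ln ROR ± 1.96 sqrt(1/a + 1/b + 1/c + 1/d)); undefined (NaN) when any
  cell is zero — no continuity correction is applied, since the three-part
  signal rule below makes corrected small-cell estimates irrelevant.
* IC = log2((a + 0.5)/(E + 0.5)) with expected count E = (a+b)(a+c)/N, the
  shrinkage observed/expected measure of the Bayesian confidence
  propagation tradition; its lower credibility bound uses the Norén
  approximation IC025 = IC − 3.3 (a+0.5)^−1/2 − 2 (a+0.5)^−3/2.

A pair is a signal when n >= 3 reports, ROR025 > 1 and IC025 > 0 (strict).
"""

from __future__ import annotations

import logging
import math
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .types import CohortCase, ContingencyTable, SignalResult

log = logging.getLogger(__name__)

Z95 = 1.96  # normal quantile for two-sided 95% intervals

ICFunc = Callable[[ContingencyTable], tuple[float, float]]


def build_table(
    cohort: Sequence[CohortCase], drug: str, event: str
) -> ContingencyTable:
    """Count the 2x2 cells for one drug-event pair at report level.

    A case counts once in ``a`` however many times the PT repeats in it.
    An absent drug or event yields a valid table with the corresponding
    margin zero.
    """
    a = b = c = d = 0
    for case in cohort:
        x = case.exposed_to(drug)
        e = event in case.reaction_pts
        if x and e:
            a += 1
        elif x:
            b += 1
        elif e:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def compute_ror(t: ContingencyTable) -> tuple[float, float, float]:
    """(ROR, ROR025, ROR975); all NaN when any cell is zero."""
    if min(t.a, t.b, t.c, t.d) == 0:
        return (math.nan, math.nan, math.nan)
    ror = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    half = Z95 * se
    lnr = math.log(ror)
    return (ror, math.exp(lnr - half), math.exp(lnr + half))


def compute_ic(t: ContingencyTable) -> tuple[float, float]:
    """(IC, IC025) in bits; defined for every table thanks to shrinkage."""
    e = t.drug_total * t.event_total / t.n
    shrunk = t.a + 0.5
    ic = math.log2(shrunk / (e + 0.5))
    ic025 = ic - 3.3 * shrunk ** -0.5 - 2.0 * shrunk ** -1.5
    return (ic, ic025)


def classify_signal(n: int, ror025: float, ic025: float) -> bool:
    """The three-condition signal rule; NaN bounds never signal."""
    if math.isnan(ror025) or math.isnan(ic025):
        return False
    return n >= 3 and ror025 > 1.0 and ic025 > 0.0


def evaluate_pair(
    drug: str,
    event: str,
    table: ContingencyTable,
    level: str = "PT",
    drug_class: str = "",
    ic_method: ICFunc = compute_ic,
) -> SignalResult:
    """Assemble the full statistic set for one drug-event table."""
    ror, lo, hi = compute_ror(table)
    ic, ic025 = ic_method(table)
    return SignalResult(
        drug=drug,
        event_term=event,
        level=level,
        n_reports=table.a,
        ror=ror,
        ror025=lo,
        ror975=hi,
        ic=ic,
        ic025=ic025,
        is_signal=classify_signal(table.a, lo, ic025),
        drug_class=drug_class,
        table=table,
    )


def _event_masks_from_pts(
    cohort: Sequence[CohortCase], events: Iterable[str]
) -> dict[str, np.ndarray]:
    events = list(events)
    wanted = set(events)
    masks = {e: np.zeros(len(cohort), dtype=bool) for e in events}
    for i, case in enumerate(cohort):
        for pt in case.reaction_pts:
            if pt in wanted:
                masks[pt][i] = True
    return masks


def _exposure_masks(
    cohort: Sequence[CohortCase], drugs: Iterable[str]
) -> dict[str, np.ndarray]:
    drugs = list(drugs)
    wanted = set(drugs)
    masks = {d: np.zeros(len(cohort), dtype=bool) for d in drugs}
    for i, case in enumerate(cohort):
        for ing in case.ps_ingredients:
            if ing in wanted:
                masks[ing][i] = True
    return masks


def screen_masks(
    exposure: dict[str, np.ndarray],
    events: dict[str, np.ndarray],
    n_total: int,
    level: str,
    drug_classes: Optional[dict[str, str]] = None,
    min_a: int = 1,
    ic_method: ICFunc = compute_ic,
) -> list[SignalResult]:
    """Vectorized screen over precomputed boolean exposure/event masks."""
    results: list[SignalResult] = []
    for drug in sorted(exposure):
        x = exposure[drug]
        nx = int(x.sum())
        for event in sorted(events):
            e = events[event]
            a = int(np.count_nonzero(x & e))
            if a < min_a:
                continue
            ne = int(e.sum())
            t = ContingencyTable(a, nx - a, ne - a, n_total - nx - ne + a)
            results.append(
                evaluate_pair(
                    drug,
                    event,
                    t,
                    level=level,
                    drug_class=(drug_classes or {}).get(drug, ""),
                    ic_method=ic_method,
                )
            )
    return results


def screen_all(
    cohort: Sequence[CohortCase],
    drugs: Iterable[str],
    events: Iterable[str],
    drug_classes: Optional[dict[str, str]] = None,
    min_a: int = 1,
    ic_method: ICFunc = compute_ic,
) -> list[SignalResult]:
    """Screen every drug-event pair at PT level.

    ``events`` is the PT universe of interest (for a malignancy screen,
    the PTs under the neoplasms SOC, supplied by the caller).  Pairs with
    fewer than ``min_a`` co-reports are omitted; output is ordered by
    (drug, event) and deterministic.
    """
    events = list(events)
    if not events:
        log.warning("empty event universe: nothing to screen")
        return []
    drugs = list(drugs)
    if not drugs:
        return []
    return screen_masks(
        _exposure_masks(cohort, drugs),
        _event_masks_from_pts(cohort, events),
        len(cohort),
        "PT",
        drug_classes=drug_classes,
        min_a=min_a,
        ic_method=ic_method,
    )


def results_to_frame(results: Sequence[SignalResult]):
    """Signal results as the canonical delimited output table."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "drug": r.drug,
                "class": r.drug_class,
                "event": r.event_term,
                "level": r.level,
                "a": r.n_reports,
                "b": r.table.b if r.table else None,
                "c": r.table.c if r.table else None,
                "d": r.table.d if r.table else None,
                "ror": r.ror,
                "ror025": r.ror025,
                "ror975": r.ror975,
                "ic": r.ic,
                "ic025": r.ic025,
                "signal": r.is_signal,
            }
            for r in results
        ]
    )
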