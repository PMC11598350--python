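"""2x2 construction, ROR/IC formulas and the signal rule."""

from __future__ import annotations

import math

import numpy as np
import pytest

from signalkit.disproportionality import (
    build_table,
    classify_signal,
    compute_ic,
    compute_ror,
    evaluate_pair,
    results_to_frame,
    screen_all,
)
from signalkit.types import CohortCase, ContingencyTable


def oracle_stats(a: int, b: int, c: int, d: int) -> dict[str, float]:
    """Independent term-by-term evaluation of ROR, its Wald interval,
    IC and IC025 — written from the formulas, not the implementation."""
    n = a + b + c + d
    out: dict[str, float] = {}
    odds_exposed = a / b
    odds_background = c / d
    out["ror"] = odds_exposed / odds_background
    se = (1 / a + 1 / b + 1 / c + 1 / d) ** 0.5
    out["ror025"] = math.exp(math.log(out["ror"]) - 1.96 * se)
    out["ror975"] = math.exp(math.log(out["ror"]) + 1.96 * se)
    expected = (a + b) * (a + c) / n
    out["ic"] = math.log((a + 0.5) / (expected + 0.5), 2)
    out["ic025"] = (
        out["ic"] - 3.3 * (a + 0.5) ** (-1 / 2) - 2 * (a + 0.5) ** (-3 / 2)
    )
    return out


class TestBuildTable:
    def test_toy_cohort_counts(self, toy_cohort):
        t = build_table(toy_cohort, "drugx", "e")
        assert (t.a, t.b, t.c, t.d) == (2, 1, 4, 3)
        assert t.n == len(toy_cohort)

    def test_absent_event_gives_zero_margin(self, toy_cohort):
        t = build_table(toy_cohort, "drugx", "nonexistent-pt")
        assert (t.a, t.c) == (0, 0)
        assert t.n == len(toy_cohort)

    def test_all_cases_drug_and_event(self):
        cohort = [
            CohortCase("c", ("x",), ("bDMARD",), ("e",)) for _ in range(4)
        ]
        t = build_table(cohort, "x", "e")
        assert (t.a, t.b, t.c, t.d) == (4, 0, 0, 0)

    def test_repeated_pt_counts_once(self):
        cohort = [CohortCase("c", ("x",), ("bDMARD",), ("e", "e2", "e"))]
        t = build_table(cohort, "x", "e")
        assert t.a == 1


class TestRorIc:
    def test_frozen_ror_example(self):
        ror, lo, hi = compute_ror(ContingencyTable(5, 10, 20, 100))
        assert ror == pytest.approx(2.5)
        assert lo == pytest.approx(0.7712757876659116, rel=1e-12)
        assert hi == pytest.approx(8.103456765982742, rel=1e-12)

    def test_symmetric_table_has_unit_ror(self):
        ror, lo, hi = compute_ror(ContingencyTable(25, 25, 25, 25))
        assert ror == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_zero_cell_undefined_and_never_signal(self):
        ror, lo, hi = compute_ror(ContingencyTable(0, 10, 20, 100))
        assert math.isnan(ror) and math.isnan(lo) and math.isnan(hi)
        assert classify_signal(0, lo, 1.0) is False
        r = evaluate_pair("d", "e", ContingencyTable(5, 0, 20, 100))
        assert not r.is_signal and math.isnan(r.ror)

    def test_frozen_ic_example(self):
        # a=5, drug total 100, event total 50, N=10000 -> E=0.5
        ic, ic025 = compute_ic(ContingencyTable(5, 95, 45, 9855))
        assert ic == pytest.approx(math.log2(5.5 / 1.0), rel=1e-12)
        assert ic == pytest.approx(2.4594316186372973, rel=1e-12)
        assert ic025 == pytest.approx(0.8972518242498244, rel=1e-12)

    def test_ic_zero_when_observed_equals_expected(self):
        # a=5 with E=5: margins 50x100 over N=1000
        t = ContingencyTable(5, 45, 95, 855)
        ic, _ = compute_ic(t)
        assert ic == pytest.approx(0.0, abs=1e-12)

    def test_ic_defined_and_negative_lower_bound_at_zero_observed(self):
        t = ContingencyTable(0, 10, 0, 100)
        ic, ic025 = compute_ic(t)
        assert ic == pytest.approx(0.0, abs=1e-12)  # E=0 -> log2(0.5/0.5)
        assert ic025 == pytest.approx(-3.3 / math.sqrt(0.5) - 2 / 0.5**1.5)
        assert ic025 < 0

    def test_oracle_equivalence_on_random_tables(self):
        rng = np.random.default_rng(20240901)
        for _ in range(1000):
            a, b, c, d = (int(x) for x in rng.integers(1, 501, 4))
            t = ContingencyTable(a, b, c, d)
            ref = oracle_stats(a, b, c, d)
            ror, lo, hi = compute_ror(t)
            ic, ic025 = compute_ic(t)
            assert ror == pytest.approx(ref["ror"], rel=1e-10)
            assert lo == pytest.approx(ref["ror025"], rel=1e-10)
            assert hi == pytest.approx(ref["ror975"], rel=1e-10)
            assert ic == pytest.approx(ref["ic"], rel=1e-10, abs=1e-10)
            assert ic025 == pytest.approx(ref["ic025"], rel=1e-10, abs=1e-10)

    def test_ic025_strictly_below_ic(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 301, 4))
            if a + b + c + d == 0:
                continue
            ic, ic025 = compute_ic(ContingencyTable(a, b, c, d))
            assert ic025 < ic

    def test_monotonicity_in_a(self):
        # ror increases in a holding b,c,d; ic increases in a holding E
        prev_ror = 0.0
        for a in range(1, 30):
            ror, _, _ = compute_ror(ContingencyTable(a, 50, 50, 500))
            assert ror > prev_ror
            prev_ror = ror
        # fix E = 10 by keeping margins (a+b)=100, (a+c)=100, N=1000
        prev_ic = -math.inf
        for a in range(0, 100):
            t = ContingencyTable(a, 100 - a, 100 - a, 800 + a)
            assert t.drug_total * t.event_total / t.n == pytest.approx(10.0)
            ic, _ = compute_ic(t)
            assert ic > prev_ic
            prev_ic = ic

    def test_ror_scale_invariant_ic_not(self):
        t1 = ContingencyTable(5, 10, 20, 100)
        t5 = ContingencyTable(25, 50, 100, 500)
        assert compute_ror(t1)[0] == pytest.approx(compute_ror(t5)[0])
        assert compute_ic(t1)[0] != pytest.approx(compute_ic(t5)[0])


class TestClassifySignal:
    @pytest.mark.parametrize(
        "n, ror025, ic025, expected",
        [
            (3, 1.01, 0.01, True),
            (2, 5.0, 2.0, False),  # fewer than 3 reports
            (100, 0.99, 0.5, False),  # ROR bound not above 1
            (3, 1.0, 0.01, False),  # boundary: strictly greater required
            (3, 1.01, 0.0, False),
        ],
    )
    def test_three_condition_rule(self, n, ror025, ic025, expected):
        assert classify_signal(n, ror025, ic025) is expected

    def test_exhaustive_boundary_grid(self):
        for n in (2, 3):
            for ror025 in (0.99, 1.0, 1.01):
                for ic025 in (-0.01, 0.0, 0.01):
                    expected = n >= 3 and ror025 > 1 and ic025 > 0
                    assert classify_signal(n, ror025, ic025) is expected


class TestScreenAll:
    def test_injected_pair_is_unique_signal(self):
        # 200 cases; drug x strongly enriches event e
        cohort = []
        for i in range(40):
            pts = ("e", "f") if i < 20 else ("f",)
            cohort.append(CohortCase(f"x{i}", ("x",), ("bDMARD",), pts))
        for i in range(160):
            pts = ("e", "f") if i < 8 else ("f",)
            drug = ("y",) if i % 2 else ()
            cls = ("bDMARD",) if i % 2 else ()
            cohort.append(CohortCase(f"b{i}", drug, cls, pts))
        results = screen_all(cohort, ["x", "y"], ["e", "f"])
        signals = [r for r in results if r.is_signal]
        assert [(r.drug, r.event_term) for r in signals] == [("x", "e")]

    def test_empty_drugs_or_events_yield_empty(self, toy_cohort):
        assert screen_all(toy_cohort, [], ["e"]) == []
        assert screen_all(toy_cohort, ["drugx"], []) == []

    def test_deterministic_and_sorted(self, toy_cohort):
        r1 = screen_all(toy_cohort, ["drugy", "drugx"], ["other", "e"])
        r2 = screen_all(toy_cohort, ["drugx", "drugy"], ["e", "other"])
        assert [(r.drug, r.event_term) for r in r1] == [
            (r.drug, r.event_term) for r in r2
        ]
        assert [(r.drug, r.event_term) for r in r1] == sorted(
            (r.drug, r.event_term) for r in r1
        )

    def test_cells_sum_to_cohort_size(self, toy_cohort):
        for r in screen_all(toy_cohort, ["drugx", "drugy"], ["e", "other"]):
            assert r.table.n == len(toy_cohort)

    def test_results_frame_schema(self, toy_cohort):
        frame = results_to_frame(screen_all(toy_cohort, ["drugx"], ["e"]))
        assert list(frame.columns) == [
            "drug", "class", "event", "level", "a", "b", "c", "d",
            "ror", "ror025", "ror975", "ic", "ic025", "signal",
        ]
        assert frame.loc[0, ["a", "b", "c", "d"]].tolist() == [2, 1, 4, 3]
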