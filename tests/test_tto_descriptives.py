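"""Age normalization, time-to-onset and descriptive tabulations."""

from __future__ import annotations

import numpy as np
import pytest

from signalkit.tto_descriptives import (
    collect_onsets,
    compute_onset,
    normalize_age,
    percent_share,
    summarize_descriptives,
    summarize_onset,
)
from signalkit.types import CohortCase, OnsetExclusion, OnsetRecord, TherapyEpisode


class TestNormalizeAge:
    @pytest.mark.parametrize(
        "value, unit, expected",
        [
            (65, "YR", 65.0),
            (6.5, "DEC", 65.0),
            (780, "MON", 65.0),
            (365.25, "DY", 1.0),
            (52.1786, "WK", 1.0),
            (8766, "HR", 1.0),
        ],
    )
    def test_unit_conversion(self, value, unit, expected):
        assert normalize_age(value, unit) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "value, unit",
        [(150, "YR"), (-5, "YR"), (None, "YR"), (65, None), (65, "LIGHTYEARS"), (65, "UNK")],
    )
    def test_implausible_or_unknown_flagged_missing(self, value, unit):
        assert normalize_age(value, unit) is None


def _case(caseid, event_dt, starts, drug="adalimumab"):
    return CohortCase(
        caseid=caseid,
        ps_ingredients=(drug,),
        ps_classes=("bDMARD",),
        reaction_pts=("Breast cancer",),
        event_dt=event_dt,
        ps_drug_seqs=(1,),
        therapies=tuple(TherapyEpisode(1, s) for s in starts),
    )


class TestComputeOnset:
    def test_calendar_arithmetic(self):
        rec = compute_onset(_case("1", 20200701, [20200101]), "adalimumab")
        assert isinstance(rec, OnsetRecord)
        assert rec.onset_years == pytest.approx(182 / 365.25, rel=1e-9)

    def test_event_before_start_excluded(self):
        out = compute_onset(_case("1", 20190101, [20200101]), "adalimumab")
        assert isinstance(out, OnsetExclusion)
        assert out.reason == "negative"

    def test_earliest_start_used(self):
        rec = compute_onset(
            _case("1", 20210601, [20210101, 20190101]), "adalimumab"
        )
        assert rec.onset_years == pytest.approx(
            (2 * 365 + 151 + 1) / 365.25, rel=1e-3
        )

    def test_missing_dates_excluded_with_reason(self):
        assert compute_onset(_case("1", None, [20200101]), "a").reason == "missing_date"
        assert compute_onset(_case("1", 20200701, [None]), "a").reason == "missing_date"

    def test_partial_dates_excluded(self):
        assert compute_onset(_case("1", 202007, [20200101]), "a").reason == "partial_date"
        assert compute_onset(_case("1", 20200701, [202001]), "a").reason == "partial_date"

    def test_no_therapy_rows_excluded(self):
        case = CohortCase(
            "1", ("adalimumab",), ("bDMARD",), ("Breast cancer",),
            event_dt=20200701, ps_drug_seqs=(1,), therapies=(),
        )
        assert compute_onset(case, "adalimumab").reason == "no_therapy"

    def test_conservation_of_candidates(self):
        cohort = [
            _case("1", 20200701, [20200101]),
            _case("2", None, [20200101]),
            _case("3", 20190101, [20200101]),
        ]
        records, exclusions = collect_onsets(cohort, ["adalimumab"])
        assert len(records) + len(exclusions) == 3


class TestSummarizeOnset:
    def r(self, drug, years):
        return [OnsetRecord(str(i), drug, y) for i, y in enumerate(years)]

    def test_odd_median(self):
        out = summarize_onset(self.r("a", [0.5, 1.0, 2.0]))
        assert out.loc[0, "median"] == pytest.approx(1.0)

    def test_single_value_degenerate_iqr(self):
        out = summarize_onset(self.r("a", [3.0]))
        assert out.loc[0, "median"] == 3.0
        assert out.loc[0, "q1"] == out.loc[0, "q3"] == 3.0
        assert bool(out.loc[0, "low_n"])

    def test_even_n_interpolation(self):
        out = summarize_onset(self.r("a", [1, 2, 3, 4]))
        assert out.loc[0, "median"] == pytest.approx(2.5)
        assert out.loc[0, "q1"] == pytest.approx(1.75)  # type-7 linear

    def test_matches_sort_based_quantile_oracle(self):
        rng = np.random.default_rng(99)
        vals = rng.lognormal(0.5, 0.8, 101).tolist()
        out = summarize_onset(self.r("a", vals))
        s = sorted(vals)

        def type7(q):  # h = (n-1)q + 1 in 1-based terms
            h = (len(s) - 1) * q
            lo = int(np.floor(h))
            return s[lo] + (h - lo) * (s[min(lo + 1, len(s) - 1)] - s[lo])

        assert out.loc[0, "median"] == pytest.approx(type7(0.5), rel=1e-12)
        assert out.loc[0, "q1"] == pytest.approx(type7(0.25), rel=1e-12)
        assert out.loc[0, "q3"] == pytest.approx(type7(0.75), rel=1e-12)

    def test_empty_input_gives_empty_frame(self):
        assert summarize_onset([]).empty


class TestPercentShare:
    @pytest.mark.parametrize(
        "count, total, expected",
        [
            (3447, 17412, 19.80),
            (10274, 17412, 59.01),
            (3691, 17412, 21.20),
            (0, 17412, 0.00),
            (1, 800, 0.13),  # 0.125 rounds half-up to 0.13
        ],
    )
    def test_round_half_up(self, count, total, expected):
        assert percent_share(count, total) == expected

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError):
            percent_share(1, 0)


class TestDescriptives:
    @pytest.fixture
    def cohort(self):
        cohort = []
        for i in range(10):
            drug = "drugx" if i < 4 else "drugy"
            cls = "bDMARD" if i < 4 else "csDMARD"
            cohort.append(
                CohortCase(
                    str(i), (drug,), (cls,), ("Breast cancer",),
                    sex="F" if i < 6 else "M",
                    age_value=60.0 + i, age_unit="YR",
                    country="US" if i < 7 else "CA",
                    outcomes=("HO", "OT") if i == 0 else ("OT",),
                )
            )
        return cohort

    def test_drug_shares(self, cohort):
        desc = summarize_descriptives(cohort)
        share = dict(zip(desc.per_drug["drug"], desc.per_drug["percent"]))
        assert share == {"drugy": 60.00, "drugx": 40.00}
        assert desc.per_drug["percent"].sum() == pytest.approx(100.0, abs=0.05)

    def test_zero_count_drug_listed_when_requested(self, cohort):
        desc = summarize_descriptives(cohort, drugs=["drugx", "drugy", "drugz"])
        row = desc.per_drug[desc.per_drug["drug"] == "drugz"]
        assert row["n"].iloc[0] == 0

    def test_outcome_two_denominators(self, cohort):
        desc = summarize_descriptives(cohort)
        ot = desc.outcomes[desc.outcomes["outcome"] == "OT"].iloc[0]
        assert ot["n"] == 10
        assert ot["percent_of_reports"] == 100.00  # every report has OT
        assert ot["percent_of_entries"] == pytest.approx(
            percent_share(10, 11)
        )  # 11 outcome entries in total

    def test_all_sex_missing_shows_unk_only(self):
        cohort = [
            CohortCase(str(i), ("d",), ("bDMARD",), ("e",), sex="UNK")
            for i in range(5)
        ]
        desc = summarize_descriptives(cohort)
        counts = dict(zip(desc.sex["sex"], desc.sex["n"]))
        assert counts == {"F": 0, "M": 0, "UNK": 5}

    def test_age_median(self, cohort):
        desc = summarize_descriptives(cohort)
        overall = desc.age[desc.age["drug"] == "all"].iloc[0]
        assert overall["median"] == pytest.approx(64.5)
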