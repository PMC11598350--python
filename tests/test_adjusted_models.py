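"""Logistic-regression adjusted reporting odds ratios."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from signalkit.adjusted_models import (
    DegenerateOutcomeError,
    adjusted_screen,
    build_regression_dataset,
    crude_ror_from_dataset,
    fit_dataset,
    fit_logistic,
    fit_simulated,
    simulate_confounded_dataset,
)
from signalkit.cohort import default_dictionary
from signalkit.types import CohortCase


def _case(caseid, drug, pts, age=60.0, sex="F", conco=()):
    ing = (drug,) if drug else ()
    return CohortCase(
        caseid=caseid,
        ps_ingredients=ing,
        ps_classes=("bDMARD",) * len(ing),
        reaction_pts=pts,
        all_ingredients=frozenset(ing) | frozenset(conco),
        age_value=age,
        age_unit="YR",
        sex=sex,
    )


@pytest.fixture(scope="module")
def dictionary():
    return default_dictionary()


class TestBuildDataset:
    def test_outcome_counts(self, dictionary):
        cohort = [
            _case("1", "adalimumab", ("Breast cancer",)),
            _case("2", "adalimumab", ("Fatigue",)),
            _case("3", "methotrexate", ("Skin cancer",)),
            _case("4", "methotrexate", ("Nausea",)),
            _case("5", None, ("Breast cancer",)),  # non-DMARD PS: excluded
            _case("6", "tofacitinib", ("Breast cancer",)),
            _case("7", "tofacitinib", ("Rash",)),
            _case("8", "abatacept", ("Headache",)),
        ]
        ds = build_regression_dataset(
            cohort, "adalimumab", {"Breast cancer", "Skin cancer"}, dictionary
        )
        assert len(ds.frame) == 7  # case 5 not DMARD-suspect
        assert ds.frame["y"].sum() == 3
        assert ds.frame["x_drug"].sum() == 2

    def test_missing_age_handled_by_complete_case(self, dictionary):
        cohort = [
            _case("1", "adalimumab", ("Breast cancer",), age=None),
            _case("2", "adalimumab", ("Fatigue",)),
            _case("3", "methotrexate", ("Breast cancer",)),
        ]
        ds = build_regression_dataset(
            cohort, "adalimumab", {"Breast cancer"}, dictionary
        )
        assert ds.n_excluded_missing == 1
        assert len(ds.complete) == 2

    def test_degenerate_outcome_raises(self, dictionary):
        cohort = [
            _case("1", "adalimumab", ("Fatigue",)),
            _case("2", "methotrexate", ("Rash",)),
        ]
        with pytest.raises(DegenerateOutcomeError):
            build_regression_dataset(
                cohort, "adalimumab", {"Breast cancer"}, dictionary
            )


class TestFitLogistic:
    def test_collapsibility_exp_beta_equals_crude_or(self):
        # grouped 2x2 data: a=30,b=70,c=20,d=180 -> OR = 30*180/(70*20)
        rows = (
            [(1, 1)] * 30 + [(1, 0)] * 70 + [(0, 1)] * 20 + [(0, 0)] * 180
        )
        x = np.array([r[0] for r in rows], dtype=float)
        y = np.array([r[1] for r in rows], dtype=float)
        X = np.column_stack([np.ones_like(x), x])
        fit = fit_logistic(X, y, ["intercept", "x_drug"])
        assert fit.converged
        assert fit.adjusted_ror == pytest.approx(30 * 180 / (70 * 20), rel=1e-8)

    def test_matches_independent_mle_implementation(self):
        sm = pytest.importorskip("statsmodels.api")
        frame = simulate_confounded_dataset(4000, 2.0, seed=5)
        fit = fit_simulated(frame, adjusted=True)
        X = sm.add_constant(
            frame[["x_drug", "age_years", "sex", "conco_flag"]].to_numpy()
        )
        ref = sm.Logit(frame["y"].to_numpy(), X).fit(disp=0)
        assert fit.beta["x_drug"] == pytest.approx(ref.params[1], abs=1e-6)
        assert fit.se["x_drug"] == pytest.approx(ref.bse[1], rel=1e-4)

    def test_confounded_recovery_and_crude_bias(self):
        true_or = 2.5
        frame = simulate_confounded_dataset(20000, true_or, seed=11)
        adj = fit_simulated(frame, adjusted=True)
        crude = fit_simulated(frame, adjusted=False)
        assert adj.converged
        assert adj.adjusted_ror == pytest.approx(true_or, rel=0.10)
        # the confounder inflates the crude estimate well beyond truth
        assert crude.adjusted_ror > adj.adjusted_ror * 1.15

    def test_null_exposure_ci_covers_one(self):
        frame = simulate_confounded_dataset(20000, 1.0, seed=3, confounding=False)
        fit = fit_simulated(frame, adjusted=True)
        lo, hi = fit.ci95
        assert lo < 1.0 < hi
        assert fit.adjusted_ror == pytest.approx(1.0, abs=0.2)

    def test_separation_flagged(self):
        # perfectly separated data: y == x
        x = np.array([0.0] * 20 + [1.0] * 20)
        y = x.copy()
        X = np.column_stack([np.ones_like(x), x])
        fit = fit_logistic(X, y, ["intercept", "x_drug"])
        assert fit.separation
        assert not fit.converged

    def test_deterministic(self):
        frame = simulate_confounded_dataset(5000, 2.0, seed=9)
        f1 = fit_simulated(frame)
        f2 = fit_simulated(frame)
        assert f1.beta == f2.beta


class TestAdjustedScreen:
    def test_no_confounding_crude_close_to_adjusted(self, dictionary):
        rng = np.random.default_rng(21)
        cohort = []
        drugs = ["adalimumab", "methotrexate", "tofacitinib"]
        for i in range(3000):
            drug = drugs[i % 3]
            x = drug == "adalimumab"
            p = 0.25 if x else 0.10
            pts = ("Breast cancer",) if rng.random() < p else ("Fatigue",)
            cohort.append(
                _case(
                    str(i), drug, pts,
                    age=float(rng.normal(60, 10)),
                    sex="F" if rng.random() < 0.7 else "M",
                )
            )
        table = adjusted_screen(
            cohort, ["adalimumab"], {"Breast cancer"}, dictionary
        )
        row = table.iloc[0]
        assert row["converged"]
        assert row["adj_ror"] == pytest.approx(row["crude_ror"], rel=0.15)
        assert row["crude_lo"] < row["crude_ror"] < row["crude_hi"]
        assert row["adj_lo"] < row["adj_ror"] < row["adj_hi"]

    def test_zero_exposure_drug_row_has_na(self, dictionary):
        cohort = [
            _case("1", "methotrexate", ("Breast cancer",)),
            _case("2", "methotrexate", ("Fatigue",)),
            _case("3", "tofacitinib", ("Breast cancer",)),
        ]
        table = adjusted_screen(
            cohort, ["peficitinib"], {"Breast cancer"}, dictionary
        )
        row = table.iloc[0]
        assert row["n_exposed"] == 0
        assert math.isnan(row["adj_ror"])

    def test_rerun_identical(self, dictionary):
        cohort = [
            _case(str(i), "adalimumab" if i % 2 else "methotrexate",
                  ("Breast cancer",) if i % 3 == 0 else ("Rash",))
            for i in range(60)
        ]
        t1 = adjusted_screen(cohort, ["adalimumab"], {"Breast cancer"}, dictionary)
        t2 = adjusted_screen(cohort, ["adalimumab"], {"Breast cancer"}, dictionary)
        pd.testing.assert_frame_equal(t1, t2)
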