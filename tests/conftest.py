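"""Shared fixtures: hand-written quarterly tables and toy cohorts."""

from __future__ import annotations

from pathlib import Path

import pytest

from signalkit.types import CohortCase, TherapyEpisode


def write_table(path: Path, columns: list[str], rows: list[tuple]) -> Path:
    """Write a '$'-delimited quarterly table."""
    lines = ["$".join(columns)]
    lines += ["$".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def toy_quarter(tmp_path: Path) -> dict[str, Path]:
    """Three cases; case 100 has two versions, case 102 is deletable.

    Case 100 v2 (primaryid 10002) supersedes v1; its PS drug is HUMIRA for
    rheumatoid arthritis with a breast-cancer reaction.  Case 101 has PS
    METHOTREXATE (psoriasis indication).  Case 102 is a background case.
    """
    d = tmp_path / "quarter"
    d.mkdir()
    paths = {
        "demo": write_table(
            d / "DEMO.txt",
            ["primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod", "sex", "reporter_country"],
            [
                ("10001", "100", "20220101", "20211201", "65", "YR", "F", "US"),
                ("10002", "100", "20230301", "20211201", "65", "YR", "F", "US"),
                ("10101", "101", "20220615", "", "6.2", "DEC", "M", "CA"),
                ("10201", "102", "20221001", "20220815", "", "", "", "GB"),
            ],
        ),
        "drug": write_table(
            d / "DRUG.txt",
            ["primaryid", "drug_seq", "role_cod", "drugname"],
            [
                ("10001", "1", "PS", "HUMIRA"),
                ("10002", "1", "PS", "HUMIRA"),
                ("10002", "2", "C", "METHOTREXATE SODIUM 25MG"),
                ("10101", "1", "PS", "METHOTREXATE"),
                ("10201", "1", "PS", "PREDNISONE"),
            ],
        ),
        "reac": write_table(
            d / "REAC.txt",
            ["primaryid", "pt"],
            [
                ("10001", "Breast cancer"),
                ("10002", "Breast cancer"),
                ("10002", "Breast cancer"),  # repeated PT, must collapse
                ("10002", "Fatigue"),
                ("10101", "Skin cancer"),
                ("10201", "Nausea"),
            ],
        ),
        "indi": write_table(
            d / "INDI.txt",
            ["primaryid", "indi_drug_seq", "indi_pt"],
            [
                ("10001", "1", "Rheumatoid arthritis"),
                ("10002", "1", "Rheumatoid arthritis"),
                ("10101", "1", "Psoriasis"),
                ("10201", "1", "Rheumatoid arthritis"),
            ],
        ),
        "outc": write_table(
            d / "OUTC.txt",
            ["primaryid", "outc_cod"],
            [("10002", "HO"), ("10002", "OT"), ("10101", "DE"), ("10201", "OT")],
        ),
        "ther": write_table(
            d / "THER.txt",
            ["primaryid", "dsg_drug_seq", "start_dt", "end_dt"],
            [
                ("10002", "1", "20200101", ""),
                ("10101", "1", "202001", ""),  # partial start date
                ("10201", "1", "20220101", ""),
            ],
        ),
    }
    return paths


def make_case(
    caseid: str,
    drug: str | None,
    pts: tuple[str, ...],
    cls: str = "bDMARD",
    **kw,
) -> CohortCase:
    return CohortCase(
        caseid=caseid,
        ps_ingredients=(drug,) if drug else (),
        ps_classes=(cls,) if drug else (),
        reaction_pts=pts,
        **kw,
    )


@pytest.fixture
def toy_cohort() -> list[CohortCase]:
    """Ten hand-written cases: 3 exposed to drug X (2 with event e),
    4 background cases with e, 3 with neither -> a=2, b=1, c=4, d=3."""
    cases = [
        make_case("c1", "drugx", ("e", "other")),
        make_case("c2", "drugx", ("e",)),
        make_case("c3", "drugx", ("other",)),
        make_case("c4", None, ("e",)),
        make_case("c5", None, ("e", "other")),
        make_case("c6", "drugy", ("e",)),
        make_case("c7", "drugy", ("e",)),
        make_case("c8", None, ("other",)),
        make_case("c9", "drugy", ("other",)),
        make_case("c10", None, ("other",)),
    ]
    return cases
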