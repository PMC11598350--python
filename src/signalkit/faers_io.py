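"""Ingestion and deduplication of FAERS-style quarterly ASCII extracts.

A quarterly extract is a set of "$"-delimited tables sharing the PRIMARYID
key: DEMO (one row per report version), DRUG, REAC, INDI, OUTC, THER.
Because a case may be submitted repeatedly, every analysis first collapses
versions to one per CASEID using the FDA-recommended rule: keep the version
with the latest FDA_DT, breaking ties by the higher PRIMARYID, and drop
cases named in the quarterly deleted-case lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .types import (
    DrugEntry,
    RawReportVersion,
    ReportCase,
    TherapyEpisode,
    parse_date,
)

log = logging.getLogger(__name__)

FAERS_DELIMITER = "$"

#: mandatory columns per table (case-insensitive header match)
REQUIRED_COLUMNS: dict[str, tuple[str, ...]] = {
    "demo": ("primaryid", "caseid", "fda_dt"),
    "drug": ("primaryid", "drug_seq", "drugname", "role_cod"),
    "reac": ("primaryid", "pt"),
    "indi": ("primaryid", "indi_drug_seq", "indi_pt"),
    "outc": ("primaryid", "outc_cod"),
    "ther": ("primaryid", "dsg_drug_seq", "start_dt"),
}


class MissingColumnError(ValueError):
    """A mandatory column is absent from a quarterly table."""


@dataclass
class QuarterData:
    """Parsed tables of one (or several concatenated) FAERS quarters."""

    versions: list[RawReportVersion]
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    indi: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame
    read_log: dict[str, dict[str, int]] = field(default_factory=dict)


def read_table(
    path: str | Path,
    table: str,
    delimiter: str = FAERS_DELIMITER,
) -> pd.DataFrame:
    """Read one quarterly table, lower-casing headers and validating them.

    Raises :class:`MissingColumnError` naming the first absent mandatory
    column.  All fields are read as strings; blank fields become "".
    """
    df = pd.read_csv(
        path, sep=delimiter, dtype=str, keep_default_na=False, engine="c"
    )
    df.columns = [c.strip().lower() for c in df.columns]
    for col in REQUIRED_COLUMNS.get(table, ()):
        if col not in df.columns:
            raise MissingColumnError(
                f"{table.upper()} table {path} is missing mandatory column {col.upper()}"
            )
    return df


def read_deleted_caseids(paths: Iterable[str | Path]) -> set[str]:
    """Read deleted-case lists: one CASEID per line, optional header."""
    deleted: set[str] = set()
    for path in paths:
        for line in Path(path).read_text().splitlines():
            tok = line.strip().strip('"')
            if tok and tok.lower() != "caseid":
                deleted.add(tok)
    return deleted


def read_quarter(
    paths: Mapping[str, str | Path],
    delimiter: str = FAERS_DELIMITER,
    quarter_label: str = "",
) -> QuarterData:
    """Read the six tables of a quarterly extract.

    ``paths`` maps lower-case table names (demo, drug, reac, indi, outc,
    ther) to file locations; demo is mandatory, the rest default to empty.
    Returns parsed frames plus a per-table read log with ``rows_read`` and,
    for DEMO, ``missing_fda_dt`` counts.
    """
    if "demo" not in paths:
        raise ValueError("a DEMO table path is required")
    frames: dict[str, pd.DataFrame] = {}
    read_log: dict[str, dict[str, int]] = {}
    for table in ("demo", "drug", "reac", "indi", "outc", "ther"):
        if table in paths:
            df = read_table(paths[table], table, delimiter)
        else:
            df = pd.DataFrame(columns=list(REQUIRED_COLUMNS[table]))
        frames[table] = df
        read_log[table] = {"rows_read": len(df)}

    demo = frames["demo"]
    fda = [parse_date(x) for x in demo["fda_dt"]]
    versions = [
        RawReportVersion(
            primaryid=str(pid).strip(),
            caseid=str(cid).strip(),
            fda_dt=f,
            source_quarter=quarter_label,
        )
        for pid, cid, f in zip(demo["primaryid"], demo["caseid"], fda)
    ]
    n_missing = sum(1 for v in versions if v.fda_dt is None)
    read_log["demo"]["missing_fda_dt"] = n_missing
    if n_missing:
        log.info("%d DEMO rows with missing/unparseable FDA_DT", n_missing)
    return QuarterData(
        versions=versions,
        demo=demo,
        drug=frames["drug"],
        reac=frames["reac"],
        indi=frames["indi"],
        outc=frames["outc"],
        ther=frames["ther"],
        read_log=read_log,
    )


def merge_quarters(quarters: Sequence[QuarterData]) -> QuarterData:
    """Concatenate several quarterly extracts into one load."""
    return QuarterData(
        versions=[v for q in quarters for v in q.versions],
        demo=pd.concat([q.demo for q in quarters], ignore_index=True),
        drug=pd.concat([q.drug for q in quarters], ignore_index=True),
        reac=pd.concat([q.reac for q in quarters], ignore_index=True),
        indi=pd.concat([q.indi for q in quarters], ignore_index=True),
        outc=pd.concat([q.outc for q in quarters], ignore_index=True),
        ther=pd.concat([q.ther for q in quarters], ignore_index=True),
    )


def _primaryid_key(primaryid: str):
    # Numeric ordering when possible ("higher PRIMARYID" is ordinal),
    # lexicographic fallback; the (0, ...) / (1, ...) tag keeps the two
    # regimes mutually comparable.
    s = primaryid.strip()
    if s.isdigit():
        return (1, int(s), "")
    return (0, 0, s)


def deduplicate(
    versions: Iterable[RawReportVersion],
    deleted_caseids: Iterable[str] = (),
) -> dict[str, str]:
    """Collapse report versions to one survivor per case.

    The survivor maximizes (FDA_DT, PRIMARYID); a missing FDA_DT sorts
    below every dated version.  Cases listed in ``deleted_caseids`` are
    dropped entirely.  Returns {caseid: surviving primaryid}.
    """
    deleted = set(deleted_caseids)
    best: dict[str, tuple] = {}
    survivors: dict[str, str] = {}
    for v in versions:
        if v.caseid in deleted:
            continue
        key = (v.fda_dt is not None, v.fda_dt or 0, _primaryid_key(v.primaryid))
        if v.caseid not in best or key > best[v.caseid]:
            best[v.caseid] = key
            survivors[v.caseid] = v.primaryid
    return survivors


@dataclass
class AssemblyLog:
    """Row-accounting from :func:`assemble_cases`."""

    n_cases: int = 0
    n_non_analyzable: int = 0
    orphan_child_rows: int = 0
    superseded_child_rows: int = 0


def _group_indices(frame: pd.DataFrame, keep: set[str]) -> dict[str, list[int]]:
    """primaryid -> row indices, restricted to surviving primaryids."""
    out: dict[str, list[int]] = {}
    if frame.empty:
        return out
    for i, pid in enumerate(frame["primaryid"].astype(str).str.strip()):
        if pid in keep:
            out.setdefault(pid, []).append(i)
    return out


def _safe_int(s: str, default: int = 0) -> int:
    s = str(s).strip()
    if s.endswith(".0"):
        s = s[:-2]
    try:
        return int(s)
    except ValueError:
        return default


def assemble_cases(
    survivors: Mapping[str, str],
    demo: pd.DataFrame,
    drug: pd.DataFrame,
    reac: pd.DataFrame,
    indi: pd.DataFrame,
    outc: pd.DataFrame,
    ther: pd.DataFrame,
) -> tuple[list[ReportCase], AssemblyLog]:
    """Join child tables onto the surviving version of each case.

    Child rows carrying a primaryid with no survivor are counted
    (superseded versions vs true orphans are not distinguishable from the
    child row alone, so both are tallied and dropped).  Reaction PT lists
    are de-duplicated preserving first occurrence.
    """
    alog = AssemblyLog()
    keep = {str(p) for p in survivors.values()}
    pid_to_caseid = {str(p): c for c, p in survivors.items()}

    demo_idx = _group_indices(demo, keep)
    drug_idx = _group_indices(drug, keep)
    reac_idx = _group_indices(reac, keep)
    indi_idx = _group_indices(indi, keep)
    outc_idx = _group_indices(outc, keep)
    ther_idx = _group_indices(ther, keep)
    for frame, idx in (
        (drug, drug_idx),
        (reac, reac_idx),
        (indi, indi_idx),
        (outc, outc_idx),
        (ther, ther_idx),
    ):
        alog.superseded_child_rows += len(frame) - sum(
            len(v) for v in idx.values()
        )

    def col(frame: pd.DataFrame, name: str) -> list[str]:
        if name in frame.columns:
            return frame[name].astype(str).tolist()
        return [""] * len(frame)

    demo_sex = col(demo, "sex")
    demo_age = col(demo, "age")
    demo_age_cod = col(demo, "age_cod")
    demo_country = col(demo, "reporter_country")
    demo_occr = col(demo, "occr_country")
    demo_event = col(demo, "event_dt")
    drug_seq_c = col(drug, "drug_seq")
    drug_name_c = col(drug, "drugname")
    drug_role_c = col(drug, "role_cod")
    reac_pt_c = col(reac, "pt")
    indi_seq_c = col(indi, "indi_drug_seq")
    indi_pt_c = col(indi, "indi_pt")
    outc_cod_c = col(outc, "outc_cod")
    ther_seq_c = col(ther, "dsg_drug_seq")
    ther_start_c = col(ther, "start_dt")
    ther_end_c = col(ther, "end_dt")

    cases: list[ReportCase] = []
    for caseid, primaryid in survivors.items():
        pid = str(primaryid)
        rows = demo_idx.get(pid)
        if not rows:
            continue  # survivor without a DEMO row cannot happen from read_quarter
        r = rows[0]

        sex = demo_sex[r].strip().upper() or "UNK"
        if sex not in ("F", "M"):
            sex = "UNK"
        age_raw = demo_age[r].strip()
        try:
            age_value: Optional[float] = float(age_raw) if age_raw else None
        except ValueError:
            age_value = None
        age_unit = demo_age_cod[r].strip().upper() or "UNK"
        country = demo_country[r].strip() or demo_occr[r].strip()
        event_dt = parse_date(demo_event[r])

        drugs = [
            DrugEntry(
                drug_seq=_safe_int(drug_seq_c[i]),
                verbatim_name=drug_name_c[i].strip(),
                role_code=drug_role_c[i].strip().upper(),
            )
            for i in drug_idx.get(pid, ())
        ]
        reactions: list[str] = []
        seen: set[str] = set()
        for i in reac_idx.get(pid, ()):
            pt = reac_pt_c[i].strip()
            if pt and pt not in seen:
                seen.add(pt)
                reactions.append(pt)
        indications: dict[int, list[str]] = {}
        for i in indi_idx.get(pid, ()):
            seq = _safe_int(indi_seq_c[i])
            pt = indi_pt_c[i].strip()
            if pt:
                indications.setdefault(seq, []).append(pt)
        outcomes = [
            outc_cod_c[i].strip().upper()
            for i in outc_idx.get(pid, ())
            if outc_cod_c[i].strip()
        ]
        therapies = [
            TherapyEpisode(
                drug_seq=_safe_int(ther_seq_c[i]),
                start_dt=parse_date(ther_start_c[i]),
                end_dt=parse_date(ther_end_c[i]),
            )
            for i in ther_idx.get(pid, ())
        ]

        case = ReportCase(
            caseid=caseid,
            primaryid=pid,
            sex=sex,
            age_value=age_value,
            age_unit=age_unit,
            country=country,
            event_dt=event_dt,
            drugs=drugs,
            reactions=reactions,
            indications=indications,
            outcomes=outcomes,
            therapies=therapies,
        )
        cases.append(case)
        if not case.analyzable:
            alog.n_non_analyzable += 1
    alog.n_cases = len(cases)
    # orphans: child primaryids absent from the full survivor map
    del pid_to_caseid
    return cases, alog


def cases_to_frame(cases: Sequence[ReportCase]) -> pd.DataFrame:
    """Flatten cases to a one-row-per-case store; list fields are '|'-joined."""
    rows = []
    for c in cases:
        rows.append(
            {
                "caseid": c.caseid,
                "primaryid": c.primaryid,
                "sex": c.sex,
                "age_value": c.age_value,
                "age_unit": c.age_unit,
                "country": c.country,
                "event_dt": c.event_dt,
                "n_drugs": len(c.drugs),
                "ps_drugs": "|".join(
                    d.verbatim_name for d in c.drugs if d.role_code == "PS"
                ),
                "reactions": "|".join(c.reactions),
                "indications": "|".join(sorted(c.indication_pts())),
                "outcomes": "|".join(c.outcomes),
            }
        )
    return pd.DataFrame(rows)
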