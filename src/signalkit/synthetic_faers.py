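"""Generator of FAERS-like quarterly tables with known ground truth.

The generator emulates the structure the ingestion and screening stages
consume: "$"-delimited DEMO/DRUG/REAC/INDI/OUTC/THER tables plus a
deleted-case list, with duplicate report versions sharing a CASEID,
FAERS age-unit codes, role codes, indication PTs, outcome codes, therapy
start dates and field-level missingness.  Drug-event dependence is
injected on the odds scale: for a case whose primary-suspect drug is the
index drug, each event's odds are multiplied by the configured relative
reporting rate RR, which makes the reporting odds ratio the natural
estimand and lets recovered RORs be compared directly with the generating
RR.  Everything is a deterministic function of the seed: the same config
yields byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25

#: default primary-suspect marginal probabilities (fraction of ALL reports).
#: Shares among the DMARD reports mirror the relative reporting volumes
#: seen for these drugs in public spontaneous-report data; the three
#: ingredients with no spontaneous reports keep probability zero so
#: zero-count drugs are exercised end to end.
DEFAULT_DRUGS: tuple[tuple[str, str, float], ...] = (
    ("methotrexate", "csDMARD", 0.105),
    ("leflunomide", "csDMARD", 0.012),
    ("sulfasalazine", "csDMARD", 0.008),
    ("hydroxychloroquine", "csDMARD", 0.018),
    ("adalimumab", "bDMARD", 0.093),
    ("etanercept", "bDMARD", 0.054),
    ("infliximab", "bDMARD", 0.022),
    ("golimumab", "bDMARD", 0.018),
    ("certolizumab pegol", "bDMARD", 0.015),
    ("anakinra", "bDMARD", 0.004),
    ("tocilizumab", "bDMARD", 0.025),
    ("sarilumab", "bDMARD", 0.008),
    ("abatacept", "bDMARD", 0.056),
    ("rituximab", "bDMARD", 0.022),
    ("iguratimod", "tsDMARD", 0.0),
    ("upadacitinib", "tsDMARD", 0.035),
    ("baricitinib", "tsDMARD", 0.012),
    ("tofacitinib", "tsDMARD", 0.063),
    ("filgotinib", "tsDMARD", 0.0),
    ("peficitinib", "tsDMARD", 0.0),
)

#: non-DMARD primary suspects forming the comparator background
DEFAULT_BACKGROUND_PS: tuple[str, ...] = (
    "PREDNISONE",
    "IBUPROFEN",
    "OMEPRAZOLE",
    "PARACETAMOL",
    "NAPROXEN",
    "CELECOXIB",
    "FOLIC ACID",
    "GABAPENTIN",
)

#: neoplasm-area event PTs with background reporting probabilities
DEFAULT_EVENTS: tuple[tuple[str, float], ...] = (
    ("Breast cancer", 0.010),
    ("Breast cancer female", 0.004),
    ("Skin cancer", 0.008),
    ("Squamous cell carcinoma of skin", 0.006),
    ("Basal cell carcinoma", 0.007),
    ("Malignant melanoma", 0.005),
    ("Lymphoproliferative disorder", 0.004),
    ("Diffuse large B-cell lymphoma", 0.003),
    ("B-cell lymphoma", 0.003),
    ("Lung neoplasm malignant", 0.006),
    ("Non-small cell lung cancer", 0.003),
    ("Prostate cancer", 0.006),
    ("Colon cancer", 0.005),
    ("Renal cancer", 0.004),
    ("Bladder cancer", 0.003),
    ("Ovarian cancer", 0.003),
    ("Uterine leiomyoma", 0.004),
    ("Thyroid neoplasm", 0.003),
    ("Pancreatic carcinoma", 0.003),
    ("Leukaemia", 0.004),
    ("Acute myeloid leukaemia", 0.002),
    ("Myelodysplastic syndrome", 0.002),
    ("Neoplasm malignant", 0.005),
    ("Metastases to liver", 0.003),
    ("Gastric cancer", 0.003),
    ("Hepatic neoplasm malignant", 0.002),
    ("Oesophageal carcinoma", 0.002),
    ("Tongue neoplasm malignant stage unspecified", 0.002),
)

#: non-neoplasm filler PTs guaranteeing a non-empty reaction list
DEFAULT_FILLER_PTS: tuple[str, ...] = (
    "Arthralgia",
    "Drug ineffective",
    "Headache",
    "Nausea",
    "Fatigue",
    "Rash",
    "Pyrexia",
    "Diarrhoea",
)

DEFAULT_ASSOCIATIONS: Mapping[tuple[str, str], float] = {
    ("methotrexate", "Lymphoproliferative disorder"): 4.0,
    ("upadacitinib", "Squamous cell carcinoma of skin"): 5.0,
    ("baricitinib", "Breast cancer"): 3.0,
    ("adalimumab", "Uterine leiomyoma"): 3.0,
}

#: log-normal time-to-onset parameters per drug class (log-years)
DEFAULT_TTO_LOGNORMAL: Mapping[str, tuple[float, float]] = {
    "csDMARD": (math.log(5.0), 0.6),
    "bDMARD": (math.log(2.0), 0.7),
    "tsDMARD": (math.log(1.2), 0.7),
    "other": (math.log(2.0), 0.8),
}

_NON_RA_INDICATIONS = (
    "Psoriasis",
    "Psoriatic arthropathy",
    "Crohn's disease",
    "Ulcerative colitis",
    "Ankylosing spondylitis",
)

_COUNTRIES = ("US", "CA", "GB", "JP", "FR", "DE", "IT", "AU")
_COUNTRY_P = (0.45, 0.15, 0.09, 0.07, 0.06, 0.06, 0.05, 0.07)

_OUTCOMES = ("OT", "HO", "DE", "LT", "DS", "CA", "RI")
_OUTCOME_P = (0.55, 0.25, 0.06, 0.05, 0.04, 0.02, 0.03)

#: occasional verbatim-name decorations exercising dictionary normalization
_BRANDS: Mapping[str, str] = {
    "methotrexate": "TREXALL",
    "adalimumab": "HUMIRA",
    "etanercept": "ENBREL",
    "infliximab": "REMICADE",
    "golimumab": "SIMPONI",
    "certolizumab pegol": "CIMZIA",
    "anakinra": "KINERET",
    "tocilizumab": "ACTEMRA",
    "sarilumab": "KEVZARA",
    "abatacept": "ORENCIA",
    "rituximab": "RITUXAN",
    "upadacitinib": "RINVOQ",
    "baricitinib": "OLUMIANT",
    "tofacitinib": "XELJANZ",
    "leflunomide": "ARAVA",
    "sulfasalazine": "AZULFIDINE",
    "hydroxychloroquine": "PLAQUENIL",
}


@dataclass
class SynthConfig:
    """Knobs of the synthetic spontaneous-report generator.

    ``associations`` maps (ingredient, event PT) to the relative reporting
    rate RR multiplying the event's odds for exposed cases; absent pairs
    have RR = 1.  ``duplicate_rate`` is the fraction of cases emitted as
    multiple report versions, ``deleted_rate`` the fraction listed in the
    deleted-case file.  ``confounding`` adds age/sex effects on both
    DMARD exposure and event odds to exercise the adjusted-ROR stage.
    """

    seed: int = 0
    n_cases: int = 5_000
    drugs: tuple[tuple[str, str, float], ...] = DEFAULT_DRUGS
    background_ps: tuple[str, ...] = DEFAULT_BACKGROUND_PS
    events: tuple[tuple[str, float], ...] = DEFAULT_EVENTS
    filler_pts: tuple[str, ...] = DEFAULT_FILLER_PTS
    associations: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_ASSOCIATIONS)
    )
    ra_fraction: float = 0.70
    duplicate_rate: float = 0.10
    deleted_rate: float = 0.01
    age_missing_rate: float = 0.20
    sex_unknown_rate: float = 0.05
    event_dt_missing_rate: float = 0.30
    event_dt_partial_rate: float = 0.08
    ther_start_missing_rate: float = 0.25
    fda_dt_missing_rate: float = 0.01
    indication_missing_rate: float = 0.03
    conco_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "methotrexate": 0.18,
            "tofacitinib": 0.03,
            "leflunomide": 0.04,
            "sulfasalazine": 0.03,
            "hydroxychloroquine": 0.05,
        }
    )
    tto_lognormal: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TTO_LOGNORMAL)
    )
    confounding: bool = False
    quarter_label: str = "2023Q1"

    def validate(self) -> None:
        probs = [p for _, _, p in self.drugs] + [p for _, p in self.events]
        probs += [
            self.ra_fraction,
            self.duplicate_rate,
            self.deleted_rate,
            self.age_missing_rate,
            self.sex_unknown_rate,
            self.event_dt_missing_rate,
            self.event_dt_partial_rate,
            self.ther_start_missing_rate,
            self.fda_dt_missing_rate,
            self.indication_missing_rate,
        ]
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        if sum(p for _, _, p in self.drugs) > 1.0:
            raise ValueError("drug marginal probabilities sum above 1")
        for pair, rr in self.associations.items():
            if rr < 0:
                raise ValueError(f"negative RR for {pair}")

    @classmethod
    def from_json(cls, path: str | Path) -> "SynthConfig":
        raw = json.loads(Path(path).read_text())
        if "associations" in raw:
            raw["associations"] = {
                (k.split("||")[0], k.split("||")[1]): v
                for k, v in raw["associations"].items()
            }
        for key in ("drugs", "background_ps", "events", "filler_pts"):
            if key in raw:
                raw[key] = tuple(
                    tuple(x) if isinstance(x, list) else x for x in raw[key]
                )
        if "tto_lognormal" in raw:
            raw["tto_lognormal"] = {
                k: tuple(v) for k, v in raw["tto_lognormal"].items()
            }
        return cls(**raw)

    def to_json(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["associations"] = {
            f"{d}||{e}": rr for (d, e), rr in self.associations.items()
        }
        Path(path).write_text(json.dumps(raw, indent=1, default=list))


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    associations: dict[tuple[str, str], float]
    survivors: dict[str, str]  # caseid -> latest-version primaryid
    deleted_caseids: set[str]
    duplicate_caseids: set[str]
    onset_days: dict[str, int]  # caseid -> true onset (exposed cases)
    ps_ingredient: dict[str, str]  # caseid -> generating PS ingredient ("" none)
    expected_a: dict[tuple[str, str], float]  # expected exposed-event count


def _dates_to_str(days: np.ndarray, origin: str = "1970-01-01") -> np.ndarray:
    d = (
        np.datetime64(origin)
        + days.astype("timedelta64[D]")
    )
    return (
        pd.Series(d)
        .dt.strftime("%Y%m%d")
        .to_numpy(dtype=object)
    )


def generate(
    config: SynthConfig, outdir: str | Path
) -> tuple[dict[str, Path], GroundTruth]:
    """Write one synthetic quarterly extract; return file paths and truth."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    n = config.n_cases

    caseid = 10_000_000 + np.arange(n, dtype=np.int64)
    is_ra = rng.random(n) < config.ra_fraction

    # --- demographics -------------------------------------------------
    age_years = np.clip(rng.normal(62.0, 13.0, n), 18.0, 100.0)
    sex_u = rng.random(n)
    sex = np.where(sex_u < 0.68, "F", np.where(sex_u < 0.95, "M", ""))
    country = rng.choice(_COUNTRIES, size=n, p=_COUNTRY_P)

    # --- primary-suspect drug ----------------------------------------
    ingredients = [d for d, _, _ in config.drugs]
    classes = {d: c for d, c, _ in config.drugs}
    base_p = np.array([p for _, _, p in config.drugs])
    p_dmard = base_p.sum()
    if config.confounding:
        # older and female cases are modestly more likely DMARD-exposed
        tilt = 1.0 + 0.010 * (age_years - 62.0) + 0.15 * (sex == "F")
        p_case = np.clip(p_dmard * tilt, 0.0, 0.95)
    else:
        p_case = np.full(n, p_dmard)
    exposed = rng.random(n) < p_case
    rel = base_p / p_dmard if p_dmard > 0 else base_p
    drug_idx = np.where(
        exposed, rng.choice(len(ingredients), size=n, p=rel), -1
    )
    ps_name = np.where(
        exposed,
        np.array(ingredients, dtype=object)[drug_idx],
        rng.choice(np.array(config.background_ps, dtype=object), size=n),
    )

    # verbatim decoration: brand names and dose suffixes
    u = rng.random(n)
    verbatim = ps_name.astype(object).copy()
    for i in np.nonzero(exposed & (u < 0.15))[0]:
        verbatim[i] = _BRANDS.get(str(ps_name[i]), str(ps_name[i]).upper())
    suffix = rng.random(n) < 0.15
    verbatim = np.array(
        [
            (str(v).upper() + (" SODIUM 25MG" if s else ""))
            for v, s in zip(verbatim, suffix)
        ],
        dtype=object,
    )

    # --- events -------------------------------------------------------
    event_names = [e for e, _ in config.events]
    bg_p = np.array([p for _, p in config.events])
    odds = bg_p / (1.0 - bg_p)
    rr_matrix = np.ones((len(ingredients), len(event_names)))
    for (d, e), rr in config.associations.items():
        if d in ingredients and e in event_names:
            rr_matrix[ingredients.index(d), event_names.index(e)] = rr
    case_rr = np.ones((n, len(event_names)))
    mask = drug_idx >= 0
    case_rr[mask] = rr_matrix[drug_idx[mask]]
    if config.confounding:
        conf = np.exp(
            0.02 * (age_years - 62.0) + 0.2 * (sex == "F")
        )[:, None]
    else:
        conf = 1.0
    o = odds[None, :] * case_rr * conf
    p_event = o / (1.0 + o)
    event_draw = rng.random((n, len(event_names))) < p_event

    # fillers: one guaranteed, a second with probability 0.4
    filler1 = rng.choice(np.array(config.filler_pts, dtype=object), size=n)
    filler2 = rng.choice(np.array(config.filler_pts, dtype=object), size=n)
    has_f2 = rng.random(n) < 0.4

    # --- concomitant medications -------------------------------------
    conco_items = sorted(config.conco_probs.items())
    conco_masks = {
        w: rng.random(n) < q for w, q in conco_items
    }

    # --- therapy / onset dates ---------------------------------------
    start_day = rng.integers(14_610, 19_353, n)  # 2010-01-01 .. 2022-12-30
    cls_arr = np.array(
        [classes.get(str(d), "other") if e else "other" for d, e in zip(ps_name, exposed)],
        dtype=object,
    )
    mus = np.array(
        [config.tto_lognormal.get(str(c), DEFAULT_TTO_LOGNORMAL["other"])[0] for c in cls_arr]
    )
    sigmas = np.array(
        [config.tto_lognormal.get(str(c), DEFAULT_TTO_LOGNORMAL["other"])[1] for c in cls_arr]
    )
    onset_days = np.maximum(
        1, np.round(np.exp(rng.normal(mus, sigmas)) * DAYS_PER_YEAR).astype(np.int64)
    )
    event_day = start_day + onset_days
    lag = rng.integers(30, 300, n)
    fda_day = np.clip(event_day + lag, 17_898, 19_722)  # 2019-01-01..2023-12-31

    # --- outcomes -----------------------------------------------------
    outc1 = rng.choice(np.array(_OUTCOMES, dtype=object), size=n, p=_OUTCOME_P)
    outc2 = rng.choice(np.array(_OUTCOMES, dtype=object), size=n, p=_OUTCOME_P)
    has_o2 = rng.random(n) < 0.15

    # --- indications --------------------------------------------------
    indi_pt = np.where(
        is_ra,
        "Rheumatoid arthritis",
        rng.choice(np.array(_NON_RA_INDICATIONS, dtype=object), size=n),
    )
    indi_missing = rng.random(n) < config.indication_missing_rate

    # --- missingness draws -------------------------------------------
    age_missing = rng.random(n) < config.age_missing_rate
    agecod_u = rng.random(n)
    event_missing = rng.random(n) < config.event_dt_missing_rate
    event_partial = (~event_missing) & (
        rng.random(n) < config.event_dt_partial_rate
    )
    ther_missing = rng.random(n) < config.ther_start_missing_rate

    # --- duplicate versions ------------------------------------------
    dup = rng.random(n) < config.duplicate_rate
    extra = np.where(dup, 1 + (rng.random(n) < 0.3).astype(np.int64), 0)
    k = 1 + extra  # versions per case
    fda_missing = (~dup) & (rng.random(n) < config.fda_dt_missing_rate)
    same_fda = rng.random(n) < 0.2  # duplicate clusters sharing FDA_DT
    dup_lag = np.where(same_fda, 0, rng.integers(20, 150, n))

    deleted = rng.random(n) < config.deleted_rate

    # expand cases to versions
    total = int(k.sum())
    case_of_version = np.repeat(np.arange(n), k)
    vstart = np.cumsum(k) - k
    vidx = np.arange(total) - np.repeat(vstart, k)
    pid = caseid[case_of_version] * 100 + vidx + 1
    v_fda_day = fda_day[case_of_version] - dup_lag[case_of_version] * (
        k[case_of_version] - 1 - vidx
    )

    # --- age unit encoding -------------------------------------------
    age_val = np.empty(n, dtype=object)
    age_cod = np.empty(n, dtype=object)
    for i in range(n):
        if age_missing[i]:
            age_val[i], age_cod[i] = "", ""
        elif agecod_u[i] < 0.05:
            age_val[i] = f"{age_years[i] / 10.0:.2f}"
            age_cod[i] = "DEC"
        elif agecod_u[i] < 0.08:
            age_val[i] = str(int(round(age_years[i] * 12.0)))
            age_cod[i] = "MON"
        else:
            age_val[i] = str(int(round(age_years[i])))
            age_cod[i] = "YR"

    event_str = _dates_to_str(event_day)
    event_field = np.where(
        event_missing, "", np.where(event_partial, [s[:6] for s in event_str], event_str)
    ).astype(object)
    start_str = _dates_to_str(start_day)
    start_field = np.where(ther_missing, "", start_str).astype(object)

    # ---------------- DEMO ----------------
    fda_field = _dates_to_str(v_fda_day)
    fda_field[fda_missing[case_of_version]] = ""
    demo = pd.DataFrame(
        {
            "primaryid": pid.astype(str),
            "caseid": caseid[case_of_version].astype(str),
            "caseversion": (vidx + 1).astype(str),
            "fda_dt": fda_field,
            "event_dt": event_field[case_of_version],
            "age": age_val[case_of_version],
            "age_cod": age_cod[case_of_version],
            "sex": sex[case_of_version],
            "reporter_country": country[case_of_version],
        }
    )

    # ---------------- DRUG (per version: PS row + concomitant rows) ---
    drug_frames = [
        pd.DataFrame(
            {
                "primaryid": pid.astype(str),
                "caseid": caseid[case_of_version].astype(str),
                "drug_seq": "1",
                "role_cod": "PS",
                "drugname": verbatim[case_of_version],
            }
        )
    ]
    seq = 2
    for w, _q in conco_items:
        m = conco_masks[w][case_of_version]
        drug_frames.append(
            pd.DataFrame(
                {
                    "primaryid": pid[m].astype(str),
                    "caseid": caseid[case_of_version][m].astype(str),
                    "drug_seq": str(seq),
                    "role_cod": "C",
                    "drugname": w.upper(),
                }
            )
        )
        seq += 1
    drug_df = pd.concat(drug_frames, ignore_index=True)
    drug_df = drug_df.sort_values(
        ["primaryid", "drug_seq"], kind="stable"
    ).reset_index(drop=True)

    # ---------------- REAC ----------------
    ev_case, ev_j = np.nonzero(event_draw)
    reac_case = np.concatenate(
        [np.arange(n), np.nonzero(has_f2)[0], ev_case]
    )
    reac_pt = np.concatenate(
        [filler1, filler2[has_f2], np.array(event_names, dtype=object)[ev_j]]
    )
    rep = k[reac_case]
    r_case = np.repeat(reac_case, rep)
    r_pt = np.repeat(reac_pt, rep)
    rstart = np.cumsum(rep) - rep
    r_vidx = np.arange(int(rep.sum())) - np.repeat(rstart, rep)
    r_pid = caseid[r_case] * 100 + r_vidx + 1
    reac_df = (
        pd.DataFrame(
            {
                "primaryid": r_pid.astype(str),
                "caseid": caseid[r_case].astype(str),
                "pt": r_pt,
            }
        )
        .sort_values(["primaryid", "pt"], kind="stable")
        .reset_index(drop=True)
    )

    # ---------------- INDI ----------------
    ind_case = np.nonzero(~indi_missing)[0]
    rep = k[ind_case]
    i_case = np.repeat(ind_case, rep)
    istart = np.cumsum(rep) - rep
    i_vidx = np.arange(int(rep.sum())) - np.repeat(istart, rep)
    i_pid = caseid[i_case] * 100 + i_vidx + 1
    indi_df = pd.DataFrame(
        {
            "primaryid": i_pid.astype(str),
            "caseid": caseid[i_case].astype(str),
            "indi_drug_seq": "1",
            "indi_pt": indi_pt[i_case],
        }
    )

    # ---------------- OUTC ----------------
    o_case = np.concatenate([np.arange(n), np.nonzero(has_o2)[0]])
    o_cod = np.concatenate([outc1, outc2[has_o2]])
    rep = k[o_case]
    oo_case = np.repeat(o_case, rep)
    ostart = np.cumsum(rep) - rep
    o_vidx = np.arange(int(rep.sum())) - np.repeat(ostart, rep)
    o_pid = caseid[oo_case] * 100 + o_vidx + 1
    outc_df = (
        pd.DataFrame(
            {
                "primaryid": o_pid.astype(str),
                "caseid": caseid[oo_case].astype(str),
                "outc_cod": np.repeat(o_cod, rep),
            }
        )
        .sort_values(["primaryid", "outc_cod"], kind="stable")
        .reset_index(drop=True)
    )

    # ---------------- THER ----------------
    ther_df = pd.DataFrame(
        {
            "primaryid": pid.astype(str),
            "caseid": caseid[case_of_version].astype(str),
            "dsg_drug_seq": "1",
            "start_dt": start_field[case_of_version],
            "end_dt": "",
        }
    )

    paths: dict[str, Path] = {}
    for name, frame in (
        ("demo", demo),
        ("drug", drug_df),
        ("reac", reac_df),
        ("indi", indi_df),
        ("outc", outc_df),
        ("ther", ther_df),
    ):
        p = out / f"{name.upper()}{config.quarter_label}.txt"
        frame.to_csv(p, sep="$", index=False, lineterminator="\n")
        paths[name] = p

    deleted_ids = caseid[deleted].astype(str)
    del_path = out / f"DELETED{config.quarter_label}.txt"
    del_path.write_text("\n".join(deleted_ids.tolist()) + ("\n" if len(deleted_ids) else ""))
    paths["deleted"] = del_path

    # ---------------- ground truth ------------------------------------
    survivors = {
        str(c): str(c * 100 + kk) for c, kk in zip(caseid.tolist(), k.tolist())
    }
    keep = ~deleted
    eff = float(keep.sum()) / n
    expected_a: dict[tuple[str, str], float] = {}
    for di, d in enumerate(ingredients):
        pd_i = base_p[di]
        for ej, e in enumerate(event_names):
            oo = odds[ej] * rr_matrix[di, ej]
            expected_a[(d, e)] = (
                n
                * eff
                * config.ra_fraction
                * (1 - config.indication_missing_rate)
                * pd_i
                * (oo / (1 + oo))
            )
    truth = GroundTruth(
        associations={
            (d, e): float(rr_matrix[ingredients.index(d), event_names.index(e)])
            for d in ingredients
            for e in event_names
            if rr_matrix[ingredients.index(d), event_names.index(e)] != 1.0
        },
        survivors=survivors,
        deleted_caseids=set(deleted_ids.tolist()),
        duplicate_caseids=set(caseid[dup].astype(str).tolist()),
        onset_days={
            str(c): int(o)
            for c, o, e in zip(caseid.tolist(), onset_days.tolist(), exposed.tolist())
            if e
        },
        ps_ingredient={
            str(c): (str(d) if e else "")
            for c, d, e in zip(caseid.tolist(), ps_name.tolist(), exposed.tolist())
        },
        expected_a=expected_a,
    )
    return paths, truth


def recovery_benchmark_config(seed: int, n_cases: int = 200_000) -> SynthConfig:
    """Benchmark config for operating-characteristic checks.

    Three drug-event pairs carry RR = 5 against an otherwise-null
    drug x event grid (557 RR = 1 pairs), at a report volume where each
    injected pair expects well over 20 exposed-event reports, so signal
    sensitivity and the false-signal rate can both be measured.
    """
    return SynthConfig(
        seed=seed,
        n_cases=n_cases,
        associations={
            ("methotrexate", "Lymphoproliferative disorder"): 5.0,
            ("upadacitinib", "Squamous cell carcinoma of skin"): 5.0,
            ("baricitinib", "Breast cancer"): 5.0,
        },
    )


@dataclass
class RecoveryReport:
    """Pipeline-vs-truth comparison from :func:`roundtrip_check`."""

    n_injected_evaluable: int
    n_injected_flagged: int
    sensitivity: float
    n_null_pairs: int
    n_false_signals: int
    false_signal_rate: float
    ror_log_bias: float  # mean ln(ROR_hat / RR) over evaluable injected pairs
    dedup_resolution_rate: float
    cohort_size: int

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def roundtrip_check(
    config: SynthConfig,
    workdir: str | Path,
    min_expected_a: float = 20.0,
) -> RecoveryReport:
    """Generate data, run the full screen, and score recovery against truth."""
    from . import faers_io
    from .cohort import build_cohort, default_dictionary
    from .disproportionality import screen_all

    paths, truth = generate(config, workdir)
    quarter = faers_io.read_quarter(paths, quarter_label=config.quarter_label)
    deleted = faers_io.read_deleted_caseids([paths["deleted"]])
    survivors = faers_io.deduplicate(quarter.versions, deleted)

    expected_survivors = {
        c: p for c, p in truth.survivors.items() if c not in truth.deleted_caseids
    }
    n_match = sum(
        1 for c, p in expected_survivors.items() if survivors.get(c) == p
    )
    dedup_rate = n_match / max(1, len(expected_survivors))

    cases, _alog = faers_io.assemble_cases(
        survivors,
        quarter.demo,
        quarter.drug,
        quarter.reac,
        quarter.indi,
        quarter.outc,
        quarter.ther,
    )
    cohort = build_cohort(cases, default_dictionary())

    ingredients = [d for d, _, _ in config.drugs]
    event_names = [e for e, _ in config.events]
    results = screen_all(cohort, ingredients, event_names)
    by_pair = {(r.drug, r.event_term): r for r in results}

    injected = {
        pair: rr for pair, rr in config.associations.items() if rr != 1.0
    }
    evaluable = [
        pair
        for pair in injected
        if truth.expected_a.get(pair, 0.0) >= min_expected_a
    ]
    flagged = [
        pair
        for pair in evaluable
        if pair in by_pair and by_pair[pair].is_signal
    ]
    log_ratios = [
        math.log(by_pair[pair].ror / injected[pair])
        for pair in evaluable
        if pair in by_pair and by_pair[pair].ror_defined
    ]

    null_pairs = [
        (d, e)
        for d in ingredients
        for e in event_names
        if (d, e) not in injected
    ]
    false_signals = [
        p for p in null_pairs if p in by_pair and by_pair[p].is_signal
    ]
    return RecoveryReport(
        n_injected_evaluable=len(evaluable),
        n_injected_flagged=len(flagged),
        sensitivity=len(flagged) / len(evaluable) if evaluable else math.nan,
        n_null_pairs=len(null_pairs),
        n_false_signals=len(false_signals),
        false_signal_rate=len(false_signals) / len(null_pairs)
        if null_pairs
        else math.nan,
        ror_log_bias=float(np.mean(log_ratios)) if log_ratios else math.nan,
        dedup_resolution_rate=dedup_rate,
        cohort_size=len(cohort),
    )
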