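"""Indication restriction and suspect-drug mapping.

The analysis population is spontaneous reports filed for rheumatoid
arthritis.  Within it, each case is attributed to the canonical ingredient
of its primary-suspect (PS) drug via a verbatim-string dictionary; cases
whose PS drug is not a watched ingredient stay in the cohort as the
comparator background, which is what the reporting odds ratio is computed
against.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .types import CohortCase, ReportCase, DMARD_CLASSES

log = logging.getLogger(__name__)

DEFAULT_INDICATION_TERMS = frozenset({"Rheumatoid arthritis"})

#: the four frequently co-administered drugs used as regression confounders
DEFAULT_CONCOMITANT_WATCHLIST = (
    "methotrexate",
    "tofacitinib",
    "leflunomide",
    "sulfasalazine",
)

# (pattern, ingredient, class) — patterns are matched as substrings of the
# normalized verbatim drug name; the longest matching pattern wins.
_DEFAULT_DICTIONARY_ROWS: tuple[tuple[str, str, str], ...] = (
    # conventional synthetic
    ("methotrexate", "methotrexate", "csDMARD"),
    ("trexall", "methotrexate", "csDMARD"),
    ("rheumatrex", "methotrexate", "csDMARD"),
    ("otrexup", "methotrexate", "csDMARD"),
    ("rasuvo", "methotrexate", "csDMARD"),
    ("leflunomide", "leflunomide", "csDMARD"),
    ("arava", "leflunomide", "csDMARD"),
    ("sulfasalazine", "sulfasalazine", "csDMARD"),
    ("azulfidine", "sulfasalazine", "csDMARD"),
    ("salazopyrin", "sulfasalazine", "csDMARD"),
    ("hydroxychloroquine", "hydroxychloroquine", "csDMARD"),
    ("plaquenil", "hydroxychloroquine", "csDMARD"),
    # biologic
    ("adalimumab", "adalimumab", "bDMARD"),
    ("humira", "adalimumab", "bDMARD"),
    ("etanercept", "etanercept", "bDMARD"),
    ("enbrel", "etanercept", "bDMARD"),
    ("infliximab", "infliximab", "bDMARD"),
    ("remicade", "infliximab", "bDMARD"),
    ("golimumab", "golimumab", "bDMARD"),
    ("simponi", "golimumab", "bDMARD"),
    ("certolizumab pegol", "certolizumab pegol", "bDMARD"),
    ("certolizumab", "certolizumab pegol", "bDMARD"),
    ("cimzia", "certolizumab pegol", "bDMARD"),
    ("anakinra", "anakinra", "bDMARD"),
    ("kineret", "anakinra", "bDMARD"),
    ("tocilizumab", "tocilizumab", "bDMARD"),
    ("actemra", "tocilizumab", "bDMARD"),
    ("sarilumab", "sarilumab", "bDMARD"),
    ("kevzara", "sarilumab", "bDMARD"),
    ("abatacept", "abatacept", "bDMARD"),
    ("orencia", "abatacept", "bDMARD"),
    ("rituximab", "rituximab", "bDMARD"),
    ("rituxan", "rituximab", "bDMARD"),
    ("mabthera", "rituximab", "bDMARD"),
    # targeted synthetic (iguratimod classed with the targeted group here,
    # matching the analysis grouping this package reproduces)
    ("iguratimod", "iguratimod", "tsDMARD"),
    ("upadacitinib", "upadacitinib", "tsDMARD"),
    ("rinvoq", "upadacitinib", "tsDMARD"),
    ("baricitinib", "baricitinib", "tsDMARD"),
    ("olumiant", "baricitinib", "tsDMARD"),
    ("tofacitinib", "tofacitinib", "tsDMARD"),
    ("xeljanz", "tofacitinib", "tsDMARD"),
    ("filgotinib", "filgotinib", "tsDMARD"),
    ("jyseleca", "filgotinib", "tsDMARD"),
    ("peficitinib", "peficitinib", "tsDMARD"),
    ("smyraf", "peficitinib", "tsDMARD"),
)

# tokens dropped from verbatim names before matching: doses, salt and
# formulation descriptors
_DOSE_RE = re.compile(r"\b\d+(\.\d+)?\s*(mg|mcg|ug|g|ml|%)\b")
_NOISE_TOKENS = frozenset(
    {
        "sodium",
        "citrate",
        "hydrochloride",
        "hcl",
        "sulfate",
        "sulphate",
        "tablet",
        "tablets",
        "capsule",
        "capsules",
        "injection",
        "solution",
        "oral",
        "subcutaneous",
        "prefilled",
        "syringe",
        "pen",
    }
)


def normalize_verbatim(name: str) -> str:
    """Lower-case, strip dose/salt/formulation tokens, squeeze whitespace."""
    s = name.strip().casefold()
    s = _DOSE_RE.sub(" ", s)
    s = re.sub(r"[()\[\],;/\\]", " ", s)
    tokens = [t for t in s.split() if t not in _NOISE_TOKENS]
    return " ".join(tokens)


@dataclass
class DrugDictionary:
    """Verbatim-pattern -> (canonical ingredient, DMARD class) lookup.

    Matching is case-insensitive, deterministic and longest-pattern-first:
    among the patterns occurring as substrings of the normalized verbatim
    string, the longest wins (alphabetical tie-break).
    """

    rows: tuple[tuple[str, str, str], ...]
    _by_len: list[tuple[str, str, str]] = field(init=False, repr=False)
    _cache: dict[str, Optional[tuple[str, str]]] = field(
        init=False, repr=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        classes: dict[str, str] = {}
        norm_rows = []
        for pattern, ingredient, cls in self.rows:
            if cls not in DMARD_CLASSES:
                raise ValueError(f"unknown drug class {cls!r} for {ingredient!r}")
            if classes.setdefault(ingredient, cls) != cls:
                raise ValueError(f"ingredient {ingredient!r} mapped to two classes")
            norm_rows.append((normalize_verbatim(pattern), ingredient, cls))
        self._by_len = sorted(norm_rows, key=lambda r: (-len(r[0]), r[0]))

    @property
    def ingredients(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for _, ing, _cls in self.rows:
            seen.setdefault(ing)
        return tuple(seen)

    def class_of(self, ingredient: str) -> str:
        for _, ing, cls in self.rows:
            if ing == ingredient:
                return cls
        raise KeyError(ingredient)

    def match(self, verbatim: str) -> Optional[tuple[str, str]]:
        """Map a verbatim drug string to (ingredient, class), or None."""
        norm = normalize_verbatim(verbatim)
        if norm in self._cache:
            return self._cache[norm]
        hit: Optional[tuple[str, str]] = None
        for pattern, ingredient, cls in self._by_len:
            if pattern and pattern in norm:
                hit = (ingredient, cls)
                break
        self._cache[norm] = hit
        return hit


def default_dictionary() -> DrugDictionary:
    """The bundled dictionary: 20 DMARD ingredients with common brand names."""
    return DrugDictionary(_DEFAULT_DICTIONARY_ROWS)


def load_dictionary(path: str | Path, delimiter: str = ",") -> DrugDictionary:
    """Load a dictionary file with columns pattern, ingredient, class."""
    rows: list[tuple[str, str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        for i, row in enumerate(reader):
            if not row or row[0].strip().lower() == "pattern":
                continue
            if len(row) < 3:
                log.warning("dictionary row %d malformed, skipped: %r", i, row)
                continue
            rows.append((row[0].strip(), row[1].strip(), row[2].strip()))
    return DrugDictionary(tuple(rows))


def match_drug(
    verbatim: str, dictionary: DrugDictionary
) -> Optional[tuple[str, str]]:
    """Functional wrapper around :meth:`DrugDictionary.match`."""
    return dictionary.match(verbatim)


def build_cohort(
    cases: Iterable[ReportCase],
    dictionary: DrugDictionary,
    indication_terms: Iterable[str] = DEFAULT_INDICATION_TERMS,
    multi_ps: str = "all",
) -> list[CohortCase]:
    """Restrict cases to the target indication and attribute PS exposure.

    A case qualifies when ANY of its drugs carries an indication PT in
    ``indication_terms`` (compared case-insensitively).  Non-analyzable
    cases (no reactions) are dropped.  ``multi_ps`` controls cases whose
    several PS entries map to different ingredients: "all" lets the case
    contribute to each ingredient's exposed set, "first" keeps only the
    lowest drug-seq match.
    """
    terms = {t.strip().casefold() for t in indication_terms}
    cohort: list[CohortCase] = []
    for case in cases:
        if not case.analyzable:
            continue
        if not any(pt.strip().casefold() in terms for pt in case.indication_pts()):
            continue

        ps_ing: list[str] = []
        ps_cls: list[str] = []
        ps_seqs: list[int] = []
        all_ing: set[str] = set()
        for entry in sorted(case.drugs, key=lambda d: d.drug_seq):
            hit = dictionary.match(entry.verbatim_name)
            if hit is None:
                continue
            ingredient, cls = hit
            all_ing.add(ingredient)
            if entry.role_code == "PS" and ingredient not in ps_ing:
                ps_ing.append(ingredient)
                ps_cls.append(cls)
                ps_seqs.append(entry.drug_seq)
        if multi_ps == "first" and len(ps_ing) > 1:
            ps_ing, ps_cls, ps_seqs = ps_ing[:1], ps_cls[:1], ps_seqs[:1]
        # therapy episodes of any PS entry (matched or not) are retained so
        # time-to-onset can use the suspect drug's start dates
        ps_all_seqs = {d.drug_seq for d in case.drugs if d.role_code == "PS"}
        cohort.append(
            CohortCase(
                caseid=case.caseid,
                ps_ingredients=tuple(ps_ing),
                ps_classes=tuple(ps_cls),
                reaction_pts=tuple(case.reactions),
                all_ingredients=frozenset(all_ing),
                sex=case.sex,
                age_value=case.age_value,
                age_unit=case.age_unit,
                country=case.country,
                event_dt=case.event_dt,
                outcomes=tuple(case.outcomes),
                ps_drug_seqs=tuple(sorted(ps_all_seqs)),
                therapies=tuple(case.therapies),
            )
        )
    return cohort


def flag_concomitants(
    case: CohortCase, watchlist: Iterable[str]
) -> dict[str, bool]:
    """Per-watchlist-ingredient co-administration flags for one case.

    An ingredient counts as concomitant when present in the case in any
    entry other than the index (PS) exposure itself — self-exposure is not
    co-medication.
    """
    conco = case.concomitants_for(case.ps_ingredient)
    return {w: (w in conco) for w in watchlist}


def exposed_background_split(
    cohort: Sequence[CohortCase], ingredient: str
) -> tuple[list[CohortCase], list[CohortCase]]:
    """Partition the cohort into index-exposed cases and the background."""
    exposed = [c for c in cohort if c.exposed_to(ingredient)]
    background = [c for c in cohort if not c.exposed_to(ingredient)]
    return exposed, background
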