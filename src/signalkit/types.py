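"""Core record types shared across the pipeline.

The pipeline moves spontaneous safety reports through four representations:
raw per-version rows (:class:`RawReportVersion`), deduplicated case records
(:class:`ReportCase`), indication-restricted analysis cases
(:class:`CohortCase`), and per drug-event statistics
(:class:`ContingencyTable` / :class:`SignalResult`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})
SEX_CODES = frozenset({"F", "M", "UNK"})
AGE_UNIT_CODES = frozenset({"DEC", "YR", "MON", "WK", "DY", "HR", "UNK"})

DMARD_CLASSES = ("csDMARD", "bDMARD", "tsDMARD")


@dataclass(frozen=True, slots=True)
class RawReportVersion:
    """One version of a safety report (a DEMO row).

    A case (``caseid``) may be reported several times; each submission gets
    its own ``primaryid``.  ``fda_dt`` is the FDA receipt date as a YYYYMMDD
    integer, or ``None`` when blank/unparseable.
    """

    primaryid: str
    caseid: str
    fda_dt: Optional[int]
    source_quarter: str = ""


@dataclass(frozen=True, slots=True)
class DrugEntry:
    """A DRUG row: one drug mention within a report version."""

    drug_seq: int
    verbatim_name: str
    role_code: str  # PS / SS / C / I


@dataclass(frozen=True, slots=True)
class TherapyEpisode:
    """A THER row: start/end dates for one drug sequence, YYYYMMDD[MM|DD may be absent]."""

    drug_seq: int
    start_dt: Optional[int] = None
    end_dt: Optional[int] = None


@dataclass(slots=True)
class ReportCase:
    """A deduplicated safety report with all child tables joined in.

    ``indications`` maps a drug sequence number to the indication PTs
    reported for that drug.  ``reactions`` preserves first-occurrence order
    with duplicates removed.  A case with no reactions is kept but is not
    analyzable (``analyzable`` is False).
    """

    caseid: str
    primaryid: str
    sex: str = "UNK"
    age_value: Optional[float] = None
    age_unit: str = "UNK"
    country: str = ""
    event_dt: Optional[int] = None
    drugs: list[DrugEntry] = field(default_factory=list)
    reactions: list[str] = field(default_factory=list)
    indications: dict[int, list[str]] = field(default_factory=dict)
    outcomes: list[str] = field(default_factory=list)
    therapies: list[TherapyEpisode] = field(default_factory=list)

    @property
    def analyzable(self) -> bool:
        return len(self.reactions) > 0

    def indication_pts(self) -> set[str]:
        out: set[str] = set()
        for pts in self.indications.values():
            out.update(pts)
        return out


@dataclass(slots=True)
class CohortCase:
    """An analysis case after indication restriction and drug mapping.

    ``ps_ingredients`` holds the canonical ingredient(s) of the
    primary-suspect drug(s) that matched the dictionary (usually one;
    empty when the PS drug is not a watched ingredient, in which case the
    case contributes only to the comparator background).
    ``all_ingredients`` holds every matched ingredient in any role.
    """

    caseid: str
    ps_ingredients: tuple[str, ...]
    ps_classes: tuple[str, ...]
    reaction_pts: tuple[str, ...]
    all_ingredients: frozenset[str] = frozenset()
    sex: str = "UNK"
    age_value: Optional[float] = None
    age_unit: str = "UNK"
    country: str = ""
    event_dt: Optional[int] = None
    outcomes: tuple[str, ...] = ()
    ps_drug_seqs: tuple[int, ...] = ()
    therapies: tuple[TherapyEpisode, ...] = ()

    @property
    def ps_ingredient(self) -> Optional[str]:
        return self.ps_ingredients[0] if self.ps_ingredients else None

    @property
    def ps_class(self) -> Optional[str]:
        return self.ps_classes[0] if self.ps_classes else None

    def exposed_to(self, ingredient: str) -> bool:
        return ingredient in self.ps_ingredients

    def concomitants_for(self, index_ingredient: Optional[str]) -> frozenset[str]:
        """Ingredients co-reported with (and distinct from) the index drug."""
        if index_ingredient is None:
            return self.all_ingredients
        return self.all_ingredients - {index_ingredient}


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 report counts of a drug-event pair against the cohort background.

    a: index drug and index event; b: index drug, no event;
    c: event without index drug; d: neither.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0:
                raise ValueError("contingency cells must be non-negative")
        if self.n == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def drug_total(self) -> int:
        return self.a + self.b

    @property
    def event_total(self) -> int:
        return self.a + self.c


@dataclass(frozen=True)
class SignalResult:
    """Disproportionality statistics for one drug-event pair.

    ``ror``/``ror025``/``ror975`` are NaN when any 2x2 cell is zero (the
    Wald interval is undefined and no correction is applied).  ``ic`` and
    ``ic025`` are always defined thanks to the +0.5 shrinkage.
    """

    drug: str
    event_term: str
    level: str  # "PT" or "SMQ"
    n_reports: int
    ror: float
    ror025: float
    ror975: float
    ic: float
    ic025: float
    is_signal: bool
    drug_class: str = ""
    table: Optional["ContingencyTable"] = None

    @property
    def ror_defined(self) -> bool:
        return not math.isnan(self.ror)


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference.

    ``beta`` and ``se`` are keyed by design-column name; the exposure
    column is ``x_drug`` so ``adjusted_ror`` is exp(beta["x_drug"]).
    """

    beta: Mapping[str, float]
    se: Mapping[str, float]
    converged: bool
    n_used: int
    n_iter: int
    loglik: float
    separation: bool = False
    exposure_col: str = "x_drug"

    @property
    def adjusted_ror(self) -> float:
        return math.exp(self.beta[self.exposure_col])

    @property
    def ci95(self) -> tuple[float, float]:
        b = self.beta[self.exposure_col]
        s = self.se[self.exposure_col]
        return (math.exp(b - 1.96 * s), math.exp(b + 1.96 * s))


@dataclass(frozen=True, slots=True)
class OnsetRecord:
    """Time from first therapy start of the suspect drug to event onset."""

    caseid: str
    drug: str
    onset_years: float


@dataclass(frozen=True, slots=True)
class OnsetExclusion:
    """A case that could not contribute a time-to-onset value."""

    caseid: str
    drug: str
    reason: str  # missing_date | partial_date | negative | no_therapy


def parse_date(raw: object) -> Optional[int]:
    """Parse a FAERS date field (YYYYMMDD, YYYYMM or YYYY) to int, else None.

    Full 8-digit values must be valid calendar dates; partial dates are
    kept as-is (their precision is checked by consumers that need days).
    """
    if raw is None:
        return None
    s = str(raw).strip()
    if not s or s.lower() == "nan":
        return None
    if s.endswith(".0"):  # pandas float passthrough
        s = s[:-2]
    if not s.isdigit():
        return None
    if len(s) == 8:
        return _valid_ymd(s)
    if len(s) == 6:
        y, m = int(s[:4]), int(s[4:6])
        return int(s) if 1900 <= y <= 2100 and 1 <= m <= 12 else None
    if len(s) == 4:
        y = int(s)
        return y if 1900 <= y <= 2100 else None
    return None


def _valid_ymd(s: str) -> Optional[int]:
    import datetime

    try:
        datetime.date(int(s[:4]), int(s[4:6]), int(s[6:8]))
    except ValueError:
        return None
    return int(s)


def date_precision(dt: Optional[int]) -> Optional[str]:
    """'day' for YYYYMMDD, 'month' for YYYYMM, 'year' for YYYY."""
    if dt is None:
        return None
    n = len(str(dt))
    return {8: "day", 6: "month", 4: "year"}.get(n)


def to_date(dt: int):
    """Convert a full-precision YYYYMMDD integer to datetime.date."""
    import datetime

    s = f"{dt:08d}"
    return datetime.date(int(s[:4]), int(s[4:6]), int(s[6:8]))
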