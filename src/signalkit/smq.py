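"""PT -> Standardised MedDRA Query (SMQ) aggregation.

An SMQ is a curated, possibly overlapping grouping of preferred terms
describing one medical condition; a case counts once toward an SMQ no
matter how many member PTs it carries.  SMQ membership content is part of
the licensed MedDRA distribution and is therefore always user-supplied as
a delimited (pt, smq[, scope]) file; only the nine malignancy-related SMQ
names used as the default analysis universe ship with the package.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .disproportionality import ICFunc, compute_ic, screen_masks, _exposure_masks
from .types import CohortCase, SignalResult

log = logging.getLogger(__name__)

#: the nine cancer-risk SMQs forming the default analysis universe
DEFAULT_SMQ_UNIVERSE: tuple[str, ...] = (
    "Malignancies",
    "Breast neoplasms, malignant and unspecified",
    "Skin neoplasms, malignant and unspecified",
    "Premalignant disorders",
    "Malignant lymphomas",
    "Prostate neoplasms, malignant and unspecified",
    "Ovarian neoplasms, malignant and unspecified",
    "Uterine and fallopian tube neoplasms, malignant and unspecified",
    "Tumour lysis syndrome",
)


@dataclass
class SmqMap:
    """Many-to-many PT -> SMQ membership plus the declared SMQ universe."""

    pt_to_smqs: dict[str, frozenset[str]]
    universe: tuple[str, ...] = DEFAULT_SMQ_UNIVERSE

    def __post_init__(self) -> None:
        declared = set(self.universe)
        mapped = set().union(*self.pt_to_smqs.values()) if self.pt_to_smqs else set()
        stray = mapped - declared
        if stray:
            # widen rather than fail: a user map defines its own universe
            self.universe = self.universe + tuple(sorted(stray))

    def smqs_of(self, pt: str) -> frozenset[str]:
        return self.pt_to_smqs.get(pt, frozenset())

    def __len__(self) -> int:
        return len(self.pt_to_smqs)


def load_smq_map(
    path: str | Path,
    delimiter: str = ",",
    universe: Sequence[str] = DEFAULT_SMQ_UNIVERSE,
) -> SmqMap:
    """Load a (pt, smq[, scope]) file; malformed rows are logged and skipped.

    When a scope column is present it is appended to the SMQ name as
    " (narrow)"/" (broad)" so the two scopes screen as distinct groups.
    """
    mapping: dict[str, set[str]] = {}
    n_bad = 0
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter=delimiter)):
            if not row or (i == 0 and row[0].strip().lower() == "pt"):
                continue
            if len(row) < 2 or not row[0].strip() or not row[1].strip():
                n_bad += 1
                log.warning("SMQ map row %d malformed, skipped: %r", i, row)
                continue
            pt, smq = row[0].strip(), row[1].strip()
            if len(row) > 2 and row[2].strip():
                smq = f"{smq} ({row[2].strip().lower()})"
            mapping.setdefault(pt, set()).add(smq)
    if not mapping:
        log.warning("SMQ map %s is empty", path)
    return SmqMap(
        {pt: frozenset(s) for pt, s in mapping.items()}, tuple(universe)
    )


def annotate_smq(case: CohortCase, smq_map: SmqMap) -> set[str]:
    """The set of SMQs a case belongs to (union over its reaction PTs)."""
    out: set[str] = set()
    for pt in case.reaction_pts:
        out |= smq_map.smqs_of(pt)
    return out


def smq_event_masks(
    cohort: Sequence[CohortCase], smq_map: SmqMap
) -> dict[str, np.ndarray]:
    """Boolean per-SMQ membership masks over the cohort."""
    names = sorted({s for ss in smq_map.pt_to_smqs.values() for s in ss})
    masks = {name: np.zeros(len(cohort), dtype=bool) for name in names}
    for i, case in enumerate(cohort):
        for smq in annotate_smq(case, smq_map):
            masks[smq][i] = True
    return masks


def screen_smq(
    cohort: Sequence[CohortCase],
    drugs: Iterable[str],
    smq_map: SmqMap,
    drug_classes: Optional[dict[str, str]] = None,
    min_a: int = 1,
    ic_method: ICFunc = compute_ic,
) -> list[SignalResult]:
    """The PT-level screen with the event indicator replaced by SMQ membership."""
    if len(smq_map) == 0:
        log.warning("empty SMQ map: nothing to screen")
        return []
    drugs = list(drugs)
    if not drugs:
        return []
    return screen_masks(
        _exposure_masks(cohort, drugs),
        smq_event_masks(cohort, smq_map),
        len(cohort),
        "SMQ",
        drug_classes=drug_classes,
        min_a=min_a,
        ic_method=ic_method,
    )
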