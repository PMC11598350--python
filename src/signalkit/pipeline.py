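"""End-to-end orchestration: ingest -> dedup -> cohort -> screens -> adjusted -> TTO -> descriptives.

Every stage writes a plain delimited table into the output directory so
each intermediate is independently inspectable, and a manifest records
parameters, per-stage row counts and a content hash of every artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from . import faers_io
from .adjusted_models import adjusted_screen
from .cohort import (
    DEFAULT_CONCOMITANT_WATCHLIST,
    DEFAULT_INDICATION_TERMS,
    DrugDictionary,
    build_cohort,
    default_dictionary,
    load_dictionary,
)
from .disproportionality import results_to_frame, screen_all
from .smq import SmqMap, load_smq_map, screen_smq
from .tto_descriptives import (
    collect_onsets,
    summarize_descriptives,
    summarize_onset,
)

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything :func:`run_pipeline` needs.

    Either ``input_paths`` (table name -> file) or ``synth_config`` must be
    given.  ``event_universe`` is the PT list screened at PT level; when
    None and synthetic input is used, the generator's event list serves.
    """

    output_dir: Path
    input_paths: Optional[Mapping[str, Path]] = None
    deleted_paths: Sequence[Path] = ()
    synth_config: Optional[object] = None  # SynthConfig
    dictionary_path: Optional[Path] = None
    smq_map_path: Optional[Path] = None
    indication_terms: Sequence[str] = tuple(DEFAULT_INDICATION_TERMS)
    event_universe: Optional[Sequence[str]] = None
    covariate_watchlist: Sequence[str] = DEFAULT_CONCOMITANT_WATCHLIST
    level: str = "both"  # pt | smq | both
    min_reports: int = 3
    delimiter: str = "$"

    def __post_init__(self) -> None:
        if self.min_reports < 1:
            raise ValueError("min_reports must be >= 1")
        if self.level not in ("pt", "smq", "both"):
            raise ValueError("level must be pt, smq or both")
        if self.input_paths is None and self.synth_config is None:
            raise ValueError("either input_paths or synth_config is required")
        if self.level in ("smq", "both") and self.smq_map_path is None:
            raise ValueError(
                "level=%s requires an SMQ map file (smq_map_path)" % self.level
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage, writing one table per stage plus manifest.json.

    Returns the output directory.  A stage failure raises
    :class:`StageError` naming the stage; tables already written remain.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    written: list[Path] = []
    stage = "setup"

    def write(name: str, frame: pd.DataFrame) -> None:
        p = out / name
        frame.to_csv(p, index=False)
        written.append(p)

    try:
        stage = "ingest"
        if config.synth_config is not None:
            from .synthetic_faers import generate

            paths, _truth = generate(config.synth_config, out / "synth_input")
            deleted_paths = [paths.pop("deleted")]
            event_universe = config.event_universe or [
                e for e, _ in config.synth_config.events
            ]
        else:
            paths = dict(config.input_paths)
            deleted_paths = list(config.deleted_paths)
            if "deleted" in paths:
                deleted_paths.append(paths.pop("deleted"))
            event_universe = list(config.event_universe or [])
        quarter = faers_io.read_quarter(paths, delimiter=config.delimiter)
        counts["versions_read"] = len(quarter.versions)

        stage = "dedup"
        deleted = (
            faers_io.read_deleted_caseids(deleted_paths) if deleted_paths else set()
        )
        survivors = faers_io.deduplicate(quarter.versions, deleted)
        counts["cases_after_dedup"] = len(survivors)
        n_not_deleted = sum(
            1 for v in quarter.versions if v.caseid not in deleted
        )
        counts["versions_deleted"] = len(quarter.versions) - n_not_deleted
        counts["versions_superseded"] = n_not_deleted - len(survivors)

        stage = "assemble"
        cases, alog = faers_io.assemble_cases(
            survivors,
            quarter.demo,
            quarter.drug,
            quarter.reac,
            quarter.indi,
            quarter.outc,
            quarter.ther,
        )
        counts["cases_assembled"] = alog.n_cases
        counts["cases_non_analyzable"] = alog.n_non_analyzable
        write("cases.csv", faers_io.cases_to_frame(cases))

        stage = "cohort"
        dictionary: DrugDictionary = (
            load_dictionary(config.dictionary_path)
            if config.dictionary_path
            else default_dictionary()
        )
        cohort = build_cohort(cases, dictionary, config.indication_terms)
        counts["cohort_cases"] = len(cohort)
        counts["cohort_exposed"] = sum(1 for c in cohort if c.ps_ingredients)
        drugs = list(dictionary.ingredients)
        drug_classes = {d: dictionary.class_of(d) for d in drugs}

        if not event_universe:
            raise ValueError("event universe is empty; supply --events")

        stage = "screen_pt"
        if config.level in ("pt", "both"):
            res = screen_all(cohort, drugs, event_universe, drug_classes)
            pt_frame = results_to_frame(res)
            write("signals_pt.csv", pt_frame)
            counts["pt_pairs"] = len(pt_frame)
            counts["pt_signals"] = (
                int(pt_frame["signal"].sum()) if len(pt_frame) else 0
            )

        stage = "screen_smq"
        if config.level in ("smq", "both"):
            smq_map: SmqMap = load_smq_map(config.smq_map_path)
            res = screen_smq(cohort, drugs, smq_map, drug_classes)
            smq_frame = results_to_frame(res)
            write("signals_smq.csv", smq_frame)
            counts["smq_pairs"] = len(smq_frame)
            counts["smq_signals"] = (
                int(smq_frame["signal"].sum()) if len(smq_frame) else 0
            )

        stage = "adjusted"
        adj = adjusted_screen(
            cohort,
            drugs,
            event_universe,
            dictionary,
            config.covariate_watchlist,
        )
        write("adjusted.csv", adj)
        counts["adjusted_rows"] = len(adj)

        stage = "tto"
        records, exclusions = collect_onsets(cohort, drugs)
        tto = summarize_onset(records)
        write("tto.csv", tto)
        excl = pd.DataFrame(
            [
                {"caseid": e.caseid, "drug": e.drug, "reason": e.reason}
                for e in exclusions
            ]
        )
        write("tto_exclusions.csv", excl)
        counts["tto_records"] = len(records)
        counts["tto_exclusions"] = len(exclusions)

        stage = "descriptives"
        desc = summarize_descriptives(cohort, drugs)
        write("descriptives_drug.csv", desc.per_drug)
        write("descriptives_class.csv", desc.per_class)
        write("descriptives_sex.csv", desc.sex)
        write("descriptives_age.csv", desc.age)
        write("descriptives_country.csv", desc.country)
        write("descriptives_outcomes.csv", desc.outcomes)
        counts["descriptive_reports"] = desc.n_reports
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError(f"pipeline failed in stage '{stage}': {exc}") from exc

    manifest = {
        "signalkit_version": __version__,
        "stage_counts": counts,
        "parameters": {
            "indication_terms": list(config.indication_terms),
            "level": config.level,
            "min_reports": config.min_reports,
            "watchlist": list(config.covariate_watchlist),
            "seed": getattr(config.synth_config, "seed", None),
        },
        "outputs": {
            p.name: _sha256(p) for p in written
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
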