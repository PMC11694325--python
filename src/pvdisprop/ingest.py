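"""Reading FAERS-shaped tables and the case-selection cascade.

The selection cascade mirrors standard spontaneous-report cleaning:

1. deduplicate versioned records to one per CASEID, keeping the latest
   FDA_DT and breaking ties by the higher PRIMARYID;
2. drop delete-file members;
3. drop records whose *present* age lies outside [0, 150] years;
4. drop records whose *present* weight exceeds 150 kg;
5. optionally keep only cases where a study drug carries a suspect role
   (the machine-checkable reading of "exclude events attributable to
   concomitant medication");
6. collapse exact-duplicate reports filed under different CASEIDs.

Missing age or weight is retained by default (the filters apply only to
present values); a ``drop_missing_demo`` switch drops them instead.  Every
stage count is recorded in a :class:`FilterLedger` whose stage sum equals
input minus output, exactly.
"""
from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import STUDY_PPIS
from .meddra import normalize_term
from .synthetic_faers import (
    DELETE_FILE,
    TABLE_FILES,
    DrugExposure,
    RawReportRecord,
)

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A mandatory column is absent from an input table."""


@dataclass(slots=True)
class ReportCase:
    """One deduplicated spontaneous report (the analysis unit)."""

    primaryid: int
    caseid: int
    fda_dt: dt.date | None
    age: float | None
    sex: str
    weight_kg: float | None
    reporter_country: str | None
    drugs: tuple[DrugExposure, ...]
    reactions: tuple[str, ...]
    event_dt: dt.date | None
    outcome_fatal: bool | None


@dataclass
class FilterLedger:
    """Records removed at each stage of the cascade, in application order."""

    input_records: int = 0
    duplicate_cases_removed: int = 0
    delete_file_removed: int = 0
    age_out_of_range: int = 0
    weight_out_of_range: int = 0
    no_suspect_study_drug: int = 0
    exact_duplicates_removed: int = 0
    missing_demo_removed: int = 0
    output_records: int = 0

    STAGES = (
        "duplicate_cases_removed",
        "delete_file_removed",
        "age_out_of_range",
        "weight_out_of_range",
        "no_suspect_study_drug",
        "exact_duplicates_removed",
        "missing_demo_removed",
    )

    def stage_counts(self) -> tuple[int, ...]:
        return tuple(getattr(self, s) for s in self.STAGES)

    def conserved(self) -> bool:
        return self.input_records - sum(self.stage_counts()) == self.output_records

    def as_dict(self) -> dict[str, int]:
        d = {"input_records": self.input_records}
        d.update({s: getattr(self, s) for s in self.STAGES})
        d["output_records"] = self.output_records
        return d

    def merge(self, other: "FilterLedger") -> "FilterLedger":
        """Chain two ledgers (this stage's output feeds the other's input)."""
        merged = FilterLedger(
            input_records=self.input_records, output_records=other.output_records
        )
        for s in self.STAGES:
            setattr(merged, s, getattr(self, s) + getattr(other, s))
        return merged


_DEDUP_EPOCH = dt.date.min  # records with missing fda_dt lose all dated ties


def deduplicate(
    records: Sequence[RawReportRecord],
) -> tuple[list[RawReportRecord], FilterLedger]:
    """Keep one record per CASEID: latest FDA_DT, ties to the higher PRIMARYID.

    Output is sorted by PRIMARYID so the surviving set is independent of the
    input order.
    """
    best: dict[int, RawReportRecord] = {}
    for r in records:
        key = (r.fda_dt or _DEDUP_EPOCH, r.primaryid)
        cur = best.get(r.caseid)
        if cur is None or key > (cur.fda_dt or _DEDUP_EPOCH, cur.primaryid):
            best[r.caseid] = r
    survivors = sorted(best.values(), key=lambda r: r.primaryid)
    ledger = FilterLedger(
        input_records=len(records),
        duplicate_cases_removed=len(records) - len(survivors),
        output_records=len(survivors),
    )
    return survivors, ledger


def _content_key(r: RawReportRecord) -> tuple:
    """Record identity ignoring version bookkeeping (primaryid/caseid/fda_dt)."""
    return (
        r.age,
        r.sex,
        r.weight_kg,
        r.reporter_country,
        r.drugs,
        r.reactions,
        r.event_dt,
        r.outcome_fatal,
    )


def apply_exclusions(
    records: Sequence[RawReportRecord],
    delete_ids: Iterable[int] = (),
    suspect_only: bool = False,
    study_drugs: Sequence[str] = STUDY_PPIS,
    drop_missing_demo: bool = False,
    drop_exact_duplicates: bool = True,
) -> tuple[list[ReportCase], FilterLedger]:
    """Apply the post-dedup exclusion stages and convert to analysis cases.

    ``records`` must already be deduplicated (one per CASEID).
    """
    delete_set = set(delete_ids)
    study = {normalize_term(d) for d in study_drugs}
    ledger = FilterLedger(input_records=len(records))

    kept: list[RawReportRecord] = []
    for r in records:
        if r.primaryid in delete_set or r.deleted:
            ledger.delete_file_removed += 1
            continue
        if r.age is not None and not 0.0 <= r.age <= 150.0:
            ledger.age_out_of_range += 1
            continue
        if r.weight_kg is not None and r.weight_kg > 150.0:
            ledger.weight_out_of_range += 1
            continue
        if suspect_only and not any(
            d.suspect and normalize_term(d.name) in study for d in r.drugs
        ):
            ledger.no_suspect_study_drug += 1
            continue
        if drop_missing_demo and (r.age is None or r.weight_kg is None):
            ledger.missing_demo_removed += 1
            continue
        kept.append(r)

    if drop_exact_duplicates:
        seen: dict[tuple, int] = {}
        deduped: list[RawReportRecord] = []
        for r in sorted(kept, key=lambda r: r.caseid):
            key = _content_key(r)
            if key in seen:
                ledger.exact_duplicates_removed += 1
            else:
                seen[key] = r.caseid
                deduped.append(r)
        kept = sorted(deduped, key=lambda r: r.primaryid)

    cases = [
        ReportCase(
            r.primaryid,
            r.caseid,
            r.fda_dt,
            r.age,
            r.sex,
            r.weight_kg,
            r.reporter_country,
            r.drugs,
            r.reactions,
            r.event_dt,
            r.outcome_fatal,
        )
        for r in kept
    ]
    ledger.output_records = len(cases)
    return cases, ledger


def run(
    records: Sequence[RawReportRecord],
    delete_ids: Iterable[int] = (),
    suspect_only: bool = False,
    study_drugs: Sequence[str] = STUDY_PPIS,
    drop_missing_demo: bool = False,
) -> tuple[list[ReportCase], FilterLedger]:
    """Full cascade: deduplicate then apply every exclusion stage."""
    deduped, ledger1 = deduplicate(records)
    cases, ledger2 = apply_exclusions(
        deduped,
        delete_ids=delete_ids,
        suspect_only=suspect_only,
        study_drugs=study_drugs,
        drop_missing_demo=drop_missing_demo,
    )
    return cases, ledger1.merge(ledger2)


# --------------------------------------------------------------------------
# Readers.

_MANDATORY = {
    "demo": ("primaryid", "caseid", "fda_dt", "age", "sex", "weight_kg", "event_dt"),
    "drug": ("primaryid", "drugname"),
    "reac": ("primaryid", "pt"),
    "outc": ("primaryid", "fatal"),
}


def _parse_date(value) -> dt.date | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    ts = pd.to_datetime(value, errors="coerce")
    if pd.isna(ts):
        logger.warning("unparseable date %r treated as missing", value)
        return None
    return ts.date()


def _read_table(path: Path, name: str, sep: str) -> pd.DataFrame:
    if not path.exists():
        raise SchemaError(f"table {name!r} not found at {path}")
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY[name] if c not in frame.columns]
    if missing:
        raise SchemaError(f"table {name!r} missing mandatory columns {missing}")
    extra = [c for c in frame.columns if c not in _known_columns(name)]
    if extra:
        logger.warning("table %r has unknown columns %s; ignored", name, extra)
    return frame


def _known_columns(name: str) -> tuple[str, ...]:
    known = {
        "demo": _MANDATORY["demo"] + ("reporter_country",),
        "drug": _MANDATORY["drug"] + ("dose_mg_day", "therapy_start_dt", "role"),
        "reac": _MANDATORY["reac"],
        "outc": _MANDATORY["outc"],
    }
    return known[name]


def _opt_float(value: str) -> float | None:
    return None if value == "" else float(value)


def read_delete_list(path) -> set[int]:
    path = Path(path)
    if not path.exists():
        return set()
    return {
        int(line) for line in path.read_text().splitlines() if line.strip()
    }


def read_dataset(path_prefix, sep: str = "\t") -> list[RawReportRecord]:
    """Read the four-table layout written by the generator.

    Every demo row is materialized; unparseable dates become missing with a
    logged warning.  The delete list (if present) populates the ``deleted``
    flag.
    """
    prefix = Path(path_prefix)
    tables = {
        name: _read_table(prefix / fname, name, sep)
        for name, fname in TABLE_FILES.items()
    }
    deleted = read_delete_list(prefix / DELETE_FILE)

    drugs_by_id: dict[int, list[DrugExposure]] = {}
    for row in tables["drug"].itertuples(index=False):
        pid = int(row.primaryid)
        drugs_by_id.setdefault(pid, []).append(
            DrugExposure(
                name=row.drugname,
                dose_mg=_opt_float(getattr(row, "dose_mg_day", "")),
                start_dt=_parse_date(getattr(row, "therapy_start_dt", "")),
                suspect=getattr(row, "role", "PS") in ("PS", "SS"),
            )
        )
    reac_by_id: dict[int, list[str]] = {}
    for row in tables["reac"].itertuples(index=False):
        reac_by_id.setdefault(int(row.primaryid), []).append(row.pt)
    fatal_by_id = {
        int(row.primaryid): bool(int(row.fatal))
        for row in tables["outc"].itertuples(index=False)
    }

    records = []
    for row in tables["demo"].itertuples(index=False):
        pid = int(row.primaryid)
        records.append(
            RawReportRecord(
                primaryid=pid,
                caseid=int(row.caseid),
                fda_dt=_parse_date(row.fda_dt),
                age=_opt_float(row.age),
                sex=row.sex or "missing",
                weight_kg=_opt_float(row.weight_kg),
                reporter_country=getattr(row, "reporter_country", "") or None,
                drugs=tuple(drugs_by_id.get(pid, ())),
                reactions=tuple(reac_by_id.get(pid, ())),
                event_dt=_parse_date(row.event_dt),
                outcome_fatal=fatal_by_id.get(pid),
                deleted=pid in deleted,
            )
        )
    return records


def cases_to_frame(
    cases: Sequence[ReportCase], study_drugs: Sequence[str] = STUDY_PPIS
) -> pd.DataFrame:
    """Flatten cases to one row each, keyed on the first suspect study drug."""
    study = {normalize_term(d): d for d in study_drugs}
    rows = []
    for c in cases:
        group = None
        dose = None
        start = None
        for d in c.drugs:
            key = normalize_term(d.name)
            if key in study and d.suspect:
                group, dose, start = study[key], d.dose_mg, d.start_dt
                break
        rows.append(
            {
                "primaryid": c.primaryid,
                "caseid": c.caseid,
                "fda_dt": c.fda_dt,
                "age": c.age,
                "sex": c.sex,
                "weight_kg": c.weight_kg,
                "reporter_country": c.reporter_country,
                "event_dt": c.event_dt,
                "outcome_fatal": c.outcome_fatal,
                "group": group,
                "dose_mg_day": dose,
                "therapy_start_dt": start,
                "n_reactions": len(c.reactions),
                "reactions": ";".join(c.reactions),
            }
        )
    return pd.DataFrame(rows)
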