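"""Synthetic FAERS-shaped spontaneous-report generator with planted structure.

The generator emulates the relational layout of a spontaneous reporting
system — per-case demographics, drug exposures with daily dose and therapy
start date, MedDRA-PT reactions, an event date and a fatal/non-fatal outcome —
together with the data pathologies the ingest cascade must handle: versioned
duplicate records (same CASEID, later FDA_DT, different PRIMARYID), delete-file
members, and out-of-range ages and weights.

Planted associations use an odds-scale tilt.  Each case is exposed to exactly
one suspect drug; for every PT the reaction is drawn independently with
baseline probability ``p0`` (``background_event_prob``), except that for a
(drug, PT) pair with target reporting odds ratio ``R`` the exposed-case
probability ``p1`` satisfies ``odds(p1) = R * odds(p0)``.  Because the
reporting odds ratio estimates exactly this odds ratio (exposed vs all other
drugs, event vs not), the planted ``R`` is the estimand of the downstream
ROR, making recovery and calibration directly checkable.

Cases that draw no reaction at all receive one filler PT drawn uniformly from
the non-tumor vocabulary, so every report carries at least one reaction (as
in FAERS, where a report without a reaction cannot exist).
"""
from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import STUDY_PPIS
from .meddra import default_hierarchy, normalize_term

logger = logging.getLogger(__name__)

#: Non-PPI background drugs so the dataset contains unexposed comparator cases.
COMPARATOR_DRUGS: tuple[str, ...] = ("metformin", "atorvastatin", "lisinopril")

SEX_LEVELS = ("female", "male", "missing")


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the offending field."""


class ValidationError(ValueError):
    """A record set violates a dataset invariant (e.g. duplicate PRIMARYID)."""


class DrugExposure(NamedTuple):
    """One drug mention on a report."""

    name: str
    dose_mg: float | None
    start_dt: dt.date | None
    suspect: bool


@dataclass(slots=True)
class RawReportRecord:
    """One version of a spontaneous report, before deduplication."""

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
    deleted: bool = False


def _default_dose_levels() -> dict[float, float]:
    # Daily-dose mix echoing the observed Low/Medium/High split (~39/49/12).
    return {20.0: 0.39, 40.0: 0.49, 80.0: 0.12}


def _default_sex_probs() -> dict[str, float]:
    return {"female": 0.31, "male": 0.37, "missing": 0.32}


def _default_country_probs() -> dict[str | None, float]:
    # US-dominated reporter mix, as in the real database.
    return {
        "US": 0.8155,
        "JP": 0.0696,
        "GB": 0.0220,
        "CA": 0.0300,
        "FR": 0.0300,
        "DE": 0.0248,
        None: 0.0081,
    }


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic report generator.

    ``association`` maps (drug label, PT label) pairs to target reporting odds
    ratios (1.0 = null).  ``background_event_prob`` is either a single per-PT
    baseline reporting probability or a mapping PT -> probability.
    ``onset_days_distribution`` is ``("lognormal", median_days, sigma)``; the
    default median of 2,556 days with sigma 1.1 gives the long right-skewed
    onset profile typical of tumor adverse events.
    """

    n_cases: int = 10_000
    drug_names: tuple[str, ...] = STUDY_PPIS + COMPARATOR_DRUGS
    drug_weights: tuple[float, ...] | None = None
    event_vocabulary: tuple[str, ...] | None = None
    tumor_pts: tuple[str, ...] | None = None
    association: Mapping[tuple[str, str], float] = field(default_factory=dict)
    background_event_prob: float | Mapping[str, float] = 0.01
    duplicate_rate: float = 0.05
    invalid_age_rate: float = 0.005
    invalid_weight_rate: float = 0.005
    delete_rate: float = 0.005
    nonsuspect_rate: float = 0.0
    age_missing_rate: float = 0.30
    weight_missing_rate: float = 0.40
    fatal_prob: float = 0.297
    nontumor_fatal_prob: float = 0.05
    sex_probs: Mapping[str, float] = field(default_factory=_default_sex_probs)
    country_probs: Mapping[str | None, float] = field(
        default_factory=_default_country_probs
    )
    onset_days_distribution: tuple = ("lognormal", 2556.0, 1.1)
    dose_levels: Mapping = field(default_factory=_default_dose_levels)
    date_window: tuple[dt.date, dt.date] = (dt.date(2004, 1, 1), dt.date(2024, 3, 31))
    seed: int = 0

    def resolved_vocabulary(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        """(tumor PTs, non-tumor PTs), defaulting to the bundled hierarchy."""
        if self.event_vocabulary is None:
            h = default_hierarchy()
            return h.tumor_display_labels(), h.nontumor_display_labels()
        vocab = tuple(self.event_vocabulary)
        if self.tumor_pts is None:
            h = default_hierarchy()
            tumor = tuple(p for p in vocab if h.is_tumor(p))
        else:
            tset = {normalize_term(p) for p in self.tumor_pts}
            tumor = tuple(p for p in vocab if normalize_term(p) in tset)
        nontumor = tuple(p for p in vocab if p not in tumor)
        return tumor, nontumor

    def validate(self) -> None:
        if not isinstance(self.n_cases, (int, np.integer)) or self.n_cases < 1:
            raise ConfigError("n_cases must be a positive integer")
        missing_ppis = [d for d in STUDY_PPIS if d not in self.drug_names]
        if missing_ppis:
            raise ConfigError(f"drug_names must include the study drugs {missing_ppis}")
        if self.drug_weights is not None:
            if len(self.drug_weights) != len(self.drug_names):
                raise ConfigError("drug_weights must match drug_names in length")
            if any(w < 0 for w in self.drug_weights) or sum(self.drug_weights) <= 0:
                raise ConfigError("drug_weights must be non-negative with positive sum")
        for name in (
            "duplicate_rate",
            "invalid_age_rate",
            "invalid_weight_rate",
            "delete_rate",
            "nonsuspect_rate",
            "age_missing_rate",
            "weight_missing_rate",
        ):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0:
                raise ConfigError(f"{name} must lie in [0, 1)")
        for name in ("fatal_prob", "nontumor_fatal_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        tumor, nontumor = self.resolved_vocabulary()
        vocab = set(tumor) | set(nontumor)
        if not nontumor:
            raise ConfigError("event_vocabulary needs at least one non-tumor PT")
        probs = self.background_event_prob
        if isinstance(probs, Mapping):
            bad = [p for p in probs.values() if not 0.0 < p < 1.0]
            unknown = [t for t in probs if t not in vocab]
            if bad or unknown:
                raise ConfigError(
                    "background_event_prob entries must be in (0,1) and name known PTs"
                )
        elif not 0.0 < probs < 1.0:
            raise ConfigError("background_event_prob must lie in (0, 1)")
        norm_vocab = {normalize_term(t) for t in vocab}
        for (drug, pt), ror in self.association.items():
            if drug not in self.drug_names:
                raise ConfigError(f"association names unknown drug {drug!r}")
            if normalize_term(pt) not in norm_vocab:
                raise ConfigError(f"association names unknown PT {pt!r}")
            if not ror > 0:
                raise ConfigError("association target RORs must be > 0")
        for key, value in _flat_dose_levels(self.dose_levels, self.drug_names).items():
            for dose, weight in value.items():
                if not dose > 0:
                    raise ConfigError("dose levels must be strictly positive")
                if weight < 0:
                    raise ConfigError("dose-level weights must be non-negative")
        family = self.onset_days_distribution[0]
        if family != "lognormal":
            raise ConfigError(
                f"onset_days_distribution family {family!r} not supported"
            )
        if self.date_window[0] > self.date_window[1]:
            raise ConfigError("date_window start must not exceed its end")
        probs_sum = sum(self.sex_probs.get(s, 0.0) for s in SEX_LEVELS)
        if abs(probs_sum - 1.0) > 1e-6:
            raise ConfigError("sex_probs must sum to 1 over female/male/missing")


def _flat_dose_levels(levels: Mapping, drug_names: Sequence[str]) -> dict:
    """Normalize dose_levels to {drug: {dose: weight}} (shared map allowed)."""
    if levels and all(isinstance(k, (int, float)) for k in levels):
        shared = {float(k): float(v) for k, v in levels.items()}
        return {d: shared for d in drug_names}
    return {
        d: {float(k): float(v) for k, v in levels.get(d, _default_dose_levels()).items()}
        for d in drug_names
    }


def _tilt(p0: np.ndarray, ror: np.ndarray) -> np.ndarray:
    """Event probability after multiplying baseline odds by ``ror``."""
    odds = ror * p0 / (1.0 - p0)
    return odds / (1.0 + odds)


def generate_dataset(config: GeneratorConfig) -> list[RawReportRecord]:
    """Generate a deterministic synthetic report set.

    The realized number of unique CASEIDs equals ``config.n_cases``; duplicate
    versions are appended after the base records with higher PRIMARYIDs and
    later FDA_DTs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(config.n_cases)
    drugs = list(config.drug_names)
    tumor_pts, nontumor_pts = config.resolved_vocabulary()
    pts = list(tumor_pts) + list(nontumor_pts)
    n_pts = len(pts)
    tumor_mask = np.zeros(n_pts, dtype=bool)
    tumor_mask[: len(tumor_pts)] = True

    if isinstance(config.background_event_prob, Mapping):
        p0 = np.array(
            [float(config.background_event_prob.get(pt, 0.01)) for pt in pts]
        )
    else:
        p0 = np.full(n_pts, float(config.background_event_prob))

    weights = config.drug_weights
    if weights is None:
        w = np.full(len(drugs), 1.0 / len(drugs))
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    drug_idx = rng.choice(len(drugs), size=n, p=w)

    # Odds-scale tilt matrix: one row per drug, one column per PT.
    ror_mat = np.ones((len(drugs), n_pts))
    norm_pt_index = {normalize_term(pt): j for j, pt in enumerate(pts)}
    for (drug, pt), target in config.association.items():
        ror_mat[drugs.index(drug), norm_pt_index[normalize_term(pt)]] = float(target)
    prob_mat = _tilt(p0[None, :], ror_mat)
    reacted = rng.random((n, n_pts)) < prob_mat[drug_idx]

    # Guarantee >=1 reaction: filler non-tumor PT for empty draws.
    filler = rng.integers(len(tumor_pts), n_pts, size=n)
    empty = ~reacted.any(axis=1)
    reacted[np.nonzero(empty)[0], filler[empty]] = True
    is_tae = reacted[:, tumor_mask].any(axis=1)

    counts = reacted.sum(axis=1)
    _, cols = np.nonzero(reacted)
    flat = [pts[j] for j in cols.tolist()]
    ends = np.cumsum(counts).tolist()
    starts = [0] + ends[:-1]
    reactions = [tuple(flat[s:e]) for s, e in zip(starts, ends)]

    # Dates: event uniform in the study window; onset lognormal; receipt
    # shortly after the event.
    start64 = np.datetime64(config.date_window[0])
    end64 = np.datetime64(config.date_window[1])
    span = int((end64 - start64).astype(int)) + 1
    event64 = start64 + rng.integers(0, span, size=n).astype("timedelta64[D]")
    _, onset_median, onset_sigma = config.onset_days_distribution
    # capped at 100 years: longer pre-event exposure is nonphysical
    onset_days = np.clip(
        np.round(rng.lognormal(np.log(onset_median), onset_sigma, size=n)),
        0.0,
        36_500.0,
    ).astype(int)
    therapy64 = event64 - onset_days.astype("timedelta64[D]")
    fda64 = event64 + rng.integers(0, 181, size=n).astype("timedelta64[D]")
    event_dates = event64.astype("datetime64[D]").tolist()
    therapy_dates = therapy64.astype("datetime64[D]").tolist()
    fda_dates = fda64.astype("datetime64[D]").tolist()

    # Demographics.
    age = np.clip(np.round(rng.normal(60.0, 15.0, size=n), 1), 18.0, 100.0)
    age_missing = rng.random(n) < config.age_missing_rate
    age_invalid = (~age_missing) & (rng.random(n) < config.invalid_age_rate)
    invalid_high = rng.random(n) < 0.5
    invalid_age_vals = np.where(
        invalid_high,
        np.round(rng.uniform(151.0, 200.0, size=n), 1),
        np.round(rng.uniform(-20.0, -1.0, size=n), 1),
    )
    age = np.where(age_invalid, invalid_age_vals, age)

    weight = np.clip(np.round(rng.normal(75.0, 15.0, size=n), 1), 35.0, 149.0)
    weight_missing = rng.random(n) < config.weight_missing_rate
    weight_invalid = (~weight_missing) & (rng.random(n) < config.invalid_weight_rate)
    weight = np.where(
        weight_invalid, np.round(rng.uniform(151.0, 250.0, size=n), 1), weight
    )

    sex_p = np.array([config.sex_probs[s] for s in SEX_LEVELS])
    sex_codes = rng.choice(len(SEX_LEVELS), size=n, p=sex_p / sex_p.sum())
    country_labels = list(config.country_probs)
    country_p = np.array([config.country_probs[c] for c in country_labels])
    country_codes = rng.choice(len(country_labels), size=n, p=country_p / country_p.sum())

    fatal_p = np.where(is_tae, config.fatal_prob, config.nontumor_fatal_prob)
    fatal = rng.random(n) < fatal_p
    suspect = rng.random(n) >= config.nonsuspect_rate

    dose_map = _flat_dose_levels(config.dose_levels, drugs)
    dose = np.empty(n)
    for j, drug in enumerate(drugs):
        mask = drug_idx == j
        levels = dose_map[drug]
        vals = np.array(list(levels), dtype=float)
        lw = np.array(list(levels.values()), dtype=float)
        dose[mask] = vals[rng.choice(len(vals), size=int(mask.sum()), p=lw / lw.sum())]

    dup_mask = rng.random(n) < config.duplicate_rate

    age_list = [
        None if miss else a for a, miss in zip(age.tolist(), age_missing.tolist())
    ]
    weight_list = [
        None if miss else wkg
        for wkg, miss in zip(weight.tolist(), weight_missing.tolist())
    ]
    drug_name_list = [drugs[j] for j in drug_idx.tolist()]
    sex_list = [SEX_LEVELS[c] for c in sex_codes.tolist()]
    country_list = [country_labels[c] for c in country_codes.tolist()]

    records = [
        RawReportRecord(
            i,
            i,
            fda,
            a,
            sex,
            wkg,
            country,
            (DrugExposure(drug, ds, start, susp),),
            rx,
            ev,
            ft,
        )
        for i, fda, a, sex, wkg, country, drug, ds, start, susp, rx, ev, ft in zip(
            range(1, n + 1),
            fda_dates,
            age_list,
            sex_list,
            weight_list,
            country_list,
            drug_name_list,
            dose.tolist(),
            therapy_dates,
            suspect.tolist(),
            reactions,
            event_dates,
            fatal.tolist(),
        )
    ]

    # Duplicate versions: same CASEID and content, later FDA_DT, new PRIMARYID.
    dup_indices = np.nonzero(dup_mask)[0]
    dup_delay = rng.integers(1, 91, size=len(dup_indices))
    for k, i in enumerate(dup_indices.tolist()):
        base = records[i]
        records.append(
            replace(
                base,
                primaryid=n + k + 1,
                fda_dt=base.fda_dt + dt.timedelta(days=int(dup_delay[k])),
            )
        )

    # Delete-file membership over all emitted records.
    del_mask = rng.random(len(records)) < config.delete_rate
    records = [
        replace(r, deleted=True) if flag else r
        for r, flag in zip(records, del_mask.tolist())
    ]
    logger.info(
        "generated %d records (%d cases, %d duplicates, %d delete-file)",
        len(records),
        n,
        len(dup_indices),
        int(del_mask.sum()),
    )
    return records


def delete_ids(records: Iterable[RawReportRecord]) -> set[int]:
    """PRIMARYIDs of records flagged as delete-file members."""
    return {r.primaryid for r in records if r.deleted}


# --------------------------------------------------------------------------
# Relational layout: demo / drug / reac / outc tables plus a delete list.

TABLE_FILES = {
    "demo": "demo.tsv",
    "drug": "drug.tsv",
    "reac": "reac.tsv",
    "outc": "outc.tsv",
}
DELETE_FILE = "deleted.txt"


def _iso(d: dt.date | None) -> str:
    return d.isoformat() if d is not None else ""


def write_dataset(
    records: Sequence[RawReportRecord], path_prefix, sep: str = "\t"
) -> dict[str, Path]:
    """Write the four-table relational layout plus the delete list.

    Returns the mapping table name -> written path.  Raises
    :class:`ValidationError` on an empty record set or duplicate PRIMARYIDs.
    """
    if not records:
        raise ValidationError("cannot write an empty record set")
    ids = [r.primaryid for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate primaryid in record set")
    out = Path(path_prefix)
    out.mkdir(parents=True, exist_ok=True)

    demo_rows = []
    drug_rows = []
    reac_rows = []
    outc_rows = []
    deleted: list[int] = []
    for r in records:
        demo_rows.append(
            {
                "primaryid": r.primaryid,
                "caseid": r.caseid,
                "fda_dt": _iso(r.fda_dt),
                "age": "" if r.age is None else r.age,
                "sex": r.sex,
                "weight_kg": "" if r.weight_kg is None else r.weight_kg,
                "reporter_country": r.reporter_country or "",
                "event_dt": _iso(r.event_dt),
            }
        )
        for d in r.drugs:
            drug_rows.append(
                {
                    "primaryid": r.primaryid,
                    "drugname": d.name,
                    "dose_mg_day": "" if d.dose_mg is None else d.dose_mg,
                    "therapy_start_dt": _iso(d.start_dt),
                    "role": "PS" if d.suspect else "C",
                }
            )
        for pt in r.reactions:
            reac_rows.append({"primaryid": r.primaryid, "pt": pt})
        if r.outcome_fatal is not None:
            outc_rows.append(
                {"primaryid": r.primaryid, "fatal": int(r.outcome_fatal)}
            )
        if r.deleted:
            deleted.append(r.primaryid)

    columns = {
        "demo": [
            "primaryid",
            "caseid",
            "fda_dt",
            "age",
            "sex",
            "weight_kg",
            "reporter_country",
            "event_dt",
        ],
        "drug": ["primaryid", "drugname", "dose_mg_day", "therapy_start_dt", "role"],
        "reac": ["primaryid", "pt"],
        "outc": ["primaryid", "fatal"],
    }
    written: dict[str, Path] = {}
    for name, rows in (
        ("demo", demo_rows),
        ("drug", drug_rows),
        ("reac", reac_rows),
        ("outc", outc_rows),
    ):
        path = out / TABLE_FILES[name]
        pd.DataFrame(rows, columns=columns[name]).to_csv(path, sep=sep, index=False)
        written[name] = path
    delete_path = out / DELETE_FILE
    delete_path.write_text("".join(f"{pid}\n" for pid in deleted))
    written["delete"] = delete_path
    return written
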