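"""Reporting-odds-ratio disproportionality analysis.

For a target drug group and an event term, the 2x2 contingency table over
deduplicated cases is

=============  =========  =============
               event      no event
=============  =========  =============
drug group     ``a``      ``c``
all others     ``b``      ``d``
=============  =========  =============

and the reporting odds ratio is the cross-product ratio
``ROR = (a/c) / (b/d) = (a*d) / (b*c)`` with the Wald 95% confidence interval
``exp(ln ROR +/- z * sqrt(1/a + 1/b + 1/c + 1/d))`` (log-symmetric: the point
estimate is the geometric mean of its bounds).  A drug-event pair is a signal
when at least ``min_cases`` cases report the event under the drug group and
the lower CI bound exceeds one.  The comparator is every case in the loaded
dataset with no exposure to the target drug group.

Counting is case-level throughout: a case contributes at most one to each
cell regardless of how many group drugs or matching reactions it carries.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import ALL_PPI_GROUP, STUDY_PPIS
from .meddra import MedDRAHierarchy, normalize_term

logger = logging.getLogger(__name__)

Z_95 = 1.96


class DegenerateTableError(ValueError):
    """Raised when a contingency table has an empty margin."""


class UnknownEventError(KeyError):
    """Raised when an event label is absent from the hierarchy."""


@dataclass(frozen=True)
class ContingencyTable:
    """Case-level 2x2 cells for one (drug group, event) pair."""

    a: int
    b: int
    c: int
    d: int
    drug_group: str = ""
    event: str = ""

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or int(cell) != cell:
                raise ValueError("contingency cells must be non-negative integers")

    @property
    def n_target(self) -> int:
        return self.a + self.c

    @property
    def n_comparator(self) -> int:
        return self.b + self.d


@dataclass(frozen=True)
class SignalResult:
    """ROR point estimate, 95% CI and the signal flag for one pair."""

    drug_group: str
    event: str
    a: int
    b: int
    c: int
    d: int
    ror: float
    ci_low: float
    ci_high: float
    n_cases: int
    is_signal: bool
    correction_applied: bool


def compute_ror(
    table: ContingencyTable,
    correction: str = "haldane",
    z: float = Z_95,
    min_cases: int = 3,
) -> SignalResult:
    """Compute the ROR and Wald CI for one table.

    ``correction`` is ``"haldane"`` (add 0.5 to every cell, applied only when
    some cell is zero) or ``"none"`` (zero cells yield non-finite estimates,
    flagged but not raised).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + c == 0 or b + d == 0:
        raise DegenerateTableError(
            f"empty margin in table ({a}, {b}, {c}, {d}) for "
            f"{table.drug_group!r} x {table.event!r}"
        )
    has_zero = min(a, b, c, d) == 0
    corrected = has_zero and correction == "haldane"
    if corrected:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aa, bb, cc, dd = float(a), float(b), float(c), float(d)

    if min(aa, bb, cc, dd) == 0.0:
        # correction == "none" with a zero cell: non-finite, not an exception
        if (aa == 0.0 or dd == 0.0) and (bb == 0.0 or cc == 0.0):
            ror = math.nan
        elif bb == 0.0 or cc == 0.0:
            ror = math.inf
        else:
            ror = 0.0
        return SignalResult(
            drug_group=table.drug_group,
            event=table.event,
            a=a,
            b=b,
            c=c,
            d=d,
            ror=ror,
            ci_low=math.nan,
            ci_high=math.nan,
            n_cases=a,
            is_signal=False,
            correction_applied=False,
        )

    ror = (aa * dd) / (bb * cc)
    se = math.sqrt(1.0 / aa + 1.0 / bb + 1.0 / cc + 1.0 / dd)
    ci_low = math.exp(math.log(ror) - z * se)
    ci_high = math.exp(math.log(ror) + z * se)
    return SignalResult(
        drug_group=table.drug_group,
        event=table.event,
        a=a,
        b=b,
        c=c,
        d=d,
        ror=ror,
        ci_low=ci_low,
        ci_high=ci_high,
        n_cases=a,
        is_signal=a >= min_cases and ci_low > 1.0,
        correction_applied=corrected,
    )


def implied_point(ci_low: float, ci_high: float) -> float:
    """Point estimate implied by a log-symmetric CI (geometric mean of bounds)."""
    return math.exp((math.log(ci_low) + math.log(ci_high)) / 2.0)


def build_table(
    cases: Sequence,
    drug_group: Iterable[str],
    event: str | Iterable[str],
    hierarchy: MedDRAHierarchy | None = None,
    drug_group_label: str | None = None,
    event_label: str | None = None,
) -> ContingencyTable:
    """Case-level 2x2 table for one drug group and one event (or event set)."""
    group = {normalize_term(d) for d in drug_group}
    if not group:
        raise ValueError("drug_group must be non-empty")
    if isinstance(event, str):
        event_terms = {normalize_term(event)}
        label = event_label or event
    else:
        event_terms = {normalize_term(e) for e in event}
        label = event_label or "|".join(sorted(event_terms))
    if hierarchy is not None:
        unknown = [e for e in event_terms if e not in hierarchy.paths]
        if unknown:
            raise UnknownEventError(f"event label(s) not in hierarchy: {unknown}")

    a = b = c = d = 0
    for case in cases:
        exposed = any(normalize_term(d.name) in group for d in case.drugs)
        has_event = any(normalize_term(pt) in event_terms for pt in case.reactions)
        if exposed and has_event:
            a += 1
        elif exposed:
            c += 1
        elif has_event:
            b += 1
        else:
            d += 1
    return ContingencyTable(
        a=a,
        b=b,
        c=c,
        d=d,
        drug_group=drug_group_label or "|".join(sorted(group)),
        event=label,
    )


def default_drug_groups(
    study_drugs: Sequence[str] = STUDY_PPIS,
) -> dict[str, tuple[str, ...]]:
    """Per-drug groups for each study PPI plus the combined group."""
    groups: dict[str, tuple[str, ...]] = {d: (d,) for d in study_drugs}
    groups[ALL_PPI_GROUP] = tuple(study_drugs)
    return groups


def scan_all(
    cases: Sequence,
    hierarchy: MedDRAHierarchy,
    drug_groups: Mapping[str, Sequence[str]] | None = None,
    min_cases: int = 3,
    z: float = Z_95,
    correction: str = "haldane",
    events: Sequence[str] | None = None,
    include_zero_a: bool = False,
) -> list[SignalResult]:
    """Scan every (drug group, tumor PT) pair and flag signals.

    Results with ``a == 0`` are skipped unless ``include_zero_a``; pairs with
    fewer than ``min_cases`` cases always carry ``is_signal=False``.  Output
    is sorted with signals first (descending ROR), then the remaining pairs.
    """
    if drug_groups is None:
        drug_groups = default_drug_groups()
    if events is None:
        events = hierarchy.tumor_display_labels()

    n = len(cases)
    # Single pass over cases: per-drug and per-event boolean masks.
    member_drugs = {
        normalize_term(d) for drugs in drug_groups.values() for d in drugs
    }
    event_keys = {}
    for pt in events:
        key = normalize_term(pt)
        if key not in hierarchy.paths:
            raise UnknownEventError(f"event label not in hierarchy: {pt!r}")
        event_keys[pt] = key
    drug_masks: dict[str, np.ndarray] = {d: np.zeros(n, dtype=bool) for d in member_drugs}
    event_masks: dict[str, np.ndarray] = {pt: np.zeros(n, dtype=bool) for pt in events}
    key_to_pt = {key: pt for pt, key in event_keys.items()}
    for i, case in enumerate(cases):
        for d in case.drugs:
            mask = drug_masks.get(normalize_term(d.name))
            if mask is not None:
                mask[i] = True
        for pt in case.reactions:
            label = key_to_pt.get(normalize_term(pt))
            if label is not None:
                event_masks[label][i] = True

    exposure = {}
    for label, drugs in drug_groups.items():
        members = [drug_masks[normalize_term(d)] for d in drugs]
        exposure[label] = np.logical_or.reduce(members) if members else np.zeros(n, bool)

    results: list[SignalResult] = []
    for glabel, exp_mask in exposure.items():
        n_exposed = int(exp_mask.sum())
        for pt, ev_mask in event_masks.items():
            a = int((exp_mask & ev_mask).sum())
            if a == 0 and not include_zero_a:
                continue
            b = int(ev_mask.sum()) - a
            c = n_exposed - a
            d = n - n_exposed - b
            table = ContingencyTable(
                a=a, b=b, c=c, d=d, drug_group=glabel, event=pt
            )
            try:
                results.append(
                    compute_ror(table, correction=correction, z=z, min_cases=min_cases)
                )
            except DegenerateTableError:
                logger.warning("degenerate table for %s x %s skipped", glabel, pt)
    results.sort(
        key=lambda r: (
            not r.is_signal,
            -(r.ror if math.isfinite(r.ror) else math.inf if r.is_signal else 0.0),
        )
    )
    return results


def results_frame(results: Sequence[SignalResult]) -> pd.DataFrame:
    """Tabular view of scan results."""
    return pd.DataFrame(
        [
            {
                "drug_group": r.drug_group,
                "event": r.event,
                "a": r.a,
                "b": r.b,
                "c": r.c,
                "d": r.d,
                "ror": r.ror,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "n_cases": r.n_cases,
                "is_signal": r.is_signal,
                "correction_applied": r.correction_applied,
            }
            for r in results
        ]
    )


def ror_matrix(results: Sequence[SignalResult]) -> pd.DataFrame:
    """Wide drugs-x-events matrix of ROR values (heatmap-style export)."""
    frame = results_frame(results)
    if frame.empty:
        return frame
    return frame.pivot_table(
        index="drug_group", columns="event", values="ror", aggfunc="first"
    )
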