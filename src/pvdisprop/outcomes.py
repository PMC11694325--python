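"""Descriptive epidemiology of the tumor-event case set.

Covers the stratified clinical-feature summary (fatal vs non-fatal, with
Wilcoxon rank-sum / Pearson chi-square / Fisher exact group tests), annual
tumor-event proportions, tumor-site aggregation, the co-reported-AE profile
and time-to-onset analysis (Kaplan-Meier event-free curves with log-rank and
Mann-Whitney comparisons).

Conventions pinned for reproducibility:

* quantiles (median, IQR) use linear interpolation between order statistics;
* the group test is Pearson chi-square, switching to Fisher exact for 2x2
  tables with any expected cell below 5 (larger sparse tables keep chi-square
  with a low-expected-count note);
* time to onset runs from the earliest suspect study-drug therapy start to
  the event date; cases missing either date are excluded and counted;
* calendar periods are left-closed five-year bins [2000, 2005), ...;
* a missing fatal outcome counts as non-fatal.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from . import STUDY_PPIS
from .meddra import MedDRAHierarchy, UNSPECIFIED_SITE, normalize_term

logger = logging.getLogger(__name__)

YEAR_BINS = ((2000, 2005), (2005, 2010), (2010, 2015), (2015, 2020), (2020, 2025))

COUNTRY_BUCKETS = ("GB", "JP", "US")


@dataclass(frozen=True)
class StratumSummary:
    """One stratum of one variable, split by fatal outcome."""

    variable: str
    stratum: str
    overall_n: int
    overall_pct: float
    fatal_n: int
    fatal_pct: float
    nonfatal_n: int
    nonfatal_pct: float


@dataclass(frozen=True)
class ContinuousSummary:
    """Median and IQR of a continuous variable, split by fatal outcome."""

    variable: str
    overall: tuple[float, float, float]  # (median, q25, q75)
    fatal: tuple[float, float, float]
    nonfatal: tuple[float, float, float]
    n_missing: int


@dataclass
class TestResult:
    variable: str
    test: str
    statistic: float
    p_value: float
    note: str = ""


@dataclass
class Table1:
    """Stratified clinical-feature summary of the tumor-event case set."""

    n_total: int
    n_fatal: int
    n_nonfatal: int
    categorical: list[StratumSummary]
    continuous: list[ContinuousSummary]
    tests: dict[str, TestResult]

    @property
    def fatality_pct(self) -> float:
        return 100.0 * self.n_fatal / self.n_total

    def frame(self) -> pd.DataFrame:
        rows = [
            {
                "variable": s.variable,
                "stratum": s.stratum,
                "overall_n": s.overall_n,
                "overall_pct": s.overall_pct,
                "fatal_n": s.fatal_n,
                "fatal_pct": s.fatal_pct,
                "nonfatal_n": s.nonfatal_n,
                "nonfatal_pct": s.nonfatal_pct,
                "test": self.tests[s.variable].test if s.variable in self.tests else "",
                "p_value": self.tests[s.variable].p_value
                if s.variable in self.tests
                else math.nan,
            }
            for s in self.categorical
        ]
        def fmt(t: tuple[float, float, float]) -> str:
            return f"{t[0]:g} ({t[1]:g}, {t[2]:g})"

        for c in self.continuous:
            rows.append(
                {
                    "variable": c.variable,
                    "stratum": f"median (IQR): overall {fmt(c.overall)}; "
                    f"fatal {fmt(c.fatal)}; non-fatal {fmt(c.nonfatal)}",
                    "overall_n": self.n_total - c.n_missing,
                    "overall_pct": math.nan,
                    "fatal_n": math.nan,
                    "fatal_pct": math.nan,
                    "nonfatal_n": math.nan,
                    "nonfatal_pct": math.nan,
                    "test": self.tests[c.variable].test if c.variable in self.tests else "",
                    "p_value": self.tests[c.variable].p_value
                    if c.variable in self.tests
                    else math.nan,
                }
            )
        return pd.DataFrame(rows)


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, 25th, 75th percentile) with linear interpolation."""
    arr = np.asarray([v for v in values if v is not None and not pd.isna(v)], float)
    if arr.size == 0:
        return (math.nan, math.nan, math.nan)
    q25, med, q75 = np.percentile(arr, [25, 50, 75], method="linear")
    return (float(med), float(q25), float(q75))


def _is_fatal(case) -> bool:
    return bool(case.outcome_fatal) if case.outcome_fatal is not None else False


def _case_group(case, study_drugs: Sequence[str]) -> str | None:
    study = {normalize_term(d): d for d in study_drugs}
    for d in case.drugs:
        key = normalize_term(d.name)
        if key in study and d.suspect:
            return study[key]
    for d in case.drugs:  # fall back to any study-drug mention
        key = normalize_term(d.name)
        if key in study:
            return study[key]
    return None


def _earliest_study_start(case, study_drugs: Sequence[str]):
    study = {normalize_term(d) for d in study_drugs}
    starts = [
        d.start_dt
        for d in case.drugs
        if normalize_term(d.name) in study and d.start_dt is not None
    ]
    return min(starts) if starts else None


def onset_days(case, study_drugs: Sequence[str] = STUDY_PPIS) -> float | None:
    """Days from earliest study-drug therapy start to the event date."""
    start = _earliest_study_start(case, study_drugs)
    if start is None or case.event_dt is None:
        return None
    return float((case.event_dt - start).days)


def _year_bin(year: int) -> str | None:
    for lo, hi in YEAR_BINS:
        if lo <= year < hi:
            return f"{lo}-{hi}"
    return None


def _case_year(case) -> int | None:
    if case.event_dt is not None:
        return case.event_dt.year
    if case.fda_dt is not None:
        return case.fda_dt.year
    return None


def _categorical_test(counts: pd.DataFrame, variable: str) -> TestResult:
    """Pearson chi-square, or Fisher exact for sparse 2x2 tables."""
    table = counts.loc[(counts.sum(axis=1) > 0), counts.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return TestResult(
            variable, "skipped", math.nan, math.nan, note="single populated stratum"
        )
    expected = stats.contingency.expected_freq(table.to_numpy())
    if (expected < 5).any() and table.shape == (2, 2):
        odds, p = stats.fisher_exact(table.to_numpy())
        return TestResult(variable, "fisher_exact", float(odds), float(p))
    chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    note = "expected cell < 5" if (expected < 5).any() else ""
    return TestResult(variable, "pearson_chi2", float(chi2), float(p), note=note)


def _rank_test(fatal_vals, nonfatal_vals, variable: str) -> TestResult:
    if len(fatal_vals) == 0 or len(nonfatal_vals) == 0:
        return TestResult(variable, "skipped", math.nan, math.nan, note="empty group")
    stat, p = stats.mannwhitneyu(fatal_vals, nonfatal_vals, alternative="two-sided")
    return TestResult(variable, "wilcoxon_rank_sum", float(stat), float(p))


def summarize_table1(
    cases: Sequence, study_drugs: Sequence[str] = STUDY_PPIS
) -> Table1:
    """Clinical-feature summary of a tumor-event case set, split by fatality."""
    if not cases:
        raise ValueError("empty case set")
    fatal_flags = [_is_fatal(c) for c in cases]
    n_total = len(cases)
    n_fatal = sum(fatal_flags)

    def strata_for(variable: str, labels: Sequence[str], values: Sequence[str | None]):
        out = []
        counts = pd.DataFrame(
            0, index=list(labels), columns=["fatal", "nonfatal"], dtype=int
        )
        for val, fat in zip(values, fatal_flags):
            if val is None:
                continue
            counts.loc[val, "fatal" if fat else "nonfatal"] += 1
        total_col = counts.sum(axis=1)
        denom = total_col.sum()
        for label in labels:
            t = int(total_col[label])
            f = int(counts.loc[label, "fatal"])
            nf = int(counts.loc[label, "nonfatal"])
            out.append(
                StratumSummary(
                    variable=variable,
                    stratum=label,
                    overall_n=t,
                    overall_pct=100.0 * t / denom if denom else math.nan,
                    fatal_n=f,
                    fatal_pct=100.0 * f / counts["fatal"].sum()
                    if counts["fatal"].sum()
                    else 0.0,
                    nonfatal_n=nf,
                    nonfatal_pct=100.0 * nf / counts["nonfatal"].sum()
                    if counts["nonfatal"].sum()
                    else 0.0,
                )
            )
        return out, counts

    categorical: list[StratumSummary] = []
    tests: dict[str, TestResult] = {}

    sex_vals = [c.sex if c.sex in ("female", "male") else "missing" for c in cases]
    strata, counts = strata_for("sex", ("female", "male", "missing"), sex_vals)
    categorical += strata
    tests["sex"] = _categorical_test(counts.T, "sex")

    def bucket_country(c):
        if c.reporter_country is None or c.reporter_country == "":
            return "missing"
        return c.reporter_country if c.reporter_country in COUNTRY_BUCKETS else "OTHER"

    country_vals = [bucket_country(c) for c in cases]
    strata, counts = strata_for(
        "reporter_country", ("GB", "JP", "US", "OTHER", "missing"), country_vals
    )
    categorical += strata
    tests["reporter_country"] = _categorical_test(counts.T, "reporter_country")

    group_vals = [_case_group(c, study_drugs) for c in cases]
    strata, counts = strata_for("group", tuple(study_drugs), group_vals)
    categorical += strata
    tests["group"] = _categorical_test(counts.T, "group")

    year_vals = []
    for c in cases:
        year = _case_year(c)
        year_vals.append(_year_bin(year) if year is not None else None)
    year_labels = [f"{lo}-{hi}" for lo, hi in YEAR_BINS]
    strata, counts = strata_for("year", tuple(year_labels), year_vals)
    categorical += strata
    tests["year"] = _categorical_test(counts.T, "year")

    continuous: list[ContinuousSummary] = []
    ages = [c.age for c in cases]
    age_f = [a for a, fat in zip(ages, fatal_flags) if fat and a is not None]
    age_nf = [a for a, fat in zip(ages, fatal_flags) if not fat and a is not None]
    continuous.append(
        ContinuousSummary(
            variable="age",
            overall=median_iqr(ages),
            fatal=median_iqr(age_f),
            nonfatal=median_iqr(age_nf),
            n_missing=sum(a is None for a in ages),
        )
    )
    tests["age"] = _rank_test(age_f, age_nf, "age")

    tto = [onset_days(c, study_drugs) for c in cases]
    tto_f = [t for t, fat in zip(tto, fatal_flags) if fat and t is not None]
    tto_nf = [t for t, fat in zip(tto, fatal_flags) if not fat and t is not None]
    continuous.append(
        ContinuousSummary(
            variable="time_to_event",
            overall=median_iqr(tto),
            fatal=median_iqr(tto_f),
            nonfatal=median_iqr(tto_nf),
            n_missing=sum(t is None for t in tto),
        )
    )
    tests["time_to_event"] = _rank_test(tto_f, tto_nf, "time_to_event")

    return Table1(
        n_total=n_total,
        n_fatal=n_fatal,
        n_nonfatal=n_total - n_fatal,
        categorical=categorical,
        continuous=continuous,
        tests=tests,
    )


def annual_proportions(cases: Sequence, is_tae: Sequence[bool]) -> pd.DataFrame:
    """Per-year tumor-event counts and percentages over all cases."""
    rows: dict[int, list[int]] = {}
    for case, flag in zip(cases, is_tae):
        year = _case_year(case)
        if year is None:
            continue
        cell = rows.setdefault(year, [0, 0])
        cell[0] += int(bool(flag))
        cell[1] += 1
    frame = pd.DataFrame(
        [
            {"year": y, "tae_n": t, "total_n": n, "percent": 100.0 * t / n}
            for y, (t, n) in sorted(rows.items())
        ]
    )
    return frame


def tumor_site_profile(
    tae_cases: Sequence, hierarchy: MedDRAHierarchy
) -> pd.DataFrame:
    """Per-site tumor-case counts and fatality shares.

    Each case is assigned exactly one site — the site of its alphabetically
    first matched tumor PT — so the site percentages partition to 100%.
    """
    site_counts: dict[str, int] = {}
    site_fatal: dict[str, int] = {}
    n_fatal_total = 0
    for case in tae_cases:
        matched = sorted(
            pt for pt in case.reactions if hierarchy.is_tumor(pt)
        )
        if not matched:
            continue
        site = hierarchy.site(matched[0]) or UNSPECIFIED_SITE
        site_counts[site] = site_counts.get(site, 0) + 1
        if _is_fatal(case):
            site_fatal[site] = site_fatal.get(site, 0) + 1
            n_fatal_total += 1
    n_total = sum(site_counts.values())
    return pd.DataFrame(
        [
            {
                "site": site,
                "n": n,
                "pct_of_taes": 100.0 * n / n_total if n_total else 0.0,
                "n_fatal": site_fatal.get(site, 0),
                "pct_of_fatal": 100.0 * site_fatal.get(site, 0) / n_fatal_total
                if n_fatal_total
                else 0.0,
            }
            for site, n in sorted(site_counts.items(), key=lambda kv: -kv[1])
        ]
    )


@dataclass
class CoReportSummary:
    """Share of tumor cases carrying co-reported (non-tumor) reactions."""

    n_taes: int
    n_with_co: int
    soc_table: pd.DataFrame  # SOC, n, pct of co-AE cases
    pt_table: pd.DataFrame  # PT, SOC, n, pct of co-AE cases

    @property
    def share_with_co_pct(self) -> float:
        return 100.0 * self.n_with_co / self.n_taes if self.n_taes else 0.0


def co_reported_profile(
    tae_cases: Sequence, hierarchy: MedDRAHierarchy
) -> CoReportSummary:
    """Co-reported-AE profile of the tumor case set.

    A co-AE is any non-tumor reaction on a tumor case; each case credits a
    SOC (or PT) at most once.  Percentages use the cases-with-any-co-AE
    denominator.
    """
    n_with_co = 0
    soc_counts: dict[str, int] = {}
    pt_counts: dict[str, int] = {}
    pt_soc: dict[str, str] = {}
    for case in tae_cases:
        co_pts = {
            hierarchy.display(pt)
            for pt in case.reactions
            if not hierarchy.is_tumor(pt)
        }
        if not co_pts:
            continue
        n_with_co += 1
        case_socs = set()
        for pt in co_pts:
            pt_counts[pt] = pt_counts.get(pt, 0) + 1
            soc = hierarchy.soc(pt) or "unknown"
            pt_soc[pt] = soc
            case_socs.add(soc)
        for soc in case_socs:
            soc_counts[soc] = soc_counts.get(soc, 0) + 1

    denom = n_with_co if n_with_co else 1
    soc_table = pd.DataFrame(
        [
            {"soc": soc, "n": n, "pct_of_co_cases": 100.0 * n / denom}
            for soc, n in sorted(soc_counts.items(), key=lambda kv: -kv[1])
        ]
    )
    pt_table = pd.DataFrame(
        [
            {
                "pt": pt,
                "soc": pt_soc[pt],
                "n": n,
                "pct_of_co_cases": 100.0 * n / denom,
            }
            for pt, n in sorted(pt_counts.items(), key=lambda kv: -kv[1])
        ]
    )
    return CoReportSummary(
        n_taes=len(tae_cases),
        n_with_co=n_with_co,
        soc_table=soc_table,
        pt_table=pt_table,
    )


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit event-free curve for one group."""

    group: str
    times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
            }
        )


@dataclass
class KMResult:
    curves: dict[str, SurvivalCurve]
    logrank_statistic: float
    logrank_p: float
    mannwhitney_statistic: float | None = None
    mannwhitney_p: float | None = None
    n_excluded: int = 0


def time_to_onset_frame(
    cases: Sequence,
    group_by: str = "group",
    study_drugs: Sequence[str] = STUDY_PPIS,
) -> tuple[pd.DataFrame, int]:
    """Onset days per case with a grouping label.

    ``group_by`` is ``"group"`` (suspect study drug) or ``"fatal"``.  Cases
    with missing therapy-start or event date are excluded and counted.
    """
    rows = []
    n_excluded = 0
    for case in cases:
        days = onset_days(case, study_drugs)
        if days is None or days < 0:
            n_excluded += 1
            continue
        if group_by == "fatal":
            label = "fatal" if _is_fatal(case) else "non-fatal"
        else:
            label = _case_group(case, study_drugs) or "other"
        rows.append({"days": days, "group": label, "observed": 1})
    return pd.DataFrame(rows, columns=["days", "group", "observed"]), n_excluded


def km_curve(
    tto: pd.DataFrame,
    durations_col: str = "days",
    group_col: str = "group",
    observed_col: str = "observed",
) -> KMResult:
    """Kaplan-Meier event-free curves per group, log-rank across groups and
    Mann-Whitney on raw onset days for two-group comparisons.

    With no censoring the product-limit estimate equals the empirical
    survival function.  Groups with zero cases are dropped with a warning.
    """
    curves: dict[str, SurvivalCurve] = {}
    groups = [g for g, sub in tto.groupby(group_col) if len(sub) > 0]
    if not groups:
        raise ValueError("no non-empty groups for Kaplan-Meier analysis")
    for g in groups:
        sub = tto[tto[group_col] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub[durations_col], event_observed=sub[observed_col], label=str(g))
        table = kmf.event_table
        # keep the actual event/censoring times (drop the synthetic t=0 row)
        keep = (table["removed"] > 0).to_numpy()
        times = table.index.to_numpy(dtype=float)[keep]
        survival = (
            kmf.survival_function_.iloc[:, 0]
            .reindex(table.index, method="ffill")
            .to_numpy()[keep]
        )
        curves[str(g)] = SurvivalCurve(
            group=str(g),
            times=times,
            at_risk=table["at_risk"].to_numpy()[keep],
            events=table["observed"].to_numpy()[keep],
            survival=survival,
        )

    if len(groups) >= 2:
        lr = multivariate_logrank_test(
            tto[durations_col], tto[group_col], tto[observed_col]
        )
        lr_stat, lr_p = float(lr.test_statistic), float(lr.p_value)
    else:
        lr_stat, lr_p = math.nan, math.nan
        logger.warning("log-rank test skipped: fewer than two groups")

    mw_stat = mw_p = None
    if len(groups) == 2:
        x = tto.loc[tto[group_col] == groups[0], durations_col]
        y = tto.loc[tto[group_col] == groups[1], durations_col]
        method = "exact" if max(len(x), len(y)) <= 8 else "auto"
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        mw_stat, mw_p = float(stat), float(p)
    return KMResult(
        curves=curves,
        logrank_statistic=lr_stat,
        logrank_p=lr_p,
        mannwhitney_statistic=mw_stat,
        mannwhitney_p=mw_p,
    )
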