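"""Descriptive summaries, group tests, site/co-AE profiles, survival analysis."""
import datetime as dt
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pvdisprop import meddra, outcomes
from pvdisprop.ingest import ReportCase
from pvdisprop.outcomes import (
    annual_proportions,
    co_reported_profile,
    km_curve,
    median_iqr,
    summarize_table1,
    time_to_onset_frame,
    tumor_site_profile,
)
from pvdisprop.synthetic_faers import DrugExposure


def make_case(
    caseid,
    reactions=("Gastric cancer",),
    fatal=False,
    age=59.0,
    sex="female",
    country="US",
    drug="esomeprazole",
    event=dt.date(2021, 6, 1),
    start=dt.date(2015, 6, 1),
):
    return ReportCase(
        primaryid=caseid,
        caseid=caseid,
        fda_dt=event,
        age=age,
        sex=sex,
        weight_kg=70.0,
        reporter_country=country,
        drugs=(DrugExposure(drug, 20.0, start, True),),
        reactions=tuple(reactions),
        event_dt=event,
        outcome_fatal=fatal,
    )


def test_median_iqr_linear_interpolation():
    med, q25, q75 = median_iqr([50.0, 59.0, 70.0])
    assert (med, q25, q75) == (59.0, 54.5, 64.5)


def test_median_iqr_ignores_missing():
    med, _, _ = median_iqr([None, 10.0, float("nan"), 20.0, 30.0])
    assert med == 20.0


class TestTable1:
    def test_percent_partition_and_tests(self):
        cases = [
            make_case(i, fatal=i < 4, sex="male" if i % 2 else "female")
            for i in range(10)
        ]
        t1 = summarize_table1(cases)
        assert t1.n_fatal == 4 and t1.n_nonfatal == 6
        for variable in ("sex", "group", "reporter_country", "year"):
            strata = [s for s in t1.categorical if s.variable == variable]
            assert sum(s.overall_pct for s in strata) == pytest.approx(100.0)
            assert sum(s.overall_n for s in strata) == len(cases)

    def test_single_stratum_test_skipped_with_reason(self):
        cases = [make_case(i) for i in range(6)]
        t1 = summarize_table1(cases)
        assert t1.tests["group"].test == "skipped"
        assert t1.tests["group"].note

    def test_missing_stratum_is_a_stratum(self):
        cases = [make_case(1, sex="missing"), make_case(2, sex="female")]
        t1 = summarize_table1(cases)
        sex = {s.stratum: s.overall_n for s in t1.categorical if s.variable == "sex"}
        assert sex["missing"] == 1

    def test_empty_case_set_rejected(self):
        with pytest.raises(ValueError):
            summarize_table1([])

    def test_rank_test_matches_scipy_direct(self):
        cases = [
            make_case(i, fatal=(i < 5), age=float(30 + 7 * i)) for i in range(12)
        ]
        t1 = summarize_table1(cases)
        fatal_ages = [30.0 + 7 * i for i in range(5)]
        nonfatal_ages = [30.0 + 7 * i for i in range(5, 12)]
        _, p = stats.mannwhitneyu(fatal_ages, nonfatal_ages, alternative="two-sided")
        assert t1.tests["age"].p_value == pytest.approx(p)


class TestAnnualProportions:
    def test_partition_and_percent(self):
        cases = [make_case(i, event=dt.date(2010 + (i % 2), 1, 1)) for i in range(10)]
        flags = [i < 3 for i in range(10)]
        frame = annual_proportions(cases, flags)
        assert frame["total_n"].sum() == 10
        assert frame["tae_n"].sum() == 3
        year_2010 = frame.set_index("year").loc[2010]
        assert year_2010["percent"] == pytest.approx(
            100.0 * year_2010["tae_n"] / year_2010["total_n"]
        )

    def test_constant_rate_within_binomial_band(self, hierarchy):
        rng = np.random.default_rng(42)
        rate = 0.03
        cases, flags = [], []
        for i in range(4000):
            year = 2005 + (i % 10)
            flag = bool(rng.random() < rate)
            cases.append(make_case(i, event=dt.date(year, 1, 1)))
            flags.append(flag)
        frame = annual_proportions(cases, flags)
        for row in frame.itertuples():
            low, high = stats.binom.interval(0.999, row.total_n, rate)
            assert low <= row.tae_n <= high


class TestSiteProfile:
    def test_gastric_terms_grouped_under_stomach(self, hierarchy):
        cases = [
            make_case(1, ["Gastric cancer"]),
            make_case(2, ["Gastric adenocarcinoma"], fatal=True),
            make_case(3, ["Metastatic gastric cancer"]),
            make_case(4, ["Gastric cancer stage III"]),
            make_case(5, ["Renal cell carcinoma"]),
        ]
        profile = tumor_site_profile(cases, hierarchy)
        by_site = profile.set_index("site")
        assert by_site.loc["stomach", "n"] == 4
        assert by_site.loc["kidney", "n"] == 1
        assert by_site.loc["stomach", "pct_of_fatal"] == 100.0

    def test_percents_partition(self, small_cases, hierarchy):
        cl = meddra.classify_cases(small_cases, hierarchy)
        taes = [small_cases[i] for i in cl.tae_indices()]
        profile = tumor_site_profile(taes, hierarchy)
        assert profile["pct_of_taes"].sum() == pytest.approx(100.0)
        assert profile["n"].sum() == len(taes)

    def test_empty_fatal_set_gives_zero_shares(self, hierarchy):
        profile = tumor_site_profile([make_case(1, ["Gastric cancer"])], hierarchy)
        assert (profile["pct_of_fatal"] == 0).all()


class TestCoReported:
    def test_hand_counted_share(self, hierarchy):
        cases = [make_case(i, ["Gastric cancer", "Diarrhoea"]) for i in range(8)]
        cases += [make_case(8, ["Gastric cancer"]), make_case(9, ["Renal cancer"])]
        summary = co_reported_profile(cases, hierarchy)
        assert summary.n_taes == 10 and summary.n_with_co == 8
        assert summary.share_with_co_pct == pytest.approx(80.0)

    def test_soc_credited_once_per_case(self, hierarchy):
        cases = [make_case(1, ["Gastric cancer", "Diarrhoea", "Nausea", "Renal cyst"])]
        summary = co_reported_profile(cases, hierarchy)
        soc = summary.soc_table.set_index("soc")
        assert soc.loc["Gastrointestinal disorders", "n"] == 1
        assert soc.loc["Renal and urinary disorders", "n"] == 1

    def test_tumor_only_case_counts_as_no_co_ae(self, hierarchy):
        summary = co_reported_profile(
            [make_case(1, ["Gastric cancer", "Renal cancer"])], hierarchy
        )
        assert summary.n_with_co == 0


class TestSurvival:
    def test_uncensored_km_equals_empirical_survival(self):
        tto = pd.DataFrame(
            {"days": [1.0, 2.0, 3.0], "group": ["all"] * 3, "observed": [1, 1, 1]}
        )
        km = km_curve(tto)
        curve = km.curves["all"]
        assert curve.times.tolist() == [1.0, 2.0, 3.0]
        assert curve.survival.tolist() == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert curve.at_risk.tolist() == [3, 2, 1]

    def test_product_limit_with_censoring_matches_hand_calculation(self):
        # subjects: events at 1, 2, 3, 4; censored at 2
        tto = pd.DataFrame(
            {
                "days": [1.0, 2.0, 2.0, 3.0, 4.0],
                "group": ["all"] * 5,
                "observed": [1, 1, 0, 1, 1],
            }
        )
        curve = km_curve(tto).curves["all"]
        # S(1)=4/5; S(2)=4/5*3/4=3/5; S(3)=3/5*1/2=3/10; S(4)=0
        by_time = dict(zip(curve.times.tolist(), curve.survival.tolist()))
        assert by_time[1.0] == pytest.approx(0.8)
        assert by_time[2.0] == pytest.approx(0.6)
        assert by_time[3.0] == pytest.approx(0.3)
        assert by_time[4.0] == pytest.approx(0.0)

    def test_identical_groups_logrank_zero(self):
        days = [3.0, 5.0, 8.0, 13.0]
        tto = pd.DataFrame(
            {
                "days": days * 2,
                "group": ["a"] * 4 + ["b"] * 4,
                "observed": [1] * 8,
            }
        )
        km = km_curve(tto)
        assert km.logrank_statistic == pytest.approx(0.0, abs=1e-12)
        assert km.logrank_p == pytest.approx(1.0)
        assert km.mannwhitney_p == pytest.approx(1.0)

    def test_mannwhitney_exact_matches_enumeration(self):
        x = [1.0, 4.0, 6.0, 9.0]
        y = [2.0, 3.0, 7.0, 11.0, 12.0]
        tto = pd.DataFrame(
            {
                "days": x + y,
                "group": ["a"] * len(x) + ["b"] * len(y),
                "observed": [1] * (len(x) + len(y)),
            }
        )
        km = km_curve(tto)

        pooled = sorted(x + y)
        ranks = {v: i + 1 for i, v in enumerate(pooled)}
        observed_u = sum(ranks[v] for v in x) - len(x) * (len(x) + 1) / 2
        n_extreme = 0
        n_total = 0
        for combo in itertools.combinations(range(len(pooled)), len(x)):
            u = sum(c + 1 for c in combo) - len(x) * (len(x) + 1) / 2
            n_total += 1
            if abs(u - len(x) * len(y) / 2) >= abs(observed_u - len(x) * len(y) / 2):
                n_extreme += 1
        assert km.mannwhitney_p == pytest.approx(n_extreme / n_total)

    def test_time_to_onset_excludes_missing_dates(self):
        complete = make_case(1)
        missing_start = make_case(2)
        missing_start.drugs = (DrugExposure("esomeprazole", 20.0, None, True),)
        frame, n_excluded = time_to_onset_frame([complete, missing_start])
        assert len(frame) == 1 and n_excluded == 1
        assert frame["days"].iloc[0] == (
            complete.event_dt - complete.drugs[0].start_dt
        ).days


def test_fisher_exact_matches_hypergeometric_enumeration():
    # the sparse-table branch of the categorical test must agree with a
    # from-scratch hypergeometric enumeration
    tables = [
        np.array([[2, 7], [8, 2]]),
        np.array([[1, 9], [11, 3]]),
        np.array([[5, 0], [1, 4]]),
    ]
    for table in tables:
        _, p_scipy = stats.fisher_exact(table)
        row0 = table[0].sum()
        col0 = table[:, 0].sum()
        n = table.sum()
        observed_pmf = stats.hypergeom.pmf(table[0, 0], n, row0, col0)
        p_manual = sum(
            stats.hypergeom.pmf(k, n, row0, col0)
            for k in range(max(0, row0 + col0 - n), min(row0, col0) + 1)
            if stats.hypergeom.pmf(k, n, row0, col0) <= observed_pmf * (1 + 1e-9)
        )
        assert p_scipy == pytest.approx(p_manual)
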