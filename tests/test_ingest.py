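"""Deduplication rules, exclusion cascade, ledger conservation, readers."""
import datetime as dt
import random

import pytest

from pvdisprop import ingest
from pvdisprop.ingest import SchemaError, apply_exclusions, deduplicate
from pvdisprop.synthetic_faers import (
    DrugExposure,
    GeneratorConfig,
    RawReportRecord,
    generate_dataset,
    write_dataset,
)


def make_record(
    primaryid,
    caseid,
    fda=dt.date(2023, 1, 1),
    age=50.0,
    weight=70.0,
    drug="esomeprazole",
    suspect=True,
    deleted=False,
):
    return RawReportRecord(
        primaryid=primaryid,
        caseid=caseid,
        fda_dt=fda,
        age=age,
        sex="female",
        weight_kg=weight,
        reporter_country="US",
        drugs=(DrugExposure(drug, 20.0, dt.date(2020, 1, 1), suspect),),
        reactions=("Gastric cancer",),
        event_dt=dt.date(2022, 1, 1),
        outcome_fatal=False,
        deleted=deleted,
    )


class TestDeduplicate:
    def test_latest_fda_dt_wins(self):
        records = [
            make_record(100, 7, fda=dt.date(2023, 1, 1)),
            make_record(101, 7, fda=dt.date(2023, 3, 1)),
        ]
        survivors, ledger = deduplicate(records)
        assert [r.primaryid for r in survivors] == [101]
        assert ledger.duplicate_cases_removed == 1

    def test_date_tie_broken_by_higher_primaryid(self):
        records = [
            make_record(100, 7, fda=dt.date(2023, 1, 1)),
            make_record(200, 7, fda=dt.date(2023, 1, 1)),
        ]
        survivors, _ = deduplicate(records)
        assert [r.primaryid for r in survivors] == [200]

    def test_missing_fda_dt_loses_to_any_dated_record(self):
        records = [
            make_record(999, 7, fda=None),
            make_record(1, 7, fda=dt.date(2004, 1, 1)),
        ]
        survivors, _ = deduplicate(records)
        assert [r.primaryid for r in survivors] == [1]

    def test_single_record_unchanged(self):
        records = [make_record(1, 1)]
        survivors, ledger = deduplicate(records)
        assert survivors == records
        assert ledger.duplicate_cases_removed == 0

    def test_idempotent_and_order_independent(self):
        base = [
            make_record(pid, cid, fda=dt.date(2023, 1, 1 + pid % 5))
            for pid, cid in [(1, 1), (2, 1), (3, 2), (4, 2), (5, 3), (6, 4)]
        ]
        once, _ = deduplicate(base)
        twice, ledger = deduplicate(once)
        assert twice == once
        assert ledger.duplicate_cases_removed == 0
        shuffled = base[:]
        random.Random(0).shuffle(shuffled)
        survivors_shuffled, _ = deduplicate(shuffled)
        assert {r.primaryid for r in survivors_shuffled} == {
            r.primaryid for r in once
        }


class TestExclusions:
    def test_age_boundaries(self):
        records = [
            make_record(1, 1, age=151.0),
            make_record(2, 2, age=150.0),
            make_record(3, 3, age=-1.0),
            make_record(4, 4, age=0.0),
        ]
        cases, ledger = apply_exclusions(records)
        assert {c.primaryid for c in cases} == {2, 4}
        assert ledger.age_out_of_range == 2

    def test_weight_boundary(self):
        records = [make_record(1, 1, weight=160.0), make_record(2, 2, weight=150.0)]
        cases, ledger = apply_exclusions(records)
        assert {c.primaryid for c in cases} == {2}
        assert ledger.weight_out_of_range == 1

    def test_missing_age_and_weight_retained(self):
        records = [make_record(1, 1, age=None, weight=None)]
        cases, ledger = apply_exclusions(records)
        assert len(cases) == 1
        assert ledger.stage_counts() == (0,) * len(ledger.STAGES)

    def test_delete_list_and_flagged_records_removed(self):
        records = [
            make_record(1, 1),
            make_record(2, 2, deleted=True),
            make_record(3, 3),
        ]
        cases, ledger = apply_exclusions(records, delete_ids={3})
        assert {c.primaryid for c in cases} == {1}
        assert ledger.delete_file_removed == 2

    def test_suspect_role_restriction(self):
        records = [
            make_record(1, 1, suspect=False),
            make_record(2, 2, suspect=True),
            make_record(3, 3, drug="metformin", suspect=True),
        ]
        cases, ledger = apply_exclusions(records, suspect_only=True)
        assert {c.primaryid for c in cases} == {2}
        assert ledger.no_suspect_study_drug == 2

    def test_exact_duplicate_rows_collapsed(self):
        twin_a = make_record(1, 1)
        twin_b = make_record(2, 2)  # identical content, new caseid/primaryid
        other = make_record(3, 3, age=60.0)
        cases, ledger = apply_exclusions([twin_a, twin_b, other])
        assert ledger.exact_duplicates_removed == 1
        assert {c.caseid for c in cases} == {1, 3}  # lowest caseid survives

    def test_exclusion_idempotence(self):
        records = [make_record(i, i, age=float(30 + i)) for i in range(1, 8)]
        records.append(make_record(99, 99, age=200.0))
        cases, _ = apply_exclusions(records)
        again, ledger = apply_exclusions(
            [make_record(c.primaryid, c.caseid, age=c.age) for c in cases]
        )
        assert len(again) == len(cases)
        assert sum(ledger.stage_counts()) == 0


def test_ledger_conservation_on_generated_data():
    records = generate_dataset(
        GeneratorConfig(
            n_cases=1500,
            seed=13,
            duplicate_rate=0.15,
            invalid_age_rate=0.02,
            invalid_weight_rate=0.02,
            delete_rate=0.02,
            nonsuspect_rate=0.05,
        )
    )
    cases, ledger = ingest.run(records, suspect_only=True)
    assert ledger.conserved()
    assert ledger.input_records == len(records)
    assert ledger.output_records == len(cases)
    assert len({c.caseid for c in cases}) == len(cases)
    for stage in ("duplicate_cases_removed", "delete_file_removed", "age_out_of_range"):
        assert getattr(ledger, stage) > 0


class TestReader:
    def test_round_trip_counts(self, tmp_path):
        records = generate_dataset(GeneratorConfig(n_cases=100, seed=6, duplicate_rate=0.1))
        write_dataset(records, tmp_path)
        back = ingest.read_dataset(tmp_path)
        assert len(back) == len(records)

    def test_missing_mandatory_column_raises(self, tmp_path):
        records = generate_dataset(GeneratorConfig(n_cases=5, seed=1))
        written = write_dataset(records, tmp_path)
        demo = written["demo"].read_text().splitlines()
        header = demo[0].split("\t")
        drop = header.index("caseid")
        rewritten = [
            "\t".join(v for i, v in enumerate(line.split("\t")) if i != drop)
            for line in demo
        ]
        written["demo"].write_text("\n".join(rewritten) + "\n")
        with pytest.raises(SchemaError, match="caseid"):
            ingest.read_dataset(tmp_path)

    def test_unknown_extra_column_ignored_with_warning(self, tmp_path, caplog):
        records = generate_dataset(GeneratorConfig(n_cases=5, seed=1))
        written = write_dataset(records, tmp_path)
        demo = written["demo"].read_text().splitlines()
        patched = [demo[0] + "\tmystery"] + [line + "\tx" for line in demo[1:]]
        written["demo"].write_text("\n".join(patched) + "\n")
        with caplog.at_level("WARNING"):
            back = ingest.read_dataset(tmp_path)
        assert len(back) == len(records)
        assert any("mystery" in message for message in caplog.messages)

    def test_unparseable_date_becomes_missing(self, tmp_path, caplog):
        records = generate_dataset(GeneratorConfig(n_cases=3, seed=1))
        written = write_dataset(records, tmp_path)
        demo = written["demo"].read_text().splitlines()
        header = demo[0].split("\t")
        idx = header.index("fda_dt")
        row = demo[1].split("\t")
        row[idx] = "not-a-date"
        demo[1] = "\t".join(row)
        written["demo"].write_text("\n".join(demo) + "\n")
        with caplog.at_level("WARNING"):
            back = ingest.read_dataset(tmp_path)
        assert back[0].fda_dt is None
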