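from __future__ import annotations

import math

import numpy as np
import pytest

from faerspv.cohort import CaseReport, DrugEntry, RegimenClass
from faerspv.descriptives import (
    OnsetRecord,
    compute_onset,
    compute_onsets,
    onset_bin_table,
    summarize_cohort,
    summarize_onset,
)
from faerspv.fixtures import SubgroupSpec, build_characteristic_cohort
from faerspv.synthetic import example_config, simulate_truth


def _report(event_dt="", starts=(), pid="1", regimen=RegimenClass.MONO):
    drugs = tuple(DrugEntry(name="avastin", start_dt=s) for s in starts) + (
        DrugEntry(name="aspirin", start_dt="20190101"),
    )
    return CaseReport(primaryid=pid, event_dt=event_dt, drugs=drugs, regimen=regimen)


def _onset(days, pid="1", regimen=RegimenClass.MONO):
    return OnsetRecord(primaryid=pid, regimen=regimen, onset_days=days)


class TestComputeOnset:
    def test_calendar_difference(self, lexicon):
        rec = compute_onset(_report("20200213", ("20200101",)), lexicon)
        assert rec.onset_days == 43

    def test_same_day_is_zero(self, lexicon):
        rec = compute_onset(_report("20200101", ("20200101",)), lexicon)
        assert rec.onset_days == 0

    def test_event_before_start_excluded(self, lexicon):
        rec = compute_onset(_report("20200101", ("20200301",)), lexicon)
        assert rec.exclusion_reason == "event_before_start"

    def test_partial_start_excluded(self, lexicon):
        rec = compute_onset(_report("20200601", ("202001",)), lexicon)
        assert rec.exclusion_reason == "partial_or_missing_start_date"

    def test_partial_event_excluded_first(self, lexicon):
        # both dates partial: the event-date rule fires first
        rec = compute_onset(_report("202006", ("202001",)), lexicon)
        assert rec.exclusion_reason == "partial_or_missing_event_date"

    def test_missing_event_excluded(self, lexicon):
        rec = compute_onset(_report("", ("20200101",)), lexicon)
        assert rec.exclusion_reason == "partial_or_missing_event_date"

    def test_earliest_full_index_start_used(self, lexicon):
        rec = compute_onset(
            _report("20200213", ("20200201", "20200101", "202001")), lexicon
        )
        assert rec.onset_days == 43

    def test_non_index_start_ignored(self, lexicon):
        # only the aspirin entry has a start date -> no usable index start
        rec = compute_onset(_report("20200213", (None,)), lexicon)
        assert rec.exclusion_reason == "partial_or_missing_start_date"

    def test_record_invariants(self):
        with pytest.raises(ValueError):
            OnsetRecord(primaryid="1", regimen=None)
        with pytest.raises(ValueError):
            OnsetRecord(primaryid="1", regimen=None, onset_days=-1)
        with pytest.raises(ValueError):
            OnsetRecord(primaryid="1", regimen=None, onset_days=1, exclusion_reason="event_before_start")

    def test_used_plus_excluded_equals_cohort(self, pipeline_result, lexicon):
        result, _ = pipeline_result
        target = [r for r in result.cohort if r.is_target_event]
        records = compute_onsets(target, lexicon)
        assert len(records) == len(target)
        used = sum(1 for r in records if r.usable)
        excluded = sum(1 for r in records if r.exclusion_reason is not None)
        assert used + excluded == len(target)


class TestSummarizeOnset:
    def test_odd_length_median(self):
        s = summarize_onset([_onset(d) for d in (10, 43, 100)])
        assert s.median_days == 43

    def test_even_length_type7_quartiles(self):
        s = summarize_onset([_onset(d) for d in (1, 2, 3, 4)])
        assert s.median_days == 2.5
        assert s.q1_days == 1.75
        assert s.q3_days == 3.25

    def test_quartile_order(self):
        rng = np.random.default_rng(1)
        s = summarize_onset([_onset(int(d)) for d in rng.integers(0, 400, 100)])
        assert s.q1_days <= s.median_days <= s.q3_days

    def test_empty_summary_marker(self):
        s = summarize_onset([])
        assert s.empty and s.n_used == 0 and math.isnan(s.median_days)

    def test_cdf_monotone_ends_at_one(self):
        rng = np.random.default_rng(2)
        s = summarize_onset([_onset(int(d)) for d in rng.integers(0, 400, 250)])
        fracs = [f for _, f in s.cumulative_curve]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] == pytest.approx(1.0)

    def test_group_filter(self):
        records = [
            _onset(10, regimen=RegimenClass.MONO),
            _onset(100, regimen=RegimenClass.PLUS_CHEMO),
        ]
        assert summarize_onset(records, RegimenClass.MONO).median_days == 10

    def test_simulated_median_recovery(self):
        cfg = example_config(
            n_reports=500,
            seed=77,
            onset_median_days=40.0,
            onset_dispersion=0.8,
        )
        truth = simulate_truth(cfg)
        records = [
            _onset(int(d), pid=str(i)) for i, d in enumerate(truth.reports["onset_days"])
        ]
        s = summarize_onset(records)
        assert s.n_used == 500
        assert abs(s.median_days - 40) / 40 <= 0.10


class TestOnsetBins:
    def test_default_bins(self):
        records = [_onset(d) for d in (0, 30, 31, 90, 91, 360, 361, 1000)]
        table = onset_bin_table(records)
        assert list(table["bin"]) == ["0-30", "31-60", "61-90", "91-180", "181-360", ">360"]
        assert list(table["count"]) == [2, 1, 1, 1, 1, 2]
        assert table["pct"].sum() == pytest.approx(100.0, abs=0.3)

    def test_custom_edges(self):
        table = onset_bin_table([_onset(5), _onset(15)], edges=(10,))
        assert list(table["bin"]) == ["0-10", ">10"]
        assert list(table["count"]) == [1, 1]


@pytest.fixture(scope="module")
def summary():
    specs = {
        RegimenClass.MONO: SubgroupSpec(size=150, deaths=57),
        RegimenClass.PLUS_CHEMO: SubgroupSpec(size=292, deaths=148),
        RegimenClass.PLUS_ICI: SubgroupSpec(size=13, deaths=6),
        RegimenClass.PLUS_TARGETED: SubgroupSpec(size=42, deaths=15),
    }
    return summarize_cohort(build_characteristic_cohort(specs))


class TestSummarizeCohort:

    def test_subgroup_death_percentages(self, summary):
        pct = summary.percentages("outcomes")
        row = pct.loc["Death (DE)"]
        assert row["MONO"] == 38.0
        assert row["PLUS_CHEMO"] == 50.7
        assert row["PLUS_ICI"] == 46.2
        assert row["PLUS_TARGETED"] == 35.7

    def test_overall_death_percentage(self, summary):
        assert summary.percentages("outcomes").loc["Death (DE)", "Overall"] == 45.5

    def test_sizes(self, summary):
        assert summary.subgroup_sizes == {
            "Overall": 497, "MONO": 150, "PLUS_CHEMO": 292,
            "PLUS_ICI": 13, "PLUS_TARGETED": 42,
        }

    def test_single_valued_conservation(self, summary):
        for characteristic in ("gender", "reporting_year", "countries", "reporters", "indications"):
            counts = summary.counts[characteristic]
            for col in counts.columns:
                assert counts[col].sum() == summary.subgroup_sizes[col], characteristic

    def test_multi_outcome_report_counts_in_each_row(self):
        report = CaseReport(
            primaryid="1", regimen=RegimenClass.MONO,
            outcomes=frozenset({"DE", "HO"}), is_target_event=True,
        )
        counts = summarize_cohort([report]).counts["outcomes"]
        assert counts.loc["Death (DE)", "Overall"] == 1
        assert counts.loc["Hospitalization (HO)", "Overall"] == 1
        assert counts.loc["Unspecified", "Overall"] == 0

    def test_all_missing_lands_in_unknown_rows(self):
        report = CaseReport(primaryid="1", regimen=RegimenClass.MONO, is_target_event=True)
        summary = summarize_cohort([report])
        assert summary.counts["gender"].loc["Unknown", "Overall"] == 1
        assert summary.counts["outcomes"].loc["Unspecified", "Overall"] == 1
        assert summary.counts["indications"].loc["Unspecified", "Overall"] == 1
        assert summary.counts["countries"].loc["Unspecified", "Overall"] == 1
        assert summary.counts["reporters"].loc["Unspecified", "Overall"] == 1
        for characteristic in ("gender", "reporting_year", "countries", "reporters"):
            assert summary.counts[characteristic]["Overall"].sum() == 1

    def test_country_and_year_classification(self):
        report = CaseReport(
            primaryid="1", regimen=RegimenClass.MONO, is_target_event=True,
            reporter_country="JP", fda_dt="20101231", sex="f", occp_cod="md",
        )
        summary = summarize_cohort([report])
        assert summary.counts["countries"].loc["Japan", "Overall"] == 1
        assert summary.counts["reporting_year"].loc["2009-2013", "Overall"] == 1
        assert summary.counts["gender"].loc["Female", "Overall"] == 1
        assert summary.counts["reporters"].loc["Physician (MD)", "Overall"] == 1

    def test_age_missingness_reported(self, summary):
        counts = summary.counts["age_missingness"]
        assert counts["Overall"].sum() == 497
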