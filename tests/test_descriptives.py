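"""Demographic tables and time-to-onset summaries."""

import math

import numpy as np
import pytest

from faersignal.cohort import CohortConfig, MeddraMap
from faersignal.descriptives import (
    DEFAULT_BIN_EDGES,
    bin_label,
    category_percentages,
    collect_onset_records,
    onset_by_soc,
    onset_days,
    onset_summary,
    summarize_demographics,
)
from faersignal.faers_io import (
    AnomalyLog,
    CaseReport,
    DrugRecord,
    TherapyRecord,
)
from faersignal.synthetic import OnsetMixture, example_config, simulate

TARGET = CohortConfig(("TARGETINIB",))


def onset_case(caseid, start, event, drug="TARGETINIB", role="PS"):
    return CaseReport(
        primaryid=caseid,
        caseid=caseid,
        event_date=event,
        drugs=[DrugRecord("1", drug, drug, role)],
        therapies=[TherapyRecord("1", start)],
    )


class TestDemographics:
    def test_counts_sum_to_reports_and_percents_to_100(self, linked):
        cases, _ = linked
        ids = {c.caseid for c in cases if any(d.name == "TARGETINIB" for d in c.drugs)}
        summary = summarize_demographics(cases, ids)
        assert summary.n_reports == len(ids)
        for cat in ("sex", "weight_kg", "age_years", "occupation", "country"):
            rows = summary.categories[cat]
            assert sum(n for _, n, _ in rows) == summary.n_reports
            assert sum(p for _, _, p in rows) == pytest.approx(100.0, abs=0.1)

    def test_outcome_percents_over_entries(self):
        cases = [
            CaseReport("1", "1", outcomes={"DE", "HO"}),
            CaseReport("2", "2", outcomes=set()),
        ]
        summary = summarize_demographics(cases, {"1", "2"})
        assert summary.outcome_entries == 3
        rows = dict((lab, (n, p)) for lab, n, p in summary.categories["outcome"])
        assert rows["Death"] == (1, pytest.approx(100 / 3))
        assert rows["Missing"] == (1, pytest.approx(100 / 3))

    def test_published_style_percentages_from_counts(self):
        rows = dict(
            (lab, round(p, 1))
            for lab, _, p in category_percentages(
                {"Male": 1704, "Female": 1392, "Missing": 65}, 3161
            )
        )
        assert rows["Male"] == 53.9

    def test_empty_cohort_all_zero(self):
        summary = summarize_demographics([], set())
        assert summary.n_reports == 0
        for rows in summary.categories.values():
            assert all(p == 0.0 for _, _, p in rows)

    def test_permutation_invariant(self, linked):
        cases, _ = linked
        ids = {c.caseid for c in cases[:50]}
        a = summarize_demographics(cases, ids)
        b = summarize_demographics(list(reversed(cases)), ids)
        assert a.categories == b.categories


class TestOnsetDays:
    def test_same_day_is_zero(self):
        days, reason = onset_days(onset_case("1", "20230101", "20230101"), TARGET)
        assert (days, reason) == (0, None)

    def test_calendar_arithmetic(self):
        days, _ = onset_days(onset_case("1", "20230101", "20230410"), TARGET)
        assert days == 99

    @pytest.mark.parametrize(
        "start, event, reason",
        [
            ("20230101", None, "missing_event_date"),
            ("20230101", "202304", "partial_date"),
            ("202301", "20230410", "partial_date"),
            (None, "20230410", "missing_start_date"),
            ("20230601", "20230410", "negative_interval"),
        ],
    )
    def test_exclusion_reasons(self, start, event, reason):
        days, got = onset_days(onset_case("1", start, event), TARGET)
        assert days is None and got == reason

    def test_earliest_matched_start_used(self):
        c = onset_case("1", "20230301", "20230410")
        c.drugs.append(DrugRecord("2", "TARGETINIB", "TARGETINIB", "PS"))
        c.therapies.append(TherapyRecord("2", "20230101"))
        days, _ = onset_days(c, TARGET)
        assert days == 99

    def test_unmatched_drug_start_ignored(self):
        c = onset_case("1", "20230101", "20230410", drug="OTHERMAB")
        days, reason = onset_days(c, TARGET)
        assert days is None and reason == "missing_start_date"

    def test_translation_invariance(self):
        base, _ = onset_days(onset_case("1", "20230215", "20230520"), TARGET)
        shifted, _ = onset_days(onset_case("1", "20230315", "20230617"), TARGET)
        assert base == shifted


class TestOnsetSummary:
    def test_order_statistic_quartiles(self):
        s = onset_summary([27, 99, 245])
        assert (s.median, s.q1, s.q3) == (99, 27, 245)

    def test_first_month_share(self):
        s = onset_summary([10] * 165 + [200] * 452)
        lab, count, pct = s.bins[0]
        assert (lab, count) == ("0–1 m", 165)
        assert round(pct, 2) == 26.74

    def test_all_in_first_bin(self):
        s = onset_summary([29] * 10)
        assert s.bins[0][2] == 100.0
        assert all(c == 0 for _, c, _ in s.bins[1:])

    def test_bin_percents_sum_to_100(self):
        rng = np.random.default_rng(0)
        s = onset_summary(list(rng.integers(0, 700, size=500)))
        assert sum(p for _, _, p in s.bins) == pytest.approx(100.0, abs=0.1)

    def test_empty_summary_is_explicit(self):
        s = onset_summary([])
        assert s.empty and math.isnan(s.median) and s.bins == []

    def test_custom_edges(self):
        s = onset_summary([5, 45, 100], edges=(0, 30, 60, 90))
        assert len(s.bins) == 4  # 3 edges + overflow
        assert bin_label(100, (0, 30, 60, 90)) == ">=90 d"

    def test_default_edge_labels(self):
        assert bin_label(0) == "0–1 m"
        assert bin_label(359) == "6–12 m"
        assert bin_label(360) == ">12 m"


class TestOnsetBySoc:
    def test_rows_per_soc_ordered_by_n(self):
        from faersignal.descriptives import OnsetRecord

        records = [
            OnsetRecord("1", 10, "A", "SOC1", "0–1 m"),
            OnsetRecord("2", 20, "B", "SOC2", "0–1 m"),
            OnsetRecord("3", 30, "C", "SOC2", "0–1 m"),
        ]
        rows = onset_by_soc(records)
        assert [soc for soc, _ in rows] == ["SOC2", "SOC1"]
        assert rows[0][1].n == 2

    def test_empty(self):
        assert onset_by_soc([]) == []

    def test_generated_early_soc_precedes_late_soc(self):
        """Per-SOC onset overrides must surface in the per-SOC medians:
        an early-onset SOC (short-scale Weibull) reports consistently
        shorter times than a late-onset SOC across replicates."""
        early = OnsetMixture(weights=(1.0,), shapes=(1.2,), scales=(15.0,))
        late = OnsetMixture(weights=(1.0,), shapes=(2.0,), scales=(400.0,))
        wins = 0
        reps = 30
        for seed in range(reps):
            cfg = example_config(n_reports=400, seed=seed)
            cfg.onset_by_soc = {
                "Gastrointestinal disorders": early,
                "Nervous system disorders": late,
            }
            sim = simulate(cfg)
            days = {"gi": [], "nerv": []}
            socs = [e.soc for e in cfg.events]
            first = sim.event_matrix.argmax(axis=1)
            for i, cid in enumerate(sorted(sim.truth.onset_days)):
                soc = socs[first[i]]
                if soc == "Gastrointestinal disorders":
                    days["gi"].append(sim.truth.onset_days[cid])
                elif soc == "Nervous system disorders":
                    days["nerv"].append(sim.truth.onset_days[cid])
            if np.median(days["gi"]) < np.median(days["nerv"]):
                wins += 1
        assert wins >= int(0.9 * reps)


class TestCollectRecords:
    def test_records_and_exclusions_on_synthetic_data(self, dataset, linked):
        from faersignal.cohort import load_meddra_map

        _, out, truth = dataset
        cases, _ = linked
        ids = set(truth.drug_reports["TARGETINIB"]["ps"])
        log = AnomalyLog()
        records = collect_onset_records(
            cases, ids, TARGET, load_meddra_map(out / "meddra_map.tsv"),
            DEFAULT_BIN_EDGES, log,
        )
        included = {r.report_id for r in records}
        excluded = sum(v for k, v in log.items() if k.startswith("onset_excluded"))
        assert len(included) + excluded == len(ids)
        # day counts must equal the generator's sampled values
        for r in records:
            assert r.days == truth.onset_days[r.report_id]
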