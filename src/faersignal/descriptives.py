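"""Demographic summaries and time-to-onset analysis.

Demographics are tabulated per cohort report in the bands conventional
for spontaneous-report safety profiles: weight <50 / 50–100 / >100 kg,
age <18 / 18–64.9 / 65–85 / >85 years, consumer vs health-professional
reporters, reporting country, and the FAERS outcome codes.  Within
each characteristic the counts (including the missing row) sum to the
number of reports — except outcomes, whose percentages are over the
total number of outcome *entries*, because one report may carry several
outcome codes (or none, which counts as one missing entry).

Time to onset (TTO) is days from the earliest full-precision therapy
start date of a matched target-drug mention to the report's event
date.  Reports with missing or partial dates, or an event before the
therapy start, are excluded with a tallied reason.  Summaries use
order-statistic (inverted-CDF) medians and quartiles, so the reported
median and IQR are always observed day counts, plus 30-day bins with a
single 6–12-month bin and an open-ended >12-month bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .cohort import CohortConfig, MeddraMap
from .faers_io import AnomalyLog, CaseReport, date_to_ordinal

__all__ = [
    "DemographicsSummary",
    "OnsetRecord",
    "OnsetSummary",
    "summarize_demographics",
    "category_percentages",
    "onset_days",
    "collect_onset_records",
    "onset_summary",
    "onset_by_soc",
    "DEFAULT_BIN_EDGES",
    "bin_label",
]

#: lower edges of the default onset bins, in days (30-day months; one
#: coarse 6–12-month bin; the last bin is open-ended)
DEFAULT_BIN_EDGES = (0, 30, 60, 90, 120, 150, 180, 360)

_DEFAULT_LABELS = ("0–1 m", "1–2 m", "2–3 m", "3–4 m", "4–5 m", "5–6 m",
                   "6–12 m", ">12 m")

_OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-threatening",
    "HO": "Hospitalization",
    "DS": "Disability",
    "CA": "Congenital anomaly",
    "RI": "Required intervention",
    "OT": "Other",
}


def category_percentages(
    counts: dict[str, float], denominator: float | None = None
) -> list[tuple[str, float, float]]:
    """(label, count, percent) rows; percent of *denominator*, which
    defaults to the sum of the counts.  Empty input → empty list; a
    zero denominator yields 0.0 percents."""
    denom = sum(counts.values()) if denominator is None else denominator
    return [
        (label, n, (100.0 * n / denom) if denom else 0.0)
        for label, n in counts.items()
    ]


def _band_weight(w: float | None) -> str:
    if w is None:
        return "Missing"
    if w < 50:
        return "<50"
    if w <= 100:
        return "50–100"
    return ">100"


def _band_age(a: float | None) -> str:
    if a is None:
        return "Missing"
    if a < 18:
        return "<18"
    if a < 65:
        return "18–64.9"
    if a <= 85:
        return "65–85"
    return ">85"


_OCC_LABELS = {
    "consumer": "Consumer",
    "health_professional": "Health professional",
    "unknown": "Missing",
}


@dataclass
class DemographicsSummary:
    """Per-characteristic (label, count, percent) rows for one cohort."""

    n_reports: int
    categories: dict[str, list[tuple[str, float, float]]]
    outcome_entries: int

    def table(self):
        """Long-format pandas DataFrame (characteristic, label, count, percent)."""
        import pandas as pd

        rows = [
            {"characteristic": cat, "label": label, "count": n, "percent": pct}
            for cat, items in self.categories.items()
            for label, n, pct in items
        ]
        return pd.DataFrame(rows)


def summarize_demographics(
    cases: Iterable[CaseReport], cohort_ids: set[str]
) -> DemographicsSummary:
    """Tabulate sex, weight, age, reporter occupation, country and
    outcomes for the cohort reports."""
    cohort = [c for c in cases if c.caseid in cohort_ids]
    n = len(cohort)

    def tally(labels: Iterable[str], order: Sequence[str]) -> dict[str, int]:
        counts = {k: 0 for k in order}
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
        return {k: v for k, v in counts.items() if v or k in order}

    sex = tally(
        ("Male" if c.sex == "male" else "Female" if c.sex == "female" else "Missing"
         for c in cohort),
        ("Male", "Female", "Missing"),
    )
    weight = tally((_band_weight(c.weight_kg) for c in cohort),
                   ("<50", "50–100", ">100", "Missing"))
    age = tally((_band_age(c.age_years) for c in cohort),
                ("<18", "18–64.9", "65–85", ">85", "Missing"))
    occupation = tally((_OCC_LABELS[c.reporter_occupation] for c in cohort),
                       ("Consumer", "Health professional", "Missing"))
    country_counts: dict[str, int] = {}
    for c in cohort:
        country_counts[c.country or "Missing"] = (
            country_counts.get(c.country or "Missing", 0) + 1
        )
    country = dict(
        sorted(country_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    )

    outcome_counts = {label: 0 for label in _OUTCOME_LABELS.values()}
    outcome_counts["Missing"] = 0
    entries = 0
    for c in cohort:
        if c.outcomes:
            for code in sorted(c.outcomes):
                outcome_counts[_OUTCOME_LABELS.get(code, code)] += 1
                entries += 1
        else:
            outcome_counts["Missing"] += 1
            entries += 1
    outcome_counts = {k: v for k, v in outcome_counts.items() if v}

    return DemographicsSummary(
        n_reports=n,
        categories={
            "sex": category_percentages(sex, n),
            "weight_kg": category_percentages(weight, n),
            "age_years": category_percentages(age, n),
            "occupation": category_percentages(occupation, n),
            "country": category_percentages(country, n),
            "outcome": category_percentages(outcome_counts, entries),
        },
        outcome_entries=entries,
    )


@dataclass(frozen=True)
class OnsetRecord:
    report_id: str
    days: int
    pt: str
    soc: str
    bin: str


def onset_days(case: CaseReport, config: CohortConfig):
    """Days from the earliest full-precision matched-drug therapy start
    to the event date, or ``(None, reason)`` when excluded.

    Exclusion reasons: ``missing_event_date``, ``partial_date`` (either
    date below day precision), ``missing_start_date`` (no therapy row
    for a matched drug mention), ``negative_interval``.
    """
    if not case.event_date:
        return None, "missing_event_date"
    event_ord = date_to_ordinal(case.event_date)
    if event_ord is None:
        return None, "partial_date"
    matched_seqs = {d.drug_seq for d in case.drugs if config.drug_matches(d)}
    starts = [t.start_date for t in case.therapies if t.drug_seq in matched_seqs]
    full = [date_to_ordinal(s) for s in starts if s]
    full = [o for o in full if o is not None]
    if not starts or all(not s for s in starts):
        return None, "missing_start_date"
    if not full:
        return None, "partial_date"
    days = event_ord - min(full)
    if days < 0:
        return None, "negative_interval"
    return days, None


def bin_label(days: int, edges: Sequence[int] = DEFAULT_BIN_EDGES) -> str:
    """Label of the half-open bin [edge_i, edge_{i+1}) containing *days*."""
    edges = tuple(edges)
    idx = int(np.searchsorted(edges, days, side="right")) - 1
    idx = max(idx, 0)
    if edges == DEFAULT_BIN_EDGES:
        return _DEFAULT_LABELS[idx]
    if idx == len(edges) - 1:
        return f">={edges[idx]} d"
    return f"{edges[idx]}–{edges[idx + 1]} d"


def collect_onset_records(
    cases: Iterable[CaseReport],
    cohort_ids: set[str],
    config: CohortConfig,
    meddra_map: MeddraMap,
    edges: Sequence[int] = DEFAULT_BIN_EDGES,
    anomalies: AnomalyLog | None = None,
) -> list[OnsetRecord]:
    """One onset record per (cohort report, distinct SOC), with the
    report's first PT of that SOC attached; exclusions are tallied on
    *anomalies* by reason."""
    anomalies = AnomalyLog() if anomalies is None else anomalies
    records: list[OnsetRecord] = []
    for case in cases:
        if case.caseid not in cohort_ids:
            continue
        days, reason = onset_days(case, config)
        if days is None:
            anomalies.bump(f"onset_excluded_{reason}")
            continue
        lab = bin_label(days, edges)
        per_soc: dict[str, str] = {}
        for r in case.reactions:
            per_soc.setdefault(meddra_map.lookup(r.pt), r.pt)
        for soc in sorted(per_soc):
            records.append(OnsetRecord(case.caseid, days, per_soc[soc], soc, lab))
    return records


@dataclass
class OnsetSummary:
    n: int
    median: float
    q1: float
    q3: float
    bins: list[tuple[str, int, float]] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return self.n == 0


def _order_stat_quantiles(days: Sequence[int]) -> tuple[float, float, float]:
    arr = np.sort(np.asarray(days, dtype=float))
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="inverted_cdf")
    return float(med), float(q1), float(q3)


def onset_summary(
    records: Sequence[OnsetRecord] | Sequence[int],
    edges: Sequence[int] = DEFAULT_BIN_EDGES,
) -> OnsetSummary:
    """Median, quartiles and binned distribution of onset days.

    Accepts onset records (deduplicated to one day count per report) or
    a bare sequence of day counts.  Quantiles are order statistics
    (inverted-CDF convention), so median and IQR endpoints are observed
    values.  Empty input yields an explicit empty summary.
    """
    if records and isinstance(records[0], OnsetRecord):
        per_report: dict[str, int] = {}
        for r in records:  # type: ignore[union-attr]
            per_report.setdefault(r.report_id, r.days)
        days = list(per_report.values())
    else:
        days = [int(d) for d in records]  # type: ignore[arg-type]
    if not days:
        return OnsetSummary(0, math.nan, math.nan, math.nan, [])
    med, q1, q3 = _order_stat_quantiles(days)
    edges = tuple(edges)
    labels = (
        _DEFAULT_LABELS
        if edges == DEFAULT_BIN_EDGES
        else tuple(bin_label(e, edges) for e in edges)
    )
    bin_counts = {lab: 0 for lab in labels}
    for d in days:
        bin_counts[bin_label(d, edges)] += 1
    n = len(days)
    bins = [(lab, c, 100.0 * c / n) for lab, c in bin_counts.items()]
    return OnsetSummary(n, med, q1, q3, bins)


def onset_by_soc(
    records: Sequence[OnsetRecord], edges: Sequence[int] = DEFAULT_BIN_EDGES
) -> list[tuple[str, OnsetSummary]]:
    """Per-SOC onset summaries, ordered by record count descending
    (ties alphabetically)."""
    groups: dict[str, list[int]] = {}
    for r in records:
        groups.setdefault(r.soc, []).append(r.days)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return [(soc, onset_summary(days, edges)) for soc, days in ordered]
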