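"""Target-drug cohort extraction and PT/SOC event counting.

A report belongs to the target cohort when at least one of its drug
mentions matches a configured keyword (case-insensitive substring match
after stripping whitespace and hyphens, applied to both the verbatim
drug name and the active-ingredient field) **and** that mention's role
code is in the configured role set.  The default role set is
``{"PS"}`` — primary suspect only — the usual restriction when the
drug is treated as the single factor associated with the events.

Counts are over distinct deduplicated reports: a report mentioning a
PT twice contributes one to that PT, and one to the PT's System Organ
Class regardless of how many of its PTs share the SOC.  These
marginals are exactly the a, a+b, a+c, N cells the disproportionality
statistics need.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from .faers_io import AnomalyLog, CaseReport

__all__ = [
    "CohortConfig",
    "MeddraMap",
    "EventCounts",
    "load_meddra_map",
    "match_target_reports",
    "count_events",
]

UNMAPPED_SOC = "UNMAPPED"

_SQUASH = re.compile(r"[\s\-]+")


def _norm_name(s: str) -> str:
    """Matching form of a drug name: lower-case, whitespace/hyphens removed."""
    return _SQUASH.sub("", s).lower()


def _norm_pt(s: str) -> str:
    """Lookup form of a PT: internal whitespace collapsed, case-folded."""
    return " ".join(s.split()).casefold()


@dataclass(frozen=True)
class CohortConfig:
    keywords: tuple[str, ...]
    roles: frozenset[str] = frozenset({"PS"})

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError("cohort keywords must be non-empty")
        if not self.roles:
            raise ValueError("cohort roles must be non-empty")
        bad = set(self.roles) - {"PS", "SS", "C", "I"}
        if bad:
            raise ValueError(f"unknown drug role codes: {sorted(bad)}")

    def drug_matches(self, record) -> bool:
        """Keyword + role test for one drug mention."""
        if record.role not in self.roles:
            return False
        hay = _norm_name(record.name) + "\x00" + _norm_name(record.active_ingredient)
        return any(_norm_name(k) in hay for k in self.keywords if k)


class MeddraMap:
    """PT → SOC lookup with normalized keys and preserved casing.

    An unmapped PT resolves to the sentinel SOC ``"UNMAPPED"`` (callers
    tally these); MedDRA itself is licensed, so the mapping always
    arrives as a user-supplied two-column file.
    """

    def __init__(self, mapping: dict[str, str] | None = None):
        self._map: dict[str, str] = {}
        if mapping:
            for pt, soc in mapping.items():
                self.add(pt, soc)

    def add(self, pt: str, soc: str) -> None:
        key = _norm_pt(pt)
        soc = " ".join(soc.split())
        if key in self._map and self._map[key] != soc:
            raise ValueError(f"PT {pt!r} mapped to conflicting SOCs")
        self._map[key] = soc

    def lookup(self, pt: str) -> str:
        return self._map.get(_norm_pt(pt), UNMAPPED_SOC)

    def __contains__(self, pt: str) -> bool:
        return _norm_pt(pt) in self._map

    def __len__(self) -> int:
        return len(self._map)


def load_meddra_map(path: str | Path) -> MeddraMap:
    """Read a tab-separated ``pt<TAB>soc`` file (header row optional)."""
    mapping = MeddraMap()
    lines = Path(path).read_text().splitlines()
    for i, line in enumerate(lines):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}: line {i + 1} is not two tab-separated columns")
        pt, soc = parts[0].strip(), parts[1].strip()
        if i == 0 and pt.casefold() in ("pt", "preferred term", "preferred_term"):
            continue
        mapping.add(pt, soc)
    return mapping


def match_target_reports(cases: list[CaseReport], config: CohortConfig) -> set[str]:
    """Identifiers (CASEIDs) of reports with a matching target-drug
    mention.  Zero matches is a valid outcome."""
    return {
        case.caseid
        for case in cases
        if any(config.drug_matches(d) for d in case.drugs)
    }


@dataclass
class EventCounts:
    """Distinct-report marginals for every PT and SOC.

    ``pt_target[t]`` = a, ``pt_total[t]`` = a+c, ``n_target_total`` =
    a+b, ``n_all`` = N; likewise at SOC level.
    """

    pt_target: dict[str, int] = field(default_factory=dict)
    pt_total: dict[str, int] = field(default_factory=dict)
    soc_target: dict[str, int] = field(default_factory=dict)
    soc_total: dict[str, int] = field(default_factory=dict)
    pt_to_soc: dict[str, str] = field(default_factory=dict)
    n_target_total: int = 0
    n_all: int = 0

    def terms(self, level: str = "PT") -> list[str]:
        if level == "PT":
            return sorted(self.pt_total)
        if level == "SOC":
            return sorted(self.soc_total)
        raise ValueError(f"unknown level {level!r}")

    def term_counts(self, term: str, level: str = "PT") -> tuple[int, int]:
        """(n_target, n_term_total) for a term at the given level."""
        target, total = (
            (self.pt_target, self.pt_total)
            if level == "PT"
            else (self.soc_target, self.soc_total)
        )
        if term not in total:
            raise KeyError(f"{level} term {term!r} not present in counts")
        return target.get(term, 0), total[term]


def count_events(
    cases: list[CaseReport],
    target_ids: set[str],
    meddra_map: MeddraMap,
    anomalies: AnomalyLog | None = None,
) -> EventCounts:
    """Count distinct reports per PT and per SOC, overall and within
    the target cohort."""
    anomalies = AnomalyLog() if anomalies is None else anomalies
    counts = EventCounts(n_all=len(cases), n_target_total=0)
    display_of: dict[str, str] = {}  # normalized PT -> first-seen casing
    for case in cases:
        is_target = case.caseid in target_ids
        if is_target:
            counts.n_target_total += 1
        pts: dict[str, str] = {}  # normalized -> display form, per report
        for r in case.reactions:
            pts.setdefault(_norm_pt(r.pt), r.pt)
        socs: set[str] = set()
        for key, raw_display in pts.items():
            if key not in display_of:
                display_of[key] = raw_display
                if raw_display not in meddra_map:
                    anomalies.bump("unmapped_pt")
            display = display_of[key]
            soc = meddra_map.lookup(display)
            counts.pt_to_soc.setdefault(display, soc)
            socs.add(soc)
            counts.pt_total[display] = counts.pt_total.get(display, 0) + 1
            if is_target:
                counts.pt_target[display] = counts.pt_target.get(display, 0) + 1
        for soc in socs:
            counts.soc_total[soc] = counts.soc_total.get(soc, 0) + 1
            if is_target:
                counts.soc_target[soc] = counts.soc_target.get(soc, 0) + 1
    return counts
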