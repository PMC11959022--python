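"""Reading and linking FAERS-style quarterly ASCII tables.

FAERS distributes each quarter as seven "$"-delimited text tables —
DEMO (demographics), DRUG, REAC (MedDRA-coded reactions), OUTC
(outcome codes), RPSR (report sources), THER (therapy dates) and INDI
(indications) — keyed by PRIMARYID (a case version) and CASEID (the
case).  A case may appear as several versions; analysis keeps one row
per case: the version with the latest FDA receipt date, ties broken by
the larger PRIMARYID, with FDA-published deleted cases removed.

All parsing is forgiving: ragged or keyless rows are skipped and
tallied, malformed ages/weights/dates become missing, and nothing here
raises on dirty data except a structurally unusable file (no PRIMARYID
column).
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

__all__ = [
    "AnomalyLog",
    "DrugRecord",
    "ReactionRecord",
    "TherapyRecord",
    "CaseReport",
    "read_table",
    "read_deleted_cases",
    "dedupe",
    "link_cases",
    "load_dataset",
    "parse_date",
    "parse_age_years",
    "parse_weight_kg",
    "OUTCOME_CODES",
    "TABLE_KINDS",
]

DELIMITER = "$"
TABLE_KINDS = ("DEMO", "DRUG", "REAC", "OUTC", "RPSR", "THER", "INDI")
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})

#: years per unit for FAERS age codes
_AGE_FACTORS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.18,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / (365.25 * 24.0),
}

_WEIGHT_MAX_KG = 400.0  # crude outlier guard; larger values -> missing

_OCCUPATION_MAP = {
    "CN": "consumer",
    "LW": "consumer",
    "MD": "health_professional",
    "PH": "health_professional",
    "RN": "health_professional",
    "HP": "health_professional",
    "OT": "health_professional",
}


class AnomalyLog(Counter):
    """Counter of non-fatal parse/link anomalies, keyed by kind."""

    def bump(self, kind: str, n: int = 1) -> None:
        self[kind] += n


def _read_text(path: Path) -> str:
    raw = (gzip.open(path, "rb") if str(path).endswith(".gz") else open(path, "rb")).read()
    try:
        return raw.decode("utf-8")
    except UnicodeDecodeError:
        return raw.decode("latin-1")


def read_table(
    path: str | Path, table_kind: str, anomalies: AnomalyLog | None = None
) -> list[dict[str, str]]:
    """Parse one "$"-delimited table into a list of field dicts.

    The first line names the fields (upper-cased on read).  Empty
    strings are preserved as missing values.  Rows with the wrong field
    count or an empty PRIMARYID are skipped and tallied; a file whose
    header lacks PRIMARYID is rejected outright.
    """
    if table_kind not in TABLE_KINDS:
        raise ValueError(f"unknown table kind {table_kind!r}")
    path = Path(path)
    anomalies = AnomalyLog() if anomalies is None else anomalies
    text = _read_text(path)
    lines = text.splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file, no header")
    header = [h.strip().upper() for h in lines[0].split(DELIMITER)]
    if "PRIMARYID" not in header:
        raise ValueError(f"{path}: no PRIMARYID column in header")
    rows: list[dict[str, str]] = []
    for line in lines[1:]:
        fields = line.split(DELIMITER)
        if len(fields) != len(header):
            anomalies.bump(f"{table_kind}_ragged_row")
            continue
        row = dict(zip(header, fields))
        if not row["PRIMARYID"].strip():
            anomalies.bump(f"{table_kind}_missing_primaryid")
            continue
        rows.append(row)
    return rows


def read_deleted_cases(path: str | Path) -> set[str]:
    """Deleted-case list: one CASEID per line, blanks ignored."""
    return {ln.strip() for ln in _read_text(Path(path)).splitlines() if ln.strip()}


def parse_date(value: str | None) -> str | None:
    """Validate a FAERS date string; returns the digits or None.

    Accepts 8-digit YYYYMMDD (day precision), 6-digit YYYYMM and
    4-digit YYYY partial dates.  Because partial dates are prefixes of
    the full form, zero-padded lexicographic comparison orders them
    consistently for deduplication.
    """
    if value is None:
        return None
    v = value.strip()
    if not v.isdigit() or len(v) not in (4, 6, 8):
        return None
    return v


def date_to_ordinal(value: str | None) -> int | None:
    """Proleptic ordinal of a full-precision (8-digit) date; else None."""
    v = parse_date(value)
    if v is None or len(v) != 8:
        return None
    try:
        return date(int(v[:4]), int(v[4:6]), int(v[6:8])).toordinal()
    except ValueError:
        return None


def parse_age_years(age: str | None, unit: str | None) -> float | None:
    if not age:
        return None
    try:
        value = float(age)
    except ValueError:
        return None
    factor = _AGE_FACTORS.get((unit or "YR").strip().upper() or "YR")
    if factor is None or value < 0:
        return None
    years = value * factor
    return years if 0 <= years <= 150 else None


def parse_weight_kg(wt: str | None) -> float | None:
    if not wt:
        return None
    try:
        value = float(wt)
    except ValueError:
        return None
    return value if 0 < value <= _WEIGHT_MAX_KG else None


@dataclass
class DrugRecord:
    drug_seq: str
    name: str
    active_ingredient: str = ""
    role: str = ""  # PS / SS / C / I


@dataclass
class ReactionRecord:
    pt: str  # MedDRA Preferred Term, whitespace-normalized


@dataclass
class TherapyRecord:
    drug_seq: str
    start_date: str | None = None


@dataclass
class CaseReport:
    """One deduplicated safety report with its linked child rows."""

    primaryid: str
    caseid: str
    fda_date: str | None = None
    event_date: str | None = None
    sex: str = "unknown"  # male / female / unknown
    age_years: float | None = None
    weight_kg: float | None = None
    country: str | None = None
    reporter_occupation: str = "unknown"
    outcomes: set[str] = field(default_factory=set)
    drugs: list[DrugRecord] = field(default_factory=list)
    reactions: list[ReactionRecord] = field(default_factory=list)
    therapies: list[TherapyRecord] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "primaryid": self.primaryid,
            "caseid": self.caseid,
            "fda_date": self.fda_date,
            "event_date": self.event_date,
            "sex": self.sex,
            "age_years": self.age_years,
            "weight_kg": self.weight_kg,
            "country": self.country,
            "reporter_occupation": self.reporter_occupation,
            "outcomes": sorted(self.outcomes),
            "drugs": [
                [d.drug_seq, d.name, d.active_ingredient, d.role] for d in self.drugs
            ],
            "reactions": [r.pt for r in self.reactions],
            "therapies": [[t.drug_seq, t.start_date] for t in self.therapies],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CaseReport":
        return cls(
            primaryid=d["primaryid"],
            caseid=d["caseid"],
            fda_date=d["fda_date"],
            event_date=d["event_date"],
            sex=d["sex"],
            age_years=d["age_years"],
            weight_kg=d["weight_kg"],
            country=d["country"],
            reporter_occupation=d["reporter_occupation"],
            outcomes=set(d["outcomes"]),
            drugs=[DrugRecord(*row) for row in d["drugs"]],
            reactions=[ReactionRecord(pt) for pt in d["reactions"]],
            therapies=[TherapyRecord(*row) for row in d["therapies"]],
        )


def _dedup_sort_key(row: dict[str, str]) -> tuple[str, float]:
    fda = parse_date(row.get("FDA_DT", "")) or ""
    try:
        pid = float(row["PRIMARYID"])
    except ValueError:
        pid = -1.0
    return (fda, pid)


def dedupe(
    demo_rows: list[dict[str, str]], deleted_caseids: set[str] | frozenset[str] = frozenset()
) -> list[dict[str, str]]:
    """One DEMO row per case: latest FDA date wins, ties to the larger
    numeric PRIMARYID; cases on the deleted list are dropped.  Output
    is sorted by CASEID for determinism.  Idempotent, never invents
    rows."""
    best: dict[str, dict[str, str]] = {}
    for row in demo_rows:
        caseid = row.get("CASEID", "").strip() or row["PRIMARYID"].strip()
        if caseid in deleted_caseids:
            continue
        cur = best.get(caseid)
        if cur is None or _dedup_sort_key(row) > _dedup_sort_key(cur):
            best[caseid] = row

    def caseid_key(item: tuple[str, dict]) -> tuple[int, float | str]:
        cid = item[0]
        return (0, float(cid)) if cid.replace(".", "", 1).isdigit() else (1, cid)

    return [row for _, row in sorted(best.items(), key=caseid_key)]


def _norm_pt(pt: str) -> str:
    return " ".join(pt.split())


def link_cases(
    demo: list[dict[str, str]],
    drug: list[dict[str, str]],
    reac: list[dict[str, str]],
    outc: list[dict[str, str]],
    ther: list[dict[str, str]],
    anomalies: AnomalyLog | None = None,
) -> list[CaseReport]:
    """Join deduplicated DEMO rows with their child tables on PRIMARYID.

    Child rows whose PRIMARYID is absent from the deduplicated DEMO set
    (orphans, including rows from superseded case versions) are dropped
    and tallied.  Ages and weights are normalized to years/kg where
    well-formed, otherwise missing.
    """
    anomalies = AnomalyLog() if anomalies is None else anomalies
    cases: dict[str, CaseReport] = {}
    for row in demo:
        sex_raw = row.get("SEX", row.get("GNDR_COD", "")).strip().upper()
        sex = {"M": "male", "F": "female"}.get(sex_raw, "unknown")
        occ = _OCCUPATION_MAP.get(row.get("OCCP_COD", "").strip().upper(), "unknown")
        country = (
            row.get("OCCR_COUNTRY", "").strip()
            or row.get("REPORTER_COUNTRY", "").strip()
            or None
        )
        case = CaseReport(
            primaryid=row["PRIMARYID"].strip(),
            caseid=row.get("CASEID", "").strip() or row["PRIMARYID"].strip(),
            fda_date=parse_date(row.get("FDA_DT")),
            event_date=parse_date(row.get("EVENT_DT")),
            sex=sex,
            age_years=parse_age_years(row.get("AGE"), row.get("AGE_COD")),
            weight_kg=parse_weight_kg(row.get("WT")),
            country=country,
            reporter_occupation=occ,
        )
        cases[case.primaryid] = case

    def target(row: dict[str, str], tally: str) -> CaseReport | None:
        case = cases.get(row["PRIMARYID"].strip())
        if case is None:
            anomalies.bump(tally)
        return case

    for row in drug:
        case = target(row, "DRUG_orphan")
        if case is not None:
            case.drugs.append(
                DrugRecord(
                    drug_seq=row.get("DRUG_SEQ", "").strip(),
                    name=row.get("DRUGNAME", "").strip(),
                    active_ingredient=row.get("PROD_AI", "").strip(),
                    role=row.get("ROLE_COD", "").strip().upper(),
                )
            )
    for row in reac:
        case = target(row, "REAC_orphan")
        if case is not None:
            pt = _norm_pt(row.get("PT", ""))
            if pt:
                case.reactions.append(ReactionRecord(pt))
            else:
                anomalies.bump("REAC_empty_pt")
    for row in outc:
        case = target(row, "OUTC_orphan")
        if case is not None:
            code = row.get("OUTC_COD", "").strip().upper()
            if code in OUTCOME_CODES:
                case.outcomes.add(code)
            elif code:
                anomalies.bump("OUTC_unknown_code")
    for row in ther:
        case = target(row, "THER_orphan")
        if case is not None:
            case.therapies.append(
                TherapyRecord(
                    drug_seq=row.get("DSG_DRUG_SEQ", row.get("DRUG_SEQ", "")).strip(),
                    start_date=parse_date(row.get("START_DT")),
                )
            )
    return [cases[pid] for pid in sorted(cases, key=lambda p: (len(p), p))]


def _find_table(directory: Path, kind: str) -> Path | None:
    for suffix in (".txt", ".txt.gz", ".TXT"):
        p = directory / f"{kind}{suffix}"
        if p.exists():
            return p
    return None


def load_dataset(
    directory: str | Path, anomalies: AnomalyLog | None = None
) -> list[CaseReport]:
    """Read, deduplicate and link a dataset directory containing
    DEMO/DRUG/REAC/OUTC/THER tables (and optionally DELETED.txt)."""
    directory = Path(directory)
    anomalies = AnomalyLog() if anomalies is None else anomalies
    tables: dict[str, list[dict[str, str]]] = {}
    for kind in ("DEMO", "DRUG", "REAC", "OUTC", "THER"):
        path = _find_table(directory, kind)
        if path is None:
            if kind in ("DEMO", "DRUG", "REAC"):
                raise FileNotFoundError(f"{directory}: missing required {kind} table")
            tables[kind] = []
            continue
        tables[kind] = read_table(path, kind, anomalies)
    deleted_path = directory / "DELETED.txt"
    deleted = read_deleted_cases(deleted_path) if deleted_path.exists() else set()
    demo = dedupe(tables["DEMO"], deleted)
    return link_cases(
        demo, tables["DRUG"], tables["REAC"], tables["OUTC"], tables["THER"], anomalies
    )
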