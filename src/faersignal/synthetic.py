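"""Synthetic FAERS-style dataset generator with known ground truth.

Spontaneous-report databases cannot be redistributed and carry no
ground truth, so every downstream stage of this package is exercised on
simulated data whose answers are known by construction: planted
drug–event reporting-rate multipliers, known duplicate case versions,
a known deleted-case list and known therapy-start/event day counts.

The generative model is case-first.  For each report the generator
samples demographics, a set of drugs (independent Bernoulli per drug,
with one drug designated primary suspect), and then reactions: each
Preferred Term (PT) is reported with probability ``min(1, λ·q)`` where
``q`` is the PT's background reporting probability and ``λ`` is the
largest planted multiplier among the report's drugs (λ = 1 when no
signal is planted).  This makes the expected 2×2 cell counts analytic:
for a planted pair the conditional reporting probability of the event
given the drug is exactly ``min(1, λ·q)`` up to the rare fallback that
guarantees every report at least one reaction.

Duplicate case versions perturb only the PRIMARYID and FDA receipt
date — never the clinical content — so the canonical version (latest
FDA date) is unambiguous.  Identical config + seed yields byte-identical
output files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path

import numpy as np

from .faers_io import OUTCOME_CODES

__all__ = [
    "DrugSpec",
    "EventSpec",
    "PlantedSignal",
    "OnsetMixture",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedData",
    "simulate",
    "generate_dataset",
    "write_meddra_map",
    "default_demographics",
    "example_config",
]

logger = logging.getLogger(__name__)

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class DrugSpec:
    name: str
    prob: float  # marginal probability a report mentions the drug


@dataclass(frozen=True)
class EventSpec:
    pt: str
    soc: str
    prob: float  # background per-report reporting probability


@dataclass(frozen=True)
class PlantedSignal:
    drug: str
    pt: str
    multiplier: float  # reporting-rate multiplier λ ≥ 0; 1 = null


@dataclass(frozen=True)
class OnsetMixture:
    """Weibull mixture for days from therapy start to event.

    The default two-component mixture mimics the empirical shape of
    time-to-onset curves for chronically dosed oncology drugs: an early
    peak within the first weeks (sub-exponential short-scale component)
    plus a late rise over the first year (long-scale component).
    """

    weights: tuple[float, ...] = (0.5, 0.5)
    shapes: tuple[float, ...] = (0.8, 1.6)
    scales: tuple[float, ...] = (60.0, 280.0)  # days

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        w = np.asarray(self.weights, dtype=float)
        comp = rng.choice(len(w), size=n, p=w / w.sum())
        days = np.empty(n)
        for i, (k, lam) in enumerate(zip(self.shapes, self.scales)):
            mask = comp == i
            days[mask] = lam * rng.weibull(k, size=int(mask.sum()))
        return np.floor(days).astype(int)


def default_demographics() -> dict:
    """Categorical distributions shaped like a US-dominated oncology
    drug's spontaneous-report stream: male-skewed sex ratio, mostly
    missing weight, elderly-skewed known ages, consumer-heavy reporters
    and sparse outcome coding."""
    return {
        "sex": {"male": 0.539, "female": 0.44, "missing": 0.021},
        "age_band": {
            "<18": 0.001,
            "18-64.9": 0.149,
            "65-85": 0.214,
            ">85": 0.012,
            "missing": 0.624,
        },
        "weight_band": {"<50": 0.009, "50-100": 0.061, ">100": 0.005, "missing": 0.925},
        "country": {"US": 0.929, "FR": 0.017, "CA": 0.015, "DE": 0.005, "GB": 0.005, "missing": 0.029},
        "occupation": {"consumer": 0.597, "health_professional": 0.401, "missing": 0.002},
        # independent per-code probabilities; a report may carry several
        "outcome": {"DE": 0.10, "HO": 0.18, "LT": 0.005, "DS": 0.001, "OT": 0.15},
    }


def _zipf_probs(n: int, scale: float = 0.35, exponent: float = 0.75) -> list[float]:
    """Zipf-like background reporting probabilities: scale/(rank+1)^exponent."""
    return [scale / (rank + 1) ** exponent for rank in range(n)]


def example_config(n_reports: int = 3000, seed: int = 0) -> "SimulationConfig":
    """A ready-to-run configuration: one target drug with planted
    signals against a Zipf-like background event catalogue.

    The catalogue is dense enough (about two expected reactions per
    report, several common concomitant drugs) that the fallbacks
    guaranteeing at least one drug and one reaction per report fire
    rarely and the planted conditional probabilities hold closely.
    """
    socs = {
        "skin": "Skin and subcutaneous tissue disorders",
        "gi": "Gastrointestinal disorders",
        "general": "General disorders and administration site conditions",
        "msk": "Musculoskeletal and connective tissue disorders",
        "nerv": "Nervous system disorders",
        "inv": "Investigations",
        "vasc": "Vascular disorders",
        "psych": "Psychiatric disorders",
    }
    # decreasing background frequency; the planted PTs sit in the tail
    pts = [
        ("Fatigue", "general"),
        ("Nausea", "gi"),
        ("Headache", "nerv"),
        ("Diarrhoea", "gi"),
        ("Dizziness", "nerv"),
        ("Vomiting", "gi"),
        ("Rash", "skin"),
        ("Pain", "general"),
        ("Constipation", "gi"),
        ("Asthenia", "general"),
        ("Insomnia", "psych"),
        ("Pruritus", "skin"),
        ("Weight decreased", "inv"),
        ("Hypertension", "vasc"),
        ("Arthralgia", "msk"),
        ("Anxiety", "psych"),
        ("Dry skin", "skin"),
        ("Pain in extremity", "msk"),
        ("Alopecia", "skin"),
        ("Blood pressure increased", "inv"),
        ("Myalgia", "msk"),
        ("Muscle spasms", "msk"),
        ("Hyperkeratosis", "skin"),
        ("Palmar-plantar erythrodysaesthesia syndrome", "skin"),
    ]
    probs = _zipf_probs(len(pts))
    events = [EventSpec(pt, socs[s], p) for (pt, s), p in zip(pts, probs)]
    return SimulationConfig(
        n_reports=n_reports,
        drugs=[
            DrugSpec("TARGETINIB", 0.08),
            DrugSpec("OTHERMAB", 0.45),
            DrugSpec("PLACEBIX", 0.35),
            DrugSpec("COMEDIX", 0.55),
            DrugSpec("VITAPLEX", 0.50),
        ],
        events=events,
        signals=[
            PlantedSignal("TARGETINIB", "Alopecia", 8.0),
            PlantedSignal("TARGETINIB", "Palmar-plantar erythrodysaesthesia syndrome", 12.0),
            PlantedSignal("TARGETINIB", "Muscle spasms", 5.0),
        ],
        seed=seed,
    )


@dataclass
class SimulationConfig:
    """Full description of one simulated reporting stream.

    All probabilities live in [0, 1]; each demographics distribution
    (except the independent per-code ``outcome`` block) must sum to 1
    within 1e-9; multipliers are ≥ 0 with 1 meaning no association.
    """

    n_reports: int
    drugs: list[DrugSpec]
    events: list[EventSpec]
    signals: list[PlantedSignal] = field(default_factory=list)
    demographics: dict = field(default_factory=default_demographics)
    onset: OnsetMixture = field(default_factory=OnsetMixture)
    onset_by_soc: dict[str, OnsetMixture] = field(default_factory=dict)
    duplicate_fraction: float = 0.0
    deleted_fraction: float = 0.0
    partial_date_fraction: float = 0.0
    missing_rates: dict[str, float] = field(
        default_factory=lambda: {"event_dt": 0.0, "start_dt": 0.0}
    )
    study_start: str = "20200501"
    study_end: str = "20240301"
    seed: int = 0
    ensure_reaction: bool = True

    def validate(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        if not self.drugs:
            raise ValueError("drugs: catalogue must be non-empty")
        if not self.events:
            raise ValueError("events: catalogue must be non-empty")
        drug_names = [d.name for d in self.drugs]
        pt_names = [e.pt for e in self.events]
        if len(set(drug_names)) != len(drug_names):
            raise ValueError("drugs: duplicate drug names")
        if len(set(pt_names)) != len(pt_names):
            raise ValueError("events: duplicate PT names")
        for d in self.drugs:
            if not 0 <= d.prob <= 1:
                raise ValueError(f"drugs[{d.name!r}].prob must be in [0, 1]")
        for e in self.events:
            if not 0 <= e.prob <= 1:
                raise ValueError(f"events[{e.pt!r}].prob must be in [0, 1]")
        for s in self.signals:
            if s.drug not in drug_names:
                raise ValueError(f"signals: unknown drug {s.drug!r}")
            if s.pt not in pt_names:
                raise ValueError(f"signals: unknown PT {s.pt!r}")
            if s.multiplier < 0:
                raise ValueError(f"signals[{s.drug!r}/{s.pt!r}].multiplier must be >= 0")
        for key, dist in self.demographics.items():
            for label, p in dist.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"demographics[{key!r}][{label!r}] must be in [0, 1]")
            if key != "outcome" and abs(sum(dist.values()) - 1.0) > _PROB_TOL:
                raise ValueError(f"demographics[{key!r}] must sum to 1")
        for key in ("outcome",):
            for code in self.demographics.get(key, {}):
                if code not in OUTCOME_CODES:
                    raise ValueError(f"demographics['outcome']: unknown code {code!r}")
        for frac_name in ("duplicate_fraction", "deleted_fraction", "partial_date_fraction"):
            if not 0 <= getattr(self, frac_name) <= 1:
                raise ValueError(f"{frac_name} must be in [0, 1]")
        for key, p in self.missing_rates.items():
            if not 0 <= p <= 1:
                raise ValueError(f"missing_rates[{key!r}] must be in [0, 1]")
        for soc in self.onset_by_soc:
            if soc not in {e.soc for e in self.events}:
                raise ValueError(f"onset_by_soc: unknown SOC {soc!r}")


@dataclass
class GroundTruth:
    """What the generator knows that the pipeline must recover."""

    n_reports: int
    seed: int
    signals: list[dict]  # per planted pair: λ, expected a, observed a
    canonical: dict[str, str]  # caseid -> canonical PRIMARYID (kept cases)
    deleted_caseids: list[str]
    onset_days: dict[str, int]  # caseid -> sampled days to onset
    drug_reports: dict[str, dict[str, list[str]]]  # drug -> role-set -> caseids
    case_reactions: dict[str, list[str]]  # caseid -> PTs (sorted)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SimulatedData:
    """In-memory form of one simulated dataset.

    ``tables`` holds the FAERS-style row dicts ready for writing;
    the boolean ``drug_matrix``/``event_matrix`` (kept cases only,
    canonical versions) allow tests to form 2×2 tables instantly."""

    tables: dict[str, list[dict[str, str]]]
    deleted_caseids: list[str]
    truth: GroundTruth
    drug_names: list[str]
    event_names: list[str]
    drug_matrix: np.ndarray
    event_matrix: np.ndarray
    ps_drug_index: np.ndarray

    def contingency(self, drug: str, pt: str, ps_only: bool = False):
        """2×2 cell counts (a, b, c, d) for a drug–event pair over the
        kept (deduplicated, non-deleted) reports."""
        j = self.drug_names.index(drug)
        e = self.event_names.index(pt)
        exposed = self.drug_matrix[:, j]
        if ps_only:
            exposed = exposed & (self.ps_drug_index == j)
        with_event = self.event_matrix[:, e]
        a = int(np.sum(exposed & with_event))
        b = int(np.sum(exposed & ~with_event))
        c = int(np.sum(~exposed & with_event))
        d = int(np.sum(~exposed & ~with_event))
        return a, b, c, d


def _format_date(ordinal: int) -> str:
    return date.fromordinal(int(ordinal)).strftime("%Y%m%d")


def _truncate_dates(
    dates: list[str], rng: np.random.Generator, partial_frac: float, missing_rate: float
) -> list[str]:
    out = []
    for s in dates:
        u = rng.random()
        if u < missing_rate:
            out.append("")
        elif u < missing_rate + partial_frac:
            out.append(s[:6] if rng.random() < 0.7 else s[:4])
        else:
            out.append(s)
    return out


def _sample_categorical(
    rng: np.random.Generator, dist: dict[str, float], n: int
) -> list[str]:
    labels = list(dist)
    probs = np.array([dist[k] for k in labels], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(labels), size=n, p=probs)
    return [labels[i] for i in idx]


_AGE_RANGES = {"<18": (2, 17), "18-64.9": (18, 64), "65-85": (65, 85), ">85": (86, 100)}
_WEIGHT_RANGES = {"<50": (32.0, 49.9), "50-100": (50.0, 100.0), ">100": (100.5, 160.0)}
_OCC_CODES = {"consumer": "CN", "health_professional": "MD", "missing": ""}


def simulate(config: SimulationConfig) -> SimulatedData:
    """Run the generative model; see the module docstring for the model."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_kept = config.n_reports
    n_deleted = int(round(config.deleted_fraction * n_kept))
    n_cases = n_kept + n_deleted
    caseids = [str(10_000_000 + i) for i in range(n_cases)]
    deleted_mask = np.zeros(n_cases, dtype=bool)
    if n_deleted:
        deleted_mask[rng.choice(n_cases, size=n_deleted, replace=False)] = True

    k = len(config.drugs)
    m = len(config.events)
    drug_probs = np.array([d.prob for d in config.drugs])
    event_probs = np.array([e.prob for e in config.events])
    drug_names = [d.name for d in config.drugs]
    event_names = [e.pt for e in config.events]

    # --- drugs: independent Bernoulli, every report gets >= 1 drug
    drug_matrix = rng.random((n_cases, k)) < drug_probs
    empty = ~drug_matrix.any(axis=1)
    if empty.any():
        fallback = rng.choice(k, size=int(empty.sum()), p=drug_probs / drug_probs.sum())
        drug_matrix[np.flatnonzero(empty), fallback] = True

    # primary suspect: uniform among the report's drugs
    noise = rng.random((n_cases, k))
    noise[~drug_matrix] = -1.0
    ps_idx = noise.argmax(axis=1)

    # --- reactions: per-PT probability min(1, λ·q), λ = max over drugs
    mult = np.ones((n_cases, m))
    for sig in config.signals:
        j = drug_names.index(sig.drug)
        e = event_names.index(sig.pt)
        rows = drug_matrix[:, j]
        mult[rows, e] = np.maximum(mult[rows, e], sig.multiplier)
    probs = event_probs * mult
    capped = probs > 1.0
    if capped.any():
        logger.warning(
            "capping %d per-report event probabilities at 1 (λ·q > 1)",
            int(capped.any(axis=0).sum()),
        )
        probs = np.minimum(probs, 1.0)
    event_matrix = rng.random((n_cases, m)) < probs
    empty = ~event_matrix.any(axis=1)
    if config.ensure_reaction and empty.any():
        fallback = rng.choice(
            m, size=int(empty.sum()), p=event_probs / event_probs.sum()
        )
        event_matrix[np.flatnonzero(empty), fallback] = True

    # --- demographics
    demo_cfg = config.demographics
    sex = _sample_categorical(rng, demo_cfg["sex"], n_cases)
    age_band = _sample_categorical(rng, demo_cfg["age_band"], n_cases)
    weight_band = _sample_categorical(rng, demo_cfg["weight_band"], n_cases)
    country = _sample_categorical(rng, demo_cfg["country"], n_cases)
    occupation = _sample_categorical(rng, demo_cfg["occupation"], n_cases)
    ages = [
        str(int(rng.integers(lo, hi + 1)))
        if band in _AGE_RANGES
        else ""
        for band, (lo, hi) in ((b, _AGE_RANGES.get(b, (0, 0))) for b in age_band)
    ]
    weights = [
        f"{rng.uniform(*_WEIGHT_RANGES[band]):.1f}" if band in _WEIGHT_RANGES else ""
        for band in weight_band
    ]
    outcome_cfg = demo_cfg.get("outcome", {})
    outcome_codes = sorted(outcome_cfg)
    outcome_draws = rng.random((n_cases, len(outcome_codes)))
    outcome_sets = [
        [c for ci, c in enumerate(outcome_codes) if outcome_draws[i, ci] < outcome_cfg[c]]
        for i in range(n_cases)
    ]

    # --- dates: therapy start, onset days (possibly per-SOC), event, FDA
    base = date(int(config.study_start[:4]), int(config.study_start[4:6]),
                int(config.study_start[6:8])).toordinal()
    end = date(int(config.study_end[:4]), int(config.study_end[4:6]),
               int(config.study_end[6:8])).toordinal()
    start_ord = base + rng.integers(0, max(end - base, 1), size=n_cases)
    days = config.onset.sample(rng, n_cases)
    if config.onset_by_soc:
        first_event = event_matrix.argmax(axis=1)  # every row has >= 1 event
        event_socs = [e.soc for e in config.events]
        for soc, model in config.onset_by_soc.items():
            rows = np.array(
                [event_matrix[i].any() and event_socs[first_event[i]] == soc
                 for i in range(n_cases)]
            )
            if rows.any():
                days[rows] = model.sample(rng, int(rows.sum()))
    event_ord = start_ord + days
    fda_ord = event_ord + rng.integers(0, 61, size=n_cases)

    start_dt_full = [_format_date(o) for o in start_ord]
    event_dt_full = [_format_date(o) for o in event_ord]
    start_dt = _truncate_dates(
        start_dt_full, rng, config.partial_date_fraction,
        config.missing_rates.get("start_dt", 0.0),
    )
    event_dt = _truncate_dates(
        event_dt_full, rng, config.partial_date_fraction,
        config.missing_rates.get("event_dt", 0.0),
    )

    # --- duplicate case versions (clinical content identical)
    dup_mask = rng.random(n_cases) < config.duplicate_fraction
    early_offset = rng.integers(1, 30, size=n_cases)
    other_roles = rng.choice(["SS", "C", "I"], size=(n_cases, k), p=[0.4, 0.4, 0.2])

    demo_rows, drug_rows, reac_rows, outc_rows, ther_rows, indi_rows = (
        [], [], [], [], [], [],
    )
    canonical: dict[str, str] = {}

    for i, cid in enumerate(caseids):
        versions = []  # (primaryid, fda date string)
        if dup_mask[i]:
            versions.append((f"{cid}1", _format_date(fda_ord[i] - early_offset[i])))
            versions.append((f"{cid}2", _format_date(fda_ord[i])))
        else:
            versions.append((f"{cid}1", _format_date(fda_ord[i])))
        canonical[cid] = versions[-1][0]
        for pid, fda_dt in versions:
            demo_rows.append(
                {
                    "PRIMARYID": pid,
                    "CASEID": cid,
                    "EVENT_DT": event_dt[i],
                    "FDA_DT": fda_dt,
                    "SEX": {"male": "M", "female": "F"}.get(sex[i], ""),
                    "AGE": ages[i],
                    "AGE_COD": "YR" if ages[i] else "",
                    "WT": weights[i],
                    "WT_COD": "KG" if weights[i] else "",
                    "OCCP_COD": _OCC_CODES.get(occupation[i], ""),
                    "OCCR_COUNTRY": "" if country[i] == "missing" else country[i],
                    "REPORTER_COUNTRY": "" if country[i] == "missing" else country[i],
                }
            )
            seq = 0
            for j in np.flatnonzero(drug_matrix[i]):
                seq += 1
                role = "PS" if j == ps_idx[i] else str(other_roles[i, j])
                drug_rows.append(
                    {
                        "PRIMARYID": pid,
                        "CASEID": cid,
                        "DRUG_SEQ": str(seq),
                        "ROLE_COD": role,
                        "DRUGNAME": drug_names[j].upper(),
                        "PROD_AI": drug_names[j].upper(),
                    }
                )
                ther_rows.append(
                    {
                        "PRIMARYID": pid,
                        "CASEID": cid,
                        "DSG_DRUG_SEQ": str(seq),
                        "START_DT": start_dt[i],
                    }
                )
                indi_rows.append(
                    {
                        "PRIMARYID": pid,
                        "CASEID": cid,
                        "INDI_DRUG_SEQ": str(seq),
                        "INDI_PT": "Product used for unknown indication",
                    }
                )
            for e in np.flatnonzero(event_matrix[i]):
                reac_rows.append(
                    {"PRIMARYID": pid, "CASEID": cid, "PT": event_names[e]}
                )
            for code in outcome_sets[i]:
                outc_rows.append(
                    {"PRIMARYID": pid, "CASEID": cid, "OUTC_COD": code}
                )

    kept = ~deleted_mask
    kept_caseids = [cid for i, cid in enumerate(caseids) if kept[i]]

    # --- ground truth
    signals_truth = []
    for sig in config.signals:
        j = drug_names.index(sig.drug)
        e = event_names.index(sig.pt)
        p_event = min(1.0, sig.multiplier * event_probs[e])
        exposed = drug_matrix[:, j] & kept
        signals_truth.append(
            {
                "drug": sig.drug,
                "pt": sig.pt,
                "multiplier": sig.multiplier,
                "capped": bool(sig.multiplier * event_probs[e] > 1.0),
                "expected_a": float(n_kept * drug_probs[j] * p_event),
                "observed_a_any": int(np.sum(exposed & event_matrix[:, e])),
                "observed_a_ps": int(
                    np.sum(exposed & event_matrix[:, e] & (ps_idx == j))
                ),
            }
        )
    drug_reports = {
        name: {
            "any": [caseids[i] for i in np.flatnonzero(drug_matrix[:, j] & kept)],
            "ps": [
                caseids[i]
                for i in np.flatnonzero(drug_matrix[:, j] & kept & (ps_idx == j))
            ],
        }
        for j, name in enumerate(drug_names)
    }
    truth = GroundTruth(
        n_reports=n_kept,
        seed=config.seed,
        signals=signals_truth,
        canonical={cid: canonical[cid] for cid in kept_caseids},
        deleted_caseids=[cid for i, cid in enumerate(caseids) if deleted_mask[i]],
        onset_days={cid: int(days[i]) for i, cid in enumerate(caseids) if kept[i]},
        drug_reports=drug_reports,
        case_reactions={
            cid: sorted(event_names[e] for e in np.flatnonzero(event_matrix[i]))
            for i, cid in enumerate(caseids)
            if kept[i]
        },
    )
    return SimulatedData(
        tables={
            "DEMO": demo_rows,
            "DRUG": drug_rows,
            "REAC": reac_rows,
            "OUTC": outc_rows,
            "THER": ther_rows,
            "INDI": indi_rows,
        },
        deleted_caseids=truth.deleted_caseids,
        truth=truth,
        drug_names=drug_names,
        event_names=event_names,
        drug_matrix=drug_matrix[kept],
        event_matrix=event_matrix[kept],
        ps_drug_index=ps_idx[kept],
    )


_TABLE_COLUMNS = {
    "DEMO": [
        "PRIMARYID", "CASEID", "EVENT_DT", "FDA_DT", "SEX", "AGE", "AGE_COD",
        "WT", "WT_COD", "OCCP_COD", "OCCR_COUNTRY", "REPORTER_COUNTRY",
    ],
    "DRUG": ["PRIMARYID", "CASEID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME", "PROD_AI"],
    "REAC": ["PRIMARYID", "CASEID", "PT"],
    "OUTC": ["PRIMARYID", "CASEID", "OUTC_COD"],
    "THER": ["PRIMARYID", "CASEID", "DSG_DRUG_SEQ", "START_DT"],
    "INDI": ["PRIMARYID", "CASEID", "INDI_DRUG_SEQ", "INDI_PT"],
}


def generate_dataset(config: SimulationConfig, out_dir: str | Path) -> GroundTruth:
    """Simulate and write a dataset directory in the FAERS ASCII dialect.

    Writes DEMO/DRUG/REAC/OUTC/THER/INDI ``.txt`` tables, DELETED.txt
    (one CASEID per line), a PT→SOC mapping ``meddra_map.tsv`` covering
    the event catalogue, and ``ground_truth.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = simulate(config)
    for kind, rows in sim.tables.items():
        cols = _TABLE_COLUMNS[kind]
        lines = ["$".join(cols)]
        lines.extend("$".join(row[c] for c in cols) for row in rows)
        (out_dir / f"{kind}.txt").write_text("\n".join(lines) + "\n")
    (out_dir / "DELETED.txt").write_text(
        "".join(f"{cid}\n" for cid in sim.deleted_caseids)
    )
    write_meddra_map(config.events, out_dir / "meddra_map.tsv")
    sim.truth.save(out_dir / "ground_truth.json")
    return sim.truth


def write_meddra_map(event_catalog, path: str | Path) -> None:
    """Write a two-column tab-separated PT→SOC mapping for the catalogue.

    Accepts :class:`EventSpec` items or ``(pt, soc)`` pairs.  A PT
    mapped to two different SOCs is rejected.
    """
    pairs = []
    for item in event_catalog:
        if isinstance(item, EventSpec):
            pairs.append((item.pt, item.soc))
        else:
            pt, soc = item[0], item[1]
            pairs.append((pt, soc))
    if not pairs:
        raise ValueError("event catalogue must be non-empty")
    seen: dict[str, str] = {}
    for pt, soc in pairs:
        if pt in seen and seen[pt] != soc:
            raise ValueError(f"PT {pt!r} mapped to conflicting SOCs")
        seen[pt] = soc
    lines = ["pt\tsoc"] + [f"{pt}\t{soc}" for pt, soc in dict.fromkeys(pairs)]
    Path(path).write_text("\n".join(lines) + "\n")
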