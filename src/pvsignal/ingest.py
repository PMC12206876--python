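"""Reading, deduplication and normalization of FAERS-style quarterly tables.

FAERS distributes each quarter as ``$``-delimited ASCII tables (DEMO, DRUG,
REAC, THER, INDI) keyed by ``primaryid``.  This module parses those tables,
collapses duplicate case versions (same ``caseid``: keep the most recent FDA
receive date, ties broken by the highest ``primaryid``), and assembles one
:class:`SafetyReport` per surviving case with normalized drug names, a set of
MedDRA preferred terms (PT), and demographics binned for downstream analysis.

Dates are carried as digit strings (``YYYYMMDD``, ``YYYYMM`` or ``YYYY``);
calendar arithmetic is only ever attempted on full 8-digit dates.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import EmptyCohortError, FormatError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS: dict[str, tuple[str, ...]] = {
    "demo": ("primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
             "sex", "occp_cod", "reporter_country"),
    "drug": ("primaryid", "drug_seq", "role_cod", "drugname"),
    "reac": ("primaryid", "pt"),
    "ther": ("primaryid", "dsg_drug_seq", "start_dt"),
    "indi": ("primaryid", "indi_drug_seq", "indi_pt"),
}

#: FAERS age-unit codes -> factor converting the stated age to years.
AGE_UNIT_TO_YEARS: dict[str, float] = {
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.143,
    "DY": 1.0 / 365.25,
    "DEC": 10.0,
    "HR": 1.0 / 8766.0,
}

HCP_CODES = {"MD", "PH", "HP", "RN", "OT"}
NON_HCP_CODES = {"CN", "LW"}

#: Half-open age bins [lo, hi) and their display labels.
DEFAULT_AGE_BINS: tuple[tuple[float, float, str], ...] = (
    (0.0, 18.0, "<18"),
    (18.0, 65.0, "18-64.9"),
    (65.0, 85.0, "65-84.9"),
    (85.0, float("inf"), ">85"),
)

UNMAPPED_SOC = "UNMAPPED"


# ---------------------------------------------------------------------------
# date helpers


def date_completeness(s: str) -> str:
    """Classify a FAERS date string as ``full`` (8 digits), ``partial``
    (4 or 6 digits) or ``missing``."""
    s = (s or "").strip()
    if not s.isdigit():
        return "missing"
    if len(s) == 8:
        return "full"
    if len(s) in (4, 6):
        return "partial"
    return "missing"


def parse_full_date(s: str) -> date | None:
    """Parse an 8-digit YYYYMMDD string; return None for anything else."""
    if date_completeness(s) != "full":
        return None
    try:
        return date(int(s[:4]), int(s[4:6]), int(s[6:8]))
    except ValueError:
        return None


# ---------------------------------------------------------------------------
# domain types


@dataclass
class RawRecordSet:
    """Parsed but not yet normalized quarterly tables (all values strings)."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    indi: pd.DataFrame | None = None


@dataclass(frozen=True)
class DrugEntry:
    name_normalized: str
    role: str | None            # PS | SS | C | I | None
    therapy_start: str | None   # digit string, may be partial


@dataclass
class SafetyReport:
    primaryid: str
    caseid: str
    fda_dt: str
    event_dt: str
    sex: str | None             # "M" | "F" | None
    age_years: float | None
    age_group: str | None
    reporter_class: str | None
    country: str | None
    report_year: int | None
    drugs: list[DrugEntry]
    events: frozenset[str]
    indications: frozenset[str] = field(default_factory=frozenset)

    def soc_events(self, hierarchy: "EventHierarchy") -> frozenset[str]:
        return frozenset(hierarchy.soc_of(pt) for pt in self.events)


@dataclass
class EventHierarchy:
    """PT -> SOC map with the primary-SOC convention (one SOC per PT)."""

    pt_to_soc: dict[str, str]

    @property
    def soc_list(self) -> set[str]:
        return set(self.pt_to_soc.values())

    def soc_of(self, pt: str) -> str:
        return self.pt_to_soc.get(pt, UNMAPPED_SOC)


@dataclass
class AssemblySummary:
    """Accounting of every report-level exclusion during assembly."""

    n_demo_rows: int = 0
    n_reports: int = 0
    n_event_pairs: int = 0
    n_excluded_no_events: int = 0
    n_unmapped_pts: int = 0
    n_age_unit_fallback: int = 0


# ---------------------------------------------------------------------------
# parsing


def _read_table(path: Path, name: str, delimiter: str) -> pd.DataFrame:
    required = REQUIRED_COLUMNS[name]
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False,
                         encoding="utf-8", encoding_errors="replace",
                         engine="python")
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty file %s", name.upper(), path)
        return pd.DataFrame(columns=list(required))
    df.columns = [c.strip().lower() for c in df.columns]
    # REAC files sometimes label the event column pt_term
    if name == "reac" and "pt" not in df.columns and "pt_term" in df.columns:
        df = df.rename(columns={"pt_term": "pt"})
    for col in required:
        if col not in df.columns:
            raise FormatError(
                f"{name.upper()} file {path} is missing required column {col!r}")
    return df


def read_quarter(paths: Mapping[str, str | Path], delimiter: str = "$") -> RawRecordSet:
    """Read one quarter's DEMO/DRUG/REAC/THER (and optional INDI) tables.

    ``paths`` maps lower-case table names to file locations.  All values are
    kept as strings; dates keep their raw 8/6/4-digit form.
    """
    for name in ("demo", "drug", "reac", "ther"):
        if name not in paths:
            raise FormatError(f"no path supplied for required table {name!r}")
    tables = {name: _read_table(Path(p), name, delimiter)
              for name, p in paths.items() if name in REQUIRED_COLUMNS}
    return RawRecordSet(demo=tables["demo"], drug=tables["drug"],
                        reac=tables["reac"], ther=tables["ther"],
                        indi=tables.get("indi"))


# ---------------------------------------------------------------------------
# deduplication


def deduplicate(records: RawRecordSet) -> RawRecordSet:
    """Collapse duplicate case versions.

    Within each ``caseid`` cluster keep the row maximizing
    ``(fda_dt, primaryid)`` lexicographically: the most recent FDA receive
    date wins, and among ties the highest ``primaryid`` wins.  Child tables
    are restricted to the surviving ``primaryid`` values.  Idempotent.
    """
    demo = records.demo
    if demo.empty:
        return records
    if (demo["caseid"].str.strip() == "").any() or (demo["primaryid"].str.strip() == "").any():
        raise FormatError("DEMO rows with missing caseid/primaryid cannot be deduplicated")

    work = demo.copy()
    work["_fda"] = work["fda_dt"].map(lambda s: (s or "").strip().ljust(8, "0")
                                      if (s or "").strip().isdigit() else "")
    work["_pid"] = pd.to_numeric(work["primaryid"], errors="coerce").fillna(-1)

    dup_mask = work.duplicated("caseid", keep=False)
    if (dup_mask & (work["_fda"] == "")).any():
        logger.warning("duplicate cluster(s) with missing fda_dt: "
                       "falling back to primaryid ordering")

    keep_idx = (work.sort_values(["caseid", "_fda", "_pid"], kind="mergesort")
                .groupby("caseid", sort=False).tail(1).index)
    demo_out = demo.loc[demo.index.isin(keep_idx)].reset_index(drop=True)
    keep_pids = set(demo_out["primaryid"])

    def _restrict(df: pd.DataFrame | None) -> pd.DataFrame | None:
        if df is None:
            return None
        return df[df["primaryid"].isin(keep_pids)].reset_index(drop=True)

    return RawRecordSet(demo=demo_out, drug=_restrict(records.drug),
                        reac=_restrict(records.reac), ther=_restrict(records.ther),
                        indi=_restrict(records.indi))


# ---------------------------------------------------------------------------
# normalization helpers

_PUNCT_RE = re.compile(r"[^A-Z0-9 ]+")
_WS_RE = re.compile(r"\s+")


def normalize_drug_name(name: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Uppercase, strip punctuation, collapse whitespace, then resolve the
    result through the exact-match synonym table (no fuzzy matching)."""
    s = _WS_RE.sub(" ", _PUNCT_RE.sub(" ", (name or "").upper())).strip()
    if synonyms:
        s = synonyms.get(s, s)
    return s


def age_to_years(age: str, age_cod: str) -> tuple[float | None, bool]:
    """Convert a FAERS (age, unit-code) pair to years.

    Returns ``(years, fallback)`` where ``fallback`` records that a missing
    or unknown unit code was treated as years.
    """
    s = (age or "").strip()
    try:
        value = float(s)
    except ValueError:
        return None, False
    if value < 0:
        return None, False
    code = (age_cod or "").strip().upper()
    if code in AGE_UNIT_TO_YEARS:
        return value * AGE_UNIT_TO_YEARS[code], False
    return value, True  # treat as years, flagged


def age_group_of(age_years: float | None,
                 bins: Sequence[tuple[float, float, str]] = DEFAULT_AGE_BINS) -> str | None:
    if age_years is None:
        return None
    for lo, hi, label in bins:
        if lo <= age_years < hi:
            return label
    return None


def reporter_class_of(occp_cod: str) -> str | None:
    code = (occp_cod or "").strip().upper()
    if code in HCP_CODES:
        return "healthcare-professional"
    if code in NON_HCP_CODES:
        return "non-healthcare-professional"
    return None


# ---------------------------------------------------------------------------
# assembly


def assemble_reports(records: RawRecordSet,
                     synonyms: Mapping[str, str] | None = None,
                     hierarchy: EventHierarchy | None = None,
                     age_bins: Sequence[tuple[float, float, str]] = DEFAULT_AGE_BINS,
                     ) -> tuple[list[SafetyReport], AssemblySummary]:
    """Build one :class:`SafetyReport` per deduplicated DEMO row.

    Drug names are normalized and synonym-resolved; repeated PTs within one
    report collapse to a set; ages are converted to years and binned.
    Reports without any coded event are excluded and counted in the summary —
    nothing is dropped silently.
    """
    summary = AssemblySummary(n_demo_rows=len(records.demo))

    events_by_pid: dict[str, set[str]] = {}
    for pid, pt in zip(records.reac["primaryid"], records.reac["pt"]):
        term = (pt or "").strip().upper()
        if term:
            events_by_pid.setdefault(pid, set()).add(term)

    ther_by_key: dict[tuple[str, str], list[str]] = {}
    for pid, seq, start in zip(records.ther["primaryid"],
                               records.ther["dsg_drug_seq"],
                               records.ther["start_dt"]):
        ther_by_key.setdefault((pid, str(seq).strip()), []).append((start or "").strip())

    indi_by_key: dict[tuple[str, str], set[str]] = {}
    if records.indi is not None:
        for pid, seq, ipt in zip(records.indi["primaryid"],
                                 records.indi["indi_drug_seq"],
                                 records.indi["indi_pt"]):
            term = (ipt or "").strip().upper()
            if term:
                indi_by_key.setdefault((pid, str(seq).strip()), set()).add(term)

    drugs_by_pid: dict[str, list[tuple[str, DrugEntry]]] = {}
    for pid, seq, role, name in zip(records.drug["primaryid"],
                                    records.drug["drug_seq"],
                                    records.drug["role_cod"],
                                    records.drug["drugname"]):
        seq = str(seq).strip()
        role_norm = (role or "").strip().upper() or None
        starts = [s for s in ther_by_key.get((pid, seq), []) if s]
        # earliest therapy record defines initiation when several exist
        start = min((s for s in starts if date_completeness(s) == "full"),
                    default=(starts[0] if starts else None))
        entry = DrugEntry(name_normalized=normalize_drug_name(name, synonyms),
                          role=role_norm, therapy_start=start)
        drugs_by_pid.setdefault(pid, []).append((seq, entry))

    reports: list[SafetyReport] = []
    for row in records.demo.itertuples(index=False):
        pid = row.primaryid
        events = frozenset(events_by_pid.get(pid, set()))
        if not events:
            summary.n_excluded_no_events += 1
            continue
        if hierarchy is not None:
            summary.n_unmapped_pts += sum(
                1 for pt in events if hierarchy.soc_of(pt) == UNMAPPED_SOC)
        age_years, fallback = age_to_years(row.age, row.age_cod)
        if fallback:
            summary.n_age_unit_fallback += 1
        sex = (row.sex or "").strip().upper()
        fda = (row.fda_dt or "").strip()
        year = int(fda[:4]) if date_completeness(fda) in ("full", "partial") else None
        seq_entries = drugs_by_pid.get(pid, [])
        indications = frozenset().union(*(
            indi_by_key.get((pid, seq), set())
            for seq, entry in seq_entries if entry.role == "PS")) \
            if seq_entries else frozenset()
        reports.append(SafetyReport(
            primaryid=pid, caseid=row.caseid, fda_dt=fda,
            event_dt=(row.event_dt or "").strip(),
            sex=sex if sex in ("M", "F") else None,
            age_years=age_years,
            age_group=age_group_of(age_years, age_bins),
            reporter_class=reporter_class_of(row.occp_cod),
            country=(row.reporter_country or "").strip().upper() or None,
            report_year=year,
            drugs=[e for _, e in seq_entries],
            events=events,
            indications=indications,
        ))
    summary.n_reports = len(reports)
    summary.n_event_pairs = sum(len(r.events) for r in reports)
    if summary.n_age_unit_fallback:
        logger.warning("%d report(s) had age without a known unit code; "
                       "treated as years", summary.n_age_unit_fallback)
    return reports, summary


def select_index_cohort(reports: Sequence[SafetyReport], index_drug: str,
                        indication_filter: Iterable[str] | None = None,
                        ) -> tuple[list[SafetyReport], list[SafetyReport]]:
    """Partition the corpus into the primary-suspect index cohort and the rest.

    A report belongs to the index set when it carries a drug entry with
    ``name == index_drug`` and role PS, optionally restricted to reports
    whose primary-suspect indication falls in ``indication_filter``.
    """
    wanted = None if indication_filter is None else {t.upper() for t in indication_filter}
    index: list[SafetyReport] = []
    background: list[SafetyReport] = []
    for r in reports:
        is_index = any(d.name_normalized == index_drug and d.role == "PS"
                       for d in r.drugs)
        if is_index and wanted is not None:
            is_index = bool(r.indications & wanted)
        (index if is_index else background).append(r)
    if not index:
        raise EmptyCohortError(
            f"no report has {index_drug!r} as primary suspect"
            + ("" if wanted is None else " with the requested indication"))
    return index, background


# ---------------------------------------------------------------------------
# mapping-table loaders and report serialization


def load_synonyms(path: str | Path) -> dict[str, str]:
    """Two-column CSV (term, canonical); both sides normalized to uppercase."""
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if len(row) < 2 or row[0].lower() in ("term", "drugname"):
                continue
            out[normalize_drug_name(row[0])] = normalize_drug_name(row[1])
    return out


def load_hierarchy(path: str | Path) -> EventHierarchy:
    """Two-column CSV (pt, soc)."""
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if len(row) < 2 or row[0].lower() in ("pt", "pt_term"):
                continue
            mapping[row[0].strip().upper()] = row[1].strip().upper()
    return EventHierarchy(pt_to_soc=mapping)


def reports_to_jsonl(reports: Sequence[SafetyReport], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reports:
            fh.write(json.dumps({
                "primaryid": r.primaryid, "caseid": r.caseid,
                "fda_dt": r.fda_dt, "event_dt": r.event_dt,
                "sex": r.sex, "age_years": r.age_years,
                "age_group": r.age_group, "reporter_class": r.reporter_class,
                "country": r.country, "report_year": r.report_year,
                "drugs": [{"name": d.name_normalized, "role": d.role,
                           "therapy_start": d.therapy_start} for d in r.drugs],
                "events": sorted(r.events),
                "indications": sorted(r.indications),
            }, sort_keys=True) + "\n")


def reports_from_jsonl(path: str | Path) -> list[SafetyReport]:
    out: list[SafetyReport] = []
    with open(path) as fh:
        for line in fh:
            d = json.loads(line)
            out.append(SafetyReport(
                primaryid=d["primaryid"], caseid=d["caseid"],
                fda_dt=d["fda_dt"], event_dt=d["event_dt"], sex=d["sex"],
                age_years=d["age_years"], age_group=d["age_group"],
                reporter_class=d["reporter_class"], country=d["country"],
                report_year=d["report_year"],
                drugs=[DrugEntry(x["name"], x["role"], x["therapy_start"])
                       for x in d["drugs"]],
                events=frozenset(d["events"]),
                indications=frozenset(d.get("indications", ())),
            ))
    return out


def demographics_frame(reports: Sequence[SafetyReport]) -> pd.DataFrame:
    """Column-stable flat demographic table for CSV export."""
    return pd.DataFrame({
        "primaryid": [r.primaryid for r in reports],
        "caseid": [r.caseid for r in reports],
        "sex": [r.sex for r in reports],
        "age_years": [r.age_years for r in reports],
        "age_group": [r.age_group for r in reports],
        "reporter_class": [r.reporter_class for r in reports],
        "country": [r.country for r in reports],
        "report_year": [r.report_year for r in reports],
        "n_events": [len(r.events) for r in reports],
    })
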