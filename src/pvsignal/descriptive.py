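"""Descriptive summary of the index cohort (demographics table).

Counts and percentages by sex, age bin, reporter class, top-k reporting
countries and top-k reporting years, plus the age median/IQR on reports
with observed age.  Percentages are always against the number of reports;
the event total counts (report, PT) pairs and therefore exceeds it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ingest import DEFAULT_AGE_BINS, SafetyReport

MISSING = "missing"


@dataclass
class CohortSummary:
    n_reports: int
    n_events: int
    sex_counts: dict[str, int]
    age_counts: dict[str, int]
    reporter_counts: dict[str, int]
    country_top: list[tuple[str, int]]
    year_top: list[tuple[str, int]]
    age_median: float | None
    age_iqr: tuple[float, float] | None
    k: int = 5
    extras: dict = field(default_factory=dict)

    def pct(self, count: int) -> float:
        return 100.0 * count / self.n_reports if self.n_reports else 0.0


def _top_k(counter: Counter, k: int) -> list[tuple[str, int]]:
    # sort by count descending, ties lexicographic
    return sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))[:k]


def summarize(index: Sequence[SafetyReport], k: int = 5) -> CohortSummary:
    if not index:
        import logging
        logging.getLogger(__name__).warning("summarize called on an empty cohort")
    sex = Counter({"M": 0, "F": 0, MISSING: 0})
    age = Counter({label: 0 for *_, label in DEFAULT_AGE_BINS} | {MISSING: 0})
    reporter = Counter({"healthcare-professional": 0,
                        "non-healthcare-professional": 0, MISSING: 0})
    countries: Counter = Counter()
    years: Counter = Counter()
    ages: list[float] = []
    n_events = 0
    for r in index:
        n_events += len(r.events)
        sex[r.sex if r.sex in ("M", "F") else MISSING] += 1
        if r.age_group is None:
            age[MISSING] += 1
        else:
            age[r.age_group] += 1
        if r.age_years is not None:
            ages.append(r.age_years)
        reporter[r.reporter_class or MISSING] += 1
        if r.country:
            countries[r.country] += 1
        if r.report_year is not None:
            years[str(r.report_year)] += 1
    if ages:
        med = float(np.median(ages))
        q1, q3 = np.percentile(ages, [25, 75])
        age_median, age_iqr = med, (float(q1), float(q3))
    else:
        age_median, age_iqr = None, None
    return CohortSummary(n_reports=len(index), n_events=n_events,
                         sex_counts=dict(sex), age_counts=dict(age),
                         reporter_counts=dict(reporter),
                         country_top=_top_k(countries, k),
                         year_top=_top_k(years, k),
                         age_median=age_median, age_iqr=age_iqr, k=k)


def summary_frame(s: CohortSummary) -> pd.DataFrame:
    """Long-format CSV rendering: (section, category, count, percent)."""
    rows: list[tuple[str, str, float, float | None]] = [
        ("totals", "reports", s.n_reports, None),
        ("totals", "events", s.n_events, None),
    ]
    for section, counts in (("sex", s.sex_counts), ("age", s.age_counts),
                            ("reporter", s.reporter_counts)):
        for cat, c in counts.items():
            rows.append((section, cat, c, round(s.pct(c), 1)))
    for cat, c in s.country_top:
        rows.append(("country_top", cat, c, round(s.pct(c), 1)))
    for cat, c in s.year_top:
        rows.append(("year_top", cat, c, round(s.pct(c), 1)))
    if s.age_median is not None:
        rows.append(("age_summary", "median", s.age_median, None))
        rows.append(("age_summary", "iqr_low", s.age_iqr[0], None))
        rows.append(("age_summary", "iqr_high", s.age_iqr[1], None))
    return pd.DataFrame(rows, columns=["section", "category", "count", "percent"])


def summary_markdown(s: CohortSummary) -> str:
    df = summary_frame(s)
    lines = ["| Section | Category | Count | % |", "|---|---|---|---|"]
    for _, row in df.iterrows():
        pct = "" if row["percent"] is None or pd.isna(row["percent"]) else f"{row['percent']:.1f}"
        lines.append(f"| {row['section']} | {row['category']} | {row['count']:g} | {pct} |")
    return "\n".join(lines)
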