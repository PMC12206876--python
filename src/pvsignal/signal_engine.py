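"""Disproportionality statistics on drug-event 2x2 contingency tables.

The counting unit everywhere is the (report, term) pair: a report listing k
distinct preferred terms contributes k pairs at PT level and one pair per
distinct system organ class at SOC level.  For an index drug and a term the
cells are

    a = index reports mentioning the term        b = index pairs, other terms
    c = background reports mentioning the term   d = background pairs, other terms

Four statistics are computed per table: the reporting odds ratio (ROR) with a
Wald interval on the log scale, the proportional reporting ratio (PRR) with a
Pearson chi-square, the BCPNN information component (IC, in bits) with the
Noren lower credibility bound IC025, and (through :mod:`pvsignal.mgps`) the
empirical-Bayes geometric mean EBGM with its posterior 5th percentile EBGM05.
A term is gated positive when at least one method exceeds its threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateSampleError
from .ingest import EventHierarchy, SafetyReport

if TYPE_CHECKING:  # pragma: no cover
    from .mgps import GpsPrior


@dataclass(frozen=True)
class ContingencyTable:
    term: str
    level: str  # "PT" | "SOC"
    a: float
    b: float
    c: float
    d: float

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected pair count under row/column independence, (a+b)(a+c)/N."""
        n = self.n
        if n == 0:
            raise DegenerateSampleError("empty contingency table")
        return (self.a + self.b) * (self.a + self.c) / n


@dataclass
class SignalRow:
    term: str
    level: str
    a: int
    ror: float
    ror_low: float
    ror_high: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    corrected: bool = False          # 0.5 continuity add applied to ROR cells
    flags: dict[str, bool] = field(default_factory=dict)
    positive: bool = False


@dataclass(frozen=True)
class ThresholdPolicy:
    """Positivity thresholds for the four methods and their combination.

    Defaults are the standard published criteria: ROR lower bound > 1,
    PRR >= 2 with chi-square >= 4, IC025 > 0, EBGM05 > 2; a term qualifies
    when at least one method fires (``combination="any"``) and it has at
    least ``min_a`` index pairs.
    """

    min_a: int = 3
    ror_rule: Callable[[SignalRow], bool] = lambda r: r.ror_low > 1.0
    prr_rule: Callable[[SignalRow], bool] = lambda r: r.prr >= 2.0 and r.chi2 >= 4.0 and r.a >= 3
    ic_rule: Callable[[SignalRow], bool] = lambda r: r.ic025 > 0.0
    ebgm_rule: Callable[[SignalRow], bool] = lambda r: r.ebgm05 > 2.0
    combination: str = "any"  # "any" | "all"


DEFAULT_POLICY = ThresholdPolicy()


# ---------------------------------------------------------------------------
# table construction


def _terms_of(report: SafetyReport, hierarchy: EventHierarchy | None, level: str) -> frozenset[str]:
    if level == "PT":
        return report.events
    if level == "SOC":
        if hierarchy is None:
            raise ValueError("SOC-level tables require an event hierarchy")
        return report.soc_events(hierarchy)
    raise ValueError(f"unknown level {level!r}")


def build_tables(index: Sequence[SafetyReport], background: Sequence[SafetyReport],
                 hierarchy: EventHierarchy | None = None, level: str = "PT",
                 ) -> list[ContingencyTable]:
    """One 2x2 table per term observed anywhere in the corpus at ``level``.

    At SOC level a report contributes at most one pair per SOC regardless of
    how many of its PTs map there.  Sum of ``a`` over terms equals the index
    pair total at the level (conservation).
    """
    if not index:
        raise DegenerateSampleError("index cohort is empty")
    index_counts: dict[str, int] = {}
    bg_counts: dict[str, int] = {}
    n_index_pairs = 0
    n_bg_pairs = 0
    for r in index:
        terms = _terms_of(r, hierarchy, level)
        n_index_pairs += len(terms)
        for t in terms:
            index_counts[t] = index_counts.get(t, 0) + 1
    for r in background:
        terms = _terms_of(r, hierarchy, level)
        n_bg_pairs += len(terms)
        for t in terms:
            bg_counts[t] = bg_counts.get(t, 0) + 1
    out = []
    for term in sorted(set(index_counts) | set(bg_counts)):
        a = index_counts.get(term, 0)
        c = bg_counts.get(term, 0)
        out.append(ContingencyTable(term=term, level=level, a=a,
                                    b=n_index_pairs - a, c=c,
                                    d=n_bg_pairs - c))
    return out


# ---------------------------------------------------------------------------
# per-table statistics


def ror_stat(t: ContingencyTable, z: float = 1.959963984540054,
             ) -> tuple[float, float, float, bool]:
    """Reporting odds ratio (a*d)/(b*c) with the ln-scale Wald interval.

    Any zero cell triggers the Haldane-Anscombe 0.5 continuity add to all
    four cells; the returned ``corrected`` flag records it.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    corrected = min(a, b, c, d) <= 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_ror = math.log(ror)
    return ror, math.exp(log_ror - z * se), math.exp(log_ror + z * se), corrected


def prr_stat(t: ContingencyTable, yates: bool = False) -> tuple[float, float]:
    """Proportional reporting ratio [a/(a+b)] / [c/(c+d)] and Pearson chi2.

    With c = 0 the PRR is infinite; chi2 is then computed on the
    0.5-continuity-added table so the row stays reportable.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if a + b <= 0 or c + d <= 0:
        raise DegenerateSampleError("PRR undefined: an empty margin")
    if c <= 0:
        prr = math.inf
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        prr = (a / (a + b)) / (c / (c + d))
        a2, b2, c2, d2 = a, b, c, d
    n = a2 + b2 + c2 + d2
    denom = (a2 + b2) * (c2 + d2) * (a2 + c2) * (b2 + d2)
    if denom == 0:
        return prr, 0.0
    dev = abs(a2 * d2 - b2 * c2)
    if yates:
        dev = max(dev - n / 2.0, 0.0)
    return prr, n * dev * dev / denom


def ic025_from_ic(ic: float, a: float) -> float:
    """Noren's closed-form lower 2.5% credibility bound of the information
    component: IC - 3.3(a+0.5)^(-1/2) - 2.0(a+0.5)^(-3/2)."""
    return ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5


def ic_stat(t: ContingencyTable) -> tuple[float, float]:
    """BCPNN information component IC = log2((a+0.5)/(E+0.5)) in bits, with
    expected count E = (a+b)(a+c)/N, and its lower bound IC025."""
    if t.n == 0:
        raise DegenerateSampleError("IC undefined on an empty table")
    ic = math.log2((t.a + 0.5) / (t.expected + 0.5))
    return ic, ic025_from_ic(ic, t.a)


def ror_from_prr_inversion(a: float, n_index_pairs: float, prr: float,
                           background_pairs: float = 1_000_000.0,
                           ) -> tuple[float, float, float, bool]:
    """ROR implied by a printed (a, PRR) pair and the index pair total.

    The PRR fixes the background term proportion r = (a/n)/PRR; the table
    (a, n-a, r*M, (1-r)*M) then has an ROR independent of the background
    size M.  Used to check internal consistency of published tables.
    """
    r = (a / n_index_pairs) / prr
    t = ContingencyTable(term="", level="PT", a=a, b=n_index_pairs - a,
                         c=r * background_pairs, d=(1.0 - r) * background_pairs)
    return ror_stat(t)


# ---------------------------------------------------------------------------
# full pipeline over a table list


def compute_signals(tables: Sequence[ContingencyTable],
                    prior: "GpsPrior | None" = None,
                    policy: ThresholdPolicy = DEFAULT_POLICY,
                    ebgm_mode: str = "mgps",
                    yates: bool = False) -> list[SignalRow]:
    """All four statistics plus gating for every table.

    ``ebgm_mode="mgps"`` fits/uses the gamma-Poisson shrinker prior (fitted
    across ``tables`` when ``prior`` is None); ``ebgm_mode="ic"`` reports the
    simplified EBGM = 2**IC and EBGM05 = 2**IC025 instead.
    """
    from . import mgps  # local import to avoid a cycle

    if ebgm_mode not in ("mgps", "ic"):
        raise ValueError(f"unknown ebgm_mode {ebgm_mode!r}")
    if ebgm_mode == "mgps" and prior is None:
        prior = mgps.fit_prior(tables).prior

    rows: list[SignalRow] = []
    for t in tables:
        ror, lo, hi, corrected = ror_stat(t)
        prr, chi2 = prr_stat(t, yates=yates)
        ic, ic025 = ic_stat(t)
        if ebgm_mode == "ic":
            ebgm, ebgm05 = 2.0 ** ic, 2.0 ** ic025
        else:
            post = mgps.posterior(t, prior)
            ebgm, ebgm05 = post.ebgm, post.ebgm05
        rows.append(SignalRow(term=t.term, level=t.level, a=int(t.a),
                              ror=ror, ror_low=lo, ror_high=hi,
                              prr=prr, chi2=chi2, ic=ic, ic025=ic025,
                              ebgm=ebgm, ebgm05=ebgm05, corrected=corrected))
    return gate_signals(rows, policy)


def gate_signals(rows: Iterable[SignalRow],
                 policy: ThresholdPolicy = DEFAULT_POLICY) -> list[SignalRow]:
    """Apply per-method positivity flags and the combination rule; rows come
    back sorted by index pair count ``a`` descending (frequency ranking)."""
    out: list[SignalRow] = []
    for row in rows:
        if row.a < policy.min_a:
            flags = {m: False for m in ("ror", "prr", "ic", "ebgm")}
        else:
            flags = {"ror": bool(policy.ror_rule(row)),
                     "prr": bool(policy.prr_rule(row)),
                     "ic": bool(policy.ic_rule(row)),
                     "ebgm": bool(policy.ebgm_rule(row))}
        combine = any if policy.combination == "any" else all
        out.append(replace(row, flags=flags, positive=combine(flags.values())))
    out.sort(key=lambda r: (-r.a, r.term))
    return out


# ---------------------------------------------------------------------------
# output


def signal_frame(rows: Sequence[SignalRow]) -> pd.DataFrame:
    """Full-precision tabular view of a signal list."""
    return pd.DataFrame({
        "term": [r.term for r in rows],
        "level": [r.level for r in rows],
        "a": [r.a for r in rows],
        "ror": [r.ror for r in rows],
        "ror_low": [r.ror_low for r in rows],
        "ror_high": [r.ror_high for r in rows],
        "prr": [r.prr for r in rows],
        "chi2": [r.chi2 for r in rows],
        "ic": [r.ic for r in rows],
        "ic025": [r.ic025 for r in rows],
        "ebgm": [r.ebgm for r in rows],
        "ebgm05": [r.ebgm05 for r in rows],
        "corrected": [r.corrected for r in rows],
        "flag_ror": [r.flags.get("ror", False) for r in rows],
        "flag_prr": [r.flags.get("prr", False) for r in rows],
        "flag_ic": [r.flags.get("ic", False) for r in rows],
        "flag_ebgm": [r.flags.get("ebgm", False) for r in rows],
        "positive": [r.positive for r in rows],
    })


def format_report_style(rows: Sequence[SignalRow]) -> pd.DataFrame:
    """Two-decimal display table in the conventional column layout:
    term, case numbers, ROR (95% CI), PRR (chi2), EBGM (EBGM05), IC (IC025)."""
    def f(x: float) -> str:
        return "inf" if math.isinf(x) else f"{x:.2f}"
    return pd.DataFrame({
        "term": [r.term for r in rows],
        "case_numbers": [r.a for r in rows],
        "ROR(95%CI)": [f"{f(r.ror)} ({f(r.ror_low)}-{f(r.ror_high)})" for r in rows],
        "PRR(chi2)": [f"{f(r.prr)} ({f(r.chi2)})" for r in rows],
        "EBGM(EBGM05)": [f"{f(r.ebgm)} ({f(r.ebgm05)})" for r in rows],
        "IC(IC025)": [f"{f(r.ic)} ({f(r.ic025)})" for r in rows],
        "positive": ["*" if r.positive else "" for r in rows],
    })
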