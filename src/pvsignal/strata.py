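"""Subgroup and sensitivity re-analysis of the signal pipeline.

Subgroups slice the corpus by sex or age bin; each level is analysed
against a *within-stratum* background (the comparator is restricted to the
same level), so a stratum-specific reporting excess is not confounded by
the stratum's overall reporting profile.  Reports missing the stratifying
variable are excluded from every level and counted.

The sensitivity analysis restricts the index cohort to reports whose
co-medications all belong to a named partner-drug allowlist, i.e. it
excludes reports carrying any additional concomitant medication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .errors import EmptyCohortError
from .ingest import DEFAULT_AGE_BINS, EventHierarchy, SafetyReport
from .signal_engine import DEFAULT_POLICY, SignalRow, ThresholdPolicy, build_tables, compute_signals

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubgroupSpec:
    dimension: str  # "sex" | "age"
    levels: tuple[tuple[str, Callable[[SafetyReport], bool]], ...]


def sex_spec() -> SubgroupSpec:
    return SubgroupSpec(dimension="sex", levels=(
        ("M", lambda r: r.sex == "M"),
        ("F", lambda r: r.sex == "F"),
    ))


def age_spec(merge_65plus: bool = False) -> SubgroupSpec:
    """Age subgroups from the standard bins; ``merge_65plus`` collapses the
    two oldest bins into a single >=65 level."""
    labels = [label for *_, label in DEFAULT_AGE_BINS]
    if merge_65plus:
        merged = tuple(labels[2:])
        levels = tuple(
            [(lab, (lambda r, lab=lab: r.age_group == lab)) for lab in labels[:2]]
            + [(">=65", lambda r: r.age_group in merged)])
    else:
        levels = tuple((lab, (lambda r, lab=lab: r.age_group == lab)) for lab in labels)
    return SubgroupSpec(dimension="age", levels=levels)


@dataclass(frozen=True)
class SensitivitySpec:
    index_drug: str
    allowlist: frozenset[str]

    def __post_init__(self) -> None:
        if self.index_drug in self.allowlist:
            raise ValueError("index drug cannot be its own permitted partner")


Partition = tuple[list[SafetyReport], list[SafetyReport]]


def stratify(reports: Sequence[SafetyReport], spec: SubgroupSpec,
             index_drug: str) -> dict[str, Partition]:
    """Per-level (index, background) partitions with within-stratum
    comparators.  Levels whose index set is empty are skipped with a
    warning; reports missing the dimension fall outside every level."""
    out: dict[str, Partition] = {}
    assigned = 0
    for label, pred in spec.levels:
        members = [r for r in reports if pred(r)]
        assigned += len(members)
        index = [r for r in members
                 if any(d.name_normalized == index_drug and d.role == "PS"
                        for d in r.drugs)]
        if not index:
            logger.warning("stratum %s=%s has no index reports; skipped",
                           spec.dimension, label)
            continue
        index_ids = {id(r) for r in index}
        out[label] = (index, [m for m in members if id(m) not in index_ids])
    n_missing = len(reports) - assigned
    if n_missing:
        logger.info("%d report(s) missing %s excluded from all levels",
                    n_missing, spec.dimension)
    return out


def sensitivity_filter(index: Sequence[SafetyReport], spec: SensitivitySpec,
                       ) -> tuple[list[SafetyReport], int]:
    """Keep index reports whose non-index drugs all sit in the allowlist
    (reports with no co-medication pass vacuously).  Returns the retained
    set and the exclusion count.  Monotone in the allowlist."""
    retained = []
    for r in index:
        others = {d.name_normalized for d in r.drugs
                  if d.name_normalized != spec.index_drug}
        if others <= spec.allowlist:
            retained.append(r)
    return retained, len(index) - len(retained)


def run_stratified_signals(partitions: dict[str, Partition],
                           hierarchy: EventHierarchy | None = None,
                           level: str = "PT",
                           policy: ThresholdPolicy = DEFAULT_POLICY,
                           ebgm_mode: str = "mgps",
                           ) -> dict[str, list[SignalRow]]:
    """Full signal pipeline per stratum under one shared policy."""
    out: dict[str, list[SignalRow]] = {}
    for label, (index, background) in partitions.items():
        if not index:
            raise EmptyCohortError(f"stratum {label!r} has an empty index set")
        tables = build_tables(index, background, hierarchy=hierarchy, level=level)
        out[label] = compute_signals(tables, policy=policy, ebgm_mode=ebgm_mode)
    return out
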