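"""Synthetic FAERS-like corpora with known ground truth.

The generator emits quarterly-style DEMO/DRUG/REAC/THER tables in the same
``$``-delimited dialect the ingest module reads, plus a PT->SOC hierarchy
table and a JSON truth sidecar.  It emulates the structural features a
spontaneous-report analysis depends on: one primary-suspect drug per report
with optional co-medications, multiple coded events per report, duplicate
case versions (earlier receive date, lower primaryid), field missingness,
demographics, and onset dates whose lag after therapy start follows a
Weibull law.

Index reports sample their events from the background PT frequencies scaled
by planted relative-risk multipliers (optionally restricted to a sex or age
subgroup), so detection performance can be scored against the sidecar.
Every draw flows from a single seed; identical configs give byte-identical
files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .signal_engine import SignalRow

EPOCH = date(2004, 1, 1)
LAST_RECEIVE = date(2024, 9, 30)


@dataclass(frozen=True)
class PlantedSignal:
    pt: str
    rr: float               # relative-risk multiplier on the PT's weight
    sex: str | None = None  # restrict the excess to one sex
    age_group: str | None = None


@dataclass
class SynthConfig:
    """Full parameterization of one synthetic corpus.

    Defaults mirror the reporting structure of a carboplatin extract: index
    cohort share sized so ~20k reports yield a cohort in the thousands,
    ~3.1 events per report, onset lag Weibull(scale 51.72 d, shape 0.78),
    and demographic margins (sex, age, reporter, country) close to the
    published cohort table.
    """

    n_reports: int = 20_000
    n_pts: int = 200
    n_socs: int = 20
    index_drug: str = "CARBOPLATIN"
    p_index: float = 0.24
    drug_pool_size: int = 30
    planted_signals: tuple[PlantedSignal, ...] = ()
    mean_events: float = 3.1
    max_events: int = 10
    duplicate_rate: float = 0.05
    # demographics
    sex_probs: tuple[float, float, float] = (0.466, 0.306, 0.228)  # M, F, missing
    age_mean: float = 66.0
    age_sd: float = 13.0
    age_missing: float = 0.297
    occp_probs: tuple[tuple[str, float], ...] = (
        ("MD", 0.55), ("HP", 0.20), ("PH", 0.10), ("RN", 0.057),
        ("CN", 0.072), ("", 0.021))
    country_probs: tuple[tuple[str, float], ...] = (
        ("US", 0.233), ("DE", 0.218), ("JP", 0.091), ("GB", 0.070),
        ("FR", 0.063), ("OTHER", 0.325))
    # onset law and date completeness
    tto_scale: float = 51.72
    tto_shape: float = 0.78
    event_dt_missing: float = 0.45
    event_dt_partial: float = 0.10
    start_dt_missing: float = 0.05
    # co-medication
    allowlist_partners: tuple[str, ...] = (
        "GEMCITABINE", "PEMETREXED", "DOCETAXEL", "PACLITAXEL", "VINORELBINE",
        "PEMBROLIZUMAB", "ATEZOLIZUMAB", "AMIVANTAMAB")
    partner_prob: float = 0.5
    offlist_conmed_prob: float = 0.15
    seed: int = 0

    def pt_labels(self) -> list[str]:
        return [f"PT{i:03d}" for i in range(1, self.n_pts + 1)]

    def soc_of(self, pt_index: int) -> str:
        return f"SOC{(pt_index % self.n_socs) + 1:02d}"

    def background_weights(self) -> np.ndarray:
        """Zipf-like background PT frequencies, heavy head and long tail."""
        w = 1.0 / (np.arange(1, self.n_pts + 1) + 10.0)
        return w / w.sum()

    def validate(self) -> None:
        if not 0.0 < self.p_index < 1.0:
            raise ConfigError("p_index must lie strictly between 0 and 1")
        for name, probs in (("sex_probs", self.sex_probs),
                            ("occp_probs", [p for _, p in self.occp_probs]),
                            ("country_probs", [p for _, p in self.country_probs])):
            if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ConfigError(f"{name} must be a normalized probability vector")
        for ps in self.planted_signals:
            if ps.rr <= 0:
                raise ConfigError("planted relative risks must be positive")
            if ps.pt not in set(self.pt_labels()):
                raise ConfigError(f"planted PT {ps.pt!r} not in the vocabulary")
        if self.tto_scale <= 0 or self.tto_shape <= 0:
            raise ConfigError("Weibull onset parameters must be positive")


def _fmt(d: date) -> str:
    return d.strftime("%Y%m%d")


def _categorical(rng: np.random.Generator, items: Sequence[tuple[str, float]]) -> str:
    labels = [k for k, _ in items]
    probs = np.array([p for _, p in items])
    return labels[int(rng.choice(len(labels), p=probs))]


def generate_records(config: SynthConfig) -> tuple[dict[str, list[str]], dict]:
    """Generate the raw table rows (as pre-joined field lists) and the truth
    sidecar dict.  Deterministic given ``config`` (including its seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    pts = config.pt_labels()
    bg_w = config.background_weights()
    drug_pool = [f"DRUG{i:02d}" for i in range(1, config.drug_pool_size + 1)]

    demo_rows = [["primaryid", "caseid", "fda_dt", "event_dt", "age",
                  "age_cod", "sex", "occp_cod", "reporter_country"]]
    drug_rows = [["primaryid", "drug_seq", "role_cod", "drugname"]]
    reac_rows = [["primaryid", "pt"]]
    ther_rows = [["primaryid", "dsg_drug_seq", "start_dt"]]

    duplicate_clusters: dict[str, str] = {}
    index_pids: list[str] = []
    planted = list(config.planted_signals)
    n_index = 0
    n_tto_observable = 0

    horizon = (LAST_RECEIVE - EPOCH).days

    for i in range(config.n_reports):
        pid = str(1_000_000 + 10 * i + 5)
        caseid = str(5_000_000 + i)
        is_index = rng.random() < config.p_index

        # demographics
        u = rng.random()
        if u < config.sex_probs[0]:
            sex = "M"
        elif u < config.sex_probs[0] + config.sex_probs[1]:
            sex = "F"
        else:
            sex = ""
        if rng.random() < config.age_missing:
            age_s, age_cod, age_group = "", "", None
        else:
            age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 1.0, 99.0))
            age_s, age_cod = f"{age:.1f}", "YR"
            if age < 18:
                age_group = "<18"
            elif age < 65:
                age_group = "18-64.9"
            elif age < 85:
                age_group = "65-84.9"
            else:
                age_group = ">85"
        occp = _categorical(rng, config.occp_probs)
        country = _categorical(rng, config.country_probs)
        if country == "OTHER":
            country = ""

        # event sample: count from a truncated geometric, terms weighted
        k = int(min(rng.geometric(1.0 / config.mean_events), config.max_events,
                    config.n_pts))
        if is_index and planted:
            w = bg_w.copy()
            for psig in planted:
                if psig.sex is not None and psig.sex != sex:
                    continue
                if psig.age_group is not None and psig.age_group != age_group:
                    continue
                w[pts.index(psig.pt)] *= psig.rr
            w = w / w.sum()
        else:
            w = bg_w
        events = [pts[j] for j in rng.choice(config.n_pts, size=k, replace=False, p=w)]

        # drugs
        entries: list[tuple[str, str]] = []  # (role, name)
        if is_index:
            n_index += 1
            index_pids.append(pid)
            entries.append(("PS", config.index_drug))
            if rng.random() < config.partner_prob:
                n_partners = 1 + int(rng.random() < 0.3)
                for j in rng.choice(len(config.allowlist_partners),
                                    size=n_partners, replace=False):
                    entries.append(("C", config.allowlist_partners[int(j)]))
            if rng.random() < config.offlist_conmed_prob:
                entries.append(("C", drug_pool[int(rng.integers(len(drug_pool)))]))
        else:
            entries.append(("PS", drug_pool[int(rng.integers(len(drug_pool)))]))
            if rng.random() < 0.4:
                entries.append(("C", drug_pool[int(rng.integers(len(drug_pool)))]))

        # dates: therapy start, Weibull onset lag, receive date
        start = EPOCH + timedelta(days=int(rng.integers(0, horizon - 400)))
        tto = max(1, int(round(config.tto_scale * rng.weibull(config.tto_shape))))
        onset = start + timedelta(days=min(tto, 365))
        fda = onset + timedelta(days=int(rng.integers(7, 90)))
        if fda > LAST_RECEIVE:
            fda = LAST_RECEIVE
        u = rng.random()
        if u < config.event_dt_missing:
            event_s = ""
        elif u < config.event_dt_missing + config.event_dt_partial:
            event_s = _fmt(onset)[:6]
        else:
            event_s = _fmt(onset)
        start_s = "" if rng.random() < config.start_dt_missing else _fmt(start)
        if is_index and event_s and len(event_s) == 8 and start_s:
            n_tto_observable += 1

        def emit(pid_v: str, fda_v: date) -> None:
            demo_rows.append([pid_v, caseid, _fmt(fda_v), event_s, age_s,
                              age_cod, sex, occp, country])
            for seq, (role, name) in enumerate(entries, start=1):
                drug_rows.append([pid_v, str(seq), role, name])
                if role == "PS" and start_s:
                    ther_rows.append([pid_v, str(seq), start_s])
            for pt in events:
                reac_rows.append([pid_v, pt])

        if rng.random() < config.duplicate_rate:
            early_pid = str(1_000_000 + 10 * i + 1)
            early_fda = fda - timedelta(days=int(rng.integers(10, 200)))
            emit(early_pid, early_fda)
            duplicate_clusters[caseid] = pid
        emit(pid, fda)

    truth = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "n_reports": config.n_reports,
        "n_index": n_index,
        "index_primaryids": index_pids,
        "planted": [asdict(p) for p in planted],
        "duplicate_clusters": duplicate_clusters,
        "n_duplicates": len(duplicate_clusters),
        "n_tto_observable_index": n_tto_observable,
        "tto_law": {"scale": config.tto_scale, "shape": config.tto_shape},
    }
    tables = {"demo": demo_rows, "drug": drug_rows, "reac": reac_rows,
              "ther": ther_rows}
    return tables, truth


def generate(config: SynthConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the corpus as FAERS-dialect files plus hierarchy and truth.

    Returns the path of every file written.  Byte-identical across runs
    with the same config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables, truth = generate_records(config)
    paths: dict[str, Path] = {}
    for name, rows in tables.items():
        p = outdir / f"{name}.txt"
        with open(p, "w", newline="") as fh:
            fh.write("\n".join("$".join(r) for r in rows) + "\n")
        paths[name] = p
    hier = outdir / "hierarchy.csv"
    with open(hier, "w") as fh:
        fh.write("pt,soc\n")
        for j, pt in enumerate(config.pt_labels()):
            fh.write(f"{pt},{config.soc_of(j)}\n")
    paths["hierarchy"] = hier
    tp = outdir / "truth.json"
    with open(tp, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    paths["truth"] = tp
    return paths


@dataclass
class DetectionMetrics:
    sensitivity: float | None
    fpr: float
    n_planted: int
    n_detected: int
    n_null_terms: int
    n_false_positives: int
    per_planted: dict[str, bool] = field(default_factory=dict)


def truth_eval(rows: Sequence[SignalRow], truth: dict) -> DetectionMetrics:
    """Score gated positives against the planted PT set.

    Sensitivity is the detected fraction of planted terms (None when nothing
    was planted); the false-positive rate is the positive fraction among
    terms with no planted excess.
    """
    planted = {p["pt"] for p in truth.get("planted", []) if p["rr"] > 1.0}
    per_planted: dict[str, bool] = {}
    n_null = n_fp = 0
    for row in rows:
        if row.term in planted:
            per_planted[row.term] = per_planted.get(row.term, False) or row.positive
        else:
            n_null += 1
            n_fp += int(row.positive)
    for pt in planted:
        per_planted.setdefault(pt, False)
    n_det = sum(per_planted.values())
    return DetectionMetrics(
        sensitivity=(n_det / len(planted)) if planted else None,
        fpr=(n_fp / n_null) if n_null else 0.0,
        n_planted=len(planted), n_detected=n_det,
        n_null_terms=n_null, n_false_positives=n_fp,
        per_planted=per_planted)
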