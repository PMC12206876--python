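import json

import pytest

from pvsignal import ingest, signal_engine as se, synth


@pytest.fixture(scope="session")
def corpus(tmp_path_factory):
    """One standard synthetic corpus (20k reports, one strong planted PT)
    run through the full ingest + signal pipeline; shared across tests."""
    outdir = tmp_path_factory.mktemp("corpus")
    cfg = synth.SynthConfig(
        seed=20240101,
        planted_signals=(synth.PlantedSignal("PT150", 10.0),),
    )
    paths = synth.generate(cfg, outdir)
    truth = json.loads(paths["truth"].read_text())
    raw = ingest.read_quarter({k: paths[k] for k in ("demo", "drug", "reac", "ther")})
    deduped = ingest.deduplicate(raw)
    hierarchy = ingest.load_hierarchy(paths["hierarchy"])
    reports, summary = ingest.assemble_reports(deduped, hierarchy=hierarchy)
    index, background = ingest.select_index_cohort(reports, cfg.index_drug)
    tables = se.build_tables(index, background, hierarchy, "PT")
    rows = se.compute_signals(tables)
    return {
        "config": cfg, "paths": paths, "truth": truth, "raw": raw,
        "deduped": deduped, "hierarchy": hierarchy, "reports": reports,
        "summary": summary, "index": index, "background": background,
        "tables": tables, "rows": rows,
    }


@pytest.fixture(scope="session")
def null_corpus(tmp_path_factory):
    """A corpus with no planted excess anywhere (all relative risks 1)."""
    outdir = tmp_path_factory.mktemp("null_corpus")
    cfg = synth.SynthConfig(seed=775533)
    paths = synth.generate(cfg, outdir)
    truth = json.loads(paths["truth"].read_text())
    raw = ingest.read_quarter({k: paths[k] for k in ("demo", "drug", "reac", "ther")})
    reports, _ = ingest.assemble_reports(ingest.deduplicate(raw),
                                         hierarchy=ingest.load_hierarchy(paths["hierarchy"]))
    index, background = ingest.select_index_cohort(reports, cfg.index_drug)
    tables = se.build_tables(index, background, level="PT")
    rows = se.compute_signals(tables)
    return {"truth": truth, "rows": rows, "tables": tables}
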