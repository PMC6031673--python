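import json
from pathlib import Path

import pytest

from mirhub.ingest import DbClass, DbName, InteractionRecord
from mirhub.pipeline import run_pipeline, simulate_inputs


def make_record(
    mirna: str,
    gene: str,
    db: DbName,
    score: float | None = None,
) -> InteractionRecord:
    """Build a record with the db_class implied by the database."""
    db_class = DbClass.VALIDATED if db is DbName.MIRTARBASE else DbClass.PREDICTED
    return InteractionRecord(mirna, gene, db, db_class, score)


def passing_record(mirna: str, gene: str, db: DbName) -> InteractionRecord:
    """A record guaranteed to survive the default quality filter."""
    if db is DbName.MIRDB:
        return make_record(mirna, gene, db, 92.5)
    if db is DbName.MICRORNA_ORG:
        return make_record(mirna, gene, db, -1.5)
    return make_record(mirna, gene, db)


@pytest.fixture(scope="session")
def sim_run(tmp_path_factory) -> dict:
    """One synthetic study (seed 1) plus a completed pipeline run over it."""
    root = tmp_path_factory.mktemp("sim")
    cfg = simulate_inputs(root, seed=1)
    out = root / "out"
    report = run_pipeline(cfg, out)
    truth = json.loads((root / "truth.json").read_text())
    return {
        "dir": Path(root),
        "config": cfg,
        "out": out,
        "report": report,
        "truth": truth,
    }
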