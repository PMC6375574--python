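"""Shared fixtures: small synthetic scenarios reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from stmort import synthetic as syn


@pytest.fixture(scope="session")
def small_scenario():
    """Corrupted 6-province scenario, 2001-2015, default truth parameters."""
    return syn.simulate_scenario(n_provinces=6, seed=11)


@pytest.fixture(scope="session")
def clean_scenario():
    """Uncorrupted small scenario: registry equals the true death table."""
    params = syn.TruthParams(garbage_fraction=0.0, duplicate_fraction=0.0,
                             completeness=1.0)
    return syn.simulate_scenario(n_provinces=5, seed=7, params=params)


@pytest.fixture(scope="session")
def toy_geography():
    provinces, graph = syn.make_geography(4, seed=0)
    return provinces, graph


def records_from_rows(rows: list[dict]) -> pd.DataFrame:
    """Build a record-level registry frame from dict literals."""
    base = {"record_id": None, "year": 2005, "province_id": "P01",
            "sex": "male", "age": 60, "icd10": "I25"}
    out = []
    for i, row in enumerate(rows):
        rec = dict(base)
        rec.update(row)
        if rec["record_id"] is None:
            rec["record_id"] = f"R{i:06d}"
        out.append(rec)
    return pd.DataFrame(out)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
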