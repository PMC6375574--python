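"""Strict CSV readers and writers for every table the pipeline exchanges.

Each schema fixes the exact header (order included), column types and value
constraints; violations raise :class:`SchemaError` with the offending
column and row number.  write_table emits the canonical column order so a
write -> read -> write round trip is byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .ages import AGE_GROUPS, SEXES


class SchemaError(ValueError):
    """CSV does not conform to its declared schema."""


def _check_year(s: pd.Series) -> pd.Series:
    v = pd.to_numeric(s, errors="coerce")
    if v.isna().any() or (v != v.astype(int)).any():
        raise SchemaError(f"non-integer year at row {int(v.isna().idxmax()) + 2}")
    return v.astype(int)


def _check_nonneg(s: pd.Series, col: str) -> pd.Series:
    v = pd.to_numeric(s, errors="coerce")
    bad = v.isna() | (v < 0)
    if bad.any():
        raise SchemaError(f"negative or non-numeric {col} at row "
                          f"{int(bad.idxmax()) + 2}")
    return v.astype(float)


def _check_positive(s: pd.Series, col: str) -> pd.Series:
    v = _check_nonneg(s, col)
    bad = v <= 0
    if bad.any():
        raise SchemaError(f"nonpositive {col} at row {int(bad.idxmax()) + 2}")
    return v


def _check_age_group(s: pd.Series) -> pd.Series:
    bad = ~s.isin(AGE_GROUPS)
    if bad.any():
        raise SchemaError(
            f"unknown age_group {s[bad].iloc[0]!r} at row {int(bad.idxmax()) + 2}"
            f" (expected one of {AGE_GROUPS[0]}..{AGE_GROUPS[-1]})")
    return s


def _check_sex(s: pd.Series) -> pd.Series:
    bad = ~s.isin(SEXES + ("both",))
    if bad.any():
        raise SchemaError(f"unknown sex {s[bad].iloc[0]!r} at row "
                          f"{int(bad.idxmax()) + 2}")
    return s


SCHEMAS: dict[str, dict] = {
    "deaths": {
        "columns": ["year", "province_id", "sex", "age_group", "cause", "deaths"],
        "checks": {"year": _check_year, "sex": _check_sex,
                   "age_group": _check_age_group,
                   "deaths": lambda s: _check_nonneg(s, "deaths")},
    },
    "records": {
        "columns": ["record_id", "year", "province_id", "sex", "age", "icd10"],
        "checks": {"year": _check_year},
    },
    "population": {
        "columns": ["year", "province_id", "sex", "age_group", "population"],
        "checks": {"year": _check_year, "sex": _check_sex,
                   "age_group": _check_age_group,
                   "population": lambda s: _check_positive(s, "population")},
    },
    "censuses": {
        "columns": ["census_year", "province_id", "sex", "age_group", "population"],
        "checks": {"census_year": _check_year, "sex": _check_sex,
                   "age_group": _check_age_group,
                   "population": lambda s: _check_positive(s, "population")},
    },
    "covariates": {
        "columns": ["year", "province_id", "sex", "wealth_index",
                    "years_schooling", "urbanization"],
        "checks": {"year": _check_year, "sex": _check_sex,
                   "years_schooling": lambda s: _check_nonneg(s, "years_schooling"),
                   "urbanization": lambda s: _check_nonneg(s, "urbanization")},
    },
    "adjacency": {
        "columns": ["province_a", "province_b"],
        "checks": {},
    },
    "truth": {
        "columns": ["year", "province_id", "sex", "age_group", "cause", "log_rate"],
        "checks": {"year": _check_year, "sex": _check_sex,
                   "age_group": _check_age_group},
    },
    "estimates": {
        "columns": ["year", "province_id", "sex", "cause", "age_group",
                    "rate_mean", "rate_lo", "rate_hi"],
        "checks": {"year": _check_year, "sex": _check_sex,
                   "age_group": _check_age_group,
                   "rate_mean": lambda s: _check_nonneg(s, "rate_mean")},
    },
    "asr": {
        "columns": ["year", "province_id", "sex", "cause", "asr", "lo", "hi"],
        "checks": {"year": _check_year, "sex": _check_sex,
                   "asr": lambda s: _check_nonneg(s, "asr")},
    },
    "proportional_mortality": {
        "columns": ["year", "level", "cause", "share_percent"],
        "checks": {"year": _check_year,
                   "share_percent": lambda s: _check_nonneg(s, "share_percent")},
    },
    "splits": {
        "columns": ["child", "parent", "first_valid_year", "share"],
        "checks": {"first_valid_year": _check_year,
                   "share": lambda s: _check_positive(s, "share")},
    },
    "standard_population": {
        "columns": ["age_group", "weight"],
        "checks": {"age_group": _check_age_group,
                   "weight": lambda s: _check_nonneg(s, "weight")},
    },
    "completeness": {
        "columns": ["province_id", "completeness"],
        "checks": {"completeness": lambda s: _check_positive(s, "completeness")},
    },
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema."""
    spec = SCHEMAS[schema]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != spec["columns"]:
        raise SchemaError(
            f"{path}: header {list(df.columns)} != expected {spec['columns']}")
    for col, check in spec["checks"].items():
        df[col] = check(df[col])
    for col in spec["columns"]:
        if col not in spec["checks"] and col not in (
                "province_id", "sex", "age_group", "icd10", "record_id",
                "cause", "level", "child", "parent", "province_a", "province_b"):
            df[col] = pd.to_numeric(df[col])
    return df


def write_table(table: pd.DataFrame, path: str | Path, schema: str) -> None:
    """Write a table in canonical column order (UTF-8, header row)."""
    spec = SCHEMAS[schema]
    missing = [c for c in spec["columns"] if c not in table.columns]
    if missing:
        raise SchemaError(f"cannot write {schema}: missing column {missing[0]}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table[spec["columns"]].to_csv(path, index=False)


def graph_to_frame(graph) -> pd.DataFrame:
    rows = [{"province_a": a, "province_b": b} for a, b in sorted(graph.edges())]
    return pd.DataFrame(rows, columns=["province_a", "province_b"])


def frame_to_graph(df: pd.DataFrame, nodes=None):
    import networkx as nx

    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    g.add_edges_from(df[["province_a", "province_b"]].itertuples(index=False))
    return g
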