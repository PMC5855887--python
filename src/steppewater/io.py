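"""CSV schemas and validated readers/writers for the pipeline tables.

All tables are plain CSV with documented headers.  Readers type-check the
required columns, parse ISO-8601 dates, canonicalize treatment labels
(case/whitespace), and report the offending row number on parse failures.
Unknown columns are preserved but ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class TableSchema:
    name: str
    required: dict                    #: column -> dtype kind ("date", "float", "int", "str", "treatment", "bool")
    normalize_treatment: bool = True


SCHEMAS = {
    "weather": TableSchema("weather", {"date": "date", "precip_mm": "float", "tmean_c": "float"},
                           normalize_treatment=False),
    "sensor": TableSchema("sensor", {"date": "date", "plot_id": "str", "group_id": "int",
                                     "treatment": "treatment", "depth_cm": "int",
                                     "vwc": "float", "n_sensors": "int"}),
    "calibration": TableSchema("calibration", {"plot_id": "str", "year": "int",
                                               "r626": "float", "r652": "float",
                                               "r859": "float", "r875": "float",
                                               "biomass_g_m2": "float"},
                               normalize_treatment=False),
    "plot_year": TableSchema("plot_year", {"plot_id": "str", "treatment": "treatment",
                                           "treatment_year": "int", "anpp": "float",
                                           "vwc": "float"}),
    "community": TableSchema("community", {"plot_id": "str", "treatment": "treatment",
                                           "year": "int", "species": "str",
                                           "measure_type": "str", "value": "float"}),
    "daily_series": TableSchema("daily_series", {"date": "date", "treatment": "treatment",
                                                 "vwc_mean": "float", "source": "str"}),
}

_CANONICAL_TREATMENTS = {"control", "drought", "irrigation", "ambient"}


def normalize_treatment(value: str) -> str:
    t = str(value).strip().lower()
    if t not in _CANONICAL_TREATMENTS:
        raise ValueError(f"unknown treatment label {value!r}")
    return t


def read_table(path, schema: str | TableSchema) -> pd.DataFrame:
    """Read and validate a pipeline CSV against a named schema."""
    sch = SCHEMAS[schema] if isinstance(schema, str) else schema
    df = pd.read_csv(path)
    missing = set(sch.required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)} "
                         f"for schema {sch.name!r}")
    for col, kind in sch.required.items():
        try:
            if kind == "date":
                df[col] = pd.to_datetime(df[col], format="ISO8601")
            elif kind == "float":
                df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
            elif kind == "int":
                df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
            elif kind == "treatment":
                df[col] = df[col].map(normalize_treatment)
            elif kind == "bool":
                df[col] = df[col].astype(bool)
        except (ValueError, TypeError) as exc:
            row = _first_bad_row(df[col], kind)
            raise ValueError(f"{path}: column {col!r} row {row}: {exc}") from exc
    return df


def _first_bad_row(series: pd.Series, kind: str) -> int:
    for i, val in enumerate(series):
        try:
            if kind == "date":
                pd.Timestamp(val)
            elif kind in ("float", "int"):
                float(val)
            elif kind == "treatment":
                normalize_treatment(val)
        except (ValueError, TypeError):
            return i + 2  # header is line 1
    return -1


def write_table(df: pd.DataFrame, path) -> None:
    """Write a pipeline table as CSV (ISO dates, no index)."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
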