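"""Readers for the tidy CSV measurement schemas.

Column contracts (units fixed by the header names):

* ``design.csv`` — treatment_id, daphnia_mg_l, leaf_mg_l, community,
  n_replicates
* ``co2.csv`` — treatment_id, replicate, day, co2_umol_l, delta13C_permil,
  temperature_C
* ``poc.csv`` — treatment_id, replicate, phase, poc_mg_c_l, delta13C_permil
* ``doc.csv`` — treatment_id, replicate, phase, doc_mg_c_l
* ``plfa.csv`` — compound, treatment_id, replicate, phase, conc_ng_l,
  delta13C_permil (nullable)
* ``mims.csv`` — day, treatment_id, i32, i40, i44, i45
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "read_design",
    "read_co2",
    "read_poc",
    "read_doc",
    "read_plfa",
    "read_mims",
]

_SCHEMAS = {
    "design": ("treatment_id", "daphnia_mg_l", "leaf_mg_l", "community", "n_replicates"),
    "co2": ("treatment_id", "replicate", "day", "co2_umol_l", "delta13C_permil", "temperature_C"),
    "poc": ("treatment_id", "replicate", "phase", "poc_mg_c_l", "delta13C_permil"),
    "doc": ("treatment_id", "replicate", "phase", "doc_mg_c_l"),
    "plfa": ("compound", "treatment_id", "replicate", "phase", "conc_ng_l", "delta13C_permil"),
    "mims": ("day", "treatment_id", "i32", "i40", "i44", "i45"),
}


def _read(path, schema: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_SCHEMAS[schema]) - set(df.columns)
    if missing:
        raise KeyError(
            f"{schema} table at {path} is missing columns {sorted(missing)}; "
            f"expected header contract {_SCHEMAS[schema]}"
        )
    return df


def read_design(path) -> pd.DataFrame:
    return _read(path, "design")


def read_co2(path) -> pd.DataFrame:
    return _read(path, "co2")


def read_poc(path) -> pd.DataFrame:
    return _read(path, "poc")


def read_doc(path) -> pd.DataFrame:
    return _read(path, "doc")


def read_plfa(path) -> pd.DataFrame:
    return _read(path, "plfa")


def read_mims(path) -> pd.DataFrame:
    return _read(path, "mims")
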