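"""Bundled reference data: published per-subject results tables and device profiles.

The two CSVs transcribe the per-subject machine-learning results reported
for the simulator and in-flight experiments (accuracy in training and
testing, precision, recall and F1, all in percent, high load positive).
They serve as fixed inputs for the summary statistics, not as anything the
pipeline itself produces.
"""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path

import pandas as pd

__all__ = ["load_results_table", "profile_path"]

_TABLES = {"simulator": "table1_simulator.csv", "flight": "table2_flight.csv"}
_PROFILES = {"sim16": "sim16.yaml", "flight4": "flight4.yaml"}


def _data_dir() -> Path:
    return Path(str(files("nirsbci") / "data"))


def load_results_table(which: str) -> pd.DataFrame:
    """Per-subject results for the ``simulator`` or ``flight`` experiment."""
    if which not in _TABLES:
        raise ValueError(f"unknown table {which!r}; choose from {sorted(_TABLES)}")
    return pd.read_csv(_data_dir() / _TABLES[which], dtype={"subject": str})


def profile_path(name: str) -> Path:
    """Path to a bundled device-profile YAML (``sim16`` or ``flight4``)."""
    if name not in _PROFILES:
        raise ValueError(f"unknown profile {name!r}; choose from {sorted(_PROFILES)}")
    return _data_dir() / _PROFILES[name]
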