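"""Delimited-text I/O for cohorts, clones and configuration.

Cohort files are CSV (comma separated, UTF-8, header row, '.' decimal) with
one row per patient; the multi-state event history is serialized in a single
``history`` column as semicolon-separated ``day:state`` pairs, always
starting with ``0:1`` (admitted to the ward at day 0).  Because the model is
forward-only, a history has at most three entries: admission, an optional
ICU transfer, and an optional absorbing event.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .simulate import COVARIATE_COLUMNS, FLAG_COLUMNS, SimulationConfig
from .states import ICU, WARD

COHORT_CSV_COLUMNS = (
    ("patient_id",)
    + COVARIATE_COLUMNS
    + ("treatment_day", "history")
    + FLAG_COLUMNS
)

CLONE_CSV_COLUMNS = (
    (
        "patient_id",
        "arm",
        "censor_day",
        "censor_indicator",
        "followup_end",
        "end_reason",
        "terminal_state",
    )
    + COVARIATE_COLUMNS
    + ("icu_day", "event_day", "event_state")
)


def history_to_string(icu_day: float, event_day: float, event_state: int) -> str:
    parts = [f"0:{WARD}"]
    if not np.isnan(icu_day):
        parts.append(f"{int(icu_day)}:{ICU}")
    if event_state and not np.isnan(event_day):
        parts.append(f"{int(event_day)}:{int(event_state)}")
    return ";".join(parts)


def parse_history(text: str) -> tuple[float, float, int]:
    """Parse a serialized history into (icu_day, event_day, event_state)."""
    entries = []
    for chunk in str(text).split(";"):
        day_s, state_s = chunk.split(":")
        entries.append((int(day_s), int(state_s)))
    if not entries or entries[0] != (0, WARD):
        raise SchemaError(f"history must start with '0:{WARD}', got {text!r}")
    icu_day, event_day, event_state = np.nan, np.nan, 0
    prev_day = 0
    for day, state in entries[1:]:
        if day < prev_day or (day == prev_day and day != 0):
            raise SchemaError(f"history days must be increasing in {text!r}")
        if state == ICU:
            if not np.isnan(icu_day) or event_state:
                raise SchemaError(f"invalid transition sequence in {text!r}")
            icu_day = float(day)
        elif state in (3, 4, 5):
            if event_state:
                raise SchemaError(f"more than one absorbing event in {text!r}")
            event_day, event_state = float(day), int(state)
        else:
            raise SchemaError(f"unknown state {state} in history {text!r}")
        prev_day = day
    return icu_day, event_day, event_state


def write_cohort(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["history"] = [
        history_to_string(i, e, s)
        for i, e, s in zip(
            df["icu_day"].to_numpy(dtype=float),
            df["event_day"].to_numpy(dtype=float),
            df["event_state"].to_numpy(dtype=int),
        )
    ]
    out[list(COHORT_CSV_COLUMNS)].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in COHORT_CSV_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"cohort file is missing required column {col!r}")
    parsed = [parse_history(h) for h in df["history"]]
    df["icu_day"] = [p[0] for p in parsed]
    df["event_day"] = [p[1] for p in parsed]
    df["event_state"] = [p[2] for p in parsed]
    for col in FLAG_COLUMNS:
        df[col] = df[col].astype(bool)
    return df.drop(columns=["history"])


def write_clones(clones: pd.DataFrame, path) -> None:
    clones[list(CLONE_CSV_COLUMNS)].to_csv(path, index=False)


def read_clones(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in CLONE_CSV_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"clone file is missing required column {col!r}")
    df["event_state"] = df["event_state"].fillna(0).astype(int)
    return df


def load_yaml(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return data or {}


def dump_yaml(data: Mapping, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dict(data), fh, sort_keys=True)


def simulation_config_from_yaml(path) -> SimulationConfig:
    return SimulationConfig.from_dict(load_yaml(path))
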