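"""Reading and writing the tabular interchange formats.

Canonical format is a long (tidy) CSV with one row per reading:

    participant_id,session,position,device,variable,value

A wide dialect (one row per participant x session x variable, seven value
columns ``pos1..pos7``) is accepted on read.  Participant profiles travel in
a separate CSV.  All structural problems found on read are collected and
reported together.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd

from .model import (
    N_POSITIONS,
    Device,
    IntegrityError,
    ParticipantProfile,
    Reading,
    SchemaError,
    SessionSeries,
    Sex,
    StudyDataset,
    Variable,
    device_for_position,
)

__all__ = ["read_study", "write_study", "read_profiles", "write_profiles", "LONG_COLUMNS"]

logger = logging.getLogger(__name__)

LONG_COLUMNS = ("participant_id", "session", "position", "device", "variable", "value")
WIDE_VALUE_COLUMNS = tuple(f"pos{i}" for i in range(1, N_POSITIONS + 1))
PROFILE_COLUMNS = ("participant_id", "sex", "age", "weight_kg", "height_cm", "arm_circ_mm")


def _apply_schema(df: pd.DataFrame, schema: Optional[Mapping[str, str]]) -> pd.DataFrame:
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    return df


def read_study(
    path: Union[str, Path],
    schema: Optional[Mapping[str, str]] = None,
    profiles_path: Optional[Union[str, Path]] = None,
) -> StudyDataset:
    """Load a study CSV (long or wide dialect) into a validated StudyDataset.

    Parameters
    ----------
    path:
        CSV file with either the long columns
        ``participant_id,session,position,device,variable,value`` or the wide
        columns ``participant_id,session,variable,pos1..pos7``.
    schema:
        Optional mapping from canonical column name to the name used in the
        file, e.g. ``{"participant_id": "subject"}``.
    profiles_path:
        Optional participant-profile CSV.

    Raises
    ------
    SchemaError
        Required columns missing.
    IntegrityError
        Parity violations, bad labels or unparseable values; all offending
        rows are listed in the error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"participant_id": str})
    df = _apply_schema(df, schema)

    if set(WIDE_VALUE_COLUMNS).issubset(df.columns):
        df = _wide_to_long(df)

    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"missing required column(s) {missing} in {path.name}; "
            f"found {list(df.columns)}"
        )

    problems: list[str] = []
    dataset = StudyDataset(metadata={"source": str(path)})
    series_map: dict[tuple[str, int, str], SessionSeries] = {}

    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        pid = str(row.participant_id)
        try:
            session = int(row.session)
            position = int(row.position)
        except (TypeError, ValueError):
            problems.append(f"line {idx}: non-integer session/position")
            continue
        try:
            device = Device(str(row.device).strip().lower())
        except ValueError:
            problems.append(f"line {idx}: unknown device label {row.device!r}")
            continue
        try:
            variable = Variable(str(row.variable).strip().upper())
        except ValueError:
            problems.append(f"line {idx}: unknown variable label {row.variable!r}")
            continue
        if pd.isna(row.value):
            # a blank value marks a missing slot, not an error
            value = None
        else:
            try:
                value = float(row.value)
            except (TypeError, ValueError):
                problems.append(f"line {idx}: non-numeric value {row.value!r}")
                continue
        if position not in range(1, N_POSITIONS + 1):
            problems.append(f"line {idx}: position {position} outside 1..{N_POSITIONS}")
            continue
        if device is not device_for_position(position):
            problems.append(
                f"line {idx}: device {device.value!r} at position {position} violates "
                f"alternation (expected {device_for_position(position).value!r})"
            )
            continue
        if session not in (1, 2):
            problems.append(f"line {idx}: session {session} not in {{1, 2}}")
            continue
        key = (pid, session, variable.value)
        series = series_map.get(key)
        if series is None:
            series = SessionSeries(pid, session, variable)
            series_map[key] = series
        if value is not None and series.values[position - 1] is not None:
            problems.append(
                f"line {idx}: duplicate reading for participant {pid} session "
                f"{session} variable {variable.value} position {position}"
            )
            continue
        if value is not None:
            series.values[position - 1] = value

    if problems:
        raise IntegrityError(f"{len(problems)} integrity problem(s) in {path.name}", problems)

    for series in series_map.values():
        dataset.add_series(series)

    if profiles_path is not None:
        dataset.profiles = read_profiles(profiles_path, schema=schema)

    warnings = dataset.validate()
    incomplete = [w for w in warnings if w.startswith("incomplete series")]
    for warning in warnings:
        if warning not in incomplete:
            logger.warning(warning)
    if incomplete:
        logger.warning(
            "%d incomplete series excluded from protocol evaluation "
            "(retained for descriptive statistics)", len(incomplete)
        )
    return dataset


def _wide_to_long(df: pd.DataFrame) -> pd.DataFrame:
    required = ["participant_id", "session", "variable", *WIDE_VALUE_COLUMNS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"wide-format file missing column(s) {missing}")
    long = df.melt(
        id_vars=["participant_id", "session", "variable"],
        value_vars=list(WIDE_VALUE_COLUMNS),
        var_name="position",
        value_name="value",
    )
    long["position"] = long["position"].str.removeprefix("pos").astype(int)
    long["device"] = [device_for_position(p).value for p in long["position"]]
    return long[list(LONG_COLUMNS)]


def write_study(
    dataset: StudyDataset,
    path: Union[str, Path],
    round_to_int: bool = False,
) -> Path:
    """Write a dataset to the canonical long CSV.

    Rows are ordered by participant, session, variable, position so a
    read/write round trip preserves ordering.  ``round_to_int`` mimics the
    integer output of real devices.
    """
    path = Path(path)
    rows = []
    for key in sorted(dataset.series):
        series = dataset.series[key]
        for pos, val in enumerate(series.values, start=1):
            if val is None:
                continue
            rows.append(
                {
                    "participant_id": series.participant_id,
                    "session": series.session,
                    "position": pos,
                    "device": device_for_position(pos).value,
                    "variable": series.variable.value,
                    "value": round(val) if round_to_int else val,
                }
            )
    frame = pd.DataFrame(rows, columns=list(LONG_COLUMNS))
    frame.to_csv(path, index=False)
    return path


def read_profiles(
    path: Union[str, Path], schema: Optional[Mapping[str, str]] = None
) -> dict[str, ParticipantProfile]:
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str})
    df = _apply_schema(df, schema)
    if "participant_id" not in df.columns:
        raise SchemaError(f"profile file {path.name} lacks a participant_id column")
    out: dict[str, ParticipantProfile] = {}
    for row in df.itertuples(index=False):
        pid = str(row.participant_id)

        def _opt(name: str):
            v = getattr(row, name, None)
            return None if v is None or pd.isna(v) else float(v)

        sex = getattr(row, "sex", None)
        out[pid] = ParticipantProfile(
            participant_id=pid,
            sex=None if sex is None or pd.isna(sex) else Sex(str(sex).strip().lower()),
            age=_opt("age"),
            weight_kg=_opt("weight_kg"),
            height_cm=_opt("height_cm"),
            arm_circ_mm=_opt("arm_circ_mm"),
        )
    return out


def write_profiles(profiles: dict[str, ParticipantProfile], path: Union[str, Path]) -> Path:
    path = Path(path)
    rows = []
    for pid in sorted(profiles):
        p = profiles[pid]
        rows.append(
            {
                "participant_id": pid,
                "sex": p.sex.value if p.sex else "",
                "age": p.age,
                "weight_kg": p.weight_kg,
                "height_cm": p.height_cm,
                "arm_circ_mm": p.arm_circ_mm,
            }
        )
    pd.DataFrame(rows, columns=list(PROFILE_COLUMNS)).to_csv(path, index=False)
    return path
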