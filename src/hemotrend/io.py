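"""CSV schemas: raw measurements in, derived CO out.

Two input schemas are recognised by column presence:

* **raw** — per patient-timepoint row: ``patient_id, timepoint,
  lvot_d1..lvot_d3, vti_1..vti_5, heart_rate, pac_co_1..pac_co_5``.
  Missing cells are allowed for absent replicates.
* **derived** — per patient-timepoint row: ``patient_id, timepoint,
  co_tte, co_pac`` (``sv_tte`` optional).

A header matching both or neither is a :class:`~hemotrend.exceptions.SchemaError`,
never a guess.
"""

from __future__ import annotations

import re
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import SchemaError
from .measurement import (
    EchoMeasurement,
    ThermodilutionSeries,
    echo_cardiac_output,
    pac_cardiac_output,
)
from .synthetic import SyntheticCohort

RAW_FIXED_COLS = ("patient_id", "timepoint", "heart_rate")
DERIVED_COLS = ("patient_id", "timepoint", "co_tte", "co_pac")


def detect_schema(columns: Sequence[str]) -> str:
    """Return "raw" or "derived" from a header; ambiguity is an error."""
    cols = set(columns)
    has_raw = (
        set(RAW_FIXED_COLS) <= cols
        and any(re.fullmatch(r"lvot_d\d+", c) for c in cols)
        and any(re.fullmatch(r"vti_\d+", c) for c in cols)
        and any(re.fullmatch(r"pac_co_\d+", c) for c in cols)
    )
    has_derived = set(DERIVED_COLS) <= cols
    if has_raw and has_derived:
        raise SchemaError("header matches both the raw and the derived schema; split the file")
    if has_raw:
        return "raw"
    if has_derived:
        return "derived"
    raise SchemaError(
        f"header matches neither schema; columns found: {sorted(cols)}"
    )


def _replicate_cols(columns, prefix: str) -> list[str]:
    pat = re.compile(rf"{prefix}(\d+)")
    found = [(int(m.group(1)), c) for c in columns if (m := pat.fullmatch(c))]
    return [c for _, c in sorted(found)]


def _row_values(row, cols) -> tuple[float, ...]:
    vals = [row[c] for c in cols]
    return tuple(float(v) for v in vals if pd.notna(v))


def read_raw_csv(path) -> tuple[list[EchoMeasurement], list[ThermodilutionSeries]]:
    """Parse a raw-schema CSV into echo and thermodilution records.

    Raises :class:`SchemaError` listing the offending line numbers when any
    row fails validation.
    """
    df = pd.read_csv(path)
    if detect_schema(df.columns) != "raw":
        raise SchemaError(f"{path}: not a raw-schema file")
    d_cols = _replicate_cols(df.columns, "lvot_d")
    vti_cols = _replicate_cols(df.columns, "vti_")
    pac_cols = _replicate_cols(df.columns, "pac_co_")
    echo, pac, errors = [], [], []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            pid = str(row["patient_id"])
            tp = int(row["timepoint"])
            echo.append(
                EchoMeasurement(
                    patient_id=pid,
                    timepoint=tp,
                    lvot_diameters=_row_values(row, d_cols),
                    vti_values=_row_values(row, vti_cols),
                    heart_rate=float(row["heart_rate"]),
                )
            )
            pac.append(
                ThermodilutionSeries(
                    patient_id=pid, timepoint=tp, bolus_co=_row_values(row, pac_cols)
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise SchemaError(f"{path}: {len(errors)} invalid row(s):\n" + "\n".join(errors))
    return echo, pac


def derive_co(
    echo: Sequence[EchoMeasurement],
    pac: Sequence[ThermodilutionSeries],
    *,
    pi_literal: float | None = None,
) -> pd.DataFrame:
    """Per patient-timepoint derived CO table (co_tte, co_pac, sv_tte)."""
    echo_rows = {}
    for m in echo:
        out = echo_cardiac_output(m, pi_literal=pi_literal)
        echo_rows[(m.patient_id, m.timepoint)] = out
    rows = []
    for s in pac:
        key = (s.patient_id, s.timepoint)
        if key not in echo_rows:
            raise SchemaError(f"patient {key[0]} t{key[1]}: thermodilution record without echo record")
        rows.append(
            {
                "patient_id": key[0],
                "timepoint": key[1],
                "co_tte": echo_rows[key]["co_lmin"],
                "co_pac": pac_cardiac_output(s),
                "sv_tte": echo_rows[key]["sv_ml"],
            }
        )
    return pd.DataFrame(rows, columns=["patient_id", "timepoint", "co_tte", "co_pac", "sv_tte"])


def read_derived_csv(path) -> pd.DataFrame:
    """Parse a derived-schema CSV, validating positivity row by row."""
    df = pd.read_csv(path)
    if detect_schema(df.columns) != "derived":
        raise SchemaError(f"{path}: not a derived-schema file")
    errors = []
    for idx, row in df.iterrows():
        line = idx + 2
        for col in ("co_tte", "co_pac"):
            v = row[col]
            if pd.isna(v) or not np.isfinite(v) or v <= 0:
                errors.append(f"line {line}: {col} must be positive, got {v!r}")
    if errors:
        raise SchemaError(f"{path}: {len(errors)} invalid row(s):\n" + "\n".join(errors))
    df["patient_id"] = df["patient_id"].astype(str)
    df["timepoint"] = df["timepoint"].astype(int)
    return df


def cohort_to_raw_frame(cohort: SyntheticCohort) -> pd.DataFrame:
    """Serialise a synthetic cohort into the raw-measurements schema."""
    n_d = max(len(m.lvot_diameters) for m in cohort.echo)
    n_v = max(len(m.vti_values) for m in cohort.echo)
    n_b = max(len(s.bolus_co) for s in cohort.pac)
    pac_by_key = {(s.patient_id, s.timepoint): s for s in cohort.pac}
    rows = []
    for m in cohort.echo:
        s = pac_by_key[(m.patient_id, m.timepoint)]
        row = {"patient_id": m.patient_id, "timepoint": m.timepoint, "heart_rate": m.heart_rate}
        for i in range(n_d):
            row[f"lvot_d{i + 1}"] = m.lvot_diameters[i] if i < len(m.lvot_diameters) else np.nan
        for i in range(n_v):
            row[f"vti_{i + 1}"] = m.vti_values[i] if i < len(m.vti_values) else np.nan
        for i in range(n_b):
            row[f"pac_co_{i + 1}"] = s.bolus_co[i] if i < len(s.bolus_co) else np.nan
        rows.append(row)
    cols = (
        ["patient_id", "timepoint"]
        + [f"lvot_d{i + 1}" for i in range(n_d)]
        + [f"vti_{i + 1}" for i in range(n_v)]
        + ["heart_rate"]
        + [f"pac_co_{i + 1}" for i in range(n_b)]
    )
    return pd.DataFrame(rows, columns=cols)


def write_raw_csv(cohort: SyntheticCohort, path) -> None:
    cohort_to_raw_frame(cohort).to_csv(path, index=False)


def write_derived_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
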