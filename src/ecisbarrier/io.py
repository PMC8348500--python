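"""ECIS-style CSV dialect and LDH table I/O.

The export dialect is a plain-text emulation of an instrument export:

* a header block of ``# key: value`` lines carrying protocol metadata,
* one CSV header line,
* long-format rows ``well_id,group,time_h,frequency_hz,resistance_ohm,
  reactance_ohm`` (UTF-8, '.' decimal separator).

Numeric fields round-trip losslessly to 12 significant digits.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import ExperimentTable

__all__ = ["read_ecis_csv", "write_ecis_csv", "read_ldh_csv", "write_ldh_csv"]

_COLUMNS = ExperimentTable.REQUIRED_COLUMNS
_NUMERIC = ("time_h", "frequency_hz", "resistance_ohm", "reactance_ohm")


class EcisParseError(ValueError):
    """Malformed ECIS CSV; the message names the offending line."""


def write_ecis_csv(table: ExperimentTable, path) -> None:
    """Write an :class:`ExperimentTable` in the package's ECIS CSV dialect."""
    path = Path(path)
    buf = _io.StringIO()
    for key, value in table.metadata.items():
        buf.write(f"# {key}: {value}\n")
    buf.write(",".join(_COLUMNS) + "\n")
    df = table.data
    fmt = "%.12g"
    cols = [df["well_id"].astype(str), df["group"].astype(str)] + [
        np.char.mod(fmt, df[c].to_numpy(dtype=float)) for c in _NUMERIC
    ]
    for parts in zip(*cols):
        buf.write(",".join(parts) + "\n")
    path.write_text(buf.getvalue(), encoding="utf-8")


def read_ecis_csv(path) -> ExperimentTable:
    """Read an ECIS CSV written by :func:`write_ecis_csv`.

    Raises :class:`EcisParseError` (with the line number) for missing
    columns, non-numeric fields or duplicate (well, time, frequency) rows.
    """
    path = Path(path)
    metadata: dict = {}
    with path.open("r", encoding="utf-8") as fh:
        lineno = 0
        header = None
        for line in fh:
            lineno += 1
            line = line.rstrip("\n")
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    metadata[key.strip()] = _parse_meta(value.strip())
                continue
            header = line.split(",")
            break
        if header is None:
            raise EcisParseError(f"{path}: no column header found")
        missing = [c for c in _COLUMNS if c not in header]
        if missing:
            raise EcisParseError(f"{path}, line {lineno}: missing columns {missing}")
        idx = {c: header.index(c) for c in _COLUMNS}
        rows = {c: [] for c in _COLUMNS}
        seen = set()
        for line in fh:
            lineno += 1
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(",")
            if len(parts) != len(header):
                raise EcisParseError(
                    f"{path}, line {lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            try:
                record = {
                    c: (parts[idx[c]] if c in ("well_id", "group") else float(parts[idx[c]]))
                    for c in _COLUMNS
                }
            except ValueError as exc:
                raise EcisParseError(f"{path}, line {lineno}: {exc}") from None
            key = (record["well_id"], record["time_h"], record["frequency_hz"])
            if key in seen:
                raise EcisParseError(
                    f"{path}, line {lineno}: duplicate (well, time, frequency) row {key}"
                )
            seen.add(key)
            for c in _COLUMNS:
                rows[c].append(record[c])
    data = pd.DataFrame(rows)
    for c in _NUMERIC:
        data[c] = data[c].astype(float)
    return ExperimentTable(data, metadata)


def _parse_meta(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    if value in ("True", "False"):
        return value == "True"
    return value


def write_ldh_csv(ldh_table: pd.DataFrame, path) -> None:
    """Write an LDH absorbance table (well_id, group, timepoint_h, A490, A680)."""
    ldh_table.to_csv(path, index=False, float_format="%.12g")


def read_ldh_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"well_id", "group", "timepoint_h", "A490", "A680"}
    missing = required - set(df.columns)
    if missing:
        raise EcisParseError(f"{path}: missing LDH columns {sorted(missing)}")
    for c in ("timepoint_h", "A490", "A680"):
        df[c] = df[c].astype(float)
    return df
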