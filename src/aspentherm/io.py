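"""CSV dialects for the experiment tables and hourly series.

All tables are RFC-4180 CSV, UTF-8, "." decimal; numerics are written with
6 significant digits so files are byte-stable across platforms. Readers
validate every cell and report the failing row and column.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

from .microclimate import MicroclimateSeries
from .records import EmergenceRecord, GradientTrial, HeatShockRecord, RecordError

__all__ = ["TableError", "read_table", "write_table", "DIALECTS"]

DIALECTS = {
    "heat_shock": ("individual_id", "species", "shock_temperature", "survived"),
    "gradient": (
        "individual_id",
        "rearing_temperature",
        "position_control",
        "position_gradient",
        "dry_mass",
    ),
    "emergence": ("insect_type", "rearing_temperature", "days_to_emergence"),
    "microclimate": (
        "hour",
        "air_temperature",
        "direct_solar",
        "diffuse_solar",
        "wind",
        "relative_humidity",
        "sky_temperature",
        "zenith_angle",
    ),
}


class TableError(ValueError):
    """A CSV file does not conform to its dialect."""


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, str):
        return value
    if isinstance(value, int):
        return str(value)
    return f"{value:.6g}"


def _parse_float(text: str, row: int, column: str) -> float:
    try:
        return float(text)
    except ValueError as exc:
        raise TableError(f"row {row}, column {column!r}: cannot parse {text!r} as a number") from exc


def read_table(path: str | Path, dialect: str):
    """Read a CSV table into typed, validated records.

    Row numbers in error messages are 1-based data rows (header excluded).
    """
    if dialect not in DIALECTS:
        raise TableError(f"unknown dialect {dialect!r}; expected one of {sorted(DIALECTS)}")
    expected = DIALECTS[dialect]
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = tuple(next(reader))
        except StopIteration:
            raise TableError(f"{path}: empty file, expected header {expected}")
        required = expected[:-1] if dialect == "gradient" else expected
        if header != expected and header != required:
            raise TableError(
                f"{path}: header {header} does not match dialect {dialect!r} "
                f"(expected {expected})"
            )
        has_mass = dialect == "gradient" and header == expected
        records = []
        for i, row in enumerate(reader, start=1):
            if len(row) != len(header):
                raise TableError(f"row {i}: expected {len(header)} fields, got {len(row)}")
            try:
                records.append(_parse_row(dialect, row, i, has_mass))
            except RecordError as exc:
                raise TableError(f"row {i}: {exc}") from exc
    return records


def _parse_row(dialect: str, row: Sequence[str], i: int, has_mass: bool):
    if dialect == "heat_shock":
        survived_txt = row[3].strip()
        if survived_txt not in ("0", "1"):
            raise TableError(f"row {i}, column 'survived': must be 0 or 1, got {survived_txt!r}")
        return HeatShockRecord(
            individual_id=row[0],
            species=row[1],
            shock_temperature=_parse_float(row[2], i, "shock_temperature"),
            survived=int(survived_txt),
        )
    if dialect == "gradient":
        mass = None
        if has_mass and row[4].strip():
            mass = _parse_float(row[4], i, "dry_mass")
        return GradientTrial(
            individual_id=row[0],
            rearing_temperature=_parse_float(row[1], i, "rearing_temperature"),
            position_control=_parse_float(row[2], i, "position_control"),
            position_gradient=_parse_float(row[3], i, "position_gradient"),
            dry_mass=mass,
        )
    if dialect == "emergence":
        return EmergenceRecord(
            insect_type=row[0],
            rearing_temperature=_parse_float(row[1], i, "rearing_temperature"),
            days_to_emergence=_parse_float(row[2], i, "days_to_emergence"),
        )
    # microclimate rows come back as plain dicts keyed by column
    return {
        col: _parse_float(row[j], i, col) for j, col in enumerate(DIALECTS["microclimate"])
    }


def write_table(records: Iterable, dialect: str, path: str | Path) -> Path:
    """Write records in the given CSV dialect; returns the path."""
    if dialect not in DIALECTS:
        raise TableError(f"unknown dialect {dialect!r}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    columns = DIALECTS[dialect]
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(columns)
        for r in records:
            if dialect == "microclimate" and isinstance(r, dict):
                writer.writerow([_fmt(r[c]) for c in columns])
            else:
                writer.writerow([_fmt(getattr(r, c)) for c in columns])
    return path


def write_microclimate(series: MicroclimateSeries, path: str | Path) -> Path:
    """Write an hourly microclimate series in the microclimate dialect."""
    rows = [
        {
            "hour": int(series.hour[i]),
            "air_temperature": float(series.air_temperature[i]),
            "direct_solar": float(series.direct_solar[i]),
            "diffuse_solar": float(series.diffuse_solar[i]),
            "wind": float(series.wind[i]),
            "relative_humidity": float(series.relative_humidity[i]),
            "sky_temperature": float(series.sky_temperature[i]),
            "zenith_angle": float(series.zenith_angle[i]),
        }
        for i in range(series.hour.size)
    ]
    return write_table(rows, "microclimate", path)
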