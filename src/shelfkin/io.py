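"""Readers and writers for indicator time-series, configuration and results.

The input CSV dialect is comma-separated UTF-8 with a header row and the
columns ``indicator,temperature_c,time,time_unit,value`` (period decimal
separator). ``time_unit`` is ``hours`` or ``days`` per row; everything is
converted to days internally. Extra columns (e.g. a replicate id) are
tolerated and ignored.

Results are serialized to JSON with a ``kind`` tag per object so that
``read_results(write_results(x)) == x`` for every domain type.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import asdict
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd

from .arrhenius import ArrheniusFit
from .core import (
    CriticalLimit,
    CriticalLimits,
    IndicatorSeries,
    INDICATOR_REGISTRY,
    hours_to_days,
    normalize_indicator,
)
from .errors import (
    ConfigError,
    DuplicateRecordError,
    FormatError,
    ParseError,
)
from .kinetics import IndicatorKinetics, KineticFit
from .shelf_life import ShelfLifeModel, ValidationRecord, ValidationSummary

REQUIRED_COLUMNS = ("indicator", "temperature_c", "time", "time_unit", "value")
TIME_UNITS = ("hours", "days")


def _resolve(
    indicator: str, config: Mapping[str, Any] | None, section: str
) -> str | None:
    """Look up a per-indicator setting case-insensitively in the config."""
    if not config:
        return None
    table = config.get(section) or {}
    lowered = {str(k).lower(): v for k, v in table.items()}
    return lowered.get(indicator.lower())


def read_indicator_series(
    path: str | Path, config: Mapping[str, Any] | None = None
) -> list[IndicatorSeries]:
    """Load one :class:`IndicatorSeries` per (indicator, temperature) group.

    ``config`` may carry ``{"directions": {...}, "units": {...}}`` entries;
    they override the built-in registry and are mandatory for indicators
    the registry does not know.

    Raises
    ------
    FormatError
        Missing required column, or a ``time_unit`` outside {hours, days}.
    ParseError
        A non-numeric cell; the message cites the 1-based file line
        (header = line 1).
    DuplicateRecordError
        Two rows with the same (indicator, temperature, time).
    ConfigError
        Unknown indicator without a configured direction.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for column in REQUIRED_COLUMNS:
        if column not in frame.columns:
            raise FormatError(f"{path.name}: missing required column {column!r}")

    rows: list[tuple[str, float, float, float]] = []
    for idx, row in frame.iterrows():
        line = int(idx) + 2  # 1-based file line, header occupies line 1
        unit = row["time_unit"].strip().lower()
        if unit not in TIME_UNITS:
            raise FormatError(
                f"{path.name} line {line}: time_unit must be one of "
                f"{TIME_UNITS}, got {row['time_unit']!r}"
            )
        numeric: dict[str, float] = {}
        for column in ("temperature_c", "time", "value"):
            try:
                numeric[column] = float(row[column])
            except ValueError:
                raise ParseError(
                    f"{path.name} line {line}: cannot parse {column}="
                    f"{row[column]!r} as a number",
                    row=line,
                ) from None
            if not math.isfinite(numeric[column]):
                raise ParseError(
                    f"{path.name} line {line}: non-finite {column}", row=line
                )
        time_days = (
            hours_to_days(numeric["time"]) if unit == "hours" else numeric["time"]
        )
        rows.append(
            (
                normalize_indicator(row["indicator"]),
                numeric["temperature_c"],
                time_days,
                numeric["value"],
            )
        )

    grouped: dict[tuple[str, float], list[tuple[float, float]]] = {}
    for indicator, temp, time_days, value in rows:
        key = (indicator, temp)
        bucket = grouped.setdefault(key, [])
        if any(t == time_days for t, _ in bucket):
            raise DuplicateRecordError(
                f"duplicate record for {indicator} at {temp} °C, t = {time_days} d"
            )
        bucket.append((time_days, value))

    series: list[IndicatorSeries] = []
    for (indicator, temp), points in grouped.items():
        points.sort()
        direction = _resolve(indicator, config, "directions")
        unit_label = _resolve(indicator, config, "units")
        spec = INDICATOR_REGISTRY.get(indicator.lower())
        if direction is None:
            if spec is None:
                raise ConfigError(
                    f"unknown indicator {indicator!r}: supply its direction "
                    "in the config 'directions' section"
                )
            direction = spec.direction
        if unit_label is None:
            unit_label = spec.unit if spec is not None else ""
        series.append(
            IndicatorSeries(
                indicator=indicator,
                unit=unit_label,
                temperature_c=temp,
                times_days=tuple(t for t, _ in points),
                values=tuple(v for _, v in points),
                direction=direction,
            )
        )
    series.sort(key=lambda s: (s.indicator.lower(), s.temperature_c))
    return series


def write_indicator_series_csv(
    series: Iterable[IndicatorSeries], path: str | Path
) -> None:
    """Write series back out in the canonical input CSV dialect (days)."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(REQUIRED_COLUMNS)
        for s in series:
            for t, v in zip(s.times_days, s.values):
                writer.writerow([s.indicator, repr(s.temperature_c), repr(t), "days", repr(v)])


def read_config(path: str | Path) -> dict[str, Any]:
    """Load the JSON configuration of limits, directions and units."""
    with open(path, encoding="utf-8") as handle:
        raw = json.load(handle)
    config = dict(raw)
    if "limits" in config:
        config["limits"] = CriticalLimits.from_dict(config["limits"])
    return config


# --------------------------------------------------------------------------
# JSON round-trip serialization of domain objects


def _encode(obj: Any) -> Any:
    if isinstance(obj, (KineticFit, ArrheniusFit, ValidationRecord, ValidationSummary)):
        return {"kind": type(obj).__name__, **asdict(obj)}
    if isinstance(obj, IndicatorSeries):
        return {"kind": "IndicatorSeries", **asdict(obj)}
    if isinstance(obj, IndicatorKinetics):
        return {
            "kind": "IndicatorKinetics",
            "indicator": obj.indicator,
            "fits": [_encode(f) for f in obj.fits],
            "sum_r_squared": {str(k): v for k, v in obj.sum_r_squared.items()},
            "sum_rmse": {str(k): v for k, v in obj.sum_rmse.items()},
            "selected_order": obj.selected_order,
            "infeasible": {str(k): v for k, v in obj.infeasible.items()},
        }
    if isinstance(obj, ShelfLifeModel):
        return {
            "kind": "ShelfLifeModel",
            "indicator": obj.indicator,
            "order": obj.order,
            "arrhenius": _encode(obj.arrhenius),
            "a0": obj.a0,
            "limit": {"value": obj.limit.value, "side": obj.limit.side},
        }
    if isinstance(obj, CriticalLimits):
        return {"kind": "CriticalLimits", "limits": obj.to_dict()}
    if isinstance(obj, dict):
        return {k: _encode(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    return obj


def _decode(obj: Any) -> Any:
    if isinstance(obj, list):
        return [_decode(v) for v in obj]
    if not isinstance(obj, dict):
        return obj
    kind = obj.get("kind")
    if kind is None:
        return {k: _decode(v) for k, v in obj.items()}
    payload = {k: v for k, v in obj.items() if k != "kind"}
    if kind == "IndicatorSeries":
        payload["times_days"] = tuple(payload["times_days"])
        payload["values"] = tuple(payload["values"])
        return IndicatorSeries(**payload)
    if kind == "KineticFit":
        return KineticFit(**payload)
    if kind == "ArrheniusFit":
        return ArrheniusFit(**payload)
    if kind == "ValidationRecord":
        return ValidationRecord(**payload)
    if kind == "ValidationSummary":
        return ValidationSummary(**payload)
    if kind == "IndicatorKinetics":
        return IndicatorKinetics(
            indicator=payload["indicator"],
            fits=tuple(_decode(f) for f in payload["fits"]),
            sum_r_squared={int(k): v for k, v in payload["sum_r_squared"].items()},
            sum_rmse={int(k): v for k, v in payload["sum_rmse"].items()},
            selected_order=payload["selected_order"],
            infeasible={int(k): v for k, v in payload["infeasible"].items()},
        )
    if kind == "ShelfLifeModel":
        return ShelfLifeModel(
            indicator=payload["indicator"],
            order=payload["order"],
            arrhenius=_decode(payload["arrhenius"]),
            a0=payload["a0"],
            limit=CriticalLimit(**payload["limit"]),
        )
    if kind == "CriticalLimits":
        return CriticalLimits.from_dict(payload["limits"])
    raise FormatError(f"unknown result kind {kind!r}")


def write_results(results: Any, path: str | Path) -> None:
    """Serialize any pipeline product (or container of them) to JSON.

    The output is deterministic: keys are sorted and floats use ``repr``.
    """
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(_encode(results), handle, indent=2, sort_keys=True)
        handle.write("\n")


def read_results(path: str | Path) -> Any:
    """Inverse of :func:`write_results`."""
    with open(path, encoding="utf-8") as handle:
        return _decode(json.load(handle))


VALIDATION_CSV_COLUMNS = ("time_days", "measured", "predicted", "relative_deviation_pct")


def write_validation_csv(
    records: Sequence[ValidationRecord], path: str | Path
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(VALIDATION_CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [repr(r.time_days), repr(r.measured), repr(r.predicted), repr(r.relative_deviation_pct)]
            )


def read_validation_csv(path: str | Path) -> list[ValidationRecord]:
    frame = pd.read_csv(path)
    for column in VALIDATION_CSV_COLUMNS:
        if column not in frame.columns:
            raise FormatError(f"validation CSV missing column {column!r}")
    return [
        ValidationRecord(
            time_days=float(row.time_days),
            measured=float(row.measured),
            predicted=float(row.predicted),
            relative_deviation_pct=float(row.relative_deviation_pct),
        )
        for row in frame.itertuples()
    ]
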