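"""Shelf-life prediction: indicator trajectories, time-to-critical-limit,
and validation against measured series.

Shelf life is defined for zero- and first-order kinetics only:

* order 0 — ``SL = (limit - A0) / k``
* order 1 — ``SL = (ln limit - ln A0) / k``

with ``k`` evaluated from the Arrhenius fit at the storage temperature.
A rate constant of exactly zero yields an infinite shelf life, returned as
``math.inf``; a rate constant pointing away from the limit raises
:class:`~shelfkin.errors.InfeasibleLimitError`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .arrhenius import ArrheniusFit, rate_at
from .core import CriticalLimit, IndicatorSeries, canonical_indicator_rank
from .errors import (
    DomainError,
    InfeasibleLimitError,
    InputError,
    UnsupportedOrderError,
)

__all__ = [
    "ShelfLifeModel",
    "ValidationRecord",
    "ValidationSummary",
    "predict_value",
    "shelf_life_time",
    "overall_shelf_life",
    "relative_deviation",
    "validate",
]


@dataclass(frozen=True)
class ShelfLifeModel:
    """Everything needed to predict one indicator at any temperature.

    ``a0`` is the initial indicator value — by convention the measured
    value at t = 0 of the calibration or validation series, not a
    regression intercept.
    """

    indicator: str
    order: int
    arrhenius: ArrheniusFit
    a0: float
    limit: CriticalLimit

    def __post_init__(self) -> None:
        if self.order not in (0, 1):
            raise UnsupportedOrderError(
                f"shelf life is defined for orders 0 and 1 only, got {self.order}"
            )
        if self.order == 1 and self.a0 <= 0:
            raise DomainError("first-order model requires a positive initial value")


def predict_value(model: ShelfLifeModel, t: float, temperature_c: float) -> float:
    """Predicted indicator value after ``t`` days at a constant temperature."""
    if t < 0:
        raise InputError(f"storage time must be non-negative, got {t}")
    k = rate_at(model.arrhenius, temperature_c)
    if model.order == 0:
        return model.a0 + k * t
    return model.a0 * math.exp(k * t)


def shelf_life_time(model: ShelfLifeModel, temperature_c: float) -> float:
    """Days of storage until the indicator reaches its critical limit.

    Returns ``math.inf`` when ``k == 0`` (the indicator never moves).
    Raises :class:`InfeasibleLimitError` when the kinetic direction points
    away from the limit, or when the initial value already lies beyond it.
    """
    k = rate_at(model.arrhenius, temperature_c)
    limit = model.limit.value
    if model.order == 0:
        gap = limit - model.a0
    else:
        if limit <= 0:
            raise DomainError("first-order shelf life needs a positive limit")
        gap = math.log(limit) - math.log(model.a0)
    if k == 0.0:
        return math.inf
    sl = gap / k
    if sl <= 0:
        raise InfeasibleLimitError(
            f"{model.indicator}: critical limit {limit} ({model.limit.side}) is "
            f"unreachable from a0 = {model.a0} with k = {k:+.6g}/day "
            f"at {temperature_c} °C"
        )
    return sl


@dataclass(frozen=True)
class OverallShelfLife:
    days: float
    limiting_indicators: tuple[str, ...]
    excluded: dict[str, str]


def overall_shelf_life(
    models: Iterable[ShelfLifeModel], temperature_c: float
) -> OverallShelfLife:
    """Minimum per-indicator shelf life and the indicator(s) attaining it.

    Indicators with infeasible or infinite shelf life are excluded and
    listed with the reason. Exact ties report every tying indicator, in
    canonical indicator order.
    """
    per_indicator: dict[str, float] = {}
    excluded: dict[str, str] = {}
    for model in models:
        try:
            sl = shelf_life_time(model, temperature_c)
        except InfeasibleLimitError as exc:
            excluded[model.indicator] = str(exc)
            continue
        if math.isinf(sl):
            excluded[model.indicator] = "rate constant is zero: infinite shelf life"
            continue
        per_indicator[model.indicator] = sl
    if not per_indicator:
        raise InfeasibleLimitError(
            "no indicator yields a finite shelf life at "
            f"{temperature_c} °C: {excluded}"
        )
    best = min(per_indicator.values())
    limiting = sorted(
        (name for name, sl in per_indicator.items() if sl == best),
        key=canonical_indicator_rank,
    )
    return OverallShelfLife(days=best, limiting_indicators=tuple(limiting), excluded=excluded)


def relative_deviation(measured: float, predicted: float) -> float:
    """``100 × |measured − predicted| / predicted`` (predicted as denominator)."""
    if predicted == 0:
        raise DomainError("relative deviation undefined for predicted value 0")
    return 100.0 * abs(measured - predicted) / predicted


@dataclass(frozen=True)
class ValidationRecord:
    """One measured-vs-predicted comparison row."""

    time_days: float
    measured: float
    predicted: float
    relative_deviation_pct: float


@dataclass(frozen=True)
class ValidationSummary:
    indicator: str
    temperature_c: float
    max_deviation_pct: float
    mean_deviation_pct: float
    rmse: float
    n_points: int


def validation_records(
    times_days: Sequence[float],
    measured: Sequence[float],
    predicted: Sequence[float],
) -> list[ValidationRecord]:
    """Assemble records from parallel arrays of measurements and predictions."""
    if not (len(times_days) == len(measured) == len(predicted)):
        raise InputError("times, measured and predicted must be the same length")
    return [
        ValidationRecord(float(t), float(m), float(p), relative_deviation(m, p))
        for t, m, p in zip(times_days, measured, predicted)
    ]


def summarize(
    records: Sequence[ValidationRecord], *, indicator: str = "", temperature_c: float = math.nan
) -> ValidationSummary:
    if not records:
        raise InputError("no validation records to summarize")
    deviations = [r.relative_deviation_pct for r in records]
    resid = np.array([r.measured - r.predicted for r in records])
    return ValidationSummary(
        indicator=indicator,
        temperature_c=temperature_c,
        max_deviation_pct=max(deviations),
        mean_deviation_pct=float(np.mean(deviations)),
        rmse=float(np.sqrt(np.mean(resid**2))),
        n_points=len(records),
    )


def validate(
    measured: IndicatorSeries, model: ShelfLifeModel, temperature_c: float
) -> tuple[list[ValidationRecord], ValidationSummary]:
    """Compare a measured series against model predictions point by point."""
    if measured.n_points == 0:
        raise InputError("empty measured series")
    predicted = [predict_value(model, t, temperature_c) for t in measured.times_days]
    records = validation_records(measured.times_days, measured.values, predicted)
    return records, summarize(
        records, indicator=model.indicator, temperature_c=temperature_c
    )
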