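"""Reaction-order kinetic model fitting and model-order selection.

A quality indicator ``A(t)`` is fitted, per storage temperature, with the
three classical integrated rate laws by linear regression in a transformed
space:

========  =======================  ======================
order     transformed response     fitted model
========  =======================  ======================
0         ``A``                    ``A0 + k·t``
1         ``ln A``                 ``ln A0 + k·t``
2         ``1/A``                  ``1/A0 + k·t``
========  =======================  ======================

``k`` is the fitted slope and keeps its sign: decaying indicators yield
negative ``k`` under orders 0 and 1.  The best order for an indicator is the
one with the largest coefficient-of-determination sum across temperatures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import IndicatorSeries, normalize_indicator
from .errors import (
    DegenerateDesignError,
    DomainError,
    InputError,
    InsufficientDataError,
    ModellingError,
)

ORDERS = (0, 1, 2)


def transform(values: Sequence[float], order: int) -> np.ndarray:
    """Map indicator values into the linear space of the given rate law.

    order 0 → identity, order 1 → natural log, order 2 → reciprocal.

    Raises
    ------
    DomainError
        For a non-positive value under order 1, or a zero under order 2.
        The message carries the offending 0-based index.
    """
    arr = np.asarray(values, dtype=float)
    if order == 0:
        return arr.copy()
    if order == 1:
        bad = np.flatnonzero(arr <= 0)
        if bad.size:
            raise DomainError(
                f"order-1 transform requires positive values; "
                f"value {arr[bad[0]]} at index {bad[0]}"
            )
        return np.log(arr)
    if order == 2:
        bad = np.flatnonzero(arr == 0)
        if bad.size:
            raise DomainError(
                f"order-2 transform requires nonzero values; zero at index {bad[0]}"
            )
        return 1.0 / arr
    raise DomainError(f"unknown reaction order {order!r}")


def back_transform(transformed: Sequence[float], order: int) -> np.ndarray:
    """Exact inverse of :func:`transform`."""
    arr = np.asarray(transformed, dtype=float)
    if order == 0:
        return arr.copy()
    if order == 1:
        return np.exp(arr)
    if order == 2:
        with np.errstate(divide="ignore"):
            return 1.0 / arr
    raise DomainError(f"unknown reaction order {order!r}")


@dataclass(frozen=True)
class KineticFit:
    """OLS fit of one (indicator, temperature, order) combination.

    ``k`` is the slope of the transformed response against time in days and
    is signed. ``r_squared`` is computed in transformed space,
    ``rmse`` in original indicator units after back-transforming the fitted
    line (so Table-style RMSE values are directly comparable to the data).
    """

    indicator: str
    temperature_c: float
    order: int
    k: float
    intercept: float
    r_squared: float
    rmse: float
    n_points: int

    def __post_init__(self) -> None:
        if self.order not in ORDERS:
            raise InputError(f"unknown reaction order {self.order!r}")
        if self.n_points < 3:
            raise InputError("a kinetic fit requires at least 3 points")
        if not math.isnan(self.rmse) and self.rmse < 0:
            raise InputError("rmse must be non-negative")
        if self.r_squared > 1 + 1e-12:
            raise InputError("r_squared cannot exceed 1")


def _r_squared(observed: np.ndarray, fitted: np.ndarray) -> float:
    ss_res = float(np.sum((observed - fitted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        # constant response: a numerically perfect flat fit counts as R² = 1
        scale = max(1.0, float(np.sum(observed**2)))
        return 1.0 if ss_res <= 1e-20 * scale else float("nan")
    return 1.0 - ss_res / ss_tot


def fit_kinetic(
    series: IndicatorSeries, order: int, *, force_intercept: bool = False
) -> KineticFit:
    """Fit one rate law to one series by ordinary least squares.

    With ``force_intercept=True`` the line is pinned to the transformed
    initial value at the earliest sampling time (the textbook integrated
    form); the default free intercept matches how goodness-of-fit statistics
    are conventionally reported.
    """
    if series.n_points < 3:
        raise InsufficientDataError(
            f"{series.indicator} at {series.temperature_c} °C: "
            f"{series.n_points} points, need ≥ 3"
        )
    t = np.asarray(series.times_days, dtype=float)
    if np.ptp(t) == 0:
        raise DegenerateDesignError("all sampling times identical")
    try:
        y = transform(series.values, order)
    except DomainError as exc:
        idx = _first_bad_index(series.values, order)
        raise DomainError(
            f"{series.indicator} at {series.temperature_c} °C, order {order}: "
            f"value {series.values[idx]} at t = {series.times_days[idx]} d "
            f"is outside the model domain"
        ) from exc

    if force_intercept:
        t0, y0 = t[0], y[0]
        denom = float(np.sum((t - t0) ** 2))
        slope = float(np.sum((t - t0) * (y - y0)) / denom)
        intercept = y0 - slope * t0
    else:
        slope, intercept = (float(c) for c in np.polyfit(t, y, 1))

    fitted_transformed = intercept + slope * t
    fitted_original = back_transform(fitted_transformed, order)
    observed = np.asarray(series.values, dtype=float)
    rmse = float(np.sqrt(np.mean((fitted_original - observed) ** 2)))
    return KineticFit(
        indicator=series.indicator,
        temperature_c=series.temperature_c,
        order=order,
        k=slope,
        intercept=intercept,
        r_squared=_r_squared(y, fitted_transformed),
        rmse=rmse,
        n_points=series.n_points,
    )


def _first_bad_index(values: Sequence[float], order: int) -> int:
    for i, v in enumerate(values):
        if order == 1 and v <= 0:
            return i
        if order == 2 and v == 0:
            return i
    return 0


@dataclass(frozen=True)
class IndicatorKinetics:
    """All fits for one indicator plus the per-order selection statistics.

    ``sum_r_squared``/``sum_rmse`` only contain *candidate* orders — orders
    that were feasible at every temperature; orders that failed anywhere are
    listed in ``infeasible`` with the reason and take no part in selection.
    """

    indicator: str
    fits: tuple[KineticFit, ...]
    sum_r_squared: Mapping[int, float]
    sum_rmse: Mapping[int, float]
    selected_order: int
    infeasible: Mapping[int, str] = field(default_factory=dict)

    def fit_for(self, temperature_c: float, order: int) -> KineticFit:
        for f in self.fits:
            if f.order == order and f.temperature_c == temperature_c:
                return f
        raise KeyError((temperature_c, order))

    def selected_rates(self) -> list[tuple[float, float]]:
        """(temperature_c, k) pairs for the selected order, by temperature."""
        chosen = [f for f in self.fits if f.order == self.selected_order]
        chosen.sort(key=lambda f: f.temperature_c)
        return [(f.temperature_c, f.k) for f in chosen]


def select_order(
    sum_r_squared: Mapping[int, float], sum_rmse: Mapping[int, float] | None = None
) -> int:
    """Pick the best reaction order from per-order ΣR² (and Σrmse).

    Largest ΣR² wins; exact ties fall back to the smaller Σrmse, then to the
    lower order.
    """
    if not sum_r_squared:
        raise ModellingError("no feasible reaction order to select from")
    sum_rmse = sum_rmse or {}

    def sort_key(order: int) -> tuple[float, float, int]:
        return (
            -sum_r_squared[order],
            sum_rmse.get(order, 0.0),
            order,
        )

    return min(sum_r_squared, key=sort_key)


def aggregate_fits(
    fits: Iterable[KineticFit], infeasible: Mapping[int, str] | None = None
) -> IndicatorKinetics:
    """Aggregate per-(temperature, order) fits into selection statistics.

    Accepts hand-built :class:`KineticFit` records as readily as fitted
    ones, so selection statistics can be recomputed from published
    per-temperature R² tables.
    """
    fits = tuple(fits)
    if not fits:
        raise ModellingError("no kinetic fits to aggregate")
    indicators = {normalize_indicator(f.indicator) for f in fits}
    if len(indicators) > 1:
        raise InputError(f"mixed indicators in one aggregation: {sorted(indicators)}")
    indicator = indicators.pop()
    infeasible = dict(infeasible or {})

    temps_by_order: dict[int, set[float]] = {}
    for f in fits:
        temps_by_order.setdefault(f.order, set()).add(f.temperature_c)
    all_temps = set().union(*temps_by_order.values())

    sum_r2: dict[int, float] = {}
    sum_rmse: dict[int, float] = {}
    for order, temps in sorted(temps_by_order.items()):
        if order in infeasible:
            continue
        if temps != all_temps:
            missing = sorted(all_temps - temps)
            infeasible[order] = f"not feasible at {missing} °C"
            continue
        per_order = [f for f in fits if f.order == order]
        sum_r2[order] = float(sum(f.r_squared for f in per_order))
        sum_rmse[order] = float(sum(f.rmse for f in per_order))

    return IndicatorKinetics(
        indicator=indicator,
        fits=fits,
        sum_r_squared=sum_r2,
        sum_rmse=sum_rmse,
        selected_order=select_order(sum_r2, sum_rmse),
        infeasible=infeasible,
    )


def fit_all_orders(
    series_by_temperature: Iterable[IndicatorSeries],
    orders: Sequence[int] = ORDERS,
    *,
    force_intercept: bool = False,
) -> IndicatorKinetics:
    """Fit every requested order at every temperature and select the best.

    All series must describe the same indicator. Orders whose transform is
    undefined for some series (e.g. a log of a non-positive value) are
    excluded from selection and reported in ``infeasible``.
    """
    series = sorted(series_by_temperature, key=lambda s: s.temperature_c)
    if not series:
        raise InputError("no series supplied")
    indicators = {normalize_indicator(s.indicator) for s in series}
    if len(indicators) > 1:
        raise InputError(f"mixed indicators: {sorted(indicators)}")

    fits: list[KineticFit] = []
    infeasible: dict[int, str] = {}
    for order in orders:
        for s in series:
            try:
                fits.append(fit_kinetic(s, order, force_intercept=force_intercept))
            except (DomainError, InsufficientDataError, DegenerateDesignError) as exc:
                infeasible.setdefault(order, str(exc))
    if not fits:
        raise ModellingError(
            f"no feasible (temperature, order) fit for {indicators.pop()}"
        )
    if all(order in infeasible for order in orders):
        raise ModellingError("no reaction order is feasible at every temperature")
    return aggregate_fits(fits, infeasible)
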