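"""End-to-end orchestration: fit → select order → Arrhenius → shelf life.

The canonical product is a deterministic JSON report; every number in it is
produced by a module operation (the report layer does no arithmetic of its
own). Structure of the report::

    {
      "schema_version": 1,
      "seed": ...,
      "indicators": {
        "<name>": {
          "fits": [...],               # per (temperature, order)
          "sum_r_squared": {...},
          "selected_order": ...,
          "arrhenius": {...},          # for the selected order
          "shelf_life_days": {...},    # per requested temperature
          ...
        }
      },
      "overall_shelf_life": {...},
      "log": [ ... stage decisions ... ]
    }
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

from . import io as skio
from .arrhenius import fit_arrhenius
from .core import (
    CriticalLimits,
    DEFAULT_LIMITS,
    IndicatorSeries,
    group_by_indicator,
)
from .errors import (
    ConfigError,
    InfeasibleLimitError,
    ModellingError,
    ShelfkinError,
)
from .kinetics import fit_all_orders
from .shelf_life import ShelfLifeModel, overall_shelf_life, shelf_life_time

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    input_path: Path
    output_dir: Path | None = None
    config_path: Path | None = None
    indicators: tuple[str, ...] = ()  #: empty = all present in the input
    orders: tuple[int, ...] = (0, 1, 2)
    prediction_temperatures_c: tuple[float, ...] = ()
    seed: int = 0
    force_intercept: bool = False

    def __post_init__(self) -> None:
        if not Path(self.input_path).exists():
            raise ConfigError(f"input file not found: {self.input_path}")
        if self.config_path is not None and not Path(self.config_path).exists():
            raise ConfigError(f"config file not found: {self.config_path}")


def _mean_initial_value(series_list: Sequence[IndicatorSeries]) -> float:
    """a0 convention: mean of the t=0 values across calibration series."""
    return float(sum(s.initial_value for s in series_list) / len(series_list))


def run_pipeline(run: RunConfig) -> dict[str, Any]:
    """Execute the full chain and return the report dictionary.

    Degraded modes are handled explicitly and logged rather than failing:
    an indicator observed at a single temperature skips the Arrhenius
    stage; an indicator without a critical limit (or with an order-2
    selection) skips shelf-life prediction.
    """
    log: list[str] = []
    config: Mapping[str, Any] = (
        skio.read_config(run.config_path) if run.config_path else {}
    )
    limits: CriticalLimits = config.get("limits") or DEFAULT_LIMITS
    a0_overrides: Mapping[str, float] = config.get("a0") or {}

    all_series = skio.read_indicator_series(run.input_path, config)
    groups = group_by_indicator(all_series)
    if run.indicators:
        wanted = {name.lower() for name in run.indicators}
        groups = {k: v for k, v in groups.items() if k.lower() in wanted}
    if not groups:
        raise ModellingError("no indicator series selected")

    indicator_reports: dict[str, Any] = {}
    models: list[ShelfLifeModel] = []
    for indicator, series_list in groups.items():
        entry: dict[str, Any] = {}
        kinetics = fit_all_orders(
            series_list, run.orders, force_intercept=run.force_intercept
        )
        entry["fits"] = [skio._encode(f) for f in kinetics.fits]
        entry["sum_r_squared"] = {str(k): v for k, v in kinetics.sum_r_squared.items()}
        entry["sum_rmse"] = {str(k): v for k, v in kinetics.sum_rmse.items()}
        entry["selected_order"] = kinetics.selected_order
        entry["infeasible_orders"] = {
            str(k): v for k, v in kinetics.infeasible.items()
        }
        log.append(
            f"{indicator}: selected order {kinetics.selected_order} "
            f"(sum R^2 = {kinetics.sum_r_squared})"
        )

        rates = kinetics.selected_rates()
        if len(rates) < 2:
            log.append(
                f"{indicator}: single temperature — Arrhenius stage skipped"
            )
            entry["arrhenius"] = None
            indicator_reports[indicator] = entry
            continue
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            arr = fit_arrhenius(
                rates, indicator=indicator, order=kinetics.selected_order
            )
            for w in caught:
                log.append(f"{indicator}: {w.message}")
        entry["arrhenius"] = skio._encode(arr)

        limit = limits.get(indicator)
        if limit is None:
            log.append(f"{indicator}: no critical limit — shelf life skipped")
            entry["shelf_life_days"] = None
            indicator_reports[indicator] = entry
            continue
        if kinetics.selected_order not in (0, 1):
            log.append(
                f"{indicator}: order {kinetics.selected_order} has no "
                "shelf-life equation — skipped"
            )
            entry["shelf_life_days"] = None
            indicator_reports[indicator] = entry
            continue
        a0 = a0_overrides.get(indicator, _mean_initial_value(series_list))
        model = ShelfLifeModel(
            indicator=indicator,
            order=kinetics.selected_order,
            arrhenius=arr,
            a0=a0,
            limit=limit,
        )
        models.append(model)
        entry["model"] = skio._encode(model)

        temps = run.prediction_temperatures_c or tuple(
            s.temperature_c for s in series_list
        )
        per_temp: dict[str, Any] = {}
        for temp in temps:
            try:
                sl = shelf_life_time(model, temp)
                per_temp[str(temp)] = sl if math.isfinite(sl) else "infinite"
            except ShelfkinError as exc:
                per_temp[str(temp)] = f"infeasible: {exc}"
                log.append(f"{indicator} at {temp} °C: infeasible limit")
        entry["shelf_life_days"] = per_temp
        indicator_reports[indicator] = entry

    report: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "seed": run.seed,
        "indicators": indicator_reports,
    }
    if models and run.prediction_temperatures_c:
        overall: dict[str, Any] = {}
        for temp in run.prediction_temperatures_c:
            try:
                result = overall_shelf_life(models, temp)
                overall[str(temp)] = {
                    "days": result.days,
                    "limiting_indicators": list(result.limiting_indicators),
                    "excluded": result.excluded,
                }
            except InfeasibleLimitError as exc:
                overall[str(temp)] = f"infeasible: {exc}"
        report["overall_shelf_life"] = overall
    report["log"] = log

    if run.output_dir is not None:
        out = Path(run.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        skio.write_results(report, out / "report.json")
        if models:
            skio.write_results(models, out / "models.json")
    return report
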