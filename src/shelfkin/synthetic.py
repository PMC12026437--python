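"""Forward simulation of indicator trajectories and parameter-recovery
experiments.

Trajectories follow the same generative model the fitting chain assumes:
a temperature-dependent rate constant ``k(T) = sign · K0 · exp(-Ea/(R·T))``
drives a zero-order (linear) or first-order (exponential) trajectory from
the initial value ``a0``, with i.i.d. additive Gaussian measurement noise.
Every entry point takes an explicit seed; there is no global RNG state.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .arrhenius import ArrheniusFit, fit_arrhenius, rate_at
from .core import GAS_CONSTANT, IndicatorSeries, celsius_to_kelvin, normalize_indicator
from .errors import InputError
from .kinetics import fit_all_orders

#: Storage temperatures (°C) of the reference accelerated design.
DESIGN_TEMPERATURES = (4.0, 25.0, 37.0)

#: Sampling grid at chilled storage: days 0..10 every 2 days.
CHILLED_DAYS = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)

#: Sampling grid at ambient/abuse storage: hours 0..60 every 12, in days.
ABUSE_DAYS = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one simulated indicator experiment."""

    indicator: str
    order: int
    a0: float
    ea_kj_per_mol: float
    k0: float
    rate_sign: int = 1
    temperatures_c: tuple[float, ...] = DESIGN_TEMPERATURES
    times_days: tuple[tuple[float, ...], ...] | tuple[float, ...] = CHILLED_DAYS
    noise_sd: float = 0.0
    seed: int = 0
    unit: str = ""
    noise: str = "normal"  #: "normal" (additive) or "lognormal" (multiplicative)
    floor: float = 1e-6  #: positivity floor applied to noisy order-1 values

    def __post_init__(self) -> None:
        if self.order not in (0, 1):
            raise InputError("synthetic trajectories support orders 0 and 1")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be non-negative")
        if self.order == 1 and self.a0 <= 0:
            raise InputError("first-order trajectories need a0 > 0")
        if self.rate_sign not in (1, -1):
            raise InputError("rate_sign must be +1 or -1")
        if self.k0 <= 0:
            raise InputError("pre-exponential factor must be positive")
        if self.noise not in ("normal", "lognormal"):
            raise InputError("noise must be 'normal' or 'lognormal'")

    def times_for(self, temperature_index: int) -> tuple[float, ...]:
        """Per-temperature grid; a flat grid is shared by all temperatures."""
        grid = self.times_days
        if grid and isinstance(grid[0], (tuple, list)):
            return tuple(grid[temperature_index])  # type: ignore[arg-type]
        return tuple(grid)  # type: ignore[arg-type]

    @property
    def direction(self) -> str:
        return "increasing" if self.rate_sign > 0 else "decreasing"


def rate_constant(config: SyntheticConfig, temperature_c: float) -> float:
    """Signed k(T) implied by the config's Arrhenius parameters."""
    kelvin = celsius_to_kelvin(temperature_c)
    return config.rate_sign * config.k0 * math.exp(
        -config.ea_kj_per_mol * 1000.0 / (GAS_CONSTANT * kelvin)
    )


def _trajectory(config: SyntheticConfig, k: float, times: np.ndarray) -> np.ndarray:
    if config.order == 0:
        return config.a0 + k * times
    return config.a0 * np.exp(k * times)


def simulate_series(config: SyntheticConfig) -> list[IndicatorSeries]:
    """One noisy :class:`IndicatorSeries` per configured temperature.

    Identical config (including seed) → bit-identical output. Order-1
    values that noise pushes to or below zero are clipped to ``floor``
    with a warning, so downstream log-space fits stay defined.
    """
    rng = np.random.default_rng(config.seed)
    out: list[IndicatorSeries] = []
    for i, temp in enumerate(config.temperatures_c):
        times = np.asarray(config.times_for(i), dtype=float)
        clean = _trajectory(config, rate_constant(config, temp), times)
        if config.noise_sd > 0:
            if config.noise == "normal":
                values = clean + rng.normal(0.0, config.noise_sd, size=times.size)
            else:
                values = clean * rng.lognormal(0.0, config.noise_sd, size=times.size)
        else:
            values = clean.copy()
        if config.order == 1 and np.any(values <= 0):
            warnings.warn(
                f"{config.indicator} at {temp} °C: clipping "
                f"{int(np.sum(values <= 0))} non-positive noisy value(s) to "
                f"{config.floor}",
                stacklevel=2,
            )
            values = np.maximum(values, config.floor)
        out.append(
            IndicatorSeries(
                indicator=config.indicator,
                unit=config.unit,
                temperature_c=temp,
                times_days=tuple(times),
                values=tuple(values),
                direction=config.direction,
            )
        )
    return out


@dataclass(frozen=True)
class RecoveryReport:
    """Distribution of estimation errors over simulation replicates."""

    replicates: int
    order_accuracy: float  #: fraction of replicates selecting the true order
    true_ea_kj_per_mol: float
    true_ln_k0: float
    ea_estimates: tuple[float, ...]
    ln_k0_estimates: tuple[float, ...]
    median_rel_ea_error: float
    mean_rel_ea_error: float
    rel_ea_rmse: float
    median_rel_ln_k0_error: float
    k_rel_rmse_by_temperature: dict[float, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "replicates": self.replicates,
            "order_accuracy": self.order_accuracy,
            "true_ea_kj_per_mol": self.true_ea_kj_per_mol,
            "true_ln_k0": self.true_ln_k0,
            "median_rel_ea_error": self.median_rel_ea_error,
            "mean_rel_ea_error": self.mean_rel_ea_error,
            "rel_ea_rmse": self.rel_ea_rmse,
            "median_rel_ln_k0_error": self.median_rel_ln_k0_error,
            "k_rel_rmse_by_temperature": {
                str(t): v for t, v in self.k_rel_rmse_by_temperature.items()
            },
        }


def recovery_experiment(config: SyntheticConfig, replicates: int) -> RecoveryReport:
    """Simulate → fit all orders → select → Arrhenius, ``replicates`` times.

    Replicate ``r`` uses the derived seed ``(config.seed, r)``, so the whole
    experiment is reproducible from the config alone.
    """
    if replicates < 1:
        raise InputError("need at least 1 replicate")
    true_ea = config.ea_kj_per_mol
    true_ln_k0 = math.log(config.k0)
    true_k = {t: rate_constant(config, t) for t in config.temperatures_c}

    ea_estimates: list[float] = []
    ln_k0_estimates: list[float] = []
    selected_orders: list[int] = []
    k_errors: dict[float, list[float]] = {t: [] for t in config.temperatures_c}

    for r in range(replicates):
        rep_seed = int(np.random.SeedSequence([config.seed, r]).generate_state(1)[0])
        series = simulate_series(replace(config, seed=rep_seed))
        kinetics = fit_all_orders(series)
        selected_orders.append(kinetics.selected_order)
        fit = fit_arrhenius(
            kinetics.selected_rates(),
            indicator=config.indicator,
            order=kinetics.selected_order,
        )
        ea_estimates.append(fit.ea_kj_per_mol)
        ln_k0_estimates.append(fit.intercept)
        for temp in config.temperatures_c:
            k_errors[temp].append(
                (rate_at(fit, temp) - true_k[temp]) / true_k[temp]
            )

    ea_arr = np.asarray(ea_estimates)
    ln_k0_arr = np.asarray(ln_k0_estimates)
    rel_ea = np.abs(ea_arr - true_ea) / abs(true_ea)
    rel_ln_k0 = np.abs(ln_k0_arr - true_ln_k0) / abs(true_ln_k0)
    return RecoveryReport(
        replicates=replicates,
        order_accuracy=float(np.mean(np.asarray(selected_orders) == config.order)),
        true_ea_kj_per_mol=true_ea,
        true_ln_k0=true_ln_k0,
        ea_estimates=tuple(float(v) for v in ea_arr),
        ln_k0_estimates=tuple(float(v) for v in ln_k0_arr),
        median_rel_ea_error=float(np.median(rel_ea)),
        mean_rel_ea_error=float(np.mean(rel_ea)),
        rel_ea_rmse=float(np.sqrt(np.mean(rel_ea**2))),
        median_rel_ln_k0_error=float(np.median(rel_ln_k0)),
        k_rel_rmse_by_temperature={
            t: float(np.sqrt(np.mean(np.asarray(errs) ** 2)))
            for t, errs in k_errors.items()
        },
    )


def _arrhenius_from_rates(
    indicator: str, order: int, rates: Sequence[tuple[float, float]]
) -> ArrheniusFit:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_arrhenius(rates, indicator=indicator, order=order)


def reference_configs(noise_sd_scale: float = 0.0, seed: int = 0) -> list[SyntheticConfig]:
    """Configs for a five-indicator accelerated storage study.

    Arrhenius parameters are chosen so the noise-free endpoints land near
    typical published magnitudes for cooked crustacean products: TVB-N
    climbing from ~7 mg/100 g toward its 35 mg/100 g limit, TVC (log scale)
    from 0.57 toward ~7.8 log CFU/g at abuse temperature, AV rising gently,
    springiness and hardness decaying. ``noise_sd_scale`` scales each
    indicator's baseline noise level (0 → deterministic).
    """
    grids = (CHILLED_DAYS, ABUSE_DAYS, ABUSE_DAYS)

    def cfg(indicator, order, a0, rate_sign, rates_by_temp, noise_sd, unit) -> SyntheticConfig:
        # Anchor the line on the coldest and hottest rates so the noise-free
        # endpoint magnitudes at those temperatures are reproduced exactly.
        anchors = [rates_by_temp[0], rates_by_temp[-1]]
        fit = _arrhenius_from_rates(
            indicator, order, [(t, abs(k)) for t, k in anchors]
        )
        return SyntheticConfig(
            indicator=indicator,
            order=order,
            a0=a0,
            ea_kj_per_mol=fit.ea_kj_per_mol,
            k0=fit.k0,
            rate_sign=rate_sign,
            temperatures_c=DESIGN_TEMPERATURES,
            times_days=grids,
            noise_sd=noise_sd * noise_sd_scale,
            seed=seed,
            unit=unit,
        )

    # Per-temperature rates implied by the endpoint magnitudes above.
    tvbn = cfg(
        "TVB-N", 0, 6.9, 1,
        [(4.0, 1.27), (37.0, 28.0)], 0.5, "mg/100 g",
    )
    tvc = cfg(
        "TVC", 1, 0.57, 1,
        [(4.0, 0.10986), (37.0, 1.0465)], 0.08, "log CFU/g",
    )
    av = cfg(
        "AV", 0, 1.2, 1,
        [(4.0, 0.12), (37.0, 1.9)], 0.05, "mg KOH/g",
    )
    springiness = cfg(
        "springiness", 0, 4.23, -1,
        [(4.0, -0.063), (37.0, -0.492)], 0.04, "N/m^2",
    )
    hardness = cfg(
        "hardness", 1, 379.0, -1,
        [(4.0, -0.02712), (37.0, -0.45016)], 4.0, "g",
    )
    return [tvbn, tvc, av, springiness, hardness]


def make_paper_like_fixture(
    out_dir: str | Path, *, seed: int = 0, noise_sd_scale: float = 1.0
) -> dict[str, Path]:
    """Write a five-indicator CSV fixture plus its limits/directions config.

    Returns the paths written (``data`` and ``config``). The CSV loads
    cleanly through :func:`shelfkin.io.read_indicator_series`.
    """
    from .io import write_indicator_series_csv  # local import avoids a cycle
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series: list[IndicatorSeries] = []
    for config in reference_configs(noise_sd_scale=noise_sd_scale, seed=seed):
        series.extend(simulate_series(config))
    data_path = out_dir / "indicators.csv"
    write_indicator_series_csv(series, data_path)

    config_path = out_dir / "config.json"
    config_payload = {
        "limits": {
            "TVB-N": {"value": 35, "side": "upper"},
            "TVC": {"value": 6, "side": "upper"},
            "AV": {"value": 5.0, "side": "upper"},
        },
        "directions": {normalize_indicator(c.indicator): c.direction
                       for c in reference_configs()},
        "units": {normalize_indicator(c.indicator): c.unit
                  for c in reference_configs()},
    }
    with open(config_path, "w", encoding="utf-8") as handle:
        json.dump(config_payload, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return {"data": data_path, "config": config_path}
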