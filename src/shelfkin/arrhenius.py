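"""Arrhenius regression of rate constants against temperature.

``ln|k|`` is regressed on ``1/T`` (T in Kelvin); the slope is ``-Ea/R`` and
the intercept ``ln K0``.  Rate constants of decaying indicators are negative
— their absolute values enter the regression and the common sign is stored
and restored on prediction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .core import GAS_CONSTANT, celsius_to_kelvin
from .errors import DomainError, InputError

__all__ = ["ArrheniusFit", "fit_arrhenius", "ea_from_slope", "k0_from_intercept", "rate_at"]


@dataclass(frozen=True)
class ArrheniusFit:
    """Linear fit of ln|k| against 1/T.

    Attributes
    ----------
    slope:
        Coefficient of 1/T in Kelvin; equals ``-Ea/R``.
    intercept:
        ``ln K0``.
    ea_kj_per_mol:
        Activation energy, ``-slope * R / 1000``.
    k0:
        Pre-exponential factor, ``exp(intercept)`` (units of k).
    r_squared, rmse:
        Goodness of fit in ln-space.
    rate_sign:
        +1 or -1; the sign shared by the input rate constants, reapplied by
        :func:`rate_at`.
    """

    indicator: str
    order: int
    slope: float
    intercept: float
    ea_kj_per_mol: float
    k0: float
    r_squared: float
    rmse: float
    rate_sign: int
    n_temperatures: int

    def __post_init__(self) -> None:
        if self.rate_sign not in (1, -1):
            raise InputError("rate_sign must be +1 or -1")
        if self.k0 <= 0:
            raise InputError("pre-exponential factor must be positive")


def ea_from_slope(slope: float) -> float:
    """Activation energy in kJ/mol from an Arrhenius slope in Kelvin.

    Accepts either the fitted (negative) coefficient of 1/T or its printed
    positive magnitude; both give the same positive Ea.
    """
    return abs(slope) * GAS_CONSTANT / 1000.0


def k0_from_intercept(intercept: float) -> float:
    """Pre-exponential factor ``K0 = exp(ln K0)``."""
    return math.exp(intercept)


def fit_arrhenius(
    rates: Iterable[tuple[float, float]],
    *,
    indicator: str = "",
    order: int = 0,
) -> ArrheniusFit:
    """Regress ln|k| on 1/T(K) over ``(temperature_c, k)`` pairs.

    All rate constants must be nonzero and share one sign; mixing signs
    would mean the kinetic direction flips with temperature, which the model
    cannot represent. Two temperatures are permitted (the line is exactly
    determined) but a warning is issued.
    """
    pairs = sorted(rates, key=lambda p: p[0])
    if len(pairs) < 2:
        raise InputError("Arrhenius regression needs at least 2 temperatures")
    if len(pairs) == 2:
        warnings.warn(
            "Arrhenius fit from only 2 temperatures: goodness of fit is degenerate",
            stacklevel=2,
        )
    temps_c = [t for t, _ in pairs]
    if len(set(temps_c)) != len(temps_c):
        raise InputError("duplicate temperatures in Arrhenius input")
    ks = np.array([k for _, k in pairs], dtype=float)
    if np.any(ks == 0):
        raise DomainError("rate constant k = 0 has no Arrhenius representation")
    signs = set(np.sign(ks))
    if len(signs) > 1:
        raise InputError(
            "rate constants mix signs across temperatures; "
            "kinetic direction is inconsistent"
        )
    rate_sign = int(signs.pop())

    inv_t = np.array([1.0 / celsius_to_kelvin(t) for t in temps_c])
    ln_k = np.log(np.abs(ks))
    slope, intercept = (float(c) for c in np.polyfit(inv_t, ln_k, 1))
    fitted = intercept + slope * inv_t
    ss_res = float(np.sum((ln_k - fitted) ** 2))
    ss_tot = float(np.sum((ln_k - ln_k.mean()) ** 2))
    if ss_tot == 0.0:
        r_squared = 1.0 if ss_res <= 1e-300 else float("nan")
    else:
        r_squared = 1.0 - ss_res / ss_tot
    return ArrheniusFit(
        indicator=indicator,
        order=order,
        slope=slope,
        intercept=intercept,
        ea_kj_per_mol=-slope * GAS_CONSTANT / 1000.0,
        k0=k0_from_intercept(intercept),
        r_squared=r_squared,
        rmse=float(np.sqrt(ss_res / len(pairs))),
        rate_sign=rate_sign,
        n_temperatures=len(pairs),
    )


def rate_at(fit: ArrheniusFit, temperature_c: float) -> float:
    """Evaluate ``k = sign · K0 · exp(-Ea·1000 / (R·T))`` at a temperature."""
    kelvin = celsius_to_kelvin(temperature_c)
    return fit.rate_sign * fit.k0 * math.exp(
        -fit.ea_kj_per_mol * 1000.0 / (GAS_CONSTANT * kelvin)
    )
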