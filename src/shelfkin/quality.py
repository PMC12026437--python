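"""Ancillary quality analyses around the kinetic core.

Acid-value titration arithmetic, single-factor sensory optimum selection,
Pearson correlation screening between indicators, and acceptability
assessment against critical limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import CriticalLimits, IndicatorSeries
from .errors import ConfigError, DomainError, InputError

#: Molar mass of KOH in g/mol, the titration conversion constant.
KOH_MOLAR_MASS = 56.1


@dataclass(frozen=True)
class TitrationInput:
    """Raw numbers from a KOH back-titration of free fatty acids."""

    v_sample: float  #: titrant volume for the specimen, mL
    v_blank: float  #: titrant volume for the blank, mL
    conc: float  #: titrant molarity, mol/L
    mass: float  #: sample mass, g

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise DomainError("sample mass must be positive")
        if self.conc <= 0:
            raise DomainError("titrant concentration must be positive")
        if self.v_blank < 0 or self.v_sample < self.v_blank:
            raise DomainError("need v_sample >= v_blank >= 0 for a valid acid value")


def acid_value(titration: TitrationInput) -> float:
    """Acid value in mg KOH per g of sample.

    ``AV = (V - V0) · c · 56.1 / m``
    """
    return (
        (titration.v_sample - titration.v_blank)
        * titration.conc
        * KOH_MOLAR_MASS
        / titration.mass
    )


@dataclass(frozen=True)
class FactorTable:
    """Mean sensory scores across the levels of one processing factor."""

    factor: str
    levels: tuple[float, ...]
    mean_scores: tuple[float, ...]
    sds: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(float(v) for v in self.levels))
        object.__setattr__(self, "mean_scores", tuple(float(v) for v in self.mean_scores))
        if self.sds is not None:
            object.__setattr__(self, "sds", tuple(float(v) for v in self.sds))
            if len(self.sds) != len(self.levels):
                raise InputError("sds length must match levels")
        if len(self.levels) != len(self.mean_scores):
            raise InputError("levels and mean_scores must be the same length")
        if not self.levels:
            raise InputError(f"factor table {self.factor!r} is empty")
        if any(not (1.0 <= s <= 10.0) for s in self.mean_scores):
            raise InputError("sensory scores must lie on the 1-10 scale")


def select_optimum(table: FactorTable) -> tuple[float, float]:
    """Level with the highest mean score; ties go to the smaller level."""
    best_score = max(table.mean_scores)
    best_level = min(
        lvl for lvl, s in zip(table.levels, table.mean_scores) if s == best_score
    )
    return best_level, best_score


@dataclass(frozen=True)
class PearsonMatrix:
    """Pairwise Pearson r and two-sided p-values between aligned indicators.

    Variables with zero variance get NaN off-diagonal entries (undefined
    correlation) rather than failing the whole matrix; they are listed in
    ``degenerate``.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    degenerate: tuple[str, ...]


def pearson_matrix(
    aligned: Mapping[str, Sequence[float]] | pd.DataFrame,
) -> PearsonMatrix:
    """Correlate indicator values sampled at common time points.

    Requires at least 3 common samples. p-values come from the exact
    t-distribution with n - 2 degrees of freedom (scipy's convention).
    """
    frame = pd.DataFrame(aligned, dtype=float)
    names = list(frame.columns)
    n = len(frame)
    if n < 3:
        raise InputError(f"need >= 3 common time points, got {n}")
    degenerate = tuple(c for c in names if float(frame[c].var(ddof=0)) == 0.0)

    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    p = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j <= i:
                continue
            if a in degenerate or b in degenerate:
                rij, pij = math.nan, math.nan
            else:
                result = stats.pearsonr(frame[a], frame[b])
                rij, pij = float(result.statistic), float(result.pvalue)
            r.loc[a, b] = r.loc[b, a] = rij
            p.loc[a, b] = p.loc[b, a] = pij
    return PearsonMatrix(r=r, p=p, degenerate=degenerate)


@dataclass(frozen=True)
class Acceptability:
    """Outcome of screening a series against its critical limit.

    ``first_breach_day`` is the earliest *sampled* time past the limit
    (None when acceptable throughout). ``interpolated_day`` linearly
    interpolates between the bracketing samples — an estimate beyond the
    sampling granularity, flagged as such.
    """

    indicator: str
    temperature_c: float
    acceptable_throughout: bool
    first_breach_day: float | None = None
    interpolated_day: float | None = None
    interpolation_note: str = "interpolated estimate beyond sampling granularity"


def assess_acceptability(
    series: IndicatorSeries, limits: CriticalLimits
) -> Acceptability:
    """Find when a series first breaches its critical limit, if ever."""
    limit = limits.get(series.indicator)
    if limit is None:
        raise ConfigError(f"no critical limit configured for {series.indicator!r}")
    for i, (t, v) in enumerate(zip(series.times_days, series.values)):
        if limit.breached(v):
            if i == 0:
                interp = t
            else:
                t0, v0 = series.times_days[i - 1], series.values[i - 1]
                interp = t0 + (t - t0) * (limit.value - v0) / (v - v0)
            return Acceptability(
                indicator=series.indicator,
                temperature_c=series.temperature_c,
                acceptable_throughout=False,
                first_breach_day=t,
                interpolated_day=interp,
            )
    return Acceptability(
        indicator=series.indicator,
        temperature_c=series.temperature_c,
        acceptable_throughout=True,
    )
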