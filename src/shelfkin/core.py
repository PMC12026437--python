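"""Domain types and unit conventions.

Internal conventions used throughout the package:

* **time** — days. Hour-denominated inputs are divided by 24 on read, so
  every rate constant is per-day.
* **temperature** — degrees Celsius at the API surface, Kelvin internally
  with ``T(K) = T(°C) + 273.15``.
* **gas constant** — 8.3144 J K⁻¹ mol⁻¹ (the value conventional in the
  food-kinetics literature; not the full-precision CODATA value).
* **TVC** — handled on the log10 CFU/g scale directly: the series value *is*
  the log count, and kinetic models are applied to that number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import ConfigError, DomainError, InputError

#: Molar gas constant, J K^-1 mol^-1.
GAS_CONSTANT = 8.3144

#: Offset between Celsius and Kelvin.
KELVIN_OFFSET = 273.15

HOURS_PER_DAY = 24.0

#: Allowed quality-change directions during storage.
DIRECTIONS = ("increasing", "decreasing")


def celsius_to_kelvin(temperature_c: float) -> float:
    """Convert °C to K; reject temperatures at or below absolute zero."""
    kelvin = temperature_c + KELVIN_OFFSET
    if kelvin <= 0:
        raise DomainError(
            f"temperature {temperature_c} °C is at or below absolute zero"
        )
    return kelvin


def hours_to_days(hours: float) -> float:
    """Exact binary division by 24 (integer hour grids round-trip exactly)."""
    return hours / HOURS_PER_DAY


def days_to_hours(days: float) -> float:
    return days * HOURS_PER_DAY


@dataclass(frozen=True)
class IndicatorSpec:
    """Canonical name, default unit and default direction of an indicator."""

    name: str
    unit: str
    direction: str


#: Built-in indicator registry, keyed by lower-cased token. Order matters:
#: it defines the canonical indicator ordering used for deterministic
#: tie-breaking and report layout.
INDICATOR_REGISTRY: dict[str, IndicatorSpec] = {
    "tvb-n": IndicatorSpec("TVB-N", "mg/100 g", "increasing"),
    "tvc": IndicatorSpec("TVC", "log CFU/g", "increasing"),
    "av": IndicatorSpec("AV", "mg KOH/g", "increasing"),
    "springiness": IndicatorSpec("springiness", "N/m^2", "decreasing"),
    "hardness": IndicatorSpec("hardness", "g", "decreasing"),
    "ph": IndicatorSpec("pH", "pH", "increasing"),
    "sensory": IndicatorSpec("sensory", "score", "decreasing"),
}


def normalize_indicator(name: str) -> str:
    """Return the canonical spelling for a known indicator token.

    Unknown indicators pass through stripped but otherwise unchanged; they
    are legal everywhere as long as configuration supplies a direction.
    """
    token = name.strip()
    spec = INDICATOR_REGISTRY.get(token.lower())
    return spec.name if spec is not None else token


def canonical_indicator_rank(name: str) -> tuple[int, str]:
    """Sort key: registry order first, unknown indicators after, by name."""
    token = name.strip().lower()
    known = list(INDICATOR_REGISTRY)
    if token in known:
        return (known.index(token), "")
    return (len(known), token)


@dataclass(frozen=True)
class IndicatorSeries:
    """Measurements of one quality indicator over storage time at one
    constant storage temperature.

    Parameters
    ----------
    indicator:
        Indicator token, e.g. ``"TVB-N"``, ``"TVC"``, ``"hardness"``.
    unit:
        Free-text unit label (``mg/100 g``, ``log CFU/g``, ...).
    temperature_c:
        Storage temperature in °C.
    times_days:
        Strictly increasing sampling times in days, all non-negative.
    values:
        Measured values, one per sampling time.
    direction:
        ``"increasing"`` or ``"decreasing"`` — which way the indicator moves
        as quality degrades.
    """

    indicator: str
    unit: str
    temperature_c: float
    times_days: tuple[float, ...]
    values: tuple[float, ...]
    direction: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "times_days", tuple(float(t) for t in self.times_days))
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if self.direction not in DIRECTIONS:
            raise InputError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}"
            )
        if len(self.times_days) != len(self.values):
            raise InputError(
                f"{self.indicator}: {len(self.times_days)} times but "
                f"{len(self.values)} values"
            )
        if len(self.times_days) < 2:
            raise InputError(f"{self.indicator}: need at least 2 observations")
        if any(t < 0 for t in self.times_days):
            raise InputError(f"{self.indicator}: negative sampling time")
        for earlier, later in zip(self.times_days, self.times_days[1:]):
            if later <= earlier:
                raise InputError(
                    f"{self.indicator}: times must be strictly increasing "
                    f"({earlier} then {later})"
                )
        if not all(math.isfinite(v) for v in self.values):
            raise InputError(f"{self.indicator}: non-finite value in series")

    @property
    def n_points(self) -> int:
        return len(self.times_days)

    @property
    def initial_value(self) -> float:
        """Value at the earliest sampling time (t = 0 in a full design)."""
        return self.values[0]


@dataclass(frozen=True)
class CriticalLimit:
    """A critical value and the side on which it is breached.

    ``side="upper"`` pairs with increasing indicators (spoilage markers);
    ``side="lower"`` with decreasing ones (sensory score, texture).
    """

    value: float
    side: str

    def __post_init__(self) -> None:
        if self.side not in ("upper", "lower"):
            raise ConfigError(f"limit side must be 'upper' or 'lower', got {self.side!r}")
        if not math.isfinite(self.value):
            raise ConfigError("critical limit must be finite")

    def breached(self, value: float) -> bool:
        """True when *value* lies strictly past the limit."""
        if self.side == "upper":
            return value > self.value
        return value < self.value


@dataclass(frozen=True)
class CriticalLimits:
    """Case-insensitive mapping of indicator name to critical limit."""

    limits: Mapping[str, CriticalLimit] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "limits",
            {normalize_indicator(k): v for k, v in dict(self.limits).items()},
        )

    def get(self, indicator: str) -> CriticalLimit | None:
        return dict(self.limits).get(normalize_indicator(indicator))

    def __contains__(self, indicator: str) -> bool:
        return self.get(indicator) is not None

    def __getitem__(self, indicator: str) -> CriticalLimit:
        limit = self.get(indicator)
        if limit is None:
            raise ConfigError(f"no critical limit configured for {indicator!r}")
        return limit

    @classmethod
    def from_dict(cls, raw: Mapping[str, Mapping[str, object]]) -> "CriticalLimits":
        """Build from ``{"TVB-N": {"value": 35, "side": "upper"}, ...}``."""
        return cls(
            {
                name: CriticalLimit(float(entry["value"]), str(entry["side"]))
                for name, entry in raw.items()
            }
        )

    def to_dict(self) -> dict[str, dict[str, object]]:
        return {
            name: {"value": lim.value, "side": lim.side}
            for name, lim in self.limits.items()
        }


#: Widely used acceptability limits for cooked aquatic products.
DEFAULT_LIMITS = CriticalLimits(
    {
        "TVB-N": CriticalLimit(35.0, "upper"),
        "TVC": CriticalLimit(6.0, "upper"),
        "AV": CriticalLimit(5.0, "upper"),
        "sensory": CriticalLimit(5.0, "lower"),
    }
)


def group_by_indicator(
    series: Iterable[IndicatorSeries],
) -> dict[str, list[IndicatorSeries]]:
    """Group series by canonical indicator, each group sorted by temperature."""
    grouped: dict[str, list[IndicatorSeries]] = {}
    for s in series:
        grouped.setdefault(normalize_indicator(s.indicator), []).append(s)
    for name in grouped:
        grouped[name].sort(key=lambda s: s.temperature_c)
    return dict(
        sorted(grouped.items(), key=lambda item: canonical_indicator_rank(item[0]))
    )
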