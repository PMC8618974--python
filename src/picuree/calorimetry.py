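"""Indirect-calorimetry processing.

Turns a minute-resolution gas-exchange measurement into a validated
resting-energy-expenditure (REE) value: steady-state window detection,
respiratory-quotient plausibility filtering, and the abbreviated Weir
conversion (no urinary-nitrogen term).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, DomainError

__all__ = [
    "CalorimetrySeries",
    "SteadyStateWindow",
    "GasSummary",
    "gas_constants",
    "weir_ree",
    "respiratory_quotient",
    "window_variation",
    "find_steady_state",
    "summarize_measurement",
]

#: Default RQ plausibility band; values strictly outside are excluded.
RQ_BOUNDS = (0.67, 1.3)

#: Variation thresholds for a qualifying steady-state window.
RQ_VARIATION_MAX = 0.05
GAS_VARIATION_MAX = 0.10

MIN_STEADY_MINUTES = 5


def gas_constants() -> dict:
    """Load the versioned Weir/Mehta constants bundled with the package."""
    text = resources.files("picuree.data").joinpath("equation_constants.yaml").read_text()
    return yaml.safe_load(text)


_CONSTANTS = gas_constants()


def weir_ree(vo2: float, vco2: float) -> float:
    """Convert gas exchange (L/min) to REE (kcal/day) by the abbreviated Weir form.

    REE = 1440 * (3.941*VO2 + 1.106*VCO2); linear and homogeneous in both gases.
    """
    if vo2 < 0 or vco2 < 0:
        raise DomainError(f"gas values must be nonnegative, got vo2={vo2}, vco2={vco2}")
    w = _CONSTANTS["weir"]
    return w["minutes_per_day"] * (w["vo2_coef"] * vo2 + w["vco2_coef"] * vco2)


def respiratory_quotient(vco2: float, vo2: float) -> float:
    """RQ = VCO2/VO2 (dimensionless)."""
    if vo2 <= 0:
        raise DomainError(f"vo2 must be positive to compute RQ, got {vo2}")
    return vco2 / vo2


def window_variation(values, method: str = "range_mean") -> float:
    """Relative variation of a window of positive values.

    ``range_mean`` (default): (max - min)/mean.  ``cv``: sample SD/mean,
    selectable for sensitivity checks.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise DomainError("window_variation requires a nonempty window")
    mean = arr.mean()
    if mean <= 0:
        raise DomainError(f"window mean must be positive, got {mean}")
    if method == "range_mean":
        return float((arr.max() - arr.min()) / mean)
    if method == "cv":
        return float(arr.std(ddof=1) / mean) if arr.size > 1 else 0.0
    raise DomainError(f"unknown variation method {method!r}")


@dataclass(frozen=True)
class CalorimetrySeries:
    """Minute-by-minute VO2/VCO2/minute-ventilation over one measurement."""

    vo2: np.ndarray
    vco2: np.ndarray
    minute_ventilation: np.ndarray

    def __post_init__(self):
        for name in ("vo2", "vco2", "minute_ventilation"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.vo2)
        if len(self.vco2) != n or len(self.minute_ventilation) != n:
            raise DataError("calorimetry channels must have equal length")
        for name in ("vo2", "vco2", "minute_ventilation"):
            if np.any(getattr(self, name) <= 0):
                raise DataError(f"all {name} values must be positive")

    def __len__(self) -> int:
        return len(self.vo2)

    @property
    def rq(self) -> np.ndarray:
        return self.vco2 / self.vo2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "minute": np.arange(len(self)),
                "vo2_l_min": self.vo2,
                "vco2_l_min": self.vco2,
                "minute_ventilation_l_min": self.minute_ventilation,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CalorimetrySeries":
        df = pd.read_csv(Path(path))
        return cls(
            vo2=df["vo2_l_min"].to_numpy(),
            vco2=df["vco2_l_min"].to_numpy(),
            minute_ventilation=df["minute_ventilation_l_min"].to_numpy(),
        )


@dataclass(frozen=True)
class SteadyStateWindow:
    start: int
    end: int  # inclusive
    mean_vo2: float
    mean_vco2: float
    rq: float = field(init=False)
    ree: float = field(init=False)

    def __post_init__(self):
        if self.end - self.start + 1 < MIN_STEADY_MINUTES:
            raise DataError("steady-state window shorter than the minimum length")
        object.__setattr__(self, "rq", self.mean_vco2 / self.mean_vo2)
        object.__setattr__(self, "ree", weir_ree(self.mean_vo2, self.mean_vco2))

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GasSummary:
    """Outcome of one measurement: gases + REE, or an exclusion reason."""

    vo2: Optional[float]
    vco2: Optional[float]
    rq: Optional[float]
    ree: Optional[float]
    exclusion_reason: str = "none"  # none | no_steady_state | rq_out_of_range

    @property
    def valid(self) -> bool:
        return self.exclusion_reason == "none"

    def to_dict(self) -> dict:
        return {
            "vo2": self.vo2,
            "vco2": self.vco2,
            "rq": self.rq,
            "ree": self.ree,
            "valid": self.valid,
            "exclusion_reason": self.exclusion_reason,
        }


def _window_ok(series: CalorimetrySeries, start: int, end: int, method: str) -> bool:
    sl = slice(start, end + 1)
    return (
        window_variation(series.rq[sl], method) < RQ_VARIATION_MAX
        and window_variation(series.vo2[sl], method) < GAS_VARIATION_MAX
        and window_variation(series.vco2[sl], method) < GAS_VARIATION_MAX
        and window_variation(series.minute_ventilation[sl], method) < GAS_VARIATION_MAX
    )


def find_steady_state(
    series: CalorimetrySeries,
    min_minutes: int = MIN_STEADY_MINUTES,
    method: str = "range_mean",
) -> Optional[SteadyStateWindow]:
    """Longest contiguous window (earliest start on ties) meeting all thresholds.

    A window of >=``min_minutes`` qualifies iff RQ variation < 5% and
    VO2/VCO2/minute-ventilation variation < 10% each.  All contiguous
    windows are scanned; returns ``None`` when no window qualifies.
    """
    n = len(series)
    if n < min_minutes:
        return None
    best: Optional[tuple[int, int]] = None
    for start in range(n - min_minutes + 1):
        for end in range(start + min_minutes - 1, n):
            if not _window_ok(series, start, end, method):
                continue
            if best is None or (end - start) > (best[1] - best[0]):
                best = (start, end)
    if best is None:
        return None
    sl = slice(best[0], best[1] + 1)
    return SteadyStateWindow(
        start=best[0],
        end=best[1],
        mean_vo2=float(series.vo2[sl].mean()),
        mean_vco2=float(series.vco2[sl].mean()),
    )


def summarize_measurement(
    series: CalorimetrySeries,
    rq_bounds: tuple[float, float] = RQ_BOUNDS,
    method: str = "range_mean",
) -> GasSummary:
    """Steady-state detection + RQ filter + Weir REE for one measurement.

    No steady state -> invalid (``no_steady_state``).  Window RQ strictly
    outside ``rq_bounds`` -> invalid (``rq_out_of_range``); RQ exactly at a
    bound is retained.
    """
    window = find_steady_state(series, method=method)
    if window is None:
        return GasSummary(None, None, None, None, exclusion_reason="no_steady_state")
    if window.rq < rq_bounds[0] or window.rq > rq_bounds[1]:
        return GasSummary(
            window.mean_vo2,
            window.mean_vco2,
            window.rq,
            window.ree,
            exclusion_reason="rq_out_of_range",
        )
    return GasSummary(window.mean_vo2, window.mean_vco2, window.rq, window.ree)
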