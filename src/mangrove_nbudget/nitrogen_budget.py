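"""Deterministic nitrogen stock and accumulation arithmetic.

Units
-----
* N stock: Mg ha^-1 — bulk density (g cm^-3) x thickness (cm) x N fraction
  gives g N cm^-2; 1 g cm^-2 = 100 Mg ha^-1.
* N accumulation: g m^-2 y^-1 — SAR (mm y^-1) x bulk density x N fraction
  x 1000 (0.1 cm per mm, 10^4 cm^2 per m^2); 100 g m^-2 y^-1 = 1 Mg ha^-1 y^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from mangrove_nbudget.core_model import (
    CoreSlice,
    PeriodDefinition,
    SedimentCore,
    assign_period,
)

#: IUPAC standard atomic weights.
ATOMIC_WEIGHT_C = 12.011
ATOMIC_WEIGHT_N = 14.007

#: g cm^-2 -> Mg ha^-1
_STOCK_FACTOR = 100.0
#: (mm y^-1, g cm^-3, fraction) -> g m^-2 y^-1
_ACCUM_FACTOR = 1000.0


@dataclass(frozen=True)
class StockResult:
    """A nitrogen stock over one deposition window, Mg ha^-1."""

    value: float
    period: PeriodDefinition
    depth_range: tuple[float, float] | None

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"stock {self.value} < 0")


@dataclass(frozen=True)
class AccumulationResult:
    """A nitrogen accumulation rate, g m^-2 y^-1."""

    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"accumulation {self.value} < 0")

    @property
    def mg_ha_y(self) -> float:
        """The same rate in Mg ha^-1 y^-1 (100 g m^-2 y^-1 = 1 Mg ha^-1 y^-1)."""
        return self.value / 100.0


def slice_n_stock(sl: CoreSlice) -> float:
    """Nitrogen stock of one slice, Mg ha^-1."""
    return sl.bulk_density * sl.thickness_cm * sl.n_fraction * _STOCK_FACTOR


def core_period_stock(core: SedimentCore, period: PeriodDefinition) -> StockResult:
    """Total N stock of the slices of *core* deposited within *period*."""
    slices = assign_period(core, period)
    if not slices:
        return StockResult(0.0, period, None)
    value = sum(slice_n_stock(s) for s in slices)
    depth_range = (min(s.depth_top for s in slices),
                   max(s.depth_bottom for s in slices))
    return StockResult(value, period, depth_range)


def n_accumulation_rate(sar: float, bulk_density: float,
                        n_fraction: float) -> float:
    """N accumulation rate, g m^-2 y^-1, from SAR x bulk density x N fraction.

    Parameters are the sediment accretion rate in mm y^-1, the dry bulk
    density in g cm^-3, and the N mass fraction (0-1).
    """
    if sar < 0 or bulk_density < 0 or n_fraction < 0:
        raise ValueError("sar, bulk_density and n_fraction must be >= 0")
    return sar * bulk_density * n_fraction * _ACCUM_FACTOR


def molar_cn(c_fraction: float, n_fraction: float) -> float:
    """Molar C:N ratio from mass fractions."""
    if n_fraction <= 0:
        raise ValueError("molar C:N undefined for n_fraction <= 0")
    return (c_fraction / ATOMIC_WEIGHT_C) / (n_fraction / ATOMIC_WEIGHT_N)


def normalize_stock_rate(stock: StockResult) -> float:
    """Stock divided by its period duration, Mg ha^-1 y^-1.

    Puts the 46-year recent and 40-year historic windows on a common
    per-year scale before comparing them.
    """
    duration = stock.period.duration_y
    if duration <= 0:
        raise ValueError("period duration must be > 0")
    return stock.value / duration


class NonDecayingProfileWarning(UserWarning):
    """The fitted depth trend does not decay; extrapolation may be large."""


def extrapolate_depth_profile(
    profile: Sequence[tuple[float, float]], target_depth: float
) -> float:
    """Cumulative N stock to *target_depth* by log-linear extrapolation.

    *profile* is a sequence of ``(depth midpoint cm, N density Mg ha^-1 cm^-1)``
    pairs.  A linear model ``ln(density) = a + b * depth`` is fit by least
    squares; the cumulative stock is the trapezoidal integral of the observed
    densities from the surface to the deepest observation (the shallowest
    density is extended to depth 0) plus the analytic integral of
    ``exp(a + b * depth)`` from the deepest observation to *target_depth*.
    """
    pts = sorted(profile)
    if len(pts) < 3:
        raise ValueError("need at least 3 profile points")
    depths = np.array([p[0] for p in pts], dtype=float)
    dens = np.array([p[1] for p in pts], dtype=float)
    if np.any(dens <= 0):
        raise ValueError("densities must be positive for the log transform")
    deepest = depths[-1]
    if target_depth < deepest - 1e-12:
        raise ValueError(
            f"target_depth {target_depth} is above the deepest observation "
            f"{deepest}"
        )

    b, a = np.polyfit(depths, np.log(dens), 1)
    if b >= 0:
        warnings.warn(
            f"fitted depth coefficient {b:.3g} >= 0: density does not decay "
            "with depth; extrapolated stock may be unrealistically large",
            NonDecayingProfileWarning,
            stacklevel=2,
        )

    # observed portion: trapezoid over [0, deepest], constant above the
    # shallowest midpoint
    obs_depths = np.concatenate(([0.0], depths))
    obs_dens = np.concatenate(([dens[0]], dens))
    observed = float(np.trapezoid(obs_dens, obs_depths))

    if target_depth <= deepest + 1e-12:
        return observed
    if abs(b) < 1e-12:
        tail = float(np.exp(a)) * (target_depth - deepest)
    else:
        tail = float(np.exp(a) / b * (np.exp(b * target_depth)
                                      - np.exp(b * deepest)))
    return observed + tail
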