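"""Permanence factor: fraction of char organic C remaining after a chosen
timeframe at a chosen mean annual soil temperature.

Three parameterizations, in order of preference: the H/C_org linear
regression (when the molar ratio has been measured), the pyrolysis
temperature class lookup, and a conservative fallback that uses the
low-temperature class.  Printed grid cells are always served verbatim so
that inventory output is auditable against the published tables; off-grid
queries are evaluated from two-pool decay surfaces calibrated to the grid
(class route) or by bilinear interpolation of the regression coefficients
in (soil temperature, log timeframe) (H/C route).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from . import decay, parameters
from .carbon_fraction import BiocharSpec, temp_class_from_temp
from .parameters import CONSTANTS, OffGridError

log = logging.getLogger(__name__)

__all__ = [
    "PermanenceQuery",
    "PermanenceResult",
    "DomainError",
    "fperm_from_class",
    "fperm_from_hc",
    "fperm_conservative",
    "choose_parameterization",
    "fperm_for_spec",
]

#: supported query domain (the span of the printed grid)
SOIL_TEMP_RANGE = (5.0, 25.0)
TIMEFRAME_RANGE = (100.0, 1000.0)


class DomainError(ValueError):
    """Query outside the supported (soil_temp, timeframe) domain."""


@dataclass(frozen=True)
class PermanenceQuery:
    """A permanence request; defaults are the recommended 100-year timeframe
    at the global mean annual cropland temperature."""

    timeframe: float = CONSTANTS.default_timeframe
    soil_temp: float = CONSTANTS.global_cropland_temp
    parameterization: str = "class"  # class | hc | conservative
    temp_class: str | None = None
    hc: float | None = None

    def __post_init__(self) -> None:
        if self.timeframe <= 0:
            raise ValueError("timeframe must be positive")
        if self.parameterization not in ("class", "hc", "conservative"):
            raise ValueError(
                f"unknown parameterization {self.parameterization!r}"
            )
        if self.parameterization == "class" and self.temp_class is None:
            raise ValueError("temp_class required for class parameterization")
        if self.parameterization == "hc" and self.hc is None:
            raise ValueError("hc required for hc parameterization")


@dataclass(frozen=True)
class PermanenceResult:
    fperm: float
    method: str  # exact_cell | calibrated_surface | hc_regression | conservative
    se: float | None = None
    warnings: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not 0.0 <= self.fperm <= 1.0:
            raise ValueError(f"fperm {self.fperm} outside [0, 1]")


def _check_domain(timeframe: float, soil_temp: float, extrapolate: bool) -> list[str]:
    warnings = []
    t_ok = TIMEFRAME_RANGE[0] <= timeframe <= TIMEFRAME_RANGE[1]
    s_ok = SOIL_TEMP_RANGE[0] <= soil_temp <= SOIL_TEMP_RANGE[1]
    if t_ok and s_ok:
        return warnings
    msg = (
        f"query (timeframe={timeframe} y, soil_temp={soil_temp} C) is "
        f"outside the supported domain "
        f"{TIMEFRAME_RANGE} y x {SOIL_TEMP_RANGE} C"
    )
    if not extrapolate:
        raise DomainError(msg + "; pass extrapolate=True to override")
    warnings.append(msg + " (extrapolated)")
    log.warning(warnings[-1])
    return warnings


def _exact_cell(timeframe: float, soil_temp: float):
    try:
        return parameters.get_permanence_cell(soil_temp, timeframe)
    except OffGridError:
        return None


def fperm_from_class(
    temp_class: str,
    timeframe: float = CONSTANTS.default_timeframe,
    soil_temp: float = CONSTANTS.global_cropland_temp,
    extrapolate: bool = False,
    _method_override: str | None = None,
) -> PermanenceResult:
    """Permanence from the pyrolysis-temperature class parameterization.

    Printed grid cells are returned verbatim with their standard error;
    anywhere else the class's calibrated two-pool surface is evaluated.
    """
    warnings = _check_domain(timeframe, soil_temp, extrapolate)
    cell = _exact_cell(timeframe, soil_temp)
    if cell is not None:
        value, se = cell.fperm(temp_class)
        return PermanenceResult(
            fperm=value, se=se,
            method=_method_override or "exact_cell",
            warnings=tuple(warnings),
        )
    pools = decay.calibrate_class_pools(temp_class)
    value = decay.fraction_remaining(pools, timeframe, soil_temp)
    return PermanenceResult(
        fperm=min(1.0, max(0.0, float(value))),
        method=_method_override or "calibrated_surface",
        warnings=tuple(warnings),
    )


def _hc_coeff_interpolators():
    grid = parameters.permanence_grid()
    temps = np.array(grid.soil_temps)
    tfs = np.array(grid.timeframes)
    c = np.empty((len(temps), len(tfs)))
    m = np.empty_like(c)
    for i, T in enumerate(temps):
        for j, tf in enumerate(tfs):
            cell = grid.cell(T, tf)
            c[i, j] = cell.c_hc
            m[i, j] = cell.m_hc
    logt = np.log(tfs)
    kw = dict(method="linear", bounds_error=False, fill_value=None)
    return (
        RegularGridInterpolator((temps, logt), c, **kw),
        RegularGridInterpolator((temps, logt), m, **kw),
    )


_HC_INTERP = None


def _hc_coeffs(timeframe: float, soil_temp: float) -> tuple[float, float]:
    """(c_hc, m_hc) at a query point: printed values on-grid, bilinear in
    (soil_temp, log timeframe) off-grid, clamped to the grid hull outside."""
    cell = _exact_cell(timeframe, soil_temp)
    if cell is not None:
        return cell.c_hc, cell.m_hc
    global _HC_INTERP
    if _HC_INTERP is None:
        _HC_INTERP = _hc_coeff_interpolators()
    t = min(max(soil_temp, SOIL_TEMP_RANGE[0]), SOIL_TEMP_RANGE[1])
    lt = math.log(min(max(timeframe, TIMEFRAME_RANGE[0]), TIMEFRAME_RANGE[1]))
    ci, mi = _HC_INTERP
    return float(ci((t, lt))), float(mi((t, lt)))


def fperm_from_hc(
    hc: float,
    timeframe: float = CONSTANTS.default_timeframe,
    soil_temp: float = CONSTANTS.global_cropland_temp,
    extrapolate: bool = False,
) -> PermanenceResult:
    """Permanence from the linear regression on molar H/C_org.

    fperm = c_hc + m_hc * hc, clamped to [0, 1] with a logged warning
    (the regression intercept exceeds 1 at low soil temperatures).
    """
    if not 0.0 <= hc <= 1.5:
        raise ValueError(f"H/C_org {hc} outside [0, 1.5]")
    warnings = _check_domain(timeframe, soil_temp, extrapolate)
    if hc > CONSTANTS.hc_atypical_threshold:
        msg = (
            f"H/C_org {hc} above {CONSTANTS.hc_atypical_threshold} - "
            "atypical of carbonized material"
        )
        log.warning(msg)
        warnings.append(msg)
    c_hc, m_hc = _hc_coeffs(timeframe, soil_temp)
    raw = c_hc + m_hc * hc
    value = min(1.0, max(0.0, raw))
    if value != raw:
        msg = f"regression value {raw:.4f} clamped to {value:.1f}"
        log.warning(msg)
        warnings.append(msg)
    return PermanenceResult(
        fperm=value, method="hc_regression", warnings=tuple(warnings)
    )


def fperm_conservative(
    timeframe: float = CONSTANTS.default_timeframe,
    soil_temp: float = CONSTANTS.global_cropland_temp,
    extrapolate: bool = False,
) -> PermanenceResult:
    """Conservative fallback: the low-temperature class values, used when
    neither H/C_org nor production conditions are known."""
    return fperm_from_class(
        "low", timeframe, soil_temp, extrapolate,
        _method_override="conservative",
    )


def choose_parameterization(spec: BiocharSpec) -> str:
    """Preference order: measured H/C_org, then production temperature
    (numeric or class), then the conservative fallback."""
    if spec.measured_hc is not None:
        return "hc"
    if spec.pyrolysis_temp is not None or spec.temp_class is not None:
        return "class"
    return "conservative"


def fperm_for_spec(
    spec: BiocharSpec,
    timeframe: float = CONSTANTS.default_timeframe,
    soil_temp: float = CONSTANTS.global_cropland_temp,
    extrapolate: bool = False,
) -> tuple[PermanenceResult, str]:
    """Dispatch a biochar spec to the appropriate parameterization.

    Returns (result, parameterization).
    """
    route = choose_parameterization(spec)
    if route == "hc":
        res = fperm_from_hc(spec.measured_hc, timeframe, soil_temp, extrapolate)
    elif route == "class":
        tc = (
            temp_class_from_temp(spec.pyrolysis_temp)
            if spec.pyrolysis_temp is not None
            else spec.temp_class
        )
        res = fperm_from_class(tc, timeframe, soil_temp, extrapolate)
    else:
        res = fperm_conservative(timeframe, soil_temp, extrapolate)
    return res, route
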