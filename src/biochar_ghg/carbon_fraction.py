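"""Organic-carbon fraction of biochar on a dry-matter (DM) basis.

Two routes are provided.  The default, emission-factor style route looks the
value up in the packaged class table by feedstock and production condition.
The opt-in continuous route chains three regressions: dry-ash-free (DAF)
char carbon content as a function of peak pyrolysis temperature, DAF char
yield as a function of feedstock lignin content and temperature, and an
ash-conservation balance that converts both to a DM basis.  A directly
measured value always wins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from . import parameters
from .parameters import CONSTANTS

log = logging.getLogger(__name__)

__all__ = [
    "BiocharSpec",
    "FcEstimate",
    "FC_DAF_COEFFS",
    "YIELD_COEFFS",
    "fc_daf",
    "biochar_yield_daf",
    "ash_fraction_biochar",
    "temp_class_from_temp",
    "estimate_fc",
]

#: DAF char carbon content vs peak temperature T (deg C):
#:   fc_daf(T) = a - b * exp(-c * T)
#: Exponential saturating regression from a 128-measurement meta-analysis
#: (R^2 = 0.65 attached as metadata).
FC_DAF_COEFFS = {"a": 0.93, "b": 0.92, "c": 0.0042, "r2": 0.65}

#: DAF char yield vs lignin fraction L (DM basis) and temperature T (deg C):
#:   y_bc(L, T) = a + b * L + c * exp(-d * T / 1000)
#: Functional form follows the underlying meta-analytic regression
#: (increasing in lignin, declining and saturating in temperature; reported
#: R^2 = 0.65); the printed coefficients are not machine-readable in our
#: source, so these values were calibrated so that the continuous route
#: reproduces the packaged class table at the class-representative
#: temperatures (400 / 525 / 700 deg C) within the table's spread.
YIELD_COEFFS = {"a": 0.0, "b": 0.15, "c": 0.413714, "d": 0.837269, "r2": 0.65}


@dataclass(frozen=True)
class BiocharSpec:
    """Inputs that identify one biochar for F_C and permanence estimation."""

    feedstock_class: str | None = None
    process: str = "pyrolysis"
    pyrolysis_temp: float | None = None
    temp_class: str | None = None
    measured_fc: float | None = None
    measured_hc: float | None = None

    def __post_init__(self) -> None:
        if self.process not in ("pyrolysis", "gasification"):
            raise ValueError(
                f"process must be 'pyrolysis' or 'gasification', "
                f"got {self.process!r}"
            )
        if self.measured_fc is None and self.feedstock_class is None:
            raise ValueError(
                "either measured_fc or feedstock_class must be supplied"
            )
        if self.feedstock_class is not None:
            # validates and canonicalizes eagerly so bad labels fail here
            object.__setattr__(
                self, "feedstock_class",
                parameters.canonical_feedstock(self.feedstock_class),
            )
        if self.temp_class is not None:
            tc = self.temp_class.strip().lower()
            if tc not in parameters.TEMP_CLASSES:
                raise ValueError(
                    f"temp_class must be one of {parameters.TEMP_CLASSES}, "
                    f"got {self.temp_class!r}"
                )
            object.__setattr__(self, "temp_class", tc)
        if self.pyrolysis_temp is not None:
            if self.pyrolysis_temp < CONSTANTS.min_pyrolysis_temp:
                raise ValueError(
                    f"pyrolysis_temp {self.pyrolysis_temp} deg C is below "
                    f"{CONSTANTS.min_pyrolysis_temp} deg C; cooler chars "
                    "(torrefaction, hydrothermal carbonization) are outside "
                    "this method"
                )
        if self.measured_fc is not None and not 0.0 <= self.measured_fc <= 1.0:
            raise ValueError(f"measured_fc {self.measured_fc} outside [0, 1]")
        if self.measured_hc is not None:
            if not 0.0 <= self.measured_hc <= 1.5:
                raise ValueError(
                    f"measured_hc {self.measured_hc} outside [0, 1.5]"
                )
            if self.measured_hc > CONSTANTS.hc_atypical_threshold:
                log.warning(
                    "measured H/C_org %.3f exceeds %.1f - atypical of "
                    "carbonized material",
                    self.measured_hc, CONSTANTS.hc_atypical_threshold,
                )


@dataclass(frozen=True)
class FcEstimate:
    """An F_C estimate with its provenance and (continuous-route)
    intermediates."""

    fc: float
    source: str  # measured | class_table | continuous_equations
    sd: float | None = None
    condition: str | None = None
    fc_daf: float | None = None
    y_bc: float | None = None
    ash_bc: float | None = None
    warnings: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not 0.0 <= self.fc <= 1.0:
            raise ValueError(f"fc {self.fc} outside [0, 1]")
        for name in ("fc_daf", "y_bc", "ash_bc"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} {v} outside [0, 1]")


def _check_temp(temp: float) -> None:
    if temp < CONSTANTS.min_pyrolysis_temp:
        raise ValueError(
            f"pyrolysis temperature {temp} deg C is below the "
            f"{CONSTANTS.min_pyrolysis_temp} deg C exclusion threshold"
        )
    if temp > CONSTANTS.max_pyrolysis_temp:
        raise ValueError(
            f"pyrolysis temperature {temp} deg C is above the supported "
            f"regression range (<= {CONSTANTS.max_pyrolysis_temp} deg C)"
        )


def fc_daf(pyrolysis_temp: float) -> float:
    """Organic-C fraction of char on a dry-ash-free basis.

    Strictly increasing and bounded in (0, 1) over the supported
    350-900 deg C range.
    """
    _check_temp(pyrolysis_temp)
    c = FC_DAF_COEFFS
    return c["a"] - c["b"] * math.exp(-c["c"] * pyrolysis_temp)


def biochar_yield_daf(lignin: float, pyrolysis_temp: float) -> float:
    """DAF char yield per unit DAF feedstock.

    Non-decreasing in lignin content, non-increasing in temperature.
    """
    if not 0.0 <= lignin <= 1.0:
        raise ValueError(f"lignin fraction {lignin} outside [0, 1]")
    _check_temp(pyrolysis_temp)
    c = YIELD_COEFFS
    y = c["a"] + c["b"] * lignin + c["c"] * math.exp(
        -c["d"] * pyrolysis_temp / 1000.0
    )
    if not 0.0 < y < 1.0:  # cannot occur within validated input ranges
        raise ValueError(f"yield {y} outside (0, 1)")
    return y


def ash_fraction_biochar(ash_bm: float, y_bc: float) -> float:
    """Char ash fraction under ash conservation.

    All feedstock ash reports to the char while the organic mass shrinks by
    the DAF yield factor, so the char ash fraction is
    ash_bm / (ash_bm + y_bc * (1 - ash_bm)).
    """
    if not 0.0 <= ash_bm < 1.0:
        raise ValueError(f"ash_bm {ash_bm} outside [0, 1)")
    if not 0.0 < y_bc <= 1.0:
        raise ValueError(
            f"y_bc {y_bc} outside (0, 1]; zero yield would leave pure ash"
        )
    return ash_bm / (ash_bm + y_bc * (1.0 - ash_bm))


def temp_class_from_temp(pyrolysis_temp: float) -> str:
    """Bin a numeric pyrolysis temperature into low / medium / high.

    Bin edges: [350, 450) low, [450, 600) medium, >= 600 high.
    """
    _check_temp(pyrolysis_temp)
    if pyrolysis_temp < 450.0:
        return "low"
    if pyrolysis_temp < 600.0:
        return "medium"
    return "high"


def _class_condition(spec: BiocharSpec) -> tuple[str, list[str]]:
    """Resolve the class-table column for a spec, with warnings."""
    warnings: list[str] = []
    if spec.process == "gasification":
        return "gasification", warnings
    if spec.pyrolysis_temp is not None:
        derived = temp_class_from_temp(spec.pyrolysis_temp)
        if spec.temp_class is not None and spec.temp_class != derived:
            msg = (
                f"temp_class {spec.temp_class!r} disagrees with "
                f"pyrolysis_temp {spec.pyrolysis_temp} deg C "
                f"({derived!r}); using the numeric temperature"
            )
            log.warning(msg)
            warnings.append(msg)
        return derived, warnings
    if spec.temp_class is not None:
        return spec.temp_class, warnings
    # no production-temperature information at all: class-average value
    return "mean", warnings


def estimate_fc(spec: BiocharSpec, *, continuous: bool = False) -> FcEstimate:
    """Estimate F_C for a biochar.

    Dispatch: a measured value is passed through; otherwise the class-table
    lookup is the default route, with the continuous regression chain
    available opt-in (``continuous=True``, pyrolysis only) when a numeric
    temperature is known.

    Gasification chars whose ash has been partially removed are not
    representable here; their carbon content must be measured directly and
    supplied as ``measured_fc``.
    """
    if spec.measured_fc is not None:
        return FcEstimate(fc=spec.measured_fc, source="measured")

    if (continuous and spec.process == "pyrolysis"
            and spec.pyrolysis_temp is not None
            and spec.feedstock_class is not None):
        rec = parameters.get_feedstock(spec.feedstock_class)
        fdaf = fc_daf(spec.pyrolysis_temp)
        y = biochar_yield_daf(rec.lignin_mean, spec.pyrolysis_temp)
        ash = ash_fraction_biochar(rec.ash_mean, y)
        return FcEstimate(
            fc=fdaf * (1.0 - ash),
            source="continuous_equations",
            fc_daf=fdaf,
            y_bc=y,
            ash_bc=ash,
        )

    condition, warnings = _class_condition(spec)
    value, sd = parameters.get_fc_class(spec.feedstock_class, condition)
    return FcEstimate(
        fc=value,
        sd=sd,
        source="class_table",
        condition=condition,
        warnings=tuple(warnings),
    )
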