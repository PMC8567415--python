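"""Net avoided GHG per biochar application event, and batch processing.

The balance for one event is

    total CO2e = M_bc * F_C * 44/12 * F_perm  +  reduction * n * GWP_N2O

where ``n`` is the tier-1 baseline annual N2O from the amended land.  CH4
and priming enter as explicit zero line items: both are modelled decisions
(no significant effect at current evidence), not omissions, and belong in
an auditable report.  Applies to mineral soils only.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Any, Iterable

import pandas as pd
import yaml

from . import n2o as n2o_mod
from . import permanence
from .carbon_fraction import BiocharSpec, estimate_fc
from .parameters import CONSTANTS

log = logging.getLogger(__name__)

__all__ = [
    "InventoryConfig",
    "ApplicationEvent",
    "InventoryResult",
    "InventoryReport",
    "OrganicSoilError",
    "ghg_balance",
    "run_inventory",
    "read_activity",
    "render_report",
    "round_to_10",
]


class OrganicSoilError(ValueError):
    """The method is restricted to mineral soils."""


def round_to_10(x: float) -> float:
    """Display rounding to the nearest 10 Mg CO2e (half-to-even)."""
    return round(x / 10.0) * 10.0


@dataclass(frozen=True)
class InventoryConfig:
    """Method configuration. Defaults follow the published method
    (GWP_N2O = 273 for a 100-year horizon; N2O credit included but
    flagged optional; two-significant-figure rounding of the N2O baseline
    to match the reporting convention)."""

    gwp_n2o: float = CONSTANTS.gwp_n2o_default
    include_n2o: bool = True
    n2o_reduction: float = CONSTANTS.n2o_reduction
    round_intermediates: bool = True
    display_rounding: bool = True
    extrapolate: bool = False
    continuous_fc: bool = False
    default_timeframe: float = CONSTANTS.default_timeframe
    default_soil_temp: float = CONSTANTS.global_cropland_temp

    @classmethod
    def from_file(cls, path: str) -> "InventoryConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class ApplicationEvent:
    """One biochar addition to one land parcel (a single parcel-year)."""

    event_id: str
    biochar: BiocharSpec
    mass: float  # Mg biochar dry matter
    area_ha: float
    soil_temp: float = CONSTANTS.global_cropland_temp
    timeframe: float = CONSTANTS.default_timeframe
    nitrogen: n2o_mod.NitrogenInputs | None = None
    soil_kind: str = "mineral"

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValueError("mass must be >= 0")
        if self.soil_kind not in ("mineral", "organic_or_forest_organic_horizon"):
            raise ValueError(f"unknown soil_kind {self.soil_kind!r}")
        if self.nitrogen is not None and self.area_ha <= 0:
            raise ValueError("area_ha must be positive for N2O accounting")


@dataclass(frozen=True)
class InventoryResult:
    event_id: str
    sequestration_co2e: float
    n2o_co2e: float
    total_co2e: float
    total_co2e_display: float
    ch4_co2e: float = 0.0      # no significant net CH4 effect: modelled zero
    priming_co2e: float = 0.0  # priming not significant: modelled zero
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expect = (self.sequestration_co2e + self.n2o_co2e
                  + self.ch4_co2e + self.priming_co2e)
        if not math.isclose(self.total_co2e, expect, rel_tol=1e-12,
                            abs_tol=1e-9):
            raise ValueError("total is not the sum of its line items")


def ghg_balance(
    event: ApplicationEvent,
    config: InventoryConfig | None = None,
) -> InventoryResult:
    """Net avoided GHG for a single application event, fully itemized."""
    config = config or InventoryConfig()
    if event.soil_kind != "mineral":
        raise OrganicSoilError(
            "biochar GHG accounting applies to mineral soils only; organic "
            "soils (Histosols) and forest organic horizons are excluded "
            "because positive priming cannot be ruled out"
        )

    fc_est = estimate_fc(event.biochar, continuous=config.continuous_fc)
    fperm_res, route = permanence.fperm_for_spec(
        event.biochar, event.timeframe, event.soil_temp, config.extrapolate
    )
    sequestration = (
        event.mass * fc_est.fc * CONSTANTS.co2_per_c * fperm_res.fperm
    )

    n2o_co2e = 0.0
    n2o_prov: dict[str, Any] = {"included": False}
    if config.include_n2o and event.nitrogen is not None:
        baseline_raw = n2o_mod.baseline_n2o(event.nitrogen)
        baseline = (
            n2o_mod.round_sig(baseline_raw, 2)
            if config.round_intermediates else baseline_raw
        )
        rate_c = n2o_mod.application_rate_c(
            event.mass, fc_est.fc, event.area_ha
        )
        eligible = n2o_mod.eligibility(rate_c)
        credit = n2o_mod.n2o_credit(
            baseline, eligible, config.gwp_n2o, config.n2o_reduction
        )
        n2o_co2e = credit.co2e
        n2o_prov = {
            "included": True,
            "note": "N2O credit is optional per method; first year only",
            "baseline_n2o_raw": baseline_raw,
            "baseline_n2o_used": baseline,
            "application_rate_c": rate_c,
            "eligible": eligible,
            "reduction_fraction": config.n2o_reduction,
            "gwp_n2o": config.gwp_n2o,
            "intermediate_rounding": config.round_intermediates,
        }
    elif not config.include_n2o:
        n2o_prov = {"included": False,
                    "note": "excluded (optional per method)"}

    total = sequestration + n2o_co2e
    provenance = {
        "fc": fc_est.fc,
        "fc_source": fc_est.source,
        "fc_condition": fc_est.condition,
        "fc_sd": fc_est.sd,
        "fperm": fperm_res.fperm,
        "fperm_method": fperm_res.method,
        "fperm_se": fperm_res.se,
        "fperm_parameterization": route,
        "timeframe_years": event.timeframe,
        "soil_temp_c": event.soil_temp,
        "co2_per_c": CONSTANTS.co2_per_c,
        "n2o": n2o_prov,
        "ch4": "no significant net effect: zero by construction",
        "priming": "not significant in mineral soils: zero by construction",
        "warnings": list(fc_est.warnings) + list(fperm_res.warnings),
        "display_rounding": (
            "nearest 10 Mg CO2e, half-to-even"
            if config.display_rounding else "none"
        ),
    }
    return InventoryResult(
        event_id=event.event_id,
        sequestration_co2e=sequestration,
        n2o_co2e=n2o_co2e,
        total_co2e=total,
        total_co2e_display=(
            round_to_10(total) if config.display_rounding else total
        ),
        provenance=provenance,
    )


@dataclass(frozen=True)
class InventoryReport:
    results: tuple[InventoryResult, ...]
    errors: tuple[tuple[str, str], ...]  # (row label, message)

    @property
    def grand_total_co2e(self) -> float:
        return sum(r.total_co2e for r in self.results)


# ---------------------------------------------------------------------------
# activity-data parsing

_COLUMNS = (
    "event_id", "feedstock", "process", "pyrolysis_temp_c", "temp_class",
    "measured_fc", "measured_hc", "mass_mg", "area_ha", "soil_temp_c",
    "timeframe_years", "n_rate_mg_per_ha", "soil_kind",
)


def _get(row, name, default=None):
    v = row.get(name, default)
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return default
    return v


def _event_from_row(row: dict[str, Any]) -> ApplicationEvent:
    n_rate = _get(row, "n_rate_mg_per_ha")
    if n_rate is None and _get(row, "n_rate_kg_per_ha") is not None:
        n_rate = float(row["n_rate_kg_per_ha"]) / 1000.0
        log.warning("n_rate given in kg/ha; converted to Mg/ha")
    mass = _get(row, "mass_mg")
    if mass is None and _get(row, "mass_kg") is not None:
        mass = float(row["mass_kg"]) / 1000.0
        log.warning("mass given in kg; converted to Mg")
    if mass is None:
        raise ValueError("missing mass_mg")

    spec = BiocharSpec(
        feedstock_class=_get(row, "feedstock"),
        process=_get(row, "process", "pyrolysis"),
        pyrolysis_temp=_maybe_float(_get(row, "pyrolysis_temp_c")),
        temp_class=_get(row, "temp_class"),
        measured_fc=_maybe_float(_get(row, "measured_fc")),
        measured_hc=_maybe_float(_get(row, "measured_hc")),
    )
    area = float(_get(row, "area_ha", 0.0) or 0.0)
    nitrogen = None
    if n_rate is not None:
        nitrogen = n2o_mod.NitrogenInputs(area_ha=area, n_rate=float(n_rate))
    return ApplicationEvent(
        event_id=str(_get(row, "event_id", "")),
        biochar=spec,
        mass=float(mass),
        area_ha=area,
        soil_temp=float(_get(row, "soil_temp_c",
                             CONSTANTS.global_cropland_temp)),
        timeframe=float(_get(row, "timeframe_years",
                             CONSTANTS.default_timeframe)),
        nitrogen=nitrogen,
        soil_kind=_get(row, "soil_kind", "mineral"),
    )


def _maybe_float(v):
    return None if v is None else float(v)


def read_activity(source) -> pd.DataFrame:
    """Read an activity-data table (CSV path or DataFrame passthrough)."""
    if isinstance(source, pd.DataFrame):
        return source
    return pd.read_csv(source)


def run_inventory(
    events: "Iterable[ApplicationEvent] | pd.DataFrame | str",
    config: InventoryConfig | None = None,
    strict: bool = False,
) -> InventoryReport:
    """Process a batch of application events.

    Row-level failures are collected with their row labels and the run
    continues, unless ``strict`` is set, in which case the first failure
    raises.  Deterministic: results are in input order.
    """
    config = config or InventoryConfig()
    if isinstance(events, (pd.DataFrame, str)):
        df = read_activity(events)
        items: list[tuple[str, Any]] = [
            (f"row {i}", rec) for i, rec in
            enumerate(df.to_dict(orient="records"))
        ]
    else:
        items = [(f"event {getattr(e, 'event_id', i)}", e)
                 for i, e in enumerate(events)]

    results: list[InventoryResult] = []
    errors: list[tuple[str, str]] = []
    for label, item in items:
        try:
            event = item if isinstance(item, ApplicationEvent) \
                else _event_from_row(item)
            results.append(ghg_balance(event, config))
        except Exception as exc:
            if strict:
                raise
            log.error("%s rejected: %s", label, exc)
            errors.append((label, str(exc)))
    return InventoryReport(results=tuple(results), errors=tuple(errors))


def render_report(report: InventoryReport, fmt: str = "json") -> str:
    """Render a report as JSON (full provenance) or CSV (flat columns)."""
    if fmt == "json":
        payload = {
            "results": [
                {
                    "event_id": r.event_id,
                    "sequestration_co2e": r.sequestration_co2e,
                    "n2o_co2e": r.n2o_co2e,
                    "ch4_co2e": r.ch4_co2e,
                    "priming_co2e": r.priming_co2e,
                    "total_co2e": r.total_co2e,
                    "total_co2e_display": r.total_co2e_display,
                    "provenance": r.provenance,
                }
                for r in report.results
            ],
            "errors": [{"row": lbl, "message": msg}
                       for lbl, msg in report.errors],
            "grand_total_co2e": report.grand_total_co2e,
        }
        return json.dumps(payload, indent=2)
    if fmt == "csv":
        df = pd.DataFrame(
            [
                {
                    "event_id": r.event_id,
                    "sequestration_co2e": r.sequestration_co2e,
                    "n2o_co2e": r.n2o_co2e,
                    "ch4_co2e": r.ch4_co2e,
                    "priming_co2e": r.priming_co2e,
                    "total_co2e": r.total_co2e,
                    "total_co2e_display": r.total_co2e_display,
                }
                for r in report.results
            ]
        )
        return df.to_csv(index=False)
    raise ValueError(f"unknown report format {fmt!r} (use 'json' or 'csv')")
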