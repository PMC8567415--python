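"""Packaged parameter tables and physical constants.

All feedstock and char parameters used by the model are shipped as CSV data
files transcribed cell-for-cell from their published sources, and exposed
here through validated lookups.  Mass quantities are converted to fractions
of dry matter at load time; nothing downstream ever sees a percentage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import pandas as pd

__all__ = [
    "FeedstockRecord",
    "FcClassRecord",
    "PermanenceGridCell",
    "PermanenceGrid",
    "Constants",
    "CONSTANTS",
    "FEEDSTOCK_ALIASES",
    "TEMP_CLASSES",
    "UnknownFeedstockError",
    "UnknownConditionError",
    "OffGridError",
    "get_feedstock",
    "get_fc_class",
    "get_permanence_cell",
    "permanence_grid",
    "list_feedstocks",
]

TEMP_CLASSES = ("low", "medium", "high")

#: Accepted synonyms for feedstock labels found in heterogeneous activity data.
FEEDSTOCK_ALIASES = {
    "rice husk": "rice residues",
    "rice hulls": "rice residues",
    "rice straw": "rice residues",
    "corn stover": "maize stover",
    "corn": "maize stover",
    "maize": "maize stover",
    "nut shells": "pits/shells/stones",
    "pits": "pits/shells/stones",
    "shells": "pits/shells/stones",
    "stones": "pits/shells/stones",
    "grass": "herbaceous",
    "sugarcane bagasse": "bagasse",
    "biosolids": "sewage sludge",
    "straw": "wheat straw",
}


class UnknownFeedstockError(KeyError):
    """Raised for a feedstock label outside the packaged classes."""


class UnknownConditionError(KeyError):
    """Raised for an unknown production-condition label."""


class OffGridError(KeyError):
    """Raised when a (soil_temp, timeframe) pair is not a printed grid point.

    Off-grid permanence queries are served by :mod:`biochar_ghg.permanence`,
    which evaluates calibrated decay surfaces; this module only returns
    printed cells verbatim.
    """


@dataclass(frozen=True)
class FeedstockRecord:
    """Ash, carbon and lignin statistics for one biomass class.

    ``ash_mean`` and ``lignin_mean`` are mass fractions of dry matter;
    ``c_daf_mean`` is the carbon mass fraction of dry-ash-free matter.
    """

    feedstock_class: str
    ash_mean: float
    ash_sd: float
    n_ash: int
    c_daf_mean: float
    c_daf_sd: float
    n_c: int
    lignin_mean: float
    lignin_sd: float
    n_lignin: int

    def __post_init__(self) -> None:
        for name in ("ash_mean", "ash_sd", "c_daf_mean", "c_daf_sd",
                     "lignin_mean", "lignin_sd"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} outside [0, 1]")
        for name in ("n_ash", "n_c", "n_lignin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive sample count")


@dataclass(frozen=True)
class FcClassRecord:
    """Organic-carbon fraction of char (dry-matter basis) for one feedstock,
    by production condition, each value paired with its standard deviation."""

    feedstock_class: str
    fc_low: tuple[float, float]
    fc_medium: tuple[float, float]
    fc_high: tuple[float, float]
    fc_mean: tuple[float, float]
    fc_gasification: tuple[float, float]

    def __post_init__(self) -> None:
        for name in ("fc_low", "fc_medium", "fc_high", "fc_mean",
                     "fc_gasification"):
            v, sd = getattr(self, name)
            if not (0.0 <= v <= 1.0 and 0.0 <= sd <= 1.0):
                raise ValueError(f"{name}={v, sd} outside [0, 1]")
        # the published mean column is the average of the three temperature
        # classes; allow printed-rounding slack only
        expect = (self.fc_low[0] + self.fc_medium[0] + self.fc_high[0]) / 3.0
        if abs(expect - self.fc_mean[0]) > 0.005:
            raise ValueError(
                f"{self.feedstock_class}: mean column {self.fc_mean[0]} "
                f"inconsistent with class values (expected ~{expect:.4f})"
            )

    def value(self, condition: str) -> tuple[float, float]:
        condition = condition.strip().lower()
        try:
            return getattr(self, f"fc_{condition}")
        except AttributeError:
            raise UnknownConditionError(
                f"unknown condition {condition!r}; expected one of "
                "low, medium, high, mean, gasification"
            ) from None


@dataclass(frozen=True)
class PermanenceGridCell:
    """One printed row of the permanence grid.

    ``fperm_*`` are (value, standard error) pairs for the three pyrolysis
    temperature classes; ``c_hc``/``m_hc`` are the intercept and slope of the
    linear regression of the permanence fraction on molar H/C_org.
    """

    soil_temp: float
    timeframe: float
    fperm_low: tuple[float, float]
    fperm_medium: tuple[float, float]
    fperm_high: tuple[float, float]
    c_hc: float
    m_hc: float
    r2: float

    def __post_init__(self) -> None:
        lo, me, hi = self.fperm_low[0], self.fperm_medium[0], self.fperm_high[0]
        for v in (lo, me, hi):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"fperm value {v} outside [0, 1]")
        if not lo <= me <= hi:
            raise ValueError(
                f"cell ({self.soil_temp}, {self.timeframe}): class ordering "
                f"violated ({lo}, {me}, {hi})"
            )

    def fperm(self, temp_class: str) -> tuple[float, float]:
        temp_class = temp_class.strip().lower()
        if temp_class not in TEMP_CLASSES:
            raise UnknownConditionError(
                f"unknown temperature class {temp_class!r}; "
                f"expected one of {TEMP_CLASSES}"
            )
        return getattr(self, f"fperm_{temp_class}")


@dataclass(frozen=True)
class PermanenceGrid:
    """The full printed permanence grid (21 cells: 7 soil temperatures
    x 3 timeframes, including the two cropland-mean temperature rows)."""

    cells: tuple[PermanenceGridCell, ...]

    def __post_init__(self) -> None:
        if len(self.cells) != 21:
            raise ValueError(f"expected 21 grid cells, got {len(self.cells)}")
        # monotone in timeframe at fixed temp, and in temp at fixed timeframe
        for cls in TEMP_CLASSES:
            for t in self.soil_temps:
                vals = [c.fperm(cls)[0] for c in
                        sorted((c for c in self.cells if c.soil_temp == t),
                               key=lambda c: c.timeframe)]
                if any(a < b for a, b in zip(vals, vals[1:])):
                    raise ValueError(f"fperm not non-increasing in timeframe at {t} C")
            for tf in self.timeframes:
                vals = [c.fperm(cls)[0] for c in
                        sorted((c for c in self.cells if c.timeframe == tf),
                               key=lambda c: c.soil_temp)]
                if any(a < b for a, b in zip(vals, vals[1:])):
                    raise ValueError(f"fperm not non-increasing in soil temp at {tf} y")

    @property
    def soil_temps(self) -> tuple[float, ...]:
        return tuple(sorted({c.soil_temp for c in self.cells}))

    @property
    def timeframes(self) -> tuple[float, ...]:
        return tuple(sorted({c.timeframe for c in self.cells}))

    def cell(self, soil_temp: float, timeframe: float) -> PermanenceGridCell:
        for c in self.cells:
            if (math.isclose(c.soil_temp, soil_temp, abs_tol=1e-9)
                    and math.isclose(c.timeframe, timeframe, abs_tol=1e-9)):
                return c
        raise OffGridError(
            f"({soil_temp} C, {timeframe} y) is not a printed grid point; "
            f"printed soil temperatures are {self.soil_temps} and timeframes "
            f"{self.timeframes}.  Use biochar_ghg.permanence for off-grid "
            "queries (calibrated-surface interpolation)."
        )


@dataclass(frozen=True)
class Constants:
    """Physical constants and method defaults. Immutable at runtime."""

    co2_per_c: float = 44.0 / 12.0
    gwp_n2o_default: float = 273.0     # AR6, 100-year horizon
    gwp_n2o_ar4: float = 298.0
    n2o_reduction: float = 0.23
    n2o_reduction_ci: tuple[float, float] = (0.05, 0.41)
    n2o_eligibility_threshold: float = 10.0  # Mg C ha-1, strict inequality
    tier1_ef: float = 0.01             # Mg N2O-N per Mg N applied
    n2o_n_to_n2o: float = 1.57         # ~44/28, N2O-N -> N2O mass
    q10_a: float = 1.1
    q10_b: float = 12.0
    q10_c: float = 0.19
    global_cropland_temp: float = 14.9  # deg C
    us_cropland_temp: float = 10.9      # deg C
    min_pyrolysis_temp: float = 350.0   # deg C; cooler chars excluded
    max_pyrolysis_temp: float = 900.0   # upper end of regression support
    default_timeframe: float = 100.0    # years
    hc_atypical_threshold: float = 0.7  # H/C_org above this flagged


CONSTANTS = Constants()


def _read_table(name: str) -> pd.DataFrame:
    with resources.files("biochar_ghg.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


@lru_cache(maxsize=1)
def _feedstock_table() -> dict[str, FeedstockRecord]:
    df = _read_table("table1_feedstocks.csv")
    out = {}
    for row in df.itertuples(index=False):
        rec = FeedstockRecord(
            feedstock_class=row.feedstock,
            ash_mean=row.ash_pct / 100.0,
            ash_sd=row.ash_sd_pct / 100.0,
            n_ash=int(row.ash_n),
            c_daf_mean=row.c_daf_pct / 100.0,
            c_daf_sd=row.c_daf_sd_pct / 100.0,
            n_c=int(row.c_daf_n),
            lignin_mean=row.lignin_pct / 100.0,
            lignin_sd=row.lignin_sd_pct / 100.0,
            n_lignin=int(row.lignin_n),
        )
        out[rec.feedstock_class] = rec
    if len(out) != 11:
        raise ValueError(f"expected 11 feedstock classes, got {len(out)}")
    return out


@lru_cache(maxsize=1)
def _fc_table() -> dict[str, FcClassRecord]:
    df = _read_table("table2_carbon_fraction.csv")
    out = {}
    for row in df.itertuples(index=False):
        rec = FcClassRecord(
            feedstock_class=row.feedstock,
            fc_low=(row.fc_low, row.fc_low_sd),
            fc_medium=(row.fc_medium, row.fc_medium_sd),
            fc_high=(row.fc_high, row.fc_high_sd),
            fc_mean=(row.fc_mean, row.fc_mean_sd),
            fc_gasification=(row.fc_gasification, row.fc_gasification_sd),
        )
        out[rec.feedstock_class] = rec
    return out


@lru_cache(maxsize=1)
def permanence_grid() -> PermanenceGrid:
    """The packaged permanence grid, validated on first access."""
    df = _read_table("table3_permanence.csv")
    cells = tuple(
        PermanenceGridCell(
            soil_temp=row.soil_temp_c,
            timeframe=float(row.timeframe_years),
            fperm_low=(row.fperm_low, row.fperm_low_se),
            fperm_medium=(row.fperm_medium, row.fperm_medium_se),
            fperm_high=(row.fperm_high, row.fperm_high_se),
            c_hc=row.c_hc,
            m_hc=row.m_hc,
            r2=row.r2,
        )
        for row in df.itertuples(index=False)
    )
    return PermanenceGrid(cells=cells)


def canonical_feedstock(label: str) -> str:
    """Resolve a feedstock label (case-insensitive, alias-aware)."""
    key = label.strip().lower()
    key = FEEDSTOCK_ALIASES.get(key, key)
    if key not in _feedstock_table():
        valid = ", ".join(sorted(_feedstock_table()))
        raise UnknownFeedstockError(
            f"unknown feedstock {label!r}. Valid classes: {valid}. "
            "For feedstocks outside these classes (e.g. food waste) the char "
            "carbon fraction is too variable to tabulate and must be "
            "measured directly (supply measured_fc)."
        )
    return key


def list_feedstocks() -> list[str]:
    return sorted(_feedstock_table())


def get_feedstock(feedstock_class: str) -> FeedstockRecord:
    """Return the biomass composition record for a feedstock class."""
    return _feedstock_table()[canonical_feedstock(feedstock_class)]


def get_fc_class(feedstock_class: str, condition: str) -> tuple[float, float]:
    """Class-table organic-C fraction: (value, sd) exactly as packaged.

    ``condition`` is one of low / medium / high / mean / gasification.
    """
    rec = _fc_table()[canonical_feedstock(feedstock_class)]
    return rec.value(condition)


def get_permanence_cell(soil_temp: float, timeframe: float) -> PermanenceGridCell:
    """Return a printed permanence grid cell; off-grid queries raise
    :class:`OffGridError` (interpolation lives in the permanence module)."""
    return permanence_grid().cell(soil_temp, timeframe)
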