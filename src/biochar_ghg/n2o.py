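"""First-year soil N2O accounting: tier-1 baseline and the biochar credit.

The baseline is the simple emission-factor product
area x N rate x EF x (N2O-N -> N2O), and the credit is a one-year
percentage reduction of that baseline, granted only where the biochar
application rate exceeds the eligibility threshold on a carbon basis.
Inclusion of the credit in a GHG balance is optional by method design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .parameters import CONSTANTS

__all__ = [
    "NitrogenInputs",
    "N2OCredit",
    "baseline_n2o",
    "eligibility",
    "application_rate_c",
    "n2o_credit",
    "round_sig",
]


@dataclass(frozen=True)
class NitrogenInputs:
    """Annual direct nitrogen inputs to the land receiving biochar.

    ``n_rate`` is in Mg N per hectare per year (all direct N inputs);
    ``ef`` is the fraction of applied N emitted as N2O-N.
    """

    area_ha: float
    n_rate: float
    ef: float = CONSTANTS.tier1_ef
    source_note: str = ""

    def __post_init__(self) -> None:
        if self.area_ha < 0:
            raise ValueError("area_ha must be >= 0")
        if self.n_rate < 0:
            raise ValueError("n_rate must be >= 0")
        if not 0.0 <= self.ef <= 0.1:
            raise ValueError(f"ef {self.ef} outside the plausible [0, 0.1]")


@dataclass(frozen=True)
class N2OCredit:
    baseline_n2o: float  # Mg N2O / yr
    reduction_fraction: float
    gwp_used: float
    eligible: bool
    co2e: float  # Mg CO2e

    def __post_init__(self) -> None:
        expect = (
            self.baseline_n2o * self.reduction_fraction * self.gwp_used
            if self.eligible else 0.0
        )
        if not math.isclose(self.co2e, expect, rel_tol=1e-12, abs_tol=1e-12):
            raise ValueError("co2e inconsistent with its factors")


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def baseline_n2o(inputs: NitrogenInputs) -> float:
    """Tier-1 annual direct N2O from the amended land, Mg N2O per year.

    area x n_rate x EF gives Mg N2O-N; the 1.57 (~44/28) factor converts to
    Mg N2O.  Returned at full precision; the reporting convention rounds to
    two significant figures (see :func:`round_sig`).
    """
    return (
        inputs.area_ha * inputs.n_rate * inputs.ef * CONSTANTS.n2o_n_to_n2o
    )


def application_rate_c(mass_bc: float, fc: float, area_ha: float) -> float:
    """Biochar carbon application rate, Mg C per hectare."""
    if area_ha <= 0:
        raise ValueError("area_ha must be positive")
    return mass_bc * fc / area_ha


def eligibility(rate_c: float) -> bool:
    """Credit eligibility: application rate strictly in excess of
    10 Mg C per hectare."""
    if rate_c < 0:
        raise ValueError("application rate must be >= 0")
    return rate_c > CONSTANTS.n2o_eligibility_threshold


def n2o_credit(
    baseline: float,
    eligible: bool,
    gwp: float = CONSTANTS.gwp_n2o_default,
    reduction: float = CONSTANTS.n2o_reduction,
) -> N2OCredit:
    """First-year-only N2O credit in CO2e; zero when ineligible."""
    if baseline < 0:
        raise ValueError("baseline must be >= 0")
    if not 0.0 <= reduction <= 1.0:
        raise ValueError("reduction must be a fraction in [0, 1]")
    co2e = baseline * reduction * gwp if eligible else 0.0
    return N2OCredit(
        baseline_n2o=baseline,
        reduction_fraction=reduction,
        gwp_used=gwp,
        eligible=eligible,
        co2e=co2e,
    )
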