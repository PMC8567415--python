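import pytest

from biochar_ghg import BiocharSpec, NitrogenInputs
from biochar_ghg.inventory import ApplicationEvent, InventoryConfig


@pytest.fixture()
def worked_event() -> ApplicationEvent:
    """The published demonstration case: 15,000 Mg maize-stover biochar
    (500 deg C pyrolysis) on 1000 ha at 10 deg C soil, 100-year timeframe,
    150 kg mineral N/ha/yr."""
    return ApplicationEvent(
        event_id="worked-example",
        biochar=BiocharSpec(feedstock_class="maize stover",
                            process="pyrolysis", pyrolysis_temp=500.0),
        mass=15_000.0,
        area_ha=1000.0,
        soil_temp=10.0,
        timeframe=100.0,
        nitrogen=NitrogenInputs(area_ha=1000.0, n_rate=0.15),
    )


@pytest.fixture()
def config_ar4() -> InventoryConfig:
    """Configuration reproducing the demonstration arithmetic (GWP 298)."""
    return InventoryConfig(gwp_n2o=298.0)
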