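import numpy as np
import pytest

import cabinaer as ca


@pytest.fixture(scope="session")
def grid() -> ca.SizeGrid:
    return ca.DEFAULT_GRID


@pytest.fixture()
def simple_scenario(grid) -> ca.Scenario:
    """Hand-checkable scenario: flat outdoor counts, flat eta via fixture
    replaced per-test, no infiltration (standstill), explicit flows."""
    return ca.Scenario(
        vehicle=ca.VehicleSpec(vcabin_m3=4.1, beta_per_h=2.0),
        vent=ca.VentilationState(qoa_m3s=0.02, qrec_m3s=0.01, vspeed_kmh=0.0,
                                 qps_m3s=0.005),
        filter_spec=ca.load_filter_fixture("aged_500h", "off"),
        occupants=ca.OccupantLoad(n=2),
        cenv_particles=ca.SizeDistribution(np.full(25, 100.0), "count", grid),
        cenv_co2_ppm=716.0,
        eta_mode="upper",
    )


def flat_filter(eta: float, grid=None) -> ca.FilterSpec:
    """A filter with one flat efficiency in both bounds (test helper)."""
    g = grid or ca.DEFAULT_GRID
    return ca.FilterSpec("new", "off", np.full(25, eta), np.full(25, eta), g)
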