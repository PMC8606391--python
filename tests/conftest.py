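import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from sleevesim import (
    BougieSpec,
    LayerMaterial,
    MaterialStack,
    PressureSchedule,
    build_sleeve,
    inflate,
    load_table1,
    load_table2,
)


@pytest.fixture(scope="session")
def stack():
    """A mid-range two-layer wall used across mechanics tests."""
    return MaterialStack(
        mucosa=LayerMaterial("mucosa", c_kpa=3.0, a_dimless=1.5),
        muscularis=LayerMaterial("muscularis", c_kpa=1.5, a_dimless=2.0),
    )


@pytest.fixture(scope="session")
def ring_27fr():
    """Reference radii of a uniform 27 Fr ring: lumen 4.5 mm, wall 1.0 + 1.5 mm."""
    return np.array([4.5, 5.5, 7.0])


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def table2():
    return load_table2()


@pytest.fixture(scope="session")
def table2_corrected():
    return load_table2(corrected=True)


@pytest.fixture(scope="session")
def table1_fit():
    """Joint calibration (materials + flare) against the packaged volume table.

    Session-scoped: the 8-start seeded fit takes about a minute and is
    shared between the calibration unit tests and the acceptance suite.
    """
    from sleevesim import fit_materials

    return fit_materials(load_table1(), fit_flare=True, seed=0, n_starts=8)


@pytest.fixture(scope="session")
def result_40fr(stack):
    """Full inflation of a default 40 Fr sleeve over the five-state schedule."""
    geom = build_sleeve(BougieSpec(40))
    return inflate(geom, stack, PressureSchedule.table_default())
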