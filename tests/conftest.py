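import numpy as np
import pytest

from xasmelt import exafs, synth, xanes


@pytest.fixture(scope="session")
def energy_grid():
    return synth.default_energy_grid()


@pytest.fixture(scope="session")
def bound_norm(energy_grid):
    return xanes.normalize(synth.make_reference_xanes(synth.BOUND_PROFILE, energy_grid,
                                                      label="bound"))


@pytest.fixture(scope="session")
def buffer_norm(energy_grid):
    return xanes.normalize(synth.make_reference_xanes(synth.BUFFER_PROFILE, energy_grid,
                                                      label="buffer"))


@pytest.fixture(scope="session")
def oxygen_table():
    return exafs.default_oxygen_table()


@pytest.fixture(scope="session")
def octahedral_site_model(oxygen_table):
    """Three-shell octahedral Co-O site: 4 O at 2.02, 1 O at 2.21, 1 O at 1.85 A,
    Fermi shift +3 eV."""
    return exafs.MetalSiteModel(
        absorber="Co", e0=7720.0, delta_ef=3.0, s02=0.9,
        shells=(
            exafs.ScatteringShell(4, 2.02),
            exafs.ScatteringShell(1, 2.21),
            exafs.ScatteringShell(1, 1.85),
        ),
    )


@pytest.fixture(scope="session")
def melt_grid():
    return np.arange(20.0, 95.25, 0.5)
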