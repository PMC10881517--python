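import numpy as np
import pytest

from tipbond.langevin import FilamentSystem, LangevinParams


@pytest.fixture(scope="session")
def default_lparams() -> LangevinParams:
    return LangevinParams()


@pytest.fixture
def free_filament():
    """A single untethered, unbonded filament of 35 beads."""
    n = 35
    return FilamentSystem(
        positions=np.column_stack([np.arange(float(n)), np.zeros(n)]),
        n_filaments=1,
        beads_per_filament=n,
        breakable_bonds=np.empty((0, 2), dtype=np.int64),
        bond_rest=np.empty(0),
        permanent_links=np.empty((0, 2), dtype=np.int64),
        link_rest=np.empty(0),
        link_stiffness=np.empty(0),
        tethered=np.zeros(n, dtype=bool),
        pull_force=np.zeros((n, 2)),
    )


@pytest.fixture
def rigid_single_bond():
    """Two tethered beads joined by one breakable bond under constant load.

    Both beads are frozen, so the bond force is constant and rupture
    times are exponential with the analytic catch-slip rate.
    """
    def make(load: float, params: LangevinParams) -> FilamentSystem:
        d = 1.0 + load / params.k_m
        return FilamentSystem(
            positions=np.array([[0.0, 0.0], [d, 0.0]]),
            n_filaments=2,
            beads_per_filament=1,
            breakable_bonds=np.array([[0, 1]]),
            bond_rest=np.ones(1),
            permanent_links=np.empty((0, 2), dtype=np.int64),
            link_rest=np.empty(0),
            link_stiffness=np.empty(0),
            tethered=np.ones(2, dtype=bool),
            pull_force=np.zeros((2, 2)),
        )
    return make
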