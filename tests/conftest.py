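"""Shared fixtures: small reusable simulation runs (session scope).

Everything is generated programmatically; no stored data. The expensive
runs are session-scoped so several tests can share one simulation.
"""

import numpy as np
import pytest

from fibroslab.lattice import LatticeGeometry
from fibroslab.model import FKParameters
from fibroslab.simulation import SimulationConfig, StimulusSpec, run_simulation


@pytest.fixture(scope="session")
def homogeneous_2d_run():
    """Corner-stimulus wave on a homogeneous 6x6 mm monolayer."""
    geom = LatticeGeometry(60, 60, 1)
    config = SimulationConfig(
        geom=geom,
        params=FKParameters(tau_d=0.25),
        t_end=400.0,
        stimulus=StimulusSpec(corner=(0, 0), radius=0.1),
        snapshot_every=1.0,
        early_stop=True,
    )
    return run_simulation(config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)
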