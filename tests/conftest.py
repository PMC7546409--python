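import math

import numpy as np
import pytest

from pallisteer.anatomy import PhantomSpec, build_pallidum_phantom
from pallisteer.axons import AxonTrajectory, MembraneParameters, _fiber_layout
from pallisteer.lead import build_lead, place_at_target, rasterize_lead
from pallisteer.sweep import SweepSpec, run_sweep


@pytest.fixture(scope="session")
def phantom():
    return build_pallidum_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def placed_lead(phantom):
    return place_at_target(build_lead(1.5), phantom)


@pytest.fixture(scope="session")
def rasterized_model(phantom, placed_lead):
    return rasterize_lead(placed_lead, phantom)


def straight_axon(
    diameter_um: float = 5.7,
    n_nodes: int = 41,
    direction=(1.0, 0.0, 0.0),
    center=(0.0, 0.0, 0.0),
    params: MembraneParameters = MembraneParameters(),
) -> AxonTrajectory:
    """A straight axon through ``center`` along ``direction``."""
    lay = _fiber_layout(diameter_um, n_nodes, params)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    pos = np.asarray(center, dtype=float) + lay["offsets_mm"][:, None] * d
    return AxonTrajectory(pos, lay["kinds"], diameter_um, 0, 0, 0)


def point_source_profile(axon: AxonTrajectory, source_mm, current_A=1e-3, sigma=0.2):
    """Extracellular potential (V) of a cathodal point source in uniform sigma."""
    r = np.linalg.norm(axon.compartment_positions_mm - np.asarray(source_mm), axis=1)
    r_m = np.maximum(r, 0.05) * 1e-3
    return -current_A / (4.0 * math.pi * sigma * r_m)


@pytest.fixture(scope="session")
def sweep_result(tmp_path_factory):
    """One full default sweep (19 cells); shared across acceptance tests."""
    out = tmp_path_factory.mktemp("sweep")
    df = run_sweep(SweepSpec(), out)
    return df, out
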