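import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from rhizobridge import parameterization as pz
from rhizobridge import root_simulator as rs
from rhizobridge.synthetic_fixtures import synth_roundtrip

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def two_order_params() -> dict[int, pz.RootTypeParameters]:
    """A plausible two-order adventitious-root parameter set (cm units)."""
    return {
        1: pz.RootTypeParameters(
            l_b=1.0, l_a=1.0, l_n=1.5, l_max=12.0, r=1.2, delta_x=0.5,
            sigma=10.0, theta=60.0, N=1, a_i=0.05, a_max=0.08, a_r=0.0006,
            root_order=1,
        ),
        2: pz.RootTypeParameters(
            l_b=0.4, l_a=0.4, l_n=0.8, l_max=3.0, r=0.5, delta_x=0.1,
            sigma=15.0, theta=70.0, N=2, a_i=0.02, a_max=0.04, a_r=0.0004,
            root_order=2,
        ),
    }


def straight_primary(
    r: float = 1.2,
    l_max: float = 12.0,
    radius_cm: float = 0.05,
    sigma: float = 0.0,
) -> dict[int, pz.RootTypeParameters]:
    """Single-order parameters for a lateral-free (l_n > l_max) primary."""
    return {
        1: pz.RootTypeParameters(
            l_b=1.0, l_a=1.0, l_n=100.0, l_max=l_max, r=r, delta_x=0.5,
            sigma=sigma, theta=0.0, N=1, a_i=radius_cm, a_max=radius_cm,
            a_r=0.0, root_order=1,
        )
    }


@pytest.fixture
def demo_params():
    return two_order_params()


@pytest.fixture(scope="session")
def observed_trait_table() -> pd.DataFrame:
    """Twelve synthetic 'observed' plants: simulate, render, re-extract."""
    params = two_order_params()
    rows = []
    for s in range(12):
        cfg = rs.SimulationConfig(
            total_days=21, dt=1.0, seed=100 + s, n_primary_roots=3
        )
        out = synth_roundtrip(params, cfg, scale=0.5)
        rows.append(out["traits"].as_series())
    df = pd.DataFrame(rows)
    df.index = [f"plant_{i}" for i in range(12)]
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(0)
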