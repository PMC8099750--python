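import numpy as np
import pytest

import beeland as bl


@pytest.fixture(scope="session")
def cfg():
    return bl.PipelineConfig()


@pytest.fixture(scope="session")
def const_r_kt(cfg):
    """Noise-free constant-r approach (r = 2.0 /s from 0.3 m)."""
    tr = bl.simulate_constant_r(
        bl.StrategyParams(strategy="constant_r", y0=0.3, V0=0.3, r_set=2.0))
    return bl.compute_state_variables(tr, cfg)


@pytest.fixture(scope="session")
def taudot_kt(cfg):
    """Noise-free constant-tau-dot approach (c = -0.87)."""
    tr = bl.simulate_constant_taudot(
        bl.StrategyParams(strategy="constant_taudot", y0=0.3, V0=0.3, c=-0.87))
    return bl.compute_state_variables(tr, cfg)


@pytest.fixture(scope="session")
def two_bout():
    """Two-bout hybrid track with set points 1.5 and 3.0 /s.

    The geometry is chosen so the tau-dot schedule maps bout 1's set point
    (1.5) onto exactly 3.0 for bout 2; returns (params, clean track,
    annotations).
    """
    from beeland.flight_simulator import _hybrid_geometry

    base = bl.StrategyParams(strategy="hybrid", y0=0.32, V0=0.3, r_set=1.5,
                             c=-0.5, n_bouts=2, bout_fraction=0.18,
                             transition_fraction=0.35)
    _, bouts, _ = _hybrid_geometry(base)
    mids = [(a - b) / np.log(a / b) for a, b in bouts]
    c = float(np.log(2.0) / np.log(mids[1] / mids[0]))
    params = bl.StrategyParams(strategy="hybrid", y0=0.32, V0=0.3, r_set=1.5,
                               c=c, n_bouts=2, bout_fraction=0.18,
                               transition_fraction=0.35)
    track, anns = bl.simulate_hybrid(params, "two_bout")
    return params, track, anns


@pytest.fixture(scope="session")
def small_dataset():
    """Small full-factorial synthetic dataset (24 tracks) plus truth table."""
    spec = bl.DatasetSpec(n_per_cell=2, seed=7)
    return bl.generate_dataset(spec)


@pytest.fixture(scope="session")
def small_kts(small_dataset, cfg):
    tracks, _ = small_dataset
    return [bl.compute_state_variables(t, cfg) for t in tracks]
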