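import numpy as np
import pytest

import replisim as rs


def engine(tau_d=120.0, *, dt=0.02, n_generations=30, seed=1, **kw):
    """Engine parameters for a short deterministic lineage."""
    kw.setdefault("trace_interval", -1.0)
    return rs.EngineParams.from_doubling_time(
        tau_d, dt=dt, n_generations=n_generations, seed=seed, **kw
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def ld_slow_record():
    """Deterministic LD lineage at doubling time 2 h (shared across tests)."""
    ep = engine(120.0, trace_interval=0.5)
    return rs.run_simulation(rs.make_model("ld"), ep)


@pytest.fixture(scope="session")
def lddr_slow_record():
    ep = engine(120.0, trace_interval=0.5)
    return rs.run_simulation(rs.make_model("lddr"), ep)
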