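import numpy as np
import pytest

from tcsleep.network import NetworkSpec, assemble


@pytest.fixture(scope="session")
def reduced_net():
    return assemble(NetworkSpec.reduced())


@pytest.fixture(scope="session")
def full_net():
    return assemble(NetworkSpec.default())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def reduced_runs():
    """Cache of short reduced-network runs shared across tests.

    Keyed by (stage, seed, duration); computed lazily so only the runs a
    test session actually needs are simulated.
    """
    from tcsleep.engine import SimConfig, run

    cache = {}

    def get(stage="awake", seed=1, duration_s=12.0, discard_s=4.0, **kw):
        key = (stage, seed, duration_s, discard_s, tuple(sorted(kw.items())))
        if key not in cache:
            net = assemble(NetworkSpec.reduced())
            cfg = SimConfig(duration_s=duration_s, seed=seed, schedule=stage,
                            discard_s=discard_s, **kw)
            cache[key] = run(cfg, net)
        return cache[key]

    return get
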