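import numpy as np
import pytest

from grnrob.topology import TopologyParams, sample_topology
from grnrob.dynamics import sample_params, sample_x0


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_instance(seed, f_dim=0.3, f_regint=2.0, f_act=0.5, n_prot=6):
    """One random (topology, params, x0) triple, deterministic in seed."""
    params = TopologyParams(n_prot, f_dim, f_regint, f_act)
    topo = sample_topology(params, seed)
    kp = sample_params(topo, seed + 10_000)
    x0 = sample_x0(topo, seed + 20_000)
    return topo, kp, x0
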