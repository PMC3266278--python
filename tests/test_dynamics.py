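"""ODE construction and integration against closed forms and a fixed-step
RK4 oracle."""

import numpy as np
import pytest

from grnrob.dynamics import (
    GAMMA_MONO,
    KineticParams,
    build_rhs,
    sample_params,
    sample_x0,
    simulate,
    species_order,
)
from grnrob.fixtures import make_toy_network
from grnrob.topology import SIGN_ACT, SIGN_REP, NetworkTopology, TopologyParams, sample_topology

from tests.oracles import naive_rhs, rk4_fixed
from tests.conftest import random_instance


def _one_gene_one_regulator(sign):
    """Gene 1 regulated by gene 0; gene 0 self-activated (so it is regulated)."""
    edges = frozenset({(0, 0, SIGN_ACT), (0, 1, sign)})
    topo = NetworkTopology(2, frozenset(), edges)
    params = KineticParams(
        b={(0, 0): 100.0, (0, 1): 300.0},
        K={(0, 0): 50.0, (0, 1): 200.0},
    )
    return topo, params


def test_hill_terms_at_reference_points():
    """Repression at x=0 gives the maximal rate b; activation at x=K gives b/2."""
    topo, params = _one_gene_one_regulator(SIGN_REP)
    f = build_rhs(topo, params)
    dx = f(0.0, np.array([0.0, 0.0]))
    assert dx[1] == pytest.approx(300.0)  # b * K/(K+0)

    topo, params = _one_gene_one_regulator(SIGN_ACT)
    f = build_rhs(topo, params)
    dx = f(0.0, np.array([200.0, 0.0]))  # x_0 == K_01
    assert dx[1] == pytest.approx(300.0 / 2)


def test_dimer_detailed_balance():
    """With gamma_dim = 0 the dimer equation vanishes exactly at
    x_ij = (k_on/k_off) x_i x_j."""
    topo, params, expected = make_toy_network("dimer_pair")
    f = build_rhs(topo, params)
    x_i, x_j = 3.0, 7.0
    x_ij = expected["equilibrium_ratio"] * x_i * x_j
    dx = f(0.0, np.array([x_i, x_j, x_ij]))
    assert dx[2] == pytest.approx(0.0, abs=1e-9)


def test_homodimer_consumes_two_monomers():
    d = (0, 0)
    topo = NetworkTopology(
        2, frozenset({d}),
        frozenset({(d, 0, SIGN_ACT), (d, 1, SIGN_ACT)}),
    )
    params = KineticParams(
        k_on=0.5, k_off=0.0001, gamma_mono=0.0001, gamma_dim=0.0001,
        b={(d, 0): 1e-6, (d, 1): 1e-6}, K={(d, 0): 50.0, (d, 1): 50.0},
    )
    f = build_rhs(topo, params)
    x = np.array([10.0, 0.0, 0.0])
    dx = f(0.0, x)
    # association flux k_on * x0^2 = 50; monomer 0 loses it twice
    assert dx[2] == pytest.approx(50.0, rel=1e-6)
    assert dx[0] == pytest.approx(-100.0, rel=1e-4)


def test_mismatched_params_rejected():
    topo, params = _one_gene_one_regulator(SIGN_ACT)
    bad = KineticParams(b=dict(params.b), K=dict(params.K))
    bad.b.pop((0, 1))
    with pytest.raises(ValueError):
        build_rhs(topo, bad)


def test_constitutive_activator_steady_state():
    """Production/decay balance: the toy reaches its closed-form state."""
    topo, params, expected = make_toy_network("const_act")
    x0 = np.array([50.0, 50.0])
    res = simulate(topo, params, x0)
    assert res.success and res.converged
    np.testing.assert_allclose(res.state, expected["steady_state"], rtol=1e-6)


def test_repression_cascade_steady_state():
    topo, params, expected = make_toy_network("repression_cascade")
    res = simulate(topo, params, np.array([10.0, 90.0]))
    assert res.success and res.converged
    np.testing.assert_allclose(res.state, expected["steady_state"], rtol=1e-6)


def test_pure_decay_limit():
    """A gene whose only input is saturated repression decays to ~0."""
    topo = NetworkTopology(
        2, frozenset(),
        frozenset({(0, 0, SIGN_ACT), (0, 1, SIGN_REP)}),
    )
    params = KineticParams(
        b={(0, 0): 2400.0, (0, 1): 100.0},
        K={(0, 0): 10.0, (0, 1): 0.01},  # tiny K: repression ~ fully off
    )
    res = simulate(topo, params, np.array([100.0, 100.0]))
    assert res.state[1] < 0.5  # residual leak only


def test_monomeric_state_has_no_dimer_block():
    topo, kp, x0 = random_instance(11, f_dim=0.0)
    res = simulate(topo, kp, x0)
    assert len(res.state) == topo.n_prot
    assert species_order(topo) == list(range(topo.n_prot))


def test_rhs_matches_naive_reference_exactly():
    """The compiled vector field equals a dict-based transcription of the
    model equations, including the monomeric (Hill-only) limit."""
    for seed, f_dim in [(0, 0.0), (1, 0.3), (2, 0.6)]:
        topo, kp, x0 = random_instance(seed, f_dim=f_dim)
        f = build_rhs(topo, kp)
        ref = naive_rhs(topo, kp)
        for s in range(3):
            x = np.abs(np.random.default_rng(s).normal(50, 20, size=len(x0)))
            np.testing.assert_allclose(f(0.0, x), ref(0.0, x), rtol=1e-12)


def test_adaptive_integrator_matches_rk4_oracle():
    """End state of the production integrator agrees with an independent
    fixed-small-step RK4 integration to 1e-4 relative."""
    topo, kp, x0 = random_instance(5, f_dim=0.3)
    kp.k_on = 0.01  # mildly stiff regime where fixed-step RK4 is stable
    t_final = 200.0
    res = simulate(topo, kp, x0, t_final=t_final)
    oracle = rk4_fixed(naive_rhs(topo, kp), x0, t_final, dt=0.005)
    np.testing.assert_allclose(res.state, oracle, rtol=1e-4, atol=1e-8)


def test_integration_scheme_independence():
    """LSODA and the adaptive explicit RK pair agree at the horizon."""
    topo, kp, x0 = random_instance(8, f_dim=0.3)
    kp.k_on = 0.01
    for key in kp.b:  # moderate expression levels keep RK45 affordable
        kp.b[key] = min(kp.b[key], 400.0)
    a = simulate(topo, kp, x0, method="lsoda")
    b = simulate(topo, kp, x0, method="rk45")
    assert a.success and b.success and a.converged
    np.testing.assert_allclose(a.state, b.state, rtol=1e-4, atol=1e-6)


def test_no_negative_concentrations_across_random_networks():
    """End states stay non-negative over a few hundred random networks."""
    count = 0
    for seed in range(300):
        f_dim = (0.0, 0.3, 0.6)[seed % 3]
        topo, kp, x0 = random_instance(seed, f_dim=f_dim,
                                       f_regint=(2.0, 4.0)[seed % 2])
        res = simulate(topo, kp, x0)
        if res.success:
            count += 1
            assert np.all(res.state >= 0.0)
    assert count >= 295  # failures are rare and flagged, not silent


def test_x0_sampling_contract(rng):
    topo = sample_topology(TopologyParams(6, 0.3, 2.0, 0.5), 1)
    x0 = sample_x0(topo, rng)
    assert x0.shape == (topo.n_prot + topo.n_dim,)
    assert np.all(x0[: topo.n_prot] >= 1.0) and np.all(x0[: topo.n_prot] <= 100.0)
    assert np.all(x0[topo.n_prot:] == 0.0)


def test_param_sampling_ranges(rng):
    topo = sample_topology(TopologyParams(6, 0.3, 4.0, 0.5), 2)
    kp = sample_params(topo, rng)
    assert kp.k_on in (1e-2, 1.0)
    assert all(40.0 <= v <= 2400.0 for v in kp.b.values())
    assert all(10.0 <= v <= 1000.0 for v in kp.K.values())
    assert set(kp.b) == {(r, g) for r, g, _ in topo.reg_edges}
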