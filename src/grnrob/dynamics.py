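"""ODE dynamics of dimerizing transcription-factor networks.

State vector: the ``n_prot`` monomer concentrations followed by one
concentration per dimer (sorted pair order), all in nM.

Monomer ``i``:

    dx_i/dt = sum over regulators k of gene i of Hill(x_k)
              - gamma_mono * x_i
              - sum over dimers containing i of (k_on * x_i * x_partner
                                                 - k_off * x_dimer)

with ``Hill(x) = b * x / (K + x)`` for activation and ``b * K / (K + x)``
for repression (cooperativity fixed at 1).  A homodimer consumes two copies
of its monomer, so its net association flux enters the monomer equation
twice.

Dimer ``(i, j)``:

    dx_ij/dt = k_on * x_i * x_j - k_off * x_ij - gamma_dim * x_ij

Dimer decay removes the complex without returning monomers; dissociation
does return them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.integrate import odeint, solve_ivp

from .topology import SIGN_ACT, NetworkTopology, Regulator

__all__ = [
    "KineticParams",
    "SimulationResult",
    "species_order",
    "sample_params",
    "sample_x0",
    "build_rhs",
    "simulate",
    "B_RANGE",
    "K_RANGE",
    "K_ON_CHOICES",
    "X0_RANGE",
    "T_FINAL",
]

log = logging.getLogger(__name__)

# kinetic sampling ranges used throughout the simulation study
B_RANGE = (40.0, 2400.0)  # Hill maximal rate, nM/min
K_RANGE = (10.0, 1000.0)  # Hill activation coefficient, nM
K_ON_CHOICES = (1e-2, 1.0)  # dimer association rate, 1/(nM min)
K_OFF = 0.01  # dimer dissociation rate, 1/min
GAMMA_MONO = 0.2  # monomer decay, 1/min
GAMMA_DIM = 0.01  # dimer decay, 1/min
X0_RANGE = (1.0, 100.0)  # initial monomer concentrations, nM
T_FINAL = 15000.0  # simulation horizon, min

#: steady-state criterion: max |dx/dt| / (|x| + 1 nM) at t_final, 1/min
CONV_TOL = 1e-6


@dataclass
class KineticParams:
    """Per-network kinetic parameters.

    ``b`` and ``K`` are keyed by ``(regulator, gene)`` and must cover exactly
    the regulatory edges of the topology they parameterize.
    """

    k_on: float = K_ON_CHOICES[0]
    k_off: float = K_OFF
    gamma_mono: float = GAMMA_MONO
    gamma_dim: float = GAMMA_DIM
    b: dict = field(default_factory=dict)
    K: dict = field(default_factory=dict)
    hill_n: int = 1

    def validate_against(self, topo: NetworkTopology) -> None:
        pairs = {(r, g) for r, g, _ in topo.reg_edges}
        if set(self.b) != pairs or set(self.K) != pairs:
            raise ValueError("b/K keys do not match the topology's edges")
        if min(self.k_on, self.k_off, self.gamma_mono) <= 0 or self.gamma_dim < 0:
            raise ValueError("rates must be positive")
        if self.hill_n != 1:
            raise ValueError("only cooperativity 1 is supported")


@dataclass
class SimulationResult:
    """End state of one integration."""

    state: np.ndarray  # concentrations, species_order() layout
    species: list  # monomer ids then dimer pairs
    t_final: float
    converged: bool
    success: bool
    method: str = "lsoda"

    def as_dict(self) -> dict:
        return dict(zip(map(str, self.species), self.state))


def species_order(topo: NetworkTopology) -> list:
    """Monomers ``0..n-1`` then dimers in sorted-pair order."""
    return list(range(topo.n_prot)) + sorted(topo.dimers)


def sample_params(topo: NetworkTopology, seed) -> KineticParams:
    """Draw Hill parameters uniformly and k_on from its two admitted values."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k_on = float(K_ON_CHOICES[int(rng.integers(len(K_ON_CHOICES)))])
    b, K = {}, {}
    for r, g, _ in sorted(
        topo.reg_edges,
        key=lambda e: (e[1], (e[0],) if isinstance(e[0], int) else tuple(e[0])),
    ):
        b[(r, g)] = float(rng.uniform(*B_RANGE))
        K[(r, g)] = float(rng.uniform(*K_RANGE))
    return KineticParams(k_on=k_on, b=b, K=K)


def sample_x0(topo: NetworkTopology, seed) -> np.ndarray:
    """Random initial state: monomers uniform in [1, 100] nM, dimers at 0."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x0 = np.zeros(topo.n_prot + topo.n_dim)
    x0[: topo.n_prot] = rng.uniform(*X0_RANGE, size=topo.n_prot)
    return x0


class _Compiled:
    """Index-array form of the network for fast RHS evaluation."""

    __slots__ = (
        "n_mono", "n_dim", "di", "dj", "reg_idx", "tgt", "act",
        "b", "K", "k_on", "k_off", "g_mono", "g_dim", "n",
    )

    def __init__(self, topo: NetworkTopology, params: KineticParams):
        params.validate_against(topo)
        nm = topo.n_prot
        dimers = sorted(topo.dimers)
        dim_pos = {d: nm + k for k, d in enumerate(dimers)}
        self.n_mono = nm
        self.n_dim = len(dimers)
        self.n = nm + self.n_dim
        self.di = np.array([d[0] for d in dimers], dtype=np.intp)
        self.dj = np.array([d[1] for d in dimers], dtype=np.intp)
        edges = topo.sorted_edges()
        reg_idx, tgt, act, b, K = [], [], [], [], []
        for r, g, s in edges:
            reg_idx.append(r if isinstance(r, int) else dim_pos[tuple(r)])
            tgt.append(g)
            act.append(s == SIGN_ACT)
            b.append(params.b[(r, g)])
            K.append(params.K[(r, g)])
        self.reg_idx = np.array(reg_idx, dtype=np.intp)
        self.tgt = np.array(tgt, dtype=np.intp)
        self.act = np.array(act, dtype=bool)
        self.b = np.array(b)
        self.K = np.array(K)
        self.k_on = params.k_on
        self.k_off = params.k_off
        self.g_mono = params.gamma_mono
        self.g_dim = params.gamma_dim

    def rhs(self, t, x):
        return _rhs_core(
            np.asarray(x), self.n_mono, self.di, self.dj, self.reg_idx,
            self.tgt, self.act, self.b, self.K,
            self.k_on, self.k_off, self.g_mono, self.g_dim,
        )


@njit(cache=True)
def _rhs_core(x, n_mono, di, dj, reg_idx, tgt, act, b, K, k_on, k_off, g_mono, g_dim):
    dx = np.zeros(x.shape[0])
    for e in range(reg_idx.shape[0]):
        xk = x[reg_idx[e]]
        if act[e]:
            dx[tgt[e]] += b[e] * xk / (K[e] + xk)
        else:
            dx[tgt[e]] += b[e] * K[e] / (K[e] + xk)
    for i in range(n_mono):
        dx[i] -= g_mono * x[i]
    for d in range(di.shape[0]):
        xd = x[n_mono + d]
        flux = k_on * x[di[d]] * x[dj[d]] - k_off * xd
        dx[n_mono + d] = flux - g_dim * xd
        dx[di[d]] -= flux
        dx[dj[d]] -= flux  # a homodimer consumes its monomer twice
    return dx


def build_rhs(topo: NetworkTopology, params: KineticParams):
    """Return the vector field ``f(t, x)`` for the parameterized network."""
    return _Compiled(topo, params).rhs


def simulate(
    topo: NetworkTopology,
    params: KineticParams,
    x0: np.ndarray,
    t_final: float = T_FINAL,
    method: str = "lsoda",
    rtol: float = 1e-10,
    atol: float = 1e-10,
    first_step: float = 0.01,
) -> SimulationResult:
    """Integrate to ``t_final`` and report the end state.

    ``method='lsoda'`` (default) uses the stiffness-switching LSODA solver;
    ``'rk45'`` uses the adaptive explicit Runge-Kutta pair, and any other
    value is passed to :func:`scipy.integrate.solve_ivp` verbatim.  All run
    at local error tolerance ``1e-10`` with initial step 0.01 min.  A failed
    or non-finite integration is returned with ``success=False`` so ensemble
    code can exclude and count it.
    """
    comp = _Compiled(topo, params)
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (comp.n,):
        raise ValueError(f"x0 must have length {comp.n}")
    try:
        if method == "lsoda":
            out, info = odeint(
                comp.rhs, x0, [0.0, t_final],
                tfirst=True, rtol=rtol, atol=atol, h0=first_step,
                mxstep=10_000_000, full_output=True,
            )
            end = out[-1]
            ok = info["message"] == "Integration successful."
        else:
            sol = solve_ivp(
                comp.rhs, (0.0, t_final), x0,
                method={"rk45": "RK45"}.get(method, method),
                rtol=rtol, atol=atol, first_step=first_step,
            )
            end = sol.y[:, -1]
            ok = bool(sol.success)
    except Exception:  # pragma: no cover - solver-internal failures
        log.warning("integration raised", exc_info=True)
        end = np.full(comp.n, np.nan)
        ok = False
    finite = bool(np.all(np.isfinite(end)))
    if finite:
        # roundoff-level negatives (>-1e-9 nM) are clamped; worse is a failure
        if np.any(end < -1e-9):
            ok = False
        end = np.maximum(end, 0.0)
    converged = False
    if finite:
        rate = np.abs(comp.rhs(t_final, end)) / (np.abs(end) + 1.0)
        converged = bool(np.max(rate) < CONV_TOL)
    return SimulationResult(
        state=end,
        species=species_order(topo),
        t_final=t_final,
        converged=converged,
        success=ok and finite,
        method=method,
    )
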