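"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles — plain
Python/numpy, no reuse of the package's compiled kernels — so that tests
compare two independent routes to the same quantity.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from grnrob.topology import SIGN_ACT, SIGN_REP


# ---------------------------------------------------------------------------
# dynamics: naive RHS + fixed-step classic RK4
# ---------------------------------------------------------------------------

def naive_rhs(topo, params):
    """Direct transcription of the model equations using dict lookups."""
    monomers = list(range(topo.n_prot))
    dimers = sorted(topo.dimers)
    index = {m: i for i, m in enumerate(monomers)}
    index.update({d: topo.n_prot + k for k, d in enumerate(dimers)})

    def f(t, x):
        dx = [0.0] * len(x)
        for r, g, s in topo.reg_edges:
            key = r if isinstance(r, int) else tuple(r)
            xk = x[index[key]]
            b, K = params.b[(r, g)], params.K[(r, g)]
            dx[index[g]] += b * xk / (K + xk) if s == SIGN_ACT else b * K / (K + xk)
        for m in monomers:
            dx[index[m]] -= params.gamma_mono * x[index[m]]
        for d in dimers:
            i, j = d
            xd = x[index[d]]
            flux = params.k_on * x[index[i]] * x[index[j]] - params.k_off * xd
            dx[index[d]] += flux - params.gamma_dim * xd
            dx[index[i]] -= flux
            dx[index[j]] -= flux
        return np.array(dx)

    return f


def rk4_fixed(f, x0, t_final, dt):
    """Classic fixed-step fourth-order Runge-Kutta."""
    x = np.asarray(x0, dtype=float).copy()
    n_steps = int(round(t_final / dt))
    t = 0.0
    for _ in range(n_steps):
        k1 = f(t, x)
        k2 = f(t + dt / 2, x + dt / 2 * k1)
        k3 = f(t + dt / 2, x + dt / 2 * k2)
        k4 = f(t + dt, x + dt * k3)
        x = x + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
    return x


# ---------------------------------------------------------------------------
# metrics: exhaustive permutation test
# ---------------------------------------------------------------------------

def exact_permutation_pvalue(a, b, d_small):
    """Enumerate every label assignment (feasible for small groups)."""
    vals = np.concatenate([a, b]) < d_small
    na = len(a)
    obs = abs(vals[:na].mean() - vals[na:].mean())
    count = total = 0
    for combo in itertools.combinations(range(len(vals)), na):
        mask = np.zeros(len(vals), dtype=bool)
        mask[list(combo)] = True
        stat = abs(vals[mask].mean() - vals[~mask].mean())
        count += stat >= obs - 1e-12
        total += 1
    return count / total


# ---------------------------------------------------------------------------
# network properties: split-graph recomputation without networkx
# ---------------------------------------------------------------------------

def split_edges(topo):
    """Split multigraph as an explicit edge list [(src, dst, sign), ...]."""
    out = []
    for r, g, s in sorted(
        topo.reg_edges, key=lambda e: (str(e[0]), e[1], e[2])
    ):
        units = (r,) if isinstance(r, int) else tuple(r)
        for u in units:
            out.append((u, g, s))
    return out


def autoregulation_counts(topo):
    n_act = sum(1 for u, v, s in split_edges(topo) if u == v and s == SIGN_ACT)
    n_rep = sum(1 for u, v, s in split_edges(topo) if u == v and s == SIGN_REP)
    return n_act, n_rep


def simple_path_signs(topo, src, dst):
    """DFS over the split edge list; returns the list of path signs (+1/-1),
    counting parallel branches as distinct paths."""
    edges = split_edges(topo)
    signs = []

    def walk(node, visited, parity):
        for u, v, s in edges:
            if u != node or v in visited:
                continue
            p = parity + (1 if s == SIGN_REP else 0)
            if v == dst:
                signs.append(1 if p % 2 == 0 else -1)
            else:
                walk(v, visited | {v}, p)

    walk(src, {src}, 0)
    return signs


def pair_entropy_bits(topo, src, dst):
    signs = simple_path_signs(topo, src, dst)
    if not signs:
        return 0.0
    p = signs.count(1) / len(signs)
    if p in (0.0, 1.0):
        return 0.0
    return -p * math.log2(p) - (1 - p) * math.log2(1 - p)


def jaccard(a, b):
    union = len(a | b)
    return len(a & b) / union if union else 0.0


# ---------------------------------------------------------------------------
# aggregation oracle (no pandas)
# ---------------------------------------------------------------------------

def bin_means(records, key_fields, value_field):
    """Group a list of dicts by a tuple of fields and average a value."""
    sums: dict = {}
    for rec in records:
        key = tuple(rec[f] for f in key_fields)
        s, n = sums.get(key, (0.0, 0))
        sums[key] = (s + rec[value_field], n + 1)
    return {k: s / n for k, (s, n) in sums.items()}
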