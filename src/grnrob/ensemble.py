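"""Ensemble experiments: wildtype vs mutant simulations at scale.

Two experiment designs are provided, mirroring the simulation study:

* **set2** — many random topologies per parameter cell (one kinetic draw
  each), used for the robustness comparisons: PPI vs regulatory mutations,
  monomeric vs dimeric networks, regulator sign classes and autoregulation
  trends.
* **set1** — few topologies but many kinetic parameter draws per topology,
  used for the compensatory-mutation scan (a high-impact primary PPI
  mutation followed by many random secondary mutations).

Every random choice derives from a master seed through counter-based
``SeedSequence`` spawn keys ``(cell, network, draw, role)``, so any cell or
network can be regenerated independently and reruns are bit-identical.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .dynamics import (
    T_FINAL,
    KineticParams,
    sample_params,
    sample_x0,
    simulate,
    species_order,
)
from .metrics import DmutThresholds, classify, d_mut, randomization_test
from .mutation import AppliedMutation, random_mutation
from .netprops import count_autoregulation, regulator_class
from .topology import (
    NetworkTopology,
    TopologyParams,
    enumerate_mutation_candidates,
    sample_topology,
)

__all__ = [
    "EnsembleConfig",
    "EnsembleResult",
    "set1_config",
    "set2_config",
    "run_ensemble",
    "RobustnessSummary",
    "summarize_robustness",
    "group_by_regulator_class",
    "compensatory_scan",
    "autoregulation_robustness",
    "load_config",
]

log = logging.getLogger(__name__)

# roles for the counter-based seed derivation
_R_TOPO, _R_PARAMS, _R_X0, _R_MUT_PPI, _R_MUT_REG, _R_SECONDARY = range(6)


def _rng(master_seed: int, cell: int, network: int, draw: int, role: int):
    ss = np.random.SeedSequence(master_seed, spawn_key=(cell, network, draw, role))
    return np.random.default_rng(ss)


@dataclass
class EnsembleConfig:
    """One ensemble experiment: a grid of topology cells plus replicate
    counts, horizon, thresholds and the master seed."""

    cells: list
    n_topologies: int = 500
    n_param_draws: int = 1
    t_final: float = T_FINAL
    thresholds: DmutThresholds = field(default_factory=DmutThresholds)
    master_seed: int = 0
    name: str = "ensemble"
    method: str = "lsoda"

    def __post_init__(self) -> None:
        if self.n_topologies < 1 or self.n_param_draws < 1:
            raise ValueError("replicate counts must be >= 1")


def set2_config(
    n_topologies: int = 500,
    f_act: float = 0.5,
    master_seed: int = 0,
    n_prot: int = 6,
    **kw,
) -> EnsembleConfig:
    """All six (F_dim x F_regint) cells at one activator fraction, one
    kinetic draw per topology.  The full-scale study used 25,000 topologies
    per cell; the default here is a desk-scale 500."""
    cells = [
        TopologyParams(n_prot, fd, fr, f_act)
        for fd, fr in itertools.product((0.0, 0.3, 0.6), (2.0, 4.0))
    ]
    return EnsembleConfig(
        cells, n_topologies=n_topologies, n_param_draws=1,
        master_seed=master_seed, name=f"set2-fact{f_act}", **kw,
    )


def set1_config(
    n_topologies: int = 20,
    n_param_draws: int = 1000,
    master_seed: int = 0,
    n_prot: int = 6,
    **kw,
) -> EnsembleConfig:
    """Dimeric cells at F_regint = 2 crossed with all activator fractions,
    many kinetic draws per topology (compensatory-mutation design)."""
    cells = [
        TopologyParams(n_prot, fd, 2.0, fa)
        for fd, fa in itertools.product((0.3, 0.6), (0.25, 0.5, 0.75))
    ]
    return EnsembleConfig(
        cells, n_topologies=n_topologies, n_param_draws=n_param_draws,
        master_seed=master_seed, name="set1", **kw,
    )


@dataclass
class EnsembleResult:
    """Row-per-mutation results plus an exclusion log."""

    runs: pd.DataFrame
    exclusions: pd.DataFrame
    config: EnsembleConfig

    def to_tsv(self, path) -> None:
        self.runs.to_csv(path, sep="\t", index=False)


_RUN_COLS = [
    "cell", "f_dim", "f_regint", "f_act", "network_id", "draw", "mtype",
    "d_mut", "classification", "regulator_class", "n_act_auto", "n_rep_auto",
    "n_dim", "wt_converged", "mut_converged",
]


def _aligned_mutant_state(wt_species, mut_result, species_map):
    pos = {s: i for i, s in enumerate(mut_result.species)}
    idx = [pos[species_map[s]] for s in wt_species]
    return mut_result.state[idx]


def run_ensemble(config: EnsembleConfig, progress: bool = False) -> EnsembleResult:
    """Run wildtype + mutant simulations for every network of the ensemble.

    Per network and kinetic draw: one wildtype simulation, one PPI-mutant
    simulation (dimeric networks only) and one regulatory-mutant simulation,
    each scored with D_mut against the wildtype.  Failed integrations and
    saturated candidate lists are excluded and logged.
    """
    rows, excl = [], []
    th = config.thresholds
    for ci, cell in enumerate(config.cells):
        for k in range(config.n_topologies):
            topo = sample_topology(cell, _rng(config.master_seed, ci, k, 0, _R_TOPO))
            cands = enumerate_mutation_candidates(topo)
            n_act_auto, n_rep_auto = count_autoregulation(topo)
            wt_species = species_order(topo)
            for draw in range(config.n_param_draws):
                kp = sample_params(topo, _rng(config.master_seed, ci, k, draw, _R_PARAMS))
                x0 = sample_x0(topo, _rng(config.master_seed, ci, k, draw, _R_X0))
                wt = simulate(topo, kp, x0, config.t_final, method=config.method)
                if not wt.success:
                    excl.append(dict(cell=ci, network_id=k, draw=draw,
                                     stage="wildtype", reason="integration_failed"))
                    continue
                mtypes = (["ppi"] if not topo.is_monomeric else []) + ["regulatory"]
                for mtype in mtypes:
                    role = _R_MUT_PPI if mtype == "ppi" else _R_MUT_REG
                    am = random_mutation(
                        topo, kp, mtype,
                        _rng(config.master_seed, ci, k, draw, role), cands,
                    )
                    if am is None:
                        excl.append(dict(cell=ci, network_id=k, draw=draw,
                                         stage=mtype, reason="no_candidate"))
                        continue
                    ms = simulate(am.topo, am.params, x0, config.t_final,
                                  method=config.method)
                    if not ms.success:
                        excl.append(dict(cell=ci, network_id=k, draw=draw,
                                         stage=mtype, reason="integration_failed"))
                        continue
                    c_mut = _aligned_mutant_state(wt_species, ms, am.species_map)
                    d = d_mut(wt.state, c_mut)
                    rows.append(dict(
                        cell=ci, f_dim=cell.f_dim, f_regint=cell.f_regint,
                        f_act=cell.f_act, network_id=k, draw=draw, mtype=mtype,
                        d_mut=d, classification=classify(d, th),
                        regulator_class=regulator_class(
                            topo, am.record.affected_regulator),
                        n_act_auto=n_act_auto, n_rep_auto=n_rep_auto,
                        n_dim=topo.n_dim,
                        wt_converged=wt.converged, mut_converged=ms.converged,
                    ))
        if progress:
            log.info("cell %d/%d (%s) done: %d rows, %d exclusions",
                     ci + 1, len(config.cells), cell, len(rows), len(excl))
    runs = pd.DataFrame(rows, columns=_RUN_COLS)
    exclusions = pd.DataFrame(
        excl, columns=["cell", "network_id", "draw", "stage", "reason"])
    return EnsembleResult(runs, exclusions, config)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass
class RobustnessSummary:
    """Percent-robust table plus randomization p-values."""

    table: pd.DataFrame  # per (cell, mtype): n, pct_robust
    p_ppi_vs_reg: pd.DataFrame  # per dimeric cell
    p_mono_vs_dim: pd.DataFrame  # per (f_regint, dimeric f_dim), regulatory rows


def summarize_robustness(
    result: EnsembleResult,
    th: DmutThresholds | None = None,
    n_perm: int = 1000,
    rng=None,
) -> RobustnessSummary:
    """Fraction of networks with D_mut < D_small per cell and mutation type,
    with randomization tests for PPI vs regulatory mutations within each
    dimeric cell and for monomeric vs dimeric cells at matched F_regint."""
    th = th or result.config.thresholds
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    df = result.runs
    recs = []
    for (cell, fd, fr, fa, mtype), grp in df.groupby(
        ["cell", "f_dim", "f_regint", "f_act", "mtype"]
    ):
        recs.append(dict(
            cell=cell, f_dim=fd, f_regint=fr, f_act=fa, mtype=mtype,
            n=len(grp), pct_robust=100.0 * (grp.d_mut < th.d_small).mean(),
            mean_d_mut=grp.d_mut.mean(),
            pct_converged=100.0 * grp.mut_converged.mean(),
        ))
    table = pd.DataFrame(recs)

    pvr = []
    for cell, grp in df[df.f_dim > 0].groupby("cell"):
        a = grp.loc[grp.mtype == "ppi", "d_mut"].to_numpy()
        b = grp.loc[grp.mtype == "regulatory", "d_mut"].to_numpy()
        if a.size and b.size:
            p = randomization_test(a, b, th, n_perm=n_perm, rng=rng)
            c = grp.iloc[0]
            pvr.append(dict(cell=cell, f_dim=c.f_dim, f_regint=c.f_regint,
                            f_act=c.f_act, p=p))
    p_ppi_vs_reg = pd.DataFrame(pvr, columns=["cell", "f_dim", "f_regint", "f_act", "p"])

    pmd = []
    reg = df[df.mtype == "regulatory"]
    for fr in sorted(reg.f_regint.unique()):
        mono = reg[(reg.f_regint == fr) & (reg.f_dim == 0)]
        for fd in sorted(reg.loc[reg.f_dim > 0, "f_dim"].unique()):
            dim = reg[(reg.f_regint == fr) & (reg.f_dim == fd)]
            if len(mono) and len(dim):
                p = randomization_test(
                    mono.d_mut.to_numpy(), dim.d_mut.to_numpy(), th,
                    n_perm=n_perm, rng=rng,
                )
                pmd.append(dict(f_regint=fr, f_dim=fd, p=p))
    p_mono_vs_dim = pd.DataFrame(pmd, columns=["f_regint", "f_dim", "p"])
    return RobustnessSummary(table, p_ppi_vs_reg, p_mono_vs_dim)


def group_by_regulator_class(result: EnsembleResult) -> dict:
    """Mean +/- SD of D_mut by the affected regulator's sign class.

    Returns ``per_cell`` (one row per cell and class), ``ensemble_averaged``
    (per-cell means pooled with equal weight, the convention behind the
    study's headline repressor/activator numbers) and ``pooled`` (all rows
    weighted equally) tables.
    """
    df = result.runs
    per_cell = (
        df.groupby(["cell", "f_dim", "f_regint", "f_act", "regulator_class"])
        .d_mut.agg(n="size", mean="mean", sd="std")
        .reset_index()
    )
    ens = (
        per_cell.groupby("regulator_class")
        .agg(n_cells=("cell", "size"), mean=("mean", "mean"), sd=("sd", "mean"))
        .reset_index()
    )
    pooled = (
        df.groupby("regulator_class")
        .d_mut.agg(n="size", mean="mean", sd="std")
        .reset_index()
    )
    return {"per_cell": per_cell, "ensemble_averaged": ens, "pooled": pooled}


def autoregulation_robustness(result: EnsembleResult) -> dict:
    """Mean D_mut binned by autoregulation counts, plus the Spearman trend of
    D_mut against the total number of autoregulatory interactions for each
    mutation type (opposite signs are the expected pattern)."""
    df = result.runs.copy()
    df["n_auto"] = df.n_act_auto + df.n_rep_auto
    table = (
        df.groupby(["n_act_auto", "n_rep_auto", "mtype"])
        .d_mut.agg(n="size", mean="mean")
        .reset_index()
    )
    table["sparse"] = table.n < 10
    trend = {}
    for mtype, grp in df.groupby("mtype"):
        rho, p = stats.spearmanr(grp.n_auto, grp.d_mut)
        trend[mtype] = {"rho": float(rho), "p": float(p)}
    return {"table": table, "trend": trend}


# ---------------------------------------------------------------------------
# compensatory mutations
# ---------------------------------------------------------------------------

def _apply_secondary(topo, params, mtype, which):
    from .mutation import mutate_ppi, mutate_regulatory

    if mtype == "ppi":
        return mutate_ppi(topo, params, which)
    return mutate_regulatory(topo, params, which)


def compensatory_scan(
    f_acts=(0.25, 0.5, 0.75),
    f_dims=(0.3, 0.6),
    f_regint: float = 2.0,
    n_topologies: int = 20,
    n_param_draws: int = 100,
    n_secondary: int = 200,
    sec_types=("ppi", "regulatory"),
    th: DmutThresholds = DmutThresholds(),
    t_final: float = T_FINAL,
    master_seed: int = 0,
    max_primaries: int | None = None,
    method: str = "lsoda",
    n_prot: int = 6,
) -> dict:
    """Scan for compensatory second mutations after a high-impact primary.

    For every (topology, kinetic draw) a wildtype and a random primary PPI
    mutant are simulated.  Primaries with ``D_mut > d_large`` enter the scan:
    ``n_secondary`` random secondary mutations per type are drawn (with
    replacement from the mutant's candidate list; each distinct candidate is
    simulated once) and a secondary counts as compensatory when the double
    mutant's divergence from the *original wildtype* falls below
    ``d_small``.  ``max_primaries`` caps, per activator fraction, how many
    high-impact primaries are scanned (a deterministic subsample).

    Returns ``rows`` (one row per primary x secondary type with the rescue
    percentage) and ``summary`` (mean +/- SD rescue percentage per
    (f_act, secondary type)).
    """
    rows = []
    cells = [
        (fa, fd) for fa in f_acts for fd in f_dims
    ]
    primaries = []  # (f_act, f_dim, ci, k, draw, topo, am, wt_state, wt_species, d1)
    for ci, (fa, fd) in enumerate(cells):
        cell = TopologyParams(n_prot, fd, f_regint, fa)
        for k in range(n_topologies):
            topo = sample_topology(cell, _rng(master_seed, ci, k, 0, _R_TOPO))
            cands = enumerate_mutation_candidates(topo)
            if cands.ppi_saturated:
                continue
            wt_species = species_order(topo)
            for draw in range(n_param_draws):
                kp = sample_params(topo, _rng(master_seed, ci, k, draw, _R_PARAMS))
                x0 = sample_x0(topo, _rng(master_seed, ci, k, draw, _R_X0))
                wt = simulate(topo, kp, x0, t_final, method=method)
                if not wt.success:
                    continue
                am = random_mutation(
                    topo, kp, "ppi",
                    _rng(master_seed, ci, k, draw, _R_MUT_PPI), cands,
                )
                if am is None:
                    continue
                ms = simulate(am.topo, am.params, x0, t_final, method=method)
                if not ms.success:
                    continue
                c1 = _aligned_mutant_state(wt_species, ms, am.species_map)
                d1 = d_mut(wt.state, c1)
                if d1 > th.d_large:
                    primaries.append(
                        (fa, fd, ci, k, draw, am, wt.state, wt_species, x0, d1)
                    )
    # deterministic per-f_act subsample of the high-impact primaries
    by_fact: dict = {}
    for prim in primaries:
        by_fact.setdefault(prim[0], []).append(prim)
    for fa, prims in by_fact.items():
        if max_primaries is not None and len(prims) > max_primaries:
            sel = np.random.default_rng(
                np.random.SeedSequence(master_seed, spawn_key=(_R_SECONDARY,))
            ).choice(len(prims), size=max_primaries, replace=False)
            prims = [prims[i] for i in sorted(sel)]
        for fa_, fd, ci, k, draw, am, wt_state, wt_species, x0, d1 in prims:
            sec_cands = enumerate_mutation_candidates(am.topo)
            rng_sec = _rng(master_seed, ci, k, draw, _R_SECONDARY)
            for sec_type in sec_types:
                pool = (
                    sec_cands.ppi_swaps if sec_type == "ppi" else sec_cands.reg_swaps
                )
                if not pool:
                    continue
                picks = rng_sec.integers(len(pool), size=n_secondary)
                comp_by_cand: dict = {}
                n_comp = 0
                for idx in picks:
                    idx = int(idx)
                    if idx not in comp_by_cand:
                        am2 = _apply_secondary(
                            am.topo, am.params, sec_type, pool[idx])
                        ms2 = simulate(am2.topo, am2.params, x0, t_final,
                                       method=method)
                        if not ms2.success:
                            comp_by_cand[idx] = None
                        else:
                            total_map = {
                                s: am2.species_map[am.species_map[s]]
                                for s in wt_species
                            }
                            c2 = _aligned_mutant_state(wt_species, ms2, total_map)
                            comp_by_cand[idx] = d_mut(wt_state, c2) < th.d_small
                    if comp_by_cand[idx]:
                        n_comp += 1
                n_valid = sum(
                    1 for idx in picks if comp_by_cand[int(idx)] is not None
                )
                if n_valid == 0:
                    continue
                rows.append(dict(
                    f_act=fa_, f_dim=fd, network_id=k, draw=draw,
                    sec_type=sec_type, d_primary=d1,
                    n_secondary=int(n_valid),
                    n_unique_candidates=len(pool),
                    pct_compensatory=100.0 * n_comp / n_valid,
                ))
    rows_df = pd.DataFrame(rows, columns=[
        "f_act", "f_dim", "network_id", "draw", "sec_type", "d_primary",
        "n_secondary", "n_unique_candidates", "pct_compensatory",
    ])
    summary = (
        rows_df.groupby(["f_act", "sec_type"])
        .pct_compensatory.agg(n_primaries="size", mean="mean", sd="std")
        .reset_index()
        if len(rows_df)
        else pd.DataFrame(
            columns=["f_act", "sec_type", "n_primaries", "mean", "sd"])
    )
    return {"rows": rows_df, "summary": summary}


# ---------------------------------------------------------------------------
# YAML run configuration
# ---------------------------------------------------------------------------

def load_config(path) -> EnsembleConfig:
    """Build an :class:`EnsembleConfig` from a YAML file.

    Expected keys: ``cells`` (list of {n_prot, f_dim, f_regint, f_act}) or a
    ``preset`` (``set1``/``set2`` with its keyword arguments), plus any of
    ``n_topologies``, ``n_param_draws``, ``t_final``, ``master_seed``,
    ``name``, ``method`` and ``thresholds: {d_small, d_large}``.
    """
    with open(path) as fh:
        obj = yaml.safe_load(fh) or {}
    th = DmutThresholds(**obj.pop("thresholds", {}))
    preset = obj.pop("preset", None)
    if preset == "set2":
        cfg = set2_config(**{
            k: obj.pop(k) for k in ("n_topologies", "f_act", "master_seed", "n_prot")
            if k in obj
        })
    elif preset == "set1":
        cfg = set1_config(**{
            k: obj.pop(k)
            for k in ("n_topologies", "n_param_draws", "master_seed", "n_prot")
            if k in obj
        })
    else:
        cells = [TopologyParams(**c) for c in obj.pop("cells")]
        cfg = EnsembleConfig(cells)
    allowed = {"n_topologies", "n_param_draws", "t_final", "master_seed",
               "name", "method"}
    unknown = set(obj) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return replace(cfg, thresholds=th, **obj)
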