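"""Ensemble orchestration: accounting, determinism, summaries, config IO."""

import numpy as np
import pandas as pd
import pytest

from grnrob.ensemble import (
    EnsembleConfig,
    autoregulation_robustness,
    compensatory_scan,
    group_by_regulator_class,
    load_config,
    run_ensemble,
    set1_config,
    set2_config,
    summarize_robustness,
)
from grnrob.metrics import DmutThresholds
from grnrob.topology import TopologyParams

from tests import oracles


@pytest.fixture(scope="module")
def tiny_result():
    """Small but real ensemble shared by the tests in this module."""
    cfg = set2_config(n_topologies=12, master_seed=5)
    return run_ensemble(cfg)


def test_row_accounting(tiny_result):
    """Every (network, mutation type) appears exactly once in the rows or in
    the exclusion log."""
    cfg = tiny_result.config
    runs, excl = tiny_result.runs, tiny_result.exclusions
    for ci, cell in enumerate(cfg.cells):
        n_types = 1 if cell.f_dim == 0 else 2
        got = len(runs[runs.cell == ci])
        # a wildtype failure removes all of that network's mutant rows
        wt_fail = len(excl[(excl.cell == ci) & (excl.stage == "wildtype")])
        other = len(excl[(excl.cell == ci) & (excl.stage != "wildtype")])
        assert got + wt_fail * n_types + other == cfg.n_topologies * n_types


def test_monomeric_cells_have_no_ppi_rows(tiny_result):
    runs = tiny_result.runs
    mono = runs[runs.f_dim == 0]
    assert set(mono.mtype) == {"regulatory"}
    dimeric = runs[runs.f_dim > 0]
    assert set(dimeric.mtype) == {"ppi", "regulatory"}


def test_determinism_bit_identical_rerun(tiny_result):
    cfg = set2_config(n_topologies=12, master_seed=5)
    again = run_ensemble(cfg)
    pd.testing.assert_frame_equal(tiny_result.runs, again.runs)
    pd.testing.assert_frame_equal(tiny_result.exclusions, again.exclusions)


def test_different_seed_changes_rows():
    cfg = set2_config(n_topologies=3, master_seed=6)
    a = run_ensemble(cfg)
    b = run_ensemble(set2_config(n_topologies=3, master_seed=7))
    assert not a.runs.d_mut.equals(b.runs.d_mut)


def test_summary_contract(tiny_result):
    s = summarize_robustness(tiny_result, n_perm=200,
                             rng=np.random.default_rng(0))
    assert ((s.table.pct_robust >= 0) & (s.table.pct_robust <= 100)).all()
    # one row per (cell, mtype) present in the runs
    assert len(s.table) == tiny_result.runs.groupby(["cell", "mtype"]).ngroups
    assert ((s.p_ppi_vs_reg.p >= 0) & (s.p_ppi_vs_reg.p <= 1)).all()
    assert len(s.p_mono_vs_dim) == 4  # 2 F_regint x 2 dimeric F_dim


def test_all_zero_dmut_would_be_fully_robust(tiny_result):
    forced = tiny_result.runs.copy()
    forced["d_mut"] = 0.0
    res = type(tiny_result)(forced, tiny_result.exclusions, tiny_result.config)
    s = summarize_robustness(res, n_perm=10, rng=np.random.default_rng(0))
    assert (s.table.pct_robust == 100.0).all()


def test_regulator_class_grouping_matches_bruteforce(tiny_result):
    out = group_by_regulator_class(tiny_result)
    records = tiny_result.runs.to_dict("records")
    ref = oracles.bin_means(records, ("regulator_class",), "d_mut")
    pooled = dict(zip(out["pooled"].regulator_class, out["pooled"]["mean"]))
    for (cls,), val in ref.items():
        assert pooled[cls] == pytest.approx(val)


def test_autoregulation_binning_matches_bruteforce(tiny_result):
    out = autoregulation_robustness(tiny_result)
    records = tiny_result.runs.to_dict("records")
    ref = oracles.bin_means(
        records, ("n_act_auto", "n_rep_auto", "mtype"), "d_mut")
    for _, row in out["table"].iterrows():
        key = (row.n_act_auto, row.n_rep_auto, row.mtype)
        assert row["mean"] == pytest.approx(ref[key])
    assert set(out["trend"]) == {"ppi", "regulatory"}


def test_compensatory_scan_smoke():
    """A perfect revert counts as compensatory; structure of the output."""
    res = compensatory_scan(
        f_acts=(0.75,), f_dims=(0.3,), n_topologies=4, n_param_draws=4,
        n_secondary=30, sec_types=("ppi", "regulatory"), master_seed=2,
    )
    rows = res["rows"]
    if len(rows):  # high-impact primaries found at this tiny scale
        assert ((rows.pct_compensatory >= 0) & (rows.pct_compensatory <= 100)).all()
        assert (rows.d_primary > 1.0).all()
        # the exact-revert secondary exists in every PPI pool, so a PPI
        # secondary scan can never be all-zero across many draws
        ppi = rows[rows.sec_type == "ppi"]
        if len(ppi) >= 3:
            assert ppi.pct_compensatory.max() > 0


def test_config_presets():
    s1 = set1_config()
    assert len(s1.cells) == 6 and s1.n_param_draws == 1000
    assert all(c.f_regint == 2.0 for c in s1.cells)
    s2 = set2_config(n_topologies=100)
    assert len(s2.cells) == 6
    assert {(c.f_dim, c.f_regint) for c in s2.cells} == {
        (fd, fr) for fd in (0.0, 0.3, 0.6) for fr in (2.0, 4.0)
    }
    with pytest.raises(ValueError):
        EnsembleConfig([TopologyParams()], n_topologies=0)


def test_load_config_yaml(tmp_path):
    p = tmp_path / "run.yaml"
    p.write_text(
        "preset: set2\nn_topologies: 7\nf_act: 0.25\nmaster_seed: 3\n"
        "thresholds: {d_small: 0.3, d_large: 1.2}\n"
    )
    cfg = load_config(p)
    assert cfg.n_topologies == 7
    assert cfg.thresholds == DmutThresholds(0.3, 1.2)
    assert all(c.f_act == 0.25 for c in cfg.cells)
    p2 = tmp_path / "bad.yaml"
    p2.write_text("preset: set2\nbogus: 1\n")
    with pytest.raises(ValueError):
        load_config(p2)
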