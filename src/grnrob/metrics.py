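"""The D_mut divergence metric, effect classification and the randomization test.

``D_mut`` compares the end-state concentration vector of a mutated network
with its wildtype over all species (monomers plus dimers):

    D_mut = (1/n) * sum_i 2 |C_wt,i - C_mut,i| / (C_wt,i + C_mut,i)

i.e. the mean symmetric relative difference per species.  It is bounded in
[0, 2], symmetric in its arguments and invariant under multiplying both
vectors by any positive constant (so multiplicative normalization of
expression data does not affect it, while a log transform does).  Species
absent in both states (zero denominator) contribute 0.

Effects are classified against two calibrated cutoffs, by default
``D_small = 0.2`` and ``D_large = 1.0`` (see :mod:`grnrob.expression_dmut`
for the calibration procedure).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DmutThresholds",
    "d_mut",
    "d_mut_components",
    "classify",
    "direct_indirect_split",
    "randomization_test",
]

SMALL, INTERMEDIATE, LARGE = "small", "intermediate", "large"


@dataclass(frozen=True)
class DmutThresholds:
    """Effect-size cutoffs: below ``d_small`` an effect counts as small
    (robust outcome), above ``d_large`` as large."""

    d_small: float = 0.2
    d_large: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.d_small < self.d_large:
            raise ValueError("need 0 < d_small < d_large")


def _check_pair(c_wt, c_mut):
    a = np.asarray(c_wt, dtype=float)
    b = np.asarray(c_mut, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("concentration vectors must be 1-D and equal length")
    if a.size == 0:
        raise ValueError("empty concentration vectors")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("concentrations must be non-negative")
    return a, b


def d_mut_components(c_wt, c_mut) -> np.ndarray:
    """Per-species contributions ``2|a-b|/(a+b)`` (0 where both are 0)."""
    a, b = _check_pair(c_wt, c_mut)
    denom = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        comp = np.where(denom > 0, 2.0 * np.abs(a - b) / denom, 0.0)
    return comp


def d_mut(c_wt, c_mut) -> float:
    """Mean symmetric relative difference between two end states."""
    return float(np.mean(d_mut_components(c_wt, c_mut)))


def classify(d: float, th: DmutThresholds = DmutThresholds()) -> str:
    """Map a divergence value to ``small`` / ``intermediate`` / ``large``."""
    if d < 0:
        raise ValueError("d must be >= 0")
    if d < th.d_small:
        return SMALL
    if d > th.d_large:
        return LARGE
    return INTERMEDIATE


def direct_indirect_split(c_wt, c_mut, target_gene: int) -> tuple:
    """Split the divergence into the mutated edge's direct effect and the
    network-mediated indirect effect.

    Returns ``(direct, indirect)`` where ``direct`` is the per-species
    D_mut contribution of the mutation's target gene and ``indirect`` is the
    mean contribution over all other species.  The total recombines as
    ``(direct + (n-1)*indirect) / n``.
    """
    comp = d_mut_components(c_wt, c_mut)
    if not 0 <= target_gene < comp.size:
        raise IndexError("target_gene out of range")
    direct = float(comp[target_gene])
    others = np.delete(comp, target_gene)
    indirect = float(others.mean()) if others.size else 0.0
    return direct, indirect


def randomization_test(
    d_group_a,
    d_group_b,
    th: DmutThresholds = DmutThresholds(),
    n_perm: int = 1000,
    rng=None,
) -> float:
    """Permutation test for a difference in robustness between two groups.

    The statistic is the absolute difference between the two groups in the
    fraction of values below ``d_small``.  Group labels are reshuffled
    ``n_perm`` times; the p-value is the fraction of shuffles whose statistic
    is at least as large as the observed one (no +1 smoothing).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a = np.asarray(d_group_a, dtype=float)
    b = np.asarray(d_group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    small = np.concatenate([a < th.d_small, b < th.d_small]).astype(float)
    na = a.size

    def stat(vec):
        return abs(vec[:na].mean() - vec[na:].mean())

    obs = stat(small)
    count = 0
    for _ in range(n_perm):
        if stat(rng.permutation(small)) >= obs - 1e-12:
            count += 1
    return count / n_perm
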