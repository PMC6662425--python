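"""Multilocus linkage disequilibrium: the standardized index of association.

``rbar_d`` measures covariance of allelic state across loci, standardized so
it is comparable across locus numbers and bounded above by 1. Per-locus
pairwise distance between individuals ``i`` and ``j`` is
``|dosage_i - dosage_j| / 2``; with

* ``V_O`` the variance over individual pairs of the distance summed over loci,
* ``V_E = sum_j var_j`` the sum of per-locus distance variances,

the statistics are ``Ia = V_O / V_E - 1`` and

``rbar_d = (V_O - V_E) / (2 * sum_{j<k} sqrt(var_j * var_k))``.

Elevated values indicate non-random association of loci, as produced by
selfing or clonality. Significance is assessed by independently permuting
each locus's calls among individuals (which preserves every per-locus
distance distribution and therefore ``V_E``), upper tail,
``p = (#{perm >= obs} + 1) / (n_perm + 1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .matrix import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class IndexOfAssociation:
    ia: float
    rbar_d: float
    v_observed: float
    v_expected: float
    p_value: float
    n_permutations: int
    seed: int | None
    n_samples: int
    n_loci: int


def _pair_distance_sum(calls: np.ndarray, has_missing: bool) -> np.ndarray:
    """Matrix of summed-over-loci per-locus distances, missing pairs rescaled.

    Uses the identity ``|d| = d^2 - 2 * [|d| = 2]`` for dosage differences
    ``d in {0, +-1, +-2}`` so the whole computation is a few matmuls.
    """
    X = calls.astype(np.float64)
    if not has_missing:
        g2 = (X ** 2).sum(axis=1)
        sq = g2[:, None] + g2[None, :] - 2.0 * (X @ X.T)
        a0 = (calls == 0).astype(np.float64)
        a2 = (calls == 2).astype(np.float64)
        far = a0 @ a2.T
        total = sq - 2.0 * (far + far.T)
        return total / 2.0
    M = (calls != MISSING).astype(np.float64)
    Xm = np.where(calls == MISSING, 0.0, X)
    sq_part = ((Xm ** 2) * M) @ M.T
    sq = sq_part + sq_part.T - 2.0 * (Xm @ Xm.T)
    a0 = ((calls == 0)).astype(np.float64)
    a2 = ((calls == 2)).astype(np.float64)
    far = a0 @ a2.T
    total = (sq - 2.0 * (far + far.T)) / 2.0
    l_pair = M @ M.T
    L = calls.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(l_pair > 0, total * (L / l_pair), np.nan)


def _per_locus_distance_variance(calls: np.ndarray) -> np.ndarray:
    """Variance (over complete pairs) of |dosage_i - dosage_j| / 2 per locus,
    from genotype counts in closed form."""
    n0 = ((calls == 0)).sum(axis=0).astype(float)
    n1 = ((calls == 1)).sum(axis=0).astype(float)
    n2 = ((calls == 2)).sum(axis=0).astype(float)
    m = n0 + n1 + n2
    n_pairs = m * (m - 1) / 2.0
    c_half = n1 * (n0 + n2)   # pairs at distance 1/2
    c_one = n0 * n2           # pairs at distance 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = (0.5 * c_half + c_one) / n_pairs
        mean_sq = (0.25 * c_half + c_one) / n_pairs
        var = mean_sq - mean ** 2
    return np.where(n_pairs > 0, var, np.nan)


def rbar_d(
    g: GenotypeMatrix,
    n_permutations: int = 999,
    seed: int | None = None,
    groups=None,
) -> IndexOfAssociation | dict:
    """Standardized index of association with a permutation test.

    With ``groups`` (per-sample labels) the statistic is computed within each
    group separately and a dict of results is returned; by default all
    samples are analysed jointly.
    """
    if groups is not None:
        labels = np.asarray(groups, dtype=object)
        out = {}
        for grp in sorted(set(labels.tolist()), key=str):
            sub = g.take_samples(labels == grp)
            out[grp] = rbar_d(sub, n_permutations=n_permutations, seed=seed)
        return out

    if g.n_samples < 3:
        raise ValueError("rbar_d requires at least 3 samples")
    called = g.called
    n_called = called.sum(axis=0)
    poly = np.zeros(g.n_loci, dtype=bool)
    ok = n_called > 0
    mn = np.where(called, g.calls, 3).min(axis=0)
    mx = np.where(called, g.calls, -1).max(axis=0)
    poly[ok] = mn[ok] != mx[ok]
    if poly.sum() < 2:
        raise ValueError("rbar_d requires at least 2 polymorphic loci")
    calls = g.calls[:, poly]
    has_missing = bool((calls == MISSING).any())

    var_j = _per_locus_distance_variance(calls)
    var_j = np.where(np.isnan(var_j), 0.0, var_j)
    v_expected = float(var_j.sum())
    sqrt_v = np.sqrt(var_j)
    denom = float(sqrt_v.sum() ** 2 - var_j.sum())  # 2 * sum_{j<k} sqrt(vj vk)
    if denom <= 0:
        raise ValueError("degenerate data: zero pairwise variance denominator")

    iu = np.triu_indices(calls.shape[0], 1)

    def observed_variance(c: np.ndarray) -> float:
        total = _pair_distance_sum(c, has_missing)[iu]
        keep = ~np.isnan(total)
        if not keep.all():
            logger.warning("dropping %d sample pair(s) with no shared called loci",
                           int((~keep).sum()))
            total = total[keep]
        return float(np.var(total))

    v_obs = observed_variance(calls)
    stat = (v_obs - v_expected) / denom
    ia = v_obs / v_expected - 1.0 if v_expected > 0 else np.nan

    p = np.nan
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        n, L = calls.shape
        ge = 0
        for _ in range(n_permutations):
            order = np.argsort(rng.random((n, L)), axis=0)
            shuffled = calls[order, np.arange(L)[None, :]]
            v_perm = observed_variance(shuffled)
            if (v_perm - v_expected) / denom >= stat:
                ge += 1
        p = (ge + 1) / (n_permutations + 1)

    return IndexOfAssociation(
        ia=ia, rbar_d=stat, v_observed=v_obs, v_expected=v_expected,
        p_value=p, n_permutations=n_permutations, seed=seed,
        n_samples=g.n_samples, n_loci=int(poly.sum()),
    )
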