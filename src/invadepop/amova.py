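"""Hierarchical analysis of molecular variance (AMOVA).

Partitions genetic variance into within-locality, between-locality
(within-region) and between-region components from squared Euclidean
distances on 0/1/2 dosage vectors, following the classic sums-of-squares
decomposition with unequal group sizes. Missing data are handled by
pairwise-complete distances rescaled to the full locus count.

Phi statistics (fixation analogues) reported per level:

* ``phi_st``  — total differentiation, (sigma_a + sigma_b) / sigma_total
* ``phi_sc``  — among localities within regions, sigma_b / (sigma_b + sigma_c)
* ``phi_ct``  — among regions, sigma_a / sigma_total

P-values come from permutation: individuals among all localities for
``phi_st``, individuals among localities within their region for ``phi_sc``,
and whole localities among regions for ``phi_ct``, with
``p = (#{perm >= obs} + 1) / (n_perm + 1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


def pairwise_squared_distances(g: GenotypeMatrix) -> np.ndarray:
    """Squared Euclidean distance on dosages, pairwise-complete per locus and
    rescaled by ``L / L_complete``. Pairs sharing no called locus get ``nan``.
    """
    X = g.calls.astype(np.float64)
    M = (g.calls != MISSING).astype(np.float64)
    Xm = X * M
    sq = (Xm ** 2) @ M.T
    cross = Xm @ Xm.T
    d2 = sq + sq.T - 2.0 * cross
    l_pair = M @ M.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = np.where(l_pair > 0, d2 * (g.n_loci / l_pair), np.nan)
    np.fill_diagonal(d2, 0.0)
    return d2


@dataclass
class AmovaResult:
    """Variance components, percent variance, phi statistics and p-values."""

    sigma: dict[str, float]
    percent: dict[str, float]
    phi: dict[str, float]
    p_values: dict[str, float]
    df: dict[str, int]
    n_permutations: int
    seed: int | None
    flags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Three-row table mirroring the usual AMOVA presentation."""
        rows = [
            ("Within localities", "within_localities", "phi_st"),
            ("Between localities", "between_localities", "phi_sc"),
            ("Between regions", "between_regions", "phi_ct"),
        ]
        out = []
        for name, level, phi_key in rows:
            if level not in self.sigma:
                continue
            out.append({
                "level": name,
                "df": self.df.get(level, np.nan),
                "sigma": self.sigma[level],
                "percent_variance": self.percent.get(level, np.nan),
                "phi": self.phi.get(phi_key, np.nan),
                "p": self.p_values.get(phi_key, np.nan),
            })
        return pd.DataFrame(out)


def _group_pair_sums(D: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """Sum of D over unordered pairs within each group (diag(D) must be 0)."""
    A = np.zeros((n_groups, D.shape[0]))
    A[codes, np.arange(D.shape[0])] = 1.0
    return 0.5 * np.einsum("ij,ij->i", A @ D, A)


def _components(D, loc_codes, reg_codes, n_loc, n_reg):
    """Variance components (sigma_a, sigma_b, sigma_c) from the distance
    matrix and integer locality/region codes. sigma_a is the among-region
    component (0 when there is a single region, which also flags that level
    as undefined upstream)."""
    N = D.shape[0]
    total = D[np.triu_indices(N, 1)].sum() / N
    loc_sizes = np.bincount(loc_codes, minlength=n_loc).astype(float)
    reg_sizes = np.bincount(reg_codes, minlength=n_reg).astype(float)
    t_loc = _group_pair_sums(D, loc_codes, n_loc)
    with np.errstate(invalid="ignore", divide="ignore"):
        ssd_wp = float(np.sum(np.where(loc_sizes > 0, t_loc / np.maximum(loc_sizes, 1), 0.0)))
    # region of each locality (codes are consistent by construction)
    loc_region = np.full(n_loc, -1, dtype=int)
    loc_region[loc_codes] = reg_codes
    t_reg = _group_pair_sums(D, reg_codes, n_reg)
    ssd_groups = float(np.sum(np.where(reg_sizes > 0, t_reg / np.maximum(reg_sizes, 1), 0.0)))

    P = int((loc_sizes > 0).sum())
    G = int((reg_sizes > 0).sum())
    df_wp = N - P
    df_ap = P - G
    df_ag = G - 1

    ssd_ap = ssd_groups - ssd_wp
    ssd_ag = total - ssd_groups

    sigma_c = ssd_wp / df_wp if df_wp > 0 else 0.0

    # sums of squared locality sizes per region, and overall
    sum_np2 = float((loc_sizes ** 2).sum())
    per_region = np.zeros(n_reg)
    np.add.at(per_region, loc_region[loc_region >= 0],
              loc_sizes[loc_region >= 0] ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sum_np2_over_ng = float(np.sum(np.where(reg_sizes > 0,
                                                per_region / np.maximum(reg_sizes, 1), 0.0)))
    if df_ap > 0:
        n_prime = (N - sum_np2_over_ng) / df_ap
        sigma_b = (ssd_ap / df_ap - sigma_c) / n_prime
    else:
        sigma_b = 0.0
    if df_ag > 0:
        n_dprime = (sum_np2_over_ng - sum_np2 / N) / df_ag
        n_tprime = (N - float((reg_sizes ** 2).sum()) / N) / df_ag
        sigma_a = (ssd_ag / df_ag - sigma_c - n_dprime * sigma_b) / n_tprime
    else:
        sigma_a = 0.0
    return sigma_a, sigma_b, sigma_c, (df_ag, df_ap, df_wp)


def _phis(sigma_a, sigma_b, sigma_c):
    tot = sigma_a + sigma_b + sigma_c
    with np.errstate(invalid="ignore", divide="ignore"):
        phi_st = (sigma_a + sigma_b) / tot if tot != 0 else np.nan
        phi_sc = sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) != 0 else np.nan
        phi_ct = sigma_a / tot if tot != 0 else np.nan
    return phi_st, phi_sc, phi_ct


def amova(
    g: GenotypeMatrix,
    localities,
    regions=None,
    n_permutations: int = 999,
    seed: int | None = None,
) -> AmovaResult:
    """Run the hierarchical AMOVA.

    ``localities`` and (optionally) ``regions`` are per-sample labels; every
    locality must map to exactly one region. With ``regions=None`` (or a
    single region) a two-level analysis is performed and the region level is
    flagged undefined.
    """
    loc = np.asarray(localities, dtype=object)
    if loc.shape != (g.n_samples,):
        raise ValueError("need one locality label per sample")
    if regions is None:
        reg = np.asarray(["_all_"] * g.n_samples, dtype=object)
    else:
        reg = np.asarray(regions, dtype=object)
        if reg.shape != (g.n_samples,):
            raise ValueError("need one region label per sample")
    # locality -> region consistency
    mapping: dict[object, object] = {}
    for l, r in zip(loc, reg):
        if l in mapping and mapping[l] != r:
            raise ValueError(f"locality {l!r} maps to multiple regions")
        mapping[l] = r
    if len(mapping) < 2:
        raise ValueError("AMOVA requires at least 2 localities")

    flags: list[str] = []
    D = pairwise_squared_distances(g)
    usable = ~np.all(np.isnan(D) | np.eye(g.n_samples, dtype=bool), axis=1)
    if np.isnan(D[np.ix_(usable, usable)]).any():
        bad = np.unique(np.where(np.isnan(D))[0])
        logger.warning("excluding %d sample(s) with no called loci shared "
                       "with some others", len(bad))
        usable = np.ones(g.n_samples, dtype=bool)
        usable[bad] = False
        flags.append(f"excluded {len(bad)} sample(s) with all-missing overlap")
    D = D[np.ix_(usable, usable)]
    loc = loc[usable]
    reg = reg[usable]

    loc_names, loc_codes = np.unique(loc.astype(str), return_inverse=True)
    reg_names, reg_codes = np.unique(reg.astype(str), return_inverse=True)
    n_loc, n_reg = len(loc_names), len(reg_names)
    single_region = n_reg < 2

    sigma_a, sigma_b, sigma_c, dfs = _components(D, loc_codes, reg_codes, n_loc, n_reg)
    df_ag, df_ap, df_wp = dfs
    phi_st, phi_sc, phi_ct = _phis(sigma_a, sigma_b, sigma_c)
    total = sigma_a + sigma_b + sigma_c
    if total == 0:
        flags.append("zero total variance; phi undefined")
        phi_st = phi_sc = phi_ct = np.nan
        percent = {k: np.nan for k in
                   ("within_localities", "between_localities", "between_regions")}
    else:
        percent = {
            "within_localities": 100.0 * sigma_c / total,
            "between_localities": 100.0 * sigma_b / total,
            "between_regions": 100.0 * sigma_a / total,
        }
    for name, s in (("within_localities", sigma_c), ("between_localities", sigma_b),
                    ("between_regions", sigma_a)):
        if s < 0:
            flags.append(f"negative variance component at level {name}")
    if single_region:
        flags.append("single region; between-region level undefined")
        phi_ct = np.nan

    # permutation p-values
    rng = np.random.default_rng(seed)
    p_values: dict[str, float] = {}
    if n_permutations > 0 and total != 0:
        loc_region_code = np.full(n_loc, -1, dtype=int)
        loc_region_code[loc_codes] = reg_codes

        ge_st = ge_sc = 0
        region_members = [np.flatnonzero(reg_codes == r) for r in range(n_reg)]
        for _ in range(n_permutations):
            # phi_st: individuals among all localities
            perm = rng.permutation(len(loc_codes))
            a, b, c = _components(D, loc_codes[perm], reg_codes[perm], n_loc, n_reg)[:3]
            st = _phis(a, b, c)[0]
            if np.isfinite(st) and np.isfinite(phi_st) and st >= phi_st:
                ge_st += 1
            # phi_sc: individuals among localities within their region
            lp = loc_codes.copy()
            for members in region_members:
                lp[members] = lp[members[rng.permutation(len(members))]]
            a, b, c = _components(D, lp, reg_codes, n_loc, n_reg)[:3]
            sc = _phis(a, b, c)[1]
            if np.isfinite(sc) and np.isfinite(phi_sc) and sc >= phi_sc:
                ge_sc += 1
        p_values["phi_st"] = (ge_st + 1) / (n_permutations + 1)
        p_values["phi_sc"] = (ge_sc + 1) / (n_permutations + 1)
        if not single_region:
            ge_ct = 0
            for _ in range(n_permutations):
                shuffled = rng.permutation(loc_region_code)
                a, b, c = _components(D, loc_codes, shuffled[loc_codes], n_loc, n_reg)[:3]
                ct = _phis(a, b, c)[2]
                if np.isfinite(ct) and np.isfinite(phi_ct) and ct >= phi_ct:
                    ge_ct += 1
            p_values["phi_ct"] = (ge_ct + 1) / (n_permutations + 1)
        else:
            p_values["phi_ct"] = np.nan
    else:
        p_values = {"phi_st": np.nan, "phi_sc": np.nan, "phi_ct": np.nan}

    sigma = {
        "within_localities": sigma_c,
        "between_localities": sigma_b,
        "between_regions": sigma_a,
    }
    if single_region:
        del sigma["between_regions"]
        percent.pop("between_regions", None)
    return AmovaResult(
        sigma=sigma,
        percent=percent,
        phi={"phi_st": phi_st, "phi_sc": phi_sc, "phi_ct": phi_ct},
        p_values=p_values,
        df={"between_regions": df_ag, "between_localities": df_ap,
            "within_localities": df_wp},
        n_permutations=n_permutations,
        seed=seed,
        flags=flags,
    )
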