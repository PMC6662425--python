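import numpy as np
import pytest
from scipy import stats

from invadepop import GenotypeMatrix, amova
from invadepop.amova import pairwise_squared_distances

from conftest import make_matrix


# --------------------------------------------------------------------- oracle
def brute_force_amova(calls, localities, regions):
    """Naive sums-of-squares AMOVA, written independently with plain loops.

    Distances: squared Euclidean on dosages over pairwise-complete loci,
    rescaled by L / L_complete.
    """
    calls = np.asarray(calls, float)
    n, L = calls.shape
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            s, m = 0.0, 0
            for l in range(L):
                if calls[i, l] >= 0 and calls[j, l] >= 0:
                    s += (calls[i, l] - calls[j, l]) ** 2
                    m += 1
            D[i, j] = s * L / m

    def ssd(index_groups):
        total = 0.0
        for members in index_groups:
            sub = 0.0
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    sub += D[members[a], members[b]]
            total += sub / len(members)
        return total

    locs = sorted(set(localities))
    regs = sorted(set(regions))
    loc_groups = [[i for i in range(n) if localities[i] == l] for l in locs]
    reg_groups = [[i for i in range(n) if regions[i] == r] for r in regs]
    ssd_total = ssd([list(range(n))])
    ssd_wp = ssd(loc_groups)
    ssd_regions = ssd(reg_groups)
    ssd_ap = ssd_regions - ssd_wp
    ssd_ag = ssd_total - ssd_regions

    P, G = len(locs), len(regs)
    sizes = {l: len(g) for l, g in zip(locs, loc_groups)}
    reg_of_loc = {l: regions[localities.index(l)] for l in locs}
    reg_sizes = {r: len(g) for r, g in zip(regs, reg_groups)}

    sigma_c = ssd_wp / (n - P)
    sum_np2_over_ng = sum(
        sum(sizes[l] ** 2 for l in locs if reg_of_loc[l] == r) / reg_sizes[r]
        for r in regs)
    n_prime = (n - sum_np2_over_ng) / (P - G)
    sigma_b = (ssd_ap / (P - G) - sigma_c) / n_prime
    if G > 1:
        n_dp = (sum_np2_over_ng - sum(v ** 2 for v in sizes.values()) / n) / (G - 1)
        n_tp = (n - sum(v ** 2 for v in reg_sizes.values()) / n) / (G - 1)
        sigma_a = (ssd_ag / (G - 1) - sigma_c - n_dp * sigma_b) / n_tp
    else:
        sigma_a = 0.0
    tot = sigma_a + sigma_b + sigma_c
    return {
        "sigma": (sigma_a, sigma_b, sigma_c),
        "percent": (100 * sigma_a / tot, 100 * sigma_b / tot, 100 * sigma_c / tot),
        "phi_st": (sigma_a + sigma_b) / tot,
        "phi_sc": sigma_b / (sigma_b + sigma_c),
        "phi_ct": sigma_a / tot,
    }


@pytest.fixture
def twelve_sample_fixture():
    rng = np.random.default_rng(7)
    calls = rng.integers(0, 3, size=(12, 8)).astype(np.int8)
    calls[rng.random(calls.shape) < 0.1] = -1
    # ensure every pair shares called loci
    calls[:, 0] = rng.integers(0, 3, 12)
    localities = ["a"] * 4 + ["b"] * 3 + ["c"] * 5
    regions = ["R1"] * 7 + ["R2"] * 5
    return make_matrix(calls), localities, regions


def test_matches_independent_oracle(twelve_sample_fixture):
    g, localities, regions = twelve_sample_fixture
    res = amova(g, localities, regions, n_permutations=0)
    expected = brute_force_amova(g.calls, localities, regions)
    assert res.sigma["between_regions"] == pytest.approx(expected["sigma"][0], abs=1e-9)
    assert res.sigma["between_localities"] == pytest.approx(expected["sigma"][1], abs=1e-9)
    assert res.sigma["within_localities"] == pytest.approx(expected["sigma"][2], abs=1e-9)
    assert res.phi["phi_st"] == pytest.approx(expected["phi_st"], abs=1e-9)
    assert res.phi["phi_sc"] == pytest.approx(expected["phi_sc"], abs=1e-9)
    assert res.phi["phi_ct"] == pytest.approx(expected["phi_ct"], abs=1e-9)
    assert res.percent["between_regions"] == pytest.approx(expected["percent"][0], abs=1e-9)


def test_fixed_difference_localities_give_phi_one():
    g = make_matrix([[0, 0], [0, 0], [2, 2], [2, 2]])
    res = amova(g, ["L1", "L1", "L2", "L2"], n_permutations=99, seed=0)
    assert res.phi["phi_st"] == pytest.approx(1.0)
    assert res.percent["between_localities"] == pytest.approx(100.0)
    assert res.percent["within_localities"] == pytest.approx(0.0)


def test_identical_individuals_flagged_undefined():
    g = make_matrix(np.ones((6, 3), dtype=np.int8))
    res = amova(g, ["a", "a", "a", "b", "b", "b"], n_permutations=0)
    assert all(np.isnan(v) for v in res.phi.values())
    assert any("zero total variance" in f for f in res.flags)


def test_percent_variance_sums_to_100(twelve_sample_fixture):
    g, localities, regions = twelve_sample_fixture
    res = amova(g, localities, regions, n_permutations=0)
    assert sum(res.percent.values()) == pytest.approx(100.0, abs=1e-9)


def test_invariant_to_sample_and_locus_order(twelve_sample_fixture):
    g, localities, regions = twelve_sample_fixture
    base = amova(g, localities, regions, n_permutations=0)
    rng = np.random.default_rng(0)
    si = rng.permutation(g.n_samples)
    lj = rng.permutation(g.n_loci)
    g2 = g.take_samples(si).take_loci(lj)
    res = amova(g2, [localities[i] for i in si], [regions[i] for i in si],
                n_permutations=0)
    for key in base.phi:
        assert res.phi[key] == pytest.approx(base.phi[key], abs=1e-12)


def test_requires_two_localities(small_matrix):
    with pytest.raises(ValueError, match="2 localities"):
        amova(small_matrix, ["x"] * 4)


def test_inconsistent_hierarchy_rejected(small_matrix):
    with pytest.raises(ValueError, match="multiple regions"):
        amova(small_matrix, ["a", "a", "b", "b"], ["R1", "R2", "R2", "R2"])


def test_distance_matrix_handles_missing_rescaling():
    # one missing call: the pair distance is rescaled to the full locus count
    g = make_matrix([[0, 0], [2, -1]])
    D = pairwise_squared_distances(g)
    assert D[0, 1] == pytest.approx(4 * 2 / 1)


def test_null_permutation_pvalues_are_uniform():
    """Under a random-label null the permutation p-values are ~U(0,1)."""
    rng = np.random.default_rng(123)
    pvals = []
    for _ in range(200):
        calls = rng.integers(0, 3, size=(12, 10)).astype(np.int8)
        g = make_matrix(calls)
        localities = rng.permutation(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
        res = amova(g, list(localities), n_permutations=99,
                    seed=int(rng.integers(2**31)))
        pvals.append(res.p_values["phi_st"])
    stat = stats.kstest(pvals, "uniform").statistic
    # critical value at alpha=0.01 for n=200 is ~0.115 (plus discreteness slack)
    assert stat < 0.125
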