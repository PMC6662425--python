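import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from invadepop import (GenotypeMatrix, MISSING, allele_frequencies,
                       diversity_summary, expected_heterozygosity,
                       fis_from_selfing, flag_rare_variants,
                       inbreeding_coefficient, observed_heterozygosity,
                       outcrossing_rate, private_alleles, selfing_rate,
                       simulate_selfing_population)
from invadepop.popgen import LocusFrequencies

from conftest import make_matrix


class TestAlleleFrequencies:
    def test_hand_counted_frequency(self):
        g = make_matrix(np.array([[0], [0], [1], [2]]))
        f = allele_frequencies(g)
        assert f.p[0] == pytest.approx(3 / 8)
        assert f.maf[0] == pytest.approx(0.375)

    @pytest.mark.parametrize("calls,expected_p", [
        ([[0], [0], [0]], 0.0),
        ([[2], [2]], 1.0),
    ])
    def test_monomorphic_extremes(self, calls, expected_p):
        f = allele_frequencies(make_matrix(np.array(calls)))
        assert f.p[0] == expected_p
        assert f.maf[0] == 0.0

    def test_missing_calls_excluded(self):
        g = make_matrix(np.array([[1], [MISSING], [2]]))
        f = allele_frequencies(g)
        assert f.p[0] == pytest.approx(3 / 4)
        assert f.n_called[0] == 2

    def test_empty_subset_rejected(self, small_matrix):
        with pytest.raises(ValueError, match="empty"):
            allele_frequencies(small_matrix, [])


class TestRareVariants:
    @pytest.mark.parametrize("maf,expected", [
        (0.05, True),    # below the threshold
        (0.10, False),   # strict inequality at the threshold
        (0.0, False),    # monomorphic loci are not rare variants
    ])
    def test_threshold_semantics(self, maf, expected):
        f = LocusFrequencies(p=np.array([maf]), n_called=np.array([50]))
        assert flag_rare_variants(f, 0.10)[0] == expected

    def test_undefined_loci_never_rare(self):
        f = LocusFrequencies(p=np.array([np.nan]), n_called=np.array([0]))
        assert not flag_rare_variants(f)[0]


class TestHeterozygosity:
    def test_observed_per_locus_and_mean(self):
        # Ho = 0.2 and 0.4 at the two loci -> mean 0.3
        calls = np.array([[1, 1], [0, 1], [0, 0], [0, 0], [0, 0]])
        per_locus, summary = observed_heterozygosity(make_matrix(calls))
        assert per_locus.tolist() == [0.2, 0.4]
        assert summary.mean == pytest.approx(0.3)

    def test_all_heterozygous(self):
        _, s = observed_heterozygosity(make_matrix(np.ones((4, 2), dtype=int)))
        assert s.mean == 1.0

    @pytest.mark.parametrize("p,he", [(0.5, 0.5), (0.1, 0.18), (0.0, 0.0)])
    def test_expected_closed_form(self, p, he):
        f = LocusFrequencies(p=np.array([p]), n_called=np.array([10]))
        per_locus, _ = expected_heterozygosity(f)
        assert per_locus[0] == pytest.approx(he)

    def test_mean_he_at_half(self):
        f = LocusFrequencies(p=np.full(30, 0.5), n_called=np.full(30, 10))
        _, s = expected_heterozygosity(f)
        assert s.mean == 0.5


class TestInbreedingAndSelfing:
    def test_fis_formula(self):
        assert inbreeding_coefficient(0.1, 0.2) == pytest.approx(0.5)
        assert inbreeding_coefficient(0.3, 0.3) == 0.0

    def test_fis_from_published_cluster_means_is_low(self):
        # mean Ho 0.0577 / mean He 0.0697 gives a modest multilocus Fis;
        # per-site aggregation schemes can differ (documented in methods).
        assert inbreeding_coefficient(0.0577, 0.0697) == pytest.approx(
            0.1722, abs=1e-4)

    def test_fis_undefined_at_zero_he(self):
        assert np.isnan(inbreeding_coefficient(0.0, 0.0))

    @pytest.mark.parametrize("fis,s,t", [
        (0.8425, 0.9145, 0.0855),
        (0.7865, 0.8805, 0.1195),
        (0.0, 0.0, 1.0),
    ])
    def test_selfing_conversion(self, fis, s, t):
        assert selfing_rate(fis) == pytest.approx(s, abs=5e-5)
        assert outcrossing_rate(fis) == pytest.approx(t, abs=5e-5)

    def test_selfing_rejects_boundary(self):
        with pytest.raises(ValueError):
            selfing_rate(-1.0)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=0.0, max_value=0.99))
    def test_selfing_round_trip(self, s):
        assert selfing_rate(fis_from_selfing(s)) == pytest.approx(s, abs=1e-12)

    def test_random_mating_simulation_has_near_zero_fis(self):
        """Random-mating forward simulations should sit at Hardy-Weinberg."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pop = simulate_selfing_population(
                rng.uniform(0.05, 0.95, 1000), 0.0, 10, 500, seed=rng)
            g = GenotypeMatrix([f"s{i}" for i in range(500)],
                               [f"l{j}" for j in range(1000)], pop)
            f = allele_frequencies(g)
            _, ho = observed_heterozygosity(g)
            _, he = expected_heterozygosity(f)
            if abs(inbreeding_coefficient(ho.mean, he.mean)) < 0.05:
                hits += 1
        assert hits >= 19


def brute_force_private_alleles(g, labels):
    """Independent double loop over loci x clusters."""
    labels = np.asarray(labels, dtype=object)
    clusters = sorted(set(labels.tolist()), key=str)
    counts = {c: 0 for c in clusters}
    for j in range(g.n_loci):
        for allele in ("ref", "alt"):
            seen_in = set()
            for i in range(g.n_samples):
                call = g.calls[i, j]
                if call == MISSING:
                    continue
                if allele == "alt" and call >= 1:
                    seen_in.add(labels[i])
                if allele == "ref" and call <= 1:
                    seen_in.add(labels[i])
            if len(seen_in) == 1:
                counts[seen_in.pop()] += 1
    return counts


class TestPrivateAlleles:
    def test_minimal_fixture(self):
        # alt allele present only in cluster A at the single locus
        g = make_matrix(np.array([[1], [0], [0], [0]]))
        counts = private_alleles(g, ["A", "A", "B", "B"])
        assert counts == {"A": 1, "B": 0}

    def test_single_cluster_all_observed_alleles_private(self):
        g = make_matrix(np.array([[0], [1], [2]]))
        assert private_alleles(g, ["A", "A", "A"]) == {"A": 2}

    def test_shared_allele_counts_for_neither(self):
        g = make_matrix(np.array([[1], [1]]))
        assert private_alleles(g, ["A", "B"]) == {"A": 0, "B": 0}

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 10))
        L = int(rng.integers(1, 10))
        calls = rng.integers(-1, 3, size=(n, L)).astype(np.int8)
        g = make_matrix(calls)
        labels = rng.choice(["A", "B", "C"], size=n)
        assert private_alleles(g, labels) == brute_force_private_alleles(g, labels)

    def test_unassigned_sample_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            private_alleles(small_matrix, ["A", None, "B", "B"])


def test_diversity_summary_table_shape(two_pop_matrix):
    labels = ["A"] * 5 + ["B"] * 5
    table = diversity_summary(two_pop_matrix, labels)
    assert list(table.index) == ["A", "B"]
    assert {"n", "Ho", "He", "Fis", "S", "T", "private"} <= set(table.columns)
    assert table.loc["A", "n"] == 5
    # T = 1 - S wherever defined
    defined = table["S"].notna()
    assert np.allclose(table.loc[defined, "T"], 1 - table.loc[defined, "S"])
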