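import numpy as np
import pandas as pd
import pytest
from scipy import stats

from invadepop import (allele_frequencies, distance_decay, flag_rare_variants,
                       iterative_peeling, peak_site, simulate_invasion,
                       site_rare_variant_density)

from conftest import make_matrix


def _meta(samples, sites, coords):
    return pd.DataFrame({
        "sample": samples,
        "site": sites,
        "lat": [coords[s][0] for s in sites],
        "lon": [coords[s][1] for s in sites],
        "ecoregion": ["e"] * len(samples),
    })


class TestSiteDensity:
    def test_hand_counted_density(self):
        """Site A carries minor alleles at 3 of 10 assessed rare loci."""
        # 10 loci; alt is globally rare everywhere (one copy max)
        calls = np.zeros((4, 10), dtype=np.int8)
        calls[0, 0] = 1  # site A, loci 0-2
        calls[0, 1] = 1
        calls[1, 2] = 1
        g = make_matrix(calls)
        meta = _meta(g.samples, ["A", "A", "B", "B"],
                     {"A": (34.0, -118.0), "B": (35.0, -119.0)})
        rare = np.ones(10, dtype=bool)
        table = site_rare_variant_density(g, meta, rare)
        row_a = table.set_index("site").loc["A"]
        assert row_a["n_rare_segregating"] == 3
        assert row_a["n_loci_assessed"] == 10
        assert row_a["density"] == pytest.approx(0.3)
        assert table.set_index("site").loc["B", "density"] == 0.0

    def test_density_invariant_to_sample_order(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 3, size=(8, 12)).astype(np.int8)
        g = make_matrix(calls)
        sites = ["A"] * 4 + ["B"] * 4
        meta = _meta(g.samples, sites, {"A": (34, -118), "B": (35, -119)})
        rare = flag_rare_variants(allele_frequencies(g), 0.4)
        base = site_rare_variant_density(g, meta, rare)
        perm = rng.permutation(8)
        g2 = g.take_samples(perm)
        meta2 = _meta(g2.samples, [sites[i] for i in perm],
                      {"A": (34, -118), "B": (35, -119)})
        rare2 = flag_rare_variants(allele_frequencies(g2), 0.4)
        other = site_rare_variant_density(g2, meta2, rare2)
        pd.testing.assert_frame_equal(
            base.sort_values("site").reset_index(drop=True),
            other.sort_values("site").reset_index(drop=True))

    def test_peak_site_and_tie_break(self):
        table = pd.DataFrame({"site": ["C", "A", "B"],
                              "density": [0.2, 0.3, 0.3],
                              "lat": [0, 0, 0], "lon": [0, 0, 0]})
        assert peak_site(table)["site"] == "A"  # tie A/B -> lexicographic
        table.loc[0, "density"] = 0.9
        assert peak_site(table)["site"] == "C"


class TestDistanceDecay:
    def test_linear_decay_matches_ols_line(self):
        lats = np.array([34.0, 34.2, 34.4, 34.6, 34.8, 35.0, 35.2])
        lons = np.full(7, -118.0)
        from invadepop import haversine_km
        d = haversine_km(lats, lons, 34.0, -118.0)
        dens = 0.5 - 0.001 * d  # exactly linear in distance
        table = pd.DataFrame({"site": [f"s{i}" for i in range(7)],
                              "lat": lats, "lon": lons, "density": dens})
        fit = distance_decay(table, (34.0, -118.0), span=0.75)
        slope, intercept = np.polyfit(fit.distances_km, dens, 1)
        expected = intercept + slope * fit.distances_km
        interior = (d > d.min()) & (d < d.max())
        assert np.allclose(fit.fitted[interior], expected[interior], atol=1e-6)
        assert fit.spearman_rho == pytest.approx(-1.0)

    def test_constant_density_flat(self):
        table = pd.DataFrame({"site": list("abcde"),
                              "lat": [34, 34.5, 35, 35.5, 36],
                              "lon": [-118] * 5, "density": [0.2] * 5})
        fit = distance_decay(table, (34.0, -118.0))
        assert fit.spearman_rho == 0.0
        assert np.allclose(fit.fitted, 0.2, atol=1e-9)

    def test_identical_distances_rejected(self):
        table = pd.DataFrame({"site": list("abcde"),
                              "lat": [34] * 5, "lon": [-118] * 5,
                              "density": [0.1, 0.2, 0.3, 0.4, 0.5]})
        with pytest.raises(ValueError, match="identical distance"):
            distance_decay(table, (34.0, -118.0))


class TestIterativePeeling:
    def _hand_fixture(self):
        """10 samples (A: 6 across A1/A2, B: 4 across B1/B2), 12 loci.

        Loci 0-2: one alt copy each, only in B1 -> rare, private to B.
        Loci 3-4: one alt copy each, only in A1 -> rare, private to A.
        Loci 5-11: alt at frequency 0.5 in every site -> common, shared.
        """
        calls = np.zeros((10, 12), dtype=np.int8)
        for i in range(10):  # common loci alternate 0/2 across samples

            calls[i, 5:] = 0 if i % 2 == 0 else 2
        calls[6, 0] = 1  # B1 samples are indices 6,7; B2: 8,9
        calls[6, 1] = 1
        calls[7, 2] = 1
        calls[0, 3] = 1  # A1 samples are indices 0,1,2
        calls[1, 4] = 1
        g = make_matrix(calls)
        sites = ["A1"] * 3 + ["A2"] * 3 + ["B1"] * 2 + ["B2"] * 2
        coords = {"A1": (34.0, -118.0), "A2": (34.5, -118.5),
                  "B1": (35.0, -120.0), "B2": (35.5, -120.5)}
        meta = _meta(g.samples, sites, coords)
        labels = ["A"] * 6 + ["B"] * 4
        return g, meta, labels

    def test_hand_fixture_round_one_oracle(self):
        g, meta, labels = self._hand_fixture()
        inf = iterative_peeling(g, meta, labels, compute_decay=False)
        r1 = inf.rounds[0]
        # hand oracle: B1 density 3/12 beats A1's 2/12; B's private loci peel
        assert r1.peak_site == "B1"
        assert r1.focal_cluster == "B"
        assert r1.n_rare == 5
        assert r1.removed_loci == ["L0", "L1", "L2"]
        # round 2 finds the remaining cluster's origin
        assert len(inf.rounds) == 2
        assert inf.rounds[1].peak_site == "A1"
        assert inf.rounds[1].focal_cluster == "A"

    def test_single_cluster_single_round(self):
        g, meta, _ = self._hand_fixture()
        inf = iterative_peeling(g, meta, ["Z"] * 10, compute_decay=False)
        assert len(inf.rounds) == 1
        assert inf.rounds[0].peak_site == "B1"  # densest site overall

    def test_no_rare_variants_stops_with_reason(self):
        calls = np.zeros((4, 6), dtype=np.int8)
        calls[::2, :] = 2  # every locus at frequency 0.5
        g = make_matrix(calls)
        meta = _meta(g.samples, ["A", "A", "B", "B"],
                     {"A": (34, -118), "B": (35, -119)})
        inf = iterative_peeling(g, meta, ["A", "A", "B", "B"],
                                compute_decay=False)
        assert inf.rounds == []
        assert "no rare variants" in inf.stop_reason

    def test_simulated_invasion_orders_introductions(self):
        hits = 0
        for seed in range(5):
            ds = simulate_invasion(seed=seed)
            inf = iterative_peeling(ds.genotypes, ds.metadata,
                                    ds.cluster_labels, compute_decay=False)
            truth = [o["site"] for o in ds.origins_newest_first]
            hits += inf.origin_sites() == truth
        assert hits >= 4

    def test_rare_density_decays_with_hop_count(self):
        """Serial founder hops erode rare variation away from the origin."""
        hits = 0
        for seed in range(5):
            ds = simulate_invasion(seed=seed)
            rare = flag_rare_variants(allele_frequencies(ds.genotypes))
            den = site_rare_variant_density(ds.genotypes, ds.metadata, rare)
            den = den[den["site"].str.startswith("Malibu")]
            hops = den["site"].map(ds.site_hops)
            rho = stats.spearmanr(hops, den["density"]).statistic
            hits += rho < 0
        assert hits >= 5
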