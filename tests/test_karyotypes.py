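"""Region PCA, exact 1-D k-means, karyotype assignment, and classification."""
import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans

from invscan import (assign_karyotypes, classify_soc_cause, inversion_fst,
                     karyotype_frequencies, kmeans_1d, region_pca)

from helpers import karyotype_concordance, make_dataset


@pytest.fixture(scope="module")
def soc_fixture(pipeline_result_module):
    res = pipeline_result_module
    soc = res.socs[0]
    return res, soc


@pytest.fixture(scope="module")
def pipeline_result_module(request):
    return request.getfixturevalue("pipeline_result")


class TestKmeans1d:
    def test_well_separated_triples(self):
        res = kmeans_1d([-10, -9, 0, 1, 9, 10], k=3)
        assert res.labels.tolist() == [0, 0, 1, 1, 2, 2]
        assert not res.degenerate

    def test_fewer_distinct_values_flagged_degenerate(self):
        res = kmeans_1d([0, 0, 0, 5, 5, 5], k=3)
        assert res.degenerate
        assert len(np.unique(res.labels)) == 2

    def test_dp_beats_random_restart_lloyd(self, rng):
        for _ in range(10):
            v = rng.normal(size=rng.integers(20, 80)) * rng.uniform(0.5, 4)
            dp = kmeans_1d(v, k=3)
            lloyd = KMeans(n_clusters=3, n_init=100, init="random",
                           random_state=0).fit(v.reshape(-1, 1))
            assert dp.inertia <= lloyd.inertia_ + 1e-9

    def test_deterministic(self, rng):
        v = rng.normal(size=50)
        a = kmeans_1d(v, 3)
        b = kmeans_1d(v, 3)
        assert np.array_equal(a.labels, b.labels)


class TestRegionPca:
    def test_three_clusters_with_high_silhouette(self, soc_fixture):
        from sklearn.metrics import silhouette_score
        res, soc = soc_fixture
        filt, _ = res.dataset, None
        pcs = region_pca(res.dataset, soc.snp_ids)
        km = kmeans_1d(pcs["PC1"].to_numpy(), 3)
        sil = silhouette_score(pcs[["PC1"]], km.labels)
        assert sil > 0.8

    def test_unlinked_region_shows_no_three_cluster_structure(self, rng):
        from sklearn.metrics import silhouette_score
        gt = rng.binomial(2, 0.5, size=(60, 40)).astype(np.int8)
        ds = make_dataset(gt, {f"s{i}": "P" for i in range(60)})
        pcs = region_pca(ds, ds.snp_ids)
        km = kmeans_1d(pcs["PC1"].to_numpy(), 3)
        # a forced 3-way split of unimodal 1-D data scores ~0.55; genuine
        # karyotype structure scores > 0.8, so the gate sits between
        assert silhouette_score(pcs[["PC1"]], km.labels) < 0.7

    def test_duplicating_individuals_preserves_pc1_structure(self, rng):
        gt = np.vstack([np.zeros((10, 20)), np.full((10, 20), 1),
                        np.full((10, 20), 2)]).astype(np.int8)
        pm = {f"s{i}": ("anc" if i < 10 else "fw") for i in range(30)}
        ds = make_dataset(gt, pm, ecotype={"anc": "ancestral", "fw": "derived"})
        pcs1 = region_pca(ds, ds.snp_ids)
        gt2 = np.vstack([gt, gt])
        pm2 = {f"s{i}": ("anc" if i % 30 < 10 else "fw") for i in range(60)}
        ds2 = make_dataset(gt2, pm2, ecotype={"anc": "ancestral", "fw": "derived"})
        pcs2 = region_pca(ds2, ds2.snp_ids)
        km1 = kmeans_1d(pcs1["PC1"].to_numpy(), 3).labels
        km2 = kmeans_1d(pcs2["PC1"].to_numpy(), 3).labels
        assert np.array_equal(km2[:30], km1) and np.array_equal(km2[30:], km1)

    def test_ancestral_mean_is_negative(self, soc_fixture):
        res, soc = soc_fixture
        pcs = region_pca(res.dataset, soc.snp_ids)
        anc = [s for s in pcs.index if res.dataset.popmap[s] == "anc"]
        assert pcs.loc[anc, "PC1"].mean() < 0


class TestAssignment:
    def test_simulated_truth_fully_recovered(self, soc_fixture):
        res, soc = soc_fixture
        ka = res.karyotypes[list(res.karyotypes)[0]]
        assert not ka.failed
        assert karyotype_concordance(ka.table, res.truth.karyotypes) == 1.0

    def test_ab_group_has_highest_heterozygosity(self, soc_fixture):
        res, _ = soc_fixture
        ka = res.karyotypes[list(res.karyotypes)[0]]
        assert ka.group_het_means["AB"] > ka.group_het_means["AA"]
        assert ka.group_het_means["AB"] > ka.group_het_means["BB"]

    def test_all_ancestral_single_group_all_aa(self):
        gt = np.zeros((12, 10), dtype=np.int8)
        pm = {f"s{i}": "anc" for i in range(12)}
        ds = make_dataset(gt, pm, ecotype={"anc": "ancestral"})
        ka = assign_karyotypes(ds, ds.snp_ids)
        assert ka.degenerate
        assert set(ka.table["karyotype"]) == {"AA"}

    def test_failed_het_gate_flagged_not_relabeled(self, rng):
        # three PC1 groups but middle group is NOT the most heterozygous:
        # construct genotypes where the "middle" individuals are homozygous
        g0 = np.zeros((8, 30))
        g1 = np.tile(np.repeat([0, 2], 15), (8, 1))  # middle by dosage sum, all hom
        g2 = np.full((8, 30), 2)
        gt = np.vstack([g0, g1, g2]).astype(np.int8)
        pm = {f"s{i}": ("anc" if i < 8 else "fw") for i in range(24)}
        ds = make_dataset(gt, pm, ecotype={"anc": "ancestral", "fw": "derived"})
        ka = assign_karyotypes(ds, ds.snp_ids)
        assert ka.failed
        assert "heterozygosity" in ka.reason


class TestFrequencies:
    def _assignment(self, karyos, pop="anc"):
        from invscan.karyotypes import KaryotypeAssignment
        tab = pd.DataFrame({
            "sample": [f"s{i}" for i in range(len(karyos))],
            "population": pop,
            "pc1": np.linspace(-1, 1, len(karyos)),
            "karyotype": karyos,
            "region_het": 0.1,
            "dist_to_center": 0.0,
        })
        return KaryotypeAssignment(soc_id="t", table=tab, group_het_means={})

    def test_printed_counts_give_81_percent(self):
        ka = self._assignment(["AA"] * 17 + ["AB"] * 3 + ["BB"])
        fr = karyotype_frequencies(ka)
        assert fr.loc[0, "freq_AA"] == pytest.approx(17 / 21)
        assert fr.loc[0, "freq_B"] == pytest.approx(5 / 42)

    def test_all_bb_gives_freq_b_one(self):
        fr = karyotype_frequencies(self._assignment(["BB"] * 10))
        assert fr.loc[0, "freq_B"] == 1.0

    def test_frequencies_sum_to_one(self, soc_fixture):
        res, _ = soc_fixture
        fr = list(res.arrangement_freqs.values())[0]
        s = fr[["freq_AA", "freq_AB", "freq_BB"]].sum(axis=1)
        assert np.allclose(s, 1.0)

    def test_recovered_freq_b_matches_drawing_frequency(self, soc_fixture):
        res, _ = soc_fixture
        fr = list(res.arrangement_freqs.values())[0].set_index("population")
        for pop, f_true in res.truth.arrangement_freq_b.items():
            n = fr.loc[pop, "n"]
            se = np.sqrt(f_true * (1 - f_true) / (2 * n))
            assert abs(fr.loc[pop, "freq_B"] - f_true) < 4 * se + 1e-9


class TestInversionFst:
    def test_elevated_over_neutral_background(self, soc_fixture):
        res, soc = soc_fixture
        tab = list(res.inversion_fst.values())[0]
        assert (tab["theta_inversion"] > 5 * tab["theta_neutral"]).all()

    def test_neutral_soc_ratio_near_one(self, soc_fixture):
        res, _ = soc_fixture
        neutral = np.array(res.neutral_ids)
        fake_soc = neutral[:200]
        tab = inversion_fst(res.dataset, fake_soc, neutral[200:], "anc",
                            ["fw1", "fw2", "fw3", "fw4"])
        assert np.all(tab["ratio"] < 2.5) and np.all(tab["ratio"] > 0.4)

    def test_ratio_invariant_to_snp_order(self, soc_fixture, rng):
        res, soc = soc_fixture
        ids = soc.snp_ids.copy()
        a = inversion_fst(res.dataset, ids, res.neutral_ids, "anc", ["fw1"])
        b = inversion_fst(res.dataset, rng.permutation(ids), res.neutral_ids,
                          "anc", ["fw1"])
        assert a["ratio"].iloc[0] == pytest.approx(b["ratio"].iloc[0])


class TestClassification:
    def _freqs(self, anc, derived):
        rows = [{"population": "anc", "n": 20, "freq_B": anc}]
        rows += [{"population": f"fw{i+1}", "n": 20, "freq_B": f}
                 for i, f in enumerate(derived)]
        return pd.DataFrame(rows)

    ECOTYPE = {"anc": "ancestral", "fw1": "derived", "fw2": "derived",
               "fw3": "derived", "fw4": "derived"}

    def test_parallel_shift_pattern(self):
        fr = self._freqs(0.10, [0.85, 0.90, 0.80, 0.75])
        assert classify_soc_cause(fr, self.ECOTYPE) == "parallel adaptation"

    def test_geographic_split_pattern(self):
        fr = self._freqs(0.5, [0.95, 0.92, 0.05, 0.08])
        assert classify_soc_cause(fr, self.ECOTYPE) == "geographic structure"

    def test_no_shift_unresolved(self):
        fr = self._freqs(0.4, [0.4, 0.4, 0.4, 0.4])
        assert classify_soc_cause(fr, self.ECOTYPE) == "unresolved"

    def test_requires_two_derived_pops(self):
        fr = self._freqs(0.4, [0.9])
        with pytest.raises(ValueError):
            classify_soc_cause(fr, {"anc": "ancestral", "fw1": "derived"})
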