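"""LD matrices, the merger tree and lambda, SOC extraction, spans and gaps."""
import numpy as np
import pytest

from invscan import (LDnaParams, build_merger_tree, extract_ocs, ld_r2,
                     select_phi, soc_postfilter, soc_span)
from invscan.ldna import LDCluster, LDMatrix

from helpers import make_dataset


def _ld_from_matrix(r2, positions=None):
    r2 = np.asarray(r2, np.float32)
    p = r2.shape[0]
    positions = np.asarray(positions) if positions is not None else (np.arange(p) + 1) * 1000
    return LDMatrix("chrT", np.array([f"s{i}" for i in range(p)]), positions, r2)


def _toy_tree(merge_median="cross"):
    """3-clique at r2=1 plus 3 unlinked loci."""
    r2 = np.zeros((6, 6), np.float32)
    r2[:3, :3] = 1.0
    np.fill_diagonal(r2, 0.0)
    return build_merger_tree(_ld_from_matrix(r2), merge_median=merge_median)


class TestLdR2:
    def test_perfectly_covarying_dosages(self):
        gt = np.array([[0, 0], [1, 1], [2, 2], [0, 0], [2, 2]], dtype=np.int8)
        ds = make_dataset(gt, {f"s{i}": "P" for i in range(5)})
        ld = ld_r2(ds, "chr1", maf_floor=0.0)
        assert ld.r2[0, 1] == pytest.approx(1.0)

    def test_independent_snps_low_mean_r2(self, rng):
        gt = rng.binomial(2, 0.5, size=(100, 60)).astype(np.int8)
        ds = make_dataset(gt, {f"s{i}": "P" for i in range(100)})
        ld = ld_r2(ds, "chr1", floor=0.0)
        iu = np.triu_indices(ld.n_snps, 1)
        assert ld.r2[iu].mean() < 0.05

    def test_invariant_to_allele_swap(self, rng):
        gt = rng.binomial(2, 0.4, size=(40, 10)).astype(np.int8)
        pm = {f"s{i}": "P" for i in range(40)}
        a = ld_r2(make_dataset(gt, pm), "chr1", floor=0.0)
        swapped = gt.copy()
        swapped[:, 3] = 2 - swapped[:, 3]
        b = ld_r2(make_dataset(swapped, pm), "chr1", floor=0.0)
        np.testing.assert_allclose(a.r2, b.r2, atol=1e-6)

    def test_maf_floor_excludes_rare_snps(self, rng):
        gt = rng.binomial(2, 0.5, size=(60, 5)).astype(np.int8)
        gt[:, 2] = 0
        gt[0, 2] = 1  # MAF ~ 0.008
        ds = make_dataset(gt, {f"s{i}": "P" for i in range(60)})
        ld = ld_r2(ds, "chr1", maf_floor=0.1)
        assert ld.n_snps == 4


class TestMergerTree:
    @pytest.mark.parametrize("mode", ["cross", "all"])
    def test_toy_lambda_exactly_three(self, mode):
        tree = _toy_tree(mode)
        lams = [n.lam for n in tree.mergers]
        assert lams == [pytest.approx(3.0)]
        node = tree.mergers[0]
        assert node.x1 == pytest.approx(1.0)
        assert node.x2 == pytest.approx(0.0)

    def test_fully_connected_graph_single_root_no_lambda(self):
        r2 = np.full((4, 4), 0.9, np.float32)
        np.fill_diagonal(r2, 0.0)
        tree = build_merger_tree(_ld_from_matrix(r2))
        assert len(tree.mergers) == 0  # born whole from singletons, never dies

    def test_component_count_nonincreasing_with_descending_threshold(self, rng):
        p = 30
        r2 = rng.uniform(0, 1, (p, p)).astype(np.float32)
        r2 = ((r2 + r2.T) / 2)
        np.fill_diagonal(r2, 0.0)
        tree = build_merger_tree(_ld_from_matrix(r2))
        # multi-SNP component count never decreases... clusters only merge,
        # so the number of distinct clusters alive can rise then fall, but
        # membership is monotone: every cluster is contained in its parent.
        for n in tree.nodes:
            if n.parent is not None:
                assert set(n.members) <= set(tree.nodes[n.parent].members)

    def test_singleton_component_counts_nonincreasing(self):
        r2 = np.zeros((5, 5), np.float32)
        r2[0, 1] = r2[1, 0] = 0.8
        r2[2, 3] = r2[3, 2] = 0.5
        r2[0, 2] = r2[2, 0] = 0.2
        tree = build_merger_tree(_ld_from_matrix(r2))
        counts = [tree.components_at(t) for t in (0.9, 0.7, 0.4, 0.1)]
        assert counts == sorted(counts, reverse=True)  # components only coalesce


def _structured_tree(n_background=40, seed=0):
    """One 8-locus clique at r2=0.9 over a noisy background."""
    rng = np.random.default_rng(seed)
    p = 8 + n_background
    r2 = (rng.uniform(0, 0.18, (p, p))).astype(np.float32)
    r2 = (r2 + r2.T) / 2
    r2[:8, :8] = 0.9
    np.fill_diagonal(r2, 0.0)
    positions = np.concatenate([(np.arange(8) + 1) * 1000,
                                50_000 + (np.arange(n_background) + 1) * 1000])
    return build_merger_tree(_ld_from_matrix(r2, positions))


class TestExtraction:
    def test_dominant_cluster_extracted_as_soc(self):
        tree = _structured_tree()
        params = LDnaParams(e_min=5, phi=2.0, min_cluster_loci=5)
        ocs = extract_ocs(tree, params)
        socs = [c for c in ocs if c.soc]
        assert len(socs) >= 1
        best = max(ocs, key=lambda c: c.lam)
        assert best.soc and best.n_loci == 8
        assert set(best.snp_ids) == {f"s{i}" for i in range(8)}

    def test_equal_lambdas_extract_nothing(self):
        # every merger identical -> MAD and std both 0 -> no OCs
        r2 = np.zeros((10, 10), np.float32)
        for a in range(0, 10, 2):
            r2[a, a + 1] = r2[a + 1, a] = 0.9
        tree = build_merger_tree(_ld_from_matrix(r2))
        assert extract_ocs(tree, LDnaParams(e_min=1, phi=2.0)) == []

    def test_fewer_than_five_lambdas_warns_and_returns_empty(self):
        tree = _toy_tree()
        with pytest.warns(UserWarning):
            assert extract_ocs(tree, LDnaParams(e_min=1, phi=2.0)) == []

    def test_nested_high_lambda_cluster_labeled_coc(self):
        tree = _structured_tree()
        params = LDnaParams(e_min=5, phi=2.0, min_cluster_loci=5)
        ocs = extract_ocs(tree, params)
        clique = {f"s{i}" for i in range(8)}
        outer = [c for c in ocs if set(c.snp_ids) > clique]
        assert all(not c.soc for c in outer)  # anything containing the SOC is a COC

    def test_select_phi_stable_dominant_cluster(self):
        tree = _structured_tree()
        phi = select_phi(tree, e_min=5, phi_start=2)
        assert phi >= 2

    def test_select_phi_empty_tree_returns_start(self):
        r2 = np.zeros((4, 4), np.float32)
        tree = build_merger_tree(_ld_from_matrix(r2))
        assert select_phi(tree, e_min=1, phi_start=2) == 2


class TestPostfilter:
    def _cluster(self, n_loci=53, median_r2=1.0, n_edges=1109, soc=True):
        pos = (np.arange(n_loci) + 1) * 10_000
        return LDCluster(
            chromosome="chrT", snp_ids=np.array([f"s{i}" for i in range(n_loci)]),
            positions=pos, n_loci=n_loci, n_edges=n_edges, lam=1.61,
            median_r2=median_r2, merge_threshold=0.5,
            span=(int(pos[0]), int(pos[-1])), soc=soc,
        )

    def test_small_cluster_dropped(self):
        kept = soc_postfilter([self._cluster(n_loci=29)], LDnaParams())
        assert kept == []

    def test_low_median_ld_dropped(self):
        kept = soc_postfilter([self._cluster(median_r2=0.29)], LDnaParams())
        assert kept == []

    def test_table1_shaped_cluster_retained(self):
        kept = soc_postfilter([self._cluster(n_loci=53, median_r2=1.0)], LDnaParams())
        assert len(kept) == 1

    def test_coc_never_retained(self):
        kept = soc_postfilter([self._cluster(soc=False)], LDnaParams())
        assert kept == []


class TestSocSpan:
    def _soc_with_gap(self):
        left = np.arange(1_000_000, 5_000_001, 1_000_000)
        right = np.arange(15_000_000, 20_000_001, 1_000_000)
        pos = np.concatenate([left, right])
        n = pos.size
        r2 = np.full((n, n), 0.8, np.float32)
        np.fill_diagonal(r2, 0.0)
        ld = _ld_from_matrix(r2, pos)
        soc = LDCluster("chrT", ld.snp_ids, pos, n, n * (n - 1) // 2, 5.0, 0.8,
                        0.5, (int(pos[0]), int(pos[-1])))
        return soc, ld

    def test_high_cross_gap_ld_excluded_from_span(self):
        soc, ld = self._soc_with_gap()
        out = soc_span(soc, ld, min_gap_bp=5_000_000, min_cross_gap_r2=0.5)
        assert out["raw_length"] == 19_000_000
        assert len(out["excluded_gaps"]) == 1
        assert out["adjusted_length"] == 9_000_000

    def test_small_gaps_keep_raw_span(self):
        soc, ld = self._soc_with_gap()
        out = soc_span(soc, ld, min_gap_bp=50_000_000)
        assert out["adjusted_length"] == out["raw_length"]
        assert out["excluded_gaps"] == []

    def test_low_cross_gap_ld_treated_as_genuine_extent(self):
        soc, ld = self._soc_with_gap()
        ld.r2[:5, 5:] = 0.1  # cross-gap LD low -> gap is real
        ld.r2[5:, :5] = 0.1
        out = soc_span(soc, ld, min_gap_bp=5_000_000, min_cross_gap_r2=0.5)
        assert out["adjusted_length"] == out["raw_length"]
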