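"""VCF round-trips, the filtering ladder, and neutral-set construction."""
import numpy as np
import pytest

from invscan import (FilterConfig, apply_filters, build_neutral_set, read_vcf,
                     simulate, write_vcf)
from invscan.simulate import SimConfig, write_sim

from helpers import greedy_prune_oracle, make_dataset

POPMAP6 = {f"a{i}": "A" for i in range(3)} | {f"b{i}": "B" for i in range(3)}


def _write_maps(tmp_path, popmap, ecotype):
    pm = tmp_path / "popmap.tsv"
    pm.write_text("".join(f"{s}\t{p}\n" for s, p in popmap.items()))
    ec = tmp_path / "ecotype.tsv"
    ec.write_text("".join(f"{p}\t{e}\n" for p, e in ecotype.items()))
    return pm, ec


class TestVcfIO:
    def test_hand_written_vcf_transcribes_exactly(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="x">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
            "chr1\t100\t.\tA\tT\t50\t.\t.\tGT\t0/0\t0/1\t1/1\n"
            "chr1\t200\t.\tG\tC\t60\t.\t.\tGT\t./.\t0/0\t0/1\n"
        )
        pm, ec = _write_maps(tmp_path, {"s1": "P", "s2": "P", "s3": "P"}, {"P": "ancestral"})
        ds = read_vcf(vcf, pm, ec)
        assert ds.genotypes.tolist() == [[0, -1], [1, 0], [2, 1]]
        assert ds.variants["pos"].tolist() == [100, 200]

    def test_multiallelic_record_skipped(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="x">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "chr1\t100\t.\tA\tT,G\t50\t.\t.\tGT\t0/1\n"
            "chr1\t200\t.\tG\tC\t60\t.\t.\tGT\t0/0\n"
        )
        pm, ec = _write_maps(tmp_path, {"s1": "P"}, {"P": "ancestral"})
        ds = read_vcf(vcf, pm, ec)
        assert ds.n_snps == 1
        assert ds.meta["skipped_records"] == 1

    def test_unknown_sample_raises_with_name(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="x">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tmystery\n"
            "chr1\t100\t.\tA\tT\t50\t.\t.\tGT\t0/0\n"
        )
        pm, ec = _write_maps(tmp_path, {"other": "P"}, {"P": "ancestral"})
        with pytest.raises(ValueError, match="mystery"):
            read_vcf(vcf, pm, ec)

    def test_simulator_vcf_round_trips(self, tmp_path):
        ds, truth = simulate(SimConfig(seed=5, n_neutral_snps=300,
                                       n_selected_snps=5, n_inversion_snps=30))
        paths = write_sim(ds, truth, tmp_path)
        back = read_vcf(paths["vcf"], paths["popmap"], paths["ecotype"])
        assert ds.equals(back)

    def test_round_trip_preserves_depth_and_missing(self, tmp_path):
        ds = make_dataset(
            [[0, 1], [2, -1], [1, 0]],
            popmap={"s1": "P", "s2": "P", "s3": "P"},
            depth=[[10, 8], [6, -1], [30, 9]],
            gq=[[99, 40], [50, -1], [60, 20]],
        )
        path = write_vcf(ds, tmp_path / "out.vcf")
        pm, ec = _write_maps(tmp_path, ds.popmap, ds.ecotype)
        back = read_vcf(path, pm, ec)
        assert ds.equals(back)
        assert np.array_equal(ds.depth, back.depth)
        assert np.array_equal(ds.gq, back.gq)

    def test_empty_variant_set_writes_header_only(self, tmp_path):
        ds = make_dataset(np.zeros((2, 0)), popmap={"s1": "P", "s2": "P"})
        path = write_vcf(ds, tmp_path / "empty.vcf")
        lines = path.read_text().splitlines()
        assert lines[-1].startswith("#CHROM")

    def test_missing_genotype_written_as_dot_slash_dot(self, tmp_path):
        ds = make_dataset([[-1]], popmap={"s1": "P"})
        text = write_vcf(ds, tmp_path / "m.vcf").read_text()
        assert "./." in text


class TestFilters:
    def test_low_depth_genotypes_masked_and_attributed_to_depth(self):
        # 12 individuals in one population; one SNP has all DP=5 -> masked,
        # so its call rate collapses and it is removed under the depth rule.
        popmap = {f"s{i}": "P" for i in range(12)}
        gt = np.ones((12, 2), dtype=np.int8)
        depth = np.full((12, 2), 20)
        depth[:, 1] = 5
        ds = make_dataset(gt * [[0, 1]], popmap, depth=depth)
        filtered, report = apply_filters(ds, FilterConfig(min_global_maf=0.0, max_pop_ho=1.0))
        assert report.removed["depth_gq"] == 1
        assert filtered.n_snps == 1

    def test_high_heterozygosity_snp_removed(self):
        popmap = {f"s{i}": "P" for i in range(20)}
        gt = np.zeros((20, 2), dtype=np.int8)
        gt[:, 0] = 1          # Ho = 1.0 -> removed
        gt[:10, 1] = 1        # Ho = 0.5 -> kept (boundary is inclusive)
        ds = make_dataset(gt, popmap)
        filtered, report = apply_filters(
            ds, FilterConfig(min_individuals_per_pop=2, min_global_maf=0.0))
        assert report.removed["pop_heterozygosity"] == 1
        assert filtered.n_snps == 1

    def test_local_maf_rescues_low_global_maf(self):
        # global MAF 0.04 but 0.25 in one small population -> retained
        pops = {f"a{i}": "A" for i in range(40)} | {f"b{i}": "B" for i in range(10)}
        gt = np.zeros((50, 1), dtype=np.int8)
        gt[40:45, 0] = 1  # pop B alt freq 0.25; global 5/100
        ds = make_dataset(gt, pops)
        cfg = FilterConfig(min_individuals_per_pop=2, min_global_maf=0.06)
        filtered, report = apply_filters(ds, cfg)
        assert filtered.n_snps == 1
        assert report.n_rescued_local_maf == 1
        # without the rescue the SNP falls to the MAF criterion
        cfg2 = FilterConfig(min_individuals_per_pop=2, min_global_maf=0.06,
                            rescue_local_maf=0.5)
        _, report2 = apply_filters(ds, cfg2)
        assert report2.removed["maf"] == 1

    def test_idempotent_and_counts_partition_input(self, default_sim):
        ds, _ = default_sim
        filtered, report = apply_filters(ds)
        assert report.n_input == ds.n_snps
        assert sum(report.removed.values()) + report.n_retained == ds.n_snps
        refiltered, report2 = apply_filters(filtered)
        assert refiltered.n_snps == filtered.n_snps
        assert sum(report2.removed.values()) == 0

    def test_small_population_logs_warning(self, caplog):
        ds = make_dataset([[0, 1], [1, 2]], {"s1": "P", "s2": "P"})
        with caplog.at_level("WARNING"):
            filtered, report = apply_filters(ds, FilterConfig(min_individuals_per_pop=12))
        assert "smaller than min_individuals_per_pop" in caplog.text
        assert report.removed["call_rate"] == 2  # criterion still applied


class TestNeutralSet:
    def test_window_pruning_matches_greedy_oracle(self):
        positions = [100, 5_100, 20_100]
        popmap = {f"s{i}": "P" for i in range(4)}
        gt = np.tile([0, 1, 2], (4, 1)).astype(np.int8)
        ds = make_dataset(gt, popmap, pos=positions)
        pruned = build_neutral_set(ds, set(), [], prune_window=10_000)
        assert pruned.variants["pos"].tolist() == greedy_prune_oracle(positions, 10_000)
        assert pruned.variants["pos"].tolist() == [100, 20_100]

    def test_random_positions_match_oracle_and_one_per_window(self, rng):
        positions = np.sort(rng.choice(10_000_000, size=300, replace=False)) + 1
        popmap = {f"s{i}": "P" for i in range(2)}
        gt = rng.integers(0, 3, size=(2, 300)).astype(np.int8)
        ds = make_dataset(gt, popmap, pos=positions)
        pruned = build_neutral_set(ds, set(), [], prune_window=10_000)
        assert pruned.variants["pos"].tolist() == greedy_prune_oracle(positions, 10_000)
        w = (pruned.variants["pos"].to_numpy() - 1) // 10_000
        assert len(np.unique(w)) == len(w)

    def test_all_outliers_or_all_in_region_error(self):
        ds = make_dataset([[0, 1], [1, 2]], {"s1": "P", "s2": "P"})
        with pytest.raises(ValueError):
            build_neutral_set(ds, set(ds.snp_ids), [])
        with pytest.raises(ValueError):
            build_neutral_set(ds, set(), [("chr1", 0, 10_000_000)])

    def test_outliers_and_regions_excluded(self, default_sim):
        ds, truth = default_sim
        chrom, s, e = truth.inversion
        neutral = build_neutral_set(ds, set(truth.selected_ids), [(chrom, s, e)])
        assert not set(truth.selected_ids) & set(neutral.snp_ids)
        v = neutral.variants
        inside = (v["chrom"] == chrom) & (v["pos"] - 1 >= s) & (v["pos"] - 1 < e)
        assert not inside.any()
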