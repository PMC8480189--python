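"""End-to-end orchestration: filter -> stats -> scans -> intersection -> FWA
-> LD network -> karyotyping -> classification, with file outputs and a run
manifest.

Each stage is a thin call into the library modules, so any stage can be rerun
in isolation; :func:`run_all` wires them together, collects the per-stage
tables, and (optionally) writes every table plus a machine-readable manifest
(package version, config hash, seed) to an output directory.  A stage failure
aborts with the stage name; partial outputs written so far are retained.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genotypes import (FilterConfig, FilterReport, GenotypeDataset,
                        apply_filters, build_neutral_set, read_vcf)
from .karyotypes import (assign_karyotypes, classify_soc_cause, inversion_fst,
                         karyotype_frequencies)
from .ldna import (LDCluster, LDnaParams, build_merger_tree, extract_ocs,
                   ld_r2, select_phi, soc_postfilter, soc_span)
from .outliers import (ScanConfig, assign_fwa, fet_scan, fwa_summary,
                       intersect_candidates, pca_outlier_scan)
from .popstats import allele_freq, het_stats, neighbor_coverage, pairwise_fst_matrix
from .simulate import SimConfig, TruthSet, simulate

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "PipelineResult", "run_all"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Configuration of a full run; exactly one of VCF paths / simulate."""

    vcf: str | None = None
    popmap: str | None = None
    ecotype: str | None = None
    sim: SimConfig | None = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    ldna: LDnaParams = field(default_factory=LDnaParams)
    karyotype_delta: float = 0.5
    neighbor_d: int = 10_000
    prune_window: int = 10_000
    min_gap_bp: int = 5_000_000
    min_cross_gap_r2: float = 0.5
    fst_permutations: int = 0
    outdir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        has_files = self.vcf is not None
        if has_files and (self.popmap is None or self.ecotype is None):
            raise ValueError("vcf input requires popmap and ecotype paths")
        if has_files == (self.sim is not None):
            raise ValueError("exactly one of (vcf, popmap, ecotype) or sim must be given")
        self.filters.validate()
        self.scan.validate()
        self.ldna.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "sim" in kwargs and kwargs["sim"] is not None:
            kwargs["sim"] = SimConfig(**kwargs["sim"])
        for key, klass in (("filters", FilterConfig), ("scan", ScanConfig),
                           ("ldna", LDnaParams)):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = klass(**kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d.get("ldna", {}).get("threshold_grid") is not None:
            d["ldna"]["threshold_grid"] = list(map(float, d["ldna"]["threshold_grid"]))
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    """All stage outputs of one run plus the summary and manifest."""

    dataset: GenotypeDataset
    truth: TruthSet | None
    filter_report: FilterReport
    het: pd.DataFrame
    scans: dict[str, pd.DataFrame]
    candidates: list[str]
    fwa_table: pd.DataFrame | None
    fwa_stats: dict | None
    socs: list[LDCluster]
    soc_table: pd.DataFrame
    soc_spans: dict[str, dict]
    karyotypes: dict[str, object]
    arrangement_freqs: dict[str, pd.DataFrame]
    classifications: dict[str, str]
    inversion_fst: dict[str, pd.DataFrame]
    fst_matrix: pd.DataFrame | None
    neutral_ids: list[str]
    summary: dict
    manifest: dict


def _soc_id(soc: LDCluster, index: int) -> str:
    return f"{soc.chromosome}_soc{index + 1}"


def run_all(config: PipelineConfig) -> PipelineResult:
    """Run the complete analysis chain described by ``config``."""
    config.validate()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    timings: dict[str, float] = {}

    def stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    logger.error("stage %s: failed (%s)", name, exc)
                    raise PipelineError(name, exc) from exc
                logger.info("stage %s: done in %.2fs", name, timings[name])
                return False
        return _Ctx()

    truth: TruthSet | None = None
    with stage("load"):
        if config.sim is not None:
            sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
            dataset, truth = simulate(sim_cfg)
        else:
            dataset = read_vcf(config.vcf, config.popmap, config.ecotype)
        anc = dataset.ancestral_populations()
        derived = dataset.derived_populations()
        if len(anc) != 1 or not derived:
            raise ValueError("need exactly one ancestral and >=1 derived population")
        ancestral = anc[0]

    with stage("filter"):
        filtered, report = apply_filters(dataset, config.filters)
        if outdir:
            report.to_frame().to_csv(outdir / "filter_report.tsv", sep="\t", index=False)

    with stage("stats"):
        het_rows = []
        for pop in filtered.populations:
            h = het_stats(filtered, pop)
            het_rows.append({"population": pop, "mean_Ho": h.mean_ho, "mean_He": h.mean_he})
        het = pd.DataFrame(het_rows)
        pos_by_chrom = {
            c: sub["pos"].to_numpy()
            for c, sub in filtered.variants.groupby("chrom", sort=False)
        }
        nn_frac, coverage = neighbor_coverage(pos_by_chrom, config.neighbor_d)
        if outdir:
            het.to_csv(outdir / "het_stats.tsv", sep="\t", index=False)

    with stage("scan"):
        flags: dict[tuple[str, str], pd.Series] = {}
        scans: dict[str, pd.DataFrame] = {}
        ids = filtered.snp_ids
        for pop in derived:
            pair = f"{pop}_vs_{ancestral}"
            p_fet = fet_scan(filtered, pop, ancestral)
            sub = filtered.subset_populations([pop, ancestral])
            pca = pca_outlier_scan(sub, k=config.scan.pca_k,
                                   random_state=config.seed)
            neglog = -np.log10(np.maximum(p_fet.to_numpy(), 1e-300))
            flag_fet = pd.Series(neglog > config.scan.fet_neglogp_threshold, index=ids)
            flag_pca = pd.Series(
                pca.q.reindex(ids).to_numpy() <= config.scan.q_threshold, index=ids
            ).fillna(False)
            flags[("fet", pair)] = flag_fet
            flags[("pca", pair)] = flag_pca
            tab = pd.DataFrame({
                "snp_id": ids,
                "chrom": filtered.variants["chrom"],
                "pos": filtered.variants["pos"],
                "p_fet": p_fet.to_numpy(),
                "neglog10_p_fet": neglog,
                "D2": pca.d2.reindex(ids).to_numpy(),
                "p_pca": pca.p.reindex(ids).to_numpy(),
                "q_pca": pca.q.reindex(ids).to_numpy(),
                "outlier_fet": flag_fet.to_numpy(),
                "outlier_pca": flag_pca.to_numpy(),
            })
            scans[pair] = tab
            if outdir:
                tab.to_csv(outdir / f"scan_{pair}.tsv", sep="\t", index=False)
        candidates = intersect_candidates(flags)
        union_outliers = set()
        for s in flags.values():
            union_outliers |= set(np.asarray(ids)[s.to_numpy(bool)])
        if outdir:
            pd.DataFrame({"snp_id": candidates}).to_csv(
                outdir / "candidates.tsv", sep="\t", index=False)

    with stage("ldna"):
        socs: list[LDCluster] = []
        spans: dict[str, dict] = {}
        phi_used: dict[str, float] = {}
        ld_by_chrom = {}
        for chrom in filtered.variants["chrom"].unique():
            try:
                ld = ld_r2(filtered, chrom)
            except ValueError:
                continue
            ld_by_chrom[chrom] = ld
            tree = build_merger_tree(ld, merge_median=config.ldna.merge_median)
            phi = (config.ldna.phi if config.ldna.phi is not None
                   else select_phi(tree, e_min=config.ldna.e_min,
                                   phi_start=config.ldna.phi_start,
                                   phi_max=config.ldna.phi_max))
            phi_used[chrom] = phi
            params = dataclasses.replace(config.ldna, phi=float(phi))
            ocs = extract_ocs(tree, params)
            kept = soc_postfilter(ocs, params)
            for soc in kept:
                sid = _soc_id(soc, len(socs))
                spans[sid] = soc_span(soc, ld, config.min_gap_bp, config.min_cross_gap_r2)
                socs.append(soc)
        soc_rows = []
        for i, soc in enumerate(socs):
            sid = _soc_id(soc, i)
            soc_rows.append({
                "soc_id": sid, "chromosome": soc.chromosome, "type": "SOC",
                "nLoci": soc.n_loci, "nE": soc.n_edges, "lambda": soc.lam,
                "median_LD": soc.median_r2,
                "size_Mb": spans[sid]["adjusted_length"] / 1e6,
                "raw_size_Mb": spans[sid]["raw_length"] / 1e6,
                "n_excluded_gaps": len(spans[sid]["excluded_gaps"]),
                "phi": phi_used.get(soc.chromosome),
            })
        soc_table = pd.DataFrame(soc_rows)
        if outdir:
            soc_table.to_csv(outdir / "soc_table.tsv", sep="\t", index=False)
            for i, soc in enumerate(socs):
                sid = _soc_id(soc, i)
                with open(outdir / f"soc_{sid}.bed", "w") as fh:
                    for snp, p in zip(soc.snp_ids, soc.positions):
                        fh.write(f"{soc.chromosome}\t{p - 1}\t{p}\t{snp}\n")

    with stage("neutral"):
        regions = []
        for i, soc in enumerate(socs):
            sid = _soc_id(soc, i)
            s, e = spans[sid]["raw_span"]
            regions.append((soc.chromosome, s - 1, e))
        neutral = build_neutral_set(filtered, union_outliers, regions,
                                    prune_window=config.prune_window)
        neutral_ids = list(neutral.snp_ids)
        fst_matrix = pairwise_fst_matrix(filtered, neutral_ids)
        if outdir:
            fst_matrix.to_csv(outdir / "fst_matrix.tsv", sep="\t")

    with stage("fwa"):
        fwa_table = None
        fwa_stats = None
        if candidates:
            fwa_table = assign_fwa(filtered, candidates, ancestral, derived)
            f_anc = allele_freq(neutral, ancestral)
            neutral_maf = np.minimum(f_anc, 1 - f_anc)
            fwa_stats = fwa_summary(fwa_table, neutral_maf)
            if outdir:
                fwa_table.to_csv(outdir / "fwa_table.tsv", sep="\t", index=False)
                pd.Series(fwa_stats).to_csv(outdir / "fwa_summary.tsv", sep="\t")

    with stage("karyotype"):
        karyos: dict[str, object] = {}
        freqs: dict[str, pd.DataFrame] = {}
        classif: dict[str, str] = {}
        inv_fst: dict[str, pd.DataFrame] = {}
        for i, soc in enumerate(socs):
            sid = _soc_id(soc, i)
            assignment = assign_karyotypes(filtered, soc.snp_ids, soc_id=sid)
            karyos[sid] = assignment
            fr = karyotype_frequencies(assignment)
            freqs[sid] = fr
            if assignment.failed:
                classif[sid] = "unresolved (failed heterozygosity gate)"
                logger.warning("SOC %s failed karyotype validity: %s", sid, assignment.reason)
            else:
                classif[sid] = classify_soc_cause(fr, filtered.ecotype,
                                                  delta=config.karyotype_delta)
            inv_fst[sid] = inversion_fst(filtered, soc.snp_ids, neutral_ids,
                                         ancestral, derived)
            if outdir:
                assignment.table.to_csv(outdir / f"karyotypes_{sid}.tsv",
                                        sep="\t", index=False)
                fr.to_csv(outdir / f"arrangement_freqs_{sid}.tsv", sep="\t", index=False)
        if outdir and classif:
            pd.DataFrame(
                [{"soc_id": k, "classification": v} for k, v in classif.items()]
            ).to_csv(outdir / "soc_classification.tsv", sep="\t", index=False)

    with stage("summary"):
        n_outliers = {
            f"{m}:{pair}": int(s.sum()) for (m, pair), s in flags.items()
        }
        summary = {
            "n_samples": dataset.n_samples,
            "n_input_snps": dataset.n_snps,
            "n_retained_snps": filtered.n_snps,
            "mean_Ho": het["mean_Ho"].mean(),
            "mean_He": het["mean_He"].mean(),
            "nn_fraction_within_d": nn_frac,
            "coverage_bases": coverage,
            "outliers_per_scan": n_outliers,
            "n_candidates": len(candidates),
            "n_retained_socs": len(socs),
            "soc_classifications": classif,
            "n_neutral_snps": len(neutral_ids),
            "fwa": fwa_stats,
            "warnings": [f"{k}: {v.reason}" for k, v in karyos.items()
                         if getattr(v, "failed", False)],
        }
        manifest = {
            "package": "invscan",
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "config": config.to_dict(),
            "timings_s": timings,
        }
        if outdir:
            (outdir / "summary.json").write_text(
                json.dumps(summary, indent=1, default=str))
            (outdir / "manifest.json").write_text(
                json.dumps(manifest, indent=1, default=str))

    return PipelineResult(
        dataset=dataset, truth=truth, filter_report=report, het=het,
        scans=scans, candidates=candidates, fwa_table=fwa_table,
        fwa_stats=fwa_stats, socs=socs, soc_table=soc_table, soc_spans=spans,
        karyotypes=karyos, arrangement_freqs=freqs, classifications=classif,
        inversion_fst=inv_fst, fst_matrix=fst_matrix, neutral_ids=neutral_ids,
        summary=summary, manifest=manifest,
    )
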