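"""Genotype matrices, VCF and metadata I/O, SNP filtering, and neutral-set construction.

The central container is :class:`GenotypeDataset`: a samples x SNPs matrix of
diploid allele dosages (0 = hom ref, 1 = het, 2 = hom alt, -1 = missing) with
per-variant metadata (chromosome, 1-based position, alleles, site quality) and
optional per-genotype depth (DP) and genotype quality (GQ).  The sample ->
population map and the population -> ecotype (ancestral / derived) map travel
with the matrix so every downstream stage can group individuals.

Coordinates are 1-based in VCF and in ``variants["pos"]``; every interval used
internally (inversion regions, pruning windows, BED output) is 0-based
half-open.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeDataset",
    "FilterConfig",
    "FilterReport",
    "read_popmap",
    "read_ecotype",
    "read_vcf",
    "write_vcf",
    "apply_filters",
    "build_neutral_set",
]


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------

@dataclass
class GenotypeDataset:
    """Diploid biallelic SNP genotypes for a set of populations.

    Attributes
    ----------
    genotypes:
        ``(n_samples, n_snps)`` int8 array of alt-allele dosages in
        ``{0, 1, 2}`` with ``-1`` for missing calls.
    variants:
        One row per SNP with columns ``chrom, pos, id, ref, alt, qual``;
        ``pos`` is 1-based, rows sorted by (chrom, pos) and strictly
        increasing within a chromosome.
    samples:
        Ordered sample ids, matching the genotype rows.
    popmap:
        sample id -> population label; every sample must be present.
    ecotype:
        population -> ``"ancestral"`` or ``"derived"``.
    depth, gq:
        Optional ``(n_samples, n_snps)`` arrays of per-genotype DP / GQ
        (``-1`` where the VCF carried no value).
    """

    genotypes: np.ndarray
    variants: pd.DataFrame
    samples: list[str]
    popmap: dict[str, str]
    ecotype: dict[str, str]
    depth: np.ndarray | None = None
    gq: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    # -- basic views --------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.variants["id"].to_numpy()

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.popmap[s], None)
        return list(seen)

    def pop_indices(self, population: str) -> np.ndarray:
        """Row indices of the samples belonging to ``population``."""
        idx = np.array(
            [i for i, s in enumerate(self.samples) if self.popmap[s] == population],
            dtype=int,
        )
        if idx.size == 0:
            raise KeyError(f"unknown or empty population: {population!r}")
        return idx

    def ancestral_populations(self) -> list[str]:
        return [p for p in self.populations if self.ecotype.get(p) == "ancestral"]

    def derived_populations(self) -> list[str]:
        return [p for p in self.populations if self.ecotype.get(p) == "derived"]

    # -- subsetting ---------------------------------------------------------

    def take_snps(self, index: np.ndarray) -> "GenotypeDataset":
        """Subset to SNP columns given by boolean mask or integer index."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            genotypes=self.genotypes[:, index],
            variants=self.variants.iloc[index].reset_index(drop=True),
            depth=None if self.depth is None else self.depth[:, index],
            gq=None if self.gq is None else self.gq[:, index],
        )

    def take_samples(self, index: Sequence[int]) -> "GenotypeDataset":
        index = np.asarray(index, dtype=int)
        samples = [self.samples[i] for i in index]
        return replace(
            self,
            genotypes=self.genotypes[index],
            samples=samples,
            depth=None if self.depth is None else self.depth[index],
            gq=None if self.gq is None else self.gq[index],
        )

    def subset_populations(self, populations: Iterable[str]) -> "GenotypeDataset":
        keep = set(populations)
        idx = [i for i, s in enumerate(self.samples) if self.popmap[s] in keep]
        return self.take_samples(idx)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Check the container invariants; raise ``ValueError`` on violation."""
        n, p = self.genotypes.shape
        if len(self.samples) != n:
            raise ValueError("sample list does not match genotype rows")
        if len(self.variants) != p:
            raise ValueError("variant table does not match genotype columns")
        missing_pop = [s for s in self.samples if s not in self.popmap]
        if missing_pop:
            raise ValueError(f"samples without population: {missing_pop[:5]}")
        g = self.genotypes
        if g.size and not np.isin(np.unique(g), [-1, 0, 2, 1]).all():
            raise ValueError("genotype codes outside {-1, 0, 1, 2}")
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    def equals(self, other: "GenotypeDataset") -> bool:
        same_gt = np.array_equal(self.genotypes, other.genotypes)
        same_var = self.variants[["chrom", "pos", "ref", "alt"]].equals(
            other.variants[["chrom", "pos", "ref", "alt"]]
        )
        return same_gt and same_var and self.samples == other.samples


# ---------------------------------------------------------------------------
# metadata I/O
# ---------------------------------------------------------------------------

def read_popmap(path: str | Path) -> dict[str, str]:
    """Read a two-column sample<TAB>population map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"], dtype=str)
    return dict(zip(df["sample"], df["population"]))


def read_ecotype(path: str | Path) -> dict[str, str]:
    """Read a two-column population<TAB>{ancestral|derived} map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["population", "ecotype"], dtype=str)
    bad = sorted(set(df["ecotype"]) - {"ancestral", "derived"})
    if bad:
        raise ValueError(f"ecotype labels must be ancestral/derived, got {bad}")
    return dict(zip(df["population"], df["ecotype"]))


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    popmap_path: str | Path,
    ecotype_path: str | Path,
) -> GenotypeDataset:
    """Read diploid biallelic SNPs from a VCF into a :class:`GenotypeDataset`.

    Multi-allelic records and non-SNP records (indels, symbolic alleles) are
    skipped; the skip count is logged and stored in ``dataset.meta``.
    Missing genotypes are coded ``-1``; per-genotype DP and GQ are captured
    when the VCF carries those FORMAT fields.
    """
    popmap = read_popmap(popmap_path)
    ecotype = read_ecotype(ecotype_path)

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in popmap]
    if unknown:
        raise ValueError(f"VCF sample(s) not in popmap: {', '.join(unknown)}")

    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    code = np.array([0, 1, MISSING, 2], dtype=np.int8)

    gts: list[np.ndarray] = []
    dps: list[np.ndarray] = []
    gqs: list[np.ndarray] = []
    rows = []
    n_skipped = 0
    any_dp = any_gq = False
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            n_skipped += 1
            continue
        gts.append(code[np.asarray(v.gt_types)])
        dp = _format_field(v, "DP", len(samples))
        gq = _format_field(v, "GQ", len(samples))
        any_dp |= dp is not None
        any_gq |= gq is not None
        dps.append(dp)
        gqs.append(gq)
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        rows.append((v.CHROM, v.POS, vid, v.REF, v.ALT[0],
                     float(v.QUAL) if v.QUAL is not None else np.nan))
    if n_skipped:
        logger.info("read_vcf: skipped %d multi-allelic/non-SNP records", n_skipped)

    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt", "qual"])
    genotypes = (
        np.array(gts, dtype=np.int8).T if gts else np.zeros((len(samples), 0), np.int8)
    )

    def stack(cols: list, present: bool) -> np.ndarray | None:
        if not present or not cols:
            return None
        filled = [c if c is not None else np.full(len(samples), -1, np.int32) for c in cols]
        return np.array(filled, dtype=np.int32).T

    ds = GenotypeDataset(
        genotypes=genotypes,
        variants=variants,
        samples=samples,
        popmap=popmap,
        ecotype=ecotype,
        depth=stack(dps, any_dp),
        gq=stack(gqs, any_gq),
        meta={"skipped_records": n_skipped, "source": str(path)},
    )
    ds = _sort_variants(ds)
    ds.validate()
    return ds


def _format_field(variant, key: str, n: int) -> np.ndarray | None:
    try:
        arr = variant.format(key)
    except KeyError:
        return None
    if arr is None:
        return None
    arr = np.asarray(arr).reshape(n, -1)[:, 0]
    arr = np.where(np.isfinite(arr.astype(float)), arr, -1)
    out = arr.astype(np.int32)
    out[out < 0] = -1
    return out


def _sort_variants(ds: GenotypeDataset) -> GenotypeDataset:
    order = np.lexsort((ds.variants["pos"].to_numpy(), ds.variants["chrom"].to_numpy()))
    if np.array_equal(order, np.arange(len(order))):
        return ds
    return ds.take_snps(order)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(dataset: GenotypeDataset, path: str | Path) -> Path:
    """Write the dataset as a minimal VCF 4.2 file.

    The emitted file round-trips: ``read_vcf(write_vcf(d)) == d`` for valid
    datasets, including DP/GQ when present.
    """
    path = Path(path)
    has_dp = dataset.depth is not None
    has_gq = dataset.gq is not None
    fmt_keys = ["GT"] + (["DP"] if has_dp else []) + (["GQ"] if has_gq else [])
    fmt = ":".join(fmt_keys)

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=invscan\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if has_gq:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        for chrom in dataset.variants["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(dataset.samples) + "\n")

        gt = dataset.genotypes
        for j, row in enumerate(dataset.variants.itertuples(index=False)):
            qual = "." if pd.isna(row.qual) else f"{row.qual:g}"
            fields = [row.chrom, str(row.pos), row.id, row.ref, row.alt, qual, ".", ".", fmt]
            for i in range(dataset.n_samples):
                cell = [_GT_STR[int(gt[i, j])]]
                if has_dp:
                    d = int(dataset.depth[i, j])
                    cell.append("." if d < 0 else str(d))
                if has_gq:
                    q = int(dataset.gq[i, j])
                    cell.append("." if q < 0 else str(q))
                fields.append(":".join(cell))
            fh.write("\t".join(fields) + "\n")
    return path


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterConfig:
    """Thresholds of the six-step SNP filtering ladder.

    Order of application: per-genotype DP/GQ masking, then per-SNP
    (1) called in at least ``min_individuals_per_pop`` individuals in every
    population, (2) site quality, (3) per-population observed heterozygosity,
    (4) global MAF with a local-MAF rescue.
    """

    min_individuals_per_pop: int = 12
    min_depth: int = 6
    min_site_quality: float = 30.0
    min_genotype_quality: float = 15.0
    max_pop_ho: float = 0.5
    min_global_maf: float = 0.05
    rescue_local_maf: float = 0.2

    def validate(self) -> None:
        for name in ("max_pop_ho", "min_global_maf", "rescue_local_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_individuals_per_pop < 1 or self.min_depth < 0:
            raise ValueError("counts must be positive")


@dataclass
class FilterReport:
    """Removal accounting for :func:`apply_filters`.

    ``removed`` attributes each dropped SNP to the first criterion it failed,
    in the order call_rate -> depth_gq (call rate reached only because of
    DP/GQ-masked genotypes) -> site_quality -> pop_heterozygosity -> maf.
    """

    n_input: int
    removed: dict[str, int]
    retained_ids: list[str]
    n_masked_genotypes: int = 0
    n_rescued_local_maf: int = 0

    @property
    def n_retained(self) -> int:
        return len(self.retained_ids)

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input)]
        rows += [(f"removed_{k}", v) for k, v in self.removed.items()]
        rows += [
            ("retained", self.n_retained),
            ("masked_genotypes", self.n_masked_genotypes),
            ("rescued_local_maf", self.n_rescued_local_maf),
        ]
        return pd.DataFrame(rows, columns=["criterion", "count"])


def apply_filters(
    dataset: GenotypeDataset, cfg: FilterConfig | None = None
) -> tuple[GenotypeDataset, FilterReport]:
    """Apply the SNP filtering ladder and report per-criterion removals.

    Genotypes with DP below ``cfg.min_depth`` or GQ below
    ``cfg.min_genotype_quality`` are first set to missing (when the dataset
    carries DP/GQ); the per-population call-rate criterion is applied to the
    masked matrix.  Retained SNPs pass call rate, site quality and
    heterozygosity, and either the global-MAF criterion or the local-MAF
    rescue.
    """
    cfg = cfg or FilterConfig()
    cfg.validate()
    if not dataset.populations:
        raise ValueError("dataset has no populations")

    pops = dataset.populations
    pop_idx = {p: dataset.pop_indices(p) for p in pops}
    small = [p for p in pops if len(pop_idx[p]) < cfg.min_individuals_per_pop]
    if small:
        logger.warning(
            "population(s) smaller than min_individuals_per_pop=%d: %s "
            "(call-rate criterion cannot be satisfied there)",
            cfg.min_individuals_per_pop, ", ".join(small),
        )

    gt_pre = dataset.genotypes
    gt = gt_pre.copy()
    n_masked = 0
    if dataset.depth is not None:
        mask = (dataset.depth >= 0) & (dataset.depth < cfg.min_depth) & (gt != MISSING)
        n_masked += int(mask.sum())
        gt[mask] = MISSING
    if dataset.gq is not None:
        mask = (dataset.gq >= 0) & (dataset.gq < cfg.min_genotype_quality) & (gt != MISSING)
        n_masked += int(mask.sum())
        gt[mask] = MISSING

    called_pre = {p: (gt_pre[pop_idx[p]] != MISSING).sum(axis=0) for p in pops}
    called_post = {p: (gt[pop_idx[p]] != MISSING).sum(axis=0) for p in pops}

    fail_rate_pre = np.zeros(dataset.n_snps, bool)
    fail_rate_post = np.zeros(dataset.n_snps, bool)
    for p in pops:
        fail_rate_pre |= called_pre[p] < cfg.min_individuals_per_pop
        fail_rate_post |= called_post[p] < cfg.min_individuals_per_pop

    qual = dataset.variants["qual"].to_numpy(float)
    fail_qual = np.isfinite(qual) & (qual < cfg.min_site_quality)

    fail_ho = np.zeros(dataset.n_snps, bool)
    for p in pops:
        sub = gt[pop_idx[p]]
        called = (sub != MISSING).sum(axis=0)
        het = (sub == 1).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ho = np.where(called > 0, het / np.maximum(called, 1), 0.0)
        fail_ho |= ho > cfg.max_pop_ho

    called_all = (gt != MISSING).sum(axis=0)
    alt_all = np.where(gt == MISSING, 0, gt).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(called_all > 0, alt_all / np.maximum(2 * called_all, 1), np.nan)
    gmaf = np.minimum(freq, 1 - freq)
    fail_gmaf = ~(gmaf >= cfg.min_global_maf)  # NaN freq counts as failing

    rescue = np.zeros(dataset.n_snps, bool)
    for p in pops:
        sub = gt[pop_idx[p]]
        c = (sub != MISSING).sum(axis=0)
        a = np.where(sub == MISSING, 0, sub).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(c > 0, a / np.maximum(2 * c, 1), np.nan)
        lmaf = np.minimum(f, 1 - f)
        rescue |= lmaf >= cfg.rescue_local_maf
    fail_maf = fail_gmaf & ~rescue

    # first-failure attribution
    removed = {}
    remaining = np.ones(dataset.n_snps, bool)
    for name, fail in [
        ("call_rate", fail_rate_pre),
        ("depth_gq", fail_rate_post),
        ("site_quality", fail_qual),
        ("pop_heterozygosity", fail_ho),
        ("maf", fail_maf),
    ]:
        hit = remaining & fail
        removed[name] = int(hit.sum())
        remaining &= ~hit

    report = FilterReport(
        n_input=dataset.n_snps,
        removed=removed,
        retained_ids=list(dataset.snp_ids[remaining]),
        n_masked_genotypes=n_masked,
        n_rescued_local_maf=int((remaining & fail_gmaf & rescue).sum()),
    )
    filtered = replace(dataset, genotypes=gt).take_snps(remaining)
    return filtered, report


# ---------------------------------------------------------------------------
# neutral, LD-pruned set
# ---------------------------------------------------------------------------

def build_neutral_set(
    dataset: GenotypeDataset,
    outlier_ids: set[str] | Iterable[str],
    inversion_regions: Sequence[tuple[str, int, int]] = (),
    prune_window: int = 10_000,
) -> GenotypeDataset:
    """Build the neutral, LD-pruned SNP set.

    Removes every SNP flagged as an outlier by either scan in any population
    pair, every SNP inside an inversion region (0-based half-open intervals),
    and thins the remainder to one SNP per ``prune_window`` bp window
    (window id = 0-based position // window; the first SNP in each window is
    kept).
    """
    outlier_ids = set(outlier_ids)
    keep = ~np.isin(dataset.snp_ids, list(outlier_ids))

    chroms = dataset.variants["chrom"].to_numpy()
    pos0 = dataset.variants["pos"].to_numpy() - 1
    for chrom, start, end in inversion_regions:
        keep &= ~((chroms == chrom) & (pos0 >= start) & (pos0 < end))

    window = pos0 // prune_window
    kept_idx = []
    seen: set[tuple[str, int]] = set()
    for j in np.flatnonzero(keep):
        key = (chroms[j], int(window[j]))
        if key not in seen:
            seen.add(key)
            kept_idx.append(j)
    if not kept_idx:
        raise ValueError(
            "neutral set is empty; all SNPs are outliers or inside inversion "
            "regions — consider a smaller prune_window or fewer exclusions"
        )
    return dataset.take_snps(np.array(kept_idx))
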