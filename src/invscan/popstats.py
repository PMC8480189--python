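"""Allele frequencies, heterozygosities, Weir–Cockerham FST, Welch t, spacing.

All statistics are computed over called genotypes only; per-SNP quantities
with no usable data are NaN.  The multi-locus FST is the Weir & Cockerham
(1984) theta with per-locus variance components combined as a ratio of sums.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)

__all__ = [
    "HetStats", "FstResult",
    "allele_freq", "het_stats", "individual_het",
    "wc_fst", "pairwise_fst_matrix", "fst_permutation_test", "by_adjust",
    "welch_t", "neighbor_coverage",
]


def _called_counts(gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP (called diploid count, alt allele count) for a genotype block."""
    called = (gt != MISSING).sum(axis=0)
    alt = np.where(gt == MISSING, 0, gt).sum(axis=0)
    return called, alt


def allele_freq(dataset: GenotypeDataset, population: str) -> np.ndarray:
    """Per-SNP alt-allele frequency in one population (NaN if all missing)."""
    gt = dataset.genotypes[dataset.pop_indices(population)]
    called, alt = _called_counts(gt)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(called > 0, alt / np.maximum(2 * called, 1), np.nan)


@dataclass
class HetStats:
    """Observed and (unbiased) expected heterozygosity for one population."""

    population: str
    ho: np.ndarray  # per-SNP observed heterozygosity
    he: np.ndarray  # per-SNP unbiased expected heterozygosity
    mean_ho: float
    mean_he: float


def het_stats(dataset: GenotypeDataset, population: str) -> HetStats:
    """Per-SNP and mean H_O / H_E for one population.

    H_O is the fraction of heterozygous calls among called genotypes; H_E is
    2p(1-p) with the small-sample correction n/(n-1), n = called individuals.
    """
    idx = dataset.pop_indices(population)
    gt = dataset.genotypes[idx]
    called = (gt != MISSING).sum(axis=0).astype(float)
    het = (gt == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(called > 0, het / np.maximum(called, 1), np.nan)
        p = np.where(called > 0,
                     np.where(gt == MISSING, 0, gt).sum(axis=0) / np.maximum(2 * called, 1),
                     np.nan)
        corr = np.where(called > 1, called / np.maximum(called - 1, 1), 1.0)
        he = 2 * p * (1 - p) * corr
    return HetStats(
        population=population, ho=ho, he=he,
        mean_ho=float(np.nanmean(ho)), mean_he=float(np.nanmean(he)),
    )


def individual_het(dataset: GenotypeDataset, snp_ids: np.ndarray | list) -> pd.Series:
    """Per-sample heterozygosity over a SNP set: het calls / called genotypes.

    Samples with no called genotype in the region are NaN (and logged).
    """
    snp_ids = np.asarray(snp_ids)
    if snp_ids.size == 0:
        raise ValueError("snp_ids must be non-empty")
    cols = np.flatnonzero(np.isin(dataset.snp_ids, snp_ids))
    gt = dataset.genotypes[:, cols]
    called = (gt != MISSING).sum(axis=1)
    het = (gt == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(called > 0, het / np.maximum(called, 1), np.nan)
    n_undef = int((called == 0).sum())
    if n_undef:
        logger.warning("individual_het: %d sample(s) with no called genotypes", n_undef)
    return pd.Series(vals, index=dataset.samples, name="het")


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) theta
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    """Per-locus and multi-locus Weir–Cockerham theta for one population pair."""

    pop_a: str
    pop_b: str
    per_locus: np.ndarray  # theta per usable locus (NaN where skipped)
    theta: float  # ratio-of-sums multi-locus estimate
    n_loci: int  # usable loci


def _wc_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus a, b, c variance components for r populations.

    ``n``: (r, L) called diploid counts, ``p``: (r, L) allele frequencies,
    ``h``: (r, L) observed heterozygote proportions.
    """
    r = n.shape[0]
    nbar = n.mean(axis=0)
    nsum = n.sum(axis=0)
    nc = (nsum - (n ** 2).sum(axis=0) / nsum) / (r - 1)
    pbar = (n * p).sum(axis=0) / nsum
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n * h).sum(axis=0) / nsum

    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def wc_fst(
    dataset: GenotypeDataset,
    pop_a: str,
    pop_b: str,
    snp_ids: np.ndarray | list | None = None,
) -> FstResult:
    """Weir–Cockerham theta between two populations.

    Loci need at least two called individuals in each population; loci whose
    a+b+c denominator is zero (monomorphic across both samples) are skipped.
    The multi-locus theta is sum(a) / sum(a+b+c) over usable loci.
    """
    if snp_ids is not None:
        cols = np.flatnonzero(np.isin(dataset.snp_ids, np.asarray(snp_ids)))
    else:
        cols = np.arange(dataset.n_snps)
    blocks = []
    for pop in (pop_a, pop_b):
        gt = dataset.genotypes[np.ix_(dataset.pop_indices(pop), cols)]
        called, alt = _called_counts(gt)
        het = (gt == 1).sum(axis=0)
        blocks.append((called.astype(float), alt, het))

    n = np.stack([b[0] for b in blocks])
    usable = (n >= 2).all(axis=0)
    if not usable.any():
        raise ValueError("no loci with >=2 called individuals in both populations")
    n = n[:, usable]
    p = np.stack([b[1][usable] / (2 * b[0][usable]) for b in blocks])
    h = np.stack([b[2][usable] / b[0][usable] for b in blocks])

    a, b_, c = _wc_components(n, p, h)
    denom = a + b_ + c
    ok = denom != 0
    per_locus = np.full(cols.size, np.nan)
    tmp = np.full(usable.sum(), np.nan)
    tmp[ok] = a[ok] / denom[ok]
    per_locus[usable] = tmp
    if not ok.any():
        raise ValueError("no polymorphic loci usable for FST")
    theta = float(a[ok].sum() / denom[ok].sum())
    return FstResult(pop_a=pop_a, pop_b=pop_b, per_locus=per_locus,
                     theta=theta, n_loci=int(ok.sum()))


def pairwise_fst_matrix(
    dataset: GenotypeDataset, snp_ids: np.ndarray | list | None = None
) -> pd.DataFrame:
    """Symmetric matrix of multi-locus theta between all population pairs."""
    pops = dataset.populations
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            theta = wc_fst(dataset, a, b, snp_ids).theta
            mat.loc[a, b] = mat.loc[b, a] = theta
    return mat


def fst_permutation_test(
    dataset: GenotypeDataset,
    pop_a: str,
    pop_b: str,
    snp_ids: np.ndarray | list | None = None,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutation p-value for multi-locus theta.

    Individuals are shuffled between the two populations ``n_perm`` times;
    p = (1 + #{theta_perm >= theta_obs}) / (n_perm + 1).
    """
    rng = np.random.default_rng(seed)
    sub = dataset.subset_populations([pop_a, pop_b])
    obs = wc_fst(sub, pop_a, pop_b, snp_ids).theta
    labels = np.array([sub.popmap[s] for s in sub.samples])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        shuffled = dict(zip(sub.samples, perm))
        ds = GenotypeDataset(
            genotypes=sub.genotypes, variants=sub.variants, samples=sub.samples,
            popmap=shuffled, ecotype=sub.ecotype,
        )
        try:
            if wc_fst(ds, pop_a, pop_b, snp_ids).theta >= obs:
                count += 1
        except ValueError:
            continue
    return obs, (1 + count) / (n_perm + 1)


def by_adjust(pvals: np.ndarray | list) -> np.ndarray:
    """Benjamini–Yekutieli adjusted p-values (for the FST pair matrix)."""
    from statsmodels.stats.multitest import multipletests
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_by")[1]


# ---------------------------------------------------------------------------
# Welch t-test
# ---------------------------------------------------------------------------

def welch_t(x: np.ndarray | list, y: np.ndarray | list) -> tuple[float, float, float]:
    """Welch two-sample t-test: (t, Welch–Satterthwaite df, two-sided p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        raise ValueError("degenerate samples: zero variance, unequal means")
    sx, sy = vx / x.size, vy / y.size
    t = (x.mean() - y.mean()) / np.sqrt(sx + sy)
    df = (sx + sy) ** 2 / (sx ** 2 / (x.size - 1) + sy ** 2 / (y.size - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


# ---------------------------------------------------------------------------
# SNP spacing and genome coverage
# ---------------------------------------------------------------------------

def neighbor_coverage(
    positions_by_chrom: dict[str, np.ndarray], d: int
) -> tuple[float, int]:
    """Nearest-neighbour fraction and +-d bp coverage of a SNP panel.

    Returns ``(fraction of SNPs whose nearest same-chromosome neighbour is
    <= d bp away, total bases within d of any SNP)``.  Chromosomes with a
    single SNP contribute to coverage but are excluded from the fraction.
    Coverage is the union length of half-open intervals [p-d, p+d+1) clipped
    at zero, so d=0 counts one base per SNP.
    """
    n_near = 0
    n_tot = 0
    coverage = 0
    for chrom, pos in positions_by_chrom.items():
        pos = np.sort(np.asarray(pos, dtype=np.int64))
        if pos.size >= 2:
            gaps = np.diff(pos)
            nearest = np.minimum(
                np.concatenate([[gaps[0]], gaps]),
                np.concatenate([gaps, [gaps[-1]]]),
            )
            n_near += int((nearest <= d).sum())
            n_tot += pos.size
        starts = np.maximum(pos - d, 0)
        ends = pos + d + 1
        cur_s, cur_e = None, None
        for s, e in zip(starts, ends):
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    coverage += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            coverage += cur_e - cur_s
    frac = n_near / n_tot if n_tot else float("nan")
    return float(frac), int(coverage)
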