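"""Divergence-outlier scans, their all-pairs intersection, and the
freshwater-favoured-allele (FWA) table.

Two complementary scans per ancestral-derived population pair:

* Fisher's exact test on the 2x2 allele-count table (exact two-sided p by
  summing hypergeometric probabilities no larger than the observed table's);
* a PCA-based statistic in the style of pcadapt: genotypes are mean-imputed,
  scaled by sqrt(p(1-p)), regressed on the top-K principal components, and
  each SNP's vector of standardised regression coefficients is scored by a
  robust Mahalanobis distance, rescaled by a genomic inflation factor and
  referred to a chi-squared(K) distribution; q-values are Benjamini-Hochberg.

A SNP is a candidate when both methods flag it in every population pair.  The
FWA at a candidate SNP is the allele whose frequency increased in every
derived population relative to the ancestral one.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .genotypes import MISSING, GenotypeDataset
from .popstats import allele_freq, welch_t

logger = logging.getLogger(__name__)

__all__ = [
    "ScanConfig", "PcaScanResult", "fet_scan", "pca_outlier_scan", "bh_q",
    "intersect_candidates", "assign_fwa", "fwa_summary",
]


@dataclass
class ScanConfig:
    """Outlier-scan thresholds: FET -log10 p cutoff, PCA K, and FDR level."""

    fet_neglogp_threshold: float = 4.0
    pca_k: int = 2
    q_threshold: float = 0.1

    def validate(self) -> None:
        if self.fet_neglogp_threshold <= 0 or self.q_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.pca_k < 1:
            raise ValueError("pca_k must be >= 1")


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def fet_pvalues(
    alt_a: np.ndarray, n_chrom_a: np.ndarray, alt_b: np.ndarray, n_chrom_b: np.ndarray
) -> np.ndarray:
    """Vectorised exact two-sided Fisher p for per-SNP 2x2 allele tables.

    Table per SNP: rows = populations, columns = (alt, ref) allele counts with
    ``n_chrom_*`` called chromosomes.  Two-sided p sums all hypergeometric
    outcomes whose probability does not exceed the observed one (with the
    conventional (1+1e-7) tie tolerance).  Degenerate tables (zero margin)
    give p = 1.
    """
    alt_a = np.asarray(alt_a, np.int64)
    alt_b = np.asarray(alt_b, np.int64)
    n_a = np.asarray(n_chrom_a, np.int64)
    n_b = np.asarray(n_chrom_b, np.int64)
    n_tot = n_a + n_b
    lf = gammaln(np.arange(int(n_tot.max(initial=0)) + 2) + 1.0)  # lf[k] = log k!

    out = np.ones(alt_a.shape, float)
    for i in range(alt_a.size):
        na, nb = n_a[i], n_b[i]
        k_tot = alt_a[i] + alt_b[i]
        n = na + nb
        if na == 0 or nb == 0 or k_tot == 0 or k_tot == n:
            continue
        lo = max(0, k_tot - nb)
        hi = min(k_tot, na)
        ks = np.arange(lo, hi + 1)
        logpmf = (
            lf[k_tot] - lf[ks] - lf[k_tot - ks]
            + lf[n - k_tot] - lf[na - ks] - lf[n - k_tot - na + ks]
            + lf[na] + lf[n - na] - lf[n]
        )
        logpmf -= logpmf.max()
        pmf = np.exp(logpmf)
        obs = pmf[alt_a[i] - lo]
        out[i] = pmf[pmf <= obs * (1 + 1e-7)].sum() / pmf.sum()
    return out


def fet_scan(dataset: GenotypeDataset, pop_a: str, pop_b: str) -> pd.Series:
    """Per-SNP exact two-sided Fisher p for the allele-frequency difference.

    Allele counts use 2 x (called individuals) chromosomes per population.
    SNPs monomorphic in both populations (or without data) get p = 1.
    """
    counts = []
    for pop in (pop_a, pop_b):
        gt = dataset.genotypes[dataset.pop_indices(pop)]
        called = (gt != MISSING).sum(axis=0)
        alt = np.where(gt == MISSING, 0, gt).sum(axis=0)
        counts.append((alt, 2 * called))
    p = fet_pvalues(counts[0][0], counts[0][1], counts[1][0], counts[1][1])
    return pd.Series(p, index=dataset.snp_ids, name=f"p_fet_{pop_a}_{pop_b}")


# ---------------------------------------------------------------------------
# PCA outlier scan (pcadapt-style)
# ---------------------------------------------------------------------------

@dataclass
class PcaScanResult:
    """Per-SNP Mahalanobis D2, chi2 p and BH q (NaN for excluded SNPs)."""

    d2: pd.Series
    p: pd.Series
    q: pd.Series
    gif: float
    k: int
    n_excluded: int = 0
    scores: np.ndarray = field(default=None, repr=False)  # samples x K PCs


def pca_outlier_scan(
    dataset: GenotypeDataset,
    k: int = 2,
    mcd_min_snps: int = 500,
    random_state: int = 0,
) -> PcaScanResult:
    """pcadapt-style scan: D2 of standardised PC regression coefficients.

    Procedure: mean-impute missing genotypes; scale each SNP by
    sqrt(pbar(1-pbar)); take the top-``k`` PCs over samples; per SNP form the
    vector of regression coefficients of the (scaled) genotypes on the PCs
    divided by the residual standard error; score SNPs by Mahalanobis D2 of
    those vectors with a robustly estimated location/scatter
    (minimum-covariance-determinant when at least ``mcd_min_snps`` SNPs are
    usable, classical covariance otherwise); divide by the genomic inflation
    factor (median D2 over the chi2_k median); p from chi2_k, q by BH.
    """
    if dataset.n_samples < k + 2:
        raise ValueError(f"need at least K+2={k + 2} samples")
    gt = dataset.genotypes.astype(float)
    gt[dataset.genotypes == MISSING] = np.nan
    called = np.isfinite(gt).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(called > 0, np.nansum(gt, axis=0) / np.maximum(called, 1), np.nan)
    pbar = mean / 2.0
    scale = np.sqrt(pbar * (1 - pbar))
    usable = (called > 0) & (scale > 0)
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info("pca_outlier_scan: excluded %d undefined/zero-variance SNPs", n_excluded)

    x = gt[:, usable]
    inds = np.where(np.isnan(x))
    x[inds] = np.take(mean[usable], inds[1])
    x = (x - mean[usable]) / scale[usable]

    u, s, _ = np.linalg.svd(x, full_matrices=False)
    pcs = u[:, :k]  # orthonormal columns
    beta = pcs.T @ x  # (k, p) regression coefficients
    resid = x - pcs @ beta
    dof = max(x.shape[0] - k, 1)
    sigma = np.sqrt((resid ** 2).sum(axis=0) / dof)
    sigma[sigma == 0] = np.nan
    z = (beta / sigma).T  # (p, k)

    finite = np.isfinite(z).all(axis=1)
    zf = z[finite]
    if zf.shape[0] >= mcd_min_snps:
        from sklearn.covariance import MinCovDet
        mcd = MinCovDet(random_state=random_state).fit(zf)
        loc, cov = mcd.location_, mcd.covariance_
    else:
        loc = zf.mean(axis=0)
        cov = (np.cov(zf, rowvar=False).reshape(k, k)
               if zf.shape[0] > 1 else np.eye(k))
    if not np.all(np.isfinite(cov)):
        cov = np.eye(k)
    prec = np.linalg.pinv(cov)
    delta = z - loc
    d2 = np.einsum("ij,jk,ik->i", delta, prec, delta)

    gif = float(np.nanmedian(d2) / stats.chi2.median(df=k))
    if not np.isfinite(gif) or gif <= 0:
        gif = 1.0
    p = stats.chi2.sf(d2 / gif, df=k)

    ids = dataset.snp_ids
    d2_full = np.full(dataset.n_snps, np.nan)
    p_full = np.full(dataset.n_snps, np.nan)
    d2_full[usable] = d2
    p_full[usable] = p
    q_full = np.full(dataset.n_snps, np.nan)
    ok = np.isfinite(p_full)
    q_full[ok] = bh_q(p_full[ok])
    return PcaScanResult(
        d2=pd.Series(d2_full, index=ids, name="D2"),
        p=pd.Series(p_full, index=ids, name="p_pca"),
        q=pd.Series(q_full, index=ids, name="q_pca"),
        gif=gif, k=k, n_excluded=n_excluded, scores=pcs,
    )


def bh_q(pvals: np.ndarray | list) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone adjusted p)."""
    from statsmodels.stats.multitest import multipletests
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# intersection and FWA
# ---------------------------------------------------------------------------

def intersect_candidates(flags: dict[object, pd.Series]) -> list[str]:
    """SNP ids flagged in every (method, pair) entry of ``flags``.

    Each value is a boolean Series over the common SNP universe; the result
    preserves the SNP order of the first entry.
    """
    if not flags:
        return []
    series = list(flags.values())
    universe = series[0].index
    for s in series[1:]:
        if len(s.index) != len(universe) or not (s.index == universe).all():
            raise ValueError("flag series must share one SNP universe")
    combined = np.logical_and.reduce([s.to_numpy(bool) for s in series])
    return list(universe[combined])


def assign_fwa(
    dataset: GenotypeDataset,
    candidates: list[str],
    ancestral_pop: str,
    derived_pops: list[str],
) -> pd.DataFrame:
    """Assign the freshwater-favoured allele per candidate SNP.

    FWA = the allele (ref or alt) whose frequency is strictly higher in every
    derived population than in the ancestral one; SNPs without such an allele
    are "unassigned".  Returns one row per candidate with FWA identity,
    per-population FWA frequency, per-derived-population increment, and a
    standing-variation flag (FWA present in the ancestral population).
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    cols = np.isin(dataset.snp_ids, candidates)
    sub = dataset.take_snps(cols)
    freqs = {p: allele_freq(sub, p) for p in [ancestral_pop, *derived_pops]}

    rows = []
    for j, snp in enumerate(sub.snp_ids):
        fa = freqs[ancestral_pop][j]
        fd = np.array([freqs[p][j] for p in derived_pops])
        if np.isnan(fa) or np.isnan(fd).any():
            fwa = "unassigned"
        elif (fd > fa).all():
            fwa = "alt"
        elif (fd < fa).all():
            fwa = "ref"
        else:
            fwa = "unassigned"
        row = {"snp_id": snp, "fwa": fwa}
        for p in [ancestral_pop, *derived_pops]:
            f = freqs[p][j]
            row[f"freq_{p}"] = f if fwa != "ref" else 1 - f
        if fwa == "unassigned":
            for p in [ancestral_pop, *derived_pops]:
                row[f"freq_{p}"] = np.nan
        for p in derived_pops:
            row[f"increment_{p}"] = row[f"freq_{p}"] - row[f"freq_{ancestral_pop}"]
        row["standing_variation"] = (
            bool(row[f"freq_{ancestral_pop}"] > 0) if fwa != "unassigned" else False
        )
        rows.append(row)
    return pd.DataFrame(rows)


def fwa_summary(fwa_table: pd.DataFrame, neutral_maf: np.ndarray) -> dict:
    """Summarise an FWA table against the neutral-MAF background.

    Returns per-population mean FWA frequency and mean increment, the
    fraction of (SNP, derived population) shifts of at least 0.5, the
    standing-variation fraction, and the Welch t-test of ancestral FWA
    frequency against neutral minor-allele frequency.
    """
    if fwa_table.empty:
        raise ValueError("FWA table is empty")
    assigned = fwa_table[fwa_table["fwa"] != "unassigned"]
    freq_cols = [c for c in fwa_table.columns if c.startswith("freq_")]
    inc_cols = [c for c in fwa_table.columns if c.startswith("increment_")]
    anc_col = freq_cols[0]

    out: dict = {
        "n_candidates": int(len(fwa_table)),
        "n_assigned": int(len(assigned)),
        "frac_standing_variation": float(assigned["standing_variation"].mean())
        if len(assigned) else float("nan"),
    }
    for c in freq_cols:
        out[f"mean_{c}"] = float(assigned[c].mean()) if len(assigned) else float("nan")
    incs = assigned[inc_cols].to_numpy() if len(assigned) else np.empty((0, 0))
    for c in inc_cols:
        out[f"mean_{c}"] = float(assigned[c].mean()) if len(assigned) else float("nan")
    out["frac_increment_ge_0.5"] = (
        float((incs >= 0.5).mean()) if incs.size else float("nan")
    )
    neutral_maf = np.asarray(neutral_maf, float)
    neutral_maf = neutral_maf[np.isfinite(neutral_maf)]
    if len(assigned) >= 2 and neutral_maf.size >= 2:
        anc = assigned[anc_col].to_numpy()
        t, df, p = welch_t(anc, neutral_maf)
        out.update({"welch_t": t, "welch_df": df, "welch_p": p})
    return out
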