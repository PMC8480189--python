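"""Inversion karyotyping from SOC genotypes.

An inversion suppresses recombination in heterokaryotypes, so PCA over the
SNPs of an inversion-derived LD cluster separates individuals into three
groups along PC1 — the two homokaryotypes (AA, BB) at the extremes and the
heterokaryotypes (AB) in between, the latter with the highest heterozygosity.
Group assignment uses an exact 1-D k-means (dynamic programming, so it is
deterministic and globally optimal); orientation is anchored by the ancestral
population, whose majority group at one PC1 extreme is called AA.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeDataset
from .popstats import individual_het, wc_fst

logger = logging.getLogger(__name__)

__all__ = [
    "KaryotypeAssignment", "Kmeans1DResult",
    "region_pca", "kmeans_1d", "assign_karyotypes",
    "karyotype_frequencies", "inversion_fst", "classify_soc_cause",
]


# ---------------------------------------------------------------------------
# region PCA
# ---------------------------------------------------------------------------

def region_pca(dataset: GenotypeDataset, snp_ids: np.ndarray | list) -> pd.DataFrame:
    """Per-individual PC coordinates over a SOC's SNPs.

    Genotypes are mean-imputed and centred (not scaled); PC1's sign is fixed
    so the ancestral-population mean is negative, making the AA/BB orientation
    reproducible.  Individuals with no called genotype in the region are
    excluded (logged).
    """
    snp_ids = np.asarray(snp_ids)
    if snp_ids.size < 2:
        raise ValueError("need at least 2 SNPs for a region PCA")
    cols = np.flatnonzero(np.isin(dataset.snp_ids, snp_ids))
    gt = dataset.genotypes[:, cols].astype(float)
    gt[gt == MISSING] = np.nan

    keep_rows = np.isfinite(gt).any(axis=1)
    if (~keep_rows).any():
        dropped = [s for s, k in zip(dataset.samples, keep_rows) if not k]
        logger.warning("region_pca: excluded %d all-missing individuals: %s",
                       len(dropped), dropped[:5])
    gt = gt[keep_rows]
    samples = [s for s, k in zip(dataset.samples, keep_rows) if k]
    if len(samples) < 3:
        raise ValueError("need at least 3 individuals with data in the region")

    col_mean = np.nanmean(gt, axis=0)
    inds = np.where(np.isnan(gt))
    gt[inds] = np.take(col_mean, inds[1])
    x = gt - gt.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u * s  # principal-component coordinates

    anc_pops = {p for p, e in dataset.ecotype.items() if e == "ancestral"}
    anc_rows = [i for i, smp in enumerate(samples) if dataset.popmap[smp] in anc_pops]
    if anc_rows and scores[anc_rows, 0].mean() > 0:
        scores[:, 0] *= -1
    out = pd.DataFrame(scores[:, : min(4, scores.shape[1])],
                       index=samples,
                       columns=[f"PC{i + 1}" for i in range(min(4, scores.shape[1]))])
    return out


# ---------------------------------------------------------------------------
# exact 1-D k-means
# ---------------------------------------------------------------------------

@dataclass
class Kmeans1DResult:
    labels: np.ndarray  # group index per input value, ordered by group mean
    centers: np.ndarray
    inertia: float
    degenerate: bool = False  # fewer than k distinct values


def kmeans_1d(values: np.ndarray | list, k: int = 3) -> Kmeans1DResult:
    """Globally optimal 1-D k-means by dynamic programming over sorted values.

    Deterministic (no seed); labels are ordered so group 0 has the smallest
    center.  With fewer than ``k`` distinct values the result is flagged
    degenerate and uses one group per distinct value.
    """
    v = np.asarray(values, float)
    n = v.size
    if n == 0:
        raise ValueError("empty input")
    distinct = np.unique(v)
    if distinct.size < k:
        centers = distinct
        labels = np.searchsorted(distinct, v)
        return Kmeans1DResult(labels=labels, centers=centers,
                              inertia=0.0, degenerate=True)

    order = np.argsort(v, kind="stable")
    s = v[order]
    csum = np.concatenate([[0.0], np.cumsum(s)])
    csq = np.concatenate([[0.0], np.cumsum(s * s)])

    def seg_cost(i: int, j: int) -> float:
        # within-cluster sum of squares for s[i:j]
        m = j - i
        tot = csum[j] - csum[i]
        return (csq[j] - csq[i]) - tot * tot / m

    INF = float("inf")
    dp = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    dp[0, 0] = 0.0
    for g in range(1, k + 1):
        for j in range(g, n + 1):
            best, arg = INF, g - 1
            for i in range(g - 1, j):
                c = dp[g - 1, i]
                if c == INF:
                    continue
                c += seg_cost(i, j)
                if c < best:
                    best, arg = c, i
            dp[g, j] = best
            back[g, j] = arg

    bounds = [n]
    j = n
    for g in range(k, 0, -1):
        j = back[g, j]
        bounds.append(j)
    bounds = bounds[::-1]  # 0 = b0 < b1 < ... < bk = n

    labels_sorted = np.zeros(n, dtype=int)
    centers = np.zeros(k)
    for g in range(k):
        i, j = bounds[g], bounds[g + 1]
        labels_sorted[i:j] = g
        centers[g] = s[i:j].mean()
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return Kmeans1DResult(labels=labels, centers=centers,
                          inertia=float(dp[k, n]), degenerate=False)


# ---------------------------------------------------------------------------
# karyotype assignment
# ---------------------------------------------------------------------------

@dataclass
class KaryotypeAssignment:
    """Per-individual AA/AB/BB calls for one SOC plus validity diagnostics."""

    soc_id: str
    table: pd.DataFrame  # sample, population, pc1, karyotype, region_het, dist_to_center
    group_het_means: dict[str, float]
    failed: bool = False
    reason: str = ""
    degenerate: bool = False


def assign_karyotypes(
    dataset: GenotypeDataset,
    snp_ids: np.ndarray | list,
    soc_id: str = "soc",
) -> KaryotypeAssignment:
    """Karyotype each individual for one SOC by PC1 + exact 1-D k-means.

    The three PC1 groups are ordered by center; the extreme group holding the
    majority of ancestral-population individuals is AA, the middle is AB, the
    other extreme is BB.  A heterozygosity gate validates the labelling: the
    AB group must have the strictly highest mean region heterozygosity,
    otherwise the assignment is flagged failed (never silently relabelled) —
    as is an assignment whose ancestral majority sits in the middle group.
    """
    pcs = region_pca(dataset, snp_ids)
    pc1 = pcs["PC1"]
    het = individual_het(dataset, snp_ids).reindex(pc1.index)

    km = kmeans_1d(pc1.to_numpy(), k=3)
    labels = km.labels
    degenerate = km.degenerate
    failed = False
    reason = ""

    anc_pops = {p for p, e in dataset.ecotype.items() if e == "ancestral"}
    is_anc = np.array([dataset.popmap[s] in anc_pops for s in pc1.index])

    n_groups = km.centers.size
    if degenerate or n_groups < 3:
        karyos = {g: "AA" for g in range(n_groups)}
        if n_groups == 2:
            karyos = {0: "AA", 1: "BB"}
            failed, reason = True, "only two PC1 groups"
        elif n_groups == 1:
            reason = "single PC1 group (no inversion signal or fixed arrangement)"
        kary = np.array([karyos[g] for g in labels])
    else:
        if is_anc.any():
            counts = np.bincount(labels[is_anc], minlength=3)
            anc_major = int(np.argmax(counts))
        else:
            anc_major = 0
        if anc_major == 1:
            failed = True
            reason = "ancestral majority in the middle PC1 group"
            mapping = {0: "AA", 1: "AB", 2: "BB"}
        elif anc_major == 0:
            mapping = {0: "AA", 1: "AB", 2: "BB"}
        else:
            mapping = {2: "AA", 1: "AB", 0: "BB"}
        kary = np.array([mapping[g] for g in labels])

    table = pd.DataFrame({
        "sample": pc1.index,
        "population": [dataset.popmap[s] for s in pc1.index],
        "pc1": pc1.to_numpy(),
        "karyotype": kary,
        "region_het": het.to_numpy(),
        "dist_to_center": np.abs(pc1.to_numpy() - km.centers[labels]),
    })
    group_means = {
        g: float(table.loc[table["karyotype"] == g, "region_het"].mean())
        for g in ("AA", "AB", "BB")
        if (table["karyotype"] == g).any()
    }
    if not degenerate and n_groups == 3 and not failed:
        ab = group_means.get("AB", np.nan)
        homos = [group_means.get(g) for g in ("AA", "BB") if g in group_means]
        if not homos or not np.all(ab > np.asarray(homos)):
            failed = True
            reason = "AB group does not show the highest mean heterozygosity"
    return KaryotypeAssignment(
        soc_id=soc_id, table=table, group_het_means=group_means,
        failed=failed, reason=reason, degenerate=degenerate,
    )


def karyotype_frequencies(assignment: KaryotypeAssignment) -> pd.DataFrame:
    """Karyotype and arrangement frequencies per population.

    freq(B) = (nAB + 2 nBB) / 2N; karyotype frequencies sum to one per
    population.  Populations with no karyotyped individuals are excluded.
    """
    rows = []
    for pop, sub in assignment.table.groupby("population", sort=False):
        n = len(sub)
        if n == 0:
            logger.warning("karyotype_frequencies: empty population %s", pop)
            continue
        counts = sub["karyotype"].value_counts()
        n_aa = int(counts.get("AA", 0))
        n_ab = int(counts.get("AB", 0))
        n_bb = int(counts.get("BB", 0))
        rows.append({
            "population": pop, "n": n,
            "freq_AA": n_aa / n, "freq_AB": n_ab / n, "freq_BB": n_bb / n,
            "freq_A": (2 * n_aa + n_ab) / (2 * n),
            "freq_B": (n_ab + 2 * n_bb) / (2 * n),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# differentiation and classification
# ---------------------------------------------------------------------------

def inversion_fst(
    dataset: GenotypeDataset,
    soc_snp_ids: np.ndarray | list,
    neutral_snp_ids: np.ndarray | list,
    ancestral_pop: str,
    derived_pops: list[str],
) -> pd.DataFrame:
    """Per-pair multi-locus theta over SOC SNPs and its elevation over neutral.

    For each ancestral-derived pair, theta is computed over the SOC's SNPs and
    over the neutral set; the ratio quantifies how much differentiation the
    putative inversion carries relative to the genomic background.
    """
    rows = []
    for pop in derived_pops:
        t_inv = wc_fst(dataset, ancestral_pop, pop, soc_snp_ids).theta
        t_neu = wc_fst(dataset, ancestral_pop, pop, neutral_snp_ids).theta
        rows.append({
            "pair": f"{pop}_vs_{ancestral_pop}",
            "theta_inversion": t_inv,
            "theta_neutral": t_neu,
            "ratio": t_inv / t_neu if t_neu != 0 else np.inf,
        })
    return pd.DataFrame(rows)


def classify_soc_cause(
    frequencies: pd.DataFrame,
    ecotype: dict[str, str],
    delta: float = 0.5,
) -> str:
    """Classify a SOC's inferred cause from arrangement frequencies.

    ``parallel adaptation``: every derived population's freq(B) is shifted by
    at least ``delta`` from the ancestral one, all in the same direction.
    ``geographic structure``: the derived populations split among themselves
    by at least ``delta`` while not all shifting against the ancestral
    population.  Anything else is ``unresolved``.
    """
    anc_pops = [p for p in frequencies["population"] if ecotype.get(p) == "ancestral"]
    der_pops = [p for p in frequencies["population"] if ecotype.get(p) == "derived"]
    if len(anc_pops) < 1 or len(der_pops) < 2:
        raise ValueError("need >=1 ancestral and >=2 derived populations")
    fb = frequencies.set_index("population")["freq_B"]
    f_anc = float(fb[anc_pops].mean())
    shifts = np.array([fb[p] - f_anc for p in der_pops])
    if np.all(np.abs(shifts) >= delta) and (np.all(shifts > 0) or np.all(shifts < 0)):
        return "parallel adaptation"
    der_vals = fb[der_pops].to_numpy()
    if der_vals.max() - der_vals.min() >= delta:
        return "geographic structure"
    return "unresolved"
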