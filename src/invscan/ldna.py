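"""Linkage-disequilibrium network analysis: r2 graphs, the threshold-descent
merger tree, lambda scoring, and single-outlier-cluster (SOC) extraction.

Clusters of SNPs in unusually high mutual LD are candidate signatures of
chromosomal rearrangements.  The analysis descends a grid of r2 thresholds;
at each level the connected components of the graph (edges = SNP pairs with
r2 at or above the level) are tracked, and every time a cluster is absorbed
into a larger one it receives a score

    lambda = nLoci * (x1 - x2)

where x1 is the median pairwise r2 within the focal cluster and x2 the median
r2 of the pairs the merger adds between the focal cluster and the rest of the
merged component.  Clusters whose lambda stands far above the distribution
(median + phi * MAD, among clusters with at least ``E_min`` internal edges)
are outlier clusters (OCs); an OC containing no previously extracted OC is a
single-outlier cluster (SOC), otherwise a compound one (COC).  Retained SOCs
additionally need at least ``min_cluster_loci`` members and median r2 of at
least ``min_median_r2``.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)

__all__ = [
    "LDMatrix", "LDnaParams", "LDCluster", "MergerTree",
    "ld_r2", "build_merger_tree", "select_phi", "extract_ocs",
    "soc_postfilter", "soc_span",
]


# ---------------------------------------------------------------------------
# r2 matrix
# ---------------------------------------------------------------------------

@dataclass
class LDMatrix:
    """Dense pairwise r2 for one chromosome (pairs below ``floor`` zeroed)."""

    chromosome: str
    snp_ids: np.ndarray
    positions: np.ndarray  # 1-based, ascending
    r2: np.ndarray  # (p, p) float32, symmetric, zero diagonal
    maf_floor: float = 0.1
    floor: float = 0.05

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


def ld_r2(
    dataset: GenotypeDataset,
    chromosome: str,
    maf_floor: float = 0.1,
    floor: float = 0.05,
) -> LDMatrix:
    """Pairwise r2 between SNP dosages on one chromosome, samples pooled.

    r2 is the squared Pearson correlation of allele dosages over
    pairwise-complete called genotypes.  Only SNPs with pooled MAF at or above
    ``maf_floor`` enter; pairs with undefined correlation (constant dosage
    among jointly called samples) are set to zero, as are pairs below the
    sparsity ``floor``.
    """
    on_chrom = dataset.variants["chrom"].to_numpy() == chromosome
    gt = dataset.genotypes[:, on_chrom].astype(np.float64)
    gt[gt == MISSING] = np.nan
    called = np.isfinite(gt).sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(gt, axis=0) / np.maximum(2 * called, 1)
    maf = np.minimum(freq, 1 - freq)
    keep = (called > 0) & (maf >= maf_floor)
    if keep.sum() < 2:
        raise ValueError(f"fewer than 2 SNPs pass MAF >= {maf_floor} on {chromosome}")

    x = gt[:, keep]
    w = np.isfinite(x).astype(np.float64)
    z = np.where(np.isfinite(x), x, 0.0)
    z2 = z * z

    n = w.T @ w
    sx = z.T @ w
    sy = sx.T
    sxy = z.T @ z
    sxx = z2.T @ w
    syy = sxx.T

    with np.errstate(invalid="ignore", divide="ignore"):
        num = n * sxy - sx * sy
        den = (n * sxx - sx ** 2) * (n * syy - sy ** 2)
        r2 = np.where(den > 0, num ** 2 / den, 0.0)
    r2[n < 2] = 0.0
    r2 = np.clip(r2, 0.0, 1.0).astype(np.float32)
    np.fill_diagonal(r2, 0.0)
    r2[r2 < floor] = 0.0

    idx = np.flatnonzero(on_chrom)[keep]
    return LDMatrix(
        chromosome=chromosome,
        snp_ids=dataset.snp_ids[idx],
        positions=dataset.variants["pos"].to_numpy()[idx],
        r2=r2,
        maf_floor=maf_floor,
        floor=floor,
    )


# ---------------------------------------------------------------------------
# parameters and cluster records
# ---------------------------------------------------------------------------

@dataclass
class LDnaParams:
    """Extraction parameters for the LD network analysis."""

    e_min: int = 30
    phi: float | None = None  # None -> select via select_phi
    threshold_grid: np.ndarray | None = None  # descending; None -> derived
    min_cluster_loci: int = 30
    min_median_r2: float = 0.3
    phi_start: int = 2
    phi_max: int = 20
    merge_median: str = "cross"  # "cross" | "all" (see build_merger_tree)

    def validate(self) -> None:
        if self.e_min < 1:
            raise ValueError("e_min must be >= 1")
        if self.phi is not None and self.phi < 0:
            raise ValueError("phi must be >= 0")
        if self.threshold_grid is not None:
            g = np.asarray(self.threshold_grid, float)
            if np.any(np.diff(g) >= 0) or g.min() < 0 or g.max() >= 1.0001:
                raise ValueError("threshold_grid must be strictly descending in (0, 1)")


@dataclass
class LDCluster:
    """One extracted LD cluster with its Table-1-style summary fields."""

    chromosome: str
    snp_ids: np.ndarray
    positions: np.ndarray
    n_loci: int
    n_edges: int
    lam: float
    median_r2: float
    merge_threshold: float
    span: tuple[int, int]  # min/max member position (bp, 1-based)
    soc: bool = True

    @property
    def size_bp(self) -> int:
        return self.span[1] - self.span[0]


# ---------------------------------------------------------------------------
# merger tree
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    node_id: int
    members: np.ndarray  # indices into the LDMatrix SNP order
    birth_thr: float
    median_within: float
    parent: int | None = None
    death_thr: float | None = None
    lam: float | None = None
    n_edges: int | None = None
    x1: float | None = None
    x2: float | None = None


@dataclass
class MergerTree:
    """All clusters observed while descending the r2 threshold grid."""

    ld: LDMatrix
    grid: np.ndarray
    nodes: list[_Node] = field(default_factory=list)
    merge_median: str = "cross"

    @property
    def mergers(self) -> list[_Node]:
        """Clusters that died in a merger (their lambda is defined)."""
        return [n for n in self.nodes if n.lam is not None]

    def components_at(self, threshold: float) -> int:
        """Number of graph components (incl. singletons) at a threshold."""
        r2 = self.ld.r2
        p = r2.shape[0]
        parent = list(range(p))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        ii, jj = np.nonzero(np.triu(r2 >= threshold, 1))
        for a, b in zip(ii, jj):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
        return len({find(v) for v in range(p)})


def _median_upper(mat: np.ndarray) -> float:
    iu = np.triu_indices(mat.shape[0], k=1)
    return float(np.median(mat[iu]))


def build_merger_tree(
    ld: LDMatrix,
    grid: np.ndarray | None = None,
    merge_median: str = "cross",
) -> MergerTree:
    """Descend the r2 threshold grid, tracking cluster mergers and lambda.

    ``grid`` defaults to descending steps of 0.01 from the maximum observed r2
    down to the matrix floor.  At each level the components of the
    at-or-above-threshold graph are formed; when previously distinct clusters
    (and/or singletons) coalesce, each focal cluster of two or more loci
    receives lambda = nLoci * (x1 - x2), with x1 its median internal pairwise
    r2 and x2 either the median r2 of the cross pairs it gains in the merger
    (``merge_median="cross"``, default) or the median of all pairs of the
    merged cluster (``merge_median="all"``).  The cross form scores the LD
    drop a merger introduces independently of the partner's size; the all-pairs
    form dilutes it when a large tight cluster absorbs small ones.
    """
    if merge_median not in ("cross", "all"):
        raise ValueError("merge_median must be 'cross' or 'all'")
    r2 = ld.r2
    p = r2.shape[0]
    tree = MergerTree(ld=ld, grid=np.empty(0), nodes=[], merge_median=merge_median)
    ii, jj = np.nonzero(np.triu(r2 > 0, 1))
    if ii.size == 0:
        logger.warning("build_merger_tree: no edges above floor on %s", ld.chromosome)
        tree.grid = np.array([1.0, 0.0])
        return tree
    w = r2[ii, jj]
    if grid is None:
        top = np.ceil(float(w.max()) * 100) / 100
        grid = np.round(np.arange(top, 0.005, -0.01), 10)
        grid = np.append(grid, 0.0)
    grid = np.asarray(grid, float)
    tree.grid = grid

    order = np.argsort(-w, kind="stable")
    ii, jj, w = ii[order], jj[order], w[order]

    parent = np.arange(p)

    def find(a: int) -> int:
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:
            parent[a], a = root, parent[a]
        return int(root)

    members: dict[int, list[int]] = {v: [v] for v in range(p)}  # root -> member list
    node_of_root: dict[int, int] = {}  # root -> node id of current cluster
    edge_ptr = 0

    for t in grid:
        batch_end = edge_ptr
        while batch_end < w.size and w[batch_end] >= t - 1e-12:
            batch_end += 1
        at_zero = t <= 1e-12 and p > 1
        if batch_end == edge_ptr and not at_zero:
            continue
        touched_roots: set[int] = set()
        pre_clusters: dict[int, int] = {}  # pre-merger root -> node id (size>=2 only)
        pre_members: dict[int, list[int]] = {}

        def union(a: int, b: int) -> None:
            ra, rb = find(a), find(b)
            if ra == rb:
                return
            for r in (ra, rb):
                if r not in pre_members:
                    pre_members[r] = members[r]
                    if r in node_of_root:
                        pre_clusters[r] = node_of_root[r]
            if len(members[ra]) < len(members[rb]):
                ra, rb = rb, ra
            parent[rb] = ra
            members[ra] = members[ra] + members[rb]
            del members[rb]
            node_of_root.pop(rb, None)
            node_of_root.pop(ra, None)
            touched_roots.add(ra)

        for e in range(edge_ptr, batch_end):
            union(int(ii[e]), int(jj[e]))
        if at_zero:  # at threshold 0 every locus joins one component
            for v_ in range(1, p):
                union(0, v_)
        edge_ptr = batch_end

        # resolve final components formed at this threshold
        final_roots = {find(r) for r in touched_roots}
        for root in final_roots:
            mem = np.array(sorted(members[root]), dtype=int)
            children = [
                (r, nid) for r, nid in pre_clusters.items() if find(r) == root
            ]
            sub = r2[np.ix_(mem, mem)]
            med_all = _median_upper(sub)
            new_id = len(tree.nodes)
            for r, nid in children:
                child = tree.nodes[nid]
                x1 = child.median_within
                cm = child.members
                rest = np.setdiff1d(mem, cm, assume_unique=False)
                if merge_median == "cross":
                    x2 = float(np.median(r2[np.ix_(cm, rest)])) if rest.size else x1
                else:
                    x2 = med_all
                inner = r2[np.ix_(cm, cm)]
                n_edges = int(np.count_nonzero(
                    inner[np.triu_indices(cm.size, k=1)] >= t - 1e-12))
                child.parent = new_id
                child.death_thr = float(t)
                child.lam = float(cm.size * (x1 - x2))
                child.n_edges = n_edges
                child.x1, child.x2 = float(x1), float(x2)
            tree.nodes.append(_Node(
                node_id=new_id, members=mem, birth_thr=float(t),
                median_within=med_all,
            ))
            node_of_root[root] = new_id
    return tree


# ---------------------------------------------------------------------------
# OC / SOC extraction
# ---------------------------------------------------------------------------

def _lambda_limit(lams: np.ndarray, phi: float) -> float | None:
    """median + phi * MAD (normal-consistent); std fallback when MAD is 0."""
    med = float(np.median(lams))
    mad = float(np.median(np.abs(lams - med))) * 1.4826
    if mad == 0.0:
        mad = float(np.std(lams))
        if mad == 0.0:
            return None
    return med + phi * mad


def extract_ocs(tree: MergerTree, params: LDnaParams) -> list[LDCluster]:
    """Extract outlier clusters and label each SOC or COC.

    The lambda reference distribution (median + phi * MAD) is taken over all
    mergers of the tree; only clusters with at least ``e_min`` internal edges
    are eligible for extraction.  A nested chain of versions of one tight
    cluster would otherwise dominate the reference distribution whenever the
    background produces few large clusters, and no outlier could ever stand
    out from itself.  Extraction walks OCs from the highest merge threshold
    down; an OC that contains a previously extracted OC is a COC, the rest
    are SOCs.  With fewer than 5 lambda values no OC is declared.
    """
    params.validate()
    phi = params.phi if params.phi is not None else float(params.phi_start)
    mergers = tree.mergers
    lams = np.array([n.lam for n in mergers])
    if lams.size < 5:
        warnings.warn("fewer than 5 lambda values; no outlier clusters declared")
        return []
    lim = _lambda_limit(lams, phi)
    if lim is None:
        return []
    ocs = [n for n in mergers
           if n.lam > lim and n.n_edges is not None and n.n_edges >= params.e_min]
    ocs.sort(key=lambda n: (-n.death_thr, n.node_id))

    out: list[LDCluster] = []
    extracted_members: list[set[int]] = []
    for n in ocs:
        mset = set(n.members.tolist())
        is_soc = not any(prev <= mset for prev in extracted_members)
        extracted_members.append(mset)
        pos = tree.ld.positions[n.members]
        out.append(LDCluster(
            chromosome=tree.ld.chromosome,
            snp_ids=tree.ld.snp_ids[n.members],
            positions=pos,
            n_loci=int(n.members.size),
            n_edges=int(n.n_edges),
            lam=float(n.lam),
            median_r2=float(n.median_within),
            merge_threshold=float(n.death_thr),
            span=(int(pos.min()), int(pos.max())),
            soc=is_soc,
        ))
    return out


def select_phi(tree: MergerTree, e_min: int = 30, phi_start: int = 2,
               phi_max: int = 20) -> int:
    """Smallest phi whose extracted cluster set is stable for 3 increments.

    Starting at ``phi_start``, phi increases by one until the extracted OC set
    is identical for three consecutive unit increments; that stable phi is
    returned (``phi_max`` with a warning if it never stabilises).
    """
    def oc_ids(phi: float) -> frozenset:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mergers = tree.mergers
            lams = np.array([n.lam for n in mergers])
            if lams.size < 5:
                return frozenset()
            lim = _lambda_limit(lams, phi)
            if lim is None:
                return frozenset()
            return frozenset(
                n.node_id for n in mergers
                if n.lam > lim and n.n_edges is not None and n.n_edges >= e_min
            )

    phi = phi_start
    while phi <= phi_max - 3:
        base = oc_ids(phi)
        if all(oc_ids(phi + k) == base for k in (1, 2, 3)):
            return phi
        phi += 1
    warnings.warn(f"phi did not stabilise below phi_max={phi_max}")
    return phi_max


def soc_postfilter(ocs: list[LDCluster], params: LDnaParams) -> list[LDCluster]:
    """Retain SOCs with enough loci and high enough median LD."""
    return [
        c for c in ocs
        if c.soc
        and c.n_loci >= params.min_cluster_loci
        and c.median_r2 >= params.min_median_r2
        and c.n_edges >= params.e_min
    ]


# ---------------------------------------------------------------------------
# span and gap exclusion
# ---------------------------------------------------------------------------

def soc_span(
    soc: LDCluster,
    ld: LDMatrix | None = None,
    min_gap_bp: int = 5_000_000,
    min_cross_gap_r2: float = 0.5,
) -> dict:
    """Raw and gap-adjusted span of a SOC.

    The raw span is max - min member position.  Any internal interval of at
    least ``min_gap_bp`` containing no member SNP, whose flanking members show
    median cross-gap r2 of at least ``min_cross_gap_r2`` (all left-side by
    right-side member pairs; requires ``ld``), is excluded from the adjusted
    span — high LD straight across an empty gap marks an assembly artefact
    rather than genuine extent.  Returns raw span, adjusted intervals and
    length, and the excluded gaps.
    """
    pos = np.sort(np.asarray(soc.positions))
    raw = (int(pos[0]), int(pos[-1]))
    gaps = []
    if ld is not None:
        order = {int(p): i for i, p in enumerate(ld.positions)}
        idx_sorted = np.array([order[int(p)] for p in pos])
    for i in range(len(pos) - 1):
        gap = int(pos[i + 1] - pos[i])
        if gap < min_gap_bp:
            continue
        if ld is None:
            continue
        left = idx_sorted[: i + 1]
        right = idx_sorted[i + 1:]
        cross = float(np.median(ld.r2[np.ix_(left, right)]))
        if cross >= min_cross_gap_r2:
            gaps.append({"start": int(pos[i]), "end": int(pos[i + 1]),
                         "length": gap, "median_cross_r2": cross})
    intervals = []
    cursor = raw[0]
    for g in gaps:
        intervals.append((cursor, g["start"]))
        cursor = g["end"]
    intervals.append((cursor, raw[1]))
    adjusted_length = sum(e - s for s, e in intervals)
    return {
        "raw_span": raw,
        "raw_length": raw[1] - raw[0],
        "adjusted_intervals": intervals,
        "adjusted_length": int(adjusted_length),
        "excluded_gaps": gaps,
    }
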