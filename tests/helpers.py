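"""Shared builders and independent oracles for the test suite.

The oracles here are deliberately naive (exact rational arithmetic, brute
force scans) and independent of the implementation paths they check.
"""
from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd

from invscan.genotypes import GenotypeDataset


def make_dataset(
    genotypes,
    popmap: dict[str, str],
    ecotype: dict[str, str] | None = None,
    chrom=None,
    pos=None,
    depth=None,
    gq=None,
    qual=60.0,
) -> GenotypeDataset:
    """Build a small GenotypeDataset from plain arrays."""
    gt = np.asarray(genotypes, dtype=np.int8)
    n, p = gt.shape
    samples = list(popmap)
    assert len(samples) == n
    chrom = np.asarray(chrom) if chrom is not None else np.array(["chr1"] * p)
    pos = np.asarray(pos) if pos is not None else (np.arange(p) + 1) * 1000
    variants = pd.DataFrame({
        "chrom": chrom, "pos": pos,
        "id": [f"{c}:{x}" for c, x in zip(chrom, pos)],
        "ref": "A", "alt": "G",
        "qual": np.broadcast_to(np.asarray(qual, float), (p,)).copy(),
    })
    if ecotype is None:
        pops = list(dict.fromkeys(popmap.values()))
        ecotype = {pops[0]: "ancestral", **{q: "derived" for q in pops[1:]}}
    ds = GenotypeDataset(
        genotypes=gt, variants=variants, samples=samples,
        popmap=dict(popmap), ecotype=ecotype,
        depth=None if depth is None else np.asarray(depth, np.int32),
        gq=None if gq is None else np.asarray(gq, np.int32),
    )
    ds.validate()
    return ds


def exact_fisher_two_sided(table) -> Fraction:
    """Exact two-sided Fisher p for a 2x2 table, in rational arithmetic.

    Enumerates every table with the observed margins and sums the
    hypergeometric probabilities that do not exceed the observed table's.
    """
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    denom = comb(n, col1)

    def pk(k: int) -> Fraction:
        return Fraction(comb(row1, k) * comb(row2, col1 - k), denom)

    lo, hi = max(0, col1 - row2), min(col1, row1)
    p_obs = pk(a)
    return sum((pk(k) for k in range(lo, hi + 1) if pk(k) <= p_obs), Fraction(0))


def greedy_prune_oracle(positions, window: int) -> list[int]:
    """Brute-force left-to-right one-SNP-per-window scan on one chromosome."""
    kept, seen = [], set()
    for p in sorted(positions):
        w = (p - 1) // window
        if w not in seen:
            seen.add(w)
            kept.append(p)
    return kept


def karyotype_concordance(assignment_table, truth_karyotypes: dict[str, str]) -> float:
    hits = [
        truth_karyotypes[s] == k
        for s, k in zip(assignment_table["sample"], assignment_table["karyotype"])
    ]
    return float(np.mean(hits))


def span_jaccard(intervals, truth_span: tuple[int, int]) -> float:
    """Jaccard between a union of [s, e] intervals and the true span (bp)."""
    ts, te = truth_span
    inter = sum(max(0, min(e, te) - max(s, ts)) for s, e in intervals)
    length = sum(e - s for s, e in intervals)
    union = length + (te - ts) - inter
    return inter / union if union else float("nan")
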