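"""Synthetic genotype data with the structure the analysis pipeline assumes.

The generator emulates a one-ancestral / four-derived population design:

* neutral SNPs differentiated by drift — each population's allele frequency is
  a Balding–Nichols Beta draw around a shared ancestral frequency,
  parameterised directly by the target multi-locus FST;
* selected SNPs whose favoured (alt) allele sits at low frequency in the
  ancestral population and at high frequency in every derived population;
* one recombination-suppressed inversion: two arrangement haplotype pools that
  are fixed for alternative alleles at a "diagnostic" fraction of the
  inversion's SNPs, with arrangement B at low frequency in the ancestral and
  high frequency in the derived populations.  Each individual draws two
  arrangement labels (its true karyotype) and one haplotype per label.

Every draw comes from a single seeded generator, so a config with a fixed
seed reproduces its VCF byte for byte.  Alongside the genotype dataset the
generator returns a :class:`TruthSet` (selected SNP ids, inversion span, true
karyotypes and arrangement frequencies) for recovery tests.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeDataset, write_vcf

__all__ = ["SimConfig", "TruthSet", "simulate", "simulate_null", "write_sim"]


@dataclass
class SimConfig:
    """Parameters of the synthetic study design.

    Defaults mirror the emulated study: 1 ancestral + 4 derived populations of
    ~22 individuals, ~5,000 neutral SNPs on 3 chromosomes at neutral FST 0.03,
    60 selected SNPs shifting from p0=0.12 to p1=0.85, and one 20-Mb inversion
    of 300 SNPs (80% diagnostic) whose B arrangement moves from frequency 0.1
    (ancestral) to 0.8 (each derived population).  96% of the selected SNPs
    are placed inside the inversion span, matching the concentration of
    outliers inside inversions that the design emulates.
    """

    n_derived_pops: int = 4
    samples_per_pop: int = 22
    n_chromosomes: int = 3
    chrom_length: int = 40_000_000
    n_neutral_snps: int = 5_000
    n_selected_snps: int = 60
    neutral_fst: float = 0.03
    anc_freq_low: float = 0.05
    anc_freq_high: float = 0.95
    selected_p0: float = 0.12
    selected_p1: float = 0.85
    inversion_chrom_index: int = 2
    inversion_span: tuple[int, int] = (10_000_000, 30_000_000)  # 0-based half-open
    n_inversion_snps: int = 300
    d_arr: float = 0.8
    inv_freq_b_ancestral: float = 0.1
    inv_freq_b_derived: float = 0.8
    frac_selected_in_inversion: float = 0.96
    missing_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        for name in ("neutral_fst", "selected_p0", "selected_p1", "d_arr",
                     "inv_freq_b_ancestral", "inv_freq_b_derived",
                     "missing_rate", "frac_selected_in_inversion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        s, e = self.inversion_span
        if self.n_inversion_snps > 0:
            if not (0 <= s < e <= self.chrom_length):
                raise ValueError("inversion span outside chromosome")
            if not 0 <= self.inversion_chrom_index < self.n_chromosomes:
                raise ValueError("inversion chromosome index out of range")
        if self.samples_per_pop < 2 or self.n_chromosomes < 1:
            raise ValueError("need at least 2 samples per population and 1 chromosome")

    @property
    def population_names(self) -> list[str]:
        return ["anc"] + [f"fw{i + 1}" for i in range(self.n_derived_pops)]

    def chrom_name(self, index: int) -> str:
        return f"chr{index + 1}"


@dataclass
class TruthSet:
    """Ground truth emitted with a simulated dataset."""

    selected_ids: list[str]
    inversion: tuple[str, int, int] | None  # (chrom, start0, end0), half-open
    karyotypes: dict[str, str]  # sample -> AA/AB/BB ('' when no inversion)
    arrangement_freq_b: dict[str, float]  # population -> drawing freq of B
    config: SimConfig = field(repr=False, default=None)

    def to_json(self) -> str:
        d = {
            "selected_ids": self.selected_ids,
            "inversion": list(self.inversion) if self.inversion else None,
            "karyotypes": self.karyotypes,
            "arrangement_freq_b": self.arrangement_freq_b,
            "config": dataclasses.asdict(self.config) if self.config else None,
        }
        return json.dumps(d, indent=1)


def _balding_nichols(rng, p_anc: np.ndarray, fst: float, n_pops: int) -> np.ndarray:
    """Per-population allele frequencies: Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    if fst <= 0.0:
        return np.tile(p_anc, (n_pops, 1))
    a = p_anc * (1 - fst) / fst
    b = (1 - p_anc) * (1 - fst) / fst
    return rng.beta(a, b, size=(n_pops, p_anc.size))


def _unique_positions(rng, low: int, high: int, size: int) -> np.ndarray:
    """Draw ``size`` distinct integer positions in [low, high)."""
    if high - low < size:
        raise ValueError("interval too small for requested SNP count")
    pos = np.unique(rng.integers(low, high, size=size))
    while pos.size < size:
        extra = rng.integers(low, high, size=size - pos.size + 8)
        pos = np.unique(np.concatenate([pos, extra]))
    return rng.permutation(pos)[:size]


def simulate(config: SimConfig | None = None) -> tuple[GenotypeDataset, TruthSet]:
    """Generate a genotype dataset plus its ground truth."""
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    pops = config.population_names
    n_per = config.samples_per_pop
    samples = [f"{p}_{i:02d}" for p in pops for i in range(n_per)]
    popmap = {s: s.rsplit("_", 1)[0] for s in samples}
    ecotype = {p: ("ancestral" if p == "anc" else "derived") for p in pops}
    pop_of = np.repeat(np.arange(len(pops)), n_per)
    n_samples = len(samples)

    inv_chrom = config.chrom_name(config.inversion_chrom_index)
    inv_start, inv_end = config.inversion_span
    has_inv = config.n_inversion_snps > 0

    # --- SNP placement ------------------------------------------------------
    chrom_of_neutral = rng.integers(0, config.n_chromosomes, config.n_neutral_snps)
    n_sel_in = (
        int(round(config.frac_selected_in_inversion * config.n_selected_snps))
        if has_inv else 0
    )
    n_sel_out = config.n_selected_snps - n_sel_in
    chrom_of_sel_out = rng.integers(0, config.n_chromosomes, n_sel_out)

    records = []  # (chrom_idx, pos0, kind, sub_index)
    for c in range(config.n_chromosomes):
        neutral_here = int((chrom_of_neutral == c).sum())
        sel_out_here = int((chrom_of_sel_out == c).sum())
        inv_here = config.n_inversion_snps if (has_inv and c == config.inversion_chrom_index) else 0
        sel_in_here = n_sel_in if (has_inv and c == config.inversion_chrom_index) else 0

        pos_all = _unique_positions(rng, 0, config.chrom_length,
                                    neutral_here + sel_out_here + inv_here + sel_in_here)
        # selected-outside and inversion-bound SNPs need constrained positions:
        # reuse draws where possible, redraw the constrained ones inside/outside.
        cursor = 0
        neutral_pos = pos_all[cursor:cursor + neutral_here]; cursor += neutral_here
        sel_out_pos = pos_all[cursor:cursor + sel_out_here]; cursor += sel_out_here
        if inv_here or sel_in_here:
            in_span = _unique_positions(rng, inv_start, inv_end, inv_here + sel_in_here)
            inv_pos, sel_in_pos = in_span[:inv_here], in_span[inv_here:]
        else:
            inv_pos = sel_in_pos = np.empty(0, int)
        if has_inv and c == config.inversion_chrom_index:
            # keep selected-outside SNPs genuinely outside the span
            bad = (sel_out_pos >= inv_start) & (sel_out_pos < inv_end)
            while bad.any():
                sel_out_pos[bad] = rng.integers(0, config.chrom_length, int(bad.sum()))
                bad = (sel_out_pos >= inv_start) & (sel_out_pos < inv_end)
        for p in neutral_pos:
            records.append((c, int(p), "neutral", 0))
        for p in sel_out_pos:
            records.append((c, int(p), "selected", 0))
        for p in sel_in_pos:
            records.append((c, int(p), "selected", 0))
        for i, p in enumerate(inv_pos):
            records.append((c, int(p), "inversion", i))

    rec = pd.DataFrame(records, columns=["c", "pos0", "kind", "sub"])
    rec = rec.drop_duplicates(subset=["c", "pos0"]).sort_values(["c", "pos0"]).reset_index(drop=True)
    n_snps = len(rec)

    # --- genotypes ----------------------------------------------------------
    genotypes = np.zeros((n_samples, n_snps), dtype=np.int8)

    is_neutral = (rec["kind"] == "neutral").to_numpy()
    is_selected = (rec["kind"] == "selected").to_numpy()
    is_inversion = (rec["kind"] == "inversion").to_numpy()

    # neutral: Balding-Nichols around ancestral law
    n_neu = int(is_neutral.sum())
    p_anc = rng.uniform(config.anc_freq_low, config.anc_freq_high, n_neu)
    p_pop = _balding_nichols(rng, p_anc, config.neutral_fst, len(pops))
    for k in range(len(pops)):
        rows = np.flatnonzero(pop_of == k)
        genotypes[np.ix_(rows, np.flatnonzero(is_neutral))] = rng.binomial(
            2, p_pop[k], size=(rows.size, n_neu)
        ).astype(np.int8)

    # selected: ancestral p0, derived p1 (favoured allele = alt by construction)
    n_sel = int(is_selected.sum())
    if n_sel:
        cols = np.flatnonzero(is_selected)
        for k, pop in enumerate(pops):
            p = config.selected_p0 if ecotype[pop] == "ancestral" else config.selected_p1
            rows = np.flatnonzero(pop_of == k)
            genotypes[np.ix_(rows, cols)] = rng.binomial(
                2, p, size=(rows.size, cols.size)
            ).astype(np.int8)

    # inversion: arrangement pools with fixed differences at diagnostic sites
    karyotypes: dict[str, str] = {s: "" for s in samples}
    arrangement_freq_b: dict[str, float] = {}
    if has_inv:
        cols = np.flatnonzero(is_inversion)
        sub = rec.loc[cols, "sub"].to_numpy()
        n_inv = cols.size
        diagnostic = np.zeros(n_inv, bool)
        diag_idx = rng.permutation(n_inv)[: int(round(config.d_arr * n_inv))]
        diagnostic[diag_idx] = True
        # non-diagnostic sites: one frequency shared by both pools
        q_shared = rng.uniform(config.anc_freq_low, config.anc_freq_high, n_inv)

        for k, pop in enumerate(pops):
            fb = (config.inv_freq_b_ancestral if ecotype[pop] == "ancestral"
                  else config.inv_freq_b_derived)
            arrangement_freq_b[pop] = fb
            rows = np.flatnonzero(pop_of == k)
            n_b = rng.binomial(2, fb, size=rows.size)  # true karyotype = #B arrangements
            for r, nb in zip(rows, n_b):
                karyotypes[samples[r]] = {0: "AA", 1: "AB", 2: "BB"}[int(nb)]
                # haplotype draw per arrangement copy
                hap = np.zeros(n_inv, np.int8)
                hap[diagnostic] = nb  # A fixed ref, B fixed alt at diagnostic sites
                n_copies_nondiag = rng.binomial(
                    2, q_shared[~diagnostic]
                ).astype(np.int8)
                hap[~diagnostic] = n_copies_nondiag
                genotypes[r, cols] = hap
    else:
        arrangement_freq_b = {p: 0.0 for p in pops}

    # --- missingness --------------------------------------------------------
    if config.missing_rate > 0:
        miss = rng.random(genotypes.shape) < config.missing_rate
        genotypes[miss] = MISSING

    chrom_names = np.array([config.chrom_name(c) for c in rec["c"]])
    pos1 = rec["pos0"].to_numpy() + 1
    ids = np.array([f"{c}:{p}" for c, p in zip(chrom_names, pos1)])
    # alleles are arbitrary but fixed; A ref / G alt keeps every record a SNP
    variants = pd.DataFrame({
        "chrom": chrom_names, "pos": pos1, "id": ids,
        "ref": "A", "alt": "G", "qual": 60.0,
    })

    dataset = GenotypeDataset(
        genotypes=genotypes, variants=variants, samples=samples,
        popmap=popmap, ecotype=ecotype,
        meta={"simulated": True, "seed": config.seed},
    )
    dataset.validate()

    truth = TruthSet(
        selected_ids=list(ids[is_selected]),
        inversion=(inv_chrom, inv_start, inv_end) if has_inv else None,
        karyotypes=karyotypes,
        arrangement_freq_b=arrangement_freq_b,
        config=config,
    )
    return dataset, truth


def simulate_null(config: SimConfig | None = None) -> tuple[GenotypeDataset, TruthSet]:
    """Drift-only dataset: no selected SNPs and no inversion.

    ``neutral_fst`` is honoured as configured; 0 gives a panmictic dataset.
    """
    config = config or SimConfig()
    cfg = dataclasses.replace(config, n_selected_snps=0, n_inversion_snps=0)
    return simulate(cfg)


def write_sim(dataset: GenotypeDataset, truth: TruthSet, outdir: str | Path) -> dict[str, Path]:
    """Write VCF, popmap/ecotype TSVs, truth JSON, and the inversion BED."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "simulated.vcf",
        "popmap": outdir / "popmap.tsv",
        "ecotype": outdir / "ecotype.tsv",
        "truth": outdir / "truth.json",
        "bed": outdir / "inversion.bed",
    }
    write_vcf(dataset, paths["vcf"])
    with open(paths["popmap"], "w") as fh:
        for s in dataset.samples:
            fh.write(f"{s}\t{dataset.popmap[s]}\n")
    with open(paths["ecotype"], "w") as fh:
        for p, e in dataset.ecotype.items():
            fh.write(f"{p}\t{e}\n")
    paths["truth"].write_text(truth.to_json())
    with open(paths["bed"], "w") as fh:
        if truth.inversion:
            c, s, e = truth.inversion
            fh.write(f"{c}\t{s}\t{e}\tinversion\n")
    return paths
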