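# Methods

`invscan` implements an inference chain for detecting parallel adaptation and
putative chromosomal inversions from diploid biallelic SNP genotypes, in a
study design with one ancestral population and several independently derived
populations (the motivating system is an anadromous fish with landlocked
freshwater-resident lake populations).  This note documents the models and
procedures, the parameters that matter, the synthetic data the package
validates itself against, and the numerical and design choices that were
genuinely open.

## Data model and filtering

Genotypes are alt-allele dosages in {0, 1, 2} with missing calls; VCF
positions are 1-based and every internal interval is 0-based half-open, with
conversion only at I/O boundaries.  The filtering ladder mirrors RAD-era
practice:

1. per-genotype masking: calls with DP < 6 or GQ < 15 are set to missing.
   The depth criterion is applied per genotype (not per site) because that is
   how SAMtools/Stacks-era filters behave and it makes the next criterion
   meaningful;
2. call rate: a SNP must be called in at least 12 individuals in *every*
   population, evaluated after masking.  A SNP whose call rate collapses
   only because of masking is attributed to the depth/quality rule in the
   filter report, one that fails even before masking to the call-rate rule;
3. site quality: QUAL >= 30;
4. per-population observed heterozygosity <= 0.5 (a paralog/collapsed-repeat
   guard). Note that on clean Hardy–Weinberg data this criterion is
   conservative: at allele frequency ~0.5 with ~22 diploids per population,
   sampling noise pushes a large share of genuinely well-behaved SNPs above
   the cutoff in at least one of five populations. That thins mid-frequency
   neutral SNPs (on the default simulation roughly half the input is removed
   here) but leaves the selected and inversion-diagnostic SNPs — whose
   per-population heterozygosity stays well below 0.5 — untouched, and does
   not measurably bias the multi-locus FST;
5. global MAF >= 0.05, with a rescue for SNPs having local MAF >= 0.2 in any
   single population.

Each removed SNP is attributed to the first criterion it fails, so the report
counts partition the input.  The "neutral set" used for population-genetic
background statistics removes every SNP flagged by either outlier scan in any
pair, every SNP inside a detected inversion span, and thins the remainder to
one SNP per 10-kb window (window id = position // window, first SNP kept — a
deterministic representative; any two retained SNPs on a chromosome are in
distinct windows).

## Summary statistics

* Observed heterozygosity is the fraction of heterozygous calls among called
  genotypes.  Expected heterozygosity uses 2p(1−p)·n/(n−1) with n the number
  of called diploids; at n ≈ 20 the difference from the allele-count form
  2n/(2n−1) is below 0.02 of the statistic and does not affect any decision
  the pipeline takes.
* F_ST is Weir & Cockerham's (1984) θ from per-locus a/b/c variance
  components, combined across loci as a ratio of sums (not a mean of
  per-locus ratios), the standard choice for multi-locus estimates.  Loci
  need ≥ 2 called individuals per population; monomorphic loci (zero
  denominator) are skipped.  A permutation test (individuals shuffled
  between the pair, default 10,000 permutations) with Benjamini–Yekutieli
  adjustment across pairs is available (`fst_permutation_test`, `by_adjust`);
  the pipeline default leaves permutations off and the functions are invoked
  explicitly, since the point estimate drives every downstream decision.
* Welch's t statistic and Satterthwaite degrees of freedom are computed
  directly; the p-value comes from the t distribution.
* SNP spacing: the nearest-neighbour fraction counts SNPs whose closest
  same-chromosome neighbour is within d bp (single-SNP chromosomes excluded);
  genome coverage is the union length of half-open intervals [p−d, p+d+1)
  clipped at zero, so d = 0 counts one base per SNP.  The genome size needed
  to turn coverage into a fraction is a user input.

## Outlier scans and the favoured allele

Two scans are run per ancestral–derived pair and intersected:

* **Fisher's exact test** on the 2×2 table of allele counts (2 × called
  diploids chromosomes per population).  The two-sided p sums all
  hypergeometric outcomes whose probability does not exceed the observed
  table's (with the conventional (1+1e−7) tie tolerance) — the standard
  exact two-sided definition.  The implementation is a vectorised
  log-gamma evaluation of the hypergeometric pmf; the test suite checks it
  against an exact rational enumeration to 1e−12.  The operating threshold
  is −log10 p > 4.
* **PCA outlier statistic** (pcadapt-style), K = 2: mean-imputed genotypes
  scaled by sqrt(p̄(1−p̄)), top-K PCs over samples, per-SNP z-vector of PC
  regression coefficients over the residual standard error, robust
  Mahalanobis D² of the z-vectors (minimum covariance determinant with a
  fixed seed when ≥ 500 SNPs are usable, classical covariance otherwise),
  rescaled by the genomic inflation factor median(D²)/median(χ²_K), p from
  χ²_K.  Multiplicity is controlled with Benjamini–Hochberg q-values
  (q ≤ 0.1); BH upper-bounds the q-value on dense p-value grids and is
  therefore slightly conservative relative to smoothed q-value estimators.

A **candidate** SNP is flagged by both methods in all pairs.  The favoured
allele (FWA) at a candidate is the allele whose frequency is strictly higher
in every derived population than in the ancestral one; if no allele
qualifies the SNP stays unassigned rather than being forced.  The FWA table
carries per-population frequencies, per-pair increments, and a
standing-variation flag (FWA present in the ancestral sample); the summary
reports mean frequencies/increments, the fraction of shifts ≥ 0.5, and a
Welch test of ancestral FWA frequency against the neutral-set minor-allele
frequency.  Note the *direction* of that Welch contrast depends on the shape
of the neutral frequency spectrum: with the simulator's uniform ancestral
law the neutral MAF mean (~0.25) exceeds the low starting frequency of
selected alleles, whereas a real RAD spectrum concentrated at rare alleles
gives the opposite sign.

## LD network analysis

LD (r²) is the squared Pearson correlation of dosages over pairwise-complete
called genotypes, computed per chromosome with all populations pooled
(deliberately creating admixture LD), among SNPs with pooled MAF ≥ 0.1.
Pairs below r² = 0.05 are dropped (sparsity floor; they cannot influence any
decision made at meaningful thresholds and are treated as 0 in medians).

A threshold grid descends in steps of 0.01 from the maximum observed r² to 0
(everything coalesces at 0).  Connected components of the at-threshold graph
are tracked; when clusters coalesce, each focal cluster C of ≥ 2 loci is
scored

λ = nLoci(C) · (x̄1 − x̄2),

with x̄1 the median pairwise r² inside C. For x̄2 the package defaults to the
median r² of the **cross pairs** the merger adds between C and the rest of
the merged component (`merge_median="cross"`); the median over **all pairs**
of the merged cluster is available as `merge_median="all"`.  The two agree on
balanced mergers (and on the 3+3 toy oracle, λ = 3 exactly) but diverge when
a large tight cluster absorbs small ones: the all-pairs median then remains
pinned at the cluster's own internal LD until the absorbed loci outnumber
roughly 40% of it, so the λ spike that identifies the cluster fires only
after it has accreted a chromosome-wide halo of background SNPs, and the
extracted cluster's span degenerates to the whole chromosome.  The cross-pair
median scores the LD drop a merger introduces independently of the partner's
size, fires at the first absorption, and keeps the extracted membership tight
— which is what makes the recovered span of a simulated inversion meaningful.

Outlier clusters (OCs) are clusters whose λ exceeds median(λ) + φ·MAD(λ).
The reference distribution is taken over *all* mergers of the chromosome's
tree; the minimum-edge gate |E|min = 30 restricts which clusters may be
*extracted*, not the reference distribution — a nested chain of versions of
one tight cluster would otherwise dominate the eligible set whenever the
background produces few large clusters, and no cluster could stand out from
its own versions.  MAD is normal-consistent (×1.4826); if MAD is 0 the
standard deviation substitutes, and if that is also 0 nothing is extracted.
φ is selected per chromosome by starting at 2 and incrementing until the
extracted set is unchanged for three consecutive increments (capped at 20
with a warning).  Extraction proceeds from the highest merge threshold
downwards; an OC containing a previously extracted OC is a compound outlier
cluster (COC), the rest are single outlier clusters (SOCs).  Retained SOCs
need ≥ 30 loci, median internal r² ≥ 0.3, and |E| ≥ 30.

**Spans.**  A SOC's raw span is the extent of its member positions.  Internal
empty intervals ≥ 5 Mb whose flanking members show median cross-gap r² ≥ 0.5
are subtracted from the adjusted span: high LD straight across a large empty
gap is the signature of a mis-joined assembly rather than genuine physical
extent.  Gaps with low cross-LD are kept as genuine extent.

## Karyotyping and classification

For each retained SOC, a PCA over its member SNPs (mean-imputed, centred,
unscaled — the conventional choice for karyotyping PCAs, with scaling
available as a flagged variant of the scan PCA) orders individuals along
PC1; the sign is fixed so the ancestral-population mean is negative, making
orientation reproducible.  Groups come from an **exact 1-D k-means** solved
by dynamic programming over sorted values — deterministic and globally
optimal, removing the seed-dependence of iterative k-means while returning
the same optimum; the test suite verifies it is never beaten by 1,000
random-restart Lloyd runs.  The extreme group holding the majority of
ancestral individuals is AA, the middle group AB, the other extreme BB.  The
heterozygosity gate — the AB group must have the strictly highest mean
region heterozygosity — is a validity check, not part of labelling: a SOC
failing it (or whose ancestral majority sits in the middle group) is
reported failed rather than silently relabelled.  Boundary individuals keep
a distance-to-centre diagnostic because genuinely intermediate samples
remain biologically uncertain however deterministic the clustering is.

Arrangement frequencies follow from karyotype counts, freq(B) =
(nAB + 2nBB)/2N.  A SOC is classified **parallel adaptation** when every
derived population's freq(B) shifts from the ancestral one by ≥ δ in the
same direction; **geographic structure** when the derived populations split
among themselves by ≥ δ without all shifting against the ancestral
population; otherwise **unresolved**.  δ defaults to 0.5, chosen because
ecotype-associated inversions in this kind of system show arrangement
frequency shifts of ~0.7–1.0 while background noise at these sample sizes
stays far below 0.5; it is configurable.  Inversion-region differentiation
is summarised as θ over SOC SNPs per ancestral–derived pair with its ratio
to the neutral-set θ.

## Synthetic data

The generator draws the statistical structure the analysis assumes, not a
coalescent history:

* design: 1 ancestral + 4 derived populations, 22 diploids each, 3
  chromosomes of 40 Mb — matching the emulated study's sampling scale;
* ~5,000 neutral SNPs: ancestral frequency ~ Uniform(0.05, 0.95), each
  population's frequency a Balding–Nichols Beta draw parameterised directly
  by the target neutral F_ST = 0.03 (the observable the analysis actually
  measures; explicit Wright–Fisher generations would add realism the
  estimator tests do not need), genotypes binomial;
* 60 selected SNPs: ancestral alt frequency 0.12, alt frequency 0.85 in
  every derived population (the favoured allele is alt by construction);
  96% of them are placed inside the inversion span, matching the
  concentration of outliers inside inversions in the kind of data emulated,
  with the remainder scattered;
* one inversion of 300 SNPs across a 20-Mb span: two arrangement haplotype
  pools fixed for alternative alleles at 80% of the sites (diagnostic
  sites), the rest sharing a common frequency in both pools; each individual
  draws two arrangement labels from its population's freq(B) (0.1 ancestral,
  0.8 derived) — its true karyotype — and one haplotype per label;
* 2% uniform missingness; one seeded generator, so a fixed seed reproduces
  the VCF byte for byte.

What this deliberately does **not** emulate: physical background LD along
chromosomes (neutral SNPs are independent), LD decay inside the inversion,
mutation within arrangement pools (diagnostic sites are perfectly
correlated), linked selection, or realistic site-frequency spectra.  Passing
the recovery tests therefore shows the chain is correct under its own
assumptions — clean arrangement divergence, drift-calibrated background —
not that it is robust to assembly errors, partial recombination in long
heterokaryotypes, or low-coverage genotyping noise in real data.

## Problem sizes and numerics

The validation suite runs the full chain at the design scale above (about
5,400 SNPs × 110 samples), 20 drift-only replicates for false-positive
control, 1,000 random tables for the exact-test oracle, and 100 random
inputs × 1,000 restarts for the k-means optimality check — sizes chosen so
the whole suite completes in a few minutes on one core while keeping
Monte-Carlo error well inside every asserted tolerance.  Numerical notes:
the exact-test pmf is evaluated in log space and normalised before summing;
r² uses pairwise-complete sufficient statistics assembled from five matrix
products; undefined correlations (constant dosage among jointly called
samples) and pairs with < 2 joint samples are treated as absent; the merger
tree batches all coalescences within one 0.01 grid step into a single event,
so simultaneous accretions are scored once; k-means dynamic programming uses
prefix sums for O(k·n²) cost.

## Known limitations

* λ and the φ rule are a reconstruction of the LD-network clustering method
  from an ambiguous description; cluster scores are comparable in spirit,
  not numerically, to other implementations.
* The inversion span is defined by member SNP positions; breakpoints are not
  localised, and spans inherit any reference-assembly misordering (the gap
  rule mitigates only the large, high-cross-LD case).
* The PCA scan assumes the top-K PCs capture the relevant structure; K is
  fixed (default 2) rather than chosen by a scree criterion.
* With fewer than three distinct PC1 values, or arrangements fixed in all
  populations, karyotyping degenerates and is flagged rather than resolved.
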