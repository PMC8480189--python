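"""Generate a synthetic five-population dataset and inspect its structure.

One ancestral + four derived populations, drift-differentiated neutral SNPs
(FST 0.03), 60 selection-shifted SNPs, and a 20-Mb inversion whose B
arrangement is rare in the ancestral population and common in the derived
ones.  The ground truth (selected SNP ids, inversion span, per-individual
karyotypes) travels with the dataset.
"""
import collections

from invscan import SimConfig, simulate

dataset, truth = simulate(SimConfig(seed=1))

print(f"samples: {dataset.n_samples}  SNPs: {dataset.n_snps}")
print(f"populations: {dataset.populations}")
print(f"selected SNPs: {len(truth.selected_ids)}")
chrom, start, end = truth.inversion
print(f"inversion: {chrom}:{start}-{end} ({(end - start) / 1e6:.0f} Mb)")
counts = collections.Counter(truth.karyotypes.values())
print(f"true karyotypes: {dict(counts)}")
print()
print("AA/AB/BB counts mix because each individual draws two arrangement")
print("copies from its population's B frequency (0.1 ancestral, 0.8 derived).")
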