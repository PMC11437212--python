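"""Simulate a full-sib pedigree SNP dataset and run the genotype filters.

Builds a small four-chromosome genome with sex-specific crossover
models (male map 15.7% longer, male crossovers near chromosome ends),
genotypes 12 two-offspring families with realistic error and
missingness, and pushes the data through the PLINK-style filter chain.
"""

import hetmap as hm
from hetmap import qc, simulate

genome = hm.GenomeSpec.from_lengths(
    {"1": 60_000_000, "2": 30_000_000, "10": 15_000_000, "20": 8_000_000},
    macro_names={"1", "2"},
)
genome, panel, genes = simulate.simulate_genome(genome, markers_per_chrom=400, seed=1)
model = simulate.default_crossover_model(genome)
pedspec = simulate.PedigreeSpec(n_families=12, offspring_per_family=2)
gd, truth = simulate.simulate_pedigree_genotypes(genome, panel, model, pedspec, seed=2)

print(f"simulated {gd.n_samples} individuals x {gd.n_markers} SNPs")
for chrom in genome.names:
    print(f"  true map {chrom}: female {truth.length('F', chrom):6.1f} cM, "
          f"male {truth.length('M', chrom):6.1f} cM")

filtered, report = qc.run_qc(gd, qc.QCConfig())
print("\nfilter chain (removed samples / markers per step):")
print(report.to_frame().to_string(index=False))
print(f"\nretained {filtered.n_samples} samples, {filtered.n_markers} markers")
# Each step applies the strict PLINK-style threshold; Z-linked markers
# (none here) would bypass the HWE and Mendel filters.
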