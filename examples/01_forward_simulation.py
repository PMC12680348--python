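"""Forward simulation of STR allele frequencies under mutation-selection-drift.

Simulates batches of dinucleotide loci (optimal allele 11 repeats) under the
European demographic model at several selection strengths and prints the mean
heterozygosity of each batch. Heterozygosity (1 - sum p^2) falls as selection
strengthens because alleles away from the optimum are purged.

Runs at rescale factor 10 (sizes/durations divided by 10, rates and s
multiplied by 10), which preserves 4*N*mu and N*s, so the numbers match what
a full 55,920-generation simulation would give in a fraction of the time.
"""

import numpy as np

from strsel import AlleleGrid, default_mutation_model, european_demography, \
    simulate_batch

rng = np.random.default_rng(1)
grid = AlleleGrid(xopt=11, repeat_unit_len=2)
mut = default_mutation_model(2)  # mu0=1e-4 at the optimum, L=0.05/unit
demog = european_demography()

print("selection s | mean heterozygosity over 100 loci (sample of 1,068 alleles)")
for s in (0.0, 1e-4, 1e-3, 1e-2, 1e-1):
    freqs = simulate_batch(mut, np.full(100, s), demog, grid, rng,
                           sample_size=1068, rescale=10)
    het = 1 - (freqs**2).sum(axis=1)
    print(f"  {s:7.0e}  |  {het.mean():.3f}")

print()
print("Weak selection (s <~ 1e-4, N*s < 1) leaves diversity untouched;")
print("by s = 0.01 most loci are nearly fixed for the optimal allele.")
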