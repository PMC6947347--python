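"""Genotype quality control with injected defects.

Corrupts a clean simulated genotype matrix (missing calls + parent-progeny
opposing-homozygote conflicts), then runs the fixed-order QC: call rate >= 0.9,
minor allele frequency >= 0.01, Hardy-Weinberg p >= 1e-6, and removal of
progeny whose Mendelian-conflict rate exceeds 1%.
"""

import wgblup as w

sim = w.simulate(
    w.SimConfig(n_founders=80, n_generations=3, offspring_per_mating=2,
                n_snps=400, n_qtl=5, seed=2)
)
corrupted, truth = w.corrupt_genotypes(
    sim.genotypes,
    missing_rate=0.08,
    conflict_pairs=3,
    conflicts_per_progeny=8,
    pedigree=sim.pedigree,
    seed=2,
)
clean, report = w.run_qc(corrupted, pedigree=sim.pedigree)

print(report.summary())
print()
injected = sorted(c["progeny"] for c in truth["conflicts"])
print(f"progeny with injected conflicts: {injected}")
print(f"progeny removed by the filter:   {sorted(report.removed_animals)}")
print()
print("8 conflicts over ~400 jointly-called SNPs is a 2% rate, above the 1%")
print("threshold, so every injected progeny is removed; missing dosages in the")
print("kept SNPs are mean-imputed to 2p so they center to zero downstream.")
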