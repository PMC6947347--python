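"""Full method comparison: PBLUP vs GBLUP vs weighted GBLUP.

Runs the complete evaluation on one simulated population with major QTL:
quality control, pedigree REML, corrected phenotypes, then plain GBLUP and
two iterative SNP-weighting schemes (linear d_i = u_i^2; nonlinearA
d_i = 1.25^min(|u_i|/sd - 2, 20)), each re-estimating SNP effects from the
weighted genomic relationship matrix at every round.
"""

import wgblup as w
from wgblup.pipeline import default_cutoff, run_study

config = w.SimConfig(
    n_founders=300, n_generations=4, offspring_per_mating=2,
    matings_per_generation=(110, 110, 110), n_snps=800, n_qtl=10,
    qtl_variance_fraction=0.5, h2_true=0.4, seed=4,
)
sim = w.simulate(config)
result = run_study(
    sim.pedigree, sim.genotypes, sim.phenotypes, w.ModelSpec(),
    schemes=[
        {"kind": "nonlinearA", "ct": 1.25, "exponent_limit": 20, "n_iterations": 4},
        {"kind": "linear", "n_iterations": 10},
    ],
    cutoff_date=default_cutoff(config),
)

print("per-iteration accuracy and bias on the validation generation:")
print(result.report.rows.round(3).to_string(index=False))
print()
print("selected-iteration summary (best accuracy per method):")
print(w.compare_methods(result.report).round(3).to_string(index=False))
print()
print("expected pattern: GBLUP clearly beats PBLUP; nonlinearA weighting adds")
print("a further gain and declines only gently after its peak, while linear")
print("weighting degrades steadily after iteration ~2 with worsening bias")
print("(slopes drifting far below 1 mean over-dispersed predictions).")
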