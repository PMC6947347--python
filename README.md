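# wgblup

Pedigree BLUP, GBLUP and iteratively weighted GBLUP (WGBLUP) for genomic
evaluation of quantitative traits, with a synthetic-data generator for
pedigreed, genotyped populations.

The package is aimed at animal-breeding researchers who want a transparent,
fully tested desk-scale implementation of the classic genomic-evaluation
stack: it reproduces, on simulated data, the standard comparison of
pedigree-based prediction (PBLUP), genomic prediction with an unweighted
relationship matrix (GBLUP), and iterative SNP-weighting variants (WGBLUP
with linear and VanRaden "nonlinearA" weights) under forward validation.

## The models

All methods fit the single-trait animal model

```
y = Xb + Za + e,    a ~ N(0, K sigma_a^2),    e ~ N(0, I sigma_e^2)
```

where `b` holds fixed effects (herd, sex, an age covariate), `a` the additive
genetic effects, and the kernel `K` is:

- **PBLUP** — the pedigree numerator relationship matrix `A` (tabular method;
  diagonal `1 + F` with `F` the inbreeding coefficient);
- **GBLUP** — VanRaden's genomic relationship matrix
  `G = M M' / Σ 2 p_i (1 − p_i)`, `M` the column-centered dosage matrix;
- **WGBLUP** — the weighted matrix `G* = M D M' / Σ 2 p_i (1 − p_i)` with a
  diagonal matrix `D` of per-SNP weights.

The WGBLUP weights are updated iteratively (10 rounds by convention): solve
GBLUP with the current `G*` for direct genomic values `ĝ`, backsolve SNP
effects `û = λ D M' G*⁻¹ ĝ`, update `d_i = û_i²` (linear) or
`d_i = CT^min(|û_i|/sd(û) − 2, limit)` (nonlinearA, `CT` ∈ {1.125, 1.25},
limit ∈ {5, 10, 20}), then rescale so `Σ d_i = m`. Iteration 1 uses `D = I`
and is exactly plain GBLUP.

Genomic models use corrected phenotypes `Yc = y − Xb̂` (fixed effects from
the pedigree fit) as the response. Variance components come from an exact
one-dimensional REML (eigendecomposition of the projected kernel). Forward
validation splits animals by birth date; prediction quality is

```
accuracy = cor(GEBV, Yc) / sqrt(h2)        bias = slope of Yc on GEBV
```

with slopes near 1 indicating no dispersion bias.

The simulator generates multi-generation pedigrees with half-sib family
structure, gene-drops independent SNPs through them, and builds traits from a
configurable mix of major QTL and polygenic background, plus herd/sex/age
fixed effects — everything the models above assume, with the truth (breeding
values, SNP effects) retained for checking.

## Worked example

`examples/05_weighted_gblup.py` simulates a 930-animal population (10 QTL
carrying 50% of the additive variance of a trait with h² = 0.4), evaluates
all methods, and prints the per-iteration validation table; abbreviated:

```
                        method  iteration  accuracy  bias
                         PBLUP          0     0.233 0.569
                         GBLUP          1     0.547 0.939
WGBLUP_nonlinearA_CT1.25_lim20          2     0.557 0.814
                 WGBLUP_linear          2     0.517 0.581
                 WGBLUP_linear         10     0.402 0.417
```

Genomic information lifts accuracy far above the pedigree-only baseline;
nonlinearA weighting adds a further gain on this major-QTL trait, while
linear weighting over-concentrates weight on large effects and degrades with
iteration, its slope drifting well below 1 (over-dispersion). The other
examples cover simulation, pedigree relationships, QC, REML/GBLUP, and the
config-driven pipeline; a thin CLI (`wgblup run|simulate|validate-config`)
wraps the same code.

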