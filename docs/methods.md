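# Methods

## Model

All predictions come from the single-trait animal model
`y = Xb + Za + e` with `a ~ N(0, K σ²_a)` and `e ~ N(0, I σ²_e)`. Fixed
effects are herd and sex as factors (reference-level dummy coding) and
slaughter age in days as a covariate; sex is treated as a factor rather than
a covariate because it is categorical. `Z` maps phenotype records to the
animals carried by the kernel, so animals without records (e.g. validation
animals) still receive predictions through their relationships.

Solutions come from Henderson's mixed-model equations

```
[ X'X   X'Z            ] [b]   [X'y]
[ Z'X   Z'Z + K⁻¹ k    ] [a] = [Z'y],   k = σ²_e / σ²_a,
```

solved densely by default (this is a desk-scale package; everything is
`n ≤ a few thousand`). A Jacobi-preconditioned conjugate-gradient path with a
relative-residual tolerance of 1e-15 is available for the iterative-solver
convention.

## Kernels

- **A** (pedigree): tabular method, `A_ii = 1 + 0.5 A_sd`,
  `A_ij = 0.5 (A_js + A_jd)`; unknown parents map to the base population (no
  unknown-parent groups). Inbreeding is also computed by a Meuwissen–Luo
  style recursion that traces each animal's ancestor contributions without
  storing A; the two agree on the diagonal to 1e-12. Parents appearing only
  in sire/dam columns are auto-added as founders.
- **G** (genomic): `G = M M' / Σ 2 p_i (1 − p_i)` with `M = dosages − 2 p_i`.
  Frequencies are observed post-QC frequencies (base-population frequencies
  are not estimated). A consequence worth knowing: with own-data frequencies
  the column means of `M` are zero, so `G·1 = 0` and G is always singular.
- **G\*** (weighted): `G* = M D M' / Σ 2 p_i (1 − p_i)`. With `D = I` this
  code path reproduces G bit-for-bit, which is what makes the iteration-1 ≡
  GBLUP identity exact rather than approximate.

**Conditioning.** Before inversion G (or G\*) is blended:
`G_c = 0.95 G + 0.05 A22` when a pedigree is available, else `0.95 G +
0.05 I`. The 5% default mirrors the common preprocessing convention in
genomic-evaluation pipelines; invertibility is then verified by a Cholesky
factorization of `G_c − 1e-8 I` (i.e. the smallest eigenvalue must exceed
1e-8). No further scaling of G toward A is attempted.

## Variance components

REML for the one-kernel model is exact: with `H = Z K Z' = U S U'`, rotating
by `U` makes the covariance diagonal, `σ²_e (γ s_i + 1)` with
`γ = σ²_a/σ²_e`; `σ²_e` is profiled out in closed form and the restricted
likelihood is maximized over `log γ` by bounded scalar search
(`log γ ∈ [−14, 14]`, xatol 1e-10). Estimates at the search bounds are
flagged as boundary solutions. Standard errors come from the numerical
Hessian of the restricted log-likelihood at the optimum, with the h² SE by
the delta method. Correctness anchors: the balanced one-way layout, where
REML equals the ANOVA closed form (σ²_e = MSW, σ²_a = (MSB − MSW)/k), and
recovery of the generative h² on simulated data.

Variance components are estimated once per trait — on the training data,
with the unweighted (iteration-1) kernel for the genomic models — and held
fixed across all weighting iterations; per-iteration re-estimation is not
part of the iterative scheme.

## Corrected phenotypes and validation

`Yc = y − X b̂` with the fixed effects estimated from the pedigree-based fit
on **all** phenotyped animals: validation animals need corrected phenotypes
too, and fixed-effect contrasts (herd, sex, age) are not what forward
validation is meant to test. Validation animals' phenotypes are excluded
from every training fit (pedigree and genomic). The split is by birth date:
validation = born strictly after the cut-off; an animal born exactly on the
cut-off date trains.

`accuracy = cor(prediction, Yc)/√h²` uses the pedigree-model training REML
h² as the denominator — a single per-trait value applied to every method, so
method comparisons are unaffected by the choice. `bias` is the OLS slope of
Yc on predictions (1 = no dispersion bias; < 1 = over-dispersed
predictions).

## Iterative SNP weighting

Per round `t` (weights `d(1) = 1`):

1. build `G*(t)` from `d(t)` and condition it;
2. solve the GBLUP system on Yc for direct genomic values `ĝ(t)` (in this
   genotyped-only setting DGV and GEBV coincide);
3. backsolve SNP effects `û(t) = λ D(t) M' G*(t)⁻¹ ĝ(t)`, using the inverse
   of the conditioned kernel — the same matrix the solver used;
4. update weights: linear `d_i = û_i²`, or nonlinearA
   `d_i = CT^min(|û_i|/sd(û) − 2, limit)` with `sd` the sample SD (m−1
   denominator) of the current effect vector, recomputed each round;
5. normalize `d ← d · m / Σd` immediately after the update, so the trace of
   D (total genetic variance) is constant at m;
6. repeat; 10 rounds by default, full trace retained, no early stopping.

Choices made where the procedure is genuinely open: the exponent cap applies
on the upper side only (its natural floor is −2 at `û_i = 0`, so weights are
bounded in `[CT⁻², CT^limit]`; the cap exists to prevent extreme *large*
weights); weights are per-SNP (no windowing); the 1e-15 convergence constant
is assigned to the linear-system solver, not to the weight loop, which runs a
fixed iteration count. The backsolve's design matrix is the centered dosage
matrix M — the same object that defines G and G\*.

The ridge/kernel duality is the central correctness oracle: with a full-rank
unblended G (external allele frequencies), GEBV from the animal model must
equal `M û` from the equivalent SNP-BLUP ridge system with
`σ²_u = λ σ²_a`, and the backsolve with `D = I` must return the ridge
solutions; both hold to < 1e-8 in the tests.

## Quality control

Fixed filter order — call rate, MAF, Hardy–Weinberg, Mendelian conflict —
with each removed SNP attributed to the first filter that rejects it (order
changes counts, so it is pinned and recorded in the report). Boundary
semantics are strict inequalities: removal requires call rate < 0.9,
MAF < 0.01, HWE p < 1e-6, conflict rate > 1%. HWE is the 1-df Pearson
chi-square goodness-of-fit test (not the exact test), computed from allele
frequencies of the non-missing calls; monomorphic SNPs fit HWE trivially but
fall to the MAF filter first. The Mendelian-conflict rate divides
opposing-homozygote counts by *jointly-called* SNPs of the parent–progeny
pair (the plausible reading; recorded in the report), and removes the
progeny. Remaining missing dosages are mean-imputed to `2 p_i`, which is
exactly zero after centering.

## The simulator

What it emulates: a multi-generation livestock population — non-overlapping
generations, a small set of sires reused across matings (half-sib families,
which give A its information), dams mated once, sexes alternating within a
generation so both sexes always exist; birth dates advance one year per
generation with sub-year jitter so a date cut-off cleanly separates
generations. Founder allele frequencies are uniform on (0.05, 0.5];
genotypes descend by Mendelian segregation (heterozygous parents transmit a
fair coin). Traits: `n_qtl` designated QTL carry `qtl_variance_fraction` of
the additive variance, remaining SNPs a small equal-variance polygenic
background; `σ²_a = residual_sd² · h²/(1 − h²)` and the true breeding values
are rescaled so their realized variance matches it exactly (so h² recovery
experiments test the estimator, not the generator's sampling noise). QTL are
members of the SNP panel by default (`hide_qtl` exists but defaults off),
matching evaluation settings where models see only the panel. Fixed effects:
random herd assignment with N(0, herd_sd²) herd effects, an additive sex
effect, and a linear age effect on an age of N(900, 30²) days.

What it does **not** emulate — and what passing tests therefore do not show
about real data: linkage disequilibrium (SNPs segregate independently; no
recombination map, no LD decay), selection across generations, genotyping
batch effects or allele miscalls beyond the injected missingness/conflict
defects, and non-additive genetic variance. Results on simulated data speak
to the correctness and relative behavior of the estimators under the stated
architecture, not to absolute accuracies achievable in any particular breed.

Defaults: h² = 0.4 (a typical moderate-to-high carcass-trait heritability),
residual_sd = 1 (trait units are arbitrary), herd_sd = 0.5, sex effect 0.3,
age slope 0.01/day. One RNG stream per run, seeded in the config; every
stochastic operation takes the stream, so equal seeds give byte-identical
output.

## Problem sizes used by the tests and the acceptance script

The identity checks run at n = 200 animals × m = 500 SNPs; REML parameter
recovery at n = 2000 × m = 2000 over 20 replicates; the method-comparison
experiments (major-QTL gain, polygenic no-harm, linear-weighting
degradation) at n_train = 1000, n_valid = 300, m = 1000 over 20 replicates
— sizes chosen so the complete suite runs in minutes on a single CPU while
keeping the qualitative contrasts far clearer than their sampling noise.
`scripts/acceptance.py` uses the same scenario with 6 replicates per
architecture.

## Known limitations

Genotyped-animals-only analyses (no single-step H-matrix combining genotyped
and non-genotyped animals); single-trait REML only (no genetic
correlations); dense linear algebra throughout (no sparse A-inverse, APY or
windowed weighting variants); mean imputation only. The PLINK codec covers
the v1.00 SNP-major .bed layout only.
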