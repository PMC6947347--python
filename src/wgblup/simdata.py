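"""Synthetic pedigreed populations for genomic-evaluation experiments.

The generator mirrors the data structure a single-trait animal model assumes:
a multi-generation pedigree with half-sib families (sires reused across
matings), SNP genotypes gene-dropped through the pedigree, a trait controlled
by a configurable mix of major QTL and polygenic background, and fixed effects
(herd, sex, slaughter-age covariate) on top of the breeding value.

Generations are non-overlapping and SNPs segregate independently (no
recombination map); the point is statistical structure, not LD realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, default_snp_meta
from .pedigree import UNKNOWN, Pedigree

BASE_DATE = pd.Timestamp("2010-01-01")
DAYS_PER_GENERATION = 365


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of one simulated population.

    ``h2_true`` and ``residual_sd`` jointly fix the additive variance:
    sigma_a^2 = residual_sd^2 * h2 / (1 - h2), and SNP effects are rescaled so
    the realized variance of the true breeding values matches it exactly.
    ``qtl_variance_fraction`` is the share of that additive variance carried by
    the ``n_qtl`` designated QTL; 0 means a purely polygenic trait (every SNP
    an equal-variance effect), 1 means only the QTL have effects.
    """

    n_founders: int = 100
    n_generations: int = 3
    offspring_per_mating: int = 2
    matings_per_generation: int | Sequence[int] | None = None
    n_snps: int = 500
    n_qtl: int = 10
    qtl_variance_fraction: float = 0.5
    h2_true: float = 0.4
    n_herds: int = 5
    herd_sd: float = 0.5
    sex_effect: float = 0.3
    age_slope: float = 0.01
    age_mean_days: float = 900.0
    age_sd_days: float = 30.0
    mean: float = 0.0
    residual_sd: float = 1.0
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    sire_fraction: float = 0.1
    hide_qtl: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.h2_true < 1:
            raise SimulationError("h2_true must lie in (0, 1)")
        if not 0 <= self.qtl_variance_fraction <= 1:
            raise SimulationError("qtl_variance_fraction must lie in [0, 1]")
        if self.n_qtl > self.n_snps:
            raise SimulationError("n_qtl cannot exceed n_snps")
        lo, hi = self.founder_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise SimulationError("founder_maf_range must lie within (0, 0.5]")
        for name in ("n_founders", "n_generations", "offspring_per_mating", "n_snps"):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def matings_for_generation(self, g: int, n_dams: int) -> int:
        """Number of matings producing generation ``g`` (1-based)."""
        m = self.matings_per_generation
        if m is None:
            return n_dams
        if isinstance(m, (int, np.integer)):
            return int(m)
        seq = list(m)
        if len(seq) < self.n_generations - 1:
            raise SimulationError(
                "matings_per_generation sequence shorter than n_generations - 1"
            )
        return int(seq[g - 1])


@dataclass
class SimOutput:
    """Everything a downstream evaluation needs, plus the simulation truth."""

    pedigree: Pedigree
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    true_breeding_values: pd.Series
    true_snp_effects: pd.Series
    qtl_ids: list[str]
    realized_h2: float

    def write(self, outdir) -> None:
        """Dump pedigree/phenotypes/truth as CSV and genotypes as text dosages."""
        from pathlib import Path

        from .genotypes import write_dosage_text

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.pedigree.write_csv(outdir / "pedigree.csv")
        self.phenotypes.to_csv(outdir / "phenotypes.csv", index=False)
        write_dosage_text(self.genotypes, outdir / "genotypes.tsv")
        self.true_breeding_values.rename("tbv").to_csv(outdir / "true_breeding_values.csv")
        self.true_snp_effects.rename("effect").to_csv(outdir / "true_snp_effects.csv")


def simulate_pedigree(config: SimConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Non-overlapping-generation pedigree with half-sib family structure.

    Founders form generation 0; each later generation is produced by mating a
    small set of sires (``sire_fraction`` of the previous generation's males,
    reused across matings) to dams used once each.  Sex alternates within each
    generation so both sexes are always available.  Birth dates advance one
    year per generation with a small within-generation jitter, so a cut-off
    date between generations splits them cleanly.
    """
    rng = config.rng() if rng is None else rng
    animals: list[dict] = []
    counter = 0

    def new_animal(gen: int, sire, dam) -> dict:
        nonlocal counter
        counter += 1
        idx_in_gen = len([a for a in animals if a["generation"] == gen])
        jitter = int(rng.integers(0, 180))
        return {
            "animal": f"A{counter}",
            "sire": sire,
            "dam": dam,
            "sex": "M" if idx_in_gen % 2 == 0 else "F",
            "generation": gen,
            "birth_date": BASE_DATE + pd.Timedelta(days=DAYS_PER_GENERATION * gen + jitter),
        }

    for _ in range(config.n_founders):
        animals.append(new_animal(0, None, None))

    for g in range(1, config.n_generations):
        prev = [a for a in animals if a["generation"] == g - 1]
        males = [a["animal"] for a in prev if a["sex"] == "M"]
        females = [a["animal"] for a in prev if a["sex"] == "F"]
        if not males or not females:
            raise SimulationError(
                f"generation {g} has no candidate parents "
                f"({len(males)} sires, {len(females)} dams available)"
            )
        n_matings = config.matings_for_generation(g, len(females))
        if n_matings < 1:
            raise SimulationError(f"generation {g} has no matings")
        if n_matings > len(females):
            raise SimulationError(
                f"generation {g} requests {n_matings} matings but only "
                f"{len(females)} dams are available"
            )
        n_sires = max(1, int(round(config.sire_fraction * len(males))))
        sires = rng.choice(males, size=min(n_sires, len(males)), replace=False)
        dams = rng.choice(females, size=n_matings, replace=False)
        for dam in dams:
            sire = str(rng.choice(sires))
            for _ in range(config.offspring_per_mating):
                animals.append(new_animal(g, sire, str(dam)))

    return Pedigree(pd.DataFrame(animals))


def gene_drop_genotypes(
    pedigree: Pedigree, config: SimConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Drop alleles through the pedigree by Mendelian segregation.

    Founder genotypes are two Bernoulli(p_i) draws per SNP, with p_i uniform on
    ``founder_maf_range``; every non-founder receives one allele per parent
    (heterozygous parents transmit a fair coin).  No missingness is produced —
    use :func:`corrupt_genotypes` to create QC fixtures.
    """
    rng = config.rng() if rng is None else rng
    m = config.n_snps
    lo, hi = config.founder_maf_range
    founder_freqs = rng.uniform(lo, hi, size=m)

    n = pedigree.n
    dosages = np.empty((n, m))
    s_idx, d_idx = pedigree.sire_idx, pedigree.dam_idx
    for i in range(n):
        si, di = s_idx[i], d_idx[i]
        if si == UNKNOWN and di == UNKNOWN:
            dosages[i] = rng.binomial(2, founder_freqs)
        elif si == UNKNOWN or di == UNKNOWN:
            raise SimulationError(
                f"non-founder '{pedigree.ids[i]}' has an unknown parent; "
                "gene dropping needs both parents"
            )
        else:
            dosages[i] = _transmit(dosages[si], rng) + _transmit(dosages[di], rng)
    g = GenotypeMatrix(dosages, pedigree.ids, default_snp_meta(m))
    g.founder_freqs = founder_freqs  # type: ignore[attr-defined]
    return g


def _transmit(parent_dosage: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    het = parent_dosage == 1
    allele = (parent_dosage == 2).astype(float)
    allele[het] = rng.integers(0, 2, size=int(het.sum()))
    return allele


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    snp_effects: np.ndarray | None = None,
) -> SimOutput:
    """Attach QTL effects, breeding values, fixed effects and residuals.

    QTL indices are drawn without replacement and their effects rescaled so the
    designated QTL carry ``qtl_variance_fraction`` of the additive variance;
    the remaining SNPs carry small equal-variance polygenic effects when the
    fraction is below 1.  True breeding values are centered to the founder mean
    and rescaled so their realized variance equals sigma_a^2 exactly.

    ``snp_effects`` overrides the sampled/scaled allele-substitution effects
    (useful for constructing exact scenarios); no rescaling is applied then.
    """
    rng = config.rng() if rng is None else rng
    m = genotypes.n_snps
    n = genotypes.n_animals
    W = genotypes.dosages
    if np.isnan(W).any():
        raise SimulationError("genotypes must be complete before phenotype simulation")

    sigma_a2 = config.residual_sd**2 * config.h2_true / (1 - config.h2_true)
    if config.residual_sd == 0:
        sigma_a2 = 1.0  # noise-free mode: scale of u is set by the raw effects

    qtl_idx = np.sort(rng.choice(m, size=config.n_qtl, replace=False))
    u = np.zeros(m)
    frac = config.qtl_variance_fraction
    if snp_effects is not None:
        u = np.asarray(snp_effects, dtype=float).copy()
        if u.shape != (m,):
            raise SimulationError("snp_effects must have one entry per SNP")
        qtl_idx = np.flatnonzero(u != 0)
    elif frac > 0:
        u_q = rng.normal(size=config.n_qtl)
        u[qtl_idx] = u_q
        a_q = W[:, qtl_idx] @ u_q
        v = np.var(a_q, ddof=1)
        if v <= 0:
            raise SimulationError("degenerate QTL variance (monomorphic genotypes?)")
        u[qtl_idx] *= np.sqrt(frac * sigma_a2 / v)
    if snp_effects is None and frac < 1:
        bg_idx = np.setdiff1d(np.arange(m), qtl_idx) if frac > 0 else np.arange(m)
        u_b = rng.normal(size=bg_idx.size)
        a_b = W[:, bg_idx] @ u_b
        v = np.var(a_b, ddof=1)
        if v <= 0:
            raise SimulationError("degenerate polygenic variance (monomorphic genotypes?)")
        u[bg_idx] = u_b * np.sqrt((1 - frac) * sigma_a2 / v)

    tbv = W @ u
    founders = pedigree.is_founder()
    tbv = tbv - tbv[founders].mean()
    v_tbv = np.var(tbv, ddof=1)
    if v_tbv <= 0:
        raise SimulationError("degenerate additive variance: all genotypes monomorphic")
    if snp_effects is None and config.residual_sd > 0:
        scale = np.sqrt(sigma_a2 / v_tbv)
        u *= scale
        tbv *= scale

    rec = pedigree.records
    herd = rng.integers(0, config.n_herds, size=n)
    herd_effects = (
        rng.normal(0.0, config.herd_sd, size=config.n_herds)
        if config.herd_sd > 0
        else np.zeros(config.n_herds)
    )
    sex = rec["sex"].to_numpy() if "sex" in rec else np.full(n, "M")
    age = rng.normal(config.age_mean_days, config.age_sd_days, size=n)
    resid = rng.normal(0.0, config.residual_sd, size=n) if config.residual_sd > 0 else np.zeros(n)

    y = (
        config.mean
        + herd_effects[herd]
        + np.where(sex == "M", config.sex_effect, 0.0)
        + config.age_slope * age
        + tbv
        + resid
    )
    var_e = np.var(resid, ddof=1) if config.residual_sd > 0 else 0.0
    realized_h2 = np.var(tbv, ddof=1) / (np.var(tbv, ddof=1) + var_e) if var_e > 0 else 1.0

    phenotypes = pd.DataFrame(
        {
            "animal": pedigree.ids,
            "herd": [f"H{h + 1}" for h in herd],
            "sex": sex,
            "age": age,
            "birth_date": rec["birth_date"].to_numpy() if "birth_date" in rec else pd.NaT,
            "generation": rec["generation"].to_numpy() if "generation" in rec else 0,
            "y": y,
        }
    )
    snp_ids = genotypes.snp_ids
    qtl_ids = [snp_ids[i] for i in qtl_idx]
    out_genotypes = genotypes
    if config.hide_qtl and frac > 0:
        keep = np.ones(m, dtype=bool)
        keep[qtl_idx] = False
        out_genotypes = genotypes.subset_snps(keep)
    return SimOutput(
        pedigree=pedigree,
        genotypes=out_genotypes,
        phenotypes=phenotypes,
        true_breeding_values=pd.Series(tbv, index=pedigree.ids, name="tbv"),
        true_snp_effects=pd.Series(u, index=snp_ids, name="effect"),
        qtl_ids=qtl_ids,
        realized_h2=float(realized_h2),
    )


def simulate(config: SimConfig) -> SimOutput:
    """Pedigree + gene drop + phenotypes from one seeded RNG stream."""
    rng = config.rng()
    ped = simulate_pedigree(config, rng)
    geno = gene_drop_genotypes(ped, config, rng)
    return simulate_phenotypes(geno, ped, config, rng)


def corrupt_genotypes(
    genotypes: GenotypeMatrix,
    missing_rate: float = 0.0,
    conflict_pairs: int = 0,
    conflicts_per_progeny: int = 2,
    pedigree: Pedigree | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, dict]:
    """Inject known defects for QC testing; returns (corrupted, truth log).

    Randomly masks ``missing_rate`` of all calls and, for ``conflict_pairs``
    progeny with a genotyped parent, overwrites ``conflicts_per_progeny``
    progeny calls to the homozygote opposite the parent's.  Conflict sites (and
    the parent's calls there) are protected from masking so every injected
    defect remains detectable.
    """
    if not 0 <= missing_rate <= 1:
        raise SimulationError("missing_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed) if rng is None else rng
    g = genotypes.copy()
    n, m = g.dosages.shape
    log: dict = {"masked": [], "conflicts": []}

    protected = np.zeros((n, m), dtype=bool)
    if conflict_pairs > 0:
        if pedigree is None:
            raise SimulationError("conflict injection needs a pedigree")
        pos = {a: i for i, a in enumerate(g.animal_ids)}
        pairs = [
            (p, c)
            for p, c in pedigree.parent_pairs()
            if p in pos and c in pos
        ]
        # one injected pair per progeny
        seen: set[str] = set()
        pairs = [pc for pc in pairs if not (pc[1] in seen or seen.add(pc[1]))]
        if conflict_pairs > len(pairs):
            raise SimulationError(
                f"requested {conflict_pairs} conflict pairs but only "
                f"{len(pairs)} genotyped parent-progeny pairs exist"
            )
        chosen = rng.choice(len(pairs), size=conflict_pairs, replace=False)
        for k in chosen:
            parent, child = pairs[k]
            pi, ci = pos[parent], pos[child]
            hom = np.flatnonzero(np.isin(g.dosages[pi], (0.0, 2.0)))
            if hom.size < conflicts_per_progeny:
                raise SimulationError(f"parent {parent} has too few homozygous sites")
            sites = rng.choice(hom, size=conflicts_per_progeny, replace=False)
            g.dosages[ci, sites] = 2.0 - g.dosages[pi, sites]
            protected[ci, sites] = True
            protected[pi, sites] = True
            log["conflicts"].append(
                {"parent": parent, "progeny": child, "snp_cols": sites.tolist()}
            )

    if missing_rate > 0:
        mask = rng.random((n, m)) < missing_rate
        mask &= ~protected
        g.dosages[mask] = np.nan
        log["masked"] = np.argwhere(mask).tolist()
    return g, log
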