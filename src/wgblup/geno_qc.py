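"""SNP and animal quality control for dosage matrices.

Filter order is fixed — call rate, then minor allele frequency, then
Hardy–Weinberg, then parent–progeny Mendelian conflict — and each removed SNP
is attributed to the first filter that rejects it, so the report counts always
reconcile with the matrix dimensions.  Boundary semantics follow strict
inequalities: a SNP is removed when call rate < threshold or MAF < threshold
or HWE p-value < alpha, and a progeny is removed when its conflict rate is
strictly greater than the rate threshold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .pedigree import Pedigree


class QCError(ValueError):
    pass


@dataclass
class QCReport:
    n_snps_in: int
    n_snps_out: int
    n_animals_in: int
    n_animals_out: int
    removed_call_rate: int
    removed_maf: int
    removed_hwe: int
    removed_animals: list[str]
    conflict_rates: pd.DataFrame  # per parent-progeny pair
    allele_freqs: pd.Series  # post-QC p_i per kept SNP
    thresholds: dict = field(default_factory=dict)
    notes: str = (
        "filter order: call rate -> MAF -> HWE -> Mendelian conflict; "
        "HWE by 1-df Pearson chi-square; conflict rate over jointly-called SNPs"
    )

    def __post_init__(self) -> None:
        removed = self.removed_call_rate + self.removed_maf + self.removed_hwe
        assert self.n_snps_out == self.n_snps_in - removed

    def summary(self) -> str:
        return (
            f"QC: {self.n_snps_in} SNPs in, {self.n_snps_out} kept "
            f"(call rate -{self.removed_call_rate}, MAF -{self.removed_maf}, "
            f"HWE -{self.removed_hwe}); {self.n_animals_in} animals in, "
            f"{len(self.removed_animals)} removed for Mendelian conflict"
        )

    def to_json(self, path=None) -> str:
        payload = {
            "n_snps_in": self.n_snps_in,
            "n_snps_out": self.n_snps_out,
            "n_animals_in": self.n_animals_in,
            "n_animals_out": self.n_animals_out,
            "removed_call_rate": self.removed_call_rate,
            "removed_maf": self.removed_maf,
            "removed_hwe": self.removed_hwe,
            "removed_animals": self.removed_animals,
            "conflict_rates": self.conflict_rates.to_dict(orient="records"),
            "thresholds": self.thresholds,
            "notes": self.notes,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def filter_call_rate(g: GenotypeMatrix, threshold: float = 0.9) -> np.ndarray:
    """Kept-SNP mask: call rate (non-missing / animals) >= threshold."""
    if not 0 < threshold <= 1:
        raise QCError("call-rate threshold must lie in (0, 1]")
    if g.n_animals == 0 or g.n_snps == 0:
        raise QCError("empty genotype matrix")
    return g.call_rates() >= threshold


def filter_maf(g: GenotypeMatrix, threshold: float = 0.01) -> np.ndarray:
    """Kept-SNP mask: minor allele frequency (on non-missing calls) >= threshold."""
    freqs = g.allele_frequencies()
    if np.isnan(freqs).any():
        raise QCError(
            "SNP with all calls missing; run the call-rate filter first"
        )
    maf = np.minimum(freqs, 1.0 - freqs)
    return maf >= threshold


def hwe_test(genotype_counts: tuple[int, int, int]) -> float:
    """Hardy–Weinberg goodness-of-fit p-value (1-df Pearson chi-square).

    ``genotype_counts`` are (n_AA, n_Aa, n_aa).  Expected counts are
    (n p^2, 2 n p q, n q^2) with p taken from the allele counts.  Monomorphic
    SNPs fit HWE exactly (p-value 1).
    """
    n_aa_, n_ab, n_bb = genotype_counts
    if min(genotype_counts) < 0:
        raise QCError("genotype counts must be non-negative")
    n = n_aa_ + n_ab + n_bb
    if n == 0:
        raise QCError("no genotype calls")
    p = (2 * n_aa_ + n_ab) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_aa_, n_ab, n_bb], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def filter_hwe(g: GenotypeMatrix, alpha: float = 1e-6) -> np.ndarray:
    """Kept-SNP mask: HWE chi-square p-value >= alpha (vectorized)."""
    d = g.dosages
    n2 = np.nansum(d == 2, axis=0).astype(float)
    n1 = np.nansum(d == 1, axis=0).astype(float)
    n0 = np.nansum(d == 0, axis=0).astype(float)
    n = n2 + n1 + n0
    if (n == 0).any():
        raise QCError("SNP with all calls missing; run the call-rate filter first")
    p = (2 * n2 + n1) / (2 * n)
    q = 1.0 - p
    mono = (p == 0) | (q == 0)
    pq = np.where(mono, 0.5, p * q)  # dummy to avoid division by zero
    e2, e1, e0 = n * p * p, 2 * n * pq, n * q * q
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = (n2 - e2) ** 2 / np.where(e2 > 0, e2, 1) + (n1 - e1) ** 2 / np.where(
            e1 > 0, e1, 1
        ) + (n0 - e0) ** 2 / np.where(e0 > 0, e0, 1)
    chi2 = np.where(mono, 0.0, chi2)
    pvals = stats.chi2.sf(chi2, df=1)
    pvals = np.where(mono, 1.0, pvals)
    return pvals >= alpha


def mendelian_conflict_filter(
    g: GenotypeMatrix, pedigree: Pedigree, rate_threshold: float = 0.01
) -> tuple[list[str], pd.DataFrame]:
    """Remove progeny whose opposing-homozygote rate with a parent exceeds the
    threshold (strictly).

    A conflict is parent dosage 0 with progeny 2 or parent 2 with progeny 0 at
    a SNP where both calls are non-missing; the rate divides by the number of
    jointly-called SNPs of the pair.  Returns (removed progeny ids, per-pair
    rate table).
    """
    pos = {a: i for i, a in enumerate(g.animal_ids)}
    rows = []
    for parent, child in pedigree.parent_pairs():
        if parent not in pos or child not in pos:
            continue
        dp = g.dosages[pos[parent]]
        dc = g.dosages[pos[child]]
        joint = ~np.isnan(dp) & ~np.isnan(dc)
        n_joint = int(joint.sum())
        conflicts = int(np.sum(np.abs(dp[joint] - dc[joint]) == 2.0))
        rate = conflicts / n_joint if n_joint else np.nan
        rows.append(
            {
                "parent": parent,
                "progeny": child,
                "n_joint": n_joint,
                "n_conflicts": conflicts,
                "rate": rate,
            }
        )
    table = pd.DataFrame(rows, columns=["parent", "progeny", "n_joint", "n_conflicts", "rate"])
    if table.empty:
        warnings.warn("no genotyped parent-progeny pairs; conflict filter is a no-op", stacklevel=2)
        return [], table
    removed = sorted(set(table.loc[table["rate"] > rate_threshold, "progeny"]))
    return removed, table


def impute_mean(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages at SNP i by 2 p_i, which becomes exactly zero
    after the usual centering by 2 p_i."""
    out = g.copy()
    freqs = out.allele_frequencies()
    if np.isnan(freqs).any():
        raise QCError("all-missing SNP cannot be mean-imputed; filter it first")
    miss = np.isnan(out.dosages)
    if miss.any():
        fill = np.broadcast_to(2.0 * freqs, out.dosages.shape)
        out.dosages[miss] = fill[miss]
    return out


def run_qc(
    g: GenotypeMatrix,
    pedigree: Pedigree | None = None,
    call_rate_threshold: float = 0.9,
    maf_threshold: float = 0.01,
    hwe_alpha: float = 1e-6,
    conflict_rate_threshold: float = 0.01,
    impute: bool = True,
) -> tuple[GenotypeMatrix, QCReport]:
    """Full QC pipeline in the fixed filter order, with mean imputation last."""
    n_in, m_in = g.n_animals, g.n_snps
    keep_cr = filter_call_rate(g, call_rate_threshold)
    g1 = g.subset_snps(keep_cr)
    keep_maf = filter_maf(g1, maf_threshold)
    g2 = g1.subset_snps(keep_maf)
    keep_hwe = filter_hwe(g2, hwe_alpha)
    g3 = g2.subset_snps(keep_hwe)

    removed_animals: list[str] = []
    conflict_rates = pd.DataFrame(
        columns=["parent", "progeny", "n_joint", "n_conflicts", "rate"]
    )
    if pedigree is not None:
        removed_animals, conflict_rates = mendelian_conflict_filter(
            g3, pedigree, conflict_rate_threshold
        )
        if removed_animals:
            keep_ids = [a for a in g3.animal_ids if a not in set(removed_animals)]
            g3 = g3.subset_animals(keep_ids)

    if impute:
        g3 = impute_mean(g3)

    report = QCReport(
        n_snps_in=m_in,
        n_snps_out=g3.n_snps,
        n_animals_in=n_in,
        n_animals_out=g3.n_animals,
        removed_call_rate=int((~keep_cr).sum()),
        removed_maf=int((~keep_maf).sum()),
        removed_hwe=int((~keep_hwe).sum()),
        removed_animals=removed_animals,
        conflict_rates=conflict_rates,
        allele_freqs=pd.Series(g3.allele_frequencies(), index=g3.snp_ids, name="p"),
        thresholds={
            "call_rate": call_rate_threshold,
            "maf": maf_threshold,
            "hwe_alpha": hwe_alpha,
            "conflict_rate": conflict_rate_threshold,
        },
    )
    return g3, report
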