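"""Genomic relationship matrices: VanRaden G and its SNP-weighted form G*.

G = M M' / sum_i 2 p_i (1 - p_i), with M the column-centered dosage matrix;
G* replaces M M' by M D M' for a diagonal matrix of per-SNP weights.  Because
both share the same denominator, identity weights reproduce G bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import GenotypeMatrix


class RelmatError(ValueError):
    pass


@dataclass
class CenteredGenotypes:
    """Centered dosages M (animals x SNPs), frequencies and VanRaden scale."""

    M: np.ndarray
    freqs: np.ndarray
    scale: float  # lambda = 1 / sum 2 p (1 - p)
    animal_ids: list[str]
    snp_ids: list[str]

    @property
    def n_animals(self) -> int:
        return self.M.shape[0]

    @property
    def n_snps(self) -> int:
        return self.M.shape[1]


@dataclass
class RelationshipMatrix:
    """Dense symmetric kinship; kind is one of A, G, Gstar."""

    values: np.ndarray
    kind: str
    ids: list[str] = field(default_factory=list)
    conditioning: dict | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def write_lower_triangle(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# " + " ".join(self.ids) + "\n")
            for i in range(self.n):
                for j in range(i + 1):
                    fh.write(f"{i + 1} {j + 1} {self.values[i, j]:.10g}\n")


def center_genotypes(
    g: GenotypeMatrix, freqs: np.ndarray | None = None
) -> CenteredGenotypes:
    """Subtract 2 p_i per SNP and compute lambda = 1 / sum 2 p_i (1 - p_i).

    Frequencies default to those observed in ``g`` (which must be complete,
    i.e. QC'd and imputed).
    """
    if np.isnan(g.dosages).any():
        raise RelmatError("genotypes contain missing calls; impute before centering")
    p = g.allele_frequencies() if freqs is None else np.asarray(freqs, dtype=float)
    if p.shape != (g.n_snps,):
        raise RelmatError("frequency vector length must match the SNP count")
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if denom <= 0:
        raise RelmatError(
            "sum 2p(1-p) is zero: all SNPs monomorphic; MAF-filter the data"
        )
    M = g.dosages - 2.0 * p
    return CenteredGenotypes(M, p, 1.0 / denom, list(g.animal_ids), g.snp_ids)


def build_G(cg: CenteredGenotypes) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix G = lambda M M'."""
    return build_weighted_G(cg, np.ones(cg.n_snps))


def build_weighted_G(cg: CenteredGenotypes, weights) -> RelationshipMatrix:
    """Weighted genomic relationship matrix G* = lambda M diag(d) M'."""
    d = np.asarray(getattr(weights, "d", weights), dtype=float)
    if d.shape != (cg.n_snps,):
        raise RelmatError("one weight per SNP required")
    if (d < 0).any():
        raise RelmatError("SNP weights must be non-negative")
    G = cg.scale * ((cg.M * d) @ cg.M.T)
    G = 0.5 * (G + G.T)
    kind = "G" if np.all(d == 1.0) else "Gstar"
    return RelationshipMatrix(G, kind, list(cg.animal_ids))


def condition_G(
    G: RelationshipMatrix,
    A22: RelationshipMatrix | None = None,
    blend: float = 0.05,
    min_eigenvalue: float = 1e-8,
) -> RelationshipMatrix:
    """Blend G with A22 (or I) so the result is safely invertible.

    G_c = (1 - blend) G + blend A22; identity target when no pedigree matrix
    is supplied.  Invertibility is verified by a Cholesky factorization of
    G_c - min_eigenvalue I, i.e. the smallest eigenvalue must exceed
    ``min_eigenvalue``.
    """
    if not 0 <= blend <= 1:
        raise RelmatError("blend must lie in [0, 1]")
    n = G.n
    if A22 is not None:
        if A22.n != n:
            raise RelmatError("A22 must be ordered and sized like G")
        target = A22.values
        target_name = "A22"
    else:
        target = np.eye(n)
        target_name = "I"
    Gc = (1.0 - blend) * G.values + blend * target
    try:
        np.linalg.cholesky(Gc - min_eigenvalue * np.eye(n))
    except np.linalg.LinAlgError:
        raise RelmatError(
            f"matrix still singular after blending {blend:g} with {target_name}; "
            "increase the blend fraction"
        ) from None
    return RelationshipMatrix(
        Gc,
        G.kind,
        list(G.ids),
        conditioning={"blend": blend, "target": target_name},
    )
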