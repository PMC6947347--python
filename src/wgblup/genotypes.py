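"""Allele-dosage container shared by the simulator, QC and relationship modules.

Dosages count copies of the alternate (a1) allele, so values live in
{0, 1, 2} with ``NaN`` marking a missing call.  Post-imputation dosages are
real numbers in [0, 2].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SNP_META_COLUMNS = ["snp_id", "chrom", "pos", "a1", "a2"]


@dataclass
class GenotypeMatrix:
    """Animals x SNPs dosage matrix with per-SNP metadata.

    Parameters
    ----------
    dosages
        Float array of shape (n_animals, n_snps); NaN encodes a missing call.
    animal_ids
        Ordered animal identifiers (rows).
    snp_meta
        DataFrame with columns snp_id, chrom, pos, a1, a2 (one row per SNP).
    """

    dosages: np.ndarray
    animal_ids: list[str]
    snp_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D animals x SNPs array")
        self.animal_ids = [str(a) for a in self.animal_ids]
        if len(self.animal_ids) != self.dosages.shape[0]:
            raise ValueError(
                f"{len(self.animal_ids)} animal ids for "
                f"{self.dosages.shape[0]} dosage rows"
            )
        if self.snp_meta is None:
            self.snp_meta = default_snp_meta(self.dosages.shape[1])
        self.snp_meta = self.snp_meta.reset_index(drop=True)
        if len(self.snp_meta) != self.dosages.shape[1]:
            raise ValueError(
                f"{len(self.snp_meta)} metadata rows for "
                f"{self.dosages.shape[1]} SNP columns"
            )
        ids = self.snp_meta["snp_id"]
        if ids.duplicated().any():
            raise ValueError("duplicate SNP ids in metadata")

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return self.snp_meta["snp_id"].tolist()

    def allele_frequencies(self) -> np.ndarray:
        """Per-SNP frequency of the counted (a1) allele over non-missing calls.

        SNPs with no non-missing calls yield NaN.
        """
        counts = (~np.isnan(self.dosages)).sum(axis=0)
        sums = np.nansum(self.dosages, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan) / 2.0

    def call_rates(self) -> np.ndarray:
        """Fraction of non-missing calls per SNP."""
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages.copy(), list(self.animal_ids), self.snp_meta.copy()
        )

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeMatrix(
            self.dosages[:, idx],
            list(self.animal_ids),
            self.snp_meta.iloc[idx].reset_index(drop=True),
        )

    def subset_animals(self, keep_ids: list[str]) -> "GenotypeMatrix":
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        idx = [pos[str(a)] for a in keep_ids]
        return GenotypeMatrix(
            self.dosages[idx, :], [self.animal_ids[i] for i in idx], self.snp_meta.copy()
        )

    def animal_index(self, ids: list[str]) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        return np.array([pos[str(a)] for a in ids], dtype=int)


def default_snp_meta(n_snps: int, chrom: int = 1) -> pd.DataFrame:
    """Placeholder metadata for genotypes that carry none (e.g. simulations)."""
    return pd.DataFrame(
        {
            "snp_id": [f"snp{i + 1}" for i in range(n_snps)],
            "chrom": chrom,
            "pos": np.arange(1, n_snps + 1) * 1000,
            "a1": "A",
            "a2": "B",
        }
    )


def write_dosage_text(g: GenotypeMatrix, path) -> None:
    """Write the plain-text dosage dialect: animals x SNPs, TSV, NA missing."""
    df = pd.DataFrame(g.dosages, index=g.animal_ids, columns=g.snp_ids)
    df.index.name = "animal"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")


def read_dosage_text(path, snp_meta: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read the plain-text dosage dialect written by :func:`write_dosage_text`."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    meta = snp_meta
    if meta is None:
        meta = default_snp_meta(df.shape[1])
        meta["snp_id"] = list(df.columns)
    return GenotypeMatrix(df.to_numpy(dtype=float), [str(i) for i in df.index], meta)
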