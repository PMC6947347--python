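"""Minimal PLINK 1 binary (.bed/.bim/.fam) codec for dosage matrices.

Only the SNP-major v1.00 layout is supported (magic bytes 6c 1b 01).  Dosages
count copies of the A1 allele, matching :class:`~wgblup.genotypes.GenotypeMatrix`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit code -> A1 dosage (01 is the missing code)
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def write_plink(g: GenotypeMatrix, prefix) -> None:
    """Write ``prefix``.bed/.bim/.fam.  Non-integer dosages are rejected."""
    prefix = Path(prefix)
    d = g.dosages
    ok = np.isnan(d) | np.isin(d, (0.0, 1.0, 2.0))
    if not ok.all():
        raise ValueError("PLINK bed stores only dosages in {0,1,2,missing}")

    n = g.n_animals
    # dosage -> 2-bit code; index 3 is the NaN sentinel
    codes_lut = np.array([0b11, 0b10, 0b00, 0b01], dtype=np.uint8)
    idx = np.nan_to_num(d, nan=3.0).astype(np.intp)
    codes = codes_lut[idx]  # animals x snps

    pad = (-n) % 4
    if pad:
        # padding animals are written as homozygous A2 (code 0b11 is NOT used:
        # plink pads with zero bits, i.e. code 00; readers ignore them anyway)
        codes = np.vstack([codes, np.zeros((pad, g.n_snps), dtype=np.uint8)])
    c = codes.T.reshape(g.n_snps, -1, 4)  # snp-major groups of 4 animals
    packed = c[:, :, 0] | (c[:, :, 1] << 2) | (c[:, :, 2] << 4) | (c[:, :, 3] << 6)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.astype(np.uint8).tobytes())

    bim = g.snp_meta[["chrom", "snp_id", "pos", "a1", "a2"]].copy()
    bim.insert(2, "cm", 0)
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    fam = pd.DataFrame(
        {
            "fid": g.animal_ids,
            "iid": g.animal_ids,
            "sire": 0,
            "dam": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def read_plink(prefix) -> GenotypeMatrix:
    """Read ``prefix``.bed/.bim/.fam into a :class:`GenotypeMatrix`."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "sire", "dam", "sex", "pheno"],
        dtype=str,
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _MAGIC:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK v1 bed file")
    body = raw[3:]
    bytes_per_snp = (n + 3) // 4
    if body.size != bytes_per_snp * m:
        raise ValueError("bed payload size inconsistent with bim/fam dimensions")
    b = body.reshape(m, bytes_per_snp)
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (b >> (2 * k)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T  # animals x snps
    meta = bim[["snp_id", "chrom", "pos", "a1", "a2"]]
    return GenotypeMatrix(dosages, fam["iid"].tolist(), meta)
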