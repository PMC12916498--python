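"""Minimal PLINK-1 binary trio (.bed/.bim/.fam) reader and writer.

Implements the variant-major 2-bit encoding: per variant, packed pairs of
bits code hom-A1 (00 -> dosage 2), missing (01), het (10 -> 1) and hom-A2
(11 -> 0), where A1 is the .bim allele-1 column and dosages count A1.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from crossmeta.errors import FormatError
from crossmeta.simulate import GenotypeMatrix

_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code per A1 dosage: 2 -> 00, missing -> 01, 1 -> 10, 0 -> 11
_CODE_OF_DOSAGE = {2: 0b00, 1: 0b10, 0: 0b11}
_DOSAGE_OF_CODE = np.array([2, -1, 1, 0], dtype=np.int8)  # -1 = missing


def write_plink(geno: GenotypeMatrix, prefix) -> None:
    """Write dosages and metadata as PLINK-1 .bed/.bim/.fam."""
    prefix = Path(prefix)
    n, m = geno.dosages.shape
    fam = pd.DataFrame({
        "FID": [f"F{i + 1}" for i in range(n)],
        "IID": [f"I{i + 1}" for i in range(n)],
        "PAT": 0, "MAT": 0, "SEX": 0, "PHENO": -9,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", index=False, header=False)
    v = geno.variants
    bim = pd.DataFrame({
        "CHR": v["CHR"], "SNP": v["SNP"], "CM": 0.0, "BP": v["BP"],
        "A1": v["A1"], "A2": v["A2"],
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", index=False, header=False)
    codes = np.empty((m, n), dtype=np.uint8)
    d = geno.dosages.T
    codes[d == 2] = 0b00
    codes[d == 1] = 0b10
    codes[d == 0] = 0b11
    pad = (-n) % 4
    if pad:
        codes = np.concatenate(
            [codes, np.zeros((m, pad), dtype=np.uint8)], axis=1)
    quads = codes.reshape(m, -1, 4)
    packed = (quads[:, :, 0] | (quads[:, :, 1] << 2)
              | (quads[:, :, 2] << 4) | (quads[:, :, 3] << 6))
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.astype(np.uint8).tobytes())


def read_plink(prefix) -> GenotypeMatrix:
    """Read a PLINK-1 trio back into a :class:`GenotypeMatrix`.

    Missing genotypes decode to -1 in the dosage matrix.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["CHR", "SNP", "CM", "BP", "A1", "A2"],
                      dtype={"CHR": str})
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _MAGIC:
        raise FormatError(f"{prefix}.bed is not a variant-major PLINK-1 file")
    body = raw[3:]
    bytes_per_variant = (n + 3) // 4
    if body.size != m * bytes_per_variant:
        raise FormatError(f"{prefix}.bed size does not match .bim/.fam")
    body = body.reshape(m, bytes_per_variant)
    codes = np.empty((m, bytes_per_variant * 4), dtype=np.uint8)
    codes[:, 0::4] = body & 0b11
    codes[:, 1::4] = (body >> 2) & 0b11
    codes[:, 2::4] = (body >> 4) & 0b11
    codes[:, 3::4] = (body >> 6) & 0b11
    dosages = _DOSAGE_OF_CODE[codes[:, :n]].T.copy()
    variants = bim[["SNP", "CHR", "BP", "A1", "A2"]].copy()
    with np.errstate(invalid="ignore"):
        observed = dosages >= 0
        frq = np.where(observed.any(axis=0),
                       np.where(observed, dosages, 0).sum(axis=0)
                       / (2.0 * np.maximum(observed.sum(axis=0), 1)), np.nan)
    variants["FRQ"] = frq
    return GenotypeMatrix(dosages=dosages, variants=variants)
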