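"""PLINK bed/bim/fam and phenotype-table input/output.

The bed codec follows the standard variant-major layout: three magic bytes
``0x6c 0x1b 0x01`` then ``ceil(n_samples / 4)`` bytes per variant, two bits
per sample with sample order running through the low bits first.  Two-bit
codes: ``00`` homozygous allele1, ``10`` heterozygous, ``11`` homozygous
allele2, ``01`` missing — so files written here are readable by PLINK and
vice versa.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix

_MAGIC = bytes([0x6C, 0x1B, 0x01])

# dosage (count of allele1) -> two-bit code, indexed by dosage+1 (missing=-1)
_DOSAGE_TO_CODE = np.array([0b01, 0b11, 0b10, 0b00], dtype=np.uint8)
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)

__all__ = [
    "write_plink",
    "read_plink",
    "write_phenotypes",
    "read_phenotypes",
]


def write_plink(gm: GenotypeMatrix, prefix: str | os.PathLike) -> None:
    """Write a bed/bim/fam triplet for *gm* under *prefix*."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = gm.n_samples, gm.n_variants
    if n == 0 or m == 0:
        raise ValueError("refusing to write an empty cohort")

    codes = _DOSAGE_TO_CODE[gm.dosages.T.astype(np.int16) + 1]  # (m, n)
    pad = (-n) % 4
    if pad:
        # pad bits are zeros (decode as hom-allele1) and are dropped on read
        codes = np.hstack([codes, np.zeros((m, pad), dtype=np.uint8)])
    codes = codes.reshape(m, -1, 4)
    packed = (
        codes[:, :, 0]
        | (codes[:, :, 1] << 2)
        | (codes[:, :, 2] << 4)
        | (codes[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(Path(str(prefix) + ".bed"), "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.tobytes())

    bim = pd.DataFrame(
        {
            "chrom": gm.chrom,
            "id": gm.variant_ids,
            "cm": 0,
            "pos": gm.pos,
            "a1": gm.allele1,
            "a2": gm.allele2,
        }
    )
    bim.to_csv(Path(str(prefix) + ".bim"), sep="\t", header=False, index=False)

    fam = pd.DataFrame(
        {
            "fid": gm.sample_ids,
            "iid": gm.sample_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(Path(str(prefix) + ".fam"), sep="\t", header=False, index=False)


def read_plink(prefix: str | os.PathLike) -> GenotypeMatrix:
    """Read a bed/bim/fam triplet into a :class:`GenotypeMatrix`."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        Path(str(prefix) + ".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        Path(str(prefix) + ".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"iid": str},
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(Path(str(prefix) + ".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _MAGIC:
        raise ValueError(f"{prefix}.bed: bad magic bytes (not variant-major bed)")
    body = raw[3:]
    bytes_per_variant = (n + 3) // 4
    if body.size != m * bytes_per_variant:
        raise ValueError(
            f"{prefix}.bed: expected {m * bytes_per_variant} data bytes, "
            f"found {body.size}"
        )
    body = body.reshape(m, bytes_per_variant)
    codes = np.empty((m, bytes_per_variant * 4), dtype=np.uint8)
    codes[:, 0::4] = body & 0b11
    codes[:, 1::4] = (body >> 2) & 0b11
    codes[:, 2::4] = (body >> 4) & 0b11
    codes[:, 3::4] = (body >> 6) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T  # (n, m)

    return GenotypeMatrix(
        dosages=dosages,
        variant_ids=bim["id"].to_numpy(),
        chrom=bim["chrom"].to_numpy(),
        pos=bim["pos"].to_numpy(),
        allele1=bim["a1"].to_numpy(),
        allele2=bim["a2"].to_numpy(),
        sample_ids=fam["iid"].to_numpy(),
    )


def write_phenotypes(pheno: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write the phenotype table (sample_id, true_status, channels..., billing_count)."""
    pheno = pheno.copy()
    if "sample_id" not in pheno.columns:
        raise ValueError("phenotype table must carry a sample_id column")
    pheno.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing sample_id column")
    return df
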