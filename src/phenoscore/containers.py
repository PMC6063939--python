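"""Core in-memory containers shared across the pipeline.

The central object is :class:`GenotypeMatrix`, a dense samples x variants
dosage matrix (counts of the coded allele ``allele1``) with the variant and
sample metadata a PLINK bed/bim/fam triplet carries.  Dosages are stored as
``int8`` with ``-1`` marking a missing genotype call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

MISSING = -1

__all__ = ["GenotypeMatrix", "MISSING"]


def _as_str_array(x) -> np.ndarray:
    return np.asarray(x, dtype=str)


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix plus metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_variants)`` int8 array with values in ``{0, 1, 2}``
        (count of ``allele1`` copies) or ``-1`` for missing.
    variant_ids, chrom, pos, allele1, allele2
        Per-variant metadata; ``allele1`` is the coded/effect allele
        (the allele whose copies the dosage counts), matching the first
        allele column of a bim file.
    sample_ids
        Per-sample identifiers.
    """

    dosages: np.ndarray
    variant_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    allele1: np.ndarray
    allele2: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.ascontiguousarray(self.dosages, dtype=np.int8)
        self.variant_ids = _as_str_array(self.variant_ids)
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.allele1 = _as_str_array(self.allele1)
        self.allele2 = _as_str_array(self.allele2)
        self.sample_ids = _as_str_array(self.sample_ids)
        n, m = self.dosages.shape
        for name, arr in (
            ("variant_ids", self.variant_ids),
            ("chrom", self.chrom),
            ("pos", self.pos),
            ("allele1", self.allele1),
            ("allele2", self.allele2),
        ):
            if arr.shape != (m,):
                raise ValueError(f"{name} has length {arr.shape}, expected {m}")
        if self.sample_ids.shape != (n,):
            raise ValueError(
                f"sample_ids has length {self.sample_ids.shape[0]}, expected {n}"
            )
        if len(np.unique(self.variant_ids)) != m:
            raise ValueError("duplicate variant ids")
        if len(np.unique(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        bad = ~np.isin(self.dosages, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be in {-1, 0, 1, 2}")
        # positions strictly increasing within each chromosome
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if p.size > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on chrom {c}")

    # ------------------------------------------------------------------ shape
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    # -------------------------------------------------------------- summaries
    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per variant."""
        return (self.dosages != MISSING).mean(axis=0)

    def allele1_freq(self) -> np.ndarray:
        """Frequency of the coded allele per variant (missing excluded).

        All-missing variants yield ``nan``.
        """
        obs = self.dosages != MISSING
        n_obs = obs.sum(axis=0)
        total = np.where(obs, self.dosages, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, total / (2.0 * n_obs), np.nan)

    def maf(self) -> np.ndarray:
        f = self.allele1_freq()
        return np.minimum(f, 1.0 - f)

    def genotype_counts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-variant (hom allele1, het, hom allele2) counts."""
        d = self.dosages
        return (d == 2).sum(axis=0), (d == 1).sum(axis=0), (d == 0).sum(axis=0)

    # ----------------------------------------------------------- float views
    def imputed(self, dtype=np.float64) -> np.ndarray:
        """Dense float dosages with missing calls mean-imputed per variant."""
        x = self.dosages.astype(dtype)
        miss = self.dosages == MISSING
        if miss.any():
            means = (2.0 * np.nan_to_num(self.allele1_freq())).astype(dtype)
            x = np.where(miss, means[None, :], x)
        return x

    def standardized(self, dtype=np.float64) -> np.ndarray:
        """Mean-imputed dosages scaled to (d - 2f) / sqrt(2 f (1-f)).

        Monomorphic variants (zero variance) come back as all-zero columns.
        """
        f = np.nan_to_num(self.allele1_freq())
        sd = np.sqrt(2.0 * f * (1.0 - f))
        x = self.imputed(dtype=dtype)
        x -= (2.0 * f)[None, :].astype(dtype)
        with np.errstate(invalid="ignore", divide="ignore"):
            x = np.where(sd > 0, x / sd[None, :].astype(dtype), 0.0)
        return np.ascontiguousarray(x)

    # -------------------------------------------------------------- subsetting
    def take_variants(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            dosages=np.ascontiguousarray(self.dosages[:, index]),
            variant_ids=self.variant_ids[index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            allele1=self.allele1[index],
            allele2=self.allele2[index],
        )

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            dosages=np.ascontiguousarray(self.dosages[index, :]),
            sample_ids=self.sample_ids[index],
        )
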