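"""Variant quality control: call-rate / MAF filters, exact Hardy-Weinberg
testing, and sliding-window VIF-based LD pruning.

Filter order follows common array-QC practice: non-autosomal variants are
dropped first, then call rate, then minor allele frequency (strictly greater
than the threshold), then the Hardy-Weinberg exact test, then LD pruning.
Each stage is counted separately in the :class:`QcReport`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import gammaln

from .containers import GenotypeMatrix

__all__ = [
    "QcReport",
    "compute_maf",
    "hwe_test",
    "hwe_test_many",
    "filter_variants",
    "ld_prune_vif",
    "run_qc",
]

AUTOSOMES = frozenset(range(1, 23))


@dataclass
class QcReport:
    """Per-stage removal counts for one QC run (stages applied sequentially)."""

    n_input: int
    n_removed_autosome: int = 0
    n_removed_callrate: int = 0
    n_removed_maf: int = 0
    n_removed_hwe: int = 0
    n_removed_prune: int = 0
    maf_min: float = 0.01
    callrate_min: float = 0.90
    hwe_alpha: float = 1e-6
    prune_window: int = 50
    prune_step: int = 5
    prune_vif_max: float = 10.0

    @property
    def n_retained(self) -> int:
        return self.n_input - (
            self.n_removed_autosome
            + self.n_removed_callrate
            + self.n_removed_maf
            + self.n_removed_hwe
            + self.n_removed_prune
        )

    def to_tsv(self, path) -> None:
        import pandas as pd

        rows = [(k, getattr(self, k)) for k in (
            "n_input",
            "n_removed_autosome",
            "n_removed_callrate",
            "n_removed_maf",
            "n_removed_hwe",
            "n_removed_prune",
            "n_retained",
            "maf_min",
            "callrate_min",
            "hwe_alpha",
            "prune_window",
            "prune_step",
            "prune_vif_max",
        )]
        pd.DataFrame(rows, columns=["field", "value"]).to_csv(
            Path(path), sep="\t", index=False
        )


def compute_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency of one dosage column (missing coded -1).

    Raises if every genotype is missing (such a variant fails call-rate
    filtering anyway).
    """
    d = np.asarray(dosages)
    obs = d >= 0
    n_obs = int(obs.sum())
    if n_obs == 0:
        raise ValueError("MAF undefined: all genotypes missing")
    f = d[obs].sum() / (2.0 * n_obs)
    return float(min(f, 1.0 - f))


# --------------------------------------------------------------------------
# Hardy-Weinberg exact test


def _hwe_log_probs(n_het_values: np.ndarray, n: int, n_a: int) -> np.ndarray:
    """Log conditional probabilities of heterozygote counts given allele counts."""
    n_b = 2 * n - n_a
    h = n_het_values
    return (
        h * np.log(2.0)
        + gammaln(n + 1)
        - gammaln((n_a - h) / 2 + 1)
        - gammaln(h + 1)
        - gammaln((n_b - h) / 2 + 1)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
    )


def hwe_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the probabilities of configurations no more probable than the
    observed one (the plain exact test, not mid-p).  Monomorphic variants
    return 1 by convention.
    """
    for v in (n_hom1, n_het, n_hom2):
        if v < 0:
            raise ValueError("genotype counts must be nonnegative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("no genotypes")
    n_a = 2 * n_hom1 + n_het
    n_minor = min(n_a, 2 * n - n_a)
    if n_minor == 0:
        return 1.0
    h_values = np.arange(n_minor % 2, n_minor + 1, 2)
    logp = _hwe_log_probs(h_values, n, n_a)
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[h_values == n_het][0]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def hwe_test_many(gm: GenotypeMatrix) -> np.ndarray:
    """Exact HWE p-value for every variant of *gm* (missing calls excluded)."""
    n_hom1, n_het, n_hom2 = gm.genotype_counts()
    out = np.ones(gm.n_variants)
    for j in range(gm.n_variants):
        total = n_hom1[j] + n_het[j] + n_hom2[j]
        if total == 0:
            continue  # all-missing: call-rate filter handles it
        out[j] = hwe_test(int(n_hom1[j]), int(n_het[j]), int(n_hom2[j]))
    return out


# --------------------------------------------------------------------------
# marginal filters


def filter_variants(
    gm: GenotypeMatrix,
    maf_min: float = 0.01,
    callrate_min: float = 0.90,
    hwe_alpha: float = 1e-6,
) -> tuple[GenotypeMatrix, QcReport]:
    """Sequential autosome -> call-rate -> MAF -> HWE filtering.

    MAF is strict (a variant at exactly *maf_min* is removed); call rate is
    inclusive (exactly *callrate_min* is retained).
    """
    report = QcReport(
        n_input=gm.n_variants,
        maf_min=maf_min,
        callrate_min=callrate_min,
        hwe_alpha=hwe_alpha,
    )

    autosomal = np.isin(gm.chrom, list(AUTOSOMES))
    report.n_removed_autosome = int((~autosomal).sum())
    gm = gm.take_variants(np.flatnonzero(autosomal))

    cr = gm.call_rate()
    keep = cr >= callrate_min
    report.n_removed_callrate = int((~keep).sum())
    gm = gm.take_variants(np.flatnonzero(keep))

    maf = gm.maf()
    keep = np.nan_to_num(maf) > maf_min
    report.n_removed_maf = int((~keep).sum())
    gm = gm.take_variants(np.flatnonzero(keep))

    pvals = hwe_test_many(gm)
    keep = pvals >= hwe_alpha
    report.n_removed_hwe = int((~keep).sum())
    gm = gm.take_variants(np.flatnonzero(keep))

    if gm.n_variants == 0:
        raise ValueError("all variants removed by QC filters")
    return gm, report


# --------------------------------------------------------------------------
# VIF-based LD pruning


def _window_vifs(R: np.ndarray) -> np.ndarray:
    """VIF_j = 1/(1-R^2_j) for each variant in a window correlation matrix.

    Equals the diagonal of inv(R); a tiny ridge keeps exactly collinear
    windows finite (they come out as huge VIFs and are pruned first).
    """
    k = R.shape[0]
    return np.diag(np.linalg.inv(R + 1e-8 * np.eye(k))).copy()


def ld_prune_vif(
    gm: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    vif_max: float = 10.0,
    n_rounds: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window variance-inflation-factor pruning.

    Windows of *window* surviving variants advance by *step* variants; within
    each window the variant with the largest VIF (regression of one variant
    on the other survivors in the window) is removed until all VIFs fall
    below *vif_max*.  Removals are global, and *n_rounds* full passes are
    made over the data.  Ties on the maximal VIF remove the lower-MAF
    variant, then the lower index.

    Returns ``(kept_ids, removed_ids)`` in panel order.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    m = gm.n_variants
    # empirical per-column standardization so window Gram matrices are true
    # correlation matrices (unit diagonal); zero-variance columns become
    # zero columns and are pinned to VIF=1 via fill_diagonal below
    Z = gm.imputed()
    Z -= Z.mean(axis=0)
    sd = Z.std(axis=0)
    np.divide(Z, sd, out=Z, where=sd > 0)
    Z[:, sd == 0] = 0.0
    n = Z.shape[0]
    maf = np.nan_to_num(gm.maf())
    kept = np.ones(m, dtype=bool)

    for _ in range(n_rounds):
        survivors = np.flatnonzero(kept)
        n_before = survivors.size
        start = 0
        while start < survivors.size:
            win = survivors[start : start + window]
            win = win[kept[win]]  # earlier windows of this pass may have pruned
            if win.size >= 2:
                Zw = Z[:, win]
                R = (Zw.T @ Zw) / n
                np.fill_diagonal(R, 1.0)
                live = np.ones(win.size, dtype=bool)
                while live.sum() >= 2:
                    vifs = _window_vifs(R[np.ix_(live, live)])
                    vmax = vifs.max()
                    if vmax < vif_max:
                        break
                    live_idx = np.flatnonzero(live)
                    ties = live_idx[vifs >= vmax * (1 - 1e-12)]
                    # tie-break: lower MAF, then lower panel index
                    order = np.lexsort((win[ties], maf[win[ties]]))
                    drop = ties[order[0]]
                    live[drop] = False
                    kept[win[drop]] = False
            start += step
        if kept.sum() == n_before:
            break  # a pass with no removals is a fixed point; further
                   # passes see identical windows and remove nothing

    return gm.variant_ids[kept], gm.variant_ids[~kept]


# --------------------------------------------------------------------------
# orchestration


def run_qc(
    gm: GenotypeMatrix,
    maf_min: float = 0.01,
    callrate_min: float = 0.90,
    hwe_alpha: float = 1e-6,
    prune: bool = True,
    window: int = 50,
    step: int = 5,
    vif_max: float = 10.0,
    n_rounds: int = 3,
) -> tuple[GenotypeMatrix, QcReport]:
    """Marginal filters followed (optionally) by LD pruning."""
    gm, report = filter_variants(
        gm, maf_min=maf_min, callrate_min=callrate_min, hwe_alpha=hwe_alpha
    )
    report.prune_window = window
    report.prune_step = step
    report.prune_vif_max = vif_max
    if prune and gm.n_variants >= 2:
        kept_ids, removed_ids = ld_prune_vif(
            gm, window=window, step=step, vif_max=vif_max, n_rounds=n_rounds
        )
        report.n_removed_prune = len(removed_ids)
        keep = np.isin(gm.variant_ids, kept_ids)
        gm = gm.take_variants(np.flatnonzero(keep))
    return gm, report
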