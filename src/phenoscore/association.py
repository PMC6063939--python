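"""Per-variant case/control association with PCA adjustment and
genomic-control diagnostics.

Each variant is tested with a Wald test from a logistic regression of the
binary label on the (mean-imputed) coded-allele dosage plus optional
covariates — the per-variant model PLINK's ``--logistic`` fits.  The
genomic inflation factor lambda_gc (median Wald chi-square over the
theoretical chi-square(1) median) and Q-Q plot coordinates summarize
systematic inflation across the panel.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.linalg import svds

from ._glm import fit_logistic_batch
from .containers import GenotypeMatrix

__all__ = [
    "PcaResult",
    "AssocResult",
    "pca",
    "logistic_assoc",
    "lambda_gc",
    "qq_points",
    "CHI2_1_MEDIAN",
]

#: median of the chi-square distribution with one degree of freedom
CHI2_1_MEDIAN = 0.45493642311957246


@dataclass
class PcaResult:
    """Top-k principal components of the standardized genotype matrix."""

    components: np.ndarray          # (n_samples, k) scores, zero mean
    explained_variance: np.ndarray  # (k,) singular-value variances
    k: int


@dataclass
class AssocResult:
    """Per-variant logistic association summary plus cohort diagnostics."""

    table: pd.DataFrame  # variant_id effect_allele other_allele log_or se p converged
    lambda_gc: float

    def wald_chi2(self) -> np.ndarray:
        t = self.table
        ok = t["converged"].to_numpy()
        z = t["log_or"].to_numpy()[ok] / t["se"].to_numpy()[ok]
        return z * z

    def to_tsv(self, path: str | os.PathLike) -> None:
        # %.17g: decimal round-trip of float64, so written weights re-read
        # bit-identically by the external-weights scoring path
        self.table.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "AssocResult":
        t = pd.read_csv(
            path, sep="\t", dtype={"variant_id": str}, float_precision="round_trip"
        )
        res = cls(table=t, lambda_gc=np.nan)
        chi2 = res.wald_chi2()
        res.lambda_gc = lambda_gc(chi2) if chi2.size else np.nan
        return res


def pca(gm: GenotypeMatrix, k: int) -> PcaResult:
    """Top-*k* PCs of the standardized ((d-2f)/sqrt(2f(1-f))) genotypes.

    Deterministic up to machine precision: ARPACK is started from a fixed
    vector and each component's sign is fixed by making its largest-magnitude
    variant loading positive.  ``k=0`` returns an empty covariate block.
    """
    n, m = gm.n_samples, gm.n_variants
    if k < 0 or k > min(n, m) - 1:
        raise ValueError(f"k must be in [0, {min(n, m) - 1}], got {k}")
    if k == 0:
        return PcaResult(np.empty((n, 0)), np.empty(0), 0)
    Z = gm.standardized()
    Z -= Z.mean(axis=0)  # exact column centering (mean-imputation leaves ~0)
    v0 = np.full(min(Z.shape), 1.0 / np.sqrt(min(Z.shape)))
    U, s, Vt = svds(Z, k=k, v0=v0)
    order = np.argsort(s)[::-1]
    U, s, Vt = U[:, order], s[order], Vt[order]
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    scores = U * s
    return PcaResult(
        components=scores,
        explained_variance=(s**2) / max(n - 1, 1),
        k=k,
    )


def logistic_assoc(
    gm: GenotypeMatrix,
    labels: np.ndarray,
    covariates: np.ndarray | None = None,
    max_iter: int = 25,
    tol: float = 1e-8,
) -> AssocResult:
    """Wald logistic association of *labels* on each variant of *gm*.

    Missing dosages are mean-imputed per variant.  Zero-variance variants are
    skipped (``converged=False``, no estimate); quasi-separated variants are
    flagged non-converged.  ``lambda_gc`` is computed from the Wald
    chi-squares of converged variants.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != gm.n_samples:
        raise ValueError("labels length does not match the genotype matrix")
    uniq = np.unique(labels)
    if not np.all(np.isin(uniq, (0, 1))) or uniq.size < 2:
        raise ValueError("labels must contain both classes (0 and 1)")

    G = gm.imputed()
    variance = G.var(axis=0)
    testable = variance > 0

    m = gm.n_variants
    log_or = np.full(m, np.nan)
    se = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    converged = np.zeros(m, dtype=bool)

    if testable.any():
        res = fit_logistic_batch(
            G[:, testable],
            labels.astype(np.float64),
            C=covariates,
            max_iter=max_iter,
            tol=tol,
        )
        idx = np.flatnonzero(testable)
        converged[idx] = res.converged
        ok = idx[res.converged]
        log_or[ok] = res.beta[res.converged]
        se[ok] = res.se[res.converged]
        z2 = (log_or[ok] / se[ok]) ** 2
        pval[ok] = stats.chi2.sf(z2, df=1)

    table = pd.DataFrame(
        {
            "variant_id": gm.variant_ids,
            "effect_allele": gm.allele1,
            "other_allele": gm.allele2,
            "log_or": log_or,
            "se": se,
            "p": pval,
            "converged": converged,
        }
    )
    chi2 = (log_or[converged] / se[converged]) ** 2
    lam = lambda_gc(chi2) if chi2.size else np.nan
    return AssocResult(table=table, lambda_gc=lam)


def lambda_gc(wald_chi2: np.ndarray) -> float:
    """Genomic inflation factor: median chi-square / median of chi-square(1)."""
    stats_arr = np.asarray(wald_chi2, dtype=np.float64)
    stats_arr = stats_arr[np.isfinite(stats_arr)]
    if stats_arr.size == 0:
        raise ValueError("lambda_gc needs at least one finite statistic")
    return float(np.median(stats_arr) / CHI2_1_MEDIAN)


def qq_points(p_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(expected, observed) -log10 quantile pairs for a Q-Q plot.

    Expected quantiles use the (i - 0.5)/n plotting positions; observed
    p-values are sorted ascending so the arrays pair smallest-with-smallest.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return np.empty(0), np.empty(0)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(np.sort(p))
    return expected, observed
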