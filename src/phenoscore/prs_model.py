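"""Polygenic risk scores by p-value thresholding under cross-validation.

The model follows the classic clumping/thresholding recipe: per-variant log
odds ratios estimated by logistic regression on a training split become the
weights, a p-value cutoff selects which variants enter the score, and each
test-set individual receives the mean over selected variants of
(effect-allele dosage x weight) — the PLINK ``--score`` convention.  A grid
of cutoffs is swept and the cutoff with the best fold-mean test AUC is
reported (flagged as selected on the test folds, which is optimistically
biased; the fold plan is shared across phenotype channels so their scores
are comparable).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .association import AssocResult, logistic_assoc
from .containers import GenotypeMatrix
from .evaluation import roc_auc

__all__ = [
    "EmptySelectionError",
    "FoldPlan",
    "WeightSet",
    "ScoreSet",
    "CvResult",
    "default_grid",
    "make_folds",
    "select_by_threshold",
    "score",
    "cross_validated_scores",
    "read_external_weights",
    "harmonize_weights",
    "score_with_external",
]


class EmptySelectionError(ValueError):
    """No variant passed the p-value cutoff."""


def _nan_col_mean(a: np.ndarray) -> np.ndarray:
    """Column nanmean that leaves all-nan columns nan without warnings."""
    out = np.full(a.shape[1], np.nan)
    valid = ~np.all(np.isnan(a), axis=0)
    if valid.any():
        out[valid] = np.nanmean(a[:, valid], axis=0)
    return out


def default_grid(p_min: float = 5e-5, p_max: float = 0.1, n: int = 12) -> np.ndarray:
    """Log-spaced p-value cutoffs, endpoints included (default 12 on [5e-5, 0.1])."""
    if not (0 < p_min < p_max <= 1):
        raise ValueError("need 0 < p_min < p_max <= 1")
    if n < 2:
        raise ValueError("grid needs at least 2 cutoffs")
    grid = np.logspace(np.log10(p_min), np.log10(p_max), n)
    grid[0], grid[-1] = p_min, p_max
    return grid


def _validate_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=np.float64)
    if np.any((grid <= 0) | (grid > 1)) or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing within (0, 1]")
    return grid


@dataclass
class FoldPlan:
    """k-fold assignment shared by all phenotype channels of one cohort."""

    assignments: np.ndarray  # fold index per sample, in {0..k-1}
    k: int
    seed: int

    def train_idx(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)

    def test_idx(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)


def make_folds(labels_by_channel, k: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified fold assignment on the union-of-channels case indicator.

    Using the union indicator gives every channel the same train/test splits
    (so per-channel performances are comparable) while keeping the pooled
    case fraction balanced across folds.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if isinstance(labels_by_channel, pd.DataFrame):
        mat = labels_by_channel.to_numpy()
    else:
        mat = np.column_stack(list(labels_by_channel))
    union = (mat.sum(axis=1) > 0).astype(int)
    n = union.shape[0]
    if union.sum() < k:
        raise ValueError(f"fewer union cases ({union.sum()}) than folds ({k})")
    if (n - union.sum()) < k:
        raise ValueError("fewer controls than folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(n, dtype=np.int64)
    for fold, (_, test) in enumerate(skf.split(np.zeros(n), union)):
        assignments[test] = fold
    return FoldPlan(assignments=assignments, k=k, seed=seed)


@dataclass
class WeightSet:
    """Per-variant scoring weights (log odds ratios on the effect allele)."""

    table: pd.DataFrame  # variant_id, effect_allele, weight, freq
    provenance: str = "internal"

    def __post_init__(self) -> None:
        t = self.table
        for col in ("variant_id", "effect_allele", "weight"):
            if col not in t.columns:
                raise ValueError(f"weight table missing column {col}")
        if t["variant_id"].duplicated().any():
            raise ValueError("duplicate variant ids in weight set")
        if not np.all(np.isfinite(t["weight"].to_numpy(dtype=float))):
            raise ValueError("non-finite weights")

    def __len__(self) -> int:
        return len(self.table)


def select_by_threshold(
    assoc: AssocResult,
    cutoff: float,
    freqs: pd.Series | None = None,
    provenance: str = "internal",
) -> WeightSet:
    """All converged variants with Wald p <= cutoff, weights = log OR.

    *freqs* optionally supplies training effect-allele frequencies (indexed
    by variant id) used later to impute missing dosages when scoring.
    """
    t = assoc.table
    mask = t["converged"].to_numpy() & (t["p"].to_numpy() <= cutoff)
    if not mask.any():
        raise EmptySelectionError(f"no converged variant with p <= {cutoff}")
    sel = t.loc[mask, ["variant_id", "effect_allele", "log_or"]].rename(
        columns={"log_or": "weight"}
    )
    if freqs is not None:
        sel["freq"] = freqs.reindex(sel["variant_id"]).to_numpy()
    return WeightSet(table=sel.reset_index(drop=True), provenance=provenance)


@dataclass
class ScoreSet:
    """Per-sample polygenic scores for one (channel, fold, threshold) cell."""

    sample_ids: np.ndarray
    prs: np.ndarray
    n_variants_used: int
    n_variants_dropped: int
    channel: str = ""
    fold: int = -1
    threshold: float = np.nan


def score(gm: GenotypeMatrix, weights: WeightSet) -> ScoreSet:
    """Mean over scored variants of effect-allele dosage x weight.

    Weight variants absent from the panel are skipped and counted; weights
    whose effect allele matches the panel's ``allele2`` are flipped
    (equivalent to complementing the dosage).  Missing dosages are imputed as
    2 x the training effect-allele frequency when the weight set carries one,
    else as 2 x the panel frequency.
    """
    wt = weights.table
    panel_pos = pd.Series(np.arange(gm.n_variants), index=gm.variant_ids)
    pos = panel_pos.reindex(wt["variant_id"])
    present = pos.notna().to_numpy()
    n_dropped = int((~present).sum())

    wt = wt.loc[present]
    cols = pos[present].to_numpy(dtype=np.int64)
    eff = wt["effect_allele"].to_numpy()
    a1 = gm.allele1[cols]
    a2 = gm.allele2[cols]
    match1 = eff == a1
    match2 = eff == a2
    usable = match1 | match2
    n_dropped += int((~usable).sum())
    wt, cols = wt.loc[usable], cols[usable]
    match1 = match1[usable]
    if len(wt) == 0:
        raise ValueError(
            f"no overlap between weight set and panel "
            f"({n_dropped} weight variants dropped)"
        )

    w = wt["weight"].to_numpy(dtype=np.float64)
    D = gm.dosages[:, cols].astype(np.float64)
    miss = D < 0
    if miss.any():
        if "freq" in wt.columns and wt["freq"].notna().all():
            f_eff = wt["freq"].to_numpy(dtype=np.float64)
            f1 = np.where(match1, f_eff, 1.0 - f_eff)  # as allele1 frequency
        else:
            f1 = np.nan_to_num(gm.allele1_freq()[cols])
        D = np.where(miss, 2.0 * f1[None, :], D)
    # when the effect allele is the panel's allele2, its dosage is (2 - d)
    eff_dosage = np.where(match1[None, :], D, 2.0 - D)
    prs = eff_dosage @ w / len(wt)
    return ScoreSet(
        sample_ids=gm.sample_ids,
        prs=prs,
        n_variants_used=len(wt),
        n_variants_dropped=n_dropped,
    )


@dataclass
class CvResult:
    """Cross-validated PRS scores and the per-cell AUC lattice."""

    grid: np.ndarray                 # thresholds, ascending
    plan: FoldPlan
    scores: np.ndarray               # (n_samples, n_thresholds); each sample
                                     # scored by the fold that held it out
    cell_auc: np.ndarray             # (k, n_thresholds) test AUC, nan if unusable
    cell_n_variants: np.ndarray      # (k, n_thresholds) variants entering the score
    fold_assoc: list[AssocResult]    # per-fold training association results
    fold_freqs: list[pd.Series]      # per-fold training effect-allele freqs
    channel: str
    best_threshold_idx: int
    selection_bias_note: str = (
        "best threshold selected on test-fold AUC (optimistically biased)"
    )

    @property
    def best_threshold(self) -> float:
        return float(self.grid[self.best_threshold_idx])

    def fold_mean_auc(self) -> np.ndarray:
        return _nan_col_mean(self.cell_auc)

    def scores_at_best(self) -> np.ndarray:
        return self.scores[:, self.best_threshold_idx]

    def to_frame(self, sample_ids: np.ndarray) -> pd.DataFrame:
        """Long-format scores TSV: sample_id, channel, fold, threshold, prs."""
        k, t = self.cell_auc.shape
        frames = []
        for j in range(t):
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": sample_ids,
                        "channel": self.channel,
                        "fold": self.plan.assignments,
                        "threshold": self.grid[j],
                        "prs": self.scores[:, j],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def cross_validated_scores(
    gm: GenotypeMatrix,
    labels: np.ndarray,
    covariates: np.ndarray | None,
    grid: np.ndarray,
    plan: FoldPlan,
    channel: str = "",
    best_threshold_idx: int | None = None,
) -> CvResult:
    """Train per-fold weights and score held-out samples over a cutoff grid.

    For each fold, the logistic association runs on the training samples only
    (covariate rows subset identically), weights are the training log ORs,
    and test samples are scored at every cutoff.  ``best_threshold_idx``
    pins the selected cutoff externally (used by the billing-count sweep);
    by default the cutoff with the highest fold-mean test AUC is chosen.
    """
    grid = _validate_grid(grid)
    labels = np.asarray(labels).astype(int)
    n = gm.n_samples
    if labels.shape[0] != n:
        raise ValueError("labels length does not match genotype matrix")
    k, t = plan.k, grid.size
    scores = np.full((n, t), np.nan)
    cell_auc = np.full((k, t), np.nan)
    cell_nv = np.zeros((k, t), dtype=np.int64)
    fold_assoc: list[AssocResult] = []
    fold_freqs: list[pd.Series] = []

    for fold in range(k):
        tr, te = plan.train_idx(fold), plan.test_idx(fold)
        y_tr = labels[tr]
        if len(np.unique(y_tr)) < 2:
            raise ValueError(f"fold {fold}: training labels are single-class")
        gm_tr = gm.take_samples(tr)
        gm_te = gm.take_samples(te)
        cov_tr = covariates[tr] if covariates is not None else None
        assoc = logistic_assoc(gm_tr, y_tr, covariates=cov_tr)
        freqs = pd.Series(gm_tr.allele1_freq(), index=gm_tr.variant_ids)
        fold_assoc.append(assoc)
        fold_freqs.append(freqs)

        for j, cutoff in enumerate(grid):
            try:
                ws = select_by_threshold(assoc, cutoff, freqs=freqs)
            except EmptySelectionError:
                continue  # unusable cell stays nan
            ss = score(gm_te, ws)
            scores[te, j] = ss.prs
            cell_nv[fold, j] = ss.n_variants_used
            y_te = labels[te]
            if len(np.unique(y_te)) == 2:
                cell_auc[fold, j] = roc_auc(ss.prs, y_te)

    if best_threshold_idx is None:
        fold_mean = _nan_col_mean(cell_auc)
        if np.all(np.isnan(fold_mean)):
            raise EmptySelectionError("every (fold, threshold) cell was unusable")
        best_threshold_idx = int(np.nanargmax(fold_mean))

    return CvResult(
        grid=grid,
        plan=plan,
        scores=scores,
        cell_auc=cell_auc,
        cell_n_variants=cell_nv,
        fold_assoc=fold_assoc,
        fold_freqs=fold_freqs,
        channel=channel,
        best_threshold_idx=best_threshold_idx,
    )


# --------------------------------------------------------------------------
# external (published) weights


def read_external_weights(path: str | os.PathLike) -> pd.DataFrame:
    """Read a summary-statistics weights TSV.

    Accepts either the published-GWAS dialect (``variant_id, effect_allele,
    other_allele, OR, p`` — weight = ln OR) or this package's association
    output (``log_or`` column used directly).  Malformed rows (non-finite or
    non-positive OR, missing p) are dropped and counted in the returned
    frame's ``attrs['n_rejected']``.
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"variant_id": str}, float_precision="round_trip"
    )
    return _normalize_weights_frame(df, origin=str(path))


def _normalize_weights_frame(df: pd.DataFrame, origin: str = "weights") -> pd.DataFrame:
    cols = {c.lower(): c for c in df.columns}
    path = origin
    if "variant_id" not in cols or "effect_allele" not in cols:
        raise ValueError(f"{path}: need variant_id and effect_allele columns")
    out = pd.DataFrame(
        {
            "variant_id": df[cols["variant_id"]].astype(str),
            "effect_allele": df[cols["effect_allele"]].astype(str),
        }
    )
    if "other_allele" in cols:
        out["other_allele"] = df[cols["other_allele"]].astype(str)
    if "log_or" in cols:
        out["weight"] = pd.to_numeric(df[cols["log_or"]], errors="coerce")
    elif "or" in cols:
        odds = pd.to_numeric(df[cols["or"]], errors="coerce")
        odds[odds <= 0] = np.nan
        out["weight"] = np.log(odds)
    else:
        raise ValueError(f"{path}: need an OR or log_or column")
    out["p"] = pd.to_numeric(df[cols["p"]], errors="coerce") if "p" in cols else 1.0
    if "converged" in cols:
        conv = df[cols["converged"]]
        if conv.dtype != bool:
            conv = conv.astype(str).str.lower().isin(("true", "1"))
        out.loc[~conv.to_numpy(), "weight"] = np.nan
    good = out["weight"].notna() & out["p"].notna()
    n_rejected = int((~good).sum())
    out = out.loc[good].reset_index(drop=True)
    if len(out) == 0:
        raise ValueError(f"{path}: no usable weight rows")
    out.attrs["n_rejected"] = n_rejected
    return out


def harmonize_weights(gm: GenotypeMatrix, weights: pd.DataFrame) -> pd.DataFrame:
    """Drop weight rows whose alleles match neither panel allele.

    Orientation itself (sign flips for effect allele == panel allele2) is
    handled inside :func:`score`; this reports how many rows are unmatchable.
    """
    panel = pd.DataFrame(
        {"a1": gm.allele1, "a2": gm.allele2}, index=gm.variant_ids
    )
    sub = panel.reindex(weights["variant_id"])
    eff = weights["effect_allele"].to_numpy()
    ok = (eff == sub["a1"].to_numpy()) | (eff == sub["a2"].to_numpy())
    out = weights.loc[ok].reset_index(drop=True)
    out.attrs["n_unmatched"] = int((~ok).sum())
    return out


def score_with_external(
    gm: GenotypeMatrix,
    weights: pd.DataFrame | str | os.PathLike,
    cutoff: float | None = None,
) -> ScoreSet:
    """Score the panel with published weights, optionally p-thresholded.

    ``cutoff=None`` uses every usable weight row; otherwise rows with
    ``p <= cutoff`` (same thresholding machinery as the internal path).
    """
    if not isinstance(weights, pd.DataFrame):
        weights = read_external_weights(weights)
    elif "weight" not in weights.columns:
        weights = _normalize_weights_frame(weights)
    weights = harmonize_weights(gm, weights)
    if cutoff is not None:
        weights = weights.loc[weights["p"] <= cutoff].reset_index(drop=True)
        if len(weights) == 0:
            raise EmptySelectionError(f"no external weight with p <= {cutoff}")
    if len(weights) == 0:
        raise ValueError("no usable external weights after harmonization")
    ws = WeightSet(
        table=weights[["variant_id", "effect_allele", "weight"]],
        provenance="external",
    )
    return score(gm, ws)
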