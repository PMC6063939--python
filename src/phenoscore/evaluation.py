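"""Channel comparison statistics and reports.

Each phenotyping channel is summarized by three discriminative statistics of
its cross-validated polygenic scores, computed on test folds against the
channel's own labels:

* mean difference — mean case PRS minus mean control PRS;
* AUC — probability a random case outscores a random control (ties 1/2);
* OR per SD — exponentiated logistic slope on the standardized PRS.

Fold means and sample standard deviations (n-1) give the "(S.D.)" columns.
The overlap report counts patients labeled positive by exactly one channel,
each pair, and all channels; the billing-count sweep re-runs the pipeline
with cases redefined as "billed at least t times".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._glm import fit_logistic_single

__all__ = [
    "EvalSummary",
    "OverlapReport",
    "roc_auc",
    "mean_difference",
    "or_per_sd",
    "fold_statistics",
    "summarize",
    "overlap_report",
    "billing_count_sweep",
    "compare_channels",
]


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ValueError("both classes required")
    return labels


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(random case > random control), ties half-credited."""
    labels = _check_two_classes(labels)
    scores = np.asarray(scores, dtype=np.float64)
    ranks = rankdata(scores)  # average ranks handle ties
    n1 = int(labels.sum())
    n0 = labels.size - n1
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def mean_difference(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean case score minus mean control score."""
    labels = _check_two_classes(labels)
    scores = np.asarray(scores, dtype=np.float64)
    return float(scores[labels == 1].mean() - scores[labels == 0].mean())


def or_per_sd(scores: np.ndarray, labels: np.ndarray) -> float:
    """Odds ratio per standard-deviation increase of the score.

    Exponentiated slope of a logistic regression of the label on the
    standardized score (mean/SD over all evaluated samples).  Returns nan
    when the fit does not converge (e.g. perfect separation); raises on a
    zero-variance score.
    """
    labels = _check_two_classes(labels)
    scores = np.asarray(scores, dtype=np.float64)
    sd = scores.std()
    if sd == 0:
        raise ValueError("score variance is zero")
    z = (scores - scores.mean()) / sd
    slope, _, converged = fit_logistic_single(z, labels.astype(np.float64))
    return float(np.exp(slope)) if converged else np.nan


@dataclass
class EvalSummary:
    """Fold-aggregated statistics for one channel (or billing sub-phenotype)."""

    channel: str
    mean_diff: float
    mean_diff_sd: float
    auc: float
    auc_sd: float
    or_per_sd: float
    or_per_sd_sd: float
    n_cases: int
    n_controls: int
    threshold: float = np.nan
    per_fold: pd.DataFrame | None = None

    def to_row(self) -> dict:
        return {
            "channel": self.channel,
            "mean_diff": self.mean_diff,
            "mean_diff_sd": self.mean_diff_sd,
            "auc": self.auc,
            "auc_sd": self.auc_sd,
            "or_per_sd": self.or_per_sd,
            "or_per_sd_sd": self.or_per_sd_sd,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "threshold": self.threshold,
        }


def fold_statistics(
    scores: np.ndarray,
    labels: np.ndarray,
    plan,
) -> pd.DataFrame:
    """Per-fold (mean_diff, auc, or_per_sd) of test-fold scores vs labels."""
    labels = np.asarray(labels).astype(int)
    rows = []
    for fold in range(plan.k):
        te = plan.test_idx(fold)
        s, y = scores[te], labels[te]
        ok = np.isfinite(s)
        s, y = s[ok], y[ok]
        if s.size == 0 or y.min() == y.max():
            rows.append((fold, np.nan, np.nan, np.nan))
            continue
        rows.append(
            (
                fold,
                mean_difference(s, y),
                roc_auc(s, y),
                or_per_sd(s, y) if s.std() > 0 else np.nan,
            )
        )
    return pd.DataFrame(rows, columns=["fold", "mean_diff", "auc", "or_per_sd"])


def summarize(
    per_fold: pd.DataFrame,
    channel: str,
    labels: np.ndarray,
    threshold: float = np.nan,
) -> EvalSummary:
    """Mean and sample SD across folds of the three statistics."""
    if len(per_fold) < 2:
        raise ValueError("need at least 2 folds to summarize")
    labels = np.asarray(labels).astype(int)

    def _agg(col):
        v = per_fold[col].to_numpy(dtype=np.float64)
        v = v[np.isfinite(v)]
        if v.size == 0:
            return np.nan, np.nan
        return float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else np.nan

    md, md_sd = _agg("mean_diff")
    auc, auc_sd = _agg("auc")
    orsd, orsd_sd = _agg("or_per_sd")
    return EvalSummary(
        channel=channel,
        mean_diff=md,
        mean_diff_sd=md_sd,
        auc=auc,
        auc_sd=auc_sd,
        or_per_sd=orsd,
        or_per_sd_sd=orsd_sd,
        n_cases=int(labels.sum()),
        n_controls=int((1 - labels).sum()),
        threshold=threshold,
        per_fold=per_fold,
    )


# --------------------------------------------------------------------------
# overlap report


@dataclass
class OverlapReport:
    """Exact set-region counts for the channels' positive label sets."""

    channels: list[str]
    region_counts: dict[frozenset, int]          # exact-membership regions
    channel_totals: dict[str, int]
    by_degree: pd.DataFrame                      # per channel: count/pct by
                                                 # number of agreeing channels

    def three_way_pct(self, channel: str) -> float:
        """Percent of *channel*'s positives found by all channels."""
        full = frozenset(self.channels)
        total = self.channel_totals[channel]
        if total == 0:
            return np.nan
        return 100.0 * self.region_counts.get(full, 0) / total


def overlap_report(labels_by_channel: pd.DataFrame) -> OverlapReport:
    """Region counts of positive sets across >= 2 channels."""
    channels = list(labels_by_channel.columns)
    if len(channels) < 2:
        raise ValueError("need at least 2 channels for an overlap report")
    mat = labels_by_channel.to_numpy().astype(bool)

    region_counts: dict[frozenset, int] = {}
    for r in range(1, len(channels) + 1):
        for combo in combinations(channels, r):
            in_combo = np.array([c in combo for c in channels])
            mask = mat[:, in_combo].all(axis=1) & ~mat[:, ~in_combo].any(axis=1)
            region_counts[frozenset(combo)] = int(mask.sum())

    channel_totals = {c: int(mat[:, i].sum()) for i, c in enumerate(channels)}

    rows = []
    for i, c in enumerate(channels):
        degree = mat.sum(axis=1)
        for d in range(1, len(channels) + 1):
            cnt = int((mat[:, i] & (degree == d)).sum())
            pct = 100.0 * cnt / channel_totals[c] if channel_totals[c] else np.nan
            rows.append((c, d, cnt, pct))
    by_degree = pd.DataFrame(rows, columns=["channel", "n_methods", "count", "pct"])

    # inclusion-exclusion consistency check
    for i, c in enumerate(channels):
        total_from_regions = sum(
            cnt for combo, cnt in region_counts.items() if c in combo
        )
        assert total_from_regions == channel_totals[c]

    return OverlapReport(
        channels=channels,
        region_counts=region_counts,
        channel_totals=channel_totals,
        by_degree=by_degree,
    )


# --------------------------------------------------------------------------
# billing-count sub-phenotypes


def billing_count_sweep(
    gm,
    billing_counts: np.ndarray,
    covariates,
    grid,
    plan,
    thresholds: tuple[int, ...] = (1, 2, 3),
) -> dict[int, EvalSummary]:
    """Re-run the CV PRS pipeline with cases = "billed at least t times".

    The p-value cutoff selected on the full billing cohort (t=1) is reused
    for the stricter subsets, mirroring a fixed-cutoff sensitivity analysis;
    per-fold weights are still retrained with each subset's labels.
    Thresholds leaving fewer cases than folds are reported non-estimable
    (all-nan summary).
    """
    from .prs_model import cross_validated_scores  # local: avoids import cycle

    billing_counts = np.asarray(billing_counts)
    out: dict[int, EvalSummary] = {}
    pinned_idx: int | None = None
    for t in sorted(thresholds):
        labels = (billing_counts >= t).astype(int)
        if labels.sum() < plan.k or (1 - labels).sum() < plan.k:
            out[t] = EvalSummary(
                channel=f"billing_visit{t}",
                mean_diff=np.nan, mean_diff_sd=np.nan,
                auc=np.nan, auc_sd=np.nan,
                or_per_sd=np.nan, or_per_sd_sd=np.nan,
                n_cases=int(labels.sum()),
                n_controls=int((1 - labels).sum()),
            )
            continue
        cv = cross_validated_scores(
            gm,
            labels,
            covariates,
            grid,
            plan,
            channel=f"billing_visit{t}",
            best_threshold_idx=pinned_idx,
        )
        if pinned_idx is None:
            pinned_idx = cv.best_threshold_idx  # t=1 run fixes the cutoff
        stats_df = fold_statistics(cv.scores_at_best(), labels, plan)
        out[t] = summarize(
            stats_df, f"billing_visit{t}", labels, threshold=cv.best_threshold
        )
    return out


# --------------------------------------------------------------------------
# ranking


def compare_channels(
    summaries: dict[str, EvalSummary],
    plans: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Rank channels by fold-mean AUC (descending).

    *plans* optionally maps channel -> an identifier of the fold plan used;
    mismatched identifiers raise, since statistics computed on different
    splits are not comparable.  Exact AUC ties share a rank and are flagged.
    """
    if len(summaries) == 0:
        raise ValueError("no channels to compare")
    if plans is not None and len(set(plans.values())) > 1:
        raise ValueError(f"channels evaluated on different fold plans: {plans}")

    rows = [s.to_row() for s in summaries.values()]
    df = pd.DataFrame(rows).sort_values("auc", ascending=False, kind="stable")
    df["rank"] = df["auc"].rank(ascending=False, method="min").astype(int)
    df["tied"] = df.duplicated("auc", keep=False)
    if len(df) == 1:
        df.attrs["warning"] = "single channel: degenerate ranking"
    return df.reset_index(drop=True)
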