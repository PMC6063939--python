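"""PRS checks: grids, stratified shared folds, thresholded weight selection,
scoring arithmetic, external-weights harmonization, and CV leakage freedom."""

import numpy as np
import pandas as pd
import pytest

import phenoscore as ps
from phenoscore.association import AssocResult
from phenoscore.prs_model import (
    EmptySelectionError,
    WeightSet,
    cross_validated_scores,
    read_external_weights,
)

from conftest import make_gm


def assoc_from(p, log_or=None, converged=None, ids=None):
    m = len(p)
    table = pd.DataFrame(
        {
            "variant_id": ids or [f"v{j}" for j in range(m)],
            "effect_allele": ["A"] * m,
            "other_allele": ["B"] * m,
            "log_or": log_or if log_or is not None else np.linspace(0.1, 0.5, m),
            "se": np.full(m, 0.1),
            "p": np.asarray(p, dtype=float),
            "converged": converged if converged is not None else [True] * m,
        }
    )
    return AssocResult(table=table, lambda_gc=1.0)


class TestGrid:
    def test_default_shape(self):
        g = ps.default_grid()
        assert len(g) == 12
        assert g[0] == pytest.approx(5e-5)
        assert g[-1] == pytest.approx(0.1)
        assert np.all(np.diff(g) > 0)

    @pytest.mark.parametrize("args", [(0.1, 0.1, 12), (0, 0.1, 12), (1e-4, 2, 12)])
    def test_invalid_grid_rejected(self, args):
        with pytest.raises(ValueError):
            ps.default_grid(*args)


class TestMakeFolds:
    def test_partition_and_sizes(self):
        labels = pd.DataFrame({"c": np.r_[np.ones(20), np.zeros(80)].astype(int)})
        plan = ps.make_folds(labels, k=5, seed=0)
        sizes = np.bincount(plan.assignments)
        assert sizes.tolist() == [20] * 5
        assert set(plan.assignments) == set(range(5))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        labels = pd.DataFrame({"c": rng.integers(0, 2, 200)})
        a = ps.make_folds(labels, k=5, seed=3)
        b = ps.make_folds(labels, k=5, seed=3)
        assert np.array_equal(a.assignments, b.assignments)

    def test_stratification_within_one_case(self):
        labels = pd.DataFrame(
            {"c": np.r_[np.ones(50), np.zeros(950)].astype(int)}
        )
        plan = ps.make_folds(labels, k=5, seed=1)
        cases_per_fold = [
            labels["c"].to_numpy()[plan.test_idx(f)].sum() for f in range(5)
        ]
        assert all(9 <= c <= 11 for c in cases_per_fold)

    def test_union_indicator_drives_stratification(self):
        # channels disagree; folds balance their union
        a = np.r_[np.ones(30), np.zeros(170)].astype(int)
        b = np.r_[np.zeros(170), np.ones(30)].astype(int)
        plan = ps.make_folds(pd.DataFrame({"a": a, "b": b}), k=5, seed=2)
        union = ((a + b) > 0).astype(int)
        per_fold = [union[plan.test_idx(f)].sum() for f in range(5)]
        assert max(per_fold) - min(per_fold) <= 1

    def test_too_few_cases_rejected(self):
        labels = pd.DataFrame({"c": np.r_[np.ones(3), np.zeros(97)].astype(int)})
        with pytest.raises(ValueError, match="cases"):
            ps.make_folds(labels, k=5, seed=0)


class TestSelectByThreshold:
    def test_cutoff_one_selects_all_converged(self):
        a = assoc_from([0.2, 0.9, 0.5], converged=[True, True, False])
        ws = ps.select_by_threshold(a, 1.0)
        assert list(ws.table["variant_id"]) == ["v0", "v1"]

    def test_empty_selection_signals(self):
        a = assoc_from([1.0, 1.0])
        with pytest.raises(EmptySelectionError):
            ps.select_by_threshold(a, 0.1)

    def test_simple_comparison(self):
        a = assoc_from([0.01, 0.2, 0.04])
        ws = ps.select_by_threshold(a, 0.05)
        assert list(ws.table["variant_id"]) == ["v0", "v2"]

    def test_threshold_nesting(self):
        rng = np.random.default_rng(0)
        a = assoc_from(rng.uniform(size=200))
        grid = ps.default_grid(1e-2, 0.9, 6)
        previous = set()
        for cutoff in grid:
            try:
                sel = set(ps.select_by_threshold(a, cutoff).table["variant_id"])
            except EmptySelectionError:
                sel = set()
            assert previous <= sel
            previous = sel


class TestScore:
    def test_single_variant_ln2(self):
        gm = make_gm(np.array([[0], [1], [2]]))
        ws = WeightSet(
            pd.DataFrame(
                {"variant_id": ["v0"], "effect_allele": ["A"], "weight": [np.log(2)]}
            )
        )
        ss = ps.score(gm, ws)
        assert np.allclose(ss.prs, [0.0, np.log(2), 2 * np.log(2)])

    def test_hand_worked_dot_product(self):
        gm = make_gm(np.array([[2, 1, 0], [0, 0, 2]]))
        ws = WeightSet(
            pd.DataFrame(
                {
                    "variant_id": ["v0", "v1", "v2"],
                    "effect_allele": ["A", "A", "A"],
                    "weight": [0.1, -0.2, 0.4],
                }
            )
        )
        ss = ps.score(gm, ws)
        assert ss.prs == pytest.approx([0.0, 0.8 / 3], abs=1e-12)

    def test_allele_flip_affine_shift(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.4, size=(50, 3)).astype(np.int8)
        gm = make_gm(d)
        w = np.array([0.3, -0.1, 0.2])
        ws = WeightSet(
            pd.DataFrame(
                {
                    "variant_id": ["v0", "v1", "v2"],
                    "effect_allele": ["A", "A", "A"],
                    "weight": w,
                }
            )
        )
        flipped = WeightSet(
            pd.DataFrame(
                {
                    "variant_id": ["v0", "v1", "v2"],
                    "effect_allele": ["B", "A", "A"],  # flip variant 0
                    "weight": [-w[0], w[1], w[2]],
                }
            )
        )
        a = ps.score(gm, ws).prs
        b = ps.score(gm, flipped).prs
        shift = b - a
        assert np.allclose(shift, shift[0])  # constant offset
        assert shift[0] == pytest.approx(-2 * w[0] / 3)

    def test_unknown_variant_dropped_and_counted(self):
        gm = make_gm(np.array([[0, 1], [2, 1]]))
        ws = WeightSet(
            pd.DataFrame(
                {
                    "variant_id": ["v0", "nope"],
                    "effect_allele": ["A", "A"],
                    "weight": [0.5, 0.5],
                }
            )
        )
        ss = ps.score(gm, ws)
        assert ss.n_variants_used == 1
        assert ss.n_variants_dropped == 1

    def test_zero_overlap_fails(self):
        gm = make_gm(np.array([[0], [2]]))
        ws = WeightSet(
            pd.DataFrame(
                {"variant_id": ["x"], "effect_allele": ["A"], "weight": [0.5]}
            )
        )
        with pytest.raises(ValueError, match="overlap"):
            ps.score(gm, ws)

    def test_missing_dosage_imputed_from_training_freq(self):
        d = np.array([[-1], [1], [2]], dtype=np.int8)
        gm = make_gm(d)
        ws = WeightSet(
            pd.DataFrame(
                {
                    "variant_id": ["v0"],
                    "effect_allele": ["A"],
                    "weight": [1.0],
                    "freq": [0.25],
                }
            )
        )
        ss = ps.score(gm, ws)
        assert ss.prs[0] == pytest.approx(0.5)  # 2 * 0.25 * 1.0

    def test_variant_order_invariance(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.3, size=(30, 6)).astype(np.int8)
        gm = make_gm(d)
        t = pd.DataFrame(
            {
                "variant_id": [f"v{j}" for j in range(6)],
                "effect_allele": ["A"] * 6,
                "weight": rng.normal(size=6),
            }
        )
        a = ps.score(gm, WeightSet(t)).prs
        b = ps.score(gm, WeightSet(t.iloc[::-1].reset_index(drop=True))).prs
        assert np.allclose(a, b)


class TestExternalWeights:
    def test_roundtrip_matches_internal_path(self, medium_cohort, tmp_path):
        _, cohort = medium_cohort
        gm = cohort.genotypes
        assoc = ps.logistic_assoc(gm, cohort.true_status)
        assoc.to_tsv(tmp_path / "w.tsv")
        cutoff = 0.05
        ws = ps.select_by_threshold(assoc, cutoff)
        internal = ps.score(gm, ws).prs
        external = ps.score_with_external(gm, tmp_path / "w.tsv", cutoff=cutoff).prs
        assert np.array_equal(internal, external)

    def test_swapped_alleles_same_auc(self, medium_cohort):
        _, cohort = medium_cohort
        gm = cohort.genotypes
        assoc = ps.logistic_assoc(gm, cohort.true_status)
        t = assoc.table.loc[assoc.table["converged"]].head(50)
        w = pd.DataFrame(
            {
                "variant_id": t["variant_id"],
                "effect_allele": t["effect_allele"],
                "other_allele": t["other_allele"],
                "OR": np.exp(t["log_or"]),
                "p": t["p"],
            }
        )
        swapped = w.copy()
        swapped["effect_allele"], swapped["other_allele"] = (
            w["other_allele"],
            w["effect_allele"],
        )
        swapped["OR"] = 1.0 / w["OR"]
        y = cohort.true_status
        a = ps.roc_auc(ps.score_with_external(gm, w).prs, y)
        b = ps.roc_auc(ps.score_with_external(gm, swapped).prs, y)
        assert a == pytest.approx(b, abs=1e-12)

    def test_unknown_alleles_dropped(self, tmp_path):
        gm = make_gm(np.array([[0, 1], [2, 1], [1, 0]]))
        w = pd.DataFrame(
            {
                "variant_id": ["v0", "v1"],
                "effect_allele": ["A", "T"],  # T matches neither allele
                "other_allele": ["B", "G"],
                "OR": [1.5, 2.0],
                "p": [0.01, 0.01],
            }
        )
        path = tmp_path / "w.tsv"
        w.to_csv(path, sep="\t", index=False)
        ss = ps.score_with_external(gm, path)
        assert ss.n_variants_used == 1

    def test_malformed_rows_rejected_with_count(self, tmp_path):
        w = pd.DataFrame(
            {
                "variant_id": ["v0", "v1", "v2"],
                "effect_allele": ["A", "A", "A"],
                "other_allele": ["B", "B", "B"],
                "OR": [1.5, -2.0, "bad"],
                "p": [0.01, 0.01, 0.01],
            }
        )
        path = tmp_path / "w.tsv"
        w.to_csv(path, sep="\t", index=False)
        df = read_external_weights(path)
        assert len(df) == 1
        assert df.attrs["n_rejected"] == 2

    def test_all_rows_unusable_fails(self, tmp_path):
        w = pd.DataFrame(
            {
                "variant_id": ["v0"],
                "effect_allele": ["A"],
                "other_allele": ["B"],
                "OR": [-1.0],
                "p": [0.5],
            }
        )
        path = tmp_path / "w.tsv"
        w.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError):
            read_external_weights(path)


@pytest.fixture(scope="module")
def cv_setup(medium_cohort):
    _, cohort = medium_cohort
    gm = cohort.genotypes
    grid = ps.default_grid(1e-3, 0.1, 5)
    plan = ps.make_folds(cohort.labels, k=5, seed=7)
    labels = cohort.labels["algorithm"].to_numpy()
    cv = cross_validated_scores(gm, labels, None, grid, plan, channel="algorithm")
    return gm, labels, grid, plan, cv


class TestCrossValidation:

    def test_deterministic(self, cv_setup):
        gm, labels, grid, plan, cv = cv_setup
        cv2 = cross_validated_scores(gm, labels, None, grid, plan, channel="algorithm")
        assert np.array_equal(cv.scores, cv2.scores, equal_nan=True)
        assert np.array_equal(cv.cell_auc, cv2.cell_auc, equal_nan=True)

    def test_no_test_set_leakage(self, cv_setup):
        # fold-0 weights recomputed from scratch on out-of-fold samples only
        gm, labels, grid, plan, cv = cv_setup
        tr = plan.train_idx(0)
        assoc = ps.logistic_assoc(gm.take_samples(tr), labels[tr])
        pd.testing.assert_frame_equal(assoc.table, cv.fold_assoc[0].table)

    def test_each_sample_scored_in_its_test_fold(self, cv_setup):
        gm, labels, grid, plan, cv = cv_setup
        j = cv.best_threshold_idx
        assert np.isfinite(cv.scores[:, j]).all()

    def test_single_class_fold_rejected(self, medium_cohort):
        _, cohort = medium_cohort
        gm = cohort.genotypes
        labels = np.zeros(gm.n_samples, dtype=int)
        labels[:5] = 1  # all cases end up together rarely; force via plan
        plan = ps.make_folds(pd.DataFrame({"c": labels}), k=5, seed=0)
        bad = labels.copy()
        bad[plan.train_idx(0)] = 0  # fold 0 training loses all cases
        if bad.sum() == 0:
            bad[plan.test_idx(0)[:2]] = 1
        with pytest.raises(ValueError):
            cross_validated_scores(
                gm, bad, None, ps.default_grid(1e-3, 0.1, 3), plan
            )

    def test_label_noise_degrades_true_status_auc(self, medium_cohort):
        # a noisier labeling channel yields weights that rank TRUE cases worse
        cfg, cohort = medium_cohort
        gm = cohort.genotypes
        grid = ps.default_grid(1e-3, 0.1, 5)
        plan = ps.make_folds(cohort.labels, k=5, seed=7)
        aucs = []
        for sens, spec in [(1.0, 1.0), (0.7, 0.93), (0.5, 0.85)]:
            noisy = ps.apply_label_channel(
                cohort.true_status, ps.ChannelSpec("x", sens, spec), seed=11
            )
            if len(np.unique(noisy)) < 2:
                pytest.skip("degenerate noise draw")
            cv = cross_validated_scores(gm, noisy, None, grid, plan)
            auc_true = ps.roc_auc(cv.scores_at_best(), cohort.true_status)
            aucs.append(auc_true)
        assert aucs[0] > aucs[-1]  # endpoints of the noise ladder
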