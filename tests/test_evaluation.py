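"""Cross-validation, leakage safety and the pooled metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from connectome_cbr import (
    CvResult,
    compute_metrics,
    cross_validate,
    hcp_like_spec,
    kfold_split,
    per_fold_metrics,
    subgroup_metrics,
)
from connectome_cbr.evaluation import slice_cv_result
from connectome_cbr.synthetic import generate_cohort
from tests.conftest import make_cohort_table, make_design


def cv_records(actual, predicted):
    actual = np.asarray(actual, float)
    predicted = np.asarray(predicted, float)
    return CvResult(
        records=pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(len(actual))],
                "fold": np.zeros(len(actual), dtype=int),
                "actual": actual,
                "predicted": predicted,
                "absolute_error": np.abs(predicted - actual),
            }
        ),
        attribute_name="age",
    )


class TestKfold:
    def test_1048_subjects_fold_sizes(self):
        ids = [f"S{i}" for i in range(1048)]
        folds = kfold_split(ids, k=10, seed=0)
        sizes = sorted(
            np.bincount([folds.assignment[s] for s in ids], minlength=10).tolist()
        )
        assert sizes == [104, 104] + [105] * 8

    def test_leave_one_out_boundary(self):
        folds = kfold_split([f"S{i}" for i in range(10)], k=10, seed=1)
        assert sorted(folds.assignment.values()) == list(range(10))

    def test_determinism(self):
        ids = [f"S{i}" for i in range(57)]
        assert kfold_split(ids, 10, 3).assignment == kfold_split(ids, 10, 3).assignment

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            kfold_split(["a", "b"], k=3, seed=0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(10, 200), st.integers(2, 10), st.integers(0, 2**31 - 1))
    def test_partition_is_exhaustive_and_balanced(self, n, k, seed):
        k = min(k, n)
        ids = [f"S{i}" for i in range(n)]
        folds = kfold_split(ids, k, seed)
        assert set(folds.assignment) == set(ids)
        sizes = np.bincount(list(folds.assignment.values()), minlength=k)
        assert sizes.sum() == n and sizes.max() - sizes.min() <= 1


class TestCrossValidate:
    def test_noiseless_single_edge_is_perfectly_learnable(self):
        b = np.linspace(22, 37, 40)
        A = make_design(b[:, None])
        cohort = make_cohort_table(b)
        folds = kfold_split(cohort["subject_id"], 10, seed=0)
        cv = cross_validate(A, cohort, "age", folds)
        assert (cv.records["absolute_error"] < 1e-6).all()

    def test_no_leakage_from_test_fold_attributes(self):
        # permuting attribute values inside one fold may only affect the
        # *other* folds' predictions (which train on it), never its own
        rng = np.random.default_rng(0)
        spec = hcp_like_spec(n_subjects=60, n_rois=10, n_signal_edges=3,
                             planted_rho=0.5, seed=1)
        syn = generate_cohort(spec)
        A, cohort = syn.design_matrix(), syn.cohort_table
        folds = kfold_split(cohort["subject_id"], 5, seed=2)
        baseline = cross_validate(A, cohort, "age", folds).records
        for fold in range(folds.k):
            mutated = cohort.copy()
            in_fold = mutated["subject_id"].map(folds.assignment) == fold
            vals = mutated.loc[in_fold, "age"].to_numpy()
            mutated.loc[in_fold, "age"] = rng.permutation(vals)
            result = cross_validate(A, mutated, "age", folds).records
            np.testing.assert_array_equal(
                result.loc[in_fold.to_numpy(), "predicted"],
                baseline.loc[in_fold.to_numpy(), "predicted"],
            )

    def test_constant_training_attribute_is_degenerate_split(self):
        b = np.array([25.0] * 18 + [30.0, 31.0])
        A = make_design(np.random.default_rng(0).lognormal(size=(20, 4)))
        cohort = make_cohort_table(b)
        # force the only varying subjects into one fold
        from connectome_cbr import FoldAssignment

        assignment = {f"S{i:03d}": 1 for i in range(18)}
        assignment.update({"S018": 0, "S019": 0})
        folds = FoldAssignment(k=2, assignment=assignment, seed=0)
        with pytest.raises(ValueError, match="degenerate split"):
            cross_validate(A, cohort, "age", folds)

    def test_every_subject_predicted_once(self, small_signal_cohort):
        syn = small_signal_cohort
        folds = kfold_split(syn.cohort_table["subject_id"], 10, seed=5)
        cv = cross_validate(syn.design_matrix(), syn.cohort_table, "age", folds)
        assert cv.records["subject_id"].is_unique
        assert not cv.records["predicted"].isna().any()


class TestMetrics:
    def test_perfect_prediction(self):
        rep = compute_metrics(cv_records([22, 30, 37], [22, 30, 37]))
        assert rep.mae == 0 and rep.nmae == 0 and rep.pearson_r == pytest.approx(1.0)

    def test_constant_offset(self):
        rep = compute_metrics(cv_records([22, 30, 37], [24, 32, 39]))
        assert rep.mae == pytest.approx(2.0)
        assert rep.pearson_r == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # actual range 37 - 22 = 15; errors 3, 1, 4
        rep = compute_metrics(cv_records([22, 30, 37], [25, 29, 33]))
        assert rep.mae == pytest.approx(8 / 3)
        assert rep.nmae == pytest.approx((8 / 3) / 15)
        assert rep.range_used == 15

    def test_mae_and_sd_match_bruteforce(self):
        rng = np.random.default_rng(2)
        actual = rng.normal(30, 4, 50)
        predicted = actual + rng.normal(0, 2, 50)
        rep = compute_metrics(cv_records(actual, predicted))
        err = np.abs(predicted - actual)
        assert rep.mae == pytest.approx(err.sum() / 50, abs=1e-12)
        assert rep.mae_sd == pytest.approx(
            np.sqrt(((err - err.mean()) ** 2).sum() / 49), abs=1e-12
        )

    def test_constant_actual_rejected(self):
        with pytest.raises(ValueError, match="NMAE undefined"):
            compute_metrics(cv_records([5, 5, 5], [4, 5, 6]))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            compute_metrics(cv_records([1, 2], [1, 2]))

    def test_per_fold_variant_agrees_on_single_fold(self):
        cv = cv_records([22, 30, 37, 25], [25, 29, 33, 27])
        table = per_fold_metrics(cv)
        assert table.loc[0, "mae"] == pytest.approx(cv.records["absolute_error"].mean())


class TestSubgroups:
    def test_all_subgroup_equals_plain_cv(self, small_signal_cohort):
        syn = small_signal_cohort
        A, cohort = syn.design_matrix(), syn.cohort_table
        cv_sub, rep_sub = subgroup_metrics(A, cohort, "age", "all", k=10, seed=4)
        folds = kfold_split(cohort["subject_id"], 10, seed=4)
        rep_plain = compute_metrics(cross_validate(A, cohort, "age", folds))
        assert rep_sub == rep_plain

    def test_subgroup_uses_its_own_range(self):
        # females span 14 units while the full cohort spans 15, so the
        # female NMAE denominator must be 14
        b = np.concatenate([np.linspace(23, 37, 20), np.linspace(22, 37, 20)])
        sex = np.array(["female"] * 20 + ["male"] * 20)
        A = make_design(np.tile(b[:, None], (1, 1)))
        cohort = make_cohort_table(b, sex=sex)
        _, rep = subgroup_metrics(A, cohort, "age", "female", k=5, seed=0)
        assert rep.range_used == pytest.approx(14.0)
        assert rep.n == 20

    def test_too_small_subgroup_rejected(self):
        b = np.linspace(22, 37, 12)
        cohort = make_cohort_table(b, sex=np.array(["male"] * 10 + ["female"] * 2))
        A = make_design(b[:, None])
        with pytest.raises(ValueError, match="fewer than k"):
            subgroup_metrics(A, cohort, "age", "female", k=5, seed=0)

    def test_stronger_female_signal_yields_higher_female_r(self):
        # females carry the planted signal twice as strongly; over seeds the
        # female pooled r must exceed the male pooled r on average
        diffs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 160
            b = rng.uniform(22, 37, n)
            sex = np.array(["female", "male"] * (n // 2))
            noise = rng.normal(0, 1, (n, 6))
            X = 10 + noise
            strength = np.where(sex == "female", 1.0, 0.25)
            X[:, 0] = 10 + strength * (b - b.mean()) + rng.normal(0, 2.0, n)
            X = np.clip(X, 0, None)
            cohort = make_cohort_table(b, sex=sex)
            A = make_design(X)
            _, rep_f = subgroup_metrics(A, cohort, "age", "female", k=5, seed=seed)
            _, rep_m = subgroup_metrics(A, cohort, "age", "male", k=5, seed=seed)
            diffs.append(rep_f.pearson_r - rep_m.pearson_r)
        assert np.mean(diffs) > 0

    def test_slice_variant_restricts_without_refit(self, small_signal_cohort):
        syn = small_signal_cohort
        A, cohort = syn.design_matrix(), syn.cohort_table
        folds = kfold_split(cohort["subject_id"], 10, seed=4)
        cv = cross_validate(A, cohort, "age", folds)
        sliced = slice_cv_result(cv, cohort, "female")
        female_ids = set(cohort.loc[cohort["sex"] == "female", "subject_id"])
        assert set(sliced.records["subject_id"]) == female_ids
        merged = sliced.records.merge(cv.records, on="subject_id", suffixes=("", "_full"))
        np.testing.assert_array_equal(merged["predicted"], merged["predicted_full"])
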