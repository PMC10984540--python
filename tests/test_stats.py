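"""Signed-rank comparisons and BH-FDR control, against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from connectome_cbr import (
    CvResult,
    benjamini_hochberg,
    compare_across_conditions,
    compare_feature_pair,
    feature_pair_family,
    paired_wilcoxon,
)


def wilcoxon_enumeration_p(differences):
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray(differences, float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = float(ranks[d > 0].sum())
    w_all = np.array(
        [float(np.dot(signs, ranks)) for signs in itertools.product([0, 1], repeat=n)]
    )
    cdf = np.mean(w_all <= w_obs)
    sf = np.mean(w_all >= w_obs)
    return min(1.0, 2.0 * min(cdf, sf))


def bh_stepup_oracle(p_values, q):
    """The step-up definition applied literally: largest i with p(i) <= i*q/m."""
    p = np.asarray(p_values, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    cutoff = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= i * q / m:
            cutoff = i
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:cutoff]] = True
    return rejected


def cv_from_errors(errors, label, attribute="age"):
    errors = np.asarray(errors, float)
    actual = np.linspace(22, 37, len(errors))
    return CvResult(
        records=pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(len(errors))],
                "fold": 0,
                "actual": actual,
                "predicted": actual + errors,
                "absolute_error": np.abs(errors),
            }
        ),
        attribute_name=attribute,
        dataset_label=label,
    )


class TestPairedWilcoxon:
    def test_identical_errors_degenerate(self):
        e = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        comp = paired_wilcoxon(e, e)
        assert comp.p_value == 1.0 and comp.degenerate

    def test_six_all_positive_differences(self):
        # W = 21 is the unique extreme of 2^6 patterns: p = 2/64
        comp = paired_wilcoxon(np.array([2, 3, 4, 5, 6, 7.0]), np.ones(6))
        assert comp.p_value == pytest.approx(2 / 64, abs=1e-15)
        assert comp.method == "exact"

    def test_exact_path_matches_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(5, 13))
            a = rng.normal(3, 1, n)
            b = rng.normal(3, 1, n)
            comp = paired_wilcoxon(a, b)
            assert comp.method == "exact"
            assert comp.p_value == pytest.approx(
                wilcoxon_enumeration_p(a - b), abs=1e-12
            )

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(2, 1, 15), rng.normal(2.5, 1, 15)
        c1, c2 = paired_wilcoxon(a, b), paired_wilcoxon(b, a)
        assert c1.p_value == pytest.approx(c2.p_value, abs=1e-12)
        assert c1.statistic == -c2.statistic

    def test_large_n_uses_approximation(self):
        rng = np.random.default_rng(5)
        comp = paired_wilcoxon(rng.normal(2, 1, 60), rng.normal(2, 1, 60))
        assert comp.method == "approx"
        assert 0 <= comp.p_value <= 1

    def test_mismatched_subject_sets_rejected(self):
        a = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        b = pd.Series([2.0, 3, 4, 5, 6], index=list("abcdf"))
        with pytest.raises(ValueError, match="subject sets differ"):
            paired_wilcoxon(a, b)

    def test_series_aligned_on_subject_index(self):
        idx = list("abcdef")
        a = pd.Series([1.0, 2, 3, 4, 5, 6], index=idx)
        b = a + 1
        shuffled = b.loc[list("fedcba")]
        assert paired_wilcoxon(a, shuffled).p_value == paired_wilcoxon(a, b).p_value

    def test_too_few_nonzero_differences(self):
        a = np.array([1.0, 1, 1, 1, 2, 3])
        b = np.array([1.0, 1, 1, 1, 2.5, 3.5])
        with pytest.raises(ValueError, match="nonzero"):
            paired_wilcoxon(a, b)


class TestBenjaminiHochberg:
    def test_single_p_reduces_to_raw_threshold(self):
        rejected, _ = benjamini_hochberg([0.04], q=0.05)
        assert rejected.tolist() == [True]

    def test_worked_example_rejects_exactly_two(self):
        rejected, adjusted = benjamini_hochberg([0.01, 0.02, 0.04, 0.5], q=0.05)
        assert rejected.tolist() == [True, True, False, False]
        assert np.all(np.diff(adjusted[np.argsort([0.01, 0.02, 0.04, 0.5])]) >= 0)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            benjamini_hochberg([0.2, 1.4])

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30), st.integers(0, 1000))
    def test_matches_stepup_oracle_and_brackets(self, p_values, _):
        q = 0.05
        rejected, adjusted = benjamini_hochberg(p_values, q=q)
        expected = bh_stepup_oracle(p_values, q)
        assert rejected.tolist() == expected.tolist()
        p = np.asarray(p_values)
        assert rejected.sum() <= (p <= q).sum()  # never beats the raw threshold
        assert rejected.sum() >= (p <= q / len(p)).sum()  # never below Bonferroni
        # adjusted-p decisions are consistent; re-adjusting adjusted
        # p-values can only shrink the rejection set, never grow it
        assert rejected.tolist() == (adjusted <= q).tolist()
        re_rejected, _ = benjamini_hochberg(np.minimum(adjusted, 1.0), q=q)
        assert not np.any(re_rejected & ~rejected)


class TestComparisonFamilies:
    def test_six_conditions_give_fifteen_pairs(self):
        rng = np.random.default_rng(0)
        results = [
            cv_from_errors(rng.normal(2, 0.5, 40), label=f"d{i}") for i in range(6)
        ]
        fam = compare_across_conditions(results, "age_all")
        assert len(fam.comparisons) == 15

    def test_identical_conditions_degenerate_without_rejection(self):
        errs = np.linspace(0.5, 3.0, 30)
        fam = compare_across_conditions(
            [cv_from_errors(errs, "a"), cv_from_errors(errs, "b")], "age_all"
        )
        assert len(fam.comparisons) == 1
        assert fam.comparisons[0].degenerate
        assert not fam.rejected.any()

    def test_mismatched_subject_sets_rejected(self):
        a = cv_from_errors(np.arange(1.0, 11), "a")
        b = cv_from_errors(np.arange(1.0, 12), "b")
        with pytest.raises(ValueError, match="subject sets differ"):
            compare_across_conditions([a, b], "age_all")

    def test_mixed_attributes_rejected(self):
        a = cv_from_errors(np.arange(1.0, 11), "a", attribute="age")
        b = cv_from_errors(np.arange(1.0, 11), "b", attribute="intel_total")
        with pytest.raises(ValueError, match="mix attributes"):
            compare_across_conditions([a, b], "family")

    def test_shifted_errors_are_detected(self):
        # condition b's errors are a's plus half an sd: clear paired signal
        rng = np.random.default_rng(3)
        errs = np.abs(rng.normal(2, 1, 300))
        fam = compare_across_conditions(
            [cv_from_errors(errs, "a"), cv_from_errors(errs + 0.5 * errs.std(), "b")],
            "age_all",
        )
        assert fam.rejected.all()

    def test_feature_pair_identity_and_swap(self):
        cv_a = cv_from_errors(np.linspace(0.1, 3, 20), "d", attribute="intel_cryst")
        cv_b = cv_from_errors(np.linspace(0.1, 3, 20), "d", attribute="intel_fluid")
        assert compare_feature_pair(cv_a, cv_b).p_value == 1.0
        rng = np.random.default_rng(9)
        cv_c = cv_from_errors(np.abs(rng.normal(2, 1, 20)), "d", attribute="intel_fluid")
        fwd = compare_feature_pair(cv_a, cv_c)
        rev = compare_feature_pair(cv_c, cv_a)
        assert fwd.p_value == pytest.approx(rev.p_value, abs=1e-12)
        assert np.sign(fwd.median_difference) == -np.sign(rev.median_difference)

    def test_feature_pair_family_one_comparison_per_dataset(self):
        rng = np.random.default_rng(1)
        pairs = []
        for d in range(3):
            a = cv_from_errors(np.abs(rng.normal(2, 1, 30)), f"d{d}", "intel_cryst")
            b = cv_from_errors(np.abs(rng.normal(2.5, 1, 30)), f"d{d}", "intel_fluid")
            pairs.append((a, b))
        fam = feature_pair_family(pairs)
        assert len(fam.comparisons) == 3
        frame = fam.to_frame()
        assert set(frame.columns) >= {
            "condition_a", "condition_b", "n_effective",
            "statistic", "raw_p", "adjusted_p", "rejected",
        }
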