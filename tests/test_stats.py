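"""Diagnostic-accuracy statistics: metrics, proportion tests, AUC comparisons, ROC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fedlnm.exceptions import InputError
from fedlnm.stats import (ContingencyTable, binary_auc_variance, build_contingency,
                          compare_auc_unpaired, compare_proportions, compute_metrics,
                          load_packaged_contingency, load_published_metrics,
                          roc_from_scores, round_half_up)

CT = ContingencyTable(tp=31, fp=27, fn=64, tn=317)
PET = ContingencyTable(tp=45, fp=45, fn=33, tn=270)
MRI = ContingencyTable(tp=28, fp=24, fn=50, tn=338)


class TestContingency:
    def test_single_positive_call(self):
        t = build_contingency([True], [True])
        assert (t.tp, t.fp, t.fn, t.tn) == (1, 0, 0, 0)

    def test_counts_sum_to_input_length(self, rng):
        calls = rng.random(200) < 0.4
        truths = rng.random(200) < 0.3
        t = build_contingency(calls, truths)
        assert t.total == 200

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            build_contingency([True, False], [True])

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            build_contingency([], [])

    def test_negative_count_rejected(self):
        with pytest.raises(InputError):
            ContingencyTable(tp=-1, fp=0, fn=0, tn=0)


class TestComputeMetrics:
    @pytest.mark.parametrize("table, expected", [
        (CT, dict(sensitivity=0.3263, specificity=0.9215, ppv=0.5345,
                  npv=0.8320, accuracy=0.7927, auc=0.624)),
        (PET, dict(sensitivity=0.5769, specificity=0.8571, ppv=0.5000,
                   npv=0.8911, accuracy=0.8015, auc=0.717)),
    ])
    def test_published_imaging_rows(self, table, expected):
        m = compute_metrics(table)
        for name, want in expected.items():
            digits = 3 if name == "auc" else 4
            assert round_half_up(getattr(m, name), digits) == pytest.approx(want)

    def test_perfect_test(self):
        m = compute_metrics(ContingencyTable(10, 0, 0, 10))
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy", "auc"):
            assert getattr(m, name) == 1.0

    def test_degenerate_margin_flagged_not_zeroed(self):
        m = compute_metrics(ContingencyTable(0, 0, 0, 5))
        assert m.sensitivity is None
        assert "sensitivity" in m.undefined
        assert m.specificity == 1.0

    def test_matches_per_patient_recount(self, small_cohort):
        """Brute-force oracle: recount each metric patient by patient."""
        calls = np.array([r.calls["CT"] == "positive" for r in small_cohort])
        truths = np.array([r.true_lnm for r in small_cohort])
        m = compute_metrics(build_contingency(calls, truths))
        assert m.sensitivity == sum(c and t for c, t in zip(calls, truths)) / sum(truths)
        assert m.specificity == (sum(not c and not t for c, t in zip(calls, truths))
                                 / sum(~truths))
        assert m.accuracy == np.mean(calls == truths)

    def test_ci_brackets_auc_and_overlaps_published(self):
        published = load_published_metrics().set_index("group")
        for group, table in load_packaged_contingency().items():
            m = compute_metrics(table)
            lo, hi = m.auc_ci
            assert lo <= m.auc <= hi
            pub_lo = float(published.loc[group, "auc_ci_low"])
            pub_hi = float(published.loc[group, "auc_ci_high"])
            assert max(lo, pub_lo) < min(hi, pub_hi), f"no CI overlap for {group}"

    @settings(deadline=None, max_examples=200)
    @given(st.tuples(*[st.integers(0, 400)] * 4))
    def test_metric_ranges_and_binary_auc_identity(self, counts):
        tp, fp, fn, tn = counts
        m = compute_metrics(ContingencyTable(tp, fp, fn, tn))
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy", "auc"):
            v = getattr(m, name)
            assert v is None or 0.0 <= v <= 1.0
        if m.auc is not None:
            assert m.auc == pytest.approx((m.sensitivity + m.specificity) / 2, abs=1e-15)


class TestCompareProportions:
    def test_published_sensitivity_comparisons(self):
        p_ct_pet = compare_proportions(31, 95, 45, 78).p_value
        p_ct_mri = compare_proportions(31, 95, 28, 78).p_value
        assert round_half_up(p_ct_pet, 3) == 0.001
        assert round_half_up(p_ct_mri, 3) == 0.652

    def test_statistic_matches_hand_formula(self):
        # N (ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) on the 2x2 cells
        a, b, c, d = 31, 64, 45, 33
        n = a + b + c + d
        expect = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        got = compare_proportions(31, 95, 45, 78).statistic
        assert got == pytest.approx(expect, rel=1e-12)
        assert got == pytest.approx(10.92, abs=5e-3)

    def test_equal_proportions(self):
        c = compare_proportions(10, 20, 10, 20)
        assert c.statistic == pytest.approx(0.0, abs=1e-12)
        assert c.p_value == pytest.approx(1.0)
        assert c.significant is False

    def test_symmetric_in_group_order(self):
        c1 = compare_proportions(31, 95, 45, 78)
        c2 = compare_proportions(45, 78, 31, 95)
        assert c1.p_value == pytest.approx(c2.p_value, rel=1e-12)
        assert c1.statistic >= 0

    def test_zero_margin_flagged(self):
        c = compare_proportions(0, 10, 0, 12)
        assert c.p_value is None and "p_value" in c.undefined

    def test_invalid_counts_rejected(self):
        with pytest.raises(InputError):
            compare_proportions(5, 3, 1, 2)


class TestCompareAUC:
    def test_identical_tables_z_zero(self):
        m = compute_metrics(CT)
        c = compare_auc_unpaired(m, CT, m, CT)
        assert c.statistic == pytest.approx(0.0, abs=1e-12)
        assert c.p_value == pytest.approx(1.0)

    def test_ct_vs_petct_significant_petct_higher(self):
        c = compare_auc_unpaired(compute_metrics(CT), CT, compute_metrics(PET), PET)
        assert c.significant is True
        assert c.statistic < 0  # PET/CT AUC is higher

    def test_mri_vs_petct_not_significant(self):
        c = compare_auc_unpaired(compute_metrics(MRI), MRI, compute_metrics(PET), PET)
        assert c.significant is False
        assert c.p_value > 0.05

    def test_zero_variance_flagged(self):
        t = ContingencyTable(5, 0, 0, 5)
        m = compute_metrics(t)
        c = compare_auc_unpaired(m, t, m, t)
        assert c.p_value is None


class TestROC:
    def test_perfect_scores(self):
        _, auc = roc_from_scores([0.0, 0.0, 1.0, 1.0], [0, 0, 1, 1])
        assert auc == 1.0

    def test_binary_scores_match_closed_form(self, small_cohort):
        calls = np.array([r.calls["MRI"] == "positive" for r in small_cohort])
        truths = np.array([r.true_lnm for r in small_cohort])
        m = compute_metrics(build_contingency(calls, truths))
        _, auc = roc_from_scores(calls.astype(float), truths)
        assert auc == pytest.approx((m.sensitivity + m.specificity) / 2, abs=1e-12)

    def test_agrees_with_pair_counting_oracle(self, rng):
        """Independent oracle: AUC = P(score+ > score-) + 0.5 P(tie)."""
        y = rng.random(80) < 0.4
        s = np.round(rng.random(80), 1)  # coarse scores force ties
        pos, neg = s[y], s[~y]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        _, auc = roc_from_scores(s, y)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_uninformative_scores_near_half(self, rng):
        n = 4000
        y = np.arange(n) < n // 2
        s = rng.random(n)
        _, auc = roc_from_scores(s, y)
        n1 = n0 = n // 2
        se = math.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        assert abs(auc - 0.5) < 3 * se

    def test_single_class_undefined(self):
        _, auc = roc_from_scores([0.2, 0.4], [1, 1])
        assert auc is None

    def test_variance_estimator_positive_and_symmetric(self):
        v = binary_auc_variance(0.6, 0.8, 50, 100)
        assert v > 0
        assert binary_auc_variance(0.8, 0.6, 100, 50) == pytest.approx(v)
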