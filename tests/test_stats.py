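import numpy as np
import pandas as pd
import pytest

from ccfd import (
    DegenerateDataError,
    ZeroVarianceError,
    compare_regressions,
    ks_normality,
    percent_change,
    rm_anova_2x2,
    unpaired_t_test,
)
from helpers import nested_slope_f_oracle


def long_table(rpd: np.ndarray, ctrl: np.ndarray) -> pd.DataFrame:
    """Build a long cohort table from (n, 2) per-group value matrices."""
    rows = []
    for group, mat in (("RPD", rpd), ("control", ctrl)):
        for i, (b, f) in enumerate(mat):
            sid = f"{group}_{i:02d}"
            rows.append((sid, group, "baseline", float(b)))
            rows.append((sid, group, "follow_up", float(f)))
    return pd.DataFrame(rows, columns=["subject_id", "group", "timepoint", "value"])


class TestKsNormality:
    def test_normal_draws_rarely_rejected(self):
        hits = sum(
            ks_normality(np.random.default_rng(s).normal(size=10_000)) > 0.01
            for s in range(20)
        )
        assert hits >= 19

    def test_uniform_draws_rejected(self):
        hits = sum(
            ks_normality(np.random.default_rng(s).uniform(size=10_000)) < 0.01
            for s in range(20)
        )
        assert hits >= 19

    def test_constant_sample_rejected(self):
        with pytest.raises(ZeroVarianceError):
            ks_normality([3.0, 3.0, 3.0, 3.0])


class TestTTest:
    def test_identical_samples(self):
        t, p = unpaired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_one_sd_shift_detected_at_large_n(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 10_000)
        b = rng.normal(1, 1, 10_000)
        _, p = unpaired_t_test(a, b)
        assert p < 1e-6

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError):
            unpaired_t_test([1.0], [1.0, 2.0])


class TestRmAnova:
    def test_parallel_shift_gives_zero_interaction(self):
        rng = np.random.default_rng(1)
        base = rng.normal(30, 4, (8, 1))
        rpd = np.hstack([base, base + 5.0])
        base_c = rng.normal(33, 4, (8, 1))
        ctrl = np.hstack([base_c, base_c + 5.0])
        res = rm_anova_2x2(long_table(rpd, ctrl))
        assert res.interaction_f == 0.0
        assert res.interaction_p == 1.0

    def test_all_equal_is_degenerate(self):
        mat = np.full((4, 2), 7.0)
        with pytest.raises(DegenerateDataError):
            rm_anova_2x2(long_table(mat, mat.copy()))

    def test_group_swap_leaves_interaction_unchanged(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(35, 4, (8, 2)), rng.normal(33, 3, (8, 2))
        r1 = rm_anova_2x2(long_table(a, b))
        r2 = rm_anova_2x2(long_table(b, a))
        assert r1.interaction_f == pytest.approx(r2.interaction_f)
        assert r1.group_f == pytest.approx(r2.group_f)

    def test_matches_pingouin_mixed_anova(self):
        """Closed-form sums of squares agree with an independent mixed-ANOVA
        implementation on random balanced data."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        table = long_table(rng.normal(36, 4, (8, 2)), rng.normal(32, 2, (8, 2)))
        res = rm_anova_2x2(table)
        ref = pingouin.mixed_anova(
            data=table, dv="value", within="timepoint", between="group",
            subject="subject_id",
        ).set_index("Source")
        assert res.group_f == pytest.approx(ref.loc["group", "F"], rel=1e-9)
        assert res.time_f == pytest.approx(ref.loc["timepoint", "F"], rel=1e-9)
        assert res.interaction_f == pytest.approx(ref.loc["Interaction", "F"], rel=1e-9)
        assert res.interaction_p == pytest.approx(ref.loc["Interaction", "p_unc"], rel=1e-9)

    def test_incomplete_pairs_rejected(self):
        table = long_table(np.ones((3, 2)), np.zeros((3, 2)))
        table = table.drop(table.index[-1])
        with pytest.raises(ValueError, match="incomplete"):
            rm_anova_2x2(table)

    def test_unbalanced_groups_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="unbalanced"):
            rm_anova_2x2(long_table(rng.normal(size=(5, 2)), rng.normal(size=(4, 2))))


class TestCompareRegressions:
    def test_identical_datasets(self):
        x = np.arange(10.0)
        y = 2.0 * x + 1.0 + np.sin(x)
        slopes, intercepts = compare_regressions(x, y, x, y)
        assert slopes.f_value == 0.0 and slopes.p_value == 1.0
        assert intercepts.f_value == 0.0 and intercepts.p_value == 1.0

    def test_pure_intercept_shift(self):
        x = np.arange(8.0)
        y = 3.0 * x + 2.0
        slopes, intercepts = compare_regressions(x, y, x, y + 5.0)
        assert slopes.f_value == 0.0 and slopes.p_value == 1.0
        assert np.isinf(intercepts.f_value) and intercepts.p_value == 0.0

    def test_matches_nested_model_oracle(self):
        """F statistics agree with explicit design-matrix fits of the three
        nested models to 6 significant figures."""
        rng = np.random.default_rng(7)
        x1, x2 = rng.uniform(0, 5, 20), rng.uniform(0, 5, 20)
        y1 = 1.0 * x1 + 0.5 + rng.normal(0, 0.1, 20)
        y2 = 2.0 * x2 + 0.5 + rng.normal(0, 0.1, 20)
        slopes, intercepts = compare_regressions(x1, y1, x2, y2)
        f_slope_ref, f_inter_ref = nested_slope_f_oracle(x1, y1, x2, y2)
        assert slopes.f_value == pytest.approx(f_slope_ref, rel=1e-6)
        assert intercepts.f_value == pytest.approx(f_inter_ref, rel=1e-6)
        assert slopes.df_den == 36 and intercepts.df_den == 37

    def test_symmetric_in_dataset_order(self):
        rng = np.random.default_rng(8)
        x1, x2 = rng.uniform(0, 5, 15), rng.uniform(0, 5, 12)
        y1 = x1 + rng.normal(0, 0.2, 15)
        y2 = 1.5 * x2 + rng.normal(0, 0.2, 12)
        s12, i12 = compare_regressions(x1, y1, x2, y2)
        s21, i21 = compare_regressions(x2, y2, x1, y1)
        assert s12.f_value == pytest.approx(s21.f_value)
        assert i12.f_value == pytest.approx(i21.f_value)

    def test_detects_known_slope_difference(self):
        rng = np.random.default_rng(9)
        x = np.linspace(0, 5, 20)
        y1 = 1.0 * x + rng.normal(0, 0.1, 20)
        y2 = 2.0 * x + rng.normal(0, 0.1, 20)
        slopes, _ = compare_regressions(x, y1, x, y2)
        assert slopes.p_value < 1e-6

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            compare_regressions([1, 2], [1, 2], [1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            compare_regressions([1, 1, 1], [1, 2, 3], [1, 2, 3], [1, 2, 3])


class TestPercentChange:
    def test_published_worked_example(self):
        """19.36 mm^2 to 37.77 mm^2 is a 95% increase."""
        assert round(percent_change(19.36, 37.77)) == 95

    def test_identity_and_sign(self):
        assert percent_change(10.0, 10.0) == 0.0
        assert percent_change(10.0, 5.0) == -50.0

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 5.0)
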