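"""Heteroscedastic contrasts, BH adjustment, fold changes and duration regressions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from hypoxmet.datamodel import ChangeMatrix, ValidationError
from hypoxmet.synthetic import CohortConfig, generate_cohort
from hypoxmet.univariate import (
    bh_adjust,
    cohort_balance_check,
    duration_regression,
    fold_change,
    heteroscedastic_contrast,
    signed_fold_change,
)


def _change_matrix(arrays_by_group, n_features=1):
    vals, animals, groups = [], [], []
    i = 0
    for g, arr in arrays_by_group.items():
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        if arr.shape[0] == 1 and n_features == 1:
            arr = arr.T
        for row in arr:
            animals.append(f"{g}_a{i}")
            groups.append(g)
            vals.append(row)
            i += 1
    df = pd.DataFrame(vals, index=animals, columns=[f"f{j}" for j in range(len(vals[0]))])
    return ChangeMatrix(df, "EA_over_SA", pd.Series(groups, index=animals))


def _welch_reference(x, y):
    """Independently coded Welch formula (statistic, df, p)."""
    nx, ny = len(x), len(y)
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    t = (np.mean(x) - np.mean(y)) / np.sqrt(vx / nx + vy / ny)
    df = (vx / nx + vy / ny) ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


class TestHeteroscedasticContrast:
    def test_identical_groups_give_null_statistic(self):
        ch = _change_matrix({"CONTROL": [1.0, 2.0, 3.0], "G21": [1.0, 2.0, 3.0]})
        (r,) = heteroscedastic_contrast(ch)
        assert r.t_stat == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_closed_form_welch_example(self):
        ch = _change_matrix({"CONTROL": [1.0, 2.0, 3.0], "G21": [2.0, 3.0, 4.0, 5.0]})
        (r,) = heteroscedastic_contrast(ch)
        t, df, p = _welch_reference([2, 3, 4, 5], [1, 2, 3])
        assert r.t_stat == pytest.approx(t, abs=1e-10)
        assert r.df == pytest.approx(df, abs=1e-10)
        assert r.p_value == pytest.approx(p, abs=1e-10)
        assert r.estimate == pytest.approx(np.mean([2, 3, 4, 5]) - 2.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, size=(6, 20))
        b = rng.normal(0.5, 2, size=(9, 20))
        ch = _change_matrix({"CONTROL": a, "G21": b}, n_features=20)
        for r in heteroscedastic_contrast(ch):
            j = int(r.feature_id[1:])
            ref = stats.ttest_ind(b[:, j], a[:, j], equal_var=False)
            assert r.t_stat == pytest.approx(ref.statistic, abs=1e-10)
            assert r.p_value == pytest.approx(ref.pvalue, abs=1e-10)
            assert r.df == pytest.approx(ref.df, abs=1e-10)

    def test_surge_fixture_estimate_equals_log_fc(self):
        cfg = CohortConfig(surge_fc={"Suc": 80.0}, duration_effect={}, noise_sd=0.0, seed=8)
        cm, _ = generate_cohort(cfg)
        from hypoxmet.preprocess import compute_changes

        ch = compute_changes(cm, "EA_over_SA")
        res = {r.feature_id: r for r in heteroscedastic_contrast(ch)}
        assert res["Suc"].estimate == pytest.approx(np.log(80.0), abs=1e-10)
        assert res["Suc"].p_value < 1e-20

    def test_omnibus_matches_pingouin_welch_anova(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        data = {g: rng.normal(m, s, size=(n, 2)) for g, m, s, n in
                [("G21", 0, 1, 8), ("G100_15", 0.8, 2, 8), ("G100_60", -0.3, 0.5, 11)]}
        ch = _change_matrix(data, n_features=2)
        omni = [r for r in heteroscedastic_contrast(ch, grouping=ch.groups.to_dict()) if r.contrast == "omnibus"]
        for r in omni:
            j = int(r.feature_id[1:])
            long = pd.DataFrame({
                "y": np.concatenate([data[g][:, j] for g in data]),
                "g": np.repeat(list(data), [len(data[g]) for g in data]),
            })
            ref = pg.welch_anova(long, dv="y", between="g")
            assert r.t_stat == pytest.approx(float(ref["F"].iloc[0]), rel=1e-8)
            assert r.p_value == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)

    def test_small_group_flagged_untestable(self):
        ch = _change_matrix({"CONTROL": [1.0], "G21": [1.0, 2.0, 3.0]})
        (r,) = heteroscedastic_contrast(ch)
        assert r.untestable


def _bh_bruteforce(p):
    """Literal step-up definition: q_i = min over p_(j) >= p_i of m p_(j)/j, clipped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestBHAdjust:
    def test_step_up_arithmetic(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), _bh_bruteforce(p), atol=1e-14)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_p_and_bounded(self, p):
        q = bh_adjust(p)
        assert np.all(q <= 1.0 + 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(np.asarray(q)[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


class TestFoldChange:
    def _cm_with_ratios(self, ratios, group="G21"):
        from conftest import random_cm

        rng = np.random.default_rng(0)
        cm = random_cm(rng, n_animals=len(ratios), n_analytes=1)
        vals = cm.values.copy()
        for i, r in enumerate(ratios):
            sa = f"G21_{i:02d}_SA"
            ea = f"G21_{i:02d}_EA"
            vals.loc[sa, "M00"] = 1.0
            vals.loc[ea, "M00"] = r
        from hypoxmet.datamodel import ConcentrationMatrix

        return ConcentrationMatrix(vals, cm.samples, cm.analytes)

    def test_median_arithmetic(self):
        cm = self._cm_with_ratios([8.0, 9.0, 10.0])
        (fc,) = fold_change(cm, "EA_over_SA", {"G21"})
        assert fc.median_ratio == pytest.approx(9.0)
        assert fc.percent == pytest.approx(900.0)

    def test_identity_case(self):
        cm = self._cm_with_ratios([1.0, 1.0, 1.0])
        (fc,) = fold_change(cm, "EA_over_SA", {"G21"})
        assert fc.percent == pytest.approx(100.0)

    def test_scale_invariance(self, default_cohort):
        cm, _ = default_cohort
        fc1 = {f.feature_id: f.median_ratio for f in fold_change(cm, "EA_over_SA", {"G21"})}
        scaled = cm.copy()
        scaled.values["Suc"] *= 37.0
        fc2 = {f.feature_id: f.median_ratio for f in fold_change(scaled, "EA_over_SA", {"G21"})}
        assert fc2["Suc"] == pytest.approx(fc1["Suc"], rel=1e-12)

    def test_planted_succinate_percent(self):
        cfg = CohortConfig(noise_sd=0.0, seed=10)
        cm, _ = generate_cohort(cfg)
        fcs = {f.feature_id: f for f in fold_change(cm, "EA_over_SA", {"G21", "G100_15", "G100_60"})}
        assert fcs["Suc"].percent == pytest.approx(8000.0, rel=1e-10)

    def test_direction_flag(self):
        cfg = CohortConfig(surge_fc={"Suc": 80.0}, duration_effect={}, noise_sd=0.0, seed=11)
        cm, _ = generate_cohort(cfg)
        df = signed_fold_change(cm, "EA_over_SA", ("G21", "G100_15", "G100_60")).set_index("feature_id")
        assert df.loc["Suc", "direction"] == 1


class TestDurationRegression:
    def test_exact_fit(self):
        x = pd.Series([10.0, 20, 30, 40, 50, 60], index=list("abcdef"))
        y = 2 * x + 1
        r = duration_regression(y, x)
        assert r.slope == pytest.approx(2.0)
        assert r.r2 == pytest.approx(1.0)
        assert r.r2_adj == pytest.approx(1.0)

    def test_null_r2_adj_near_zero(self):
        rng = np.random.default_rng(12)
        idx = [f"a{i}" for i in range(1000)]
        x = pd.Series(rng.uniform(10, 120, 1000), index=idx)
        y = pd.Series(rng.normal(size=1000), index=idx)
        r = duration_regression(y, x)
        assert abs(r.r2_adj) <= 0.01

    def test_r2_adj_formula(self):
        rng = np.random.default_rng(13)
        idx = [f"a{i}" for i in range(12)]
        x = pd.Series(rng.uniform(0, 100, 12), index=idx)
        y = pd.Series(0.03 * x + rng.normal(size=12), index=idx)
        r = duration_regression(y, x)
        assert r.r2_adj == pytest.approx(1 - (1 - r.r2) * 11 / 10, abs=1e-12)
        assert r.r2_adj <= r.r2

    def test_zero_variance_untestable(self):
        idx = list("abcde")
        r = duration_regression(pd.Series(1.0, index=idx), pd.Series([1.0, 2, 3, 4, 5], index=idx))
        assert r.untestable


class TestCohortBalance:
    def test_separated_groups_detected(self):
        rng = np.random.default_rng(14)
        idx = [f"a{i}" for i in range(40)]
        clinical = pd.DataFrame({"weight": np.concatenate([rng.normal(0, 1, 20), rng.normal(10, 1, 20)])}, index=idx)
        grouping = pd.Series(["G21"] * 20 + ["G100_15"] * 20, index=idx)
        out = cohort_balance_check(clinical, grouping)
        assert out.loc[0, "tukey_p[G100_15-G21]"] < 1e-6

    def test_null_anova_p_uniform(self):
        rng = np.random.default_rng(15)
        ps = []
        for _ in range(500):
            vals = rng.normal(size=24)
            groups = rng.permutation(np.repeat(["G21", "G100_15", "G100_60"], 8))
            ps.append(stats.f_oneway(*(vals[groups == g] for g in ("G21", "G100_15", "G100_60"))).pvalue)
        idx = [f"a{i}" for i in range(24)]
        # same machinery through the package entry point on one dataset
        clinical = pd.DataFrame({"x": rng.normal(size=24)}, index=idx)
        out = cohort_balance_check(clinical, pd.Series(np.repeat(["G21", "G100_15", "G100_60"], 8), index=idx))
        assert 0 <= out.loc[0, "p_value"] <= 1
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_single_group_rejected(self):
        idx = list("abcd")
        with pytest.raises(ValidationError):
            cohort_balance_check(pd.DataFrame({"x": [1.0, 2, 3, 4]}, index=idx), pd.Series(["G21"] * 4, index=idx))
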