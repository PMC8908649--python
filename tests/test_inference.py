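import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wmhnet.inference import (
    age_adjusted_group_effect,
    apply_fdr,
    chi_square_test,
    compare_groups,
    fdr_adjust,
    normality_gate,
    partial_correlation,
    pearson_with_p,
    rater_reliability,
    run_group_analysis,
)


class TestNormalityGate:
    def test_gaussian_samples_route_to_t(self, rng):
        a = rng.standard_normal(200)
        b = rng.standard_normal(200)
        assert normality_gate(a, b) == "t_test"

    def test_lognormal_routes_to_mwu(self, rng):
        a = rng.standard_normal(200)
        b = rng.lognormal(0, 1.5, 200)
        assert normality_gate(a, b) == "mann_whitney_u"

    def test_constant_sample_routes_to_mwu(self, rng):
        assert normality_gate(np.ones(20), rng.standard_normal(20)) == "mann_whitney_u"

    def test_too_small_errors(self):
        with pytest.raises(ValueError):
            normality_gate([1.0, 2.0], [1.0, 2.0, 3.0])


class TestCompareGroups:
    def test_identical_normal_samples(self, rng):
        a = rng.standard_normal(100)
        comp = compare_groups(a, a.copy(), "m")
        assert comp.test_used == "t_test"
        assert comp.statistic == pytest.approx(0.0, abs=1e-12)
        assert comp.p_raw == pytest.approx(1.0)

    def test_label_swap_flips_t_statistic(self, rng):
        a = rng.standard_normal(60)
        b = rng.standard_normal(60) + 0.5
        c1 = compare_groups(a, b)
        c2 = compare_groups(b, a)
        if c1.test_used == "t_test" == c2.test_used:
            assert c1.statistic == pytest.approx(-c2.statistic)
        assert c1.p_raw == pytest.approx(c2.p_raw)

    def test_power_for_planted_shift(self):
        # 1-SD shift at the study's group sizes should be detected nearly always
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            a = r.standard_normal(64)
            b = r.standard_normal(46) + 1.0
            if compare_groups(a, b).p_raw < 0.05:
                hits += 1
        assert hits >= 90

    def test_summary_format(self, rng):
        a = rng.standard_normal(50)
        b = rng.standard_normal(50)
        comp = compare_groups(a, b)
        if comp.test_used == "t_test":
            assert "±" in comp.group_a_summary
        else:
            assert "(" in comp.group_a_summary


class TestFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.03]), [0.03])

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(fdr_adjust([0.2] * 5), [0.2] * 5)

    def test_matches_step_up_formula_by_hand(self):
        p = [0.01, 0.02, 0.03, 0.04]
        # p * m / rank = [0.04, 0.04, 0.04, 0.04]; cumulative min from the top
        np.testing.assert_allclose(fdr_adjust(p), [0.04, 0.04, 0.04, 0.04])

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 40)
        _, expected, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(fdr_adjust(p), expected, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_monotone_order_preserving_bounded(self, p):
        # note: BH-adjusted p-values are not a fixed point of the step-up
        # procedure (e.g. [1.0, 0.25] -> [1.0, 0.5] -> [1.0, 1.0]), so
        # idempotence is deliberately NOT asserted here
        adj = fdr_adjust(p)
        assert (adj >= np.asarray(p) - 1e-15).all()
        assert (adj <= 1.0).all()
        # order preserved
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()
        # re-adjustment only moves p-values up, never revives a discovery
        assert (fdr_adjust(adj) >= adj - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])

    def test_apply_fdr_marks_significance(self, rng):
        comps = [compare_groups(rng.standard_normal(30), rng.standard_normal(30) + 3, "m")]
        apply_fdr(comps)
        assert comps[0].p_fdr >= comps[0].p_raw
        assert comps[0].significant is True


class TestChiSquare:
    def test_proportional_table_is_null(self):
        stat, p = chi_square_test([[10, 20], [30, 60]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_diagonal_2x2_hand_value(self):
        stat, _ = chi_square_test([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)  # sum (O-E)^2/E with E=5 everywhere

    def test_row_column_swap_invariance(self):
        t = [[12, 5], [7, 20]]
        s1, p1 = chi_square_test(t)
        s2, p2 = chi_square_test(np.asarray(t)[::-1])
        s3, p3 = chi_square_test(np.asarray(t).T)
        assert s1 == pytest.approx(s2) == pytest.approx(s3)
        assert p1 == pytest.approx(p2) == pytest.approx(p3)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_test([[0, 0], [3, 4]])


class TestAgeAdjustedEffect:
    def test_null_metric_gives_large_p_typically(self):
        ps = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            age = np.concatenate([r.normal(65, 5, 30), r.normal(69, 5, 30)])
            metric = r.standard_normal(60)
            labels = ["A"] * 30 + ["B"] * 30
            ps.append(age_adjusted_group_effect(metric, labels, age).p)
        assert np.mean(np.asarray(ps) < 0.05) < 0.25

    def test_separated_metric_detected(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed + 500)
            metric = np.concatenate([r.normal(0, 1, 40), r.normal(2, 1, 40)])
            age = r.normal(67, 5, 80)
            labels = ["A"] * 40 + ["B"] * 40
            res = age_adjusted_group_effect(metric, labels, age)
            if res.p < 0.05:
                hits += 1
        assert hits >= 18

    def test_constant_metric_flat_coefficient(self, rng):
        age = rng.normal(67, 5, 40)
        labels = ["A"] * 20 + ["B"] * 20
        res = age_adjusted_group_effect(np.ones(40), labels, age)
        assert res.separation_flag or abs(res.coefficient) < 1e-6

    def test_perfect_separation_flagged_not_raised(self):
        metric = np.concatenate([np.zeros(20), np.ones(20) + 5])
        labels = ["A"] * 20 + ["B"] * 20
        age = np.linspace(60, 75, 40)
        res = age_adjusted_group_effect(metric, labels, age)
        assert res.separation_flag


class TestPartialCorrelation:
    def test_zero_covariates_equals_pearson(self, rng):
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        pc = partial_correlation(x, y)
        r, p = pearson_with_p(x, y)
        assert pc.r == pytest.approx(r, abs=1e-12)
        assert pc.p == pytest.approx(p, abs=1e-10)

    def test_confounder_removed(self):
        r = np.random.default_rng(1)
        c = r.standard_normal(500)
        x = c + r.standard_normal(500)
        y = c + r.standard_normal(500)
        pc = partial_correlation(x, y, c)
        assert abs(pc.r) < 0.1

    def test_matches_double_residualization_oracle(self, rng):
        x = rng.standard_normal(80)
        y = rng.standard_normal(80)
        cov = rng.standard_normal((80, 3))
        pc = partial_correlation(x, y, cov)
        design = np.column_stack([np.ones(80), cov])
        rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
        ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        assert pc.r == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        x = rng.standard_normal(60)
        y = 0.4 * x + rng.standard_normal(60)
        cov = rng.standard_normal((60, 2))
        pc = partial_correlation(x, y, cov)
        df = pd.DataFrame({"x": x, "y": y, "c1": cov[:, 0], "c2": cov[:, 1]})
        res = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        assert pc.r == pytest.approx(float(res["r"].iloc[0]), abs=1e-9)
        assert pc.p == pytest.approx(float(res["p_val"].iloc[0]), abs=1e-9)

    def test_symmetry_in_x_and_y(self, rng):
        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        cov = rng.standard_normal(40)
        assert partial_correlation(x, y, cov).r == pytest.approx(partial_correlation(y, x, cov).r, abs=1e-12)

    def test_rank_deficient_covariates_error(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        c = rng.standard_normal(30)
        with pytest.raises(ValueError, match="rank"):
            partial_correlation(x, y, np.column_stack([c, 2 * c]))


class TestPearsonWithP:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, _ = pearson_with_p(x, 2 * x)
        assert r == pytest.approx(1.0)

    def test_independent_gaussians_small_r(self, rng):
        r, _ = pearson_with_p(rng.standard_normal(1000), rng.standard_normal(1000))
        assert abs(r) < 0.1

    def test_zero_variance_errors(self, rng):
        with pytest.raises(ValueError):
            pearson_with_p(np.ones(10), rng.standard_normal(10))


class TestRaterReliability:
    def test_identical_ratings_kappa_one(self):
        r = [0, 1, 2, 3, 1, 2, 0, 3]
        stats = rater_reliability(r, r)
        assert stats.kappa == pytest.approx(1.0)

    def test_independent_ratings_kappa_near_zero(self, rng):
        a = rng.integers(0, 4, 4000)
        b = rng.integers(0, 4, 4000)
        assert abs(rater_reliability(a, b).kappa) < 0.05

    def test_hand_computed_3x3(self):
        # raters agree on 6 of 9; marginals uniform -> pe = 1/3
        a = [0, 0, 0, 1, 1, 1, 2, 2, 2]
        b = [0, 0, 1, 1, 1, 2, 2, 2, 0]
        stats = rater_reliability(a, b)
        po, pe = 6 / 9, 3 * (3 / 9) * (3 / 9)
        assert stats.kappa == pytest.approx((po - pe) / (1 - pe))

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.metrics import cohen_kappa_score

        a = rng.integers(0, 4, 200)
        b = np.where(rng.random(200) < 0.7, a, rng.integers(0, 4, 200))
        assert rater_reliability(a, b).kappa == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_single_category_flagged(self):
        stats = rater_reliability([1, 1, 1], [1, 1, 1])
        assert stats.degenerate


def _toy_metric_tables(rng, n_a=20, n_b=15, n_nodes=8, shift=0.0):
    n = n_a + n_b
    ids = [f"s{i}" for i in range(n)]
    groups = ["A"] * n_a + ["B"] * n_b
    subjects = pd.DataFrame(
        {
            "subject_id": ids,
            "group": groups,
            "wmh_volume_ml": rng.lognormal(0.5, 0.5, n),
            "age": rng.integers(55, 80, n),
            "sex": rng.choice(["F", "M"], n),
            "education_years": rng.integers(5, 16, n),
            "moca": rng.integers(20, 30, n),
            "mmse": rng.integers(25, 30, n),
        }
    ).set_index("subject_id")
    offsets = np.where(np.asarray(groups) == "B", -shift, 0.0)[:, None]
    global_summaries = pd.DataFrame(
        rng.normal(0.5, 0.1, (n, 7)) + offsets,
        index=ids,
        columns=["gamma", "lambda_", "sigma", "cp", "lp", "eglob", "eloc"],
    )
    nodal_e = pd.DataFrame(
        rng.normal(0.1, 0.02, (n, n_nodes)) + offsets * 0.1,
        index=ids,
        columns=[f"node{j}" for j in range(n_nodes)],
    )
    nodal_eloc = nodal_e + rng.normal(0, 0.005, (n, n_nodes))
    return subjects, global_summaries, nodal_e, nodal_eloc


class TestRunGroupAnalysis:
    def test_output_schemas(self, rng):
        subjects, gs, ne, nel = _toy_metric_tables(rng)
        out = run_group_analysis(subjects, gs, ne, nel)
        assert len(out["global"]) == 7
        assert len(out["nodal"]) == 8
        assert len(out["volume"]) == 8
        assert set(out["global"].columns) >= {"metric", "p_raw", "p_fdr", "significant"}

    def test_missing_column_named(self, rng):
        subjects, gs, ne, nel = _toy_metric_tables(rng)
        with pytest.raises(ValueError, match="wmh_volume_ml"):
            run_group_analysis(subjects.drop(columns="wmh_volume_ml"), gs, ne, nel)
        with pytest.raises(ValueError, match="eglob"):
            run_group_analysis(subjects, gs.drop(columns="eglob"), ne, nel)

    def test_planted_shift_detected_with_direction(self, rng):
        subjects, gs, ne, nel = _toy_metric_tables(rng, shift=0.2)
        out = run_group_analysis(subjects, gs, ne, nel)
        assert out["global"]["significant"].all()
        assert out["nodal"]["significant"].any()
        assert len(out["cognition"]) == 2 * out["nodal"]["significant"].sum()

    def test_null_produces_few_discoveries(self):
        sig = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            subjects, gs, ne, nel = _toy_metric_tables(r, shift=0.0)
            out = run_group_analysis(subjects, gs, ne, nel)
            sig.append(out["nodal"]["significant"].mean())
        assert np.mean(sig) <= 0.05
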