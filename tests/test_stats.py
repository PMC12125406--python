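import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hipssm.io import PatientRecord
from hipssm.stats import (
    StatsError,
    derive_outcomes,
    icc_absolute_agreement,
    logistic_fit,
    outcomes_table,
    overall_weighted_icc,
    quintile_assign,
    reliability_from_sessions,
    run_association_suite,
)


def record(**kw):
    defaults = dict(hip_id="p", acetabular_index_5y=15.0)
    defaults.update(kw)
    return PatientRecord(**defaults)


class TestOutcomes:
    def test_closed_reduction_only_is_favorable(self):
        o = derive_outcomes(record(closed_reduction=True, acetabular_index_5y=18.0))
        assert (o.o1_open_reduction, o.o2_surgery, o.o3_osteotomy_or_residual,
                o.o4_unfavorable) == (False, False, False, False)

    def test_open_reduction_excluded_from_outcome3(self):
        o = derive_outcomes(record(open_reduction=True, acetabular_index_5y=None))
        assert o.o1_open_reduction and o.o2_surgery and o.o4_unfavorable
        assert o.o3_osteotomy_or_residual is None

    def test_ai_threshold_is_strict(self):
        o = derive_outcomes(record(acetabular_index_5y=21.0))
        assert not o.o4_unfavorable
        o = derive_outcomes(record(acetabular_index_5y=21.5))
        assert o.o3_osteotomy_or_residual and o.o4_unfavorable

    def test_osteotomy_counts_for_o2_o3_o4(self):
        o = derive_outcomes(record(pelvic_osteotomy=True, acetabular_index_5y=None))
        assert not o.o1_open_reduction
        assert o.o2_surgery and o.o3_osteotomy_or_residual and o.o4_unfavorable

    def test_missing_ai_for_nonsurgical_rejected(self):
        with pytest.raises(StatsError):
            derive_outcomes(record(acetabular_index_5y=None))

    def test_implication_invariants_on_simulated_records(self, cohort_small):
        for r in cohort_small["records"]:
            o = derive_outcomes(r)
            if o.o1_open_reduction:
                assert o.o2_surgery
            if o.o2_surgery:
                assert o.o4_unfavorable
            if o.o3_osteotomy_or_residual:
                assert o.o4_unfavorable
            assert (o.o3_osteotomy_or_residual is None) == o.o1_open_reduction


class TestQuintiles:
    @pytest.mark.parametrize(
        "n,sizes",
        [(92, (18, 19, 18, 19, 18)), (10, (2, 2, 2, 2, 2)), (7, (1, 2, 1, 2, 1)),
         (5, (1, 1, 1, 1, 1))],
    )
    def test_group_sizes(self, n, sizes, rng):
        values = rng.permutation(n).astype(float)  # distinct values
        labels, _ = quintile_assign(values)
        assert tuple(np.bincount(labels, minlength=5)) == sizes

    def test_labels_monotone_in_value(self, rng):
        values = rng.normal(size=40)
        labels, cuts = quintile_assign(values)
        order = np.argsort(values)
        assert np.all(np.diff(labels[order]) >= 0)
        assert cuts == sorted(cuts)

    def test_too_few_values_rejected(self):
        with pytest.raises(StatsError):
            quintile_assign([1.0, 2.0, 3.0, 4.0])

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=5, max_size=200))
    def test_size_invariants(self, values):
        labels, _ = quintile_assign(values)
        sizes = np.bincount(labels, minlength=5)
        assert sizes.sum() == len(values)
        assert sizes.max() - sizes.min() <= 1


def binary_from_counts(a, b, c, d):
    """Expand a 2x2 table: a/b events/non-events exposed, c/d unexposed."""
    y = np.array([1] * a + [0] * b + [1] * c + [0] * d)
    x = np.array([1] * (a + b) + [0] * (c + d), dtype=float)
    return pd.DataFrame({"x": x}), y


class TestLogistic:
    def test_two_by_two_closed_form(self):
        design, y = binary_from_counts(10, 10, 5, 15)
        (res,) = logistic_fit(design, y)
        assert res.odds_ratio == pytest.approx(3.0, abs=1e-6)
        assert res.ci_low < 3.0 < res.ci_high

    def test_symmetric_design_null_or(self):
        design = pd.DataFrame({"x": [1.0, 1.0, 0.0, 0.0]})
        y = np.array([1, 0, 1, 0])
        (res,) = logistic_fit(design, y)
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-8)

    def test_random_tables_match_cross_product(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(1, 20, size=4)
            design, y = binary_from_counts(a, b, c, d)
            (res,) = logistic_fit(design, y)
            assert res.odds_ratio == pytest.approx(a * d / (b * c), rel=1e-6)

    def test_separation_flagged(self):
        # all events in the exposed group: quasi-complete separation
        design, y = binary_from_counts(10, 0, 0, 10)
        (res,) = logistic_fit(design, y)
        assert res.separation

    def test_single_class_outcome_rejected(self):
        design = pd.DataFrame({"x": [0.0, 1.0, 0.0, 1.0]})
        with pytest.raises(StatsError):
            logistic_fit(design, np.zeros(4))

    def test_omnibus_p_matches_lr_test(self, rng):
        x = rng.normal(size=200)
        y = (rng.random(200) < 1 / (1 + np.exp(-(0.2 + 0.8 * x)))).astype(float)
        (res,) = logistic_fit(pd.DataFrame({"x": x}), y)
        import scipy.stats as ss
        import statsmodels.api as sm

        full = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        null = sm.Logit(y, np.ones((200, 1))).fit(disp=0)
        lr = 2 * (full.llf - null.llf)
        assert res.omnibus_p == pytest.approx(ss.chi2.sf(lr, 1), rel=1e-6)


class TestAssociationSuite:
    def test_suite_covers_all_forms(self, cohort_small):
        zs = cohort_small["zscores"]
        fhc = pd.Series(1.0, index=zs.index)
        fhc.iloc[::3] = 2.0
        fhc.iloc[1::5] = 0.0
        outcomes = outcomes_table(cohort_small["records"])
        res = run_association_suite(zs, fhc, outcomes)
        assert set(res["outcome_id"]) == {1, 2, 3, 4}
        assert set(res["model_form"]) == {"univariable", "multivariable", "categorized"}
        k = zs.shape[1]
        per_outcome = k + (k + 1) + 4 * k
        assert len(res) == 4 * per_outcome

    def test_multivariable_has_five_covariates(self, cohort_small):
        zs = cohort_small["zscores"].iloc[:, :4]
        fhc = pd.Series(np.tile([0.0, 1.0, 2.0], 20), index=zs.index)
        outcomes = outcomes_table(cohort_small["records"])
        res = run_association_suite(zs, fhc, outcomes)
        multi = res[(res.model_form == "multivariable") & (res.outcome_id == 4)]
        assert len(multi) == 5  # 4 modes + FHC category

    def test_outcome3_drops_open_reductions(self, cohort_small):
        zs = cohort_small["zscores"]
        fhc = pd.Series(np.tile([0.0, 1.0, 2.0], 20), index=zs.index)
        outcomes = outcomes_table(cohort_small["records"])
        res = run_association_suite(zs, fhc, outcomes)
        n3 = res[res.outcome_id == 3]["n"].iloc[0]
        assert n3 == int(outcomes["o3"].notna().sum())
        assert n3 < len(outcomes)

    def test_all_false_outcome_flagged_not_fatal(self, cohort_small):
        zs = cohort_small["zscores"]
        fhc = pd.Series(np.tile([0.0, 1.0, 2.0], 20), index=zs.index)
        outcomes = outcomes_table(cohort_small["records"]).copy()
        outcomes["o1"] = False
        res = run_association_suite(zs, fhc, outcomes)
        o1 = res[res.outcome_id == 1]
        assert o1["separation"].all()
        assert o1["odds_ratio"].isna().all()
        # the other outcomes still produced estimates
        assert res[res.outcome_id == 4]["odds_ratio"].notna().any()


def anova_icc_oracle(m):
    """Brute-force ICC(A,1) from an explicit two-way OLS ANOVA."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    n, k = m.shape
    df = pd.DataFrame(
        {
            "y": m.ravel(),
            "row": np.repeat(np.arange(n), k).astype(str),
            "col": np.tile(np.arange(k), n).astype(str),
        }
    )
    table = sm.stats.anova_lm(ols("y ~ C(row) + C(col)", data=df).fit(), typ=2)
    msr = table.loc["C(row)", "sum_sq"] / table.loc["C(row)", "df"]
    msc = table.loc["C(col)", "sum_sq"] / table.loc["C(col)", "df"]
    mse = table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"]
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


class TestICC:
    def test_identical_sessions_give_one(self):
        m = np.tile(np.arange(6, dtype=float)[:, None], (1, 3))
        assert icc_absolute_agreement(m) == pytest.approx(1.0)

    def test_constant_offset_penalized(self):
        base = np.arange(6, dtype=float)
        m = np.column_stack([base, base + 2.0])
        assert icc_absolute_agreement(m) < 1.0

    def test_matches_anova_oracle(self, rng):
        for _ in range(10):
            m = rng.normal(size=(6, 3))
            assert icc_absolute_agreement(m) == pytest.approx(
                anova_icc_oracle(m), abs=1e-8
            )

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        m = rng.normal(size=(8, 3))
        n, k = m.shape
        df = pd.DataFrame(
            {
                "y": m.ravel(),
                "targets": np.repeat(np.arange(n), k),
                "raters": np.tile(np.arange(k), n),
            }
        )
        icc = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="y")
        ref = float(icc.set_index("Type").loc["ICC(A,1)", "ICC"])
        assert icc_absolute_agreement(m) == pytest.approx(ref, abs=1e-8)

    def test_missing_cells_rejected(self):
        m = np.ones((4, 2))
        m[0, 0] = np.nan
        with pytest.raises(StatsError):
            icc_absolute_agreement(m)

    def test_icc_decreases_with_noise(self, rng):
        base = rng.normal(size=50)
        iccs = []
        for sd in (0.1, 0.5, 1.5):
            m = base[:, None] + rng.normal(0, sd, size=(50, 3))
            iccs.append(icc_absolute_agreement(m))
        assert iccs[0] > iccs[1] > iccs[2]


class TestWeightedICC:
    def test_constant_iccs(self):
        assert overall_weighted_icc([0.9, 0.9, 0.9], [0.6, 0.3, 0.1]) == pytest.approx(0.9)

    def test_weighted_arithmetic(self):
        assert overall_weighted_icc([1.0, 0.0], [0.75, 0.25]) == pytest.approx(0.75)

    def test_weights_renormalized(self):
        # weights that do not sum to one give the same weighted mean
        a = overall_weighted_icc([0.8, 0.4], [0.6, 0.2])
        b = overall_weighted_icc([0.8, 0.4], [0.75, 0.25])
        assert a == pytest.approx(b)

    def test_sessions_pipeline(self, rng):
        base = rng.normal(size=(12, 4))
        sessions = [base, base + rng.normal(0, 0.1, size=base.shape)]
        result = reliability_from_sessions(sessions, [0.59, 0.23, 0.10, 0.03])
        assert result.weights.sum() == pytest.approx(1.0)
        assert np.all(result.per_mode_icc <= 1.0)
        assert result.overall_icc == pytest.approx(
            float(np.sum(result.weights * result.per_mode_icc))
        )
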