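"""Outlier screen, correlation screen, design expansion, stepwise OLS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pigpex.excretion_models import Term
from pigpex.model_development import (
    ALL_CANDIDATE_TERMS,
    BW_DIETP_TERMS,
    BalanceRecord,
    correlation_matrix,
    expand_terms,
    filter_urinary_outliers,
    fit_metrics,
    forward_stepwise,
    iqr_outlier_filter,
    iqr_outlier_mask,
    validate_balance_frame,
)
from pigpex.synthetic_data import default_generator_config, generate

from conftest import iid_covariate_frame


def oracle_quartiles(values):
    """Independent quartile computation: explicit linear interpolation
    between sorted order statistics at ranks 0.25/0.75*(n-1)."""
    v = sorted(values)
    n = len(v)

    def at(q):
        pos = q * (n - 1)
        lo = int(np.floor(pos))
        hi = int(np.ceil(pos))
        return v[lo] + (pos - lo) * (v[hi] - v[lo])

    return at(0.25), at(0.75)


class TestIQRFilter:
    def test_single_gross_outlier_flagged(self):
        values = [1, 2, 3, 4, 5, 6, 7, 100]
        kept, flagged = iqr_outlier_filter(values, k=3.0)
        assert list(flagged) == [7]
        assert len(kept) == 7

    def test_constant_vector_unflagged(self):
        assert not iqr_outlier_mask([5.0] * 10).any()

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            iqr_outlier_mask([1.0, 2.0, 3.0])

    @settings(deadline=None, max_examples=200)
    @given(
        st.lists(
            st.floats(-1e6, 1e6, allow_nan=False),
            min_size=4,
            max_size=40,
        ),
        st.floats(0.5, 5.0),
    )
    def test_matches_bruteforce_oracle(self, values, k):
        q1, q3 = oracle_quartiles(values)
        fence = k * (q3 - q1)
        lo, hi = q1 - fence, q3 + fence
        expected = np.array([(x < lo) or (x > hi) for x in values])
        got = iqr_outlier_mask(values, k=k)
        # ignore entries sitting exactly on a fence, where last-ulp
        # differences between interpolation formulas could flip the bit
        eps = 1e-9 * max(1.0, abs(lo), abs(hi))
        clear = np.array([min(abs(x - lo), abs(x - hi)) > eps for x in values])
        np.testing.assert_array_equal(got[clear], expected[clear])

    def test_per_experiment_urinary_screen(self, clean_dataset):
        df = clean_dataset.copy()
        # spike the second experiment's largest urinary value tenfold
        idx = df.loc[df.experiment == "Exp2", "urinary_p_g_d"].idxmax()
        df.loc[idx, "urinary_p_g_d"] *= 10
        df.loc[idx, "total_p_g_d"] = (
            df.loc[idx, "fecal_p_g_d"] + df.loc[idx, "urinary_p_g_d"]
        )
        kept, flagged = filter_urinary_outliers(df)
        assert list(flagged.index) == [idx]
        assert (kept.experiment == "Exp2").sum() == 23
        assert len(kept) == 95


class TestCorrelation:
    def test_unit_diagonal_and_symmetry(self, clean_dataset):
        r, p = correlation_matrix(
            clean_dataset, ["bw_kg", "fi_kg_d", "diet_p_pct", "p_intake_g_d"]
        )
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r, r.T)
        assert np.allclose(p, p.T, equal_nan=True)

    def test_perfect_negative_linearity(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        df["y"] = -2 * df.x + 5
        r, _ = correlation_matrix(df, ["x", "y"])
        assert r.loc["x", "y"] == pytest.approx(-1.0)

    def test_hand_computed_r(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "y": [1.0, 3.0, 2.0, 4.0]})
        r, _ = correlation_matrix(df, ["x", "y"])
        assert r.loc["x", "y"] == pytest.approx(0.8)

    def test_p_values_match_pearsonr(self, clean_dataset):
        """scipy.stats.pearsonr as the independent oracle for r and p."""
        cols = ["bw_kg", "fi_kg_d", "fecal_p_g_d"]
        r, p = correlation_matrix(clean_dataset, cols)
        for a in cols:
            for b in cols:
                if a == b:
                    continue
                ref = stats.pearsonr(clean_dataset[a], clean_dataset[b])
                assert r.loc[a, b] == pytest.approx(ref.statistic, abs=1e-12)
                assert p.loc[a, b] == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zero_variance_flagged_not_fatal(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "c": [7.0] * 4})
        r, p = correlation_matrix(df, ["x", "c"])
        assert np.isnan(r.loc["x", "c"])
        assert r.loc["x", "x"] == 1.0

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            correlation_matrix(pd.DataFrame({"x": [1.0, 2.0]}), ["x"])


class TestExpandTerms:
    def test_products_and_squares(self):
        df = pd.DataFrame({"bw_kg": [10.0, 50.0], "fi_kg_d": [2.0, 1.0], "diet_p_pct": [0.5, 0.4]})
        X = expand_terms(df)
        assert X["BWxDIETP"].tolist() == [5.0, 20.0]
        assert X["BW_SQ"].tolist() == [100.0, 2500.0]
        assert X["FIxDIETP"].tolist() == [1.0, 0.4]

    def test_missing_field_names_term(self):
        df = pd.DataFrame({"bw_kg": [10.0]})
        with pytest.raises(ValueError, match="FIxDIETP"):
            expand_terms(df, [Term.FIxDIETP])


class TestStepwise:
    def test_noiseless_recovery_is_exact(self):
        cfg = default_generator_config(
            seed=11, residual_sd_fecal=0.0, residual_sd_urinary=0.0, outlier_rate=0.0
        )
        df = generate(cfg)
        res = forward_stepwise(df, "fecal_p_g_d")
        assert set(res.selected_terms) == {Term.BW_SQ, Term.BWxDIETP}
        assert res.intercept == pytest.approx(-0.654, rel=1e-6)
        assert res.coefficients[Term.BW_SQ] == pytest.approx(-0.000618, rel=1e-6)
        assert res.coefficients[Term.BWxDIETP] == pytest.approx(0.273, rel=1e-6)
        assert all(p < 0.05 for p in res.p_values.values())

    def test_matches_statsmodels_fit(self, clean_dataset):
        """Independent OLS oracle: statsmodels on the selected design."""
        sm = pytest.importorskip("statsmodels.api")
        res = forward_stepwise(clean_dataset, "fecal_p_g_d", candidates=BW_DIETP_TERMS)
        X = expand_terms(clean_dataset, res.selected_terms)
        fit = sm.OLS(clean_dataset["fecal_p_g_d"], sm.add_constant(X)).fit()
        assert res.intercept == pytest.approx(fit.params["const"], rel=1e-9)
        for t in res.selected_terms:
            assert res.coefficients[t] == pytest.approx(fit.params[t.value], rel=1e-9)
            assert res.p_values[t] == pytest.approx(fit.pvalues[t.value], rel=1e-6)
            assert res.std_errors[t] == pytest.approx(fit.bse[t.value], rel=1e-9)
        assert res.r2 == pytest.approx(fit.rsquared, rel=1e-9)
        assert res.rmse == pytest.approx(np.sqrt(fit.mse_resid), rel=1e-9)

    def test_permutation_invariance(self, clean_dataset):
        shuffled = clean_dataset.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = forward_stepwise(clean_dataset, "fecal_p_g_d", candidates=BW_DIETP_TERMS)
        b = forward_stepwise(shuffled, "fecal_p_g_d", candidates=BW_DIETP_TERMS)
        assert a.selected_terms == b.selected_terms
        assert a.intercept == pytest.approx(b.intercept, abs=1e-10)
        for t in a.selected_terms:
            assert a.coefficients[t] == pytest.approx(b.coefficients[t], abs=1e-10)

    def test_null_calibration_band(self):
        """On pure-noise responses the entry rate sits between the
        single-test level and the independent-tests family-wise bound;
        the 9 candidates are correlated (squares/products of 3 covariates)
        so the rate falls well short of 1 - 0.95^9."""
        enters = 0
        n_rep = 200
        for s in range(n_rep):
            rng = np.random.default_rng(60_000 + s)
            df = iid_covariate_frame(rng, 95)
            df["y"] = rng.normal(size=95)
            res = forward_stepwise(df, "y")
            enters += bool(res.selected_terms)
        rate = enters / n_rep
        assert 0.05 < rate < 0.45

    def test_strict_alpha_gives_intercept_only(self):
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(70_000 + s)
            df = iid_covariate_frame(rng, 95)
            df["y"] = rng.normal(size=95)
            res = forward_stepwise(df, "y", alpha_enter=1e-9, alpha_stay=1.0)
            hits += not res.selected_terms
        assert hits >= 99

    def test_intercept_only_is_valid_result(self):
        rng = np.random.default_rng(5)
        df = iid_covariate_frame(rng, 50)
        df["y"] = rng.normal(size=50)
        res = forward_stepwise(df, "y", alpha_enter=1e-12)
        assert res.selected_terms == []
        assert res.intercept == pytest.approx(df["y"].mean())

    def test_rank_deficient_candidate_skipped(self):
        rng = np.random.default_rng(8)
        df = iid_covariate_frame(rng, 60)
        df["diet_p_pct"] = 0.5  # constant: DIETP collinear with intercept
        df["y"] = 2.0 * df.bw_kg + rng.normal(size=60)
        res = forward_stepwise(df, "y", candidates=[Term.DIETP, Term.BW])
        assert Term.BW in res.selected_terms
        assert Term.DIETP not in res.selected_terms
        assert any(e["action"] == "skipped" for e in res.trace)

    def test_trace_records_entries(self, clean_dataset):
        res = forward_stepwise(clean_dataset, "fecal_p_g_d", candidates=BW_DIETP_TERMS)
        entered = {e["candidate"] for e in res.trace if e["action"] == "entered"}
        final = {t.value for t in res.selected_terms}
        assert final <= entered  # every kept term entered at some step
        assert all(p < 0.05 for p in res.p_values.values())

    def test_needs_more_records_than_candidates(self):
        rng = np.random.default_rng(1)
        df = iid_covariate_frame(rng, 8)
        df["y"] = rng.normal(size=8)
        with pytest.raises(ValueError):
            forward_stepwise(df, "y", candidates=ALL_CANDIDATE_TERMS)


class TestFitMetrics:
    def test_perfect_fit(self, published, clean_dataset):
        df = clean_dataset.copy()
        from pigpex.excretion_models import evaluate

        df["fecal_p_g_d"] = evaluate(
            published["Eq1"], bw_kg=df.bw_kg.to_numpy(), diet_p_pct=df.diet_p_pct.to_numpy()
        )
        m = fit_metrics(df, published["Eq1"], "fecal_p_g_d")
        assert m["r2"] == pytest.approx(1.0)
        assert m["rmse"] == pytest.approx(0.0, abs=1e-9)

    def test_intercept_at_mean_gives_zero_r2(self, clean_dataset):
        from pigpex.excretion_models import ExcretionModel

        mean_model = ExcretionModel(
            "mean", "fecal", float(clean_dataset.fecal_p_g_d.mean()), {}
        )
        m = fit_metrics(clean_dataset, mean_model, "fecal_p_g_d")
        assert m["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_residual_sd_recovery(self, published):
        rmses = []
        for s in range(10):
            df = generate(default_generator_config(seed=100 + s, outlier_rate=0.0))
            rmses.append(fit_metrics(df, published["Eq1"], "fecal_p_g_d")["rmse"])
        assert np.mean(rmses) == pytest.approx(0.656, abs=0.1)


class TestBalanceRecord:
    def test_total_must_balance(self):
        with pytest.raises(ValueError, match="total"):
            BalanceRecord("p", "e", 1, "d", 50, 2.0, 0.5, 10.0, 3.0, 0.5, 4.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            BalanceRecord("p", "e", 1, "d", 50, -2.0, 0.5, 10.0, 3.0, 0.5, 3.5)

    def test_frame_validation(self, clean_dataset):
        validate_balance_frame(clean_dataset)  # should not raise
        broken = clean_dataset.copy()
        broken.loc[broken.index[0], "total_p_g_d"] += 1.0
        with pytest.raises(ValueError, match="total_p_g_d"):
            validate_balance_frame(broken)
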