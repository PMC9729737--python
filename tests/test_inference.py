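"""The statistical engine: moderators, correlations, type II F-tests,
backward selection, FDR, pivot coefficients."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from timeuse_coda import (
    CohortConfig,
    ModelSpec,
    OutcomeEffects,
    assign_moderators,
    backward_select,
    bh_adjust,
    build_design,
    extract_pivot_coefficients,
    fit_model,
    generate_cohort,
    pairwise_correlations,
    run_study,
    type2_anova,
)
from timeuse_coda.composition import sbp_order
from timeuse_coda.inference import COMPOSITION_TERM, _check_full_rank, format_study_table
from timeuse_coda.synthetic import generate_outcomes


def small_cohort(seed, n=80, **outcome_kwargs):
    cfg = CohortConfig(n=n, seed=seed, outcomes={"y": OutcomeEffects(**outcome_kwargs)})
    return generate_cohort(cfg)


def brute_force_type2(df, spec):
    """Independent oracle: explicit statsmodels refits of both nested models
    for every term group, marginality applied by hand."""
    design = build_design(df, spec)
    X, y = design.X, design.y
    full = sm.OLS(y, X).fit()
    rows = {}
    for term in spec.terms:
        if term == COMPOSITION_TERM:
            containing = [f"{COMPOSITION_TERM}:{m}" for m in spec.interactions]
        elif term in spec.interactions:
            containing = [f"{COMPOSITION_TERM}:{term}"]
        else:
            containing = []
        g = design.groups[term]
        dropped = set(g)
        for other in containing:
            dropped |= set(design.groups[other])
        base = [c for c in X.columns if c not in dropped]
        without = sm.OLS(y, X[base]).fit()
        with_g = sm.OLS(y, X[base + g]).fit()
        f = ((without.ssr - with_g.ssr) / len(g)) / full.mse_resid
        rows[term] = (f, scipy.stats.f.sf(f, len(g), full.df_resid))
    return rows


class TestAssignModerators:
    def test_sleep_quality_dichotomy(self):
        out = assign_moderators(
            pd.Series([10.0] * 4), pd.Series([0.0] * 4), pd.Series([0, 1, 2, 3])
        )
        assert list(out["sleep_quality"]) == ["good", "good", "bad", "bad"]

    def test_recpa_category_edges(self):
        out = assign_moderators(
            pd.Series([10.0] * 3), pd.Series([0.0, 30.0, 30.5]), pd.Series([0, 0, 0])
        )
        assert list(out["recpa"]) == ["none", "upto30", "over30"]

    def test_tv_tertiles_split_at_empirical_quantiles(self):
        out = assign_moderators(
            pd.Series([10.0, 20, 30, 40, 50, 60]),
            pd.Series([0.0] * 6),
            pd.Series([0] * 6),
        )
        assert list(out["tv"]) == ["low", "low", "medium", "medium", "high", "high"]

    def test_invalid_rating_rejected(self):
        with pytest.raises(ValueError):
            assign_moderators(pd.Series([1.0]), pd.Series([0.0]), pd.Series([4]))


class TestPairwiseCorrelations:
    def test_perfect_and_inverse_correlation(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "up": [2.0, 4, 6, 8], "down": [4.0, 3, 2, 1]})
        r, p, n = pairwise_correlations(df)
        assert r.loc["x", "up"] == pytest.approx(1.0)
        assert r.loc["x", "down"] == pytest.approx(-1.0)

    def test_hand_computed_r(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [1.0, 3, 2, 4]})
        r, p, n = pairwise_correlations(df)
        assert r.loc["x", "y"] == pytest.approx(0.8)
        # p from the t transform with n-2 df
        t = 0.8 * np.sqrt(2 / (1 - 0.64))
        assert p.loc["x", "y"] == pytest.approx(2 * scipy.stats.t.sf(t, 2), rel=1e-6)

    def test_pairwise_complete_and_insufficient_pairs_flagged(self):
        df = pd.DataFrame(
            {"a": [1.0, 2, np.nan, 4, 5], "b": [2.0, 4, 6, np.nan, 10],
             "c": [1.0, np.nan, np.nan, np.nan, 2]}
        )
        r, p, n = pairwise_correlations(df)
        assert n.loc["a", "b"] == 3
        assert n.loc["a", "c"] == 2 and np.isnan(r.loc["a", "c"])


class TestFitModel:
    def test_exact_linear_outcome_recovered(self):
        df = small_cohort(31, n=120)
        effects = OutcomeEffects(
            beta_composition=(0.5, -0.4, 0.2),
            beta_covariates={"age": 0.1, "sex_female": -0.3},
            noise_sd=0.0,
        )
        df["y"] = generate_outcomes(df, effects, seed=0)
        fm = fit_model(df, ModelSpec(outcome="y", interactions=()))
        assert fm.result.rsquared == pytest.approx(1.0)
        np.testing.assert_allclose(
            fm.result.params[["z1", "z2", "z3"]], [0.5, -0.4, 0.2], atol=1e-8
        )
        assert fm.result.params["age"] == pytest.approx(0.1, abs=1e-8)

    def test_all_raw_minutes_with_intercept_is_rank_deficient(self):
        # the collinearity compositional coordinates exist to avoid
        df = small_cohort(32)
        X = df[["sleep_min", "sb_min", "lpa_min", "mvpa_min"]].copy()
        X.insert(0, "const", 1.0)
        with pytest.raises(ValueError, match="aliased"):
            _check_full_rank(X)

    def test_duplicated_covariate_is_reported(self):
        df = small_cohort(33)
        df["education"] = 2.0 * df["age"]
        with pytest.raises(ValueError, match="rank deficient"):
            fit_model(df, ModelSpec(outcome="y", interactions=()))

    def test_complete_case_count_reflects_missing_outcomes(self):
        df = small_cohort(34, n=100)
        df.loc[df.index[:7], "y"] = np.nan
        fm = fit_model(df, ModelSpec(outcome="y", interactions=()))
        assert fm.n == 93


class TestType2Anova:
    def test_single_predictor_f_equals_squared_t(self):
        rng = np.random.default_rng(41)
        df = pd.DataFrame({"age": rng.normal(65, 3, 50), "y": rng.normal(size=50)})
        spec = ModelSpec(outcome="y", covariates=("age",), moderators=(),
                         composition=False, interactions=())
        tt = type2_anova(df, spec).set_index("term")
        fm = fit_model(df, spec)
        assert tt.loc["age", "F"] == pytest.approx(fm.result.tvalues["age"] ** 2, rel=1e-10)

    def test_balanced_orthogonal_design_type2_equals_sequential(self):
        rng = np.random.default_rng(42)
        n = 80
        df = pd.DataFrame(
            {
                "sex": np.tile(["male", "female"], n // 2),
                "site": np.repeat(["adelaide", "newcastle"], n // 2),
                "y": rng.normal(size=n),
            }
        )
        spec = ModelSpec(outcome="y", covariates=("sex", "site"), moderators=(),
                         composition=False, interactions=())
        tt = type2_anova(df, spec).set_index("term")
        design = build_design(df, spec)
        X = design.X
        m0 = sm.OLS(design.y, X[["const"]]).fit()
        m1 = sm.OLS(design.y, X[["const", "sex_female"]]).fit()
        m2 = sm.OLS(design.y, X).fit()
        ss_sex_seq = m0.ssr - m1.ssr
        ss_site_seq = m1.ssr - m2.ssr
        assert tt.loc["sex", "F"] == pytest.approx(ss_sex_seq / m2.mse_resid, rel=1e-10)
        assert tt.loc["site", "F"] == pytest.approx(ss_site_seq / m2.mse_resid, rel=1e-10)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_matches_brute_force_oracle(self, seed):
        df = small_cohort(seed, n=90, beta_composition=(0.3, 0.0, -0.2))
        spec = ModelSpec(outcome="y", interactions=("sleep_quality", "tv"))
        tt = type2_anova(df, spec).set_index("term")
        oracle = brute_force_type2(df, spec)
        for term, (f, p) in oracle.items():
            assert tt.loc[term, "F"] == pytest.approx(f, rel=1e-8)
            assert tt.loc[term, "p"] == pytest.approx(p, rel=1e-8, abs=1e-12)


class TestBackwardSelect:
    def test_strong_interactions_are_all_kept(self):
        big = {"bad": (2.0, 2.0, 2.0)}
        cfg = CohortConfig(
            n=500, seed=51,
            outcomes={"y": OutcomeEffects(
                beta_composition=(0.5, 0.5, 0.5),
                beta_interaction={
                    "sleep_quality": {"bad": (2.0, 2.0, 2.0)},
                    "tv": {"medium": (2.0, 2.0, 2.0), "high": (2.0, -2.0, 2.0)},
                    "recpa": {"none": (2.0, 2.0, -2.0), "upto30": (-2.0, 2.0, 2.0)},
                },
                noise_sd=0.5,
            )},
        )
        df = generate_cohort(cfg)
        final, trace = backward_select(df, outcome="y")
        assert set(final.interactions) == {"tv", "recpa", "sleep_quality"}
        assert final.composition
        assert trace[0].action == "keep"

    def test_null_data_removes_interactions_then_composition(self):
        df = small_cohort(52, n=384)
        final, trace = backward_select(df, outcome="y")
        removed = [s.term for s in trace if s.action == "remove"]
        assert all(t.startswith("composition") for t in removed)
        # marginality: composition may only be removed after every interaction
        if COMPOSITION_TERM in removed:
            comp_at = removed.index(COMPOSITION_TERM)
            assert all(":" in t for t in removed[:comp_at])
        # the collective covariate block is tested and retained by default
        assert trace[-1].term == "covariates" and trace[-1].action == "keep"

    def test_null_replicates_remove_all_interactions_most_of_the_time(self):
        removed_all = 0
        comp_removed = 0
        n_reps = 150
        for rep in range(n_reps):
            df = small_cohort(1000 + rep, n=384)
            final, _ = backward_select(df, outcome="y")
            removed_all += not final.interactions
            comp_removed += not final.composition
        assert removed_all / n_reps >= 0.85
        # composition retention should be roughly alpha-level once eligible
        assert 0.88 <= comp_removed / n_reps <= 1.0

    def test_strict_covariate_removal_switch(self):
        df = small_cohort(53, n=300)
        final, trace = backward_select(df, outcome="y", drop_covariates=True)
        decision = [s for s in trace if s.term == "covariates"][0]
        if decision.p >= 0.05:
            assert final.covariates == () and decision.action == "remove"
        else:
            assert final.covariates and decision.action == "keep"


class TestBhAdjust:
    def test_published_family_rounds_correctly(self):
        # the eight raw term p-values of one final model, family size 8
        raw = [0.01, 0.01, 0.40, 0.51, 0.05, 0.43, 0.38, 0.05]
        adj = bh_adjust(raw)
        assert round(adj[5], 2) == 0.49  # raw 0.43
        assert round(adj[6], 2) == 0.49  # raw 0.38
        assert round(adj[3], 2) == 0.51  # raw 0.51 (the maximum)
        assert round(adj[4], 2) == 0.10  # raw 0.05
        assert round(adj[7], 2) == 0.10

    def test_single_and_tied_inputs(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
    def test_matches_statsmodels_and_is_monotone(self, pvals):
        adj = bh_adjust(pvals)
        _, ref, _, _ = multipletests(pvals, method="fdr_bh")
        np.testing.assert_allclose(adj, ref, atol=1e-12)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0)
        # order preservation: adjustment never swaps the ranking
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestPivotCoefficients:
    def test_exact_pivot_outcome_recovered(self):
        from timeuse_coda.composition import ilr_transform

        df = small_cohort(61, n=150)
        z = ilr_transform(df[["sleep_min", "sb_min", "lpa_min", "mvpa_min"]].to_numpy())
        df["y"] = 0.7 * z[:, 0]  # sleep-first pivot coordinate, zero noise
        spec = ModelSpec(outcome="y", interactions=())
        betas = extract_pivot_coefficients(df, spec)
        assert betas["sleep"] == pytest.approx(0.7, abs=1e-8)

    def test_fitted_values_identical_across_rotations(self):
        df = small_cohort(62, n=150, beta_composition=(0.4, -0.1, 0.2))
        spec = ModelSpec(outcome="y", interactions=())
        fits = [fit_model(df, spec, order=sbp_order(p)).result for p in
                ("sleep", "sb", "lpa", "mvpa")]
        for other in fits[1:]:
            np.testing.assert_allclose(fits[0].fittedvalues, other.fittedvalues, atol=1e-9)
            assert fits[0].rsquared == pytest.approx(other.rsquared, abs=1e-12)

    def test_focal_beta_ignores_non_focal_order(self):
        df = small_cohort(63, n=150, beta_composition=(0.4, -0.1, 0.2))
        spec = ModelSpec(outcome="y", interactions=())
        b1 = fit_model(df, spec, order=("mvpa", "sleep", "sb", "lpa")).result.params["z1"]
        b2 = fit_model(df, spec, order=("mvpa", "lpa", "sleep", "sb")).result.params["z1"]
        assert b1 == pytest.approx(b2, rel=1e-10)

    def test_requires_composition_block(self):
        df = small_cohort(64)
        spec = ModelSpec(outcome="y", composition=False, interactions=())
        with pytest.raises(ValueError):
            extract_pivot_coefficients(df, spec)


class TestRunStudy:
    def test_composition_effect_is_detected_where_generated(self, effect_cohort):
        results = run_study(effect_cohort, outcomes=["speed", "ltm"])
        assert results["speed"].spec.composition
        speed_terms = set(results["speed"].term_table["term"])
        assert COMPOSITION_TERM in speed_terms
        assert results["speed"].pivot_betas is not None

    def test_adjusted_p_never_below_raw(self, effect_cohort):
        results = run_study(effect_cohort, outcomes=["speed", "exec", "stm"])
        for res in results.values():
            tt = res.term_table
            assert np.all(tt["p_adj"].to_numpy() >= tt["p"].to_numpy() - 1e-15)
            assert np.all(tt["p_adj"].to_numpy() <= 1.0)

    def test_removed_terms_render_as_dashes(self, null_cohort):
        results = run_study(null_cohort, outcomes=["ltm", "speed"])
        table = format_study_table(results)
        dropped = [name for name, res in results.items() if not res.spec.composition]
        for name in dropped:
            if COMPOSITION_TERM in table.index:
                assert table.loc[COMPOSITION_TERM, name] == "–"

    def test_per_outcome_listwise_deletion(self, null_cohort):
        df = null_cohort.copy()
        df.loc[df.index[:30], "stm"] = np.nan
        results = run_study(df, outcomes=["stm", "ltm"])
        assert results["stm"].n == len(df) - 30
        assert results["ltm"].n == len(df)

    def test_marginality_asserted_on_every_trace(self, null_cohort):
        results = run_study(null_cohort, outcomes=["ltm", "stm", "speed"])
        for res in results.values():
            interactions_alive = {"tv", "recpa", "sleep_quality"}
            for step in res.trace:
                if step.term.startswith(f"{COMPOSITION_TERM}:"):
                    if step.action == "remove":
                        interactions_alive.discard(step.term.split(":", 1)[1])
                elif step.term == COMPOSITION_TERM and step.action == "remove":
                    # the composition block is only removable once no
                    # interaction block remains
                    assert not interactions_alive
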