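"""Panels and random-effects estimation: construction, estimator sanity."""

import numpy as np
import pytest

from boswellia.analysis import (
    SPECS,
    EmptyPanelError,
    InvalidComparisonError,
    build_panel,
    fit_random_effects,
    gap_test,
    summarize_rounds,
)
from boswellia.cohort import CohortConfig, generate_cohort
from boswellia.simulator import (
    EXTRACTION_COEFF_DEFAULTS,
    TARGET_COEFF_DEFAULTS,
    GameConfig,
    simulate_experiment,
)
from boswellia.survey import score_respondents


def _noiseless_records(seed=3):
    cohort, assign = generate_cohort(CohortConfig(seed=seed))
    cohort = score_respondents(cohort, on_degenerate="drop")
    cfg = GameConfig(
        target_group_re_sd=0, target_noise_sd=0,
        extraction_group_re_sd=0, extraction_noise_sd=0,
        shuffling_noise_sd=0, round_outcomes=False, seed=seed,
    )
    rec = simulate_experiment(cohort, assign, cfg,
                              rng=np.random.default_rng(seed))
    return cohort, rec


class TestBuildPanel:
    def test_group_round_shape(self, default_records):
        panel = build_panel(default_records, SPECS["group_round"])
        # 42 groups x 4 voting sessions x 3 rounds
        assert len(panel) == 42 * 4 * 3
        assert panel["round"].isin([1, 2, 3]).all()
        assert set(panel["session"]) == {3, 4, 5, 6}

    def test_session_aggregation_sums_rounds(self, default_records):
        rnd = build_panel(default_records, SPECS["individual_round"])
        ses = build_panel(default_records, SPECS["individual_session"])
        one = rnd[(rnd["individual_id"] == rnd["individual_id"].iloc[0])
                  & (rnd["session"] == 3)]
        agg = ses[(ses["individual_id"] == one["individual_id"].iloc[0])
                  & (ses["session"] == 3)]
        assert agg["extraction"].iloc[0] == one["extraction"].sum()
        assert agg["group_target"].iloc[0] == one["group_target"].sum()

    def test_period_dummies_reference_round_one(self, default_records):
        panel = build_panel(default_records, SPECS["group_round"])
        assert panel["period_2"].sum() == (panel["round"] == 2).sum()
        assert ((panel["period_2"] + panel["period_3"]) ==
                (panel["round"] != 1)).all()

    def test_session_dummies_reference_first_voting_session(self, default_records):
        panel = build_panel(default_records, SPECS["group_session"])
        assert {"session_4", "session_5", "session_6"} <= set(panel.columns)
        assert "session_3" not in panel.columns

    def test_excluded_sessions_never_appear(self, default_records):
        for spec in SPECS.values():
            panel = build_panel(default_records, spec)
            assert (panel["session"] >= 3).all()

    def test_empty_input_raises(self, default_records):
        only_excluded = default_records[default_records["analysis_excluded"]]
        with pytest.raises(EmptyPanelError):
            build_panel(only_excluded, SPECS["group_round"])

    def test_minimal_panel_one_group_session(self, default_records):
        sub = default_records[
            (default_records["group_id"] == default_records["group_id"].iloc[0])
            & (default_records["session"] == 3)
        ]
        g = build_panel(sub, SPECS["group_round"])
        assert len(g) == 3
        s = build_panel(sub, SPECS["group_session"])
        assert len(s) == 1


class TestFitRandomEffects:
    def test_noiseless_identification_target_equation(self):
        """Continuous zero-noise DGP: fitted coefficients equal the truth."""
        _, rec = _noiseless_records()
        spec = SPECS["group_round"]
        fit = fit_random_effects(build_panel(rec, spec), spec)
        for term, truth in TARGET_COEFF_DEFAULTS.items():
            if term in fit.params.index:
                assert fit.params[term] == pytest.approx(truth, abs=1e-6), term
        assert fit.params["const"] == pytest.approx(
            TARGET_COEFF_DEFAULTS["const"], abs=1e-6
        )

    def test_noiseless_identification_extraction_equation(self):
        _, rec = _noiseless_records()
        spec = SPECS["individual_round"]
        fit = fit_random_effects(build_panel(rec, spec), spec)
        for term, truth in EXTRACTION_COEFF_DEFAULTS.items():
            if term in fit.params.index:
                assert fit.params[term] == pytest.approx(truth, abs=1e-6), term

    def test_fgls_and_mle_agree(self, default_records):
        spec = SPECS["group_round"]
        panel = build_panel(default_records, spec)
        f1 = fit_random_effects(panel, spec, method="fgls")
        f2 = fit_random_effects(panel, spec, method="mle")
        assert np.allclose(f1.params, f2.params, atol=0.02)

    def test_variance_components_recovered(self, default_records):
        """Configured group-RE SD 2.0 and idiosyncratic SD 1.7 come back
        from the variance decomposition (single-run tolerance)."""
        spec = SPECS["group_round"]
        fit = fit_random_effects(build_panel(default_records, spec), spec)
        assert fit.sigma_u == pytest.approx(2.0, abs=0.8)
        assert fit.sigma_e == pytest.approx(1.7, abs=0.4)

    def test_clustered_se_exceed_pooled_classical_for_group_regressors(
        self, default_records
    ):
        """With a positive group random effect, cluster-robust SEs on
        between-group regressors dominate classical pooled-OLS SEs."""
        import statsmodels.api as sm

        spec = SPECS["group_round"]
        panel = build_panel(default_records, spec)
        fit = fit_random_effects(panel, spec)
        cols = spec.regressors(panel)
        ols = sm.OLS(
            panel[spec.outcome].astype(float),
            sm.add_constant(panel[cols].astype(float)),
        ).fit()
        # cognitive/bonding are purely between-group: ignoring the intra-
        # group correlation (pooled classical) understates their SEs.
        for term in ("cognitive", "bonding"):
            assert fit.se[term] >= ols.bse[term]

    def test_consistency_bias_shrinks_with_more_groups(self):
        """Mean cognitive-coefficient error at 420 groups is no larger than
        at 42 groups (consistency of the RE pipeline)."""
        truth = TARGET_COEFF_DEFAULTS["cognitive"]

        def mean_est(n_resp, seeds):
            vals = []
            for s in seeds:
                cohort, assign = generate_cohort(
                    CohortConfig(n_respondents=n_resp, seed=s)
                )
                cohort = score_respondents(cohort, on_degenerate="drop")
                cfg = GameConfig(seed=900 + s)
                rec = simulate_experiment(cohort, assign, cfg,
                                          rng=np.random.default_rng(900 + s))
                spec = SPECS["group_round"]
                vals.append(
                    fit_random_effects(build_panel(rec, spec), spec)
                    .params["cognitive"]
                )
            return np.mean(vals)

        small = mean_est(210, range(6))
        large = mean_est(2100, range(3))
        assert abs(large - truth) <= abs(small - truth) + 0.5

    def test_rank_deficiency_raises(self, default_records):
        spec = SPECS["group_round"]
        panel = build_panel(default_records, spec)
        panel["bonding"] = panel["cognitive"]  # force collinearity
        with pytest.raises(np.linalg.LinAlgError):
            fit_random_effects(panel, spec)

    def test_single_group_rejected(self, default_records):
        spec = SPECS["group_round"]
        panel = build_panel(default_records, spec)
        with pytest.raises(ValueError):
            fit_random_effects(panel[panel["group_id"] == 1], spec)

    def test_stars_follow_convention(self, default_records):
        spec = SPECS["group_round"]
        fit = fit_random_effects(build_panel(default_records, spec), spec)
        for term, p in fit.pvalues.items():
            star = fit.stars[term]
            if p < 0.01:
                assert star == "***"
            elif p < 0.05:
                assert star == "**"
            elif p < 0.1:
                assert star == "*"
            else:
                assert star == ""


class TestGapTest:
    def test_positive_under_default_calibration(self, default_records):
        """The configured reputation shift widens the target-extraction gap."""
        t, p = gap_test(default_records)
        assert t > 0

    def test_identical_distributions_give_small_t(self, default_records):
        rec = default_records[~default_records["analysis_excluded"]].copy()
        rng = np.random.default_rng(0)
        # destroy the scenario association by permuting labels
        rec["scenario"] = rng.permutation(rec["scenario"].to_numpy())
        rec["analysis_excluded"] = False
        t, _ = gap_test(rec)
        assert abs(t) < 3.0

    def test_single_scenario_rejected(self, default_records):
        rec = default_records[
            default_records["scenario"] == "voting_shuffling"
        ].copy()
        with pytest.raises(InvalidComparisonError):
            gap_test(rec)

    def test_degenerate_zero_variance_rejected(self, default_records):
        rec = default_records[~default_records["analysis_excluded"]].copy()
        rec["extraction"] = rec["group_target"]  # gap identically zero
        with pytest.raises(InvalidComparisonError):
            gap_test(rec)


class TestSummaries:
    def test_benchmark_column_constant_at_ten(self, default_records, params):
        s = summarize_rounds(default_records, params)
        assert (s["benchmark"] == 10).all()

    def test_zero_noise_round1_target_is_17(self):
        cfg = GameConfig(
            target_group_re_sd=0, target_noise_sd=0,
            extraction_group_re_sd=0, extraction_noise_sd=0,
            shuffling_noise_sd=0, seed=3,
        )
        cohort, assign = generate_cohort(CohortConfig(seed=3))
        cohort = score_respondents(cohort, on_degenerate="drop")
        rec = simulate_experiment(cohort, assign, cfg,
                                  rng=np.random.default_rng(3))
        s = summarize_rounds(rec)
        r1 = s[s["round"] == 1]
        # SC effects average ~0 across groups; the rounded intercept is 17
        assert r1["mean_target"].mean() == pytest.approx(17, abs=0.5)

    def test_absent_scenario_rows_absent(self, default_records):
        rec = default_records[
            default_records["scenario"] != "voting_shuffling_reputation"
        ]
        s = summarize_rounds(rec)
        assert "voting_shuffling_reputation" not in set(s["scenario"])
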