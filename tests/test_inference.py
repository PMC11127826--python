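"""Selection models (Laplace GLMM), LRT, predictions, classical tests, tables."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from somamat import (
    PlayerRecord,
    SyntheticCohortConfig,
    category_distribution,
    cohort_frame,
    compare_groups,
    crosstab_success,
    fit_selection_model,
    likelihood_ratio_test,
    nhl_spec,
    predicted_probabilities,
    simulate_cohort,
    team16_spec,
    univariable_spec,
    SelectionModelSpec,
)
from somamat.pipeline import estimate_cohort


def _fitting_frame(default_ref, n=2000, seed=7, **kw):
    cfg = SyntheticCohortConfig(
        n_players=n,
        measurement_sd=0.0,
        p_entry_error=0.0,
        p_lost_followup=1.0,
        recovered_height_policy="all",
        p_birthdate_missing=0.0,
        seed=seed,
        **kw,
    )
    records, truth = simulate_cohort(cfg, default_ref)
    return cohort_frame(records, estimate_cohort(records, default_ref)), truth


class TestFitSelectionModel:
    def test_recovers_team16_effect(self, default_ref):
        frame, _ = _fitting_frame(default_ref, seed=7)
        fit = fit_selection_model(frame, team16_spec())
        assert fit.converged
        assert fit.coefficients.loc["z_pah", "estimate"] == pytest.approx(0.21, abs=0.15)

    def test_recovers_nhl_effect_with_team_adjustment(self, default_ref):
        frame, _ = _fitting_frame(default_ref, seed=7)
        fit = fit_selection_model(frame, nhl_spec())
        assert fit.converged
        assert fit.coefficients.loc["z_pah", "estimate"] == pytest.approx(-0.50, abs=0.15)
        assert set(fit.coefficients.index) >= {"team16", "team18", "team20"}

    def test_aic_identity(self, default_ref):
        frame, _ = _fitting_frame(default_ref, n=800, seed=19)
        for spec in (team16_spec(), univariable_spec("team16")):
            fit = fit_selection_model(frame, spec)
            assert fit.aic == pytest.approx(
                2 * fit.k_params - 2 * fit.log_likelihood, rel=1e-12
            )

    def test_ci_orders_and_wald_symmetry(self, default_ref):
        frame, _ = _fitting_frame(default_ref, n=800, seed=19)
        fit = fit_selection_model(frame, team16_spec())
        c = fit.coefficients
        assert (c["ci_low"] <= c["estimate"]).all()
        assert (c["estimate"] <= c["ci_high"]).all()

    def test_zero_region_variance_reduces_to_plain_logistic(self, default_ref):
        frame, _ = _fitting_frame(default_ref, seed=43, region_sd=0.0)
        mixed = fit_selection_model(frame, team16_spec())
        plain = fit_selection_model(
            frame, SelectionModelSpec("team16", ("z_pah", "year_of_collection"), None)
        )
        assert mixed.coefficients.loc["z_pah", "estimate"] == pytest.approx(
            plain.coefficients.loc["z_pah", "estimate"], abs=0.02
        )

    def test_single_class_response_rejected(self, default_ref):
        frame, _ = _fitting_frame(default_ref, n=200, seed=3)
        frame = frame.assign(team16=0.0)
        with pytest.raises(ValueError, match="single class"):
            fit_selection_model(frame, team16_spec())

    def test_perfect_separation_flags_nonconvergence(self, caplog):
        z = np.array([-2.0, -1.5, -1.2, -1.0, -0.8, 0.8, 1.0, 1.2, 1.5, 2.0])
        frame = pd.DataFrame(
            {
                "team16": (z > 0).astype(float),
                "z_pah": z,
                "year_of_collection": 2005.0,
                "region": ["A", "B"] * 5,
            }
        )
        spec = SelectionModelSpec("team16", ("z_pah",), "region")
        with caplog.at_level("WARNING"):
            fit = fit_selection_model(frame, spec)
        assert not fit.converged

    def test_team16_spec_rejects_team_covariates(self):
        with pytest.raises(ValueError, match="team-membership"):
            SelectionModelSpec("team16", ("z_pah", "team18"), "region")

    def test_matches_lme4_glmer_laplace(self, default_ref, tmp_path):
        """Independent oracle: lme4's glmer (nAGQ=1, the same Laplace
        objective) on an identical cohort."""
        frame, _ = _fitting_frame(default_ref, n=800, seed=19)
        frame = frame.assign(year_c=frame["year_of_collection"] - 2007.0)
        spec = SelectionModelSpec("team16", ("z_pah",), "region")
        fit = fit_selection_model(frame, spec)
        csv = tmp_path / "frame.csv"
        frame.to_csv(csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(lme4))
                d <- read.csv("{csv}")
                m <- glmer(team16 ~ z_pah + (1 | region), data = d,
                           family = binomial, nAGQ = 1)
                cat(fixef(m)["z_pah"], sqrt(unlist(VarCorr(m))), logLik(m), sep = ",")
                """
            )
        )
        out = subprocess.run(
            ["Rscript", str(rscript)], capture_output=True, text=True, check=True
        )
        z_r, sigma_r, ll_r = (float(x) for x in out.stdout.strip().split(","))
        assert fit.coefficients.loc["z_pah", "estimate"] == pytest.approx(z_r, abs=0.01)
        assert fit.random_intercept_sd == pytest.approx(sigma_r, abs=0.02)
        assert fit.log_likelihood == pytest.approx(ll_r, abs=0.05)


class TestLikelihoodRatio:
    def test_identical_models_give_zero_statistic(self, default_ref):
        frame, _ = _fitting_frame(default_ref, n=600, seed=5)
        fit = fit_selection_model(frame, univariable_spec("team16"))
        res = likelihood_ratio_test(fit, fit)
        assert res.statistic == 0.0 and res.df == 0 and res.p == 1.0

    def test_full_beats_null_under_strong_effect(self, default_ref):
        frame, _ = _fitting_frame(default_ref, n=2000, seed=5, beta_team16=1.0)
        full = fit_selection_model(frame, team16_spec())
        null = fit_selection_model(
            frame, SelectionModelSpec("team16", ("year_of_collection",), "region")
        )
        res = likelihood_ratio_test(full, null)
        assert res.statistic > 0
        assert res.df == 1
        assert res.p < 0.05

    def test_non_nested_rejected(self, default_ref):
        frame, _ = _fitting_frame(default_ref, n=600, seed=5)
        fit_a = fit_selection_model(
            frame, SelectionModelSpec("team16", ("z_pah",), None)
        )
        fit_b = fit_selection_model(
            frame, SelectionModelSpec("team16", ("year_of_collection",), None)
        )
        with pytest.raises(ValueError, match="subset"):
            likelihood_ratio_test(fit_a, fit_b)

    def test_unequal_n_rejected(self, default_ref):
        frame, _ = _fitting_frame(default_ref, n=600, seed=5)
        full = fit_selection_model(frame, team16_spec())
        null = fit_selection_model(frame.iloc[:500], univariable_spec("team16"))
        with pytest.raises(ValueError, match="row counts"):
            likelihood_ratio_test(full, null)


class TestPredictedProbabilities:
    def test_probabilities_in_unit_interval_and_monotone(self, default_ref):
        frame, _ = _fitting_frame(default_ref, seed=7)
        fit = fit_selection_model(frame, team16_spec())
        p = predicted_probabilities(fit, frame)
        assert ((p > 0) & (p < 1)).all()
        # monotone in z within one region, all else equal
        base = frame.iloc[[0]].copy()
        grid = pd.concat([base] * 5, ignore_index=True)
        grid["z_pah"] = np.linspace(-2, 2, 5)
        pg = predicted_probabilities(fit, grid)
        assert (np.diff(pg) > 0).all()

    def test_calibration_against_observed_rate(self, default_ref):
        frame, _ = _fitting_frame(default_ref, n=5000, seed=41)
        fit = fit_selection_model(frame, team16_spec())
        p = predicted_probabilities(fit, frame)
        assert p.mean() == pytest.approx(frame["team16"].mean(), abs=0.02)

    def test_unknown_region_falls_back_to_population_level(self, default_ref, caplog):
        frame, _ = _fitting_frame(default_ref, n=600, seed=5)
        fit = fit_selection_model(frame, team16_spec())
        alien = frame.iloc[[0]].assign(region="Z99")
        with caplog.at_level("WARNING"):
            p = predicted_probabilities(fit, alien)
        assert 0 < p.iloc[0] < 1
        assert "unseen region" in caplog.text


class TestCompareGroups:
    def test_identical_groups_null_result(self):
        g = np.arange(10.0)
        res = compare_groups([g, g], "t_test")
        assert res.effect.estimate == 0.0
        assert res.p == pytest.approx(1.0)

    def test_welch_ci_width_closed_form(self):
        """N(0,1) vs N(1,1) at n=10,000: diff ≈ 1, CI width ≈ 2·1.96·sqrt(2/n)."""
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1.0, 10000)
        b = rng.normal(1.0, 1.0, 10000)
        res = compare_groups([a, b], "t_test")
        assert res.effect.estimate == pytest.approx(-1.0, abs=0.05)
        width = res.effect.ci_high - res.effect.ci_low
        assert width == pytest.approx(2 * 1.96 * np.sqrt(2.0 / 10000), rel=0.02)

    def test_chi_square_matches_hand_formula(self):
        table = np.array([[50.0, 50.0], [90.0, 10.0]])
        # Pearson X^2 = sum (O-E)^2/E with E from margins
        row, col, n = table.sum(1, keepdims=True), table.sum(0, keepdims=True), table.sum()
        expected = row @ col / n
        x2 = float(((table - expected) ** 2 / expected).sum())
        res = compare_groups(table, "chi_square")
        assert res.statistic == pytest.approx(x2, rel=1e-12)

    def test_anova_runs_and_agrees_with_scipy(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(m, 1.0, 50) for m in (0.0, 0.3, 0.6)]
        res = compare_groups(groups, "anova")
        f, p = stats.f_oneway(*groups)
        assert res.statistic == pytest.approx(float(f))
        assert res.p == pytest.approx(float(p))

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([[1.0], [1.0, 2.0]], "t_test")


class TestTables:
    def _table1_cohort(self):
        """Cohort reconstructed from printed success counts (n=2211, NHL 96)."""
        records = []
        i = 0

        def add(n, **flags):
            nonlocal i
            for _ in range(n):
                records.append(PlayerRecord(player_id=f"t{i}", **flags))
                i += 1

        # NHL group: 48/96 team16, 70/96 team18, 88/96 team20 (overlap is
        # irrelevant for the per-team crosstab margins; nest the flags)
        add(48, nhl=True, team16=True, team18=True, team20=True)
        add(22, nhl=True, team18=True, team20=True)
        add(18, nhl=True, team20=True)
        add(8, nhl=True)
        # non-NHL group: 169 team16, 128 team18, 112 team20 of 2115
        add(112, team16=True, team18=True, team20=True)
        add(16, team16=True, team18=True)
        add(41, team16=True)
        add(2115 - 169, nhl=False)
        return records

    def test_crosstab_reproduces_printed_percentages(self):
        tab = crosstab_success(self._table1_cohort()).set_index(["junior_team", "selected"])
        assert tab.loc[("team16", "yes"), "nhl_n"] == 48
        assert tab.loc[("team16", "yes"), "nhl_pct"] == 50
        assert tab.loc[("team18", "yes"), "nhl_pct"] == 73
        assert tab.loc[("team20", "yes"), "nhl_pct"] == 92
        assert tab.loc[("team16", "yes"), "non_nhl_pct"] == 8
        # row pairs sum to the group sizes
        assert tab.loc[("team16",), "nhl_n"].sum() == 96
        assert tab.loc[("team16",), "non_nhl_n"].sum() == 2115

    def test_all_selected_gives_100_percent(self):
        records = [
            PlayerRecord(player_id=i, team16=True, team18=True, team20=True, nhl=(i == 0))
            for i in range(4)
        ]
        tab = crosstab_success(records).set_index(["junior_team", "selected"])
        assert (tab.loc[(slice(None), "yes"), ["nhl_pct", "non_nhl_pct"]] == 100).all().all()

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            crosstab_success([])

    def test_percentages_recompute_from_counts(self, default_ref):
        cfg = SyntheticCohortConfig(n_players=500, seed=3)
        records, _ = simulate_cohort(cfg, default_ref)
        tab = crosstab_success(records)
        nhl_total = sum(r.nhl for r in records)
        for _, row in tab.iterrows():
            assert row["nhl_pct"] == int(np.floor(100 * row["nhl_n"] / nhl_total + 0.5))


class TestCategoryDistribution:
    def test_simple_proportions(self):
        frame = pd.DataFrame({"category_z": ["early"] * 3 + ["on_time"] * 5 + ["late"] * 2})
        out = category_distribution(frame)
        assert out["proportion"].tolist() == [0.3, 0.5, 0.2]
        assert out["count"].sum() == 10

    def test_standard_normal_calibration(self):
        from somamat import classify_z

        rng = np.random.default_rng(8)
        z = rng.standard_normal(100000)
        frame = pd.DataFrame({"category_z": [classify_z(v) for v in z]})
        out = category_distribution(frame)
        expected = {
            "early": stats.norm.sf(0.5),
            "on_time": stats.norm.cdf(0.5) - stats.norm.cdf(-0.5),
            "late": stats.norm.cdf(-0.5),
        }
        for cat, exp in expected.items():
            assert out.loc[cat, "proportion"] == pytest.approx(exp, abs=0.01)

    def test_single_category_group(self):
        frame = pd.DataFrame({"category_offset": ["early", "early"]})
        out = category_distribution(frame, by="category_offset")
        assert out["proportion"].tolist() == [1.0, 0.0, 0.0]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            category_distribution(pd.DataFrame({"category_z": []}))
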