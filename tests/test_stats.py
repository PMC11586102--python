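import json
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from batnight import stats


def two_group_poisson(n_per_group, rate_a, rate_b, seed, group_name="group"):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            group_name: ["a"] * n_per_group + ["b"] * n_per_group,
            "n_returns": np.concatenate(
                [rng.poisson(rate_a, n_per_group), rng.poisson(rate_b, n_per_group)]
            ),
        }
    )


class TestModelSpec:
    def test_family_link_restriction(self):
        with pytest.raises(ValueError, match="family/link"):
            stats.ModelSpec("y", "poisson", "identity")

    def test_formula_rendering(self):
        spec = stats.ModelSpec("n_returns", "poisson", "log", fixed_terms=("sex", "season"))
        assert spec.formula == "n_returns ~ sex + season"
        assert stats.ModelSpec("y", "gaussian", "identity").formula == "y ~ 1"


class TestFitGlm:
    def test_poisson_intercept_is_log_mean(self):
        table = pd.DataFrame({"n_returns": [1, 2, 3]})
        fit = stats.fit_glm(table, stats.ModelSpec("n_returns", "poisson", "log"))
        assert np.exp(fit.params["Intercept"]) == pytest.approx(2.0, abs=1e-8)
        assert fit.aic == pytest.approx(2 * 1 - 2 * fit.loglik)

    def test_two_group_rate_ratio_recovered(self):
        table = two_group_poisson(5000, 1.0, 2.0, seed=202)
        fit = stats.fit_glm(
            table, stats.ModelSpec("n_returns", "poisson", "log", fixed_terms=("group",))
        )
        ratio = float(np.exp(fit.params["group[T.b]"]))
        assert 1.9 <= ratio <= 2.1

    def test_gaussian_identity_equals_ols(self):
        rng = np.random.default_rng(7)
        table = pd.DataFrame({"x": rng.normal(size=50)})
        table["y"] = 1.5 + 2.0 * table["x"] + rng.normal(size=50)
        fit = stats.fit_glm(
            table, stats.ModelSpec("y", "gaussian", "identity", fixed_terms=("x",))
        )
        beta = np.polyfit(table["x"], table["y"], 1)
        assert fit.params["x"] == pytest.approx(beta[0], rel=1e-6)
        assert fit.params["Intercept"] == pytest.approx(beta[1], rel=1e-6)

    def test_gamma_zero_response_instructs_filtering(self):
        table = pd.DataFrame({"hours_inside": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="drop_nonpositive"):
            stats.fit_glm(table, stats.ModelSpec("hours_inside", "gamma", "inverse"))
        filtered = stats.drop_nonpositive(table, "hours_inside")
        assert len(filtered) == 2

    def test_negative_binomial_estimates_dispersion(self):
        rng = np.random.default_rng(31)
        lam = rng.gamma(2.0, 1.0, size=2000)  # overdispersed mixture
        table = pd.DataFrame({"n_returns": rng.poisson(lam)})
        fit = stats.fit_glm(table, stats.ModelSpec("n_returns", "negative_binomial", "log"))
        assert fit.dispersion is not None and fit.dispersion > 0.1
        assert np.exp(fit.params["Intercept"]) == pytest.approx(2.0, rel=0.1)


class TestLrt:
    def _fits(self, table):
        alt = stats.fit_glm(
            table, stats.ModelSpec("n_returns", "poisson", "log", fixed_terms=("group",))
        )
        null = stats.fit_glm(table, stats.ModelSpec("n_returns", "poisson", "log"))
        return alt, null

    def test_model_against_itself_is_degenerate(self):
        table = two_group_poisson(50, 1.0, 1.0, seed=3)
        alt, _ = self._fits(table)
        res = stats.lrt(alt, alt)
        assert res.chi2 == 0.0 and res.df == 0 and res.p_value == 1.0

    def test_strong_effect_rejects(self):
        table = two_group_poisson(2000, 1.0, 3.0, seed=4)
        alt, null = self._fits(table)
        res = stats.lrt(alt, null)
        assert res.df == 1
        assert res.p_value < 1e-6

    def test_non_nested_specs_rejected(self):
        table = two_group_poisson(50, 1.0, 1.0, seed=5)
        table["x"] = np.arange(len(table))
        alt = stats.fit_glm(
            table, stats.ModelSpec("n_returns", "poisson", "log", fixed_terms=("group",))
        )
        other = stats.fit_glm(
            table, stats.ModelSpec("n_returns", "poisson", "log", fixed_terms=("x",))
        )
        with pytest.raises(ValueError, match="nested"):
            stats.lrt(alt, other)

    def test_type_one_error_calibrated(self):
        """Null Poisson data: LRT rejects at roughly the nominal 5% rate."""
        n_reject = 0
        n_sims = 400
        for s in range(n_sims):
            table = two_group_poisson(40, 2.0, 2.0, seed=10_000 + s)
            alt, null = self._fits(table)
            if stats.lrt(alt, null).p_value < 0.05:
                n_reject += 1
        assert 0.02 <= n_reject / n_sims <= 0.08


class TestPairwiseContrasts:
    def _three_level_fit(self, seed=8, rates=(1.0, 1.5, 3.0), n=300):
        rng = np.random.default_rng(seed)
        frames = [
            pd.DataFrame({"cond": lvl, "n_returns": rng.poisson(rate, n)})
            for lvl, rate in zip(["lactating", "nonreproductive", "pregnant"], rates)
        ]
        table = pd.concat(frames, ignore_index=True)
        return stats.fit_glm(
            table, stats.ModelSpec("n_returns", "poisson", "log", fixed_terms=("cond",))
        )

    def test_three_levels_give_three_contrasts(self):
        cons = stats.pairwise_contrasts(self._three_level_fit(), "cond")
        assert len(cons) == 3
        pairs = {c.level_pair for c in cons}
        assert len(pairs) == 3

    def test_adjusted_p_never_below_unadjusted(self):
        for c in stats.pairwise_contrasts(self._three_level_fit(), "cond"):
            assert c.p_adjusted >= c.p_unadjusted - 1e-12
            assert c.ci_low <= c.estimate_response_scale <= c.ci_high

    def test_two_level_contrast_equals_coefficient(self):
        table = two_group_poisson(500, 1.0, 2.0, seed=9)
        fit = stats.fit_glm(
            table, stats.ModelSpec("n_returns", "poisson", "log", fixed_terms=("group",))
        )
        (con,) = stats.pairwise_contrasts(fit, "group", adjustment="none")
        # a-vs-b ratio equals exp(-coef of b)
        assert con.estimate_response_scale == pytest.approx(
            float(np.exp(-fit.params["group[T.b]"])), rel=1e-9
        )

    def test_absent_factor_rejected(self):
        fit = self._three_level_fit()
        with pytest.raises(ValueError, match="not in the fit data"):
            stats.pairwise_contrasts(fit, "sex")

    def test_inverse_link_ratio_of_means(self):
        rng = np.random.default_rng(12)
        table = pd.DataFrame(
            {
                "cond": ["a"] * 800 + ["b"] * 800,
                "hours_active": np.concatenate(
                    [rng.gamma(4.0, 1.0, 800), rng.gamma(4.0, 0.5, 800)]
                ),
            }
        )
        fit = stats.fit_glm(
            table, stats.ModelSpec("hours_active", "gamma", "inverse", fixed_terms=("cond",))
        )
        (con,) = stats.pairwise_contrasts(fit, "cond", adjustment="none")
        # true mean ratio a/b = 4.0/2.0 = 2
        assert con.estimate_response_scale == pytest.approx(2.0, rel=0.1)


class TestCandidateSet:
    def test_sixteen_models_with_null_and_closure(self):
        specs = stats.build_candidate_set("n_returns", "negative_binomial", "log")
        assert len(specs) == 16
        assert len({s.fixed_terms for s in specs}) == 16
        assert any(s.fixed_terms == () for s in specs)
        menu = {"sex", "season", "tmean_c", "precip_mm", "sex:season"}
        for s in specs:
            assert set(s.fixed_terms) <= menu
            assert s.random_terms == ("bat_id", "year")

    def test_interactive_models_present(self):
        specs = stats.build_candidate_set("y", "gaussian", "identity")
        assert sum("sex:season" in s.fixed_terms for s in specs) == 4


class TestAicSelection:
    def test_ties_share_the_best_set(self):
        table = two_group_poisson(100, 1.0, 1.0, seed=13)
        fit = stats.fit_glm(table, stats.ModelSpec("n_returns", "poisson", "log"))
        ranked = stats.select_by_aic([fit, fit])
        assert list(ranked["delta_aic"]) == [0.0, 0.0]
        assert ranked["in_best_set"].all()

    def test_ranking_sorted_and_row_order_invariant(self):
        table = two_group_poisson(2000, 1.0, 2.0, seed=14)
        fit_null = stats.fit_glm(table, stats.ModelSpec("n_returns", "poisson", "log"))
        fit_alt = stats.fit_glm(
            table, stats.ModelSpec("n_returns", "poisson", "log", fixed_terms=("group",))
        )
        shuffled = table.sample(frac=1.0, random_state=0)
        fit_alt_shuffled = stats.fit_glm(
            shuffled, stats.ModelSpec("n_returns", "poisson", "log", fixed_terms=("group",))
        )
        ranked = stats.select_by_aic([fit_null, fit_alt])
        assert ranked["aic"].is_monotonic_increasing
        assert ranked.loc[0, "terms"] == "group"
        assert fit_alt_shuffled.aic == pytest.approx(fit_alt.aic, abs=1e-6)

    def test_differing_rows_rejected(self):
        t1 = two_group_poisson(100, 1.0, 1.0, seed=15)
        t2 = two_group_poisson(90, 1.0, 1.0, seed=16)
        f1 = stats.fit_glm(t1, stats.ModelSpec("n_returns", "poisson", "log"))
        f2 = stats.fit_glm(t2, stats.ModelSpec("n_returns", "poisson", "log"))
        with pytest.raises(ValueError, match="differing"):
            stats.select_by_aic([f1, f2])


def gaussian_mixed_table(n_bats=100, nights=20, bat_sd=0.5, seed=21, effect=1.0):
    rng = np.random.default_rng(seed)
    bat_effects = rng.normal(0.0, bat_sd, n_bats)
    rows = []
    for b in range(n_bats):
        sex = "F" if b % 2 == 0 else "M"
        for k in range(nights):
            rows.append(
                {
                    "bat_id": f"b{b:03d}",
                    "year": 2016 + (k % 2),
                    "sex": sex,
                    "y": 5.0
                    + (effect if sex == "M" else 0.0)
                    + bat_effects[b]
                    + rng.normal(0.0, 1.0),
                }
            )
    return pd.DataFrame(rows)


class TestFitGlmm:
    def test_gaussian_random_intercept_sd_recovered(self):
        table = gaussian_mixed_table(n_bats=100, nights=20, bat_sd=0.5, seed=22)
        spec = stats.ModelSpec(
            "y", "gaussian", "identity", fixed_terms=("sex",), random_terms=("bat_id", "year")
        )
        fit = stats.fit_glmm(table, spec)
        assert fit.fallback is None
        assert 0.35 <= fit.random_effect_sd["bat_id"] <= 0.65

    def test_zero_variance_truth_matches_plain_glm(self):
        table = gaussian_mixed_table(n_bats=60, nights=10, bat_sd=0.0, seed=23)
        spec_mm = stats.ModelSpec(
            "y", "gaussian", "identity", fixed_terms=("sex",), random_terms=("bat_id", "year")
        )
        spec_glm = stats.ModelSpec("y", "gaussian", "identity", fixed_terms=("sex",))
        fit_mm = stats.fit_glmm(table, spec_mm)
        fit_glm = stats.fit_glm(table, spec_glm)
        # boundary estimate: variance should be negligible next to resid var 1.0
        assert fit_mm.random_effect_sd["bat_id"] ** 2 < 0.03 * fit_mm.dispersion
        assert fit_mm.params["sex[T.M]"] == pytest.approx(
            fit_glm.params["sex[T.M]"], rel=0.01
        )

    def test_non_gaussian_fallback_recorded_and_signs_agree(self):
        rng = np.random.default_rng(24)
        n = 800
        table = pd.DataFrame(
            {
                "bat_id": [f"b{i % 40:02d}" for i in range(n)],
                "year": 2016,
                "sex": ["F", "M"] * (n // 2),
            }
        )
        table["n_returns"] = rng.poisson(np.where(table["sex"] == "M", 3.0, 1.5))
        spec = stats.ModelSpec(
            "n_returns", "poisson", "log", fixed_terms=("sex",),
            random_terms=("bat_id", "year"),
        )
        fit_mm = stats.fit_glmm(table, spec)
        fit_plain = stats.fit_glm(
            table, stats.ModelSpec("n_returns", "poisson", "log", fixed_terms=("sex",))
        )
        assert fit_mm.fallback == "glm_cluster_robust"
        assert np.sign(fit_mm.params["sex[T.M]"]) == np.sign(fit_plain.params["sex[T.M]"])
        assert fit_mm.params["sex[T.M]"] == pytest.approx(fit_plain.params["sex[T.M]"], rel=1e-8)

    def test_gaussian_mixed_fit_matches_glmmtmb_oracle(self, tmp_path):
        """Independent cross-check of the linear mixed model against glmmTMB."""
        table = gaussian_mixed_table(n_bats=30, nights=8, bat_sd=0.4, seed=25)
        csv = tmp_path / "d.csv"
        table.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(glmmTMB))
                d <- read.csv("{csv}")
                m <- glmmTMB(y ~ sex + (1 | bat_id) + (1 | year), data = d, REML = FALSE)
                cat(jsonlite::toJSON(as.list(fixef(m)$cond), auto_unbox = TRUE))
                """
            )
        )
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True, timeout=300
        )
        assert proc.returncode == 0, proc.stderr
        oracle = json.loads(proc.stdout[proc.stdout.index("{"):])
        spec = stats.ModelSpec(
            "y", "gaussian", "identity", fixed_terms=("sex",), random_terms=("bat_id", "year")
        )
        fit = stats.fit_glmm(table, spec)
        assert fit.params["Intercept"] == pytest.approx(oracle["(Intercept)"], abs=0.02)
        assert fit.params["sex[T.M]"] == pytest.approx(oracle["sexM"], abs=0.02)


class TestEffectReport:
    def test_log_link_ratio_back_transform(self):
        table = two_group_poisson(500, 1.0, 2.0, seed=26)
        fit = stats.fit_glm(
            table, stats.ModelSpec("n_returns", "poisson", "log", fixed_terms=("group",))
        )
        report = stats.effect_report(fit)
        row = report[report["term"] == "group[T.b]"].iloc[0]
        assert row["effect_response_scale"] == pytest.approx(
            np.exp(fit.params["group[T.b]"]), rel=1e-9
        )
        assert row["scale"] == "ratio"
        assert row["ci_low_response"] < row["effect_response_scale"] < row["ci_high_response"]

    def test_identity_link_reports_difference(self):
        table = gaussian_mixed_table(n_bats=20, nights=5, bat_sd=0.0, seed=27)
        fit = stats.fit_glm(
            table, stats.ModelSpec("y", "gaussian", "identity", fixed_terms=("sex",))
        )
        report = stats.effect_report(fit)
        row = report[report["term"] == "sex[T.M]"].iloc[0]
        assert row["effect_response_scale"] == pytest.approx(fit.params["sex[T.M]"])
        assert row["scale"] == "difference"

    def test_ci_endpoints_stay_ordered_after_back_transform(self):
        table = two_group_poisson(200, 1.5, 1.7, seed=28)
        fit = stats.fit_glm(
            table, stats.ModelSpec("n_returns", "poisson", "log", fixed_terms=("group",))
        )
        report = stats.effect_report(fit)
        assert (report["ci_low_response"] <= report["ci_high_response"]).all()
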