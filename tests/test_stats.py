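"""Inferential layer: ANOVA partitioning, ART, correlations, centering, LMM."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import AnovaRM, anova_lm

import groovesync as gs
from tests.conftest import make_exact_correlation


def _factorial(n_subjects=10, effect_a=(0.0, 1.0, 2.0), noise=1.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for i, a in enumerate("XYZ"):
            for b in "PQR":
                rows.append(
                    {
                        "participant": s,
                        "A": a,
                        "B": b,
                        "y": effect_a[i] + noise * rng.normal(),
                    }
                )
    return pd.DataFrame(rows)


class TestAnova:
    def test_pooled_matches_statsmodels(self):
        data = _factorial()
        ours = gs.anova_two_way(data, "y", "A", "B", mode="pooled", aggregate=False)
        ref = anova_lm(smf.ols("y ~ C(A)*C(B)", data).fit(), typ=2)
        for effect, label in [("A", "C(A)"), ("B", "C(B)"), ("A:B", "C(A):C(B)")]:
            row = ours.table.set_index("effect").loc[effect]
            assert row["F"] == pytest.approx(ref.loc[label, "F"], rel=1e-10)
            assert row["SS"] == pytest.approx(ref.loc[label, "sum_sq"], rel=1e-10)

    def test_repeated_matches_statsmodels_anovarm(self):
        data = _factorial(n_subjects=8, seed=3)
        ours = gs.anova_two_way(data, "y", "A", "B", mode="repeated", aggregate=True)
        ref = AnovaRM(data, "y", "participant", within=["A", "B"]).fit().anova_table
        for effect, label in [("A", "A"), ("B", "B"), ("A:B", "A:B")]:
            row = ours.table.set_index("effect").loc[effect]
            assert row["F"] == pytest.approx(ref.loc[label, "F Value"], rel=1e-8)
            assert row["df1"] == ref.loc[label, "Num DF"]
            assert row["df2"] == ref.loc[label, "Den DF"]

    def test_balanced_decomposition_sums_to_total(self):
        data = _factorial(seed=4)
        res = gs.anova_two_way(data, "y", "A", "B", mode="pooled", aggregate=False)
        ss = res.table["SS"].sum() + res.table["SS_error"].iloc[0]
        total = ((data["y"] - data["y"].mean()) ** 2).sum()
        assert ss == pytest.approx(total, rel=1e-8)

    def test_location_invariance(self):
        data = _factorial(seed=5)
        shifted = data.assign(y=data["y"] + 5.0)
        f0 = gs.anova_two_way(data, "y", "A", "B", aggregate=False).table["F"]
        f1 = gs.anova_two_way(shifted, "y", "A", "B", aggregate=False).table["F"]
        assert np.allclose(f0, f1, rtol=1e-10)

    def test_zero_variance_rejected(self):
        data = _factorial(noise=0.0, effect_a=(1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="zero variance|equal"):
            gs.anova_two_way(data, "y", "A", "B", aggregate=False)

    def test_unbalanced_rejected(self):
        data = _factorial().iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            gs.anova_two_way(data, "y", "A", "B", aggregate=False)

    def test_table1_degrees_of_freedom_layout(self):
        # 30 participants x 3 x 3 cells aggregated -> pooled error df = 261
        rng = np.random.default_rng(0)
        design = gs.generate_design(gs.DesignSpec(n_participants=30, seed=0))
        design["y"] = rng.normal(size=len(design))
        res = gs.anova_two_way(design, "y", "syncopation", "movement", mode="pooled")
        assert list(res.table["df1"]) == [2, 2, 4]
        assert list(res.table["df2"]) == [261, 261, 261]


class TestART:
    def test_alignment_has_zero_grand_mean(self):
        data = _factorial(seed=6)
        res = gs.art_anova(data, "y", "A", "B", aggregate=False)
        assert np.all(np.abs(res.table["aligned_grand_mean"]) < 1e-9)

    def test_pure_effect_dominates_after_ranking(self):
        data = _factorial(effect_a=(0.0, 5.0, 10.0), noise=1e-6, seed=7)
        res = gs.art_anova(data, "y", "A", "B", aggregate=False)
        f = res.table.set_index("effect")["F"]
        assert f["A"] == f.max()
        assert f["A"] > 100 * max(f["B"], f["A:B"])

    def test_rank_pattern_invariant_to_monotone_transform(self):
        data = _factorial(effect_a=(0.0, 5.0, 10.0), noise=1e-6, seed=8)
        transformed = data.assign(y=data["y"] ** 3 + 2 * data["y"] + 10)
        f_raw = gs.art_anova(data, "y", "A", "B", aggregate=False).table
        f_tr = gs.art_anova(transformed, "y", "A", "B", aggregate=False).table
        # the target effect's rank-based F is unchanged, the parametric F is not
        assert f_raw.set_index("effect").loc["A", "F"] == pytest.approx(
            f_tr.set_index("effect").loc["A", "F"], rel=1e-9
        )
        p_raw = gs.anova_two_way(data, "y", "A", "B", aggregate=False).table
        p_tr = gs.anova_two_way(transformed, "y", "A", "B", aggregate=False).table
        assert not np.isclose(
            p_raw.set_index("effect").loc["A", "F"],
            p_tr.set_index("effect").loc["A", "F"],
        )

    def test_normality_gate(self):
        rng = np.random.default_rng(9)
        data = _factorial(seed=9)
        assert not gs.normality_violated(data, "y", "A", "B")
        skewed = data.assign(y=np.exp(2 * data["y"]))
        assert gs.normality_violated(skewed, "y", "A", "B")


class TestPosthoc:
    def test_holm_adjustment_ordering(self):
        data = _factorial(effect_a=(0.0, 0.1, 3.0), seed=10)
        out = gs.posthoc_pairwise(data, "y", "A")
        assert (out["p_adj"] >= out["p_raw"] - 1e-15).all()
        strongest = out.sort_values("p_adj").iloc[0]
        assert {strongest["level_a"], strongest["level_b"]} in (
            {"X", "Z"}, {"Y", "Z"},
        )

    def test_bonferroni_at_least_as_conservative(self):
        data = _factorial(seed=11)
        holm = gs.posthoc_pairwise(data, "y", "A", method="holm")
        bonf = gs.posthoc_pairwise(data, "y", "A", method="bonferroni")
        assert (bonf["p_adj"] >= holm["p_adj"] - 1e-15).all()


class TestCorrelation:
    @pytest.mark.parametrize(
        "r,expected",
        [(0.291, (0.089, 0.470)), (-0.302, (-0.479, -0.101))],
    )
    def test_fisher_interval_reproduces_published_examples(self, r, expected):
        x, y = make_exact_correlation(r, 90)
        res = gs.correlation_with_ci(x, y)
        assert res.r == pytest.approx(r, abs=1e-12)
        assert round(res.ci_low, 3) == expected[0]
        assert round(res.ci_high, 3) == expected[1]

    def test_p_value_matches_scipy(self):
        x, y = make_exact_correlation(0.35, 60, seed=2)
        from scipy.stats import pearsonr

        res = gs.correlation_with_ci(x, y)
        ref = pearsonr(x, y)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_perfect_correlation_degenerate_interval(self):
        x = np.arange(10.0)
        res = gs.correlation_with_ci(x, x)
        assert res.r == 1.0
        assert res.ci_high == 1.0
        assert res.p == 0.0

    def test_small_n_and_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            gs.correlation_with_ci([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError, match="variance"):
            gs.correlation_with_ci(np.ones(10), np.arange(10.0))

    def test_interval_contains_estimate(self):
        for seed, r in enumerate((-0.8, -0.2, 0.0, 0.4, 0.9)):
            x, y = make_exact_correlation(r, 40, seed=seed)
            res = gs.correlation_with_ci(x, y)
            assert res.ci_low <= res.r <= res.ci_high


class TestConditionwise:
    def test_grid_shape_and_cell_sizes(self):
        design = gs.generate_design(gs.DesignSpec(n_participants=30, seed=1))
        table, _ = gs.simulate_ratings(design, seed=2)
        grid = gs.conditionwise_correlations(table)
        assert len(grid) == 9 * 4  # 3x3 cells, 2 ratings x 2 PLVs
        assert (grid["n"] == 90).all()  # 30 participants x 3 patterns

    def test_shuffled_ratings_mostly_nonsignificant(self):
        design = gs.generate_design(gs.DesignSpec(n_participants=30, seed=3))
        table, _ = gs.simulate_ratings(design, seed=4)
        rng = np.random.default_rng(5)
        table = table.assign(
            urge=rng.permutation(table["urge"].to_numpy()),
            pleasure=rng.permutation(table["pleasure"].to_numpy()),
        )
        grid = gs.conditionwise_correlations(table)
        assert (grid["p"] > 0.05).sum() >= 30

    def test_empty_cell_flagged_not_dropped(self):
        design = gs.generate_design(gs.DesignSpec(n_participants=4, seed=6))
        table, _ = gs.simulate_ratings(design, seed=7)
        table.loc[
            (table.movement == "Static") & (table.syncopation == "High"), "plv1"
        ] = np.nan
        grid = gs.conditionwise_correlations(table)
        flagged = grid[(grid.movement == "Static") & (grid.syncopation == "High")]
        assert (~flagged[flagged.plv == "plv1"]["ok"]).all()
        assert len(grid) == 36


class TestCenterWithin:
    def test_within_sums_to_zero_per_participant(self, trial_table):
        out = gs.center_within(trial_table, "urge")
        sums = out.groupby("participant")["urge_within"].sum()
        assert np.all(np.abs(sums) < 1e-12)

    def test_between_constant_within_participant(self, trial_table):
        out = gs.center_within(trial_table, "urge")
        assert (out.groupby("participant")["urge_between"].nunique() == 1).all()

    def test_single_trial_participant_within_is_zero(self):
        table = pd.DataFrame({"participant": [1], "x": [3.5]})
        out = gs.center_within(table, "x")
        assert out["x_within"].iloc[0] == 0.0
        assert out["x_between"].iloc[0] == 3.5


def _lmm_data(sigma_b=1.0, seed=0, n_subj=30, n_trial=27):
    rng = np.random.default_rng(seed)
    part = np.repeat(np.arange(n_subj), n_trial)
    x1 = rng.normal(0, 1, part.size)
    x2 = rng.normal(0, 1, part.size)
    b = rng.normal(0, sigma_b, n_subj)
    y = 0.5 * x1 - 0.3 * x2 + b[part] + rng.normal(0, 1, part.size)
    return pd.DataFrame({"participant": part, "y": y, "x1": x1, "x2": x2})


class TestRandomIntercept:
    def test_matches_statsmodels_ml_fit(self):
        data = _lmm_data(seed=1)
        ours = gs.fit_random_intercept(data, "y", "x1 + x2")
        ref = smf.mixedlm("y ~ x1 + x2", data, groups=data["participant"]).fit(
            reml=False
        )
        assert np.allclose(ours.params.to_numpy(), ref.params[:3], atol=1e-4)
        assert ours.sigma_b == pytest.approx(np.sqrt(ref.cov_re.iloc[0, 0]), abs=1e-3)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-4)

    def test_zero_variance_hits_boundary_and_matches_ols(self):
        data = _lmm_data(sigma_b=0.0, seed=2)
        fit = gs.fit_random_intercept(data, "y", "x1 + x2")
        assert fit.at_boundary
        assert fit.sigma_b == pytest.approx(0.0, abs=1e-3)
        ols = smf.ols("y ~ x1 + x2", data).fit()
        assert np.all(
            np.abs(fit.params.to_numpy() - ols.params.to_numpy()) < 2 * ols.bse.to_numpy()
        )

    def test_duplicating_rows_keeps_estimates_shrinks_se(self):
        data = _lmm_data(seed=3)
        doubled = pd.concat([data, data], ignore_index=True)
        f1 = gs.fit_random_intercept(data, "y", "x1 + x2")
        f2 = gs.fit_random_intercept(doubled, "y", "x1 + x2")
        # beta moves only through the re-estimated variance ratio (GLS weights)
        assert np.allclose(f1.params.to_numpy(), f2.params.to_numpy(), atol=5e-3)
        # slope SEs shrink ~1/sqrt(2); the intercept SE is floored by the
        # between-participant variance, which extra trials cannot reduce
        assert (f2.se[["x1", "x2"]] < f1.se[["x1", "x2"]]).all()
        assert f2.se["Intercept"] < f1.se["Intercept"] * 1.05

    def test_interaction_formula_with_condition(self, trial_table):
        data = gs.center_within(trial_table, "urge")
        fit = gs.fit_random_intercept(data, "plv2", "urge_within * C(movement)")
        assert fit.converged
        assert "urge_within" in fit.params.index
        assert fit.sigma > 0

    def test_too_few_participants_rejected(self):
        data = _lmm_data(seed=4).query("participant == 0")
        with pytest.raises(ValueError, match="participants"):
            gs.fit_random_intercept(data, "y", "x1")

    def test_likelihood_dominates_boundary_model(self):
        data = _lmm_data(sigma_b=1.0, seed=5)
        fit = gs.fit_random_intercept(data, "y", "x1 + x2")
        ols = smf.ols("y ~ x1 + x2", data).fit()
        assert fit.loglik >= ols.llf  # nested-model dominance
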