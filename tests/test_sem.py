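"""Path-analysis engine: parsing, implied covariance, ML fitting, multi-group."""

import numpy as np
import pandas as pd
import pytest

import groovesync as gs
import groovesync.sem as sem


def _simulate_from_spec(paths, psi, phi_chol, n, seed, names=("y1", "y2"), xnames=("x1",)):
    """Independent simulation oracle: draw observations from the equations."""
    rng = np.random.default_rng(seed)
    nx = len(xnames)
    x = rng.standard_normal((n, nx)) @ phi_chol.T
    ny = len(names)
    zeta = rng.standard_normal((n, ny)) * np.sqrt(psi)
    y = np.zeros((n, ny))
    b, g = paths
    for _ in range(ny):  # fixed-point iteration works for recursive systems
        y = y @ b.T + x @ g.T + zeta
    cols = {nm: y[:, i] for i, nm in enumerate(names)}
    cols.update({nm: x[:, j] for j, nm in enumerate(xnames)})
    return pd.DataFrame(cols)


class TestParsing:
    def test_roundtrip_variables_and_labels(self):
        spec = sem.parse_model(
            """
            y1 <- x1 @slope
            y2 <- y1
            y1 ~~ y2
            """
        )
        assert spec.endogenous == ("y1", "y2")
        assert spec.exogenous == ("x1",)
        labels = spec.free_labels()
        assert "slope" in labels and "y2<-y1" in labels and "y1~~y2" in labels
        assert "x1~~x1" in labels  # exogenous variance auto-freed

    def test_malformed_lines_rejected(self):
        with pytest.raises(ValueError, match="unrecognized"):
            sem.parse_model("y1 ~ x1")
        with pytest.raises(ValueError, match="self-loop"):
            sem.parse_model("y1 <- y1")
        with pytest.raises(ValueError, match="no regression paths"):
            sem.parse_model("# only a comment")

    def test_duplicate_parameter_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            sem.parse_model("y1 <- x1\ny1 <- x1")

    def test_embodied_fixture_topology(self):
        spec = sem.embodied_model_spec()
        assert spec.endogenous == ("pleasure", "urge", "plv1", "plv2")
        assert spec.exogenous == ("sync_mid", "sync_high")
        cyclic = sem.embodied_model_spec(feedback=True)
        assert "urge<-plv1" in cyclic.free_labels()


class TestImpliedCovariance:
    def test_no_structure_is_block_diagonal(self):
        spec = sem.parse_model("y1 <- x1\ny2 <- x1")
        theta = {
            "y1<-x1": 0.0,
            "y2<-x1": 0.0,
            "y1~~y1": 2.0,
            "y2~~y2": 3.0,
            "x1~~x1": 1.5,
        }
        sigma = sem.implied_covariance(spec, theta)
        assert np.allclose(sigma, np.diag([2.0, 3.0, 1.5]))

    def test_single_path_hand_algebra(self):
        # y1 = b*y2: Var(y1) = b^2 psi22 + psi11, Cov = b psi22
        spec = sem.parse_model("y1 <- y2\ny2 <- x1")
        theta = {
            "y1<-y2": 0.7,
            "y2<-x1": 0.0,
            "y1~~y1": 1.0,
            "y2~~y2": 2.0,
            "x1~~x1": 1.0,
        }
        sigma = sem.implied_covariance(spec, theta)
        assert sigma.loc["y1", "y1"] == pytest.approx(0.7**2 * 2.0 + 1.0)
        assert sigma.loc["y1", "y2"] == pytest.approx(0.7 * 2.0)

    def test_matches_simulation_oracle(self):
        b = np.array([[0.0, 0.0], [0.6, 0.0]])
        g = np.array([[0.8], [0.2]])
        psi = np.array([1.0, 0.5])
        data = _simulate_from_spec((b, g), psi, np.array([[1.2]]), 400_000, seed=0)
        spec = sem.parse_model("y1 <- x1\ny2 <- y1 + x1")
        theta = {
            "y1<-x1": 0.8,
            "y2<-y1": 0.6,
            "y2<-x1": 0.2,
            "y1~~y1": 1.0,
            "y2~~y2": 0.5,
            "x1~~x1": 1.2**2,
        }
        implied = sem.implied_covariance(spec, theta).to_numpy()
        empirical_frame = data[["y1", "y2", "x1"]]
        empirical = np.cov(empirical_frame.to_numpy(), rowvar=False)
        assert np.allclose(implied, empirical, atol=0.02)

    def test_singular_system_rejected(self):
        spec = sem.parse_model("y1 <- y2\ny2 <- y1\ny1 <- x1")
        theta = {
            "y1<-y2": 2.0, "y2<-y1": 0.5, "y1<-x1": 0.3,
            "y1~~y1": 1.0, "y2~~y2": 1.0, "x1~~x1": 1.0,
        }
        with pytest.raises(np.linalg.LinAlgError):
            sem.implied_covariance(spec, theta)


class TestFitML:
    def test_saturated_model_zero_statistic(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 300)
        data = pd.DataFrame({"y": 0.5 * x + rng.normal(0, 1, 300), "x": x})
        fit = sem.fit_ml(sem.parse_model("y <- x"), data=data)
        assert fit.df == 0
        assert fit.chi2 == pytest.approx(0.0, abs=1e-8)
        assert fit.cfi == 1.0 and fit.rmsea == 0.0 and fit.srmr < 1e-6

    def test_single_regression_equals_ols(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 2, 500)
        y = 0.7 * x + rng.normal(0, 1, 500)
        data = pd.DataFrame({"y": y, "x": x})
        fit = sem.fit_ml(sem.parse_model("y <- x"), data=data)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert fit.estimate("y<-x") == pytest.approx(slope, abs=1e-6)

    def test_reordering_paths_leaves_discrepancy_invariant(self, trial_table):
        lines = [l for l in sem.EMBODIED_MODEL.strip().splitlines()]
        spec_a = sem.parse_model("\n".join(lines))
        spec_b = sem.parse_model("\n".join(lines[::-1]))
        fa = sem.fit_ml(spec_a, data=trial_table, compute_se=False)
        fb = sem.fit_ml(spec_b, data=trial_table, compute_se=False)
        assert fa.f_ml == pytest.approx(fb.f_ml, abs=1e-8)

    def test_standardized_solution_scale_invariant(self, trial_table):
        spec = sem.embodied_model_spec()
        fit = sem.fit_ml(spec, data=trial_table, compute_se=False)
        rescaled = trial_table.assign(plv2=trial_table["plv2"] * 100.0)
        fit2 = sem.fit_ml(spec, data=rescaled, compute_se=False)
        assert fit.standardized("plv2<-urge") == pytest.approx(
            fit2.standardized("plv2<-urge"), abs=1e-6
        )
        assert fit.estimate("plv2<-urge") != pytest.approx(
            fit2.estimate("plv2<-urge"), rel=0.5
        )

    def test_recovery_within_three_standard_errors(self, iid_dgp):
        design = gs.generate_design(gs.DesignSpec(n_participants=190, seed=21))
        table, _ = gs.simulate_ratings(design, iid_dgp, seed=22)  # n = 5130 trials
        fit = sem.fit_ml(sem.embodied_model_spec(), data=table)
        truth = {
            "pleasure<-sync_mid": 0.8,
            "pleasure<-sync_high": -1.0,
            "urge<-sync_mid": 0.6,
            "urge<-sync_high": -0.9,
            "urge<-pleasure": 0.55,
            "plv1<-urge": 0.015,
            "plv2<-urge": 0.035,
        }
        params = fit.params.set_index("label")
        for label, value in truth.items():
            row = params.loc[label]
            assert abs(row["est"] - value) < 3 * row["se"], label
        assert sem.classify_fit(fit) == "good"

    def test_bias_shrinks_with_sample_size(self, iid_dgp):
        errors = {}
        for n_participants, n_reps in ((19, 12), (190, 12)):
            errs = []
            for rep in range(n_reps):
                design = gs.generate_design(
                    gs.DesignSpec(n_participants=n_participants, seed=300 + rep)
                )
                table, _ = gs.simulate_ratings(design, iid_dgp, seed=400 + rep)
                fit = sem.fit_ml(
                    sem.embodied_model_spec(), data=table, compute_se=False
                )
                errs.append(abs(fit.estimate("urge<-pleasure") - 0.55))
            errors[n_participants] = np.mean(errs)
        assert errors[190] < errors[19]

    def test_observed_information_matches_bootstrap(self, iid_dgp):
        design = gs.generate_design(gs.DesignSpec(n_participants=80, seed=31))
        table, _ = gs.simulate_ratings(design, iid_dgp, seed=32)
        spec = sem.embodied_model_spec()
        fit = sem.fit_ml(spec, data=table)
        rng = np.random.default_rng(33)
        boot = []
        for _ in range(200):
            sample = table.sample(frac=1.0, replace=True, random_state=rng.integers(2**31))
            bfit = sem.fit_ml(spec, data=sample, compute_se=False)
            boot.append(bfit.estimate("urge<-pleasure"))
        analytic = float(fit.params.set_index("label").loc["urge<-pleasure", "se"])
        assert abs(analytic - np.std(boot, ddof=1)) / np.std(boot, ddof=1) < 0.15

    def test_unidentified_cycle_rejected(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(rng.normal(size=(200, 2)), columns=["a", "b"])
        with pytest.raises(sem.IdentificationError):
            sem.fit_ml(sem.parse_model("a <- b\nb <- a"), data=data)

    def test_feedback_spec_estimable_with_instruments(self, iid_dgp):
        dgp = gs.default_rating_dgp(feedback=True)
        dgp = gs.RatingDGP(
            intercepts=dgp.intercepts, paths=dgp.paths,
            random_intercept_sd={k: 0.0 for k in dgp.random_intercept_sd},
            residual_sd=dgp.residual_sd,
        )
        design = gs.generate_design(gs.DesignSpec(n_participants=150, seed=41))
        table, _ = gs.simulate_ratings(design, dgp, seed=42)
        fit = sem.fit_ml(sem.embodied_model_spec(feedback=True), data=table,
                         compute_se=False)
        assert fit.converged
        assert fit.f_ml >= 0


class TestClassifyFit:
    @pytest.mark.parametrize(
        "indices,expected",
        [
            # published per-condition indices of the restricted-movement model
            ({"cfi": 0.99, "tli": 0.94, "rmsea": 0.074, "srmr": 0.032}, "acceptable"),
            ({"cfi": 1.0, "tli": 1.0, "rmsea": 0.0, "srmr": 0.0}, "good"),
            ({"cfi": 0.80, "tli": 0.80, "rmsea": 0.15, "srmr": 0.2}, "poor"),
        ],
    )
    def test_threshold_rules(self, indices, expected):
        assert sem.classify_fit(indices) == expected


class TestMultiGroup:
    def test_single_group_rejected(self, trial_table):
        with pytest.raises(ValueError, match="two groups"):
            sem.fit_multigroup(sem.embodied_model_spec(), {"only": trial_table})

    def test_constraint_accounting(self, iid_dgp):
        spec = sem.embodied_model_spec()
        groups = {}
        for g in range(2):
            design = gs.generate_design(gs.DesignSpec(n_participants=12, seed=50 + g))
            groups[f"g{g}"], _ = gs.simulate_ratings(design, iid_dgp, seed=60 + g)
        free = sem.fit_multigroup(spec, groups, ())
        con = sem.fit_multigroup(spec, groups, "paths")
        d_chi2, d_df, p = sem.chi_square_difference(con, free)
        assert d_df == len(spec.path_labels())  # one df per constraint, 2 groups
        assert d_chi2 >= -1e-6  # nested-model dominance

    def test_releasing_constraint_never_worsens_fit(self, iid_dgp):
        spec = sem.embodied_model_spec()
        groups = {}
        for g in range(2):
            design = gs.generate_design(gs.DesignSpec(n_participants=12, seed=70 + g))
            groups[f"g{g}"], _ = gs.simulate_ratings(design, iid_dgp, seed=80 + g)
        all_paths = spec.path_labels()
        full = sem.fit_multigroup(spec, groups, all_paths)
        for drop in all_paths[:3]:
            sub = sem.fit_multigroup(
                spec, groups, tuple(l for l in all_paths if l != drop)
            )
            assert sub.chi2 <= full.chi2 + 1e-6

    def test_stepwise_release_finds_the_differing_path(self, iid_dgp):
        spec = sem.embodied_model_spec()
        base = iid_dgp
        altered = gs.RatingDGP(
            intercepts=base.intercepts,
            paths={**base.paths, ("urge", "plv1"): 0.06},  # only this path differs
            random_intercept_sd=base.random_intercept_sd,
            residual_sd=base.residual_sd,
        )
        hits = 0
        for rep in range(3):
            groups = {}
            for name, dgp in (("a", base), ("b", altered)):
                design = gs.generate_design(
                    gs.DesignSpec(n_participants=40, seed=90 + rep)
                )
                groups[name], _ = gs.simulate_ratings(
                    design, dgp, seed=100 + rep * 2 + (name == "b")
                )
            result = sem.release_stepwise(spec, groups, max_release=1)
            if result.released and result.released[0] == "plv1<-urge":
                hits += 1
        assert hits >= 2
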