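"""Inference checks: LMM vs statsmodels, contrasts, influence, simple tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gridtrack import calibration, models

SPEC = models.ModelSpec(outcome="delta_min_dist_m", predictor="pc1_vocal",
                        grouping="focal")


def _table(seed, n=13, beta_int=13.5):
    rng = np.random.default_rng(seed)
    return calibration.simulate_model_table(n, beta_int, rng)


class TestRandomInterceptFit:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_statsmodels_mixedlm(self, seed):
        """Dual-route check: profiled-ML fitter vs statsmodels MixedLM (ML).

        When statsmodels stalls before its optimum (boundary fits), the
        profiled fitter must do at least as well in log-likelihood while
        agreeing on the GLS coefficients.
        """
        import warnings

        import statsmodels.formula.api as smf

        tab = _table(seed)
        fit = models.fit_sex_interaction(tab, SPEC)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm = smf.mixedlm(
                "delta_min_dist_m ~ pc1_vocal * C(conspecific_sex, Treatment('F'))",
                tab, groups=tab["focal"],
            ).fit(reml=False)
        interaction = "pc1_vocal:C(conspecific_sex, Treatment('F'))[T.M]"
        sm_params = dict(zip(sm.params.index, sm.params))
        if sm.converged:
            assert fit.full.loglik == pytest.approx(sm.llf, abs=1e-4)
            assert fit.full.beta[0] == pytest.approx(sm_params["Intercept"], abs=1e-4)
            assert fit.estimate == pytest.approx(sm_params[interaction], abs=1e-4)
            assert fit.se == pytest.approx(sm.bse[interaction], abs=1e-3)
        else:
            assert fit.full.loglik >= sm.llf - 1e-6
            assert fit.estimate == pytest.approx(sm_params[interaction], rel=1e-3)

    @pytest.mark.parametrize("seed", range(8))
    def test_full_model_never_fits_worse(self, seed):
        """Nesting: ML loglik of the full model >= reduced model."""
        tab = _table(seed, beta_int=0.0)
        fit = models.fit_sex_interaction(tab, SPEC)
        assert fit.full.loglik >= fit.reduced.loglik - 1e-8
        assert fit.lrt_chi2 >= 0.0

    def test_reduced_vs_itself_gives_zero(self):
        tab = _table(4)
        fit = models.fit_sex_interaction(tab, SPEC)
        assert 2 * (fit.reduced.loglik - fit.reduced.loglik) == 0.0

    def test_invariant_to_subject_relabeling_and_row_order(self):
        tab = _table(5)
        fit = models.fit_sex_interaction(tab, SPEC)
        relabeled = tab.copy()
        relabeled["focal"] = relabeled["focal"].map(lambda i: f"bird_{i * 7 + 3}")
        shuffled = relabeled.sample(frac=1.0, random_state=0).reset_index(drop=True)
        fit2 = models.fit_sex_interaction(shuffled, SPEC)
        assert fit2.estimate == pytest.approx(fit.estimate, abs=1e-9)
        assert fit2.lrt_chi2 == pytest.approx(fit.lrt_chi2, abs=1e-8)

    def test_singular_fit_flagged_not_fatal(self):
        # group means all identical -> boundary solution sigma_b^2 = 0
        rng = np.random.default_rng(6)
        a = rng.normal(0, 5, 13)
        tab = pd.concat([
            pd.DataFrame({"focal": range(13), "conspecific_sex": "F",
                          "pc1_vocal": 0.0, "delta_min_dist_m": a}),
            pd.DataFrame({"focal": range(13), "conspecific_sex": "M",
                          "pc1_vocal": 0.0, "delta_min_dist_m": -a}),
        ], ignore_index=True)
        tab["pc1_vocal"] = np.tile(rng.normal(size=13), 2)
        fit = models.fit_sex_interaction(tab, SPEC)
        assert fit.full.singular
        assert fit.full.sigma2_b == 0.0

    def test_too_few_subjects_rejected(self):
        tab = _table(7, n=4)
        with pytest.raises(ValueError, match=">= 5 subjects"):
            models.fit_sex_interaction(tab, SPEC)

    def test_duplicate_sex_rows_rejected(self):
        tab = _table(8)
        dup = pd.concat([tab, tab.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="at most one row"):
            models.fit_sex_interaction(dup, SPEC)


class TestPosthoc:
    def test_contrast_algebra_identity(self):
        """male slope = female slope + interaction, on any fit."""
        tab = _table(9, beta_int=20.0)
        fit = models.fit_sex_interaction(tab, SPEC)
        ph = models.posthoc_by_sex(fit, gate_p=None)
        assert ph.female_estimate == pytest.approx(fit.full.beta[1], abs=1e-12)
        assert ph.male_estimate == pytest.approx(
            fit.full.beta[1] + fit.full.beta[3], abs=1e-12
        )

    def test_symmetric_sexes_give_identical_slopes(self):
        rng = np.random.default_rng(10)
        v = rng.normal(size=10)
        y = 2.0 * v + rng.normal(0, 0.5, 10)
        tab = pd.concat([
            pd.DataFrame({"focal": range(10), "conspecific_sex": "F",
                          "pc1_vocal": v, "delta_min_dist_m": y}),
            pd.DataFrame({"focal": range(10), "conspecific_sex": "M",
                          "pc1_vocal": v, "delta_min_dist_m": y}),
        ], ignore_index=True)
        fit = models.fit_sex_interaction(tab, SPEC)
        ph = models.posthoc_by_sex(fit, gate_p=None)
        assert ph.female_estimate == pytest.approx(ph.male_estimate, abs=1e-8)

    def test_gate_blocks_nonsignificant_interaction(self):
        tab = _table(11, beta_int=0.0)
        fit = models.fit_sex_interaction(tab, SPEC)
        if fit.lrt_p >= 0.05:
            with pytest.raises(ValueError, match="post hoc"):
                models.posthoc_by_sex(fit, gate_p=0.05)

    def test_sex_specific_power_asymmetry(self):
        """Female-only effect: female contrast powered, male near nominal."""
        rng = np.random.default_rng(12)
        n_rej_f = n_rej_m = 0
        reps = 150
        for _ in range(reps):
            tab = calibration.simulate_model_table(
                20, beta_interaction=6.0, rng=rng, beta_pred=-6.0,
                sigma_e=5.0, sigma_b=3.0,
            )  # female slope -6 (|beta|/sigma = 1.2), male slope 0
            fit = models.fit_sex_interaction(tab, SPEC)
            ph = models.posthoc_by_sex(fit, gate_p=None)
            n_rej_f += ph.female_p < 0.05
            n_rej_m += ph.male_p < 0.05
        assert n_rej_f / reps >= 0.8
        assert n_rej_m / reps <= 0.1


class TestInfluence:
    def test_noiseless_linear_data_has_no_flags(self):
        rng = np.random.default_rng(13)
        tab = calibration.simulate_model_table(13, 13.5, rng, sigma_e=1e-6,
                                               sigma_b=0.0)
        fit = models.fit_sex_interaction(tab, SPEC)
        flags = models.influence_check(fit.full)
        assert not flags["flagged"].any()

    def test_planted_outlier_subject_flagged(self):
        rng = np.random.default_rng(14)
        tab = calibration.simulate_model_table(13, 13.5, rng, sigma_e=2.0,
                                               sigma_b=1.0)
        # a single aberrant observation (one row, not the whole subject):
        # a whole-subject shift would be absorbed by its random intercept
        bad = (tab["focal"] == 5) & (tab["conspecific_sex"] == "M")
        tab.loc[bad, "delta_min_dist_m"] += 60.0  # ~30 sigma
        fit = models.fit_sex_interaction(tab, SPEC)
        flags = models.influence_check(fit.full)
        flagged_groups = set(flags.loc[flags["flagged"], "group"])
        focal_codes = dict(zip(pd.factorize(tab["focal"])[1],
                               range(tab["focal"].nunique())))
        assert flagged_groups == {focal_codes[5]}

    def test_flag_requires_both_conditions(self):
        rng = np.random.default_rng(15)
        tab = calibration.simulate_model_table(13, 0.0, rng)
        fit = models.fit_sex_interaction(tab, SPEC)
        flags = models.influence_check(fit.full)
        assert (np.abs(flags.loc[flags["flagged"], "std_residual"]) > 2).all()
        assert (flags.loc[flags["flagged"], "cooks_d_group"] > 4 / 13).all()


class TestRankTransform:
    def test_simple_ranks(self):
        assert models.rank_transform([5, 1, 3]).tolist() == [3.0, 1.0, 2.0]

    def test_ties_get_average_rank(self):
        assert models.rank_transform([2, 2, 7]).tolist() == [1.5, 1.5, 3.0]

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=40)
        assert np.array_equal(models.rank_transform(x),
                              models.rank_transform(np.exp(3 * x + 1)))

    def test_nan_passthrough(self):
        out = models.rank_transform([3.0, np.nan, 1.0])
        assert np.isnan(out[1]) and out[0] == 2.0 and out[2] == 1.0


class TestUnivariate:
    def test_welch_matches_hand_computation(self):
        x = np.array([4.1, 5.2, 6.0, 5.5, 4.8])
        y = np.array([6.9, 7.4, 8.1, 7.7, 6.5, 7.0])
        res = models.welch_t(x, y)
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
        assert res["t"] == pytest.approx(t, abs=1e-8)
        assert res["df"] == pytest.approx(df, abs=1e-8)
        assert res["p"] == pytest.approx(2 * stats.t.sf(abs(t), df), abs=1e-8)

    def test_welch_identical_groups_is_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert models.welch_t(x, x)["t"] == 0.0

    def test_welch_small_groups_rejected(self):
        with pytest.raises(ValueError):
            models.welch_t([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_wilcoxon_antisymmetric_differences_give_zero(self):
        pre = np.zeros(8)
        post = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0, 4.0, -4.0])
        res = models.paired_wilcoxon(pre, post)
        assert res["z"] == pytest.approx(0.0, abs=1e-10)

    def test_wilcoxon_identical_pairs_warns(self):
        with pytest.warns(UserWarning, match="zero"):
            res = models.paired_wilcoxon(np.arange(5.0), np.arange(5.0))
        assert res["z"] == 0.0

    def test_report_structure(self):
        from gridtrack import world, scoring

        tab = world.simulate_response_table(60, seed=17)
        scored, _ = scoring.score_subjects(tab)
        report = models.univariate_tests(scored)
        assert "pc1_vocal" in report["age"]
        assert "pc1_vocal" in report["condition"]
        # generator: older, better-condition males respond more strongly
        assert report["condition"]["pc1_vocal"]["r"] > 0.3
        assert report["age"]["pc1_vocal"]["t"] < 0  # 2cy minus older
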