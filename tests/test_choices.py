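"""GEE choice analysis: design building, estimation, inference."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from flymosaic.choices import (
    build_design,
    conditioning_contrast,
    emmeans,
    first_choice_chisq,
    fit_choice_model,
    gee_fit,
    wald_test,
)
from flymosaic.errors import InputError
from flymosaic.synth import ChoiceSimParams, gen_choices, gen_conditioning_choices


def trials_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["fly_id", "fly_species", "genus_pair", "phase", "choice_order",
                 "flower_color", "soil"],
    )


def simple_trials():
    rows = []
    for fly, species, colors, soils in [
        ("f1", "M_capensis", "ooowo", "rrppr"),
        ("f2", "M_capensis", "oooo", "rppr"),
        ("f3", "C_nigripes", "wwoww", "prrpp"),
        ("f4", "C_nigripes", "www", "rpr"),
    ]:
        for i, (c, s) in enumerate(zip(colors, soils), start=1):
            rows.append(
                (fly, species, "Ursinia", "pre", i,
                 "orange" if c == "o" else "white",
                 "red" if s == "r" else "pale")
            )
    return trials_frame(rows)


class TestBuildDesign:
    def test_long_format_expansion(self):
        d = build_design(simple_trials(), terms=("species",))
        assert d.y.size == 17
        assert (d.cluster == d.cluster[0]).sum() == 5  # f1 has 5 choices

    def test_response_coding(self):
        d = build_design(simple_trials(), terms=("species",))
        assert set(np.unique(d.y)) <= {0.0, 1.0}
        # f2 chose orange four times
        f2 = d.y[d.cluster == 1]
        assert np.all(f2 == 1.0)

    def test_reference_levels_documented(self):
        d = build_design(simple_trials())
        assert d.factors["species"][0] == "C_nigripes"
        assert d.factors["soil"][0] == "pale"
        assert "species[M_capensis]" in d.colnames

    def test_single_soil_fly_excluded(self, caplog):
        rows = simple_trials()
        extra = trials_frame(
            [("f9", "M_capensis", "Ursinia", "pre", 1, "orange", "red"),
             ("f9", "M_capensis", "Ursinia", "pre", 2, "orange", "red")]
        )
        with caplog.at_level("WARNING"):
            d = build_design(pd.concat([rows, extra], ignore_index=True))
        assert d.excluded_flies == ["f9"]
        assert d.y.size == 17

    def test_exclusion_can_be_disabled(self):
        extra = trials_frame(
            [("f9", "M_capensis", "Ursinia", "pre", 1, "orange", "red")]
        )
        d = build_design(pd.concat([simple_trials(), extra], ignore_index=True),
                         require_both_soils=False)
        assert d.excluded_flies == [] and d.y.size == 18

    def test_unknown_level_rejected(self):
        bad = simple_trials()
        bad.loc[0, "fly_species"] = "X_unknownus"
        with pytest.raises(InputError, match="unknown"):
            build_design(bad)

    def test_single_cluster_rejected(self):
        one = simple_trials().query("fly_id == 'f1'")
        with pytest.raises(InputError, match="clusters"):
            build_design(one, terms=("soil",))


class TestGeeFit:
    def test_collapses_to_glm_with_unit_clusters(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        n = 300
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        y = (rng.random(n) < expit(0.4 + 0.9 * x)).astype(float)
        fit = gee_fit(y, X, np.arange(n))
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.coef, ref.params, atol=1e-8)

    def test_intercept_only_emm_is_raw_proportion(self):
        # equal cluster sizes: marginal mean equals the pooled proportion
        y = np.array([1, 1, 0, 1, 0, 1, 1, 0], dtype=float)
        X = np.ones((8, 1))
        cluster = np.repeat([0, 1, 2, 3], 2)
        fit = gee_fit(y, X, cluster)
        assert expit(fit.coef[0]) == pytest.approx(y.mean(), abs=1e-9)

    def test_matches_statsmodels_gee(self):
        sm = pytest.importorskip("statsmodels.api")
        d = build_design(gen_choices(ChoiceSimParams(seed=11)))
        fit = gee_fit(d.y, d.X, d.cluster)
        ref = sm.GEE(
            d.y, d.X, groups=d.cluster, family=sm.families.Binomial(),
            cov_struct=sm.cov_struct.Exchangeable(),
        ).fit()
        # same marginal model; alpha moment estimators differ slightly
        np.testing.assert_allclose(fit.coef, ref.params, atol=0.05)

    def test_alpha_near_beta_mixing_value(self):
        params = ChoiceSimParams(
            n_flies={"M_capensis": 200, "C_nigripes": 200},
            median_choices=8, seed=5,
        )
        d = build_design(gen_choices(params), terms=("species",),
                         require_both_soils=False)
        fit = gee_fit(d.y, d.X, d.cluster)
        assert fit.alpha == pytest.approx(params.exchangeable_alpha, abs=0.03)

    def test_jackknife_cov_is_symmetric_psd(self):
        d = build_design(gen_choices(ChoiceSimParams(seed=2)))
        fit = gee_fit(d.y, d.X, d.cluster)
        np.testing.assert_allclose(fit.cov, fit.cov.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(fit.cov) > -1e-12)

    def test_one_step_jackknife_close_to_full_refit(self):
        d = build_design(gen_choices(ChoiceSimParams(
            n_flies={"M_capensis": 25, "C_nigripes": 25}, seed=9)),
            terms=("species",), require_both_soils=False)
        one = gee_fit(d.y, d.X, d.cluster, jackknife="one-step")
        full = gee_fit(d.y, d.X, d.cluster, jackknife="full")
        np.testing.assert_allclose(
            np.sqrt(np.diag(one.cov)), np.sqrt(np.diag(full.cov)), rtol=0.25
        )


class TestInference:
    def test_wald_equals_squared_z_for_1df_term(self):
        fit = fit_choice_model(gen_choices(ChoiceSimParams(seed=3)))
        stat, df, p = wald_test(fit, "soil")
        j = fit.terms["soil"][0]
        assert df == 1
        assert stat == pytest.approx((fit.coef[j] / fit.se()[j]) ** 2)

    def test_wald_invariant_to_covariate_rescaling(self):
        # rescaling a continuous covariate leaves its Wald statistic unchanged
        rng = np.random.default_rng(4)
        n, k = 200, 50
        cluster = np.repeat(np.arange(k), n // k)
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(0.2 + 0.5 * x)).astype(float)
        X1 = np.column_stack([np.ones(n), x])
        X2 = np.column_stack([np.ones(n), 10 * x])
        f1 = gee_fit(y, X1, cluster, terms={"x": [1]})
        f2 = gee_fit(y, X2, cluster, terms={"x": [1]})
        s1, _, _ = wald_test(f1, "x")
        s2, _, _ = wald_test(f2, "x")
        assert s1 == pytest.approx(s2, rel=1e-6)

    def test_emm_reference_level_is_inverse_logit_intercept(self):
        fit = fit_choice_model(gen_choices(ChoiceSimParams(seed=3)),
                               terms=("species", "soil"))
        emm, _ = emmeans(fit, {"species": "C_nigripes", "soil": "pale"})
        assert emm == pytest.approx(expit(fit.coef[0]))

    def test_emm_ci_inside_unit_interval_and_contains_emm(self):
        fit = fit_choice_model(gen_choices(ChoiceSimParams(seed=3)))
        for sp in ("C_nigripes", "M_capensis"):
            emm, (lo, hi) = emmeans(fit, {"species": sp})
            assert 0 < lo <= emm <= hi < 1

    def test_emm_extrapolated_combination_rejected(self):
        fit = fit_choice_model(gen_choices(ChoiceSimParams(seed=3)))
        with pytest.raises(InputError):
            emmeans(fit, {"species": "M_capensis", "phase": "post_1h"})

    def test_species_emms_recover_generating_preferences(self):
        fit = fit_choice_model(gen_choices(ChoiceSimParams(seed=8)))
        emm_m, _ = emmeans(fit, {"species": "M_capensis"})
        emm_c, _ = emmeans(fit, {"species": "C_nigripes"})
        assert emm_m == pytest.approx(0.91, abs=0.05)
        assert emm_c == pytest.approx(0.20, abs=0.08)


class TestFirstChoice:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(22, 22, 0.0), (30, 14, 256 / 44), (17, 0, 17.0)],
    )
    def test_closed_form(self, a, b, expected):
        stat, df, p = first_choice_chisq(a, b)
        assert stat == pytest.approx(expected)
        assert df == 1
        if a == b:
            assert p == pytest.approx(1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(InputError):
            first_choice_chisq(-1, 5)

    def test_empty_counts_rejected(self):
        with pytest.raises(InputError):
            first_choice_chisq(0, 0)


class TestConditioning:
    def test_identical_pre_post_gives_zero_phase_coefficient(self):
        pre = simple_trials()
        post = pre.copy()
        post["phase"] = "post_1h"
        both = pd.concat([pre, post], ignore_index=True)
        fit, (stat, df, p) = conditioning_contrast(both)
        j = fit.terms["phase"][0]
        assert fit.coef[j] == pytest.approx(0.0, abs=1e-8)
        # with duplicated data the jackknife variance of the phase effect is
        # also ~0, so the Wald ratio is not informative here; no effect means
        # the test must not reject
        assert p > 0.05

    def test_flipped_preference_detected(self):
        params = ChoiceSimParams(
            n_flies={"M_capensis": 40, "C_nigripes": 2},
            preference={"M_capensis": 0.9, "C_nigripes": 0.5},
            seed=21,
        )
        trials = gen_conditioning_choices(
            params, post_preference={"M_capensis": 0.1}
        )
        trials = trials[trials["fly_species"] == "M_capensis"]
        fit, (stat, df, p) = conditioning_contrast(trials)
        assert p < 0.01

    def test_single_phase_rejected(self):
        with pytest.raises(InputError):
            conditioning_contrast(simple_trials())
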