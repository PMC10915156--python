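import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from dyadlink import (
    GLMFit,
    MediationSpec,
    SimulationParams,
    decompose,
    delta_ci,
    mediate_pooled,
    mediate_single,
    proportion_mediated,
    score_dyad_table,
    simulate_dyads,
    true_log_effects,
)
from dyadlink import schema


def make_fits(
    beta1=0.5,
    theta1=0.4,
    theta2=0.6,
    theta3=None,
    var_beta1=0.0,
    var_theta1=0.0,
    var_theta2=0.0,
    cov_t1_t2=0.0,
    sigma2=1.0,
    beta0=0.0,
):
    """Hand-built mediator/outcome fits with controllable coefficients."""
    med_names = ["const", "a"]
    med = GLMFit(
        kind="linear",
        coef=pd.Series({"const": beta0, "a": beta1}),
        vcov=pd.DataFrame(
            [[1e-12, 0.0], [0.0, var_beta1]], index=med_names, columns=med_names
        ),
        n=100,
        sigma2=sigma2,
        x_means=pd.Series({"const": 1.0, "a": 0.5}),
    )
    out_names = ["const", "a", "m"]
    coefs = {"const": -1.0, "a": theta1, "m": theta2}
    v = np.diag([1e-12, var_theta1, var_theta2]).astype(float)
    v[1, 2] = v[2, 1] = cov_t1_t2
    if theta3 is not None:
        out_names = out_names + ["a:m"]
        coefs["a:m"] = theta3
        v = np.pad(v, ((0, 1), (0, 1)))
    out = GLMFit(
        kind="logistic",
        coef=pd.Series(coefs),
        vcov=pd.DataFrame(v, index=out_names, columns=out_names),
        n=100,
        x_means=pd.Series({k: 0.0 for k in out_names}),
    )
    return med, out


SPEC = MediationSpec(exposure="a", mediator="m", outcome="y")


class TestDecomposeClosedForms:
    def test_hand_evaluated_no_interaction(self):
        """beta1=0.5, theta2=0.6, theta1=0.4: NIE = e^0.30, NDE = e^0.40,
        TE = e^0.70."""
        med, out = make_fits()
        dec = decompose(med, out, SPEC)
        assert dec.nie.odds_ratio == pytest.approx(math.exp(0.30), rel=1e-12)
        assert dec.nde.odds_ratio == pytest.approx(math.exp(0.40), rel=1e-12)
        assert dec.te.odds_ratio == pytest.approx(math.exp(0.70), rel=1e-12)
        assert dec.nie.odds_ratio == pytest.approx(1.350, abs=5e-4)
        assert dec.nde.odds_ratio == pytest.approx(1.492, abs=5e-4)
        assert dec.te.odds_ratio == pytest.approx(2.014, abs=5e-4)

    def test_null_direct_path_gives_unit_nde(self):
        med, out = make_fits(theta1=0.0, beta1=0.9, theta2=1.2)
        dec = decompose(med, out, SPEC)
        assert dec.nde.odds_ratio == 1.0

    def test_zero_interaction_collapses_to_no_interaction(self):
        """theta3 = 0 through the interaction formulas reproduces the
        plain estimator exactly."""
        med, out = make_fits(theta3=0.0, beta0=0.3, var_beta1=0.02,
                             var_theta1=0.01, var_theta2=0.03)
        med2, out2 = make_fits(beta0=0.3, var_beta1=0.02, var_theta1=0.01,
                               var_theta2=0.03)
        with_int = decompose(med, out, replace(SPEC, interaction=True))
        without = decompose(med2, out2, SPEC)
        for a, b in ((with_int.nde, without.nde), (with_int.nie, without.nie),
                     (with_int.te, without.te)):
            assert a.odds_ratio == pytest.approx(b.odds_ratio, rel=1e-12)
            assert a.log_se == pytest.approx(b.log_se, rel=1e-9)

    def test_interaction_requested_but_absent_fails(self):
        med, out = make_fits()
        with pytest.raises(KeyError, match="a:m"):
            decompose(med, out, replace(SPEC, interaction=True))

    def test_interaction_needs_sigma2(self):
        med, out = make_fits(theta3=0.1)
        med.sigma2 = None
        with pytest.raises(ValueError, match="sigma2"):
            decompose(med, out, replace(SPEC, interaction=True))

    def test_interaction_formula_hand_value(self):
        # theta3=0.2, a*=0, a=1, c empty: kappa = beta0 + theta2*sigma2
        # log NDE = theta1 + 0.2*kappa + 0.5*0.04*sigma2
        med, out = make_fits(theta3=0.2, beta0=0.3, sigma2=2.0)
        dec = decompose(med, out, replace(SPEC, interaction=True))
        kappa = 0.3 + 0.6 * 2.0
        log_nde = 0.4 + 0.2 * kappa + 0.5 * 0.04 * 2.0
        log_nie = (0.6 + 0.2) * 0.5
        assert dec.nde.odds_ratio == pytest.approx(math.exp(log_nde), rel=1e-12)
        assert dec.nie.odds_ratio == pytest.approx(math.exp(log_nie), rel=1e-12)


class TestDeltaCI:
    def test_nde_closed_form(self):
        """Var(theta1)=0.01 -> SE(log NDE)=0.1, CI = exp(0.4 +- 0.196)."""
        med, out = make_fits(var_theta1=0.01)
        res = delta_ci(med, out, SPEC)
        assert res["log_nde"]["se"] == pytest.approx(0.1, rel=1e-9)
        z = 1.959963984540054
        assert res["log_nde"]["ci_lower"] == pytest.approx(
            math.exp(0.4 - z * 0.1), rel=1e-9
        )
        assert res["log_nde"]["ci_upper"] == pytest.approx(
            math.exp(0.4 + z * 0.1), rel=1e-9
        )

    def test_nie_closed_form(self):
        med, out = make_fits(var_beta1=0.04, var_theta2=0.09)
        res = delta_ci(med, out, SPEC)
        expected = math.sqrt(0.6**2 * 0.04 + 0.5**2 * 0.09)
        assert res["log_nie"]["se"] == pytest.approx(expected, rel=1e-9)

    def test_te_includes_cross_covariance(self):
        med, out = make_fits(
            var_beta1=0.04, var_theta1=0.01, var_theta2=0.09, cov_t1_t2=0.005
        )
        res = delta_ci(med, out, SPEC)
        expected = math.sqrt(
            0.01 + 0.6**2 * 0.04 + 0.5**2 * 0.09 + 2 * 0.005 * 0.5
        )
        assert res["log_te"]["se"] == pytest.approx(expected, rel=1e-9)

    def test_degenerate_paths_zero_variance(self):
        med, out = make_fits(beta1=0.0, theta2=0.0, var_beta1=0.1, var_theta2=0.1)
        res = delta_ci(med, out, SPEC)
        assert res["log_nie"]["se"] == 0.0
        assert res["log_nie"]["ci_lower"] == res["log_nie"]["ci_upper"] == 1.0


class TestProportionMediated:
    @pytest.mark.parametrize(
        "nde, nie, te, expected, tol",
        [
            (1.70, 1.04, 1.77, 0.09, 0.005),  # 0.0883 prints as 0.09
            (1.51, 1.23, 1.86, 0.404, 0.001),  # prints as 0.41
            (2.0, 1.0, 1.5, 0.0, 1e-12),
        ],
    )
    def test_values(self, nde, nie, te, expected, tol):
        assert proportion_mediated(nde, nie, te) == pytest.approx(expected, abs=tol)

    def test_null_total_effect_undefined(self):
        with pytest.raises(ZeroDivisionError):
            proportion_mediated(1.2, 0.8333, 1.0)

    def test_inconsistent_mediation_negative(self):
        assert proportion_mediated(1.5, 0.9, 1.3) < 0


class TestOnSimulatedData:
    def test_product_identity_machine_precision(self, complete_scored_table):
        """OR_TE = OR_NDE * OR_NIE exactly under the no-interaction
        estimator, on real fitted decompositions."""
        for med in ("depressive", "subj_ses"):
            spec = MediationSpec(
                exposure=schema.EXPOSURE_CLASS["parental"],
                mediator=med,
                outcome=schema.OUTCOME,
                covariates=tuple(schema.MEDIATION_COVARIATES),
            )
            dec = mediate_single(complete_scored_table, spec)
            assert dec.te.odds_ratio == pytest.approx(
                dec.nde.odds_ratio * dec.nie.odds_ratio, rel=1e-12
            )

    def test_monotone_in_theta2(self):
        """Raising the mediator-outcome coefficient raises OR_NIE."""
        nies = []
        for theta2 in (0.0, 0.3, 0.6, 1.2):
            med, out = make_fits(theta2=theta2)
            nies.append(decompose(med, out, SPEC).nie.odds_ratio)
        assert nies == sorted(nies) and nies[0] < nies[-1]

    def test_null_mediator_path_centers_on_one(self):
        """theta2 = 0 planted: the estimated OR_NIE is ~1 and its CI
        covers 1 at large n."""
        base = SimulationParams(
            n_pairs=20_000, seed=31, missing_rate=0.0,
            mother_available=1.0, father_available=1.0,
        )
        params = replace(
            base,
            outcome_coefs=replace(
                base.outcome_coefs, theta2={m: 0.0 for m in schema.MEDIATORS}
            ),
        )
        scored = score_dyad_table(simulate_dyads(params))
        spec = MediationSpec(
            exposure=schema.EXPOSURE_CLASS["parental"],
            mediator="depressive",
            outcome=schema.OUTCOME,
            covariates=tuple(schema.MEDIATION_COVARIATES),
        )
        dec = mediate_single(scored, spec)
        assert dec.nie.ci_lower <= 1.0 <= dec.nie.ci_upper
        assert abs(math.log(dec.nie.odds_ratio)) < 3 * dec.nie.log_se

    def test_pooled_identical_stack_equals_single(self, complete_scored_table):
        spec = MediationSpec(
            exposure=schema.EXPOSURE_CLASS["parental"],
            mediator="depressive",
            outcome=schema.OUTCOME,
            covariates=tuple(schema.MEDIATION_COVARIATES),
        )
        single = mediate_single(complete_scored_table, spec)
        pooled = mediate_pooled([complete_scored_table] * 5, spec)
        assert pooled.te.odds_ratio == pytest.approx(single.te.odds_ratio, rel=1e-10)
        assert pooled.nie.odds_ratio == pytest.approx(single.nie.odds_ratio, rel=1e-10)
        # identical datasets: no between-imputation variance, same SE
        assert pooled.nie.log_se == pytest.approx(single.nie.log_se, rel=1e-9)

    def test_pooled_recovers_planted_indirect_effect(self):
        """m=5 imputations on ~10% MAR data: pooled OR_NIE within 3
        pooled SEs of the planted e^(theta2 * beta1)."""
        from dyadlink import mice_impute

        base = SimulationParams(
            n_pairs=4000, seed=37, missing_rate=0.10, missing_mechanism="MAR",
            mother_available=1.0, father_available=1.0,
        )
        params = base.single_mediator("depressive")
        truth = true_log_effects(params, "depressive")
        scored = score_dyad_table(simulate_dyads(params))
        exposure = schema.EXPOSURE_CLASS["parental"]
        cols = [exposure, schema.OUTCOME] + schema.MEDIATORS + schema.CONFOUNDERS
        sub = scored[cols]
        stack = mice_impute(
            sub, m=5, seed=38, exclude=[exposure], outcome=schema.OUTCOME
        )
        spec = MediationSpec(
            exposure=exposure,
            mediator="depressive",
            outcome=schema.OUTCOME,
            covariates=tuple(schema.MEDIATION_COVARIATES),
        )
        dec = mediate_pooled(stack, spec)
        assert abs(math.log(dec.nie.odds_ratio) - truth["log_nie"]) < 3 * dec.nie.log_se
        assert abs(math.log(dec.nde.odds_ratio) - truth["log_nde"]) < 3 * dec.nde.log_se

    def test_complete_case_close_to_pooled_under_low_missingness(self):
        base = SimulationParams(
            n_pairs=4000, seed=41, missing_rate=0.03, missing_mechanism="MCAR",
            mother_available=1.0, father_available=1.0,
        ).single_mediator("depressive")
        scored = score_dyad_table(simulate_dyads(base))
        exposure = schema.EXPOSURE_CLASS["parental"]
        cols = [exposure, schema.OUTCOME] + schema.MEDIATORS + schema.CONFOUNDERS
        sub = scored[cols]
        spec = MediationSpec(
            exposure=exposure,
            mediator="depressive",
            outcome=schema.OUTCOME,
            covariates=tuple(schema.MEDIATION_COVARIATES),
        )
        cc = mediate_single(sub.dropna(), spec)
        from dyadlink import mice_impute

        stack = mice_impute(sub, m=5, seed=42, exclude=[exposure], outcome=schema.OUTCOME)
        pooled = mediate_pooled(stack, spec)
        # paired comparison: same generating data, low missingness
        diff = abs(math.log(cc.nie.odds_ratio) - math.log(pooled.nie.odds_ratio))
        assert diff < 2 * max(cc.nie.log_se, pooled.nie.log_se)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            MediationSpec(exposure="a", mediator="m", outcome="y", a=1.0, a_star=1.0)
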