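"""Gradient, KKT multipliers, balance equations, economy, control, adaptation."""

import numpy as np
import pytest

import gba
from gba.errors import InputError

from conftest import FIXTURE_NAMES, interior_points

SQRT2 = np.sqrt(2.0)
F_HALF = np.array([1.0, 0.5])  # reference non-optimal state of model A


def gradient_fd(model, f, h=1e-6):
    out = np.empty_like(f)
    for j in range(f.size):
        hp = h * (1 + abs(f[j]))
        fp, fm = f.copy(), f.copy()
        fp[j] += hp
        fm[j] -= hp
        out[j] = (gba.growth_rate(model, fp) - gba.growth_rate(model, fm)) / (2 * hp)
    return out


class TestGrowthGradient:
    def test_hand_value_at_reference_state(self, model_a):
        grad = gba.growth_gradient(model_a, F_HALF)
        assert grad[1] == pytest.approx(4 / 49, rel=1e-12)
        assert grad[0] == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("name", FIXTURE_NAMES)
    def test_matches_finite_differences(self, models, name):
        m = models[name]
        for f in interior_points(m, 20, seed=17):
            an = gba.growth_gradient(m, f)
            fd = gradient_fd(m, f)
            scale = np.max(np.abs(an))
            np.testing.assert_allclose(fd, an, rtol=1e-6, atol=1e-6 * scale)

    def test_ribosome_marginal_value_vanishes_at_optimum(self, model_a, optima):
        grad = gba.growth_gradient(model_a, optima["A"].f_star)
        assert abs(grad[1]) <= 1e-6 * optima["A"].mu_star


class TestKKTMultipliers:
    def test_lambda_hand_value(self, model_a):
        st_ = gba.ScaledState(model_a, F_HALF)
        assert st_.fEf == pytest.approx(-1.0, rel=1e-14)
        lam, _ = gba.kkt_multipliers(model_a, F_HALF)
        assert lam == pytest.approx(-2 / 49, rel=1e-12)

    def test_ribosome_shadow_price_zero_at_optimum(self, optima, models):
        for name, r in optima.items():
            m = models[name]
            theta_r = r.theta[m.r_index]
            scale = max(np.max(np.abs(r.theta)), r.mu_star**2)
            assert abs(theta_r) <= 1e-8 * scale

    def test_lambda_closed_form_at_model_a_optimum(self, model_a, optima):
        r = optima["A"]
        b_a = 2 - SQRT2
        expect = -SQRT2 * r.mu_star**2 / b_a
        assert r.lambda_ == pytest.approx(expect, rel=1e-8)

    def test_dual_feasibility_of_inactive_reactions(self, optima):
        # maximization with f*tau >= 0 requires theta >= 0 at optima
        for r in optima.values():
            scale = max(np.max(np.abs(r.theta)), r.mu_star**2)
            assert np.all(r.theta >= -1e-6 * scale)

    def test_two_lambda_routes_agree_at_optima(self, models, optima):
        for name, r in optima.items():
            m = models[name]
            lam_grad = gba.lambda_from_gradient(m, r.f_star)
            lam_s = gba.lambda_from_transporters(m, r.f_star)
            assert lam_grad == pytest.approx(r.lambda_, rel=1e-8)
            assert lam_s == pytest.approx(r.lambda_, rel=1e-6)


class TestBalanceResiduals:
    def test_nonoptimal_reference_state(self, model_a):
        br = gba.balance_residuals(model_a, F_HALF)
        # gamma_r = 0, so the ribosome residual is just d_r mu * f_r = 2/49
        assert br.scaled[1] == pytest.approx(2 / 49, rel=1e-12)

    def test_vanish_at_optima(self, models, optima):
        for name, r in optima.items():
            br = gba.balance_residuals(models[name], r.f_star)
            assert np.max(np.abs(br.scaled)) < 1e-8 * r.mu_star
            assert np.max(np.abs(br.by_kind)) < 1e-6

    def test_active_enzyme_condition_at_b_optimum(self, model_b, optima):
        br = gba.balance_residuals(model_b, optima["B"].f_star)
        st_ = gba.ScaledState(model_b, optima["B"].f_star)
        tau_e = st_.tau[model_b.reaction_index["e"]]
        assert abs(br.active_enzyme["e"]) < 1e-6 * tau_e

    def test_unscaled_residual_is_positive_multiple_of_scaled(self, models):
        # both vanish together; ratio = rho * b_a > 0 for active reactions
        for name, m in models.items():
            f = interior_points(m, 1, seed=23)[0]
            br = gba.balance_residuals(m, f)
            st_ = gba.ScaledState(m, f)
            mask = np.abs(br.scaled) > 1e-12
            ratio = br.unscaled[mask] / br.scaled[mask]
            np.testing.assert_allclose(ratio, m.rho * st_.b_a, rtol=1e-9)
            assert np.all(ratio > 0)


class TestEconomyDecomposition:
    def test_production_only_at_ribosome(self, models):
        for m in models.values():
            ec = gba.economy_decomposition(m, interior_points(m, 1, seed=3)[0])
            mask = np.zeros(m.n_reactions, dtype=bool)
            mask[m.r_index] = True
            assert np.all(ec.production[~mask] == 0)
            assert ec.production[m.r_index] > 0

    def test_hand_triple_at_reference_state(self, model_a):
        ec = gba.economy_decomposition(model_a, F_HALF)
        assert ec.production[1] == pytest.approx(1.0)
        assert ec.investment[1] == pytest.approx(-3 / 7, rel=1e-12)
        assert ec.opportunity[1] == pytest.approx(-2 / 7, rel=1e-12)
        # triple sum = (b_a / mu) d_j mu with b_a = 0.5, mu = 1/7
        st_ = gba.ScaledState(model_a, F_HALF)
        triple = ec.production + ec.investment + ec.opportunity
        np.testing.assert_allclose(
            triple, st_.b_a / st_.mu * ec.gradient, rtol=1e-12
        )

    @pytest.mark.parametrize("name", FIXTURE_NAMES)
    def test_proteome_derivative_form_matches_gradient(self, models, name):
        m = models[name]
        f = interior_points(m, 1, seed=29)[0]
        ec = gba.economy_decomposition(m, f)
        scale = np.max(np.abs(ec.gradient))
        np.testing.assert_allclose(ec.proteome_form, ec.gradient,
                                   rtol=1e-5, atol=1e-5 * scale)

    def test_constant_kinetics_have_zero_opportunity(self):
        m = _constant_model()
        ec = gba.economy_decomposition(m, np.array([1.0, 0.6, 0.3]))
        np.testing.assert_array_equal(ec.opportunity, 0.0)


def _constant_model():
    return gba.GBAModel(
        reactant_ids=("m1", "m2", "a"),
        reactant_kinds=("m", "m", "a"),
        reaction_ids=("s", "e", "r"),
        reaction_kinds=("s", "e", "r"),
        M=np.array([[1.0, -1.0, 0.0], [0.0, 1.0, -1.0], [0.0, 0.0, 1.0]]),
        rho=1.0,
        x={"n_ext": 1.0},
        kinetics={
            "s": gba.KineticLaw("constant", kcat_fwd=1.0),
            "e": gba.KineticLaw("constant", kcat_fwd=2.0),
            "r": gba.KineticLaw("constant", kcat_fwd=3.0),
        },
    )


class TestGrowthControlCoefficients:
    def test_single_transporter_has_zero_control(self, model_a):
        G = gba.growth_control_coefficients(model_a, F_HALF)
        assert G[0] == 0.0

    def test_equals_gradient_for_mass_conserving_reactions(self, model_b):
        f = interior_points(model_b, 1, seed=31)[0]
        G = gba.growth_control_coefficients(model_b, f)
        grad = gba.growth_gradient(model_b, f)
        for j in range(model_b.n_reactions):
            if model_b.gamma[j] == 0:
                assert G[j] == pytest.approx(grad[j], rel=1e-14)

    def test_balance_form_at_optimum(self, models, optima):
        # Gamma_j = d_j mu + lambda gamma_j and Gamma_j f_j = 0 at optima
        for name, r in optima.items():
            m = models[name]
            G = gba.growth_control_coefficients(m, r.f_star)
            grad = gba.growth_gradient(m, r.f_star)
            np.testing.assert_allclose(G, grad + r.lambda_ * m.gamma,
                                       rtol=1e-8, atol=1e-8 * abs(r.lambda_))
            assert np.max(np.abs(G * r.f_star)) < 1e-8 * r.mu_star

    def test_two_transporter_coupling_at_c_optimum(self, model_c, optima):
        r = optima["C"]
        G = gba.growth_control_coefficients(model_c, r.f_star)
        assert np.max(np.abs(G * r.f_star)) < 1e-8 * r.mu_star

    def test_inactive_or_wrong_s_prime_rejected(self, model_b):
        f = interior_points(model_b, 1, seed=37)[0]
        with pytest.raises(InputError):
            gba.growth_control_coefficients(model_b, f, s_prime="e")


class TestEnzymeControlCoefficients:
    @pytest.mark.parametrize("name", ["B", "redundant"])
    def test_protein_identity_at_optimum(self, models, optima, name):
        m = models[name]
        r = optima[name]
        ecc = gba.enzyme_control_coefficients(m, r.f_star)
        p = gba.unscale_state(m, r.f_star).p
        for k, e in enumerate(m.enzyme_indices):
            if r.active[e]:
                assert abs(ecc.residual[k]) < 1e-6 * p[e]

    def test_zero_where_turnover_independent(self, model_b):
        # tau_s depends only on the external nutrient: no enzyme controls it
        f = interior_points(model_b, 1, seed=41)[0]
        ecc = gba.enzyme_control_coefficients(model_b, f)
        s = model_b.reaction_index["s"]
        assert ecc.C[0, s] == 0.0

    def test_matches_finite_difference_definition(self, model_b):
        f = interior_points(model_b, 1, seed=43)[0]
        ecc = gba.enzyme_control_coefficients(model_b, f)
        st_ = gba.ScaledState(model_b, f)
        e = model_b.enzyme_indices[0]
        h = 1e-6
        for l in range(model_b.n_reactions):
            fp, fm = f.copy(), f.copy()
            fp[e] += h
            fm[e] -= h
            tp = gba.turnover_times(model_b, model_b.rho * (model_b.M @ fp))[l]
            tm = gba.turnover_times(model_b, model_b.rho * (model_b.M @ fm))[l]
            fd = -(f[e] / st_.tau[l]) * (tp - tm) / (2 * h)
            assert ecc.C[0, l] == pytest.approx(fd, rel=1e-5, abs=1e-9)


class TestAdaptationCoefficients:
    def test_model_a_closed_forms(self, model_a, optima):
        ad = gba.adaptation_coefficients(model_a, optima["A"].f_star)
        np.testing.assert_allclose(ad.A_tau, [-0.5, -0.5], atol=1e-7)
        assert ad.A_x["glc_ext"] == pytest.approx(0.25, abs=1e-7)
        assert ad.A_rho == pytest.approx(SQRT2 / 4, abs=1e-7)
        assert ad.phi.sum() == pytest.approx(1.0, rel=1e-10)

    def test_multiplier_identities(self, models, optima):
        for name, r in optima.items():
            ad = gba.adaptation_coefficients(models[name], r.f_star)
            ids = ad.identities
            assert ids["mu_A_rho"] == pytest.approx(-r.lambda_, rel=1e-8)
            assert ids["lambda_from_gradient"] == pytest.approx(r.lambda_, rel=1e-8)
            assert ids["A_rho_proteome_fd"] == pytest.approx(ad.A_rho, rel=1e-4)


class TestEnvelopeCheck:
    @pytest.mark.parametrize(
        "parameter, expect",
        [
            (("tau_scale", "r"), -0.5),
            (("x", "glc_ext"), 0.25),
            (("rho",), SQRT2 / 4),
        ],
    )
    def test_model_a_reoptimization_recovers_coefficients(
        self, model_a, optima, parameter, expect
    ):
        ec = gba.envelope_check(model_a, optima["A"], parameter, delta=1e-4)
        assert ec.analytic == pytest.approx(expect, abs=1e-6)
        assert ec.empirical == pytest.approx(ec.analytic, rel=0.01, abs=1e-4)
        assert not ec.active_set_changed

    def test_model_b_envelope_agreement(self, model_b, optima):
        for parameter in [("tau_scale", "e"), ("rho",)]:
            ec = gba.envelope_check(model_b, optima["B"], parameter, delta=1e-4)
            assert ec.empirical == pytest.approx(ec.analytic, rel=0.01, abs=1e-4)

    def test_zero_perturbation_changes_nothing(self, model_a, optima):
        ec = gba.envelope_check(model_a, optima["A"], ("rho",), delta=0.0)
        assert ec.empirical == 0.0 and ec.mu_perturbed == ec.mu_base


class TestAnalyzeReport:
    def test_full_report_is_self_consistent(self, model_b, optima):
        rep = gba.analyze(model_b, optima["B"].f_star)
        assert rep.mu == pytest.approx(optima["B"].mu_star, rel=1e-12)
        assert rep.s_prime == "s"
        assert rep.phi.sum() == pytest.approx(1.0, rel=1e-10)
        # at the optimum the Lagrangian reduces to mu (feasibility + slackness)
        assert rep.lagrangian_value == pytest.approx(rep.mu, rel=1e-8)
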