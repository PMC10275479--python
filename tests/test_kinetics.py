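"""Turnover-time laws, their closed-form derivatives, and elasticities."""

import numpy as np
import pytest

import gba
from gba.errors import KineticsDomainError, SingularTurnoverError
from gba.kinetics import KineticLaw

from conftest import FIXTURE_NAMES, interior_points


def central_diff(fn, x0, h):
    return (fn(x0 + h) - fn(x0 - h)) / (2 * h)


class TestTurnoverTimes:
    def test_model_a_hand_values(self, model_a):
        # tau_s = (1 + K/x)/kcat = 2, tau_r = (1 + K/c_m)/kcat = 3 at c_m = 0.5
        tau = gba.turnover_times(model_a, np.array([0.5, 0.5]))
        np.testing.assert_allclose(tau, [2.0, 3.0], rtol=1e-15)

    def test_constant_law_is_inverse_kcat_everywhere(self):
        law = KineticLaw("constant", kcat_fwd=4.0)
        for c in (0.1, 1.0, 100.0):
            assert law.tau({"m": c}) == pytest.approx(0.25)
        assert law.dtau({"m": 1.0}) == {}

    def test_reversible_law_goes_negative_when_backward_favored(self):
        law = KineticLaw(
            "reversible_mm", kcat_fwd=1.0, kcat_bwd=2.0,
            km={"su": 1.0, "pr": 1.0}, substrates=("su",), products=("pr",),
        )
        assert law.tau({"su": 0.5, "pr": 2.0}) < 0

    def test_nonpositive_concentration_raises_named_domain_error(self, model_a):
        with pytest.raises(KineticsDomainError, match="'r'.*'m'"):
            gba.turnover_times(model_a, np.array([0.0, 1.0]))

    def test_thermodynamic_equilibrium_is_singular(self):
        m = _reversible_model()
        # c chosen so kf*c_s/K = kb*c_p/K exactly
        with pytest.raises(SingularTurnoverError):
            gba.turnover_times(m, np.array([0.5, 0.5, 0.5]))


def _reversible_model():
    return gba.GBAModel(
        reactant_ids=("su", "pr", "a"),
        reactant_kinds=("m", "m", "a"),
        reaction_ids=("s", "e", "r"),
        reaction_kinds=("s", "e", "r"),
        M=np.array([[1.0, -1.0, 0.0], [0.0, 1.0, -1.0], [0.0, 0.0, 1.0]]),
        rho=1.0,
        x={"n_ext": 1.0},
        kinetics={
            "s": KineticLaw("irreversible_mm", kcat_fwd=1.0,
                            km={"n_ext": 1.0}, substrates=("n_ext",)),
            "e": KineticLaw("reversible_mm", kcat_fwd=1.0, kcat_bwd=1.0,
                            km={"su": 1.0, "pr": 1.0},
                            substrates=("su",), products=("pr",)),
            "r": KineticLaw("irreversible_mm", kcat_fwd=1.0,
                            km={"pr": 1.0}, substrates=("pr",)),
        },
    )


LAWS = {
    "irreversible_mm": KineticLaw(
        "irreversible_mm", kcat_fwd=2.0, km={"u": 0.7, "w": 1.3},
        substrates=("u", "w"),
    ),
    "irreversible_mm_inhibited": KineticLaw(
        "irreversible_mm", kcat_fwd=2.0, km={"u": 0.7}, ki={"z": 0.4},
        substrates=("u",),
    ),
    "reversible_mm": KineticLaw(
        "reversible_mm", kcat_fwd=1.5, kcat_bwd=0.3,
        km={"u": 0.7, "w": 1.3}, substrates=("u",), products=("w",),
    ),
    "reversible_mm_inhibited": KineticLaw(
        "reversible_mm", kcat_fwd=1.5, kcat_bwd=0.3,
        km={"u": 0.7, "w": 1.3}, ki={"z": 0.4},
        substrates=("u",), products=("w",),
    ),
}


class TestDerivativeContract:
    @pytest.mark.parametrize("name", list(LAWS))
    def test_closed_form_matches_central_difference(self, name):
        law = LAWS[name]
        rng = np.random.default_rng(7)
        for _ in range(20):
            conc = {r: float(rng.uniform(0.2, 3.0)) for r in ("u", "w", "z")}
            analytic = law.dtau(conc)
            for rid in law.referenced:
                h = 1e-6 * (1 + conc[rid])

                def tau_of(c):
                    return law.tau({**conc, rid: c})

                fd = central_diff(tau_of, conc[rid], h)
                assert analytic[rid] == pytest.approx(fd, rel=1e-6), (name, rid)


class TestElasticities:
    def test_direct_elasticity_hand_value(self, model_a):
        # d tau_r / d c_m = -K/c^2 = -4 at c_m = 0.5, rho = 1
        eps = gba.direct_elasticities(model_a, np.array([0.5, 0.5]))
        assert eps[0, 1] == pytest.approx(-4.0)
        assert np.count_nonzero(eps) == 1

    def test_protein_row_is_zero(self, models):
        for m in models.values():
            f = gba.initial_points(m, 1, 3)[0]
            eps = gba.direct_elasticities(m, m.rho * (m.M @ f))
            np.testing.assert_array_equal(eps[m.a_index], 0.0)

    def test_indirect_elasticity_hand_values(self, model_a):
        E = gba.indirect_elasticities(model_a, np.array([1.0, 0.5]))
        np.testing.assert_allclose(E, [[0.0, 0.0], [-4.0, 4.0]], atol=1e-12)

    def test_constant_kinetics_give_zero_elasticities(self):
        m = _all_constant_model()
        E = gba.indirect_elasticities(m, np.array([1.0, 0.5, 0.4]))
        np.testing.assert_array_equal(E, 0.0)

    def test_composition_identity_with_M(self, models):
        # E[l, j] = sum_i eps[i, l] M[i, j] exactly
        for m in models.values():
            f = gba.initial_points(m, 1, 11)[0]
            eps = gba.direct_elasticities(m, m.rho * (m.M @ f))
            E = gba.indirect_elasticities(m, f)
            np.testing.assert_array_equal(E, eps.T @ m.M)

    @pytest.mark.parametrize("name", FIXTURE_NAMES)
    def test_indirect_elasticity_matches_finite_difference(self, models, name):
        m = models[name]
        for f in interior_points(m, 10, seed=5):
            E = gba.indirect_elasticities(m, f)
            for j in range(m.n_reactions):
                h = 1e-6

                def tau_of(fj):
                    g = f.copy()
                    g[j] = fj
                    return gba.turnover_times(m, m.rho * (m.M @ g))

                fd = central_diff(tau_of, f[j], h)
                np.testing.assert_allclose(E[:, j], fd, rtol=1e-5, atol=1e-7)

    def test_density_scaling_consistency(self, model_a):
        # doubling rho at fixed f doubles c; eps re-evaluates per its definition
        f = np.array([1.0, 0.5])
        m2 = model_a.with_rho(2.0)
        c2 = m2.rho * (m2.M @ f)
        eps2 = gba.direct_elasticities(m2, c2)
        law = model_a.kinetics["r"]
        expect = m2.rho * law.dtau({"m": c2[0], "glc_ext": 1.0})["m"]
        assert eps2[0, 1] == pytest.approx(expect, rel=1e-14)


def _all_constant_model():
    return gba.GBAModel(
        reactant_ids=("m1", "m2", "a"),
        reactant_kinds=("m", "m", "a"),
        reaction_ids=("s", "e", "r"),
        reaction_kinds=("s", "e", "r"),
        M=np.array([[1.0, -1.0, 0.0], [0.0, 1.0, -1.0], [0.0, 0.0, 1.0]]),
        rho=1.0,
        x={"n_ext": 1.0},
        kinetics={
            "s": KineticLaw("constant", kcat_fwd=1.0),
            "e": KineticLaw("constant", kcat_fwd=2.0),
            "r": KineticLaw("constant", kcat_fwd=3.0),
        },
    )
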