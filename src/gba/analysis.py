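"""Optimality conditions, shadow prices, economy and control of balanced growth.

The growth maximization over flux fractions has the Lagrangian

    L(f, lambda, theta) = mu(f) + lambda (gamma^T f - 1) + theta^T (f * tau(f)),

whose stationarity yields the *balance equations* ``(d_j mu + lambda gamma_j)
f_j = 0`` deciding which reactions are active at the optimum.  This module
computes, at any state f:

* the growth gradient ``d_j mu = (mu/b_a)(M[a,j] - mu tau_j - mu (f^T E)_j)``;
* the KKT multipliers: the density shadow price ``lambda = (mu^2/b_a) f^T E f``
  and protein shadow prices ``theta_j = -(d_j mu + lambda gamma_j)/tau_j``;
* balance-equation residuals (scaled, per reaction kind, and unscaled);
* the economy decomposition of the normalized marginal value into marginal
  production ``M[a,j]``, marginal investment ``-mu tau_j`` and marginal
  opportunity ``-mu (f^T E)_j``;
* growth control coefficients ``Gamma_j`` (total growth effect of f_j after
  eliminating one transporter through the density constraint), enzyme control
  coefficients ``C[e,l] = -(f_e/tau_l) E[l,e]``, and the growth adaptation
  coefficients ``A`` of kinetic, environmental and density parameters via the
  envelope theorem.

Derivatives taken "at fixed mu" (the proteome-allocation forms) are computed
literally by central finite differences with the growth rate frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, SingularTurnoverError
from .growth import ScaledState
from .kinetics import external_tau_derivatives

#: default relative threshold deciding whether a flux fraction is active
TOL_ACTIVE = 1e-6


def _state(model, f) -> ScaledState:
    return f if isinstance(f, ScaledState) else ScaledState(model, f)


# ---------------------------------------------------------------------------
# gradient and multipliers
# ---------------------------------------------------------------------------

def growth_gradient(model, f) -> np.ndarray:
    """Marginal values ``d_j mu = (mu/b_a)(M[a,j] - mu tau_j - mu (f^T E)_j)``.

    Implemented as ``(M[a,j] - mu tau_j - mu (f^T E)_j) / (f^T tau)`` which is
    identical (``mu/b_a = 1/(f^T tau)``) but stays finite at zero ribosome
    flux.
    """
    st = _state(model, f)
    return (model.M_a - st.mu * st.tau - st.mu * st.fE) / st.denom


def kkt_multipliers(model, f):
    """Density multiplier lambda and protein shadow prices theta at ``f``.

    ``lambda = (mu^2 / b_a) f^T E f`` and ``theta_j = -(d_j mu + lambda
    gamma_j) / tau_j``; the latter reproduces the per-kind closed forms for
    ribosome, enzymes and transporters.  At an optimum, ``theta_j != 0``
    forces ``f_j = 0`` and the ribosome always has ``theta_r = 0``.
    """
    st = _state(model, f)
    if np.any(st.tau == 0):
        raise SingularTurnoverError("theta undefined where tau_j = 0")
    lam = st.mu**2 / st.b_a * st.fEf if st.b_a != 0 else st.mu / st.denom * st.fEf
    grad = growth_gradient(model, st)
    theta = -(grad + lam * model.gamma) / st.tau
    return float(lam), theta


def lambda_from_gradient(model, f) -> float:
    """``lambda = -sum_j (d_j mu) f_j`` (valid at optima; reported at any f)."""
    st = _state(model, f)
    return float(-(growth_gradient(model, st) @ st.f))


def lambda_from_transporters(model, f) -> float:
    """Transporter-local expression ``lambda = -sum_s (d_s mu) f_s / sum_s gamma_s f_s``.

    Complementary slackness concentrates the balance equations on the
    transport columns (the only ones with nonzero gamma), so at an optimum
    the density shadow price is determined by transporter marginal values
    alone.  Asserted equal to the ``f^T E f`` form at optima.
    """
    st = _state(model, f)
    s = model.transporter_indices
    grad = growth_gradient(model, st)
    denom = float(model.gamma[s] @ st.f[s])
    return float(-(grad[s] @ st.f[s]) / denom)


def lagrangian_value(model, f) -> float:
    """The Lagrangian L at ``f`` with its own optimal multipliers plugged in."""
    st = _state(model, f)
    lam, theta = kkt_multipliers(model, st)
    return float(st.mu + lam * (model.gamma @ st.f - 1.0) + theta @ (st.f * st.tau))


# ---------------------------------------------------------------------------
# balance-equation residuals
# ---------------------------------------------------------------------------

@dataclass
class BalanceResiduals:
    scaled: np.ndarray  # (d_j mu + lambda gamma_j) f_j, per reaction
    by_kind: np.ndarray  # per-kind simplified forms (ribosome/enzyme/transport)
    active_enzyme: dict  # enzyme id -> tau_e + (f^T E)_e  (0 for active e at optimum)
    unscaled: np.ndarray  # physical-variable residual, per reaction


def balance_residuals(model, f) -> BalanceResiduals:
    """Residuals of the optimality (balance) equations at ``f``.

    ``scaled`` is the canonical KKT surface ``(d_j mu + lambda gamma_j) f_j``.
    ``by_kind`` divides out the positive prefactors per reaction type:
    ribosome ``(M[a,r] - mu tau_r - mu (f^T E)_r) f_r``, enzyme
    ``(tau_e + (f^T E)_e) f_e``, transporter ``(tau_s + (f^T E)_s -
    f^T E f gamma_s) f_s``.  ``unscaled`` is the same surface in physical
    fluxes, ``(M[a,j] - mu tau_j - mu (f^T E)_j + mu f^T E f gamma_j) v_j``,
    equal to ``scaled`` times ``rho b_a > 0``.
    """
    st = _state(model, f)
    lam, _ = kkt_multipliers(model, st)
    grad = growth_gradient(model, st)
    scaled = (grad + lam * model.gamma) * st.f

    inner = model.M_a - st.mu * st.tau - st.mu * st.fE + st.mu * st.fEf * model.gamma
    by_kind = np.empty(model.n_reactions)
    for j, kind in enumerate(model.reaction_kinds):
        if kind == "r":
            by_kind[j] = (model.M_a[j] - st.mu * st.tau[j] - st.mu * st.fE[j]) * st.f[j]
        elif kind == "e":
            by_kind[j] = (st.tau[j] + st.fE[j]) * st.f[j]
        else:
            by_kind[j] = (st.tau[j] + st.fE[j] - st.fEf * model.gamma[j]) * st.f[j]

    active_enzyme = {
        model.reaction_ids[e]: float(st.tau[e] + st.fE[e])
        for e in model.enzyme_indices
    }
    v = st.mu * model.rho * st.f
    unscaled = inner * v
    return BalanceResiduals(scaled, by_kind, active_enzyme, unscaled)


# ---------------------------------------------------------------------------
# economy
# ---------------------------------------------------------------------------

@dataclass
class EconomyDecomposition:
    production: np.ndarray  # M[a,j], nonzero only at the ribosome
    investment: np.ndarray  # -mu tau_j
    opportunity: np.ndarray  # -mu (f^T E)_j
    gradient: np.ndarray  # d_j mu, equals (mu/b_a) * triple sum
    proteome_form: np.ndarray  # -mu sum_l (d phi_l / d f_j)|mu, by finite differences


def _phi_frozen_mu(model, f, mu) -> np.ndarray:
    """Proteome fractions with the growth rate frozen at ``mu``."""
    st = ScaledState(model, f)
    return mu * st.f * st.tau / (model.M_a @ st.f)


def economy_decomposition(model, f, *, fd_step: float = 1e-6) -> EconomyDecomposition:
    """Marginal production / investment / opportunity triple per reaction.

    The triple sums to ``(b_a/mu) d_j mu``.  The proteome-allocation identity
    ``d_j mu = -mu sum_l (d phi_l / d f_j)|mu`` is verified independently by
    central finite differences of the proteome fractions at frozen mu.
    """
    st = _state(model, f)
    grad = growth_gradient(model, st)
    n = model.n_reactions
    proteome = np.empty(n)
    for j in range(n):
        h = fd_step * (1.0 + abs(st.f[j]))
        fp, fm = st.f.copy(), st.f.copy()
        fp[j] += h
        fm[j] -= h
        dphi = (_phi_frozen_mu(model, fp, st.mu) - _phi_frozen_mu(model, fm, st.mu)) / (2 * h)
        proteome[j] = -st.mu * dphi.sum()
    return EconomyDecomposition(
        production=model.M_a.copy(),
        investment=-st.mu * st.tau,
        opportunity=-st.mu * st.fE,
        gradient=grad,
        proteome_form=proteome,
    )


# ---------------------------------------------------------------------------
# control
# ---------------------------------------------------------------------------

def _auto_s_prime(model, st, tol_active=TOL_ACTIVE) -> int:
    s = model.transporter_indices
    scale = np.max(np.abs(st.f)) or 1.0
    active = s[np.abs(st.f[s]) > tol_active * scale]
    if active.size == 0:
        raise InputError("no active transporter available for elimination")
    return int(active[np.argmax(np.abs(st.f[active]))])


def growth_control_coefficients(model, f, s_prime=None) -> np.ndarray:
    """Growth control coefficients ``Gamma_j = d_j mu - d_s' mu gamma_j / gamma_s'``.

    ``s_prime`` is the transport reaction eliminated through the density
    constraint (default: the active transporter with largest ``|f|``).  At an
    optimum with optimal ``s'``, ``Gamma_j = d_j mu + lambda gamma_j`` and
    ``Gamma_j f_j = 0``.
    """
    st = _state(model, f)
    if s_prime is None:
        sp = _auto_s_prime(model, st)
    else:
        if s_prime not in model.reaction_index:
            raise InputError(f"unknown reaction {s_prime!r}")
        sp = model.reaction_index[s_prime]
        if model.reaction_kinds[sp] != "s":
            raise InputError(f"{s_prime!r} is not a transport reaction")
        scale = np.max(np.abs(st.f)) or 1.0
        if abs(st.f[sp]) <= TOL_ACTIVE * scale:
            raise InputError(f"transporter {s_prime!r} is inactive at this state")
    grad = growth_gradient(model, st)
    return grad - grad[sp] * model.gamma / model.gamma[sp]


@dataclass
class EnzymeControl:
    C: np.ndarray  # (n_enzymes, n_reactions); rows follow model.enzyme_indices
    enzyme_ids: tuple
    residual: np.ndarray  # p_e - sum_l p_l C[e,l], per enzyme (0 at optimality)


def enzyme_control_coefficients(model, f) -> EnzymeControl:
    """Scaled control coefficients ``C[e,l] = -(f_e / tau_l) E[l,e]`` of enzymes.

    The optimality condition for active enzymes is equivalent to
    ``p_e = sum_l p_l C[e,l]``; the residual of that identity is reported.
    """
    st = _state(model, f)
    e_idx = model.enzyme_indices
    C = -(st.f[e_idx][:, None] / st.tau[None, :]) * st.E[:, e_idx].T
    p = st.mu * model.rho * st.f * st.tau
    residual = p[e_idx] - C @ p
    return EnzymeControl(C, tuple(model.reaction_ids[e] for e in e_idx), residual)


# ---------------------------------------------------------------------------
# adaptation (envelope theorem)
# ---------------------------------------------------------------------------

@dataclass
class AdaptationCoefficients:
    """Relative sensitivities of the optimal growth rate to model parameters.

    ``A_pi = (pi/mu*) d mu*/d pi`` computed by the envelope theorem at the
    (assumed optimal) state: ``A_tau_j = -phi_j`` for the turnover-time scale
    of reaction j; ``A_x = -sum_s phi_s (x/tau_s) d tau_s/d x`` for an
    external concentration; ``A_rho = -(mu/b_a) f^T E f`` for the density.
    """

    A_tau: np.ndarray  # per reaction
    A_x: dict  # external id -> coefficient
    A_rho: float
    phi: np.ndarray
    identities: dict = field(default_factory=dict)


def adaptation_coefficients(model, f, *, fd_step: float = 1e-6) -> AdaptationCoefficients:
    """Envelope-theorem adaptation coefficients, with consistency identities.

    ``identities`` records the multiplier cross-checks evaluated at the state:
    ``minus_lambda`` (Eq-28 route), ``mu_A_rho`` (= -lambda at optima),
    ``lambda_from_gradient`` (transport-marginal route) and the
    proteome-derivative form ``A_rho_proteome_fd`` obtained by finite
    differences at frozen mu.
    """
    st = _state(model, f)
    phi = st.phi
    A_tau = -phi
    x_der = external_tau_derivatives(model, st.c)
    A_x = {}
    for xid, dtdx in x_der.items():
        mask = dtdx != 0
        A_x[xid] = float(
            -(phi[mask] * (model.x[xid] / st.tau[mask]) * dtdx[mask]).sum()
        )
    A_rho = float(-st.mu / st.b_a * st.fEf)

    lam, _ = kkt_multipliers(model, st)
    s_idx = model.transporter_indices
    fd = 0.0
    for s in s_idx:
        h = fd_step * (1.0 + abs(st.f[s]))
        fp, fm = st.f.copy(), st.f.copy()
        fp[s] += h
        fm[s] -= h
        dphi = (_phi_frozen_mu(model, fp, st.mu) - _phi_frozen_mu(model, fm, st.mu)) / (2 * h)
        fd += dphi.sum() * st.f[s]
    identities = {
        "minus_lambda": -lam,
        "mu_A_rho": st.mu * A_rho,
        "lambda_from_gradient": lambda_from_gradient(model, st),
        "A_rho_proteome_fd": -fd,
    }
    return AdaptationCoefficients(A_tau, A_x, A_rho, phi, identities)


@dataclass
class EnvelopeComparison:
    parameter: tuple
    delta: float
    analytic: float  # adaptation coefficient at the base optimum
    empirical: float  # (pi/mu*) * Delta mu* / Delta pi from re-optimization
    mu_base: float
    mu_perturbed: float
    active_set_changed: bool


def envelope_check(model, result, parameter, delta: float = 1e-4) -> EnvelopeComparison:
    """Validate an adaptation coefficient against explicit re-optimization.

    Parameters
    ----------
    result : OptimizationResult of the unperturbed model.
    parameter : ("tau_scale", reaction_id) | ("x", external_id) | ("rho",)
        The entry of the parameter vector to perturb by the relative amount
        ``delta``.
    """
    from .optimize import maximize_growth  # local import to avoid a cycle

    coeffs = adaptation_coefficients(model, result.f_star)
    kind = parameter[0]
    if kind == "tau_scale":
        rid = parameter[1]
        pert = model.with_turnover_scale(rid, 1.0 + delta)
        analytic = float(coeffs.A_tau[model.reaction_index[rid]])
    elif kind == "x":
        xid = parameter[1]
        pert = model.with_external(xid, model.x[xid] * (1.0 + delta))
        analytic = coeffs.A_x[xid]
    elif kind == "rho":
        pert = model.with_rho(model.rho * (1.0 + delta))
        analytic = coeffs.A_rho
    else:
        raise InputError(f"unknown parameter kind {kind!r}")

    if delta == 0:
        return EnvelopeComparison(tuple(parameter), 0.0, analytic, 0.0,
                                  result.mu_star, result.mu_star, False)
    res_p = maximize_growth(
        pert, n_starts=result.n_starts, seed=result.seed, tol=result.tol
    )
    empirical = (res_p.mu_star - result.mu_star) / (delta * result.mu_star)
    changed = bool(np.any(res_p.active != result.active))
    return EnvelopeComparison(
        tuple(parameter), delta, analytic, float(empirical),
        result.mu_star, res_p.mu_star, changed,
    )


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

@dataclass
class AnalysisReport:
    f: np.ndarray
    mu: float
    marginal_values: np.ndarray
    lambda_: float
    theta: np.ndarray
    balance: BalanceResiduals
    economy: EconomyDecomposition
    Gamma: np.ndarray
    s_prime: str
    enzyme_control: EnzymeControl
    adaptation: AdaptationCoefficients
    phi: np.ndarray
    lagrangian_value: float


def analyze(model, f, s_prime=None) -> AnalysisReport:
    """Compute the full analytical layer at a state ``f``.

    The adaptation block is meaningful when ``f`` is (close to) an optimum;
    all other quantities are defined at any feasible state.
    """
    st = _state(model, f)
    lam, theta = kkt_multipliers(model, st)
    grad = growth_gradient(model, st)
    sp = _auto_s_prime(model, st) if s_prime is None else model.reaction_index[s_prime]
    return AnalysisReport(
        f=st.f.copy(),
        mu=st.mu,
        marginal_values=grad,
        lambda_=lam,
        theta=theta,
        balance=balance_residuals(model, st),
        economy=economy_decomposition(model, st),
        Gamma=growth_control_coefficients(model, st, model.reaction_ids[sp]),
        s_prime=model.reaction_ids[sp],
        enzyme_control=enzyme_control_coefficients(model, st),
        adaptation=adaptation_coefficients(model, st),
        phi=st.phi,
        lagrangian_value=lagrangian_value(model, st),
    )
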