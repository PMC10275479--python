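"""The flux-fraction state space and the growth function.

At balanced growth every quantity scales out of the problem except the
dimensionless *flux fractions* ``f = v / (mu rho)`` (flux per unit of total
biomass production).  Mass conservation fixes the *biomass fractions*
``b = M f = c / rho``; reaction kinetics fix the turnover times
``tau = tau(rho M f, x)``; and equating the two expressions for the protein
mass fraction, ``b_a = mu f^T tau`` (kinetics) and ``b_a = M[a,r] f_r``
(mass conservation), yields the growth function

    mu(f) = M[a,r] * f_r / (f^T tau(f)).

The density constraint becomes a surface flux balance ``gamma^T f = 1``, and
non-negativity of proteins and concentrations become ``f * tau(f) >= 0`` and
``M f >= 0``.  This module evaluates all of these and converts between the
scaled state ``f`` and the physical state ``(c, p, v, mu)``.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np

from .errors import GBAError, InputError, KineticsDomainError, SingularTurnoverError
from .kinetics import direct_elasticities, turnover_times

#: |density residual| below this counts as satisfying gamma^T f = 1
DENSITY_TOL = 1e-8
#: slack above this (negative) counts as satisfying an inequality constraint
SLACK_TOL = -1e-9


def _as_f(model, f) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if f.shape != (model.n_reactions,):
        raise InputError(
            f"flux-fraction vector has shape {f.shape}, expected ({model.n_reactions},)"
        )
    return f


def biomass_fractions(model, f) -> np.ndarray:
    """Biomass fractions ``b = M f`` (no positivity enforced)."""
    return model.M @ _as_f(model, f)


def _check_required_positive(model, b):
    req = model.required_positive_indices
    bad = req[b[req] <= 0]
    if bad.size:
        names = [model.reactant_ids[i] for i in bad]
        raise KineticsDomainError(
            "growth function", ", ".join(names), float(b[bad].min())
        )


def growth_rate(model, f) -> float:
    """The growth function ``mu(f) = M[a,r] f_r / (f^T tau(f))``.

    Raises a domain error if a concentration required by a kinetic law is
    non-positive, and a singular-turnover error if ``f^T tau`` vanishes.
    ``mu = 0`` at zero ribosome flux is returned, not an error.
    """
    f = _as_f(model, f)
    b = model.M @ f
    _check_required_positive(model, b)
    tau = turnover_times(model, model.rho * b)
    denom = float(f @ tau)
    if abs(denom) < 1e-300:
        raise SingularTurnoverError("f^T tau(f) = 0: growth function undefined")
    return model.Mra * f[model.r_index] / denom


@dataclass
class ConstraintReport:
    """Residuals of the balanced-growth constraints at a point f."""

    density_residual: float  # gamma^T f - 1
    protein_slack: np.ndarray  # f * tau  (>= 0 feasible)
    concentration_slack: np.ndarray  # M f    (>= 0 feasible)
    feasible: bool


def constraint_values(model, f) -> ConstraintReport:
    """Evaluate density, protein and concentration constraints at ``f``.

    Points where a turnover time is undefined (non-positive required
    concentration) are reported infeasible with NaN protein slacks rather
    than raising, so the report can be used on arbitrary candidate points.
    """
    f = _as_f(model, f)
    b = model.M @ f
    density = float(model.gamma @ f - 1.0)
    try:
        _check_required_positive(model, b)
        tau = turnover_times(model, model.rho * b)
        protein = f * tau
    except GBAError:
        protein = np.full(model.n_reactions, np.nan)
    feasible = (
        abs(density) <= DENSITY_TOL
        and np.all(np.isfinite(protein))
        and bool(np.all(protein >= SLACK_TOL))
        and bool(np.all(b >= SLACK_TOL))
    )
    return ConstraintReport(density, protein, b, feasible)


class ScaledState:
    """A flux-fraction vector with lazily derived balanced-growth caches.

    Central computation object shared by the optimizer and the analysis
    layer: biomass fractions ``b``, concentrations ``c``, turnover times
    ``tau``, growth rate ``mu``, protein mass fraction ``b_a`` and both
    elasticity matrices are computed once per state.
    """

    def __init__(self, model, f):
        self.model = model
        self.f = _as_f(model, f)

    @functools.cached_property
    def b(self) -> np.ndarray:
        return self.model.M @ self.f

    @functools.cached_property
    def c(self) -> np.ndarray:
        return self.model.rho * self.b

    @functools.cached_property
    def tau(self) -> np.ndarray:
        _check_required_positive(self.model, self.b)
        return turnover_times(self.model, self.c)

    @functools.cached_property
    def denom(self) -> float:
        """``f^T tau``, the time to produce one biomass unit per unit protein."""
        d = float(self.f @ self.tau)
        if abs(d) < 1e-300:
            raise SingularTurnoverError("f^T tau(f) = 0: growth function undefined")
        return d

    @functools.cached_property
    def mu(self) -> float:
        return self.model.Mra * self.f[self.model.r_index] / self.denom

    @functools.cached_property
    def b_a(self) -> float:
        """Protein mass fraction via mass conservation, ``M[a,r] f_r``."""
        return self.model.Mra * self.f[self.model.r_index]

    @functools.cached_property
    def b_a_kinetic(self) -> float:
        """Protein mass fraction via kinetics, ``mu f^T tau`` (equals b_a)."""
        return self.mu * self.denom

    @functools.cached_property
    def epsilon(self) -> np.ndarray:
        return direct_elasticities(self.model, self.c)

    @functools.cached_property
    def E(self) -> np.ndarray:
        """Indirect elasticities ``E[l, j] = d tau_l / d f_j``."""
        return self.epsilon.T @ self.model.M

    @functools.cached_property
    def fE(self) -> np.ndarray:
        """Row vector ``(f^T E)_j = sum_l f_l E[l, j]``."""
        return self.f @ self.E

    @functools.cached_property
    def fEf(self) -> float:
        return float(self.fE @ self.f)

    @functools.cached_property
    def phi(self) -> np.ndarray:
        """Proteome fractions ``phi_j = p_j / c_a = mu f_j tau_j / b_a``."""
        return self.mu * self.f * self.tau / self.b_a


@dataclass
class CellState:
    """Physical (unscaled) description of a balanced-growth state."""

    c: np.ndarray  # reactant concentrations, [mass][volume]^-1
    p: np.ndarray  # catalyst concentrations, [mass][volume]^-1
    v: np.ndarray  # fluxes, [mass][volume]^-1 [time]^-1
    mu: float  # growth rate, [time]^-1
    c_a: float  # total protein concentration, [mass][volume]^-1


def unscale_state(model, f) -> CellState:
    """Convert flux fractions to physical concentrations and fluxes.

    ``c = rho M f``, ``v = mu rho f``, ``p = mu rho f * tau`` and
    ``c_a = rho M[a,r] f_r``.  Requires ``mu > 0``: the scaling map
    ``f = v/(mu rho)`` is degenerate at zero growth.
    """
    st = ScaledState(model, f)
    if not st.mu > 0:
        raise GBAError(f"unscale_state requires mu > 0, got mu = {st.mu}")
    murho = st.mu * model.rho
    return CellState(
        c=st.c,
        p=murho * st.f * st.tau,
        v=murho * st.f,
        mu=st.mu,
        c_a=model.rho * st.b_a,
    )
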