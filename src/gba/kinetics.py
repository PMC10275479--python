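"""Turnover-time kinetics and their elasticities.

Every reaction ``j`` in a growth balance model is catalyzed by a protein with
concentration ``p_j``, and the flux satisfies ``v_j = p_j / tau_j(c, x)``: the
turnover time ``tau_j`` (units of time) is the inverse of the usual
concentration-dependent factor of the kinetic rate law.  ``tau_j < 0`` means
the reaction runs backward at the given concentrations.

Three law kinds are provided:

``constant``
    ``tau = 1/kcat_fwd`` independent of all concentrations.
``irreversible_mm``
    ``tau = (1/kcat_fwd) * prod_s (1 + K_s/c_s) * prod_i (1 + c_i/KI_i)``,
    multi-substrate Michaelis-Menten with optional non-competitive inhibitors.
``reversible_mm``
    ``tau = (1 + sum_s c_s/K_s + sum_p c_p/K_p) /
    (kcat_fwd * prod_s c_s/K_s - kcat_bwd * prod_p c_p/K_p)``, optionally
    times the same inhibition factor.

All kinetic quantities are in mass units: Michaelis and inhibition constants
in [mass][volume]^-1, turnover numbers in product mass per catalyst mass per
time, i.e. [time]^-1.  Concentration derivatives are coded in closed form;
finite differences serve only as an independent test oracle.

The two sensitivity matrices of the theory are

* the direct elasticity ``epsilon[i, l] = rho * d tau_l / d c_i`` (sensitivity
  of turnover times to biomass fractions ``b = c/rho``), and
* the indirect elasticity ``E[l, j] = d tau_l / d f_j = sum_i epsilon[i, l] *
  M[i, j]``, the sensitivity to flux fractions, obtained through mass
  conservation ``b = M f``.

Rate laws are assumed never to depend on the total-protein reactant, so the
protein row of ``epsilon`` is identically zero (no crowding effects).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import InputError, KineticsDomainError, SingularTurnoverError

LAW_KINDS = ("constant", "irreversible_mm", "reversible_mm")


@dataclass
class KineticLaw:
    """A parameterized turnover-time function ``tau(c, x)``.

    Parameters
    ----------
    law_kind : {"constant", "irreversible_mm", "reversible_mm"}
    kcat_fwd : float
        Forward mass-based turnover number, [time]^-1, > 0.
    kcat_bwd : float
        Backward turnover number (reversible_mm only), >= 0.
    km : mapping reactant id -> Michaelis constant, [mass][volume]^-1.
    ki : mapping internal reactant id -> non-competitive inhibition constant.
    substrates, products : tuple of reactant ids (internal or external).
    """

    law_kind: str
    kcat_fwd: float
    kcat_bwd: float = 0.0
    km: dict = field(default_factory=dict)
    ki: dict = field(default_factory=dict)
    substrates: tuple = ()
    products: tuple = ()

    def __post_init__(self):
        if self.law_kind not in LAW_KINDS:
            raise InputError(f"unknown law_kind {self.law_kind!r}")
        if not self.kcat_fwd > 0:
            raise InputError(f"kcat_fwd must be > 0, got {self.kcat_fwd}")
        if self.kcat_bwd < 0:
            raise InputError(f"kcat_bwd must be >= 0, got {self.kcat_bwd}")
        self.substrates = tuple(self.substrates)
        self.products = tuple(self.products)
        if set(self.substrates) & set(self.products):
            raise InputError("a reactant cannot be both substrate and product")
        for rid, k in {**self.km, **self.ki}.items():
            if not k > 0:
                raise InputError(f"K for {rid!r} must be > 0, got {k}")
        if self.law_kind != "constant":
            missing = [r for r in self.substrates + self.products if r not in self.km]
            if missing:
                raise InputError(f"missing km for {missing}")
            if self.law_kind == "irreversible_mm" and self.products:
                # products are inert for the irreversible law; forbid to avoid
                # silently ignoring intent
                raise InputError("irreversible_mm takes no products")

    # reactants whose concentration must be strictly positive for tau to exist
    @property
    def required_positive(self) -> tuple:
        if self.law_kind == "constant":
            return ()
        return self.substrates + self.products

    @property
    def referenced(self) -> tuple:
        """All reactant ids this law reads (substrates, products, inhibitors)."""
        return tuple(dict.fromkeys(self.substrates + self.products + tuple(self.ki)))

    def tau(self, conc: Mapping[str, float]):
        """Turnover time at the given concentrations (scalars or arrays)."""
        if self.law_kind == "constant":
            return 1.0 / self.kcat_fwd
        inh = 1.0
        for rid, kI in self.ki.items():
            inh = inh * (1.0 + conc[rid] / kI)
        if self.law_kind == "irreversible_mm":
            base = 1.0 / self.kcat_fwd
            for rid in self.substrates:
                base = base * (1.0 + self.km[rid] / conc[rid])
            return base * inh
        num = 1.0
        for rid in self.substrates + self.products:
            num = num + conc[rid] / self.km[rid]
        den = self._den(conc)
        return num / den * inh

    def _den(self, conc):
        fwd = self.kcat_fwd
        for rid in self.substrates:
            fwd = fwd * (conc[rid] / self.km[rid])
        bwd = self.kcat_bwd
        for rid in self.products:
            bwd = bwd * (conc[rid] / self.km[rid])
        return fwd - bwd

    def dtau(self, conc: Mapping[str, float]) -> dict:
        """Closed-form ``d tau / d c`` for every referenced reactant."""
        out = {}
        if self.law_kind == "constant":
            return out
        t = self.tau(conc)
        if self.law_kind == "irreversible_mm":
            for rid in self.substrates:
                c, k = conc[rid], self.km[rid]
                out[rid] = -t * k / (c * (c + k))
        else:
            inh = 1.0
            for rid, kI in self.ki.items():
                inh = inh * (1.0 + conc[rid] / kI)
            num = 1.0
            for rid in self.substrates + self.products:
                num = num + conc[rid] / self.km[rid]
            den = self._den(conc)
            fwd = self.kcat_fwd
            for rid in self.substrates:
                fwd = fwd * (conc[rid] / self.km[rid])
            bwd = self.kcat_bwd
            for rid in self.products:
                bwd = bwd * (conc[rid] / self.km[rid])
            for rid in self.substrates:
                dden = fwd / conc[rid]
                out[rid] = (den / self.km[rid] - num * dden) / den**2 * inh
            for rid in self.products:
                dden = -bwd / conc[rid]
                out[rid] = (den / self.km[rid] - num * dden) / den**2 * inh
        # non-competitive inhibition contributes multiplicatively for both laws
        for rid, kI in self.ki.items():
            extra = t / (kI + conc[rid])
            out[rid] = out.get(rid, 0.0) + extra
        return out

    def scale_turnover(self, factor: float) -> "KineticLaw":
        """Return a copy whose tau is multiplied by ``factor`` at every state.

        Implemented by dividing both turnover numbers by ``factor``; used for
        perturbation/adaptation analyses of the turnover-time scale.
        """
        return replace(
            self,
            kcat_fwd=self.kcat_fwd / factor,
            kcat_bwd=self.kcat_bwd / factor,
            km=dict(self.km),
            ki=dict(self.ki),
        )


def _conc_lookup(model, c) -> dict:
    """Merge internal concentrations with the fixed external ones.

    ``c`` may be a vector (one state) or a ``(n_states, n_reactants)`` matrix
    for vectorized grid evaluation; in the latter case each entry is a column.
    """
    conc = {rid: c[..., k] for k, rid in enumerate(model.reactant_ids)}
    conc.update(model.x)
    return conc


def turnover_times(model, c, *, check: bool = True) -> np.ndarray:
    """Turnover times ``tau_j`` at internal concentrations ``c`` (Eq. c = rho M f).

    Parameters
    ----------
    model : GBAModel
    c : array of internal reactant concentrations, aligned with
        ``model.reactant_ids``.
    check : verify strict positivity of required concentrations and raise
        :class:`KineticsDomainError` / :class:`SingularTurnoverError`;
        disable for vectorized grid evaluation where the caller masks
        invalid points.
    """
    c = np.asarray(c, dtype=float)
    conc = _conc_lookup(model, c)
    out = []
    for rid in model.reaction_ids:
        law = model.kinetics[rid]
        if check and c.ndim == 1:
            for r in law.required_positive:
                val = conc[r]
                if not val > 0:
                    raise KineticsDomainError(rid, r, float(val))
            if law.law_kind == "reversible_mm":
                den = law._den(conc)
                if abs(den) < 1e-300:
                    raise SingularTurnoverError(
                        f"reaction {rid!r} at thermodynamic equilibrium "
                        "(zero net turnover)"
                    )
        out.append(law.tau(conc))
    if c.ndim == 1:
        return np.array(out, dtype=float)
    n_states = c.shape[0]
    cols = [np.broadcast_to(np.asarray(t, dtype=float), (n_states,)) for t in out]
    return np.column_stack(cols)


def direct_elasticities(model, c) -> np.ndarray:
    """Direct elasticities ``epsilon[i, l] = rho * d tau_l / d c_i``.

    Rows are internal reactants, columns are reactions.  The total-protein
    row is identically zero by the no-crowding assumption.
    """
    c = np.asarray(c, dtype=float)
    conc = _conc_lookup(model, c)
    eps = np.zeros((model.n_reactants, model.n_reactions))
    for l, rid in enumerate(model.reaction_ids):
        for r, d in model.kinetics[rid].dtau(conc).items():
            i = model.reactant_index.get(r)
            if i is not None and i != model.a_index:
                eps[i, l] = model.rho * d
    return eps


def indirect_elasticities(model, f) -> np.ndarray:
    """Indirect elasticities ``E[l, j] = d tau_l / d f_j`` at ``c = rho M f``."""
    f = np.asarray(f, dtype=float)
    c = model.rho * (model.M @ f)
    eps = direct_elasticities(model, c)
    return eps.T @ model.M


def external_tau_derivatives(model, c) -> dict:
    """``d tau_j / d x`` for every external reactant x, per reaction.

    Returns a mapping external id -> array over reactions (only transporters
    whose laws reference that external concentration are nonzero).  Used by
    the adaptation coefficient of an external concentration.
    """
    c = np.asarray(c, dtype=float)
    conc = _conc_lookup(model, c)
    out = {xid: np.zeros(model.n_reactions) for xid in model.x}
    for j, rid in enumerate(model.reaction_ids):
        for r, d in model.kinetics[rid].dtau(conc).items():
            if r in model.x:
                out[r][j] = d
    return out
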