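"""Self-replicating cell models: the triple (M, tau, rho) plus environment x.

A growth balance model describes a cell as a set of internal reactants
(metabolites plus one pooled total-protein species "a") interconverted by
reactions (transporters across the cell surface, internal enzymatic
reactions, and one ribosome reaction "r" that produces all protein).  The
mass-fraction matrix ``M`` is the column-normalized, mass-weighted
stoichiometric matrix: each internal column's negative entries sum to -1 and
its positive entries to +1, so internal columns conserve mass exactly
(column sum gamma_e = gamma_r = 0) while transport columns import or export
net mass (gamma_s != 0).  Together with the turnover-time laws ``tau`` and
the fixed total density ``rho``, the model determines every balanced-growth
quantity from the flux fractions alone.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import InputError, MassBalanceError, ValidationError
from .kinetics import KineticLaw

#: absolute tolerance for all structural (normalization) checks
STRUCT_TOL = 1e-9

REACTANT_KINDS = ("m", "a")
REACTION_KINDS = ("s", "e", "r")


@dataclass
class GBAModel:
    """A growth balance model.

    Parameters
    ----------
    reactant_ids, reactant_kinds :
        Ordered internal reactants; kinds are ``"m"`` (metabolite) or ``"a"``
        (total protein, exactly one).
    reaction_ids, reaction_kinds :
        Ordered reactions; kinds are ``"s"`` (transport), ``"e"`` (enzyme) or
        ``"r"`` (ribosome, exactly one).
    M : (n_reactants, n_reactions) mass-fraction matrix.
    rho : total internal mass density, [mass][volume]^-1, > 0.
    x : mapping external reactant id -> fixed concentration, >= 0.
    kinetics : mapping reaction id -> :class:`~gba.kinetics.KineticLaw`.
    """

    reactant_ids: tuple
    reactant_kinds: tuple
    reaction_ids: tuple
    reaction_kinds: tuple
    M: np.ndarray
    rho: float
    x: dict
    kinetics: dict
    name: str = ""

    def __post_init__(self):
        self.reactant_ids = tuple(self.reactant_ids)
        self.reactant_kinds = tuple(self.reactant_kinds)
        self.reaction_ids = tuple(self.reaction_ids)
        self.reaction_kinds = tuple(self.reaction_kinds)
        self.M = np.asarray(self.M, dtype=float)
        self.x = dict(self.x)
        self.kinetics = dict(self.kinetics)
        if self.M.shape != (len(self.reactant_ids), len(self.reaction_ids)):
            raise InputError(
                f"M has shape {self.M.shape}, expected "
                f"({len(self.reactant_ids)}, {len(self.reaction_ids)})"
            )

    # -- index helpers -----------------------------------------------------
    @property
    def n_reactants(self) -> int:
        return len(self.reactant_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @functools.cached_property
    def reactant_index(self) -> dict:
        return {rid: i for i, rid in enumerate(self.reactant_ids)}

    @functools.cached_property
    def reaction_index(self) -> dict:
        return {rid: j for j, rid in enumerate(self.reaction_ids)}

    @functools.cached_property
    def a_index(self) -> int:
        """Row index of the total-protein reactant."""
        idx = [i for i, k in enumerate(self.reactant_kinds) if k == "a"]
        if len(idx) != 1:
            raise InputError(f"expected exactly one 'a' reactant, found {len(idx)}")
        return idx[0]

    @functools.cached_property
    def r_index(self) -> int:
        """Column index of the ribosome reaction."""
        idx = [j for j, k in enumerate(self.reaction_kinds) if k == "r"]
        if len(idx) != 1:
            raise InputError(f"expected exactly one 'r' reaction, found {len(idx)}")
        return idx[0]

    @functools.cached_property
    def transporter_indices(self) -> np.ndarray:
        return np.array(
            [j for j, k in enumerate(self.reaction_kinds) if k == "s"], dtype=int
        )

    @functools.cached_property
    def enzyme_indices(self) -> np.ndarray:
        return np.array(
            [j for j, k in enumerate(self.reaction_kinds) if k == "e"], dtype=int
        )

    @functools.cached_property
    def gamma(self) -> np.ndarray:
        """Column sums of M; nonzero only for transport reactions."""
        return self.M.sum(axis=0)

    @property
    def M_a(self) -> np.ndarray:
        """The total-protein row of M (nonzero only at the ribosome column)."""
        return self.M[self.a_index]

    @property
    def Mra(self) -> float:
        """Mass fraction of protein produced per unit ribosome flux."""
        return float(self.M[self.a_index, self.r_index])

    @functools.cached_property
    def required_positive_indices(self) -> np.ndarray:
        """Internal reactant rows that must stay strictly positive for tau."""
        ids = set()
        for law in self.kinetics.values():
            for rid in law.required_positive:
                if rid in self.reactant_index:
                    ids.add(self.reactant_index[rid])
        return np.array(sorted(ids), dtype=int)

    # -- derived model variants (used by sweeps and envelope analysis) -----
    def _clone(self, **kw) -> "GBAModel":
        new = replace(self, **kw)
        new.kinetics = dict(new.kinetics)
        new.x = dict(new.x)
        return new

    def with_rho(self, rho: float) -> "GBAModel":
        return self._clone(rho=float(rho))

    def with_external(self, xid: str, value: float) -> "GBAModel":
        if xid not in self.x:
            raise InputError(f"unknown external reactant {xid!r}")
        new = self._clone()
        new.x[xid] = float(value)
        return new

    def with_turnover_scale(self, reaction: str, factor: float) -> "GBAModel":
        """Scale tau of one reaction by ``factor`` (kcat divided by it)."""
        if reaction not in self.kinetics:
            raise InputError(f"unknown reaction {reaction!r}")
        new = self._clone()
        new.kinetics[reaction] = self.kinetics[reaction].scale_turnover(factor)
        return new

    def validate(self):
        return validate_model(self)


@dataclass
class CheckResult:
    """Outcome of one structural validation check."""

    name: str
    passed: bool
    severity: str  # "error" or "warning"
    residual: float = 0.0
    message: str = ""


@dataclass
class ValidationReport:
    checks: list = field(default_factory=list)

    def add(self, name, passed, severity="error", residual=0.0, message=""):
        self.checks.append(CheckResult(name, bool(passed), severity, float(residual), message))

    def failures(self):
        return [c for c in self.checks if not c.passed and c.severity == "error"]

    def warnings(self):
        return [c for c in self.checks if not c.passed and c.severity == "warning"]

    @property
    def valid(self) -> bool:
        return not self.failures()

    def __str__(self):
        lines = []
        for c in self.checks:
            tag = "ok  " if c.passed else ("WARN" if c.severity == "warning" else "FAIL")
            lines.append(f"[{tag}] {c.name} (residual {c.residual:.3e}) {c.message}")
        return "\n".join(lines)


def validate_model(model: GBAModel) -> ValidationReport:
    """Run all structural invariants and return a named-check report.

    The model is valid iff every error-severity check passes.  A mass-neutral
    transport column (gamma_s == 0, e.g. an antiporter exchanging equal
    masses) is admitted with a warning: the density constraint only needs at
    least one transporter with nonzero gamma to be satisfiable.
    """
    rep = ValidationReport()
    M = model.M
    tol = STRUCT_TOL

    rep.add(
        "unique identifiers",
        len(set(model.reactant_ids)) == model.n_reactants
        and len(set(model.reaction_ids)) == model.n_reactions,
    )
    n_a = sum(k == "a" for k in model.reactant_kinds)
    n_r = sum(k == "r" for k in model.reaction_kinds)
    rep.add("exactly one total-protein row", n_a == 1, residual=n_a - 1)
    rep.add("exactly one ribosome column", n_r == 1, residual=n_r - 1)
    rep.add(
        "known kind tags",
        all(k in REACTANT_KINDS for k in model.reactant_kinds)
        and all(k in REACTION_KINDS for k in model.reaction_kinds),
    )
    rep.add("positive density rho", model.rho > 0, residual=min(model.rho, 0.0))
    bad_x = {k: v for k, v in model.x.items() if v < 0}
    rep.add("non-negative external concentrations", not bad_x, message=str(bad_x))
    if not rep.valid:
        return rep

    neg = np.where(M < 0, M, 0.0).sum(axis=0)
    pos = np.where(M > 0, M, 0.0).sum(axis=0)
    for j, rid in enumerate(model.reaction_ids):
        kind = model.reaction_kinds[j]
        if kind in ("e", "r"):
            label = "enzyme" if kind == "e" else "ribosome"
            rep.add(
                f"{label} column {rid!r} negative-sum = -1",
                abs(neg[j] + 1.0) <= tol,
                residual=neg[j] + 1.0,
            )
            rep.add(
                f"{label} column {rid!r} positive-sum = +1",
                abs(pos[j] - 1.0) <= tol,
                residual=pos[j] - 1.0,
            )
        else:
            g = M[:, j].sum()
            rep.add(
                f"transport column {rid!r} |gamma| <= 1",
                abs(g) <= 1.0 + tol,
                residual=abs(g) - 1.0,
            )
            rep.add(
                f"transport column {rid!r} gamma != 0",
                abs(g) > tol,
                severity="warning",
                residual=g,
                message="mass-neutral transporter admitted",
            )

    a = model.a_index
    nonzero_a = np.flatnonzero(np.abs(M[a]) > tol)
    rep.add(
        "protein row has single nonzero entry at ribosome",
        nonzero_a.size == 1 and nonzero_a[0] == model.r_index,
        message=f"nonzero columns: {[model.reaction_ids[j] for j in nonzero_a]}",
    )
    rep.add(
        "protein produced by ribosome (M[a,r] > 0)",
        M[a, model.r_index] > tol,
        residual=M[a, model.r_index],
    )

    # kinetics completeness and reference resolution
    missing = [rid for rid in model.reaction_ids if rid not in model.kinetics]
    rep.add("every reaction has a kinetic law", not missing, message=str(missing))
    known = set(model.reactant_ids) | set(model.x)
    a_id = model.reactant_ids[a]
    for rid in model.reaction_ids:
        law = model.kinetics.get(rid)
        if law is None:
            continue
        unknown = [r for r in law.referenced if r not in known]
        rep.add(
            f"kinetic references of {rid!r} resolve",
            not unknown,
            message=str(unknown),
        )
        rep.add(
            f"law of {rid!r} independent of total protein",
            a_id not in law.referenced,
            message="rate laws may not depend on the protein pool (no crowding)",
        )
    return rep


def require_valid(model: GBAModel) -> GBAModel:
    """Validate and return the model, raising :class:`ValidationError` on failure."""
    report = validate_model(model)
    if not report.valid:
        raise ValidationError(report)
    return model


def construct_mass_fraction_matrix(
    S,
    masses: Mapping[str, float],
    external_ids: Iterable[str],
    ribosome_column: str,
    *,
    reactant_ids=None,
    reaction_ids=None,
    tol: float = STRUCT_TOL,
) -> pd.DataFrame:
    """Build the mass-fraction matrix M from a closed-system stoichiometry.

    Each column of the closed system (all reactants, including external ones)
    is multiplied row-wise by molecular masses, checked to sum to zero (mass
    balance within the reaction), and scaled so that its negative entries sum
    to -1 (hence positive entries to +1).  Rows of external reactants are then
    dropped, which leaves transport columns with nonzero column sums gamma_s.

    Parameters
    ----------
    S : DataFrame (rows reactants, columns reactions), array, or path to a
        CSV file (header row = reaction ids, first column = reactant ids).
    masses : mapping reactant id -> molecular mass (> 0), or path to a
        two-column CSV (id, mass).
    external_ids : reactant ids external to the cell (rows to drop).
    ribosome_column : id of the protein-producing column; its product row is
        tagged as the total-protein reactant "a" downstream.

    Returns
    -------
    DataFrame
        M with internal reactant rows only, same column order as ``S``.
    """
    if isinstance(S, (str, Path)):
        S = pd.read_csv(S, index_col=0)
    if isinstance(masses, (str, Path)):
        tab = pd.read_csv(masses, header=None)
        masses = dict(zip(tab.iloc[:, 0], tab.iloc[:, 1].astype(float)))
    if not isinstance(S, pd.DataFrame):
        S = pd.DataFrame(np.asarray(S, dtype=float), index=reactant_ids, columns=reaction_ids)
    if ribosome_column not in S.columns:
        raise InputError(f"ribosome column {ribosome_column!r} not in stoichiometry")

    external_ids = set(external_ids)
    unknown = external_ids - set(S.index)
    if unknown:
        raise InputError(f"external ids not in stoichiometry: {sorted(unknown)}")
    for rid in S.index:
        m = masses.get(rid)
        if m is None or not m > 0:
            raise InputError(f"reactant {rid!r} needs a positive molecular mass, got {m}")

    W = S.mul(pd.Series(masses).reindex(S.index), axis=0).astype(float)
    M = pd.DataFrame(index=S.index, columns=S.columns, dtype=float)
    for col in W.columns:
        w = W[col].to_numpy()
        scale = np.abs(w).max()
        if scale == 0:
            raise InputError(f"column {col!r} is empty")
        total = w.sum()
        if abs(total) > tol * max(scale, 1.0):
            raise MassBalanceError(str(col), float(total))
        negsum = -w[w < 0].sum()
        if negsum == 0:
            raise MassBalanceError(str(col), float(total))
        M[col] = w / negsum
    return M.drop(index=sorted(external_ids))
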