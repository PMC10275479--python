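"""Built-in analytically tractable models, random model generation, and oracles.

The built-in models are the package's reference self-replicators (chain
topologies of transporter -> metabolites -> ribosome -> protein):

``A``
    Minimal two-reaction cell: glucose-like uptake ``s`` (ext -> m) and
    ribosome ``r`` (m -> protein), M = [[1, -1], [0, 1]], rho = x = 1, all
    kcat = K = 1 with irreversible Michaelis-Menten kinetics.  Its optimum
    is known in closed form: f_r* = 2 - sqrt(2), mu* = (2 - sqrt(2))/4.
``B``
    A plus an intermediate enzymatic step (s: ext -> m1, e: m1 -> m2,
    r: m2 -> protein).
``C``
    B with a mass leak: the enzyme converts m1 into 0.7 m2 + 0.3 w, and an
    exporter excretes the waste w (a CO2-like byproduct), so the density
    constraint couples two transport fluxes: gamma_s f_s + gamma_w f_w = 1
    with gamma_w = -1.
``redundant``
    B with a second, slower parallel enzyme m1 -> m2; its M is
    column-rank-deficient and exactly one branch is active at the optimum.

`brute_force_optimum` is an exhaustive grid oracle over the (at most two)
free flux fractions, used to cross-check the nonlinear solver.
`amino_acid_variation` summarizes per-amino-acid variability of proteome
composition tables as coefficients of variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize as sopt

from .errors import GBAError, InputError
from .kinetics import KineticLaw, turnover_times
from .model import GBAModel, require_valid

_BUILTIN_NAMES = ("A", "B", "C", "redundant")


def _mm(kcat, substrates, km):
    return KineticLaw("irreversible_mm", kcat_fwd=kcat, km=dict(km),
                      substrates=tuple(substrates))


def builtin_model(name: str) -> GBAModel:
    """Return one of the reference models ``A``, ``B``, ``C``, ``redundant``.

    Parameters are fixed constants (kcat = K = rho = x = 1 except where
    noted) so that the closed-form anchors used throughout the test suite
    are stable.
    """
    if name == "A":
        return require_valid(GBAModel(
            reactant_ids=("m", "a"),
            reactant_kinds=("m", "a"),
            reaction_ids=("s", "r"),
            reaction_kinds=("s", "r"),
            M=np.array([[1.0, -1.0], [0.0, 1.0]]),
            rho=1.0,
            x={"glc_ext": 1.0},
            kinetics={
                "s": _mm(1.0, ["glc_ext"], {"glc_ext": 1.0}),
                "r": _mm(1.0, ["m"], {"m": 1.0}),
            },
            name="A",
        ))
    if name == "B":
        return require_valid(GBAModel(
            reactant_ids=("m1", "m2", "a"),
            reactant_kinds=("m", "m", "a"),
            reaction_ids=("s", "e", "r"),
            reaction_kinds=("s", "e", "r"),
            M=np.array([
                [1.0, -1.0, 0.0],
                [0.0, 1.0, -1.0],
                [0.0, 0.0, 1.0],
            ]),
            rho=1.0,
            x={"glc_ext": 1.0},
            kinetics={
                "s": _mm(1.0, ["glc_ext"], {"glc_ext": 1.0}),
                "e": _mm(1.0, ["m1"], {"m1": 1.0}),
                "r": _mm(1.0, ["m2"], {"m2": 1.0}),
            },
            name="B",
        ))
    if name == "C":
        # enzyme leaks 30% of the converted mass into a waste product w,
        # which a dedicated exporter excretes (gamma = -1)
        return require_valid(GBAModel(
            reactant_ids=("m1", "m2", "w", "a"),
            reactant_kinds=("m", "m", "m", "a"),
            reaction_ids=("s", "e", "xw", "r"),
            reaction_kinds=("s", "e", "s", "r"),
            M=np.array([
                [1.0, -1.0, 0.0, 0.0],
                [0.0, 0.7, 0.0, -1.0],
                [0.0, 0.3, -1.0, 0.0],
                [0.0, 0.0, 0.0, 1.0],
            ]),
            rho=1.0,
            x={"glc_ext": 1.0, "w_ext": 0.0},
            kinetics={
                "s": _mm(1.0, ["glc_ext"], {"glc_ext": 1.0}),
                "e": _mm(1.0, ["m1"], {"m1": 1.0}),
                "xw": _mm(2.0, ["w"], {"w": 0.5}),
                "r": _mm(1.0, ["m2"], {"m2": 1.0}),
            },
            name="C",
        ))
    if name == "redundant":
        # parallel enzymes with identical stoichiometry but e2 half as fast:
        # M is column-rank-deficient and e2 must be inactive at the optimum
        return require_valid(GBAModel(
            reactant_ids=("m1", "m2", "a"),
            reactant_kinds=("m", "m", "a"),
            reaction_ids=("s", "e1", "e2", "r"),
            reaction_kinds=("s", "e", "e", "r"),
            M=np.array([
                [1.0, -1.0, -1.0, 0.0],
                [0.0, 1.0, 1.0, -1.0],
                [0.0, 0.0, 0.0, 1.0],
            ]),
            rho=1.0,
            x={"glc_ext": 1.0},
            kinetics={
                "s": _mm(1.0, ["glc_ext"], {"glc_ext": 1.0}),
                "e1": _mm(1.0, ["m1"], {"m1": 1.0}),
                "e2": _mm(0.5, ["m1"], {"m1": 1.0}),
                "r": _mm(1.0, ["m2"], {"m2": 1.0}),
            },
            name="redundant",
        ))
    raise InputError(f"unknown builtin model {name!r}; choose from {_BUILTIN_NAMES}")


@dataclass
class FixtureSpec:
    """Recipe for a random chain-topology model.

    A chain ``s -> m1 -> ... -> mk -> (r) -> a`` with ``n_metabolites``
    internal metabolites, optional extra transporters all feeding m1, and an
    optional redundant parallel branch duplicating a middle enzyme (which
    makes M column-rank-deficient).  Kinetic parameters are drawn
    log-uniformly from [0.1, 10].
    """

    name: str = "random"
    n_metabolites: int = 2
    n_transporters: int = 1
    seed: int = 0
    redundant: bool = False


def random_model(spec: FixtureSpec) -> GBAModel:
    """Generate a validated random chain model; identical for identical seeds."""
    k = spec.n_metabolites
    if k < 1 or spec.n_transporters < 1:
        raise InputError("need at least one metabolite and one transporter")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))

    def loguni():
        return float(10.0 ** rng.uniform(-1, 1))

    reactant_ids = [f"m{i+1}" for i in range(k)] + ["a"]
    reactant_kinds = ["m"] * k + ["a"]
    reaction_ids, reaction_kinds, cols, kinetics = [], [], [], {}
    x = {"n_ext": loguni()}

    for t in range(spec.n_transporters):
        rid = "s" if t == 0 else f"s{t+1}"
        col = np.zeros(k + 1)
        col[0] = 1.0
        reaction_ids.append(rid)
        reaction_kinds.append("s")
        cols.append(col)
        kinetics[rid] = _mm(loguni(), ["n_ext"], {"n_ext": loguni()})

    for i in range(k - 1):
        rid = f"e{i+1}"
        col = np.zeros(k + 1)
        col[i], col[i + 1] = -1.0, 1.0
        reaction_ids.append(rid)
        reaction_kinds.append("e")
        cols.append(col)
        kinetics[rid] = _mm(loguni(), [f"m{i+1}"], {f"m{i+1}": loguni()})

    if spec.redundant:
        if k < 2:
            raise InputError("a redundant branch needs at least two metabolites")
        rid = "e1b"
        col = np.zeros(k + 1)
        col[0], col[1] = -1.0, 1.0
        reaction_ids.append(rid)
        reaction_kinds.append("e")
        cols.append(col)
        kinetics[rid] = _mm(loguni(), ["m1"], {"m1": loguni()})

    col = np.zeros(k + 1)
    col[k - 1], col[k] = -1.0, 1.0
    reaction_ids.append("r")
    reaction_kinds.append("r")
    cols.append(col)
    kinetics["r"] = _mm(loguni(), [f"m{k}"], {f"m{k}": loguni()})

    return require_valid(GBAModel(
        reactant_ids=tuple(reactant_ids),
        reactant_kinds=tuple(reactant_kinds),
        reaction_ids=tuple(reaction_ids),
        reaction_kinds=tuple(reaction_kinds),
        M=np.column_stack(cols),
        rho=1.0,
        x=x,
        kinetics=kinetics,
        name=spec.name,
    ))


def _free_var_bound(model, j, free_idx, sp):
    """Upper bound of a free flux fraction over the linear feasible polytope."""
    n = model.n_reactions
    c = np.zeros(n)
    c[j] = -1.0
    res = sopt.linprog(
        c, A_ub=-model.M, b_ub=np.zeros(model.n_reactants),
        A_eq=model.gamma[None, :], b_eq=[1.0],
        bounds=[(0.0, 50.0)] * n, method="highs",
    )
    if not res.success:
        raise GBAError(f"could not bound free variable {model.reaction_ids[j]!r}")
    return float(res.x[j])


def brute_force_optimum(model, resolution: float):
    """Exhaustive grid search over the free flux fractions (oracle for the solver).

    One transporter is eliminated through the density constraint; the
    remaining free dimensions (at most two) are swept with absolute step
    ``resolution`` over their feasible ranges, constraints are checked
    pointwise, and the best feasible growth rate is returned as
    ``(f_best, mu_best)``.  Refining the resolution never decreases
    ``mu_best`` (nested grids).
    """
    sp = int(model.transporter_indices[0])
    free = [j for j in range(model.n_reactions) if j != sp]
    if len(free) > 2:
        raise InputError(
            f"grid oracle supports at most 2 free dimensions, model has {len(free)}"
        )
    axes = []
    for j in free:
        ub = _free_var_bound(model, j, free, sp)
        axes.append(np.arange(0.0, ub + resolution, resolution))
    if len(axes) == 1:
        grids = [axes[0]]
    else:
        g0, g1 = np.meshgrid(axes[0], axes[1], indexing="ij")
        grids = [g0.ravel(), g1.ravel()]

    n_pts = grids[0].size
    best_mu, best_f = -np.inf, None
    chunk = 200_000
    for lo in range(0, n_pts, chunk):
        hi = min(lo + chunk, n_pts)
        F = np.zeros((hi - lo, model.n_reactions))
        for ax, j in zip(grids, free):
            F[:, j] = ax[lo:hi]
        F[:, sp] = (1.0 - F[:, free] @ model.gamma[free]) / model.gamma[sp]
        B = F @ model.M.T
        C = model.rho * B
        ok = (F[:, sp] >= 0) & np.all(B >= 0, axis=1)
        req = model.required_positive_indices
        ok &= np.all(C[:, req] > 0, axis=1)
        if not ok.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            tau = turnover_times(model, C, check=False)
            denom = np.einsum("ij,ij->i", F, tau)
            mu = model.Mra * F[:, model.r_index] / denom
            ok &= np.all(np.isfinite(tau), axis=1)
            ok &= np.all(np.where(np.isfinite(tau), F * tau, -1.0) >= 0, axis=1)
            ok &= np.isfinite(mu) & (denom > 0)
        if not ok.any():
            continue
        mu = np.where(ok, mu, -np.inf)
        k = int(np.argmax(mu))
        if mu[k] > best_mu:
            best_mu, best_f = float(mu[k]), F[k].copy()
    if best_f is None:
        raise GBAError("grid search found no feasible point")
    return best_f, best_mu


def amino_acid_variation(table):
    """Coefficients of variation of amino-acid frequencies across conditions.

    Parameters
    ----------
    table : DataFrame or 2-D array, rows = amino acids, columns = growth
        conditions (>= 2), entries >= 0.

    Returns
    -------
    (cv, mean_cv, max_cv)
        ``cv`` is the per-row coefficient of variation in percent, computed
        with the sample (n-1) standard deviation; ``mean_cv`` and ``max_cv``
        summarize it over rows.
    """
    df = table if isinstance(table, pd.DataFrame) else pd.DataFrame(np.asarray(table, float))
    if df.shape[1] < 2:
        raise InputError("need at least two conditions (columns)")
    if (df.to_numpy() < 0).any():
        raise InputError("frequencies must be non-negative")
    means = df.mean(axis=1)
    zero = means[means == 0]
    if len(zero):
        raise InputError(f"rows with zero mean have undefined CV: {list(zero.index)}")
    cv = df.std(axis=1, ddof=1) / means * 100.0
    return cv, float(cv.mean()), float(cv.max())
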