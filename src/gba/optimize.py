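"""Multistart constrained maximization of the balanced growth rate.

The problem

    maximize mu(f) = M[a,r] f_r / (f^T tau(f))
    subject to gamma^T f = 1,  f * tau(f) >= 0,  M f >= 0

is smooth but non-convex (alternative pathways create disconnected optima),
so no local solver is globally reliable.  The strategy here is the honest
baseline: deterministic multistart sequential quadratic programming (SLSQP)
from interior feasible points, followed by an active-set polish that fixes
the detected inactive reactions at zero, eliminates one transporter through
the density constraint, and drives the reduced gradient (the growth control
coefficients) to machine precision with BFGS.  The first-order (KKT)
residual of the returned point is always computed and checked.

During the search, concentrations are kept away from the kinetic
singularities by an interior margin ``M f >= eps_b``; the final point is
re-checked against the true constraints ``M f >= 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as sopt

from .analysis import growth_gradient, kkt_multipliers
from .errors import InfeasibleModelError, OptimizationFailureError
from .growth import ScaledState, constraint_values
from .kinetics import direct_elasticities, turnover_times

#: interior concentration margin during the search (relative to typical b ~ 1)
EPS_B = 1e-6
#: margin for the final polish
EPS_B_POLISH = 1e-12
#: relative threshold for calling a reaction inactive
TOL_ACTIVE = 1e-6
#: bound on |f_j| used by the solver and the feasibility LP
F_MAX = 50.0


@dataclass
class StartRecord:
    index: int
    f0: np.ndarray
    f_opt: np.ndarray | None
    mu: float
    status: str


@dataclass
class ActiveSetReport:
    active: np.ndarray  # boolean per reaction
    rank: int  # rank of M restricted to active columns
    full_column_rank: bool


@dataclass
class OptimizationResult:
    """Best growth state found, with multipliers and per-start diagnostics."""

    f_star: np.ndarray
    mu_star: float
    lambda_: float
    theta: np.ndarray
    active: np.ndarray
    kkt_residual: float
    starts: list = field(default_factory=list)
    seed: int = 0
    n_starts: int = 0
    tol: float = 1e-6
    tol_active: float = TOL_ACTIVE
    active_rank: int = 0
    full_column_rank: bool = True
    boundary_metabolites: tuple = ()


def _interior_center(model, margin, *, allow_negative=False):
    """Feasible point maximizing the smallest concentration slack (an LP)."""
    n = model.n_reactions
    n_i = model.n_reactants
    c = np.zeros(n + 1)
    c[-1] = -1.0  # maximize s
    A_ub = np.hstack([-model.M, np.ones((n_i, 1))])
    b_ub = np.zeros(n_i)
    A_eq = np.concatenate([model.gamma, [0.0]])[None, :]
    lo = -F_MAX if allow_negative else 0.0
    bounds = [(lo, F_MAX)] * n + [(0.0, 0.5)]
    res = sopt.linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=[1.0],
                       bounds=bounds, method="highs")
    if not res.success or res.x[-1] <= margin:
        raise InfeasibleModelError(
            "no interior point with gamma^T f = 1 and M f > margin exists "
            f"(best slack {res.x[-1] if res.success else 'n/a'})"
        )
    return res.x[:-1], res.x[-1]


def initial_points(model, n, seed, *, margin=EPS_B, allow_negative=False):
    """Deterministic interior feasible starting points for the optimizer.

    Each point satisfies ``gamma^T f = 1`` exactly and ``M f >= margin``.
    Random directions are drawn in the forward orthant, normalized onto the
    density plane, and blended toward an interior center (a Chebyshev-like
    LP solution) just far enough to restore the margin; blending preserves
    the density equality exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    f0, slack0 = _interior_center(model, margin, allow_negative=allow_negative)
    b0 = model.M @ f0
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    points = []
    for _ in range(n):
        for _attempt in range(100):
            u = rng.uniform(0.05, 1.0, size=model.n_reactions)
            g = float(model.gamma @ u)
            if g > 1e-9:
                break
        else:
            raise InfeasibleModelError("could not sample a direction with gamma^T u > 0")
        f_rand = u / g
        b_rand = model.M @ f_rand
        alpha = 1.0
        for i in range(model.n_reactants):
            if b_rand[i] < margin:
                alpha = min(alpha, (b0[i] - margin) / (b0[i] - b_rand[i]))
        alpha = max(0.0, 0.999 * alpha)
        points.append(alpha * f_rand + (1.0 - alpha) * f0)
    return points


def _safe_mu_grad(model, f, floor):
    """Growth rate and gradient with concentrations clipped away from zero.

    SLSQP may evaluate transiently infeasible iterates; clipping the required
    concentrations at ``floor`` keeps the turnover times finite there.  At
    interior points the clip is inactive and the values are exact.
    """
    b = model.M @ f
    c = model.rho * b
    req = model.required_positive_indices
    c = c.copy()
    c[req] = np.maximum(c[req], floor)
    try:
        tau = turnover_times(model, c, check=False)
    except Exception:
        return -1.0, np.zeros_like(f), None
    if not np.all(np.isfinite(tau)):
        return -1.0, np.zeros_like(f), None
    denom = float(f @ tau)
    if denom <= 1e-12:
        return -1.0, np.zeros_like(f), None
    mu = model.Mra * f[model.r_index] / denom
    eps = direct_elasticities(model, c)
    E = eps.T @ model.M
    fE = f @ E
    grad = (model.M_a - mu * tau - mu * fE) / denom
    return mu, grad, (tau, E)


def _slsqp_start(model, f0, eps_b, tol):
    floor = 1e-10 * model.rho

    def neg_mu(f):
        return -_safe_mu_grad(model, f, floor)[0]

    def neg_grad(f):
        return -_safe_mu_grad(model, f, floor)[1]

    def prot_slack(f):
        mu, grad, extra = _safe_mu_grad(model, f, floor)
        if extra is None:
            return np.full_like(f, -1.0)
        return f * extra[0]

    def prot_jac(f):
        mu, grad, extra = _safe_mu_grad(model, f, floor)
        if extra is None:
            return np.zeros((f.size, f.size))
        tau, E = extra
        return np.diag(tau) + f[:, None] * E

    cons = [
        {"type": "eq", "fun": lambda f: model.gamma @ f - 1.0,
         "jac": lambda f: model.gamma},
        {"type": "ineq", "fun": lambda f: model.M @ f - eps_b,
         "jac": lambda f: model.M},
        {"type": "ineq", "fun": prot_slack, "jac": prot_jac},
    ]
    res = sopt.minimize(
        neg_mu, f0, jac=neg_grad, method="SLSQP", constraints=cons,
        bounds=[(0.0, F_MAX)] * model.n_reactions,
        options={"ftol": 1e-12, "maxiter": 300},
    )
    return res


def detect_active_set(model, f, tol_active=TOL_ACTIVE) -> ActiveSetReport:
    """Flag active reactions (``|f_j| > tol_active * max|f|``) and rank-check them.

    At any optimum the active columns of M must be linearly independent (the
    active reactions form an elementary growth state); an inactive ribosome
    is reported with a warning since growth requires protein synthesis.
    """
    f = np.asarray(f, dtype=float)
    scale = np.max(np.abs(f))
    active = np.abs(f) > tol_active * (scale if scale > 0 else 1.0)
    if not active[model.r_index]:
        import warnings

        warnings.warn("ribosome flux below the active threshold: no growth state",
                      stacklevel=2)
    sub = model.M[:, active]
    rank = int(np.linalg.matrix_rank(sub)) if sub.size else 0
    return ActiveSetReport(active, rank, rank == int(active.sum()))


def _polish(model, f, active, tol):
    """Active-set polish: BFGS on the reduced coordinates.

    Inactive reactions are pinned at exactly zero; one active transporter is
    eliminated through the density constraint; the reduced gradient of mu
    (the growth control coefficients restricted to the free reactions) is
    driven to ~machine precision.  Returns None if the polished point leaves
    the feasible set.
    """
    idx_active = np.flatnonzero(active)
    s_act = [j for j in idx_active if model.reaction_kinds[j] == "s"]
    if not s_act:
        return None
    sp = max(s_act, key=lambda j: abs(f[j]))
    free = np.array([j for j in idx_active if j != sp], dtype=int)
    if free.size == 0:
        return None
    floor = 1e-10 * model.rho

    def expand(z):
        full = np.zeros(model.n_reactions)
        full[free] = z
        full[sp] = (1.0 - model.gamma[free] @ z) / model.gamma[sp]
        return full

    def fun(z):
        full = expand(z)
        mu, grad, _ = _safe_mu_grad(model, full, floor)
        red = grad[free] - grad[sp] * model.gamma[free] / model.gamma[sp]
        return -mu, -red

    res = sopt.minimize(fun, f[free], jac=True, method="BFGS",
                        options={"gtol": 1e-13, "maxiter": 200})
    z = res.x

    # Newton refinement on the reduced gradient: the free dimension is tiny,
    # so a finite-difference Hessian is cheap and drives the stationarity
    # residual to machine precision
    def red_grad(zz):
        return fun(zz)[1]

    for _ in range(8):
        g = red_grad(z)
        if np.max(np.abs(g)) < 1e-15 * max(1.0, abs(res.fun)):
            break
        n_free = z.size
        H = np.empty((n_free, n_free))
        for k in range(n_free):
            h = 1e-7 * (1.0 + abs(z[k]))
            zp, zm = z.copy(), z.copy()
            zp[k] += h
            zm[k] -= h
            H[:, k] = (red_grad(zp) - red_grad(zm)) / (2 * h)
        try:
            step = np.linalg.solve(0.5 * (H + H.T), g)
        except np.linalg.LinAlgError:
            break
        z_new = z - step
        mu_new, _ = fun(z_new)
        if not np.isfinite(mu_new) or mu_new > res.fun + 1e-10 * max(1.0, abs(res.fun)):
            break
        z = z_new

    f_new = expand(z)
    rep = constraint_values(model, f_new)
    if not rep.feasible:
        f_new = expand(res.x)
        rep = constraint_values(model, f_new)
        if not rep.feasible:
            return None
    return f_new


def maximize_growth(model, n_starts: int = 20, seed: int = 0, tol: float = 1e-6,
                    tol_active: float = TOL_ACTIVE) -> OptimizationResult:
    """Maximize the balanced growth rate over flux fractions.

    Runs ``n_starts`` SLSQP solves from deterministic interior starting
    points, keeps the best feasible local solution (ties broken by lower
    start index), polishes its active set, and populates the KKT multipliers
    and first-order residual.  Identical arguments give bit-identical
    results.

    Raises
    ------
    OptimizationFailureError
        If no start converges to a feasible point, or the best candidate
        violates feasibility or the first-order conditions beyond ``tol``.
    """
    points = initial_points(model, n_starts, seed)
    starts = []
    best = None
    for k, f0 in enumerate(points):
        res = _slsqp_start(model, f0, EPS_B, tol)
        rep = constraint_values(model, res.x) if res.success else None
        ok = res.success and rep.feasible
        mu = -res.fun if res.success else np.nan
        starts.append(StartRecord(k, f0, res.x.copy() if res.success else None,
                                  float(mu), "converged" if ok else res.message))
        if ok and (best is None or mu > best[1] + 0.0):
            best = (res.x.copy(), float(mu), k)
    if best is None:
        raise OptimizationFailureError("no start converged to a feasible point", starts)

    f_best, mu_best, _ = best
    # tight re-solve near the candidate with a relaxed interior margin
    res2 = _slsqp_start(model, f_best, EPS_B_POLISH, tol)
    if res2.success and constraint_values(model, res2.x).feasible and -res2.fun >= mu_best:
        f_best, mu_best = res2.x.copy(), float(-res2.fun)

    # polish over candidate active sets: near-zero fluxes may sit slightly
    # above the nominal threshold after SLSQP, so try pruning at several
    # levels and keep the best feasible polished point
    tried = set()
    for thr in (tol_active, 1e-4, 1e-3, 1e-2):
        mask = tuple(detect_active_set(model, f_best, thr).active)
        if mask in tried:
            continue
        tried.add(mask)
        f_pol = _polish(model, f_best, np.array(mask), tol)
        if f_pol is None:
            continue
        mu_pol = float(ScaledState(model, f_pol).mu)
        if mu_pol >= mu_best - 1e-12 * max(1.0, abs(mu_best)):
            f_best, mu_best = f_pol, mu_pol
    aset = detect_active_set(model, f_best, tol_active)

    rep = constraint_values(model, f_best)
    if not rep.feasible:
        raise OptimizationFailureError(
            f"best candidate violates feasibility (density residual "
            f"{rep.density_residual:.2e})", starts)

    st = ScaledState(model, f_best)
    lam, theta = kkt_multipliers(model, st)
    grad = growth_gradient(model, st)
    kkt = float(np.max(np.abs((grad + lam * model.gamma) * st.f)))
    if kkt > tol * max(st.mu, 1e-300):
        raise OptimizationFailureError(
            f"first-order residual {kkt:.2e} exceeds tol*mu = {tol * st.mu:.2e}",
            starts)

    boundary = tuple(
        model.reactant_ids[i]
        for i in range(model.n_reactants)
        if rep.concentration_slack[i] < EPS_B
    )
    return OptimizationResult(
        f_star=f_best,
        mu_star=float(st.mu),
        lambda_=lam,
        theta=theta,
        active=aset.active,
        kkt_residual=kkt,
        starts=starts,
        seed=seed,
        n_starts=n_starts,
        tol=tol,
        tol_active=tol_active,
        active_rank=aset.rank,
        full_column_rank=aset.full_column_rank,
        boundary_metabolites=boundary,
    )
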