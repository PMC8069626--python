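"""Sequential quadratic programming for smooth constrained minimization.

Solves

    min f(x)   s.t.   h_i(x) = 0,  g_j(x) <= 0,  lb <= x <= ub

by the classical dense SQP scheme: at each iterate a convex QP built from a
damped-BFGS model of the Lagrangian Hessian and linearized constraints is
solved by a primal active-set method; the step is globalized by a
backtracking line search on an l1 exact-penalty merit function; convergence
is declared when the max-norm KKT residual falls below ``tol`` (default
1e-4) or the QP direction collapses below it at a feasible point.

Bound constraints are folded into the general inequality list (lower bounds
first, then upper bounds, after any user inequalities), which keeps the
active-set logic uniform; multiplier vectors returned in :class:`Solution`
follow that expanded ordering.

Gradients default to forward finite differences (relative step 1e-7); pass
analytic callbacks for exactness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import InfeasibleSubproblemError, InputError

__all__ = [
    "OptimizationProblem",
    "SQPSettings",
    "Solution",
    "solve_sqp",
    "solve_qp_subproblem",
    "bfgs_update",
    "kkt_residual",
    "finite_difference_gradient",
]

_FD_STEP = 1e-7


@dataclass
class OptimizationProblem:
    """A smooth constrained minimization problem.

    ``objective`` maps a parameter vector to a finite scalar on the feasible
    set.  ``equality_constraints`` are callables h_i with h_i(x) = 0 at
    feasibility, ``inequality_constraints`` callables g_j with g_j(x) <= 0.
    Optional ``gradient`` / ``eq_jacobians`` / ``ineq_jacobians`` supply
    analytic derivatives (each jacobian callable returns the constraint's
    gradient row); finite differences are used where absent.  ``bounds`` is a
    sequence of (lo, hi) pairs, entries may be ``-inf``/``+inf``.
    """

    objective: Callable[[np.ndarray], float]
    x0: np.ndarray
    equality_constraints: Sequence[Callable] = field(default_factory=list)
    inequality_constraints: Sequence[Callable] = field(default_factory=list)
    bounds: Optional[Sequence[tuple]] = None
    gradient: Optional[Callable] = None
    eq_jacobians: Optional[Sequence[Callable]] = None
    ineq_jacobians: Optional[Sequence[Callable]] = None

    def __post_init__(self) -> None:
        self.x0 = np.asarray(self.x0, dtype=float).ravel()
        if self.bounds is not None and len(self.bounds) != self.x0.size:
            raise InputError("bounds length must match x0 length")


@dataclass
class SQPSettings:
    """Tunables of the SQP iteration.

    ``tol`` is the KKT max-norm tolerance (default 1e-4); ``bfgs_damping`` the
    Powell-damping threshold on s'y relative to s'Hs; ``merit_penalty_margin``
    the safety factor by which the l1 penalty parameter exceeds the largest
    multiplier; ``armijo`` and ``backtrack`` the sufficient-decrease constant
    and step-halving factor of the line search.
    """

    tol: float = 1e-4
    max_iter: int = 200
    fd_step: float = _FD_STEP
    bfgs_damping: float = 0.2
    merit_penalty_margin: float = 1.5
    armijo: float = 1e-4
    backtrack: float = 0.5
    max_line_search: int = 30
    record_history: bool = False

    def __post_init__(self) -> None:
        if not self.tol > 0:
            raise InputError("tol must be positive")
        if self.max_iter < 1:
            raise InputError("max_iter must be >= 1")


@dataclass
class Solution:
    """Result of :func:`solve_sqp`."""

    x: np.ndarray
    fun: float
    lambda_eq: np.ndarray
    mu_ineq: np.ndarray
    converged: bool
    iterations: int
    kkt_residual: float
    message: str = ""
    history: Optional[list] = None  # per accepted step: dict(f, merit, alpha, step_norm)


def finite_difference_gradient(f: Callable, x: np.ndarray, step: float = _FD_STEP,
                               f0: Optional[float] = None) -> np.ndarray:
    """Forward-difference gradient with per-coordinate step ``step*max(1,|x_i|)``."""
    x = np.asarray(x, dtype=float)
    if f0 is None:
        f0 = f(x)
    grad = np.empty_like(x)
    for i in range(x.size):
        h = step * max(1.0, abs(x[i]))
        xp = x.copy()
        xp[i] += h
        grad[i] = (f(xp) - f0) / h
    return grad


def bfgs_update(H: np.ndarray, s: np.ndarray, y: np.ndarray,
                damping: float = 0.2) -> np.ndarray:
    """Powell-damped BFGS update of a symmetric positive-definite matrix.

    If ``s'y`` falls below ``damping * s'Hs`` the gradient change ``y`` is
    blended toward ``Hs`` so the curvature condition holds and the update
    preserves positive definiteness.  A zero step returns ``H`` unchanged.
    """
    s = np.asarray(s, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.any(s):
        return H
    Hs = H @ s
    sHs = float(s @ Hs)
    if sHs <= 0:  # should not happen for PD H; bail out conservatively
        return H
    sy = float(s @ y)
    if sy < damping * sHs:
        theta = (1.0 - damping) * sHs / (sHs - sy)
        y = theta * y + (1.0 - theta) * Hs
        sy = float(s @ y)
    Hnew = H - np.outer(Hs, Hs) / sHs + np.outer(y, y) / sy
    return 0.5 * (Hnew + Hnew.T)


def _solve_eq_qp(H: np.ndarray, g: np.ndarray, A: np.ndarray, b: np.ndarray):
    """Solve min g'd + d'Hd/2 s.t. A d = b via the dense KKT system."""
    n = g.size
    m = A.shape[0]
    if m == 0:
        return np.linalg.solve(H, -g), np.empty(0)
    K = np.zeros((n + m, n + m))
    K[:n, :n] = H
    K[:n, n:] = A.T
    K[n:, :n] = A
    rhs = np.concatenate([-g, b])
    try:
        sol = np.linalg.solve(K, rhs)
    except np.linalg.LinAlgError:
        sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
    return sol[:n], sol[n:]


def _feasible_start(A_eq, b_eq, A_in, b_in, n):
    """A point satisfying the linearized constraints, or raise."""
    if A_eq.shape[0]:
        d, *_ = np.linalg.lstsq(A_eq, b_eq, rcond=None)
        if np.max(np.abs(A_eq @ d - b_eq)) > 1e-8 * max(1.0, np.max(np.abs(b_eq))):
            raise InfeasibleSubproblemError("inconsistent linearized equalities")
    else:
        d = np.zeros(n)
    # Repair inequality violations by treating the most violated constraints
    # as equalities (minimum-norm correction); a few sweeps suffice for the
    # polyhedral geometry that arises from bounds + simplex constraints.
    for _ in range(3 * max(1, A_in.shape[0])):
        viol = A_in @ d - b_in if A_in.shape[0] else np.empty(0)
        if not viol.size or np.max(viol) <= 1e-10:
            return d
        j = int(np.argmax(viol))
        A_act = np.vstack([A_eq, A_in[[j]]]) if A_eq.shape[0] else A_in[[j]]
        b_act = np.concatenate([b_eq, b_in[[j]]]) if A_eq.shape[0] else b_in[[j]]
        # min ||d' - d|| s.t. active rows hold with equality
        corr, *_ = np.linalg.lstsq(A_act, b_act - A_act @ d, rcond=None)
        d = d + corr
        A_eq, b_eq = A_act, b_act
    raise InfeasibleSubproblemError("could not find a feasible point for the QP subproblem")


def solve_qp_subproblem(H: np.ndarray, g: np.ndarray,
                        A_eq: Optional[np.ndarray] = None,
                        b_eq: Optional[np.ndarray] = None,
                        A_in: Optional[np.ndarray] = None,
                        b_in: Optional[np.ndarray] = None,
                        max_iter: Optional[int] = None):
    """Minimize ``g'd + d'Hd/2`` s.t. ``A_eq d = b_eq``, ``A_in d <= b_in``.

    ``H`` must be symmetric positive definite.  Solved by a primal active-set
    iteration over dense KKT systems.  Returns ``(d, lambda_eq, mu_ineq)``
    with ``mu_ineq >= 0`` and complementary to the inequalities.

    Raises
    ------
    InfeasibleSubproblemError
        If the linearized constraints admit no feasible point.
    """
    H = np.asarray(H, dtype=float)
    g = np.asarray(g, dtype=float)
    n = g.size
    A_eq = np.zeros((0, n)) if A_eq is None else np.atleast_2d(np.asarray(A_eq, dtype=float))
    b_eq = np.zeros(0) if b_eq is None else np.atleast_1d(np.asarray(b_eq, dtype=float))
    A_in = np.zeros((0, n)) if A_in is None else np.atleast_2d(np.asarray(A_in, dtype=float))
    b_in = np.zeros(0) if b_in is None else np.atleast_1d(np.asarray(b_in, dtype=float))
    m_in = A_in.shape[0]

    d = _feasible_start(A_eq.copy(), b_eq.copy(), A_in, b_in, n)
    # working set: indices of inequalities treated as active
    work = [j for j in range(m_in) if abs(A_in[j] @ d - b_in[j]) <= 1e-10]
    if max_iter is None:
        max_iter = 20 * (n + m_in + 1)

    mu = np.zeros(m_in)
    lam = np.zeros(A_eq.shape[0])
    for _ in range(max_iter):
        A_act = np.vstack([A_eq, A_in[work]]) if work else A_eq
        gk = g + H @ d
        p, mult = _solve_eq_qp(H, gk, A_act, np.zeros(A_act.shape[0]))
        if np.max(np.abs(p), initial=0.0) <= 1e-11 * max(1.0, np.max(np.abs(d), initial=1.0)):
            lam = mult[: A_eq.shape[0]]
            mu_w = mult[A_eq.shape[0]:]
            if not work or (mu_w.size and np.min(mu_w) >= -1e-9) or not mu_w.size:
                mu = np.zeros(m_in)
                for idx, j in enumerate(work):
                    mu[j] = max(0.0, mu_w[idx])
                return d, lam, mu
            j_drop = work[int(np.argmin(mu_w))]
            work.remove(j_drop)
            continue
        # step length to nearest blocking inequality not in the working set
        alpha = 1.0
        blocker = -1
        for j in range(m_in):
            if j in work:
                continue
            aj_p = A_in[j] @ p
            if aj_p > 1e-13:
                a = (b_in[j] - A_in[j] @ d) / aj_p
                if a < alpha:
                    alpha = max(a, 0.0)
                    blocker = j
        d = d + alpha * p
        if blocker >= 0:
            work.append(blocker)
    # Did not settle: return current best with multipliers from last solve
    return d, lam, mu


def _expand_inequalities(problem: OptimizationProblem):
    """User inequalities plus bounds (lb first, then ub) as (callable, jac) pairs."""
    funcs = list(problem.inequality_constraints)
    jacs = list(problem.ineq_jacobians) if problem.ineq_jacobians else [None] * len(funcs)
    n = problem.x0.size
    if problem.bounds is not None:
        for i, (lo, hi) in enumerate(problem.bounds):
            if lo is not None and np.isfinite(lo):
                row = np.zeros(n)
                row[i] = -1.0
                funcs.append(lambda x, i=i, lo=lo: lo - x[i])
                jacs.append(lambda x, row=row: row)
        for i, (lo, hi) in enumerate(problem.bounds):
            if hi is not None and np.isfinite(hi):
                row = np.zeros(n)
                row[i] = 1.0
                funcs.append(lambda x, i=i, hi=hi: x[i] - hi)
                jacs.append(lambda x, row=row: row)
    return funcs, jacs


def kkt_residual(problem: OptimizationProblem, x: np.ndarray,
                 lambda_eq: np.ndarray, mu_ineq: np.ndarray,
                 fd_step: float = _FD_STEP) -> float:
    """Max-norm KKT residual at (x, λ, μ).

    Maximum over stationarity ‖∇f + Σλ∇h + Σμ∇g‖∞, primal feasibility
    (|h| and max(0, g), bounds included as inequalities), dual feasibility
    max(0, −μ), and complementarity |μ_j g_j|.  ``mu_ineq`` follows the
    expanded inequality ordering (user inequalities, then lower bounds, then
    upper bounds).
    """
    x = np.asarray(x, dtype=float)
    lambda_eq = np.atleast_1d(np.asarray(lambda_eq, dtype=float)) if np.size(lambda_eq) else np.zeros(0)
    mu_ineq = np.atleast_1d(np.asarray(mu_ineq, dtype=float)) if np.size(mu_ineq) else np.zeros(0)
    ineq_funcs, ineq_jacs = _expand_inequalities(problem)
    if mu_ineq.size != len(ineq_funcs):
        raise InputError(f"mu_ineq must have length {len(ineq_funcs)}")
    if lambda_eq.size != len(problem.equality_constraints):
        raise InputError("lambda_eq length mismatch")

    if problem.gradient is not None:
        grad = np.asarray(problem.gradient(x), dtype=float)
    else:
        grad = finite_difference_gradient(problem.objective, x, fd_step)
    stat = grad.copy()
    h_vals = np.array([h(x) for h in problem.equality_constraints])
    for i, h in enumerate(problem.equality_constraints):
        if problem.eq_jacobians:
            Jh = np.asarray(problem.eq_jacobians[i](x), dtype=float)
        else:
            Jh = finite_difference_gradient(h, x, fd_step)
        stat += lambda_eq[i] * Jh
    g_vals = np.array([g(x) for g in ineq_funcs])
    for j, gfun in enumerate(ineq_funcs):
        if mu_ineq[j] == 0.0:
            continue
        if ineq_jacs[j] is not None:
            Jg = np.asarray(ineq_jacs[j](x), dtype=float)
        else:
            Jg = finite_difference_gradient(gfun, x, fd_step)
        stat += mu_ineq[j] * Jg
    parts = [np.max(np.abs(stat), initial=0.0)]
    if h_vals.size:
        parts.append(np.max(np.abs(h_vals)))
    if g_vals.size:
        parts.append(np.max(np.maximum(g_vals, 0.0)))
        parts.append(np.max(np.maximum(-mu_ineq, 0.0)))
        parts.append(np.max(np.abs(mu_ineq * g_vals)))
    return float(max(parts))


def _merit(f_val, h_vals, g_vals, nu):
    infeas = 0.0
    if h_vals.size:
        infeas += np.sum(np.abs(h_vals))
    if g_vals.size:
        infeas += np.sum(np.maximum(g_vals, 0.0))
    return f_val + nu * infeas


def solve_sqp(problem: OptimizationProblem, settings: Optional[SQPSettings] = None) -> Solution:
    """Solve a smooth constrained problem by SQP with damped BFGS and l1 merit.

    Iterates QP subproblem → search direction → backtracking merit line
    search → BFGS Hessian update until the KKT residual drops below
    ``settings.tol``.  Hitting ``max_iter`` returns the best iterate with
    ``converged=False`` rather than raising.
    """
    if settings is None:
        settings = SQPSettings()
    x = problem.x0.astype(float).copy()
    n = x.size
    if problem.bounds is not None:  # project a near-feasible start into the box
        lo = np.array([(-np.inf if b[0] is None else b[0]) for b in problem.bounds])
        hi = np.array([(np.inf if b[1] is None else b[1]) for b in problem.bounds])
        x = np.clip(x, lo, hi)

    f = problem.objective(x)
    if not np.isfinite(f):
        raise InputError("objective is not finite at the initial point")

    ineq_funcs, ineq_jacs = _expand_inequalities(problem)
    eq_funcs = list(problem.equality_constraints)
    eq_jacs = problem.eq_jacobians

    def eval_grad(xv, f0=None):
        if problem.gradient is not None:
            return np.asarray(problem.gradient(xv), dtype=float)
        return finite_difference_gradient(problem.objective, xv, settings.fd_step, f0=f0)

    def eval_cons(xv):
        h = np.array([c(xv) for c in eq_funcs]) if eq_funcs else np.zeros(0)
        g = np.array([c(xv) for c in ineq_funcs]) if ineq_funcs else np.zeros(0)
        return h, g

    def eval_jacs(xv):
        Jh = np.zeros((len(eq_funcs), n))
        for i, c in enumerate(eq_funcs):
            Jh[i] = (np.asarray(eq_jacs[i](xv), dtype=float) if eq_jacs
                     else finite_difference_gradient(c, xv, settings.fd_step))
        Jg = np.zeros((len(ineq_funcs), n))
        for j, c in enumerate(ineq_funcs):
            Jg[j] = (np.asarray(ineq_jacs[j](xv), dtype=float) if ineq_jacs[j] is not None
                     else finite_difference_gradient(c, xv, settings.fd_step))
        return Jh, Jg

    H = np.eye(n)
    lam = np.zeros(len(eq_funcs))
    mu = np.zeros(len(ineq_funcs))
    nu = 1.0
    grad = eval_grad(x, f0=f)
    h_vals, g_vals = eval_cons(x)

    best = (x.copy(), f, lam.copy(), mu.copy(), np.inf)
    history: list = [] if settings.record_history else None
    message = "max_iter reached"
    converged = False
    it = 0
    for it in range(1, settings.max_iter + 1):
        Jh, Jg = eval_jacs(x)
        try:
            d, lam_new, mu_new = solve_qp_subproblem(H, grad, Jh, -h_vals, Jg, -g_vals)
        except InfeasibleSubproblemError:
            # relaxation: least-squares step toward equality feasibility
            if len(eq_funcs):
                d, *_ = np.linalg.lstsq(Jh, -h_vals, rcond=None)
                lam_new, mu_new = lam, mu
            else:
                d = -grad / max(1.0, np.linalg.norm(grad))
                lam_new, mu_new = lam, mu

        res = kkt_residual(problem, x, lam_new, mu_new, settings.fd_step)
        if res < best[4]:
            best = (x.copy(), f, lam_new.copy(), mu_new.copy(), res)
        if res < settings.tol:
            lam, mu = lam_new, mu_new
            converged = True
            message = "KKT residual below tolerance"
            break
        dnorm = np.max(np.abs(d), initial=0.0)
        feas = max(np.max(np.abs(h_vals), initial=0.0),
                   np.max(np.maximum(g_vals, 0.0), initial=0.0))
        if dnorm < settings.tol * 1e-4 and feas < settings.tol:
            # direction collapsed at a feasible point: first-order stall
            lam, mu = lam_new, mu_new
            converged = res < settings.tol
            message = "search direction collapsed"
            break

        # l1 merit with penalty safely above the largest multiplier
        mult_max = max(np.max(np.abs(lam_new), initial=0.0),
                       np.max(mu_new, initial=0.0))
        nu = max(nu, settings.merit_penalty_margin * mult_max + 1e-6)
        phi0 = _merit(f, h_vals, g_vals, nu)
        infeas0 = (np.sum(np.abs(h_vals)) if h_vals.size else 0.0) + \
                  (np.sum(np.maximum(g_vals, 0.0)) if g_vals.size else 0.0)
        D = float(grad @ d) - nu * infeas0  # directional derivative bound

        alpha = 1.0
        f_new, h_new, g_new = f, h_vals, g_vals
        accepted = False
        for _ in range(settings.max_line_search):
            x_trial = x + alpha * d
            f_trial = problem.objective(x_trial)
            h_trial, g_trial = eval_cons(x_trial)
            if np.isfinite(f_trial) and \
               _merit(f_trial, h_trial, g_trial, nu) <= phi0 + settings.armijo * alpha * D:
                x_new = x_trial
                f_new, h_new, g_new = f_trial, h_trial, g_trial
                accepted = True
                break
            alpha *= settings.backtrack
        if not accepted:
            # take the smallest trial step if it at least reduces the merit
            x_trial = x + alpha * d
            f_trial = problem.objective(x_trial)
            h_trial, g_trial = eval_cons(x_trial)
            if np.isfinite(f_trial) and _merit(f_trial, h_trial, g_trial, nu) < phi0:
                x_new, f_new, h_new, g_new = x_trial, f_trial, h_trial, g_trial
            else:
                lam, mu = lam_new, mu_new
                message = "line search failed to make progress"
                break

        if history is not None:
            history.append({
                "f": float(f_new),
                "merit": float(_merit(f_new, h_new, g_new, nu)),
                "merit_before": float(phi0),
                "alpha": float(alpha),
                "step_norm": float(np.linalg.norm(x_new - x)),
            })

        grad_new = eval_grad(x_new, f0=f_new)
        s = x_new - x
        # gradient change of the Lagrangian at fixed new multipliers
        Jh_new, Jg_new = eval_jacs(x_new)
        y = grad_new - grad
        if len(eq_funcs):
            y += (lam_new @ Jh_new) - (lam_new @ Jh)
        if len(ineq_funcs) and np.any(mu_new):
            y += (mu_new @ Jg_new) - (mu_new @ Jg)
        H = bfgs_update(H, s, y, settings.bfgs_damping)

        x, f, grad = x_new, f_new, grad_new
        h_vals, g_vals = h_new, g_new
        lam, mu = lam_new, mu_new

    res = kkt_residual(problem, x, lam, mu, settings.fd_step)
    if res < best[4]:
        best = (x.copy(), f, lam.copy(), mu.copy(), res)
    if best[4] < settings.tol:
        converged = True
    x_b, f_b, lam_b, mu_b, res_b = best
    return Solution(x=x_b, fun=float(f_b), lambda_eq=lam_b, mu_ineq=mu_b,
                    converged=converged, iterations=it, kkt_residual=float(res_b),
                    message=message, history=history)
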