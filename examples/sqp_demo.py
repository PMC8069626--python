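"""The in-package SQP optimizer on a classic constrained test problem.

Minimizes the Rosenbrock function inside the unit disc with box bounds, and
prints the merit-function trace showing globalized convergence.
"""

import numpy as np

from relmech import OptimizationProblem, SQPSettings, solve_sqp


def rosen(x):
    return float((1 - x[0]) ** 2 + 100 * (x[1] - x[0] ** 2) ** 2)


def rosen_grad(x):
    return np.array([
        -400 * x[0] * (x[1] - x[0] ** 2) - 2 * (1 - x[0]),
        200 * (x[1] - x[0] ** 2),
    ])


problem = OptimizationProblem(
    objective=rosen,
    gradient=rosen_grad,
    x0=np.array([0.0, 0.0]),
    inequality_constraints=[lambda x: x[0] ** 2 + x[1] ** 2 - 1.5],
    ineq_jacobians=[lambda x: np.array([2 * x[0], 2 * x[1]])],
    bounds=[(-2, 2), (-2, 2)],
)
solution = solve_sqp(problem, SQPSettings(tol=1e-9, record_history=True))

print(f"converged: {solution.converged} in {solution.iterations} iterations")
print(f"x* = {solution.x}, f* = {solution.fun:.6e}")
print(f"KKT residual = {solution.kkt_residual:.3e}")
print("\niter   objective        merit        step")
for i, rec in enumerate(solution.history):
    print(f"{i:4d}   {rec['f']:.6e}   {rec['merit']:.6e}   {rec['step_norm']:.2e}")
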