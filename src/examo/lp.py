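"""Thin linear-programming layer over scipy's HiGHS interfaces.

All steady-state LPs in the package (FBA, FVA, consistency checks) funnel
through :func:`solve_flux_lp`; the MILP stages build their own constraint
matrices and call :func:`solve_milp`.  Keeping a single entry point keeps
solver options and tolerances consistent across modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import LinearConstraint, linprog, milp
from scipy.sparse import csr_matrix, lil_matrix

from .model import MetabolicModel

__all__ = ["FluxLpResult", "steady_state_system", "solve_flux_lp", "solve_milp", "InfeasibleProblem"]

#: Relative MILP optimality gap demanded from the solver (proven optimum).
MIP_REL_GAP = 0.0


class InfeasibleProblem(RuntimeError):
    """Raised when an optimization problem that must be feasible is not."""


def steady_state_system(model: MetabolicModel) -> tuple[csr_matrix, np.ndarray, np.ndarray]:
    """Return (S, lb, ub) defining {v : S v = 0, lb <= v <= ub}."""
    n, m = len(model.metabolites), len(model.reactions)
    S = lil_matrix((n, m))
    met_index = {met.id: i for i, met in enumerate(model.metabolites)}
    for j, rxn in enumerate(model.reactions):
        for met_id, coeff in rxn.stoich.items():
            S[met_index[met_id], j] = coeff
    return S.tocsr(), model.lb, model.ub


@dataclass
class FluxLpResult:
    status: str  # "optimal" | "infeasible" | "unbounded"
    objective: float | None
    fluxes: np.ndarray | None


def solve_flux_lp(
    model: MetabolicModel,
    objective: dict[str, float],
    sense: str = "max",
    extra_bounds: dict[str, tuple[float, float]] | None = None,
    S_lb_ub=None,
) -> FluxLpResult:
    """Optimize a linear flux objective over the steady-state polytope.

    `objective` maps reaction ids to coefficients; `sense` is "max" or
    "min".  `extra_bounds` temporarily overrides per-reaction bounds without
    copying the model.  `S_lb_ub` allows reusing a precomputed system.
    """
    S, lb, ub = steady_state_system(model) if S_lb_ub is None else S_lb_ub
    lb, ub = lb.copy(), ub.copy()
    if extra_bounds:
        for rid, (lo, hi) in extra_bounds.items():
            j = model.reaction_index(rid)
            lb[j], ub[j] = lo, hi
    c = np.zeros(len(model.reactions))
    for rid, coeff in objective.items():
        c[model.reaction_index(rid)] += coeff
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(
        sign * c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    if res.status == 2:
        return FluxLpResult("infeasible", None, None)
    if res.status == 3:
        return FluxLpResult("unbounded", None, None)
    if not res.success:  # pragma: no cover - numerical failure
        raise RuntimeError(f"LP solver failure: {res.message}")
    return FluxLpResult("optimal", sign * res.fun, res.x)


def solve_milp(
    c: np.ndarray,
    constraints: list[LinearConstraint],
    integrality: np.ndarray,
    bounds_lo: np.ndarray,
    bounds_hi: np.ndarray,
    sense: str = "max",
):
    """Solve a MILP to proven optimality; returns (objective, x) or None.

    ``None`` signals infeasibility.  The objective is reported in the
    caller's sense (maximization objectives are returned positive).
    """
    sign = -1.0 if sense == "max" else 1.0
    from scipy.optimize import Bounds

    res = milp(
        sign * c,
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(bounds_lo, bounds_hi),
        options={"mip_rel_gap": MIP_REL_GAP},
    )
    if res.status == 2 or res.x is None:
        return None
    if not res.success:  # pragma: no cover - numerical failure
        raise RuntimeError(f"MILP solver failure: {res.message}")
    return sign * res.fun, res.x
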