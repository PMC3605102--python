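"""Agreement-score maximization between fluxes and expression (iMAT).

Finds a steady-state flux distribution maximizing the number of highly
expressed reactions (rH) carrying flux of magnitude at least eps plus the
number of lowly expressed reactions (rL) carrying no flux, subject to
S v = 0, bound constraints and a forced non-zero biomass flux.  Binary
variables y+ / y- per rH reaction select forward/backward activation (big-M
linearized with the model's own finite bounds); a binary y per rL reaction
pins the flux to zero when set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import LinearConstraint
from scipy.sparse import lil_matrix

from .expression import ReactionCalls
from .lp import InfeasibleProblem, solve_milp, steady_state_system
from .model import MetabolicModel

__all__ = ["ImatProblem", "ImatSolution", "solve_imat"]

#: Fluxes with magnitude above this are "active" in numerical checks.
ACTIVITY_TOL = 1e-6


@dataclass
class ImatProblem:
    model: MetabolicModel
    calls: ReactionCalls
    eps: float = 1.0
    biomass_id: str | None = None
    biomass_min: float | None = None  # defaults to eps

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.biomass_id is None:
            biomass = self.model.biomass
            if biomass is None:
                raise ValueError("model has no biomass reaction and none was named")
            self.biomass_id = biomass.id
        if self.biomass_id not in self.model:
            raise ValueError(f"biomass reaction {self.biomass_id!r} not in model")
        missing = (self.calls.rH | self.calls.rL) - set(self.model.reaction_ids)
        if missing:
            raise ValueError(f"classified reactions not in model: {sorted(missing)}")
        if self.biomass_min is None:
            self.biomass_min = self.eps


@dataclass
class ImatSolution:
    fluxes: dict[str, float]
    score: int
    yplus: dict[str, int] = field(default_factory=dict)
    yminus: dict[str, int] = field(default_factory=dict)
    y: dict[str, int] = field(default_factory=dict)

    def flux_vector(self, model: MetabolicModel) -> np.ndarray:
        return np.array([self.fluxes[r.id] for r in model.reactions])

    def active_set(self, tol: float = ACTIVITY_TOL) -> set[str]:
        return {rid for rid, v in self.fluxes.items() if abs(v) > tol}


def solve_imat(
    problem: ImatProblem,
    extra_bounds: dict[str, tuple[float, float]] | None = None,
) -> ImatSolution:
    """Solve the agreement-score MILP to proven optimality.

    `extra_bounds` overrides per-reaction bounds, which is how the
    alternative-optima exploration forces reactions off or on.  Raises
    :class:`InfeasibleProblem` when no feasible flux distribution exists
    (for instance when the biomass reaction is blocked).
    """
    sol = _solve_imat_impl(problem, extra_bounds)
    if sol is None:
        raise InfeasibleProblem(
            "iMAT MILP infeasible: no steady-state flux distribution satisfies the "
            f"bound constraints with biomass '{problem.biomass_id}' >= {problem.biomass_min}"
        )
    return sol


def try_solve_imat(
    problem: ImatProblem,
    extra_bounds: dict[str, tuple[float, float]] | None = None,
) -> ImatSolution | None:
    """Like :func:`solve_imat` but returns None on infeasibility."""
    return _solve_imat_impl(problem, extra_bounds)


def _solve_imat_impl(problem, extra_bounds) -> ImatSolution | None:
    model = problem.model
    eps = problem.eps
    m = len(model.reactions)
    S, lb, ub = steady_state_system(model)
    lb, ub = lb.copy(), ub.copy()
    if extra_bounds:
        for rid, (lo, hi) in extra_bounds.items():
            j = model.reaction_index(rid)
            lb[j], ub[j] = lo, hi
            if lo > hi:
                return None
    jb = model.reaction_index(problem.biomass_id)
    lb[jb] = max(lb[jb], problem.biomass_min)
    if lb[jb] > ub[jb]:
        return None

    rH = sorted(problem.calls.rH)
    rL = sorted(problem.calls.rL)
    n_bin = 2 * len(rH) + len(rL)
    nv = m + n_bin

    # variable layout: v (m) | y+ (rH) | y- (rH) | y (rL)
    off_yp = m
    off_ym = m + len(rH)
    off_y = m + 2 * len(rH)

    c = np.zeros(nv)
    c[off_yp:off_yp + len(rH)] = 1.0
    c[off_ym:off_ym + len(rH)] = 1.0
    c[off_y:off_y + len(rL)] = 1.0

    rows: list[tuple[dict[int, float], float, float]] = []  # (coeffs, lo, hi)
    inf = np.inf
    for k, rid in enumerate(rH):
        j = model.reaction_index(rid)
        # y+ = 1  =>  v_j >= eps      (v_j + (lb_j - eps) y+ >= lb_j)
        rows.append(({j: 1.0, off_yp + k: lb[j] - eps}, lb[j], inf))
        # y- = 1  =>  v_j <= -eps     (v_j + (ub_j + eps) y- <= ub_j)
        rows.append(({j: 1.0, off_ym + k: ub[j] + eps}, -inf, ub[j]))
        # directions are mutually exclusive
        rows.append(({off_yp + k: 1.0, off_ym + k: 1.0}, -inf, 1.0))
    for k, rid in enumerate(rL):
        j = model.reaction_index(rid)
        # y = 1  =>  v_j = 0 exactly  (lb_j (1-y) <= v_j <= ub_j (1-y))
        rows.append(({j: 1.0, off_y + k: lb[j]}, lb[j], inf))
        rows.append(({j: 1.0, off_y + k: ub[j]}, -inf, ub[j]))

    A = lil_matrix((len(rows), nv))
    row_lo = np.empty(len(rows))
    row_hi = np.empty(len(rows))
    for i, (coeffs, lo, hi) in enumerate(rows):
        for j, val in coeffs.items():
            A[i, j] = val
        row_lo[i], row_hi[i] = lo, hi

    S_full = lil_matrix((S.shape[0], nv))
    S_full[:, :m] = S
    constraints = [
        LinearConstraint(S_full.tocsr(), 0.0, 0.0),
        LinearConstraint(A.tocsr(), row_lo, row_hi),
    ]
    integrality = np.zeros(nv)
    integrality[m:] = 1
    bounds_lo = np.concatenate([lb, np.zeros(n_bin)])
    bounds_hi = np.concatenate([ub, np.ones(n_bin)])

    out = solve_milp(c, constraints, integrality, bounds_lo, bounds_hi, sense="max")
    if out is None:
        return None
    obj, x = out
    fluxes = {r.id: float(x[j]) for j, r in enumerate(model.reactions)}
    yp = {rid: int(round(x[off_yp + k])) for k, rid in enumerate(rH)}
    ym = {rid: int(round(x[off_ym + k])) for k, rid in enumerate(rH)}
    y = {rid: int(round(x[off_y + k])) for k, rid in enumerate(rL)}
    return ImatSolution(fluxes=fluxes, score=int(round(obj)), yplus=yp, yminus=ym, y=y)


def agreement_score(
    problem: ImatProblem, fluxes: dict[str, float], tol: float = ACTIVITY_TOL
) -> int:
    """Recompute the agreement score of a flux distribution from scratch.

    Counts rH reactions with |v| >= eps - tol plus rL reactions with
    |v| <= tol; independent of the solver's binary variables.
    """
    score = 0
    for rid in problem.calls.rH:
        if abs(fluxes[rid]) >= problem.eps - tol:
            score += 1
    for rid in problem.calls.rL:
        if abs(fluxes[rid]) <= tol:
            score += 1
    return score
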