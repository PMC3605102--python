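"""Metabolic-state prediction and FBA gene essentiality.

The metabolic state of a context model is predicted by minimizing the total
flux (the sum of all split forward/reverse fluxes) subject to every
high-frequency reaction and the biomass reaction carrying flux of at least
eps.  Reversible forced reactions get a binary direction selector so that
exactly one of the forward/reverse halves is active.  Gene essentiality is
scored by single-gene FBA deletions: a gene is essential when closing every
reaction whose GPR evaluates false without it drops the maximal biomass
flux to (numerically) zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import LinearConstraint
from scipy.sparse import hstack, lil_matrix

from .lp import InfeasibleProblem, solve_flux_lp, solve_milp, steady_state_system
from .model import MetabolicModel

__all__ = [
    "MinFluxProblem",
    "FluxState",
    "EssentialityReport",
    "minimize_total_flux",
    "fba_max_biomass",
    "single_gene_deletion",
    "predict_essential_genes",
    "essentiality_metrics",
    "write_flux_state_tsv",
]

#: Biomass optima below this count as "no growth".
GROWTH_TOL = 1e-6

#: Reported flux states suppress entries below this magnitude.
FLUX_REPORT_TOL = 1e-10


@dataclass
class MinFluxProblem:
    model: MetabolicModel
    hfr: set[str]
    biomass_id: str | None = None
    eps: float = 1.0

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.biomass_id is None:
            biomass = self.model.biomass
            if biomass is None:
                raise ValueError("model has no biomass reaction and none was named")
            self.biomass_id = biomass.id
        missing = set(self.hfr) - set(self.model.reaction_ids)
        if missing:
            raise ValueError(f"forced reactions not in model: {sorted(missing)}")


@dataclass
class FluxState:
    fluxes: dict[str, float]
    total_flux: float
    directions: dict[str, int] = field(default_factory=dict)  # forced rxn -> +1/-1


def minimize_total_flux(problem: MinFluxProblem) -> FluxState:
    """Minimum total flux with all forced reactions active.

    Splits each flux into non-negative forward and reverse components
    (v = v+ - v-, with v- fixed at zero for irreversible reactions) and
    minimizes their sum.  Each forced reversible reaction carries a binary
    y choosing the active direction: y = 1 forces v+ >= eps, y = 0 forces
    v- >= eps.  On infeasibility the forced set is re-activated one reaction
    at a time to name the first conflicting reaction.
    """
    state = _try_minimize(problem, problem.hfr)
    if state is not None:
        return state
    # incremental activation to localize the conflict
    active: set[str] = set()
    for rid in sorted(problem.hfr):
        active.add(rid)
        if _try_minimize(problem, active) is None:
            raise InfeasibleProblem(
                f"joint activation of forced reactions is infeasible; first failure "
                f"when adding {rid!r} to {sorted(active - {rid})}"
            )
    raise InfeasibleProblem("joint activation of forced reactions is infeasible")


def _try_minimize(problem: MinFluxProblem, forced: set[str]) -> FluxState | None:
    model = problem.model
    eps = problem.eps
    m = len(model.reactions)
    S, lb, ub = steady_state_system(model)

    forced = set(forced) | {problem.biomass_id}
    # variable layout: v+ (m) | v- (m) | y (reversible forced)
    up_hi = np.maximum(ub, 0.0)
    dn_hi = np.maximum(-lb, 0.0)
    rev_forced = [
        rid for rid in sorted(forced)
        if model.reaction(rid).lb < 0 and model.reaction(rid).ub > 0
    ]
    y_index = {rid: 2 * m + k for k, rid in enumerate(rev_forced)}
    nv = 2 * m + len(rev_forced)

    lo = np.zeros(nv)
    hi = np.concatenate([up_hi, dn_hi, np.ones(len(rev_forced))])
    # reactions with strictly positive lower bounds keep them on v+
    pos_lb = np.maximum(lb, 0.0)
    lo[:m] = pos_lb

    for rid in forced:
        j = model.reaction_index(rid)
        if rid in y_index:
            continue
        if ub[j] >= eps and lb[j] >= 0:
            lo[j] = max(lo[j], eps)  # irreversible forward
        elif lb[j] <= -eps and ub[j] <= 0:
            lo[m + j] = max(lo[m + j], eps)  # strictly backward
        else:
            return None  # cannot reach |v| >= eps within its own bounds

    c = np.zeros(nv)
    c[: 2 * m] = 1.0

    S_split = hstack([S, -S, lil_matrix((S.shape[0], len(rev_forced)))]).tocsr()
    constraints = [LinearConstraint(S_split, 0.0, 0.0)]

    if rev_forced:
        rows = lil_matrix((2 * len(rev_forced), nv))
        r_lo = np.empty(2 * len(rev_forced))
        r_hi = np.empty(2 * len(rev_forced))
        for k, rid in enumerate(rev_forced):
            j = model.reaction_index(rid)
            # y = 1 => v+ in [eps, ub], v- = 0 : eps*y <= v+ <= up_hi*y
            rows[2 * k, j] = 1.0
            rows[2 * k, y_index[rid]] = -eps
            r_lo[2 * k], r_hi[2 * k] = 0.0, np.inf
            rows[2 * k + 1, j] = 1.0
            rows[2 * k + 1, y_index[rid]] = -up_hi[j]
            r_lo[2 * k + 1], r_hi[2 * k + 1] = -np.inf, 0.0
        constraints.append(LinearConstraint(rows.tocsr(), r_lo, r_hi))
        # y = 0 => v- in [eps, -lb], v+ = 0 : eps*(1-y) <= v- <= dn_hi*(1-y)
        rows2 = lil_matrix((2 * len(rev_forced), nv))
        r2_lo = np.empty(2 * len(rev_forced))
        r2_hi = np.empty(2 * len(rev_forced))
        for k, rid in enumerate(rev_forced):
            j = model.reaction_index(rid)
            rows2[2 * k, m + j] = 1.0
            rows2[2 * k, y_index[rid]] = eps
            r2_lo[2 * k], r2_hi[2 * k] = eps, np.inf
            rows2[2 * k + 1, m + j] = 1.0
            rows2[2 * k + 1, y_index[rid]] = dn_hi[j]
            r2_lo[2 * k + 1], r2_hi[2 * k + 1] = -np.inf, dn_hi[j]
        constraints.append(LinearConstraint(rows2.tocsr(), r2_lo, r2_hi))

    integrality = np.zeros(nv)
    integrality[2 * m:] = 1

    out = solve_milp(c, constraints, integrality, lo, hi, sense="min")
    if out is None:
        return None
    total, x = out
    vplus, vminus = x[:m], x[m: 2 * m]
    both = np.minimum(vplus, vminus)
    if both.max(initial=0.0) > 1e-6:  # pragma: no cover - excluded at optimality
        warnings.warn("simultaneous forward and reverse flux in reported optimum", stacklevel=2)
    v = vplus - vminus
    fluxes = {r.id: float(v[j]) for j, r in enumerate(model.reactions)}
    directions = {}
    for rid in sorted(forced):
        directions[rid] = 1 if fluxes[rid] >= 0 else -1
    return FluxState(fluxes=fluxes, total_flux=float(total), directions=directions)


# --------------------------------------------------------------------------
# FBA and essentiality
# --------------------------------------------------------------------------


def fba_max_biomass(model: MetabolicModel, biomass_id: str | None = None) -> float:
    """LP maximum of the biomass flux; 0 (with a warning) if infeasible."""
    if biomass_id is None:
        biomass = model.biomass
        if biomass is None:
            raise ValueError("model has no biomass reaction and none was named")
        biomass_id = biomass.id
    res = solve_flux_lp(model, {biomass_id: 1.0}, sense="max")
    if res.status == "infeasible":
        warnings.warn("FBA infeasible; reporting zero growth", stacklevel=2)
        return 0.0
    if res.status == "unbounded":
        return float(model.reaction(biomass_id).ub)
    return float(res.objective)


def knockout_bounds(model: MetabolicModel, genes: set[str]) -> dict[str, tuple[float, float]]:
    """Bounds overrides closing every reaction lost without `genes`.

    Two-valued GPR evaluation with the deleted genes false and every other
    gene true; reactions whose rule evaluates false get bounds [0, 0].
    """
    absent = {g: False for g in genes}
    closed = {}
    for rxn in model.reactions:
        if rxn.gpr.is_empty:
            continue
        if not rxn.gpr.evaluate(absent):
            closed[rxn.id] = (0.0, 0.0)
    return closed


def single_gene_deletion(
    model: MetabolicModel,
    gene: str,
    biomass_id: str | None = None,
    growth_tol: float = GROWTH_TOL,
) -> tuple[float, bool]:
    """(residual growth, essential?) after deleting one gene."""
    if gene not in model.genes:
        raise ValueError(f"gene {gene!r} not in model")
    if biomass_id is None:
        biomass = model.biomass
        if biomass is None:
            raise ValueError("model has no biomass reaction and none was named")
        biomass_id = biomass.id
    overrides = knockout_bounds(model, {gene})
    res = solve_flux_lp(model, {biomass_id: 1.0}, sense="max", extra_bounds=overrides)
    growth = 0.0 if res.status == "infeasible" else float(res.objective or 0.0)
    return growth, growth < growth_tol


def predict_essential_genes(
    model: MetabolicModel,
    biomass_id: str | None = None,
    growth_tol: float = GROWTH_TOL,
) -> set[str]:
    """All genes whose single deletion abolishes growth."""
    return {
        g
        for g in sorted(model.genes)
        if single_gene_deletion(model, g, biomass_id, growth_tol)[1]
    }


@dataclass
class EssentialityReport:
    tp: int
    fp: int
    fn: int
    sensitivity: float | None
    ppv: float | None
    classes: dict[str, str] = field(default_factory=dict)  # gene -> tp/fp/fn/tn/excluded


def essentiality_metrics(
    predicted: set[str],
    observed: set[str],
    universe: set[str],
    excluded: set[str] = frozenset(),
) -> EssentialityReport:
    """Sensitivity tp/(tp+fn) and PPV tp/(tp+fp) of essentiality calls.

    `excluded` genes (for instance genes already essential in a reference
    condition, for which no deletion mutant exists) are removed from both
    the predicted and the observed sets before counting.
    """
    if not predicted <= universe or not observed <= universe:
        raise ValueError("predicted and observed must be subsets of the universe")
    pred = predicted - excluded
    obs = observed - excluded
    classes: dict[str, str] = {}
    for g in sorted(universe):
        if g in excluded:
            classes[g] = "excluded"
        elif g in pred and g in obs:
            classes[g] = "tp"
        elif g in pred:
            classes[g] = "fp"
        elif g in obs:
            classes[g] = "fn"
        else:
            classes[g] = "tn"
    tp = sum(1 for c in classes.values() if c == "tp")
    fp = sum(1 for c in classes.values() if c == "fp")
    fn = sum(1 for c in classes.values() if c == "fn")
    sensitivity = tp / (tp + fn) if tp + fn else None
    ppv = tp / (tp + fp) if tp + fp else None
    return EssentialityReport(tp=tp, fp=fp, fn=fn, sensitivity=sensitivity, ppv=ppv, classes=classes)


def write_flux_state_tsv(state: FluxState, model: MetabolicModel, path) -> None:
    """Flux table: id, name, stoichiometry, genes, flux (small fluxes hidden)."""
    from .model import format_reaction_equation

    with open(path, "w") as fh:
        fh.write(f"# total_flux\t{state.total_flux!r}\n")
        fh.write("reaction\tname\tstoichiometry\tgenes\tflux\n")
        for rxn in model.reactions:
            v = state.fluxes[rxn.id]
            if abs(v) < FLUX_REPORT_TOL:
                continue
            genes = " ".join(sorted(rxn.gpr.genes()))
            fh.write(
                f"{rxn.id}\t{rxn.name}\t{format_reaction_equation(rxn)}\t{genes}\t{v!r}\n"
            )
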