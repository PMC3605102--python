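"""Environment-agnostic preprocessing: open exchanges, trim dead ends.

Modeling growth in an uncharacterized environment starts by allowing free
uptake or secretion of every exchange metabolite, then removing reactions
that can never carry flux (dead ends) so the working model is gapless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .lp import solve_flux_lp, steady_state_system
from .model import MetabolicModel

__all__ = ["FvaResult", "open_exchanges", "flux_variability", "trim_dead_ends"]

#: LP optima below this magnitude count as "cannot carry flux".
BLOCKED_TOL = 1e-9


@dataclass
class FvaResult:
    """Per-reaction feasible flux ranges (vmin, vmax)."""

    ranges: dict[str, tuple[float, float]]

    def __getitem__(self, reaction_id: str) -> tuple[float, float]:
        return self.ranges[reaction_id]

    def blocked(self, tol: float = BLOCKED_TOL) -> list[str]:
        return [
            rid
            for rid, (vmin, vmax) in self.ranges.items()
            if max(abs(vmin), abs(vmax)) < tol
        ]


def open_exchanges(model: MetabolicModel, bound_magnitude: float = 1000.0) -> MetabolicModel:
    """Set every exchange reaction's bounds to [-M, +M].

    Exchange reactions import or export a single metabolite across the
    system boundary; opening them models complete ignorance of nutrient
    availability.  Internal reactions are untouched.
    """
    if bound_magnitude <= 0:
        raise ValueError("bound_magnitude must be positive")
    exchanges = model.exchanges
    if not exchanges:
        warnings.warn("model has no exchange reactions; returned unchanged", stacklevel=2)
        return model
    overrides = {r.id: (-bound_magnitude, bound_magnitude) for r in exchanges}
    return model.set_bounds(overrides)


def flux_variability(
    model: MetabolicModel,
    reactions: list[str] | None = None,
) -> FvaResult:
    """Minimum and maximum feasible steady-state flux per reaction.

    Two LPs per reaction over {v : S v = 0, lb <= v <= ub}; no growth
    constraint is imposed, so the ranges are those used for dead-end
    detection.  Unbounded optima are clamped to the reaction's own bounds.
    """
    system = steady_state_system(model)
    targets = reactions if reactions is not None else model.reaction_ids
    ranges: dict[str, tuple[float, float]] = {}
    for rid in targets:
        rxn = model.reaction(rid)
        lo = _one_direction(model, rid, "min", system)
        hi = _one_direction(model, rid, "max", system)
        if lo is None:
            lo = rxn.lb
        if hi is None:
            hi = rxn.ub
        ranges[rid] = (min(lo, hi), max(lo, hi))
    return FvaResult(ranges)


def _one_direction(model, rid, sense, system) -> float | None:
    res = solve_flux_lp(model, {rid: 1.0}, sense=sense, S_lb_ub=system)
    if res.status == "infeasible":
        raise ValueError(
            "model is infeasible at steady state; check that 0 is within every reaction's bounds"
        )
    if res.status == "unbounded":
        return None
    return float(res.objective)


def trim_dead_ends(model: MetabolicModel, tol: float = BLOCKED_TOL) -> MetabolicModel:
    """Remove blocked reactions (and then orphan metabolites) to a fixed point.

    A reaction is blocked when its FVA range lies within (-tol, +tol).
    Removal can newly block other reactions, so FVA is iterated until a full
    pass removes nothing; the result is flux-consistent (every remaining
    reaction can carry |v| >= tol).
    """
    current = model
    while True:
        fva = flux_variability(current)
        blocked = fva.blocked(tol)
        if not blocked:
            break
        current = current.drop_reactions(blocked)
        if not current.reactions:
            raise ValueError("trimming removed every reaction; degenerate input model")
    # MetabolicModel construction already drops metabolites not referenced
    # by any reaction, so orphan removal is implicit.
    return current
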