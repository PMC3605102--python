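"""Environment-specific model construction: ZFR deletion + greedy pruning.

A context model is built in two steps: delete every zero-frequency reaction,
then prune the remaining non-core reactions with a greedy model-building
sweep under the constraint that every high-frequency (core) reaction stays
able to carry flux.  Candidate removals are visited in seeded random order
and sweeps repeat until a whole sweep removes nothing, so the output is
locally minimal: removing any single remaining non-core reaction would
block some core reaction.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .alt_optima import FrequencySets
from .model import MetabolicModel
from .preprocess import BLOCKED_TOL, flux_variability

__all__ = ["ContextModel", "check_core_consistency", "mba_prune", "build_context_model"]


@dataclass
class ContextModel:
    model: MetabolicModel
    core: set[str]
    removed: list[tuple[str, str]] = field(default_factory=list)  # (reaction, stage)
    seed: int = 0


def check_core_consistency(
    model: MetabolicModel, core: set[str], tol: float = BLOCKED_TOL
) -> list[str]:
    """Core reactions unable to carry flux of magnitude >= tol, by FVA."""
    present = [rid for rid in sorted(core) if rid in model]
    missing = set(core) - set(present)
    if missing:
        return sorted(missing)
    fva = flux_variability(model, present)
    return [
        rid for rid in present
        if max(abs(fva[rid][0]), abs(fva[rid][1])) < tol
    ]


def _blocks_core(model: MetabolicModel, core: set[str], tol: float) -> bool:
    """True if some core reaction cannot carry flux in `model` (early exit)."""
    present = [rid for rid in core if rid in model]
    if len(present) < len(core):
        return True
    from .lp import solve_flux_lp, steady_state_system

    system = steady_state_system(model)
    for rid in present:
        hi = solve_flux_lp(model, {rid: 1.0}, sense="max", S_lb_ub=system)
        if hi.status == "unbounded" or (hi.status == "optimal" and hi.objective >= tol):
            continue
        lo = solve_flux_lp(model, {rid: 1.0}, sense="min", S_lb_ub=system)
        if lo.status == "unbounded" or (lo.status == "optimal" and lo.objective <= -tol):
            continue
        return True
    return False


def mba_prune(
    model: MetabolicModel, core: set[str], seed: int = 0, tol: float = BLOCKED_TOL
) -> ContextModel:
    """Greedy removal of non-core reactions preserving core flux consistency.

    Visits non-core reactions in seeded random order; each is tentatively
    removed and restored if any core reaction becomes blocked.  Repeats
    sweeps until a fixed point.  Raises if the input model is already
    inconsistent with respect to the core.
    """
    blocked = check_core_consistency(model, core, tol)
    if blocked:
        raise ValueError(f"core reactions blocked in the input model: {blocked}")
    rng = random.Random(seed)
    current = model
    removed: list[tuple[str, str]] = []
    while True:
        candidates = [r.id for r in current.reactions if r.id not in core]
        rng.shuffle(candidates)
        removed_this_sweep = 0
        for rid in candidates:
            trial = current.drop_reactions([rid])
            if not trial.reactions or _blocks_core(trial, core, tol):
                continue
            current = trial
            removed.append((rid, "pruned"))
            removed_this_sweep += 1
        if removed_this_sweep == 0:
            break
    return ContextModel(model=current, core=set(core), removed=removed, seed=seed)


def build_context_model(
    parent: MetabolicModel,
    freq: FrequencySets,
    seed: int = 0,
    tol: float = BLOCKED_TOL,
) -> ContextModel:
    """Delete ZFR, then prune toward the HFR core.

    Raises with the conflict set if deleting the zero-frequency reactions
    blocks any high-frequency reaction.
    """
    without_zfr = parent.drop_reactions(freq.ZFR)
    conflicts = check_core_consistency(without_zfr, freq.HFR, tol)
    if conflicts:
        raise ValueError(
            f"deleting ZFR blocks high-frequency reactions: {conflicts}"
        )
    ctx = mba_prune(without_zfr, set(freq.HFR), seed=seed, tol=tol)
    ctx.removed = [(rid, "zfr") for rid in sorted(freq.ZFR)] + ctx.removed
    return ctx
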