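"""Test fixtures and small-network oracles.

Provides three things every stage can be tested against without external
data: (i) a ten-reaction toy network in which a five-carbon biomass
precursor is synthesized from a two-carbon and/or a three-carbon substrate,
with expression calls covering five reactions; (ii) exhaustive oracles for
small networks -- support-minimal route enumeration and brute-force
agreement-score maximization over classified-reaction decisions, both built
on plain LP/MILP feasibility and independent of the production iMAT solver;
(iii) a seeded synthetic-network generator that plants a flux-consistent
active pathway with matching expression calls.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import LinearConstraint

from .alt_optima import FrequencySets
from .expression import ExpressionCalls
from .imat import ACTIVITY_TOL, ImatProblem
from .lp import solve_flux_lp, solve_milp, steady_state_system
from .model import GprRule, MetabolicModel, Reaction, parse_gpr

__all__ = [
    "toy_network",
    "enumerate_flux_modes",
    "enumerate_optimal_patterns",
    "brute_force_max_score",
    "exhaustive_frequency_sets",
    "SyntheticSpec",
    "PlantedTruth",
    "generate_synthetic",
]

#: Largest network the exponential oracles will accept.
ORACLE_MAX_SIZE = 20


# --------------------------------------------------------------------------
# The toy network
# --------------------------------------------------------------------------


def toy_network() -> tuple[MetabolicModel, ExpressionCalls]:
    """Ten-reaction toy network plus its gene-expression calls.

    A five-carbon biomass precursor E5 can be condensed from a two-carbon
    unit (C2) and a three-carbon unit (D3), directly from the two-carbon
    substrate A2 and D3, or from the three-carbon substrate B3 and C2.  The
    carbon units interconvert (2 D3 = 3 C2 worth of carbon in either
    direction), so the precursor can be reached from either substrate alone
    or from both together: eight support-minimal routes in total, two of
    which survive when the two-carbon uptake is closed.

    Five reactions carry expression calls.  r3 is catalyzed by either of
    two isoenzymes (OR), both lowly expressed; r7 by a two-subunit complex
    (AND) with one subunit lowly expressed, so r7 is called low as well.
    r2, r5 and r6 are highly expressed.  The agreement-score optimum is 4:
    no flux distribution can satisfy all five calls because every C2 supply
    goes through r3 or r7, one of which must therefore run against its
    "low" call whenever r5 is active.
    """
    rxn = [
        Reaction("r1", {"A2[c]": 1.0}, 0.0, 10.0, name="2C substrate uptake"),
        Reaction("r2", {"B3[c]": 1.0}, 0.0, 10.0, name="3C substrate uptake",
                 gpr=parse_gpr("g2")),
        Reaction("r3", {"A2[c]": -1.0, "C2[c]": 1.0}, 0.0, 1000.0,
                 name="A2 -> C2", gpr=parse_gpr("g3a OR g3b")),
        Reaction("r4", {"B3[c]": -1.0, "D3[c]": 1.0}, 0.0, 1000.0, name="B3 -> D3"),
        Reaction("r5", {"C2[c]": -1.0, "D3[c]": -1.0, "E5[c]": 1.0}, 0.0, 1000.0,
                 name="condensation C2 + D3", gpr=parse_gpr("g5")),
        Reaction("r6", {"E5[c]": -1.0}, 0.0, 1000.0, name="biomass precursor drain",
                 gpr=parse_gpr("g6"), is_biomass=True),
        Reaction("r7", {"B3[c]": -2.0, "C2[c]": 3.0}, 0.0, 1000.0,
                 name="2 B3 -> 3 C2", gpr=parse_gpr("g7a AND g7b")),
        Reaction("r8", {"A2[c]": -3.0, "D3[c]": 2.0}, 0.0, 1000.0, name="3 A2 -> 2 D3"),
        Reaction("r9", {"A2[c]": -1.0, "D3[c]": -1.0, "E5[c]": 1.0}, 0.0, 1000.0,
                 name="condensation A2 + D3"),
        Reaction("r10", {"B3[c]": -1.0, "C2[c]": -1.0, "E5[c]": 1.0}, 0.0, 1000.0,
                 name="condensation B3 + C2"),
    ]
    model = MetabolicModel(rxn, id="toy")
    calls = ExpressionCalls(
        {"g2": 1, "g3a": -1, "g3b": -1, "g5": 1, "g6": 1, "g7a": 1, "g7b": -1}
    )
    return model, calls


# --------------------------------------------------------------------------
# Support-minimal route enumeration
# --------------------------------------------------------------------------


def _check_size(model: MetabolicModel, max_size: int) -> None:
    if len(model.reactions) > max_size:
        raise ValueError(
            f"oracle refused: model has {len(model.reactions)} reactions "
            f"(> {max_size}); exhaustive enumeration is exponential"
        )


def enumerate_flux_modes(
    model: MetabolicModel,
    max_size: int = ORACLE_MAX_SIZE,
    min_flux: float = 1e-2,
    biomass_id: str | None = None,
) -> list[dict[str, int]]:
    """All support-minimal steady-state routes producing the biomass precursor.

    A route is a signed support: a set of reactions each with a direction
    (+1 forward, -1 reverse) admitting a feasible steady-state flux vector
    with every listed reaction at |v| >= min_flux, the biomass reaction
    active, and every unlisted reaction at zero; minimal in that no proper
    signed subset is feasible.  Enumeration is by MILP over binary support
    indicators, repeatedly excluding supersets of found routes with no-good
    cuts while minimizing support size, which visits minimal supports in
    nondecreasing cardinality until the problem becomes infeasible.
    """
    _check_size(model, max_size)
    if biomass_id is None:
        biomass = model.biomass
        if biomass is None:
            raise ValueError("model has no biomass reaction and none was named")
        biomass_id = biomass.id
    m = len(model.reactions)
    S, lb, ub = steady_state_system(model)
    up_hi = np.maximum(ub, 0.0)
    dn_hi = np.maximum(-lb, 0.0)

    # variable layout: v+ (m) | v- (m) | a+ (m) | a- (m)
    nv = 4 * m
    from scipy.sparse import hstack, lil_matrix

    S_split = hstack([S, -S, lil_matrix((S.shape[0], 2 * m))]).tocsr()

    rows = lil_matrix((5 * m, nv))
    r_lo = np.full(5 * m, -np.inf)
    r_hi = np.full(5 * m, np.inf)
    for j in range(m):
        # v+ <= up_hi * a+ ; v+ >= min_flux * a+
        rows[5 * j, j] = 1.0
        rows[5 * j, 2 * m + j] = -up_hi[j]
        r_hi[5 * j] = 0.0
        rows[5 * j + 1, j] = 1.0
        rows[5 * j + 1, 2 * m + j] = -min_flux
        r_lo[5 * j + 1] = 0.0
        # v- <= dn_hi * a- ; v- >= min_flux * a-
        rows[5 * j + 2, m + j] = 1.0
        rows[5 * j + 2, 3 * m + j] = -dn_hi[j]
        r_hi[5 * j + 2] = 0.0
        rows[5 * j + 3, m + j] = 1.0
        rows[5 * j + 3, 3 * m + j] = -min_flux
        r_lo[5 * j + 3] = 0.0
        # one direction at a time
        rows[5 * j + 4, 2 * m + j] = 1.0
        rows[5 * j + 4, 3 * m + j] = 1.0
        r_hi[5 * j + 4] = 1.0

    lo = np.zeros(nv)
    hi = np.concatenate([up_hi, dn_hi, np.ones(2 * m)])
    jb = model.reaction_index(biomass_id)
    for j in range(m):
        if up_hi[j] < min_flux:
            hi[2 * m + j] = 0.0  # forward direction unreachable
        if dn_hi[j] < min_flux:
            hi[3 * m + j] = 0.0

    c = np.zeros(nv)
    c[2 * m:] = 1.0
    integrality = np.zeros(nv)
    integrality[2 * m:] = 1

    base = [LinearConstraint(S_split, 0.0, 0.0), LinearConstraint(rows.tocsr(), r_lo, r_hi)]
    cuts: list[LinearConstraint] = []
    # biomass must be active in some direction
    bio_row = lil_matrix((1, nv))
    bio_row[0, 2 * m + jb] = 1.0
    bio_row[0, 3 * m + jb] = 1.0
    base.append(LinearConstraint(bio_row.tocsr(), 1.0, 1.0))

    routes: list[dict[str, int]] = []
    while True:
        out = solve_milp(c, base + cuts, integrality, lo, hi, sense="min")
        if out is None:
            break
        _, x = out
        signed: dict[str, int] = {}
        cut_row = lil_matrix((1, nv))
        count = 0
        for j, rid in enumerate(model.reaction_ids):
            if x[2 * m + j] > 0.5:
                signed[rid] = +1
                cut_row[0, 2 * m + j] = 1.0
                count += 1
            elif x[3 * m + j] > 0.5:
                signed[rid] = -1
                cut_row[0, 3 * m + j] = 1.0
                count += 1
        routes.append(signed)
        cuts.append(LinearConstraint(cut_row.tocsr(), -np.inf, count - 1))
    return routes


def route_is_feasible(
    model: MetabolicModel,
    route: dict[str, int],
    min_flux: float = 1e-2,
    biomass_id: str | None = None,
) -> bool:
    """LP check that a signed support admits a feasible route."""
    overrides: dict[str, tuple[float, float]] = {}
    for rxn in model.reactions:
        sign = route.get(rxn.id, 0)
        if sign == 0:
            overrides[rxn.id] = (0.0, 0.0)
        elif sign > 0:
            overrides[rxn.id] = (min_flux, rxn.ub)
        else:
            overrides[rxn.id] = (rxn.lb, -min_flux)
    target = biomass_id or model.biomass.id
    res = solve_flux_lp(model, {target: 1.0}, sense="max", extra_bounds=overrides)
    return res.status != "infeasible"


def route_is_minimal(
    model: MetabolicModel,
    route: dict[str, int],
    min_flux: float = 1e-2,
    biomass_id: str | None = None,
) -> bool:
    """True if removing any single active reaction kills the route."""
    if not route_is_feasible(model, route, min_flux, biomass_id):
        return False
    for rid in route:
        sub = {k: v for k, v in route.items() if k != rid}
        if route_is_feasible(model, sub, min_flux, biomass_id):
            return False
    return True


# --------------------------------------------------------------------------
# Brute-force agreement-score oracle
# --------------------------------------------------------------------------


def _decision_bounds(model, rid, decision, eps):
    rxn = model.reaction(rid)
    if decision == "forward":
        return (max(rxn.lb, eps), rxn.ub)
    if decision == "reverse":
        return (rxn.lb, min(rxn.ub, -eps))
    if decision == "off":
        return (0.0, 0.0)
    raise ValueError(decision)


def _assignment_feasible(problem, assignment, extra=None) -> bool:
    model = problem.model
    overrides = {
        rid: _decision_bounds(model, rid, d, problem.eps)
        for rid, d in assignment.items()
    }
    if extra:
        for rid, (lo, hi) in extra.items():
            cur = overrides.get(rid, (model.reaction(rid).lb, model.reaction(rid).ub))
            overrides[rid] = (max(cur[0], lo), min(cur[1], hi))
            if overrides[rid][0] > overrides[rid][1]:
                return False
    bio = problem.biomass_id
    cur = overrides.get(bio, (model.reaction(bio).lb, model.reaction(bio).ub))
    overrides[bio] = (max(cur[0], problem.biomass_min), cur[1])
    if overrides[bio][0] > overrides[bio][1]:
        return False
    res = solve_flux_lp(model, {}, sense="min", extra_bounds=overrides)
    return res.status != "infeasible"


def _enumerate_assignments(problem):
    """Yield (assignment, score) over all classified-reaction decisions.

    For each highly expressed reaction the options are: force forward flux
    >= eps, force reverse flux <= -eps (reversible only), or leave it
    unconstrained and uncounted.  For each lowly expressed reaction: pin to
    zero, or leave unconstrained and uncounted.  The score of an assignment
    is the number of enforced decisions; feasibility is a plain LP check.
    """
    model = problem.model
    rH = sorted(problem.calls.rH)
    rL = sorted(problem.calls.rL)
    options = []
    for rid in rH:
        opts = [None, "forward"]
        if model.reaction(rid).lb < 0:
            opts.append("reverse")
        options.append((rid, opts))
    for rid in rL:
        options.append((rid, [None, "off"]))
    for combo in itertools.product(*(opts for _, opts in options)):
        assignment = {
            rid: dec for (rid, _), dec in zip(options, combo) if dec is not None
        }
        yield assignment, len(assignment)


def brute_force_max_score(problem: ImatProblem, max_size: int = ORACLE_MAX_SIZE) -> int:
    """Exhaustive maximum agreement score, by LP feasibility per decision set.

    Independent of the MILP path: enumerates every combination of
    directional activations for rH and inactivations for rL, checks each by
    one LP, and returns the largest feasible decision count.
    """
    _check_size(problem.model, max_size)
    best = -1
    candidates = sorted(
        _enumerate_assignments(problem), key=lambda t: -t[1]
    )
    for assignment, score in candidates:
        if score <= best:
            break  # sorted by score: nothing better remains
        if _assignment_feasible(problem, assignment):
            best = score
    if best < 0:
        raise ValueError("problem infeasible: biomass cannot carry flux")
    return best


def enumerate_optimal_patterns(
    problem: ImatProblem, max_size: int = ORACLE_MAX_SIZE
) -> list[dict[str, str]]:
    """All maximal-score activity patterns over the classified reactions.

    A pattern maps each enforced reaction to its decision ("forward",
    "reverse" or "off"); reactions left free do not appear.  Patterns whose
    enforced decisions are feasible and count up to the global optimum are
    returned.  Exhaustive (LP per pattern), so restricted to small models.
    """
    _check_size(problem.model, max_size)
    s_star = brute_force_max_score(problem, max_size)
    return [
        assignment
        for assignment, score in _enumerate_assignments(problem)
        if score == s_star and _assignment_feasible(problem, assignment)
    ]


def exhaustive_frequency_sets(
    problem: ImatProblem,
    max_size: int = ORACLE_MAX_SIZE,
    activity_tol: float = ACTIVITY_TOL,
) -> FrequencySets:
    """HFR/ZFR over *all* optimal solutions, by LP sweeps per pattern.

    A reaction belongs to the exhaustive HFR iff no optimal pattern admits a
    solution with that reaction at zero, and to the exhaustive ZFR iff no
    optimal pattern admits a solution with |v| above the activity tolerance.
    This is the ground truth that the modulation heuristic approximates from
    a subset of optima.
    """
    patterns = enumerate_optimal_patterns(problem, max_size)
    model = problem.model
    hfr: set[str] = set()
    zfr: set[str] = set()
    for rid in model.reaction_ids:
        rxn = model.reaction(rid)
        can_zero = any(
            _assignment_feasible(problem, pat, extra={rid: (0.0, 0.0)})
            for pat in patterns
        )
        can_fwd = rxn.ub >= activity_tol and any(
            _assignment_feasible(problem, pat, extra={rid: (activity_tol, rxn.ub)})
            for pat in patterns
        )
        can_rev = rxn.lb <= -activity_tol and any(
            _assignment_feasible(problem, pat, extra={rid: (rxn.lb, -activity_tol)})
            for pat in patterns
        )
        if not can_zero:
            hfr.add(rid)
        if not (can_fwd or can_rev):
            zfr.add(rid)
    freqs = {rid: (len(patterns) if rid in hfr else 0) for rid in model.reaction_ids}
    return FrequencySets(HFR=hfr, ZFR=zfr, frequencies=freqs, n_solutions=len(patterns))


# --------------------------------------------------------------------------
# Synthetic networks with planted active subnetworks
# --------------------------------------------------------------------------


@dataclass
class SyntheticSpec:
    """Recipe for a seeded synthetic network.

    The planted subnetwork is a linear pathway: substrate uptake, a chain of
    `planted_len` conversions, and a biomass drain; it is flux-consistent by
    construction and is the unique minimal subnetwork in which all planted
    reactions carry flux.  Remaining reactions are decoy branches hanging
    off chain metabolites, each ending in its own exchange so the generated
    model has no dead ends.  Expression calls are +1 on planted reactions'
    genes, -1 on a sampled fraction of decoy genes, and each non-zero call
    is flipped with probability `noise_rate`.
    """

    seed: int
    n_reactions: int = 30
    planted_len: int = 6
    frac_reversible: float = 0.2
    low_call_frac: float = 0.6
    noise_rate: float = 0.0
    bound: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_reactions < self.planted_len + 2:
            raise ValueError("n_reactions must cover the planted pathway plus its exchanges")
        if self.planted_len < 1:
            raise ValueError("planted pathway needs at least one conversion")
        if not (0 <= self.noise_rate < 1):
            raise ValueError("noise_rate must be in [0, 1)")


@dataclass
class PlantedTruth:
    planted_reactions: set[str] = field(default_factory=set)
    planted_genes: set[str] = field(default_factory=set)
    decoy_reactions: set[str] = field(default_factory=set)


def generate_synthetic(spec: SyntheticSpec) -> tuple[MetabolicModel, ExpressionCalls, PlantedTruth]:
    """Seeded synthetic model, expression calls and planted ground truth."""
    rng = random.Random(spec.seed)
    B = spec.bound
    reactions: list[Reaction] = []
    truth = PlantedTruth()
    calls: dict[str, int] = {}

    # planted pathway: EX_S -> M0 -> M1 -> ... -> M_{k-1} -> biomass drain
    k = spec.planted_len
    reactions.append(Reaction("EX_substrate", {"M0": 1.0}, 0.0, B, name="substrate uptake"))
    truth.planted_reactions.add("EX_substrate")
    for i in range(1, k):
        rid = f"P{i}"
        gene = f"g_{rid}"
        reactions.append(
            Reaction(rid, {f"M{i-1}": -1.0, f"M{i}": 1.0}, 0.0, B, gpr=GprRule.gene(gene))
        )
        truth.planted_reactions.add(rid)
        truth.planted_genes.add(gene)
        calls[gene] = 1
    reactions.append(
        Reaction(
            "BIOMASS", {f"M{k-1}": -1.0}, 0.0, B,
            gpr=GprRule.gene("g_BIOMASS"), is_biomass=True, name="biomass drain",
        )
    )
    truth.planted_reactions.add("BIOMASS")
    truth.planted_genes.add("g_BIOMASS")
    calls["g_BIOMASS"] = 1

    # decoy branches: chain metabolite -> Dj, plus an exchange for Dj
    n_branches = max(0, (spec.n_reactions - len(reactions)) // 2)
    for j in range(n_branches):
        src = f"M{rng.randrange(k)}"
        met = f"D{j}"
        rid = f"X{j}"
        reversible = rng.random() < spec.frac_reversible
        lb = -B if reversible else 0.0
        if rng.random() < 0.3:
            # occasional two-gene rule: isoenzymes or a complex
            op = rng.choice(["OR", "AND"])
            gpr = parse_gpr(f"g_{rid}a {op} g_{rid}b")
            genes = [f"g_{rid}a", f"g_{rid}b"]
        else:
            gpr = GprRule.gene(f"g_{rid}")
            genes = [f"g_{rid}"]
        reactions.append(Reaction(rid, {src: -1.0, met: 1.0}, lb, B, gpr=gpr))
        reactions.append(Reaction(f"EX_{met}", {met: -1.0}, 0.0, B))
        truth.decoy_reactions |= {rid, f"EX_{met}"}
        if rng.random() < spec.low_call_frac:
            for g in genes:
                calls[g] = -1
        else:
            for g in genes:
                calls[g] = 0

    if spec.noise_rate > 0:
        for gene, call in list(calls.items()):
            if call != 0 and rng.random() < spec.noise_rate:
                calls[gene] = -call

    model = MetabolicModel(reactions, id=f"synthetic-seed{spec.seed}")
    return model, ExpressionCalls(calls), truth
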