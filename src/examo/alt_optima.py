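"""Exploration of alternative optimal agreement-score solutions.

The flux distribution returned by a single iMAT solve is one of possibly
many attaining the maximal agreement score.  To sample that space, every
reaction is forced in turn to be inactive, to carry forward flux of at
least eps, and -- if reversible -- to carry reverse flux; each modulated
problem is re-solved and only solutions that still attain the global
optimum are retained.  Reactions active in every retained solution form the
high-frequency set (HFR, predicted active); reactions active in none form
the zero-frequency set (ZFR, predicted inactive).

The modulation scheme samples a subset of all optima, so HFR can only
shrink and ZFR only grow if more optima were seen; exhaustive enumeration
on small instances (see :mod:`examo.fixtures`) bounds the difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .imat import ACTIVITY_TOL, ImatProblem, ImatSolution, solve_imat, try_solve_imat

__all__ = ["Modulation", "OptimaEnsemble", "FrequencySets", "explore_optima",
           "classify_frequencies", "write_frequency_tsv"]

#: Componentwise flux tolerance for "same distribution" deduplication.
DEDUP_TOL = 1e-6


@dataclass(frozen=True)
class Modulation:
    """The bound change that produced one retained solution."""

    reaction_id: str | None  # None for the unmodified baseline
    mode: str  # "none" | "off" | "forward" | "reverse"


@dataclass
class OptimaEnsemble:
    problem: ImatProblem
    score: int
    solutions: list[ImatSolution]
    provenance: list[Modulation]
    failures: list[Modulation] = field(default_factory=list)  # infeasible or suboptimal
    activity_tol: float = ACTIVITY_TOL

    @property
    def activity_count(self) -> dict[str, int]:
        counts = {rid: 0 for rid in self.problem.model.reaction_ids}
        for sol in self.solutions:
            for rid in sol.active_set(self.activity_tol):
                counts[rid] += 1
        return counts

    @property
    def distinct_count(self) -> int:
        """Number of distinct flux distributions after deduplication."""
        distinct: list[ImatSolution] = []
        order = self.problem.model.reaction_ids
        for sol in self.solutions:
            if not any(
                all(abs(sol.fluxes[r] - kept.fluxes[r]) <= DEDUP_TOL for r in order)
                for kept in distinct
            ):
                distinct.append(sol)
        return len(distinct)


@dataclass
class FrequencySets:
    HFR: set[str]
    ZFR: set[str]
    frequencies: dict[str, int] = field(default_factory=dict)
    n_solutions: int = 0

    def __post_init__(self) -> None:
        if self.HFR & self.ZFR:
            raise ValueError("HFR and ZFR must be disjoint")


def explore_optima(problem: ImatProblem) -> OptimaEnsemble:
    """Gather alternative optimal solutions by per-reaction modulation.

    Baseline solve first (its score s* is the retention criterion), then for
    each reaction: force off (v = 0), force forward (v >= eps), and for
    reversible reactions force reverse (v <= -eps).  Modulations that are
    infeasible or score below s* are recorded as failures and discarded.
    """
    baseline = solve_imat(problem)
    s_star = baseline.score
    solutions = [baseline]
    provenance = [Modulation(None, "none")]
    failures: list[Modulation] = []
    eps = problem.eps
    for rxn in problem.model.reactions:
        variants = [("off", (0.0, 0.0)), ("forward", (eps, rxn.ub))]
        if rxn.lb < 0:
            variants.append(("reverse", (rxn.lb, -eps)))
        for mode, (lo, hi) in variants:
            mod = Modulation(rxn.id, mode)
            if lo > hi:  # e.g. forcing forward flux through a strictly backward reaction
                failures.append(mod)
                continue
            sol = try_solve_imat(problem, extra_bounds={rxn.id: (lo, hi)})
            if sol is None or sol.score < s_star:
                failures.append(mod)
            else:
                solutions.append(sol)
                provenance.append(mod)
    return OptimaEnsemble(problem, s_star, solutions, provenance, failures)


def classify_frequencies(
    ensemble: OptimaEnsemble, activity_tol: float = ACTIVITY_TOL
) -> FrequencySets:
    """HFR / ZFR from per-reaction activity counts over retained solutions."""
    if not ensemble.solutions:
        raise ValueError("ensemble is empty")
    ensemble.activity_tol = activity_tol
    counts = ensemble.activity_count
    total = len(ensemble.solutions)
    hfr = {rid for rid, cnt in counts.items() if cnt == total}
    zfr = {rid for rid, cnt in counts.items() if cnt == 0}
    return FrequencySets(HFR=hfr, ZFR=zfr, frequencies=counts, n_solutions=total)


def write_frequency_tsv(freq: FrequencySets, path) -> None:
    with open(path, "w") as fh:
        fh.write("reaction\tfrequency\tn_solutions\tclass\n")
        for rid in sorted(freq.frequencies):
            cls = "HFR" if rid in freq.HFR else ("ZFR" if rid in freq.ZFR else "")
            fh.write(f"{rid}\t{freq.frequencies[rid]}\t{freq.n_solutions}\t{cls}\n")


def read_frequency_tsv(path) -> FrequencySets:
    hfr: set[str] = set()
    zfr: set[str] = set()
    freqs: dict[str, int] = {}
    n = 0
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("reaction"):
            raise ValueError(f"{path}: expected a frequency table header")
        for line in fh:
            if not line.strip():
                continue
            rid, count, total, cls = (line.rstrip("\n").split("\t") + [""])[:4]
            freqs[rid] = int(count)
            n = int(total)
            if cls == "HFR":
                hfr.add(rid)
            elif cls == "ZFR":
                zfr.add(rid)
    return FrequencySets(HFR=hfr, ZFR=zfr, frequencies=freqs, n_solutions=n)
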