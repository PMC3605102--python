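"""Discretize gene expression and map calls onto reactions through GPRs.

Genes are ranked per condition and the extreme tails called highly (+1) or
lowly (-1) expressed; with 15% tails on an approximately log-normal
expression distribution, the cutoffs sit about one standard deviation above
and below the mean on the log scale.  Reaction calls follow from three-valued
GPR evaluation (AND = min, OR = max over -1 < 0 < +1): a protein complex is
lowly expressed as soon as one subunit is low and highly expressed only when
every subunit is high; a set of isoenzymes is highly expressed as soon as
one isoform is high and lowly expressed only when all of them are low.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .model import MetabolicModel

__all__ = ["ExpressionCalls", "ReactionCalls", "call_genes", "call_reactions",
           "read_expression_tsv", "read_calls_tsv", "write_calls_tsv",
           "write_reaction_calls_tsv"]


@dataclass
class ExpressionCalls:
    """Per-gene ternary expression calls: +1 high, -1 low, 0 neither."""

    calls: dict[str, int]
    hi_frac: float | None = None
    lo_frac: float | None = None

    def __post_init__(self) -> None:
        bad = {g: c for g, c in self.calls.items() if c not in (-1, 0, 1)}
        if bad:
            raise ValueError(f"calls must be in {{-1, 0, +1}}; offending entries: {bad}")

    def __getitem__(self, gene: str) -> int:
        return self.calls.get(gene, 0)

    @property
    def high_genes(self) -> set[str]:
        return {g for g, c in self.calls.items() if c == 1}

    @property
    def low_genes(self) -> set[str]:
        return {g for g, c in self.calls.items() if c == -1}


@dataclass
class ReactionCalls:
    """Reaction-level expression classification.

    ``rH`` and ``rL`` are disjoint sets of reaction ids; only reactions with
    a non-empty GPR can be classified.
    """

    rH: set[str] = field(default_factory=set)
    rL: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = self.rH & self.rL
        if overlap:
            raise ValueError(f"rH and rL overlap: {sorted(overlap)}")


def call_genes(values: dict[str, float], hi_frac: float = 0.15, lo_frac: float = 0.15) -> ExpressionCalls:
    """Ternary calls from one expression value per gene.

    The top ``ceil(hi_frac * G)`` genes by value are called +1 and the bottom
    ``ceil(lo_frac * G)`` are called -1 (G = number of measured genes).
    Ties at a percentile boundary are broken by gene id so the result is
    deterministic.  If every value is identical there is no meaningful
    ranking and all calls are 0 (with a warning).
    """
    if not values:
        raise ValueError("need at least one measured gene")
    if not (0 < hi_frac < 0.5 and 0 < lo_frac < 0.5):
        raise ValueError("hi_frac and lo_frac must lie in (0, 0.5)")
    genes = sorted(values)
    if len({float(v) for v in values.values()}) == 1:
        warnings.warn("all expression values identical; all calls set to 0", stacklevel=2)
        return ExpressionCalls({g: 0 for g in genes}, hi_frac, lo_frac)
    G = len(genes)
    n_hi = math.ceil(hi_frac * G)
    n_lo = math.ceil(lo_frac * G)
    by_value = sorted(genes, key=lambda g: (-values[g], g))
    calls = {g: 0 for g in genes}
    for g in by_value[:n_hi]:
        calls[g] = 1
    for g in sorted(genes, key=lambda g: (values[g], g))[:n_lo]:
        if calls[g] == 0:
            calls[g] = -1
    return ExpressionCalls(calls, hi_frac, lo_frac)


def call_reactions(model: MetabolicModel, calls: ExpressionCalls) -> ReactionCalls:
    """Classify reactions by three-valued GPR evaluation of gene calls.

    Genes without calls count as 0 (unmeasured); reactions with an empty GPR
    are never classified.
    """
    rH: set[str] = set()
    rL: set[str] = set()
    for rxn in model.reactions:
        if rxn.gpr.is_empty:
            continue
        value = rxn.gpr.evaluate_ternary(calls.calls)
        if value == 1:
            rH.add(rxn.id)
        elif value == -1:
            rL.add(rxn.id)
    return ReactionCalls(rH=rH, rL=rL)


# --------------------------------------------------------------------------
# TSV plumbing
# --------------------------------------------------------------------------


def read_expression_tsv(path) -> dict[str, float]:
    """Read a two-column TSV: gene id, expression value (no header needed)."""
    df = _read_two_column(path)
    return {str(g): float(v) for g, v in zip(df.iloc[:, 0], df.iloc[:, 1])}


def read_calls_tsv(path) -> ExpressionCalls:
    """Read pre-made ternary calls: gene id, call in {-1, 0, 1}."""
    df = _read_two_column(path)
    calls = {str(g): int(v) for g, v in zip(df.iloc[:, 0], df.iloc[:, 1])}
    return ExpressionCalls(calls)


def _read_two_column(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    # tolerate a header row: drop it if the second column is non-numeric
    try:
        float(df.iloc[0, 1])
    except (ValueError, TypeError):
        df = df.iloc[1:]
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    return df


def write_calls_tsv(calls: ExpressionCalls, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tcall\n")
        for gene in sorted(calls.calls):
            fh.write(f"{gene}\t{calls.calls[gene]}\n")


def write_reaction_calls_tsv(rcalls: ReactionCalls, model: MetabolicModel, path) -> None:
    """Reaction-call table over reactions with gene associations."""
    with open(path, "w") as fh:
        fh.write("reaction\tcall\n")
        for rxn in model.reactions:
            if rxn.gpr.is_empty:
                continue
            call = 1 if rxn.id in rcalls.rH else (-1 if rxn.id in rcalls.rL else 0)
            fh.write(f"{rxn.id}\t{call}\n")
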