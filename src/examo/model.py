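"""Domain types for constraint-based metabolic models.

A :class:`MetabolicModel` is a stoichiometric network: metabolites (rows of
the stoichiometric matrix ``S``), reactions (columns, each with flux bounds
``lb``/``ub`` and an optional Boolean gene--protein--reaction rule), a set of
exchange reactions crossing the system boundary, and at most one designated
biomass reaction.  Models round-trip through a plain reaction-list CSV whose
stoichiometry column uses arrow notation (``2 A[c] + B[c] -> C[e]``).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import lil_matrix

__all__ = [
    "Metabolite",
    "GprRule",
    "Reaction",
    "MetabolicModel",
    "parse_gpr",
    "stoichiometric_matrix",
    "read_model_csv",
    "write_model_csv",
    "ModelFormatError",
    "GprParseError",
]

#: Absolute tolerance for comparing stoichiometric coefficients.
COEFF_TOL = 1e-9


class GprParseError(ValueError):
    """Raised when a Boolean gene rule string cannot be parsed."""


class ModelFormatError(ValueError):
    """Raised when a reaction-list CSV is malformed."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("metabolite id must be non-empty")


# --------------------------------------------------------------------------
# GPR rules
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GprRule:
    """Expression tree over gene ids with AND / OR internal nodes.

    ``op`` is ``None`` for a leaf (``children`` holds the single gene id as a
    string) and ``"and"`` / ``"or"`` for internal nodes whose ``children``
    are :class:`GprRule` instances.  An empty rule (no gene association) is
    represented by ``GprRule.empty()``.
    """

    op: str | None = None
    children: tuple = ()

    @staticmethod
    def empty() -> "GprRule":
        return GprRule(None, ())

    @staticmethod
    def gene(gene_id: str) -> "GprRule":
        return GprRule(None, (gene_id,))

    @property
    def is_empty(self) -> bool:
        return self.op is None and not self.children

    @property
    def is_leaf(self) -> bool:
        return self.op is None and bool(self.children)

    def genes(self) -> frozenset[str]:
        """All gene ids appearing as leaves."""
        if self.is_empty:
            return frozenset()
        if self.is_leaf:
            return frozenset(self.children)
        return frozenset().union(*(c.genes() for c in self.children))

    def evaluate(self, present: dict[str, bool] | set[str]) -> bool:
        """Two-valued evaluation; genes absent from `present` count as True.

        Used for gene-deletion analysis, where exactly the deleted genes are
        mapped to False and every other gene is functional.
        """
        if isinstance(present, set | frozenset):
            lookup = present.__contains__
        else:
            lookup = lambda g: present.get(g, True)  # noqa: E731
        if self.is_empty:
            return True
        if self.is_leaf:
            return bool(lookup(self.children[0]))
        vals = (c.evaluate(present) for c in self.children)
        return all(vals) if self.op == "and" else any(vals)

    def evaluate_ternary(self, calls: dict[str, int]) -> int:
        """Three-valued evaluation: AND = min, OR = max over -1 < 0 < +1.

        Unmeasured genes evaluate to 0.  This is the unique monotone
        extension of the flat complex/isoenzyme classification rules: a
        complex is lowly expressed if any subunit is low and highly expressed
        only if all subunits are high; an isoenzyme set is highly expressed
        if any isoform is high and lowly expressed only if all are low.
        """
        if self.is_empty:
            return 0
        if self.is_leaf:
            return int(calls.get(self.children[0], 0))
        vals = [c.evaluate_ternary(calls) for c in self.children]
        return min(vals) if self.op == "and" else max(vals)

    def to_string(self) -> str:
        if self.is_empty:
            return ""
        if self.is_leaf:
            return self.children[0]
        sep = " AND " if self.op == "and" else " OR "
        parts = []
        for child in self.children:
            text = child.to_string()
            if not child.is_leaf:
                text = f"({text})"
            parts.append(text)
        return sep.join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


_GPR_TOKEN = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize_gpr(text: str) -> list[tuple[str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _GPR_TOKEN.match(text, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse_gpr(text: str | None) -> GprRule:
    """Parse a Boolean gene rule such as ``(g1 AND g2) OR (g3 AND g4)``.

    AND/OR keywords are case-insensitive; AND binds tighter than OR.  Gene
    ids are kept verbatim (case-sensitive).  Blank input yields the empty
    rule.  Malformed input raises :class:`GprParseError` naming the
    character position of the offending token.
    """
    if text is None or not text.strip():
        return GprRule.empty()
    tokens = _tokenize_gpr(text)
    pos = 0

    def error(msg: str, at: int) -> GprParseError:
        return GprParseError(f"{msg} at position {at} in {text!r}")

    def peek():
        return tokens[pos] if pos < len(tokens) else (None, len(text))

    def parse_or() -> GprRule:
        nonlocal pos
        node = parse_and()
        children = [node]
        while peek()[0] is not None and peek()[0].lower() == "or":
            pos += 1
            children.append(parse_and())
        if len(children) == 1:
            return node
        return GprRule("or", tuple(children))

    def parse_and() -> GprRule:
        nonlocal pos
        node = parse_atom()
        children = [node]
        while peek()[0] is not None and peek()[0].lower() == "and":
            pos += 1
            children.append(parse_atom())
        if len(children) == 1:
            return node
        return GprRule("and", tuple(children))

    def parse_atom() -> GprRule:
        nonlocal pos
        tok, at = peek()
        if tok is None:
            raise error("dangling operator or empty expression", at)
        if tok == "(":
            pos += 1
            node = parse_or()
            tok, at = peek()
            if tok != ")":
                raise error("unbalanced parentheses: expected ')'", at)
            pos += 1
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise error(f"unexpected token {tok!r}", at)
        pos += 1
        return GprRule.gene(tok)

    rule = parse_or()
    tok, at = peek()
    if tok is not None:
        raise GprParseError(f"unexpected trailing token {tok!r} at position {at} in {text!r}")
    return rule


# --------------------------------------------------------------------------
# Reactions and models
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Reaction:
    """One column of the stoichiometric matrix.

    ``stoich`` maps metabolite ids to signed coefficients (negative =
    consumed).  ``is_exchange`` marks boundary reactions: by convention a
    reaction with exactly one metabolite in its stoichiometry.
    """

    id: str
    stoich: dict[str, float]
    lb: float = -1000.0
    ub: float = 1000.0
    name: str = ""
    gpr: GprRule = field(default_factory=GprRule.empty)
    is_biomass: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("reaction id must be non-empty")
        if not self.stoich:
            raise ValueError(f"reaction {self.id!r}: stoichiometry must be non-empty")
        if self.lb > self.ub:
            raise ValueError(f"reaction {self.id!r}: lb {self.lb} > ub {self.ub}")

    @property
    def is_exchange(self) -> bool:
        return len(self.stoich) == 1

    @property
    def reversible(self) -> bool:
        return self.lb < 0 and self.ub > 0

    def with_bounds(self, lb: float, ub: float) -> "Reaction":
        return replace(self, lb=lb, ub=ub)


class MetabolicModel:
    """An ordered collection of metabolites and reactions.

    Metabolites referenced in reaction stoichiometries but not passed
    explicitly are created on the fly (compartment taken from a trailing
    ``[tag]`` on the id, if present).
    """

    def __init__(
        self,
        reactions: list[Reaction],
        metabolites: list[Metabolite] | None = None,
        id: str = "",
    ) -> None:
        self.id = id
        self.reactions: list[Reaction] = list(reactions)
        seen: dict[str, Reaction] = {}
        for rxn in self.reactions:
            if rxn.id in seen:
                raise ValueError(f"duplicate reaction id {rxn.id!r}")
            seen[rxn.id] = rxn
        if sum(r.is_biomass for r in self.reactions) > 1:
            raise ValueError("at most one reaction may be flagged as biomass")
        declared = {m.id: m for m in (metabolites or [])}
        mets: dict[str, Metabolite] = {}
        for rxn in self.reactions:
            for met_id in rxn.stoich:
                if met_id in mets:
                    continue
                mets[met_id] = declared.pop(met_id, None) or _infer_metabolite(met_id)
        # keep declared-but-unreferenced metabolites out: orphans carry no
        # stoichiometric information and trim_dead_ends drops them anyway
        self.metabolites: list[Metabolite] = list(mets.values())
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}

    # -- lookups ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.reactions)

    def __contains__(self, reaction_id: str) -> bool:
        return reaction_id in self._rxn_index

    def reaction(self, reaction_id: str) -> Reaction:
        return self.reactions[self._rxn_index[reaction_id]]

    def reaction_index(self, reaction_id: str) -> int:
        return self._rxn_index[reaction_id]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for rxn in self.reactions:
            out |= rxn.gpr.genes()
        return frozenset(out)

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    @property
    def biomass(self) -> Reaction | None:
        for rxn in self.reactions:
            if rxn.is_biomass:
                return rxn
        return None

    @property
    def lb(self) -> np.ndarray:
        return np.array([r.lb for r in self.reactions], dtype=float)

    @property
    def ub(self) -> np.ndarray:
        return np.array([r.ub for r in self.reactions], dtype=float)

    # -- editing (functional style: return new models) --------------------

    def with_reactions(self, reactions: list[Reaction]) -> "MetabolicModel":
        return MetabolicModel(reactions, self.metabolites, id=self.id)

    def replace_reaction(self, new: Reaction) -> "MetabolicModel":
        rxns = [new if r.id == new.id else r for r in self.reactions]
        return self.with_reactions(rxns)

    def drop_reactions(self, reaction_ids) -> "MetabolicModel":
        drop = set(reaction_ids)
        return self.with_reactions([r for r in self.reactions if r.id not in drop])

    def set_bounds(self, overrides: dict[str, tuple[float, float]]) -> "MetabolicModel":
        rxns = [
            r.with_bounds(*overrides[r.id]) if r.id in overrides else r
            for r in self.reactions
        ]
        return self.with_reactions(rxns)

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(list(self.reactions), list(self.metabolites), id=self.id)


def _infer_metabolite(met_id: str) -> Metabolite:
    m = re.match(r"^(.*)\[([^\[\]]+)\]$", met_id)
    if m:
        return Metabolite(id=met_id, name=m.group(1), compartment=m.group(2))
    return Metabolite(id=met_id, name=met_id)


def stoichiometric_matrix(model: MetabolicModel) -> np.ndarray:
    """Assemble the n x m stoichiometric matrix S (dense).

    Entry (i, j) is the coefficient of metabolite i in reaction j; a feasible
    steady-state flux vector v satisfies S v = 0.
    """
    n, m = len(model.metabolites), len(model.reactions)
    S = lil_matrix((n, m))
    met_index = {met.id: i for i, met in enumerate(model.metabolites)}
    for j, rxn in enumerate(model.reactions):
        for met_id, coeff in rxn.stoich.items():
            S[met_index[met_id], j] = coeff
    return S.toarray()


# --------------------------------------------------------------------------
# Reaction-list CSV dialect
# --------------------------------------------------------------------------

_CSV_COLUMNS = ["id", "name", "stoichiometry", "gpr", "lb", "ub", "biomass"]

# permissive header mapping: canonical name -> accepted aliases (lowercased)
_HEADER_ALIASES = {
    "id": {"id", "reaction", "reaction id", "rxn", "abbreviation"},
    "name": {"name", "reaction name", "description"},
    "stoichiometry": {"stoichiometry", "equation", "formula", "reaction formula"},
    "gpr": {"gpr", "gene association", "gene_association", "genes", "gene rule"},
    "lb": {"lb", "lower bound", "lower_bound", "lowerbound"},
    "ub": {"ub", "upper bound", "upper_bound", "upperbound"},
    "biomass": {"biomass", "is_biomass", "objective"},
}

_ARROW_RE = re.compile(r"(<=>|<->|-->|->|=>)")
_IRREVERSIBLE_ARROWS = {"->", "-->", "=>"}
_REVERSIBLE_ARROWS = {"<=>", "<->"}


def parse_reaction_equation(text: str, row: int | None = None) -> tuple[dict[str, float], bool]:
    """Parse ``2 A[c] + B[c] -> C[e]`` into (stoich dict, reversible flag)."""

    def err(msg: str) -> ModelFormatError:
        where = f" (row {row})" if row is not None else ""
        return ModelFormatError(f"{msg}{where}: {text!r}")

    pieces = _ARROW_RE.split(text)
    if len(pieces) != 3:
        raise err("expected exactly one arrow token ('->' or '<=>')")
    left, arrow, right = pieces
    if arrow in _REVERSIBLE_ARROWS:
        reversible = True
    elif arrow in _IRREVERSIBLE_ARROWS:
        reversible = False
    else:  # pragma: no cover - regex only matches known arrows
        raise err(f"unknown arrow token {arrow!r}")

    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise err("empty term between '+' signs")
            parts = term.split(None, 1)
            if len(parts) == 2:
                coeff_text, met = parts
                try:
                    coeff = float(coeff_text)
                except ValueError:
                    raise err(f"non-numeric coefficient {coeff_text!r}") from None
            else:
                coeff, met = 1.0, term
            if coeff <= 0:
                raise err(f"non-positive coefficient {coeff!r} for {met!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coeff
    add_side(left, -1.0)
    add_side(right, +1.0)
    stoich = {k: v for k, v in stoich.items() if abs(v) > COEFF_TOL}
    if not stoich:
        raise err("reaction has empty stoichiometry")
    return stoich, reversible


def format_reaction_equation(rxn: Reaction) -> str:
    def fmt(met: str, coeff: float) -> str:
        coeff = abs(coeff)
        if abs(coeff - 1.0) < COEFF_TOL:
            return met
        if abs(coeff - round(coeff)) < COEFF_TOL:
            return f"{int(round(coeff))} {met}"
        return f"{coeff:g} {met}"

    left = " + ".join(fmt(m, c) for m, c in rxn.stoich.items() if c < 0)
    right = " + ".join(fmt(m, c) for m, c in rxn.stoich.items() if c > 0)
    arrow = "<=>" if rxn.lb < 0 else "->"
    return f"{left} {arrow} {right}".strip()


def _map_header(header: list[str], path) -> dict[str, int]:
    mapping: dict[str, int] = {}
    for i, raw in enumerate(header):
        key = raw.strip().lower()
        for canon, aliases in _HEADER_ALIASES.items():
            if key in aliases and canon not in mapping:
                mapping[canon] = i
    missing = [c for c in ("id", "stoichiometry") if c not in mapping]
    if missing:
        raise ModelFormatError(f"{path}: missing required column(s) {missing}; header was {header}")
    return mapping


def read_model_csv(path, default_bound: float = 1000.0) -> MetabolicModel:
    """Read a reaction-list CSV.

    Columns (header aliases are accepted): reaction id, name, stoichiometry
    string, GPR string, lb, ub, and an optional biomass flag.  When bounds
    are blank they default to ``[0, default_bound]`` for ``->`` reactions and
    ``[-default_bound, default_bound]`` for ``<=>`` reactions.
    """
    reactions: list[Reaction] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ModelFormatError(f"{path}: empty file") from None
        cols = _map_header(header, path)

        def cell(rowvals: list[str], key: str) -> str:
            idx = cols.get(key)
            if idx is None or idx >= len(rowvals):
                return ""
            return rowvals[idx].strip()

        for rownum, rowvals in enumerate(reader, start=2):
            if not any(v.strip() for v in rowvals):
                continue
            rxn_id = cell(rowvals, "id")
            if not rxn_id:
                raise ModelFormatError(f"{path}: blank reaction id (row {rownum})")
            if rxn_id in seen:
                raise ModelFormatError(f"{path}: duplicate reaction id {rxn_id!r} (row {rownum})")
            seen.add(rxn_id)
            stoich, reversible = parse_reaction_equation(cell(rowvals, "stoichiometry"), rownum)
            lb_text, ub_text = cell(rowvals, "lb"), cell(rowvals, "ub")
            try:
                lb = float(lb_text) if lb_text else (-default_bound if reversible else 0.0)
                ub = float(ub_text) if ub_text else default_bound
            except ValueError as exc:
                raise ModelFormatError(f"{path}: non-numeric bound (row {rownum}): {exc}") from None
            if not reversible and not lb_text:
                lb = 0.0
            biomass_text = cell(rowvals, "biomass").lower()
            reactions.append(
                Reaction(
                    id=rxn_id,
                    name=cell(rowvals, "name"),
                    stoich=stoich,
                    lb=lb,
                    ub=ub,
                    gpr=parse_gpr(cell(rowvals, "gpr")),
                    is_biomass=biomass_text in ("1", "true", "yes", "biomass"),
                )
            )
    return MetabolicModel(reactions)


def write_model_csv(model: MetabolicModel, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for rxn in model.reactions:
            writer.writerow(
                [
                    rxn.id,
                    rxn.name,
                    format_reaction_equation(rxn),
                    rxn.gpr.to_string(),
                    repr(rxn.lb),
                    repr(rxn.ub),
                    "1" if rxn.is_biomass else "",
                ]
            )
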