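"""Stoichiometric model data structures and validation.

A :class:`MetabolicModel` is the S·v = 0 universe on which every downstream
computation operates: a list of metabolites (species with a compartment
token), a list of reactions (signed stoichiometries with flux bounds in
µmol/(g tissue · min) and an optional boolean gene rule), and free-form
annotations.

Sign conventions used throughout the package:

* negative stoichiometric coefficient = consumed, positive = produced;
* an *exchange* reaction has exactly one metabolite, in the extracellular
  compartment ``"e"``, and **positive flux means secretion** (the metabolite
  leaves the system) while negative flux means uptake.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Metabolite",
    "GeneRule",
    "GeneRuleError",
    "Reaction",
    "MetabolicModel",
    "ValidationError",
    "Violation",
    "validate",
    "stoichiometric_matrix",
]

EXTRACELLULAR = "e"


class GeneRuleError(ValueError):
    """Raised when a gene-protein-reaction rule string cannot be parsed."""


class ValidationError(ValueError):
    """Raised when a model breaches a structural invariant."""

    def __init__(self, violations: list["Violation"]):
        self.violations = violations
        msg = "; ".join(str(v) for v in violations)
        super().__init__(f"model validation failed: {msg}")


@dataclass(frozen=True)
class Metabolite:
    """A chemical species located in one compartment."""

    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None
    charge: int | None = None


# ---------------------------------------------------------------------------
# Gene rules
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|[A-Za-z0-9_.\-]+")


def _tokenize(expr: str) -> list[str]:
    tokens = _TOKEN_RE.findall(expr)
    if "".join(tokens).replace("(", "").replace(")", "") != re.sub(
        r"[\s()]+", "", expr
    ):
        raise GeneRuleError(f"unparseable characters in gene rule: {expr!r}")
    return tokens


@dataclass(frozen=True)
class GeneRule:
    """Boolean gene association over gene ids using AND/OR and parentheses.

    The empty rule means "no gene association".  Parsing happens eagerly at
    construction so malformed rules fail where they are written, naming the
    offending expression.
    """

    expr: str = ""

    def __post_init__(self):
        object.__setattr__(self, "_tree", _parse_rule(self.expr))

    @property
    def tree(self):
        return self._tree  # type: ignore[attr-defined]

    @property
    def is_empty(self) -> bool:
        return self.tree is None

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()

        def walk(node):
            if node is None:
                return
            if isinstance(node, str):
                out.add(node)
            else:
                for child in node[1]:
                    walk(child)

        walk(self.tree)
        return frozenset(out)

    def evaluate(self, values: Mapping[str, float]) -> float | None:
        """Score the rule against per-gene expression values.

        AND maps to ``min``, OR maps to ``max`` — the standard convention in
        context-specific model extraction.  Gene ids missing from *values*
        are treated as carrying no evidence and are ignored; a rule whose
        leaves are all unresolved (or an empty rule) evaluates to ``None``.
        """

        def ev(node) -> float | None:
            if node is None:
                return None
            if isinstance(node, str):
                v = values.get(node)
                return None if v is None else float(v)
            op, children = node
            vals = [x for x in (ev(c) for c in children) if x is not None]
            if not vals:
                return None
            return min(vals) if op == "and" else max(vals)

        return ev(self.tree)


def _parse_rule(expr: str):
    """Recursive-descent parser; returns None (empty), a gene id string,
    or ``(op, [children])`` with op in {"and", "or"}."""
    if not expr or not expr.strip():
        return None
    tokens = _tokenize(expr)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or():
        nodes = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            nodes.append(parse_and())
        return nodes[0] if len(nodes) == 1 else ("or", nodes)

    def parse_and():
        nodes = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            nodes.append(parse_atom())
        return nodes[0] if len(nodes) == 1 else ("and", nodes)

    def parse_atom():
        tok = peek()
        if tok is None:
            raise GeneRuleError(f"unexpected end of gene rule: {expr!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise GeneRuleError(f"unbalanced parentheses in rule: {expr!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GeneRuleError(f"misplaced token {tok!r} in rule: {expr!r}")
        return take()

    tree = parse_or()
    if pos != len(tokens):
        raise GeneRuleError(f"trailing tokens in gene rule: {expr!r}")
    return tree


# ---------------------------------------------------------------------------
# Reactions and models
# ---------------------------------------------------------------------------


@dataclass
class Reaction:
    """One reaction: signed stoichiometry, bounds in µmol/(g·min), gene rule.

    ``reversible`` is derived from the lower bound when not given; the
    validator enforces ``reversible ⇔ lb < 0``.
    """

    id: str
    name: str = ""
    stoich: dict[str, float] = field(default_factory=dict)
    lb: float = 0.0
    ub: float = 1000.0
    subsystem: str = ""
    gene_rule: GeneRule = field(default_factory=GeneRule)
    reversible: bool | None = None

    def __post_init__(self):
        if isinstance(self.gene_rule, str):
            self.gene_rule = GeneRule(self.gene_rule)
        if self.reversible is None:
            self.reversible = self.lb < 0

    def copy(self) -> "Reaction":
        return replace(self, stoich=dict(self.stoich))


def is_exchange(rxn: Reaction, model: "MetabolicModel") -> bool:
    """True when the reaction moves exactly one extracellular metabolite
    across the system boundary."""
    if len(rxn.stoich) != 1:
        return False
    (met_id,) = rxn.stoich
    met = model.metabolites_by_id.get(met_id)
    return met is not None and met.compartment == EXTRACELLULAR


def is_transport(rxn: Reaction, model: "MetabolicModel") -> bool:
    """True when the reaction spans more than one compartment."""
    comps = {
        model.metabolites_by_id[m].compartment
        for m in rxn.stoich
        if m in model.metabolites_by_id
    }
    return len(comps) > 1


@dataclass
class MetabolicModel:
    """Container for metabolites + reactions; the pipeline's model type."""

    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    annotations: dict = field(default_factory=dict)
    id: str = "model"

    @property
    def metabolites_by_id(self) -> dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    @property
    def reactions_by_id(self) -> dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self.reactions_by_id[rxn_id]
        except KeyError:
            raise KeyError(f"no reaction {rxn_id!r} in model {self.id!r}") from None

    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self.metabolites_by_id[met_id]
        except KeyError:
            raise KeyError(f"no metabolite {met_id!r} in model {self.id!r}") from None

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.gene_rule.genes
        return frozenset(out)

    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if is_exchange(r, self)]

    def transport_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if is_transport(r, self)]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            annotations=dict(self.annotations),
            id=self.id,
        )

    def subset(self, reaction_ids: Iterable[str], id: str | None = None) -> "MetabolicModel":
        """Submodel restricted to *reaction_ids*; orphan metabolites dropped."""
        keep = set(reaction_ids)
        missing = keep - set(self.reactions_by_id)
        if missing:
            raise KeyError(f"unknown reaction ids: {sorted(missing)}")
        rxns = [r.copy() for r in self.reactions if r.id in keep]
        used = {m for r in rxns for m in r.stoich}
        mets = [m for m in self.metabolites if m.id in used]
        return MetabolicModel(
            metabolites=mets,
            reactions=rxns,
            annotations=dict(self.annotations),
            id=id or f"{self.id}_sub",
        )


@dataclass(frozen=True)
class Violation:
    """One broken invariant: the entity, the rule, and a human message."""

    entity_id: str
    rule: str
    message: str

    def __str__(self) -> str:
        return f"[{self.rule}] {self.entity_id}: {self.message}"


def validate(model: MetabolicModel) -> list[Violation]:
    """Check every structural invariant; violations are returned, not raised."""
    out: list[Violation] = []
    seen_mets: set[str] = set()
    for m in model.metabolites:
        if m.id in seen_mets:
            out.append(Violation(m.id, "unique-metabolite-id", "duplicate metabolite id"))
        seen_mets.add(m.id)
        if not m.compartment:
            out.append(Violation(m.id, "compartment-nonempty", "empty compartment token"))
    seen_rxns: set[str] = set()
    for r in model.reactions:
        if r.id in seen_rxns:
            out.append(Violation(r.id, "unique-reaction-id", "duplicate reaction id"))
        seen_rxns.add(r.id)
        if not r.stoich:
            out.append(Violation(r.id, "stoich-nonempty", "reaction has no stoichiometry"))
        if r.lb > r.ub:
            out.append(Violation(r.id, "bounds-ordered", f"lb {r.lb} > ub {r.ub}"))
        if bool(r.reversible) != (r.lb < 0):
            out.append(
                Violation(r.id, "reversible-consistent",
                          f"reversible={r.reversible} but lb={r.lb}")
            )
        for met_id in r.stoich:
            if met_id not in seen_mets and met_id not in model.metabolites_by_id:
                out.append(
                    Violation(r.id, "metabolite-exists",
                              f"references unknown metabolite {met_id!r}")
                )
        ext = [
            m for m in r.stoich
            if model.metabolites_by_id.get(m) is not None
            and model.metabolites_by_id[m].compartment == EXTRACELLULAR
        ]
        if ext and len(r.stoich) == 1 and not is_exchange(r, model):
            out.append(Violation(r.id, "exchange-form", "boundary reaction malformed"))
        if len(r.stoich) > 1 and len(ext) == len(r.stoich):
            out.append(
                Violation(r.id, "exchange-single-metabolite",
                          "exchange-like reaction with more than one metabolite")
            )
    return out


def assert_valid(model: MetabolicModel) -> MetabolicModel:
    violations = validate(model)
    if violations:
        raise ValidationError(violations)
    return model


def stoichiometric_matrix(model: MetabolicModel) -> pd.DataFrame:
    """Dense metabolites × reactions matrix S with S[i, j] the coefficient of
    metabolite i in reaction j."""
    met_ids = [m.id for m in model.metabolites]
    rxn_ids = [r.id for r in model.reactions]
    S = np.zeros((len(met_ids), len(rxn_ids)))
    met_index = {m: i for i, m in enumerate(met_ids)}
    for j, r in enumerate(model.reactions):
        for met_id, coef in r.stoich.items():
            S[met_index[met_id], j] = coef
    return pd.DataFrame(S, index=met_ids, columns=rxn_ids)
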