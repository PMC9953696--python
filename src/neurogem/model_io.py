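"""Readers/writers for the native JSON model dialect and SBML Level 3 FBC.

The JSON dialect mirrors the in-memory types one-to-one and is the primary
on-disk format of the pipeline (write→read→write is byte-identical modulo
key order).  SBML support targets Level 3 + FBC v2 bounds and gene-product
associations only — enough to ingest any FBC-compliant reference model
(e.g. a Human1 export) without pinning a version; groups/layout payloads
are ignored.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import libsbml

from .model_core import (
    GeneRule,
    MetabolicModel,
    Metabolite,
    Reaction,
    ValidationError,
    assert_valid,
    validate,
)

__all__ = ["read_model", "write_model", "ModelFormatError", "JSON_SCHEMA"]

#: Shape of the native JSON dialect (documented here; mirrored by tests).
JSON_SCHEMA = {
    "id": "str",
    "annotations": "object",
    "metabolites": [
        {"id": "str", "name": "str", "compartment": "str",
         "formula": "str|null", "charge": "int|null"}
    ],
    "reactions": [
        {"id": "str", "name": "str", "stoich": {"<metabolite id>": "float"},
         "lb": "float", "ub": "float", "subsystem": "str",
         "gene_rule": "str", "reversible": "bool"}
    ],
}


class ModelFormatError(ValueError):
    """A file does not conform to the named model format."""


def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read and validate a model from *path* (``json`` or ``sbml``).

    The format is inferred from the suffix when not given.  Parse failures
    raise :class:`ModelFormatError` naming the offending element; invariant
    breaches raise :class:`~neurogem.model_core.ValidationError` listing the
    offending ids.
    """
    path = Path(path)
    fmt = format or ("sbml" if path.suffix.lower() in (".xml", ".sbml") else "json")
    if fmt == "json":
        model = _read_json(path)
    elif fmt == "sbml":
        model = _read_sbml(path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")
    return assert_valid(model)


def write_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("sbml" if path.suffix.lower() in (".xml", ".sbml") else "json")
    violations = validate(model)
    if violations:
        raise ValidationError(violations)
    if fmt == "json":
        _write_json(model, path)
    elif fmt == "sbml":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "annotations": model.annotations,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment,
             "formula": m.formula, "charge": m.charge}
            for m in model.metabolites
        ],
        "reactions": [
            {"id": r.id, "name": r.name,
             "stoich": {k: float(v) for k, v in r.stoich.items()},
             "lb": float(r.lb), "ub": float(r.ub), "subsystem": r.subsystem,
             "gene_rule": r.gene_rule.expr, "reversible": bool(r.reversible)}
            for r in model.reactions
        ],
    }


def model_from_dict(data: dict) -> MetabolicModel:
    try:
        mets = [
            Metabolite(
                id=m["id"], name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
                formula=m.get("formula"), charge=m.get("charge"),
            )
            for m in data["metabolites"]
        ]
        rxns = [
            Reaction(
                id=r["id"], name=r.get("name", ""),
                stoich={k: float(v) for k, v in r["stoich"].items()},
                lb=float(r["lb"]), ub=float(r["ub"]),
                subsystem=r.get("subsystem", ""),
                gene_rule=GeneRule(r.get("gene_rule", "")),
                reversible=r.get("reversible"),
            )
            for r in data["reactions"]
        ]
    except (KeyError, TypeError) as exc:
        raise ModelFormatError(f"malformed JSON model: missing/invalid field {exc}") from exc
    return MetabolicModel(
        metabolites=mets, reactions=rxns,
        annotations=data.get("annotations", {}), id=data.get("id", "model"),
    )


def _read_json(path: Path) -> MetabolicModel:
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    return model_from_dict(data)


def _write_json(model: MetabolicModel, path: Path) -> None:
    path.write_text(json.dumps(model_to_dict(model), indent=1, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# SBML L3 + FBC v2
# ---------------------------------------------------------------------------

_SBML_SAFE = re.compile(r"[^A-Za-z0-9_]")


def _sid(raw: str) -> str:
    """Map an arbitrary id onto an SBML SId (prefix + sanitize)."""
    s = _SBML_SAFE.sub("__", raw)
    if not s or not (s[0].isalpha() or s[0] == "_"):
        s = "x_" + s
    return s


def _assoc_to_expr(assoc, gp_label: dict) -> str:
    """libsbml FbcAssociation tree → gene-rule string."""
    if assoc is None:
        return ""
    if assoc.isGeneProductRef():
        return gp_label.get(assoc.getGeneProduct(), assoc.getGeneProduct())
    op = " and " if assoc.isFbcAnd() else " or "
    parts = [
        _assoc_to_expr(assoc.getAssociation(i), gp_label)
        for i in range(assoc.getNumAssociations())
    ]
    return "(" + op.join(parts) + ")"


def _read_sbml(path: Path) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelFormatError(
            f"{path}: SBML parse error at line {err.getLine()}: {err.getMessage()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelFormatError(f"{path}: SBML document has no <model> element")

    id_map: dict[str, str] = {}  # SId -> native id
    mets = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        native = sp.getName() or sp.getId()
        id_map[sp.getId()] = native
        fbc_sp = sp.getPlugin("fbc")
        formula = None
        charge = None
        if fbc_sp is not None:
            if fbc_sp.isSetChemicalFormula():
                formula = fbc_sp.getChemicalFormula()
            if fbc_sp.isSetCharge():
                charge = fbc_sp.getCharge()
        mets.append(
            Metabolite(id=native, name=sp.getName() or native,
                       compartment=sp.getCompartment() or "c",
                       formula=formula, charge=charge)
        )

    gp_label: dict[str, str] = {}
    fbc_model = sbml_model.getPlugin("fbc")
    if fbc_model is not None:
        for i in range(fbc_model.getNumGeneProducts()):
            gp = fbc_model.getGeneProduct(i)
            gp_label[gp.getId()] = gp.getLabel() or gp.getId()

    def bound_value(rxn_fbc, getter, default):
        pid = getter()
        if not pid:
            return default
        p = sbml_model.getParameter(pid)
        return p.getValue() if p is not None else default

    rxns = []
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        native = rx.getName() or rx.getId()
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            sr = rx.getReactant(j)
            stoich[id_map[sr.getSpecies()]] = stoich.get(id_map[sr.getSpecies()], 0.0) - sr.getStoichiometry()
        for j in range(rx.getNumProducts()):
            sr = rx.getProduct(j)
            stoich[id_map[sr.getSpecies()]] = stoich.get(id_map[sr.getSpecies()], 0.0) + sr.getStoichiometry()
        fbc_rx = rx.getPlugin("fbc")
        lb, ub = -1000.0, 1000.0
        rule = ""
        if fbc_rx is not None:
            lb = bound_value(fbc_rx, fbc_rx.getLowerFluxBound, lb)
            ub = bound_value(fbc_rx, fbc_rx.getUpperFluxBound, ub)
            gpa = fbc_rx.getGeneProductAssociation()
            if gpa is not None:
                rule = _assoc_to_expr(gpa.getAssociation(), gp_label)
        subsystem = ""
        notes = rx.getNotesString() or ""
        m = re.search(r"SUBSYSTEM:\s*([^<]*)", notes)
        if m:
            subsystem = m.group(1).strip()
        rxns.append(
            Reaction(id=native, name=rx.getName() or native, stoich=stoich,
                     lb=lb, ub=ub, subsystem=subsystem, gene_rule=GeneRule(rule))
        )
    ann = {}
    if sbml_model.getName():
        ann["sbml_name"] = sbml_model.getName()
    return MetabolicModel(metabolites=mets, reactions=rxns, annotations=ann,
                          id=sbml_model.getId() or "model")


def _fill_assoc(container, children, label_to_sid):
    for child in children:
        if isinstance(child, str):
            ref = container.createGeneProductRef()
            ref.setGeneProduct(label_to_sid[child])
        else:
            op, sub = child
            inner = container.createAnd() if op == "and" else container.createOr()
            _fill_assoc(inner, sub, label_to_sid)


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sid(model.id))
    sm.setName(model.id)
    fbc = sm.getPlugin("fbc")
    fbc.setStrict(False)

    comps = sorted({m.compartment for m in model.metabolites})
    for c in comps:
        comp = sm.createCompartment()
        comp.setId(_sid(c))
        comp.setConstant(True)

    met_sid = {}
    for m in model.metabolites:
        sp = sm.createSpecies()
        sid = "M_" + _sid(m.id)
        met_sid[m.id] = sid
        sp.setId(sid)
        sp.setName(m.id)
        sp.setCompartment(_sid(m.compartment))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        fbc_sp = sp.getPlugin("fbc")
        if m.formula:
            fbc_sp.setChemicalFormula(m.formula)
        if m.charge is not None:
            fbc_sp.setCharge(int(m.charge))

    gene_sid = {}
    for g in sorted(model.genes):
        gp = fbc.createGeneProduct()
        sid = "G_" + _sid(g)
        gene_sid[g] = sid
        gp.setId(sid)
        gp.setLabel(g)

    bound_params: dict[float, str] = {}

    def param_for(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(float(value))
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for r in model.reactions:
        rx = sm.createReaction()
        rx.setId("R_" + _sid(r.id))
        rx.setName(r.id)
        rx.setReversible(bool(r.reversible))
        rx.setFast(False)
        if r.subsystem:
            rx.setNotes(
                f'<body xmlns="http://www.w3.org/1999/xhtml">'
                f"<p>SUBSYSTEM: {r.subsystem}</p></body>"
            )
        for met_id, coef in r.stoich.items():
            if coef < 0:
                sr = rx.createReactant()
                sr.setStoichiometry(-float(coef))
            else:
                sr = rx.createProduct()
                sr.setStoichiometry(float(coef))
            sr.setSpecies(met_sid[met_id])
            sr.setConstant(True)
        fbc_rx = rx.getPlugin("fbc")
        fbc_rx.setLowerFluxBound(param_for(float(r.lb)))
        fbc_rx.setUpperFluxBound(param_for(float(r.ub)))
        if not r.gene_rule.is_empty:
            gpa = fbc_rx.createGeneProductAssociation()
            tree = r.gene_rule.tree
            if isinstance(tree, str):
                ref = gpa.createGeneProductRef()
                ref.setGeneProduct(gene_sid[tree])
            else:
                op, children = tree
                container = gpa.createAnd() if op == "and" else gpa.createOr()
                _fill_assoc(container, children, gene_sid)

    libsbml.writeSBMLToFile(doc, str(path))
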