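"""Readers and writers: SBML Level 3 + FBC v2 (via libsbml) and a
cobra-style JSON dialect.

Both formats round-trip the full semantic content of a
:class:`~diazogem.core_model.MetabolicModel`: stoichiometry, bounds,
GPR trees (as FBC gene-product associations / ``gene_reaction_rule``
strings), formulas, charges, subsystems, provenance tags and the active
objective.
"""

from __future__ import annotations

import json
import re
from typing import Optional

import libsbml

from .core_model import (
    COMPARTMENTS,
    DEFAULT_BOUND,
    GprTree,
    MetabolicModel,
    Metabolite,
    ModelParseError,
    ReactionRecord,
)

__all__ = ["read_model", "write_model"]

_PROVENANCE_RE = re.compile(r"provenance:\s*([^\s<]+)")


def _infer_format(path: str, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in ("sbml", "json"):
            raise ValueError(f"unknown model format {fmt!r}")
        return fmt
    p = str(path).lower()
    if p.endswith(".json"):
        return "json"
    if p.endswith((".xml", ".sbml")):
        return "sbml"
    raise ValueError(f"cannot infer model format from path {path!r}")


def read_model(path, format: Optional[str] = None) -> MetabolicModel:
    """Read a model from SBML-FBC or the JSON dialect and validate it."""
    fmt = _infer_format(path, format)
    model = _read_json(path) if fmt == "json" else _read_sbml(path)
    model.validate()
    return model


def write_model(model: MetabolicModel, path, format: Optional[str] = None) -> None:
    """Validate ``model`` and serialize it to ``path``."""
    model.validate()
    fmt = _infer_format(path, format)
    if fmt == "json":
        _write_json(model, path)
    else:
        _write_sbml(model, path)


# ---------------------------------------------------------------------------
# JSON dialect (community cobra-JSON layout; fixtures stay hand-writable)


def _read_json(path) -> MetabolicModel:
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelParseError(f"malformed JSON in {path}: {exc}") from exc
    model = MetabolicModel(
        id=raw.get("id", "model"),
        compartments=dict(raw.get("compartments") or COMPARTMENTS),
    )
    for met in raw.get("metabolites", []):
        try:
            model.add_metabolite(
                Metabolite(
                    id=met["id"],
                    name=met.get("name", ""),
                    formula=met.get("formula") or "",
                    charge=int(met.get("charge") or 0),
                    compartment=met.get("compartment", "c"),
                )
            )
        except KeyError as exc:
            raise ModelParseError(f"metabolite entry missing field {exc}") from exc
    for gene in raw.get("genes", []):
        gid = gene["id"] if isinstance(gene, dict) else str(gene)
        if gid not in model.genes:
            model.genes.append(gid)
    for rxn in raw.get("reactions", []):
        try:
            rid = rxn["id"]
            stoich = {str(m): float(c) for m, c in rxn["metabolites"].items()}
        except KeyError as exc:
            raise ModelParseError(f"reaction entry missing field {exc}") from exc
        annotation = rxn.get("annotation") or {}
        record = ReactionRecord(
            id=rid,
            stoichiometry=stoich,
            lower_bound=float(rxn.get("lower_bound", -DEFAULT_BOUND)),
            upper_bound=float(rxn.get("upper_bound", DEFAULT_BOUND)),
            name=rxn.get("name", ""),
            subsystem=rxn.get("subsystem", "") or "",
            gpr=GprTree.from_string(rxn.get("gene_reaction_rule", "") or ""),
            provenance=annotation.get("diazogem_provenance", "native"),
        )
        model.add_reaction(record)
        if float(rxn.get("objective_coefficient", 0.0)):
            model.objective_id = rid
    return model


def _write_json(model: MetabolicModel, path) -> None:
    raw = {
        "id": model.id,
        "version": "1",
        "compartments": dict(model.compartments),
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "charge": m.charge,
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": {m: c for m, c in r.stoichiometry.items()},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gpr.to_string() if r.gpr else "",
                "subsystem": r.subsystem,
                "objective_coefficient": 1.0 if r.id == model.objective_id else 0.0,
                "annotation": {"diazogem_provenance": r.provenance},
            }
            for r in model.reactions.values()
        ],
        "genes": [{"id": g, "name": g} for g in model.genes],
    }
    with open(path, "w") as fh:
        json.dump(raw, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# SBML L3V1 + FBC v2


def _read_sbml(path) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelParseError(f"SBML parse error in {path}: {err.getMessage()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelParseError(f"{path} contains no SBML model")
    mplug = sbml_model.getPlugin("fbc")

    model = MetabolicModel(id=sbml_model.getId() or "model", compartments={})
    for i in range(sbml_model.getNumCompartments()):
        comp = sbml_model.getCompartment(i)
        model.compartments[comp.getId()] = comp.getName() or comp.getId()

    gene_labels = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            gene_labels[gp.getId()] = gp.getLabel() or _strip(gp.getId(), "G_")

    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        splug = sp.getPlugin("fbc")
        formula, charge = "", 0
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula()
            if splug.isSetCharge():
                charge = splug.getCharge()
        model.add_metabolite(
            Metabolite(
                id=_strip(sp.getId(), "M_"),
                name=sp.getName() or "",
                formula=formula,
                charge=charge,
                compartment=sp.getCompartment(),
            )
        )

    for gid in gene_labels.values():
        if gid not in model.genes:
            model.genes.append(gid)

    objective_id = None
    if mplug is not None and mplug.getActiveObjective() is not None:
        obj = mplug.getActiveObjective()
        if obj.getNumFluxObjectives() > 0:
            objective_id = _strip(obj.getFluxObjective(0).getReaction(), "R_")

    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        stoich = {}
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            met = _strip(ref.getSpecies(), "M_")
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            met = _strip(ref.getSpecies(), "M_")
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        rplug = rxn.getPlugin("fbc")
        lb, ub = -DEFAULT_BOUND, DEFAULT_BOUND
        if rplug is not None:
            lb = _bound_value(sbml_model, rplug.getLowerFluxBound(), lb)
            ub = _bound_value(sbml_model, rplug.getUpperFluxBound(), ub)
        gpr = None
        if rplug is not None and rplug.isSetGeneProductAssociation():
            gpr = _association_to_tree(
                rplug.getGeneProductAssociation().getAssociation(), gene_labels
            )
        provenance = "native"
        if rxn.isSetNotes():
            m = _PROVENANCE_RE.search(rxn.getNotesString())
            if m:
                provenance = m.group(1)
        model.add_reaction(
            ReactionRecord(
                id=_strip(rxn.getId(), "R_"),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                name=rxn.getName() or "",
                subsystem=_subsystem_from_notes(rxn),
                gpr=gpr,
                provenance=provenance,
            )
        )
    model.objective_id = objective_id
    return model


def _strip(identifier: str, prefix: str) -> str:
    return identifier[len(prefix):] if identifier.startswith(prefix) else identifier


def _bound_value(sbml_model, param_id: str, default: float) -> float:
    if not param_id:
        return default
    param = sbml_model.getParameter(param_id)
    return param.getValue() if param is not None else default


_SUBSYSTEM_RE = re.compile(r"subsystem:\s*([^<]+?)\s*</")


def _subsystem_from_notes(rxn) -> str:
    if rxn.isSetNotes():
        m = _SUBSYSTEM_RE.search(rxn.getNotesString())
        if m:
            return m.group(1)
    return ""


def _association_to_tree(assoc, gene_labels) -> Optional[GprTree]:
    if assoc is None:
        return None
    if assoc.isGeneProductRef():
        ref = assoc.getGeneProduct()
        return GprTree.leaf(gene_labels.get(ref, _strip(ref, "G_")))
    children = [
        _association_to_tree(assoc.getAssociation(i), gene_labels)
        for i in range(assoc.getNumAssociations())
    ]
    children = [c for c in children if c is not None]
    if len(children) == 1:
        return children[0]
    kind = "and" if assoc.isFbcAnd() else "or"
    return GprTree(kind, children=tuple(children))


def _check(status, what: str) -> None:
    if status is not None and isinstance(status, int) and status != libsbml.LIBSBML_OPERATION_SUCCESS:
        raise ModelParseError(f"libsbml failed while setting {what} (code {status})")


def _write_sbml(model: MetabolicModel, path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    _check(sbml_model.setId(_sanitize(model.id)), "model id")
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    for comp_id, comp_name in model.compartments.items():
        comp = sbml_model.createCompartment()
        comp.setId(comp_id)
        comp.setName(comp_name)
        comp.setConstant(True)

    for met in model.metabolites.values():
        sp = sbml_model.createSpecies()
        _check(sp.setId("M_" + _sanitize(met.id)), f"species id {met.id!r}")
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        splug = sp.getPlugin("fbc")
        if met.formula:
            splug.setChemicalFormula(met.formula)
        splug.setCharge(int(met.charge))

    for gene in model.genes:
        gp = mplug.createGeneProduct()
        _check(gp.setId("G_" + _sanitize(gene)), f"gene id {gene!r}")
        gp.setLabel(gene)

    bound_params = {}

    def bound_param(value: float) -> str:
        key = float(value)
        if key not in bound_params:
            pid = f"fb_{len(bound_params)}"
            param = sbml_model.createParameter()
            param.setId(pid)
            param.setValue(key)
            param.setConstant(True)
            bound_params[key] = pid
        return bound_params[key]

    for rxn in model.reactions.values():
        sr = sbml_model.createReaction()
        _check(sr.setId("R_" + _sanitize(rxn.id)), f"reaction id {rxn.id!r}")
        sr.setName(rxn.name or rxn.id)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setFast(False)
        for met_id, coeff in rxn.stoichiometry.items():
            ref = sr.createReactant() if coeff < 0 else sr.createProduct()
            ref.setSpecies("M_" + _sanitize(met_id))
            ref.setStoichiometry(abs(float(coeff)))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        if rxn.gpr is not None:
            gpa = rplug.createGeneProductAssociation()
            gpa.setAssociation(_tree_to_association(gpa, rxn.gpr))
        notes = (
            '<body xmlns="http://www.w3.org/1999/xhtml">'
            f"<p>provenance: {rxn.provenance}</p>"
            f"<p>subsystem: {_xml_escape(rxn.subsystem)}</p></body>"
        )
        sr.setNotes(notes)

    if model.objective_id is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fobj = obj.createFluxObjective()
        fobj.setReaction("R_" + _sanitize(model.objective_id))
        fobj.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))


_ID_BAD = re.compile(r"[^A-Za-z0-9_]")


def _sanitize(identifier: str) -> str:
    clean = _ID_BAD.sub("_", identifier)
    if clean != identifier:
        raise ModelParseError(
            f"identifier {identifier!r} contains characters not encodable as an "
            "SBML SId"
        )
    return clean


def _xml_escape(text: str) -> str:
    return text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")


def _tree_to_association(gpa, tree: GprTree):
    if tree.kind == "gene":
        ref = libsbml.GeneProductRef(3, 1, 2)
        ref.setGeneProduct("G_" + _sanitize(tree.gene))
        return ref
    node = libsbml.FbcAnd(3, 1, 2) if tree.kind == "and" else libsbml.FbcOr(3, 1, 2)
    for child in tree.children:
        node.addAssociation(_tree_to_association(gpa, child))
    return node
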