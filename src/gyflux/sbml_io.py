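"""SBML Level 3 (+ FBC) read/write for :class:`~gyflux.model.MetabolicModel`.

Bounds and the objective travel through the FBC package; subsystems and
optional enzyme parameters (kcat in 1/h, MW in g/mmol) are stored in reaction
notes as ``key: value`` lines, the convention constraint-based tools use for
auxiliary reaction data.  Identifiers like ``glc_D[c]`` or ``EX_glc_D(e)``
are not valid SBML SIds, so brackets/parentheses are escaped on write and
restored on read.
"""

from __future__ import annotations

from pathlib import Path

import libsbml

from gyflux.model import MetabolicModel, Metabolite, Reaction

_ESCAPES = [("[", "__LB__"), ("]", "__RB__"), ("(", "__LP__"), (")", "__RP__")]


def _sid(raw: str) -> str:
    out = raw
    for ch, esc in _ESCAPES:
        out = out.replace(ch, esc)
    return "g_" + out


def _unsid(sid: str) -> str:
    out = sid.removeprefix("g_")
    for ch, esc in _ESCAPES:
        out = out.replace(esc, ch)
    return out


def _notes_string(rxn: Reaction) -> str | None:
    fields = []
    if rxn.subsystem:
        fields.append(("SUBSYSTEM", rxn.subsystem))
    if rxn.kcat is not None:
        fields.append(("KCAT_PER_H", repr(rxn.kcat)))
    if rxn.mw is not None:
        fields.append(("MW_G_PER_MMOL", repr(rxn.mw)))
    if not fields:
        return None
    body = "".join(f"<p>{k}: {v}</p>" for k, v in fields)
    return (
        '<body xmlns="http://www.w3.org/1999/xhtml">' + body + "</body>"
    )


def _parse_notes(rxn: libsbml.Reaction) -> dict[str, str]:
    if not rxn.isSetNotes():
        return {}
    text = rxn.getNotesString()
    out = {}
    for chunk in text.split("<p>")[1:]:
        line = chunk.split("</p>")[0].strip()
        if ":" in line:
            k, v = line.split(":", 1)
            out[k.strip()] = v.strip()
    return out


def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sid(model.id))
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    for comp_id in sorted({m.compartment for m in model.metabolites.values()}):
        comp = sbml_model.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    for met in model.metabolites.values():
        sp = sbml_model.createSpecies()
        sp.setId(_sid(met.id))
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)

    # flux bound parameters (shared where values repeat)
    bound_params: dict[float, str] = {}

    def bound_id(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = sbml_model.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions.values():
        sr = sbml_model.createReaction()
        sr.setId(_sid(rxn.id))
        sr.setName(rxn.name or rxn.id)
        sr.setReversible(rxn.reversible)
        sr.setFast(False)
        notes = _notes_string(rxn)
        if notes:
            sr.setNotes(notes)
        for met_id, coef in sorted(rxn.stoichiometry.items()):
            if coef < 0:
                ref = sr.createReactant()
                ref.setStoichiometry(-coef)
            else:
                ref = sr.createProduct()
                ref.setStoichiometry(coef)
            ref.setSpecies(_sid(met_id))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_id(rxn.lb))
        rplug.setUpperFluxBound(bound_id(rxn.ub))

    if model.objective:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        mplug.setActiveObjectiveId("obj")
        fo = obj.createFluxObjective()
        fo.setReaction(_sid(model.objective))
        fo.setCoefficient(1.0)

    if model.p_total is not None:
        par = sbml_model.createParameter()
        par.setId("enzyme_pool_g_per_gDCW")
        par.setValue(model.p_total)
        par.setConstant(True)

    libsbml.writeSBMLToFile(doc, str(path))


def read_sbml(path: str | Path) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ValueError(
            f"unreadable SBML at {path}: line {err.getLine()}: {err.getMessage()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ValueError(f"no model element in SBML file {path}")

    params = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }
    p_total = params.get("enzyme_pool_g_per_gDCW")

    model = MetabolicModel(model_id=_unsid(sbml_model.getId() or "model"), p_total=p_total)
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        model.add_metabolite(
            Metabolite(id=_unsid(sp.getId()), name=sp.getName(), compartment=sp.getCompartment())
        )
    for i in range(sbml_model.getNumReactions()):
        sr = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            mid = _unsid(ref.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            mid = _unsid(ref.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        rplug = sr.getPlugin("fbc")
        lb, ub = -1000.0, 1000.0
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lb = params.get(rplug.getLowerFluxBound(), lb)
            if rplug.isSetUpperFluxBound():
                ub = params.get(rplug.getUpperFluxBound(), ub)
        notes = _parse_notes(sr)
        model.add_reaction(
            Reaction(
                id=_unsid(sr.getId()),
                stoichiometry=stoich,
                reversible=sr.getReversible(),
                lb=lb,
                ub=ub,
                subsystem=notes.get("SUBSYSTEM", ""),
                name=sr.getName(),
                kcat=float(notes["KCAT_PER_H"]) if "KCAT_PER_H" in notes else None,
                mw=float(notes["MW_G_PER_MMOL"]) if "MW_G_PER_MMOL" in notes else None,
            )
        )
    mplug = sbml_model.getPlugin("fbc")
    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getActiveObjective() or mplug.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            model.objective = _unsid(obj.getFluxObjective(0).getReaction())
    return model
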