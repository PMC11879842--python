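"""SBML Level 3 Version 1 reading and writing (libsbml-backed).

Accepts both encodings of flux bounds found in the wild:

* the fbc package (``fbc:lowerFluxBound``/``fbc:upperFluxBound`` parameters),
* legacy kinetic-law parameters named ``LOWER_BOUND``/``UPPER_BOUND``.

When a file carries neither, bounds default to (-1000, 1000) for reactions
declared ``reversible`` and (0, 1000) otherwise.
"""

from __future__ import annotations

import math
from fractions import Fraction
from pathlib import Path

import libsbml

from .errors import FormatError, ValidationError
from .metnet import (
    DEFAULT_BOUND,
    Metabolite,
    Reaction,
    StoichiometricModel,
    formula_to_string,
    parse_formula,
)


def _coefficient_from_float(value: float) -> Fraction:
    if not math.isfinite(value):
        raise FormatError(f"non-finite stoichiometric coefficient {value}")
    return Fraction(repr(value))


def _coefficient_to_float(coeff: Fraction) -> float:
    # decimals with 12 significant digits; exact for short decimals like 0.5
    return float(f"{float(coeff):.12g}")


# COBRA-style SId prefixes: species are written as M_<id>, reactions as
# R_<id>, and the prefixes are stripped on read, so ids like '10fthf_c'
# (invalid as bare SIds) survive a round trip and genome-scale files expose
# their conventional unprefixed ids ('GLYAMT', 'EX_formate_e', ...).
def _strip_prefix(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) and len(sid) > len(prefix) else sid


def load_sbml(path: str | Path) -> StoichiometricModel:
    """Read an SBML L3V1 file into a :class:`StoichiometricModel`.

    The active fbc objective (if any) names the objective reaction; the
    biomass reaction is the objective when its id mentions biomass, else the
    first reaction whose id contains ``biomass`` (case-insensitive).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"SBML file not found: {path}")
    doc = libsbml.readSBMLFromFile(str(path))
    errors = [
        doc.getError(i)
        for i in range(doc.getNumErrors())
        if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
    ]
    if errors:
        first = errors[0]
        raise FormatError(
            f"{path} is not valid SBML: line {first.getLine()}: {first.getMessage()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise FormatError(f"{path}: no <model> element")

    model = StoichiometricModel(name=sbml_model.getId() or path.stem)

    seen_species: set[str] = set()
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        sid = _strip_prefix(sp.getId(), "M_")
        if sid in seen_species:
            raise ValidationError(f"{path}: duplicated species id {sid!r}")
        seen_species.add(sid)
        fbc_sp = sp.getPlugin("fbc")
        formula = None
        charge = 0
        if fbc_sp is not None:
            if fbc_sp.isSetChemicalFormula():
                formula = parse_formula(fbc_sp.getChemicalFormula())
            if fbc_sp.isSetCharge():
                charge = fbc_sp.getCharge()
        model.add_metabolite(
            Metabolite(
                id=sid,
                name=sp.getName() or "",
                formula=formula,
                charge=charge,
                compartment=sp.getCompartment() or "c",
            )
        )

    def _bound_value(parameter_id: str) -> float | None:
        p = sbml_model.getParameter(parameter_id)
        return p.getValue() if p is not None else None

    seen_reactions: set[str] = set()
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        rid = _strip_prefix(rxn.getId(), "R_")
        if rid in seen_reactions:
            raise ValidationError(f"{path}: duplicated reaction id {rid!r}")
        seen_reactions.add(rid)
        stoich: dict[str, Fraction] = {}
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            species = _strip_prefix(ref.getSpecies(), "M_")
            stoich[species] = stoich.get(
                species, Fraction(0)
            ) - _coefficient_from_float(ref.getStoichiometry())
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            species = _strip_prefix(ref.getSpecies(), "M_")
            stoich[species] = stoich.get(
                species, Fraction(0)
            ) + _coefficient_from_float(ref.getStoichiometry())

        lb = ub = None
        fbc_rxn = rxn.getPlugin("fbc")
        if fbc_rxn is not None:
            if fbc_rxn.isSetLowerFluxBound():
                lb = _bound_value(fbc_rxn.getLowerFluxBound())
            if fbc_rxn.isSetUpperFluxBound():
                ub = _bound_value(fbc_rxn.getUpperFluxBound())
        if lb is None or ub is None:
            kl = rxn.getKineticLaw()
            if kl is not None:
                for k in range(kl.getNumParameters()):
                    p = kl.getParameter(k)
                    if p.getId() == "LOWER_BOUND" and lb is None:
                        lb = p.getValue()
                    elif p.getId() == "UPPER_BOUND" and ub is None:
                        ub = p.getValue()
        reversible = rxn.getReversible()
        if lb is None:
            lb = -DEFAULT_BOUND if reversible else 0.0
        if ub is None:
            ub = DEFAULT_BOUND

        model.add_reaction(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                is_exchange=(len(stoich) == 1),
                label=rxn.getName() or "",
            )
        )

    # objective / biomass identification
    fbc_model = sbml_model.getPlugin("fbc")
    objective_id = None
    if fbc_model is not None and fbc_model.getNumObjectives() > 0:
        obj = fbc_model.getActiveObjective() or fbc_model.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            objective_id = _strip_prefix(obj.getFluxObjective(0).getReaction(), "R_")
    model.objective_reaction_id = objective_id
    biomass_id = None
    if objective_id and "biomass" in objective_id.lower():
        biomass_id = objective_id
    else:
        for rid in model.reactions:
            if "biomass" in rid.lower():
                biomass_id = rid
                break
    model.biomass_reaction_id = biomass_id
    return model


def write_sbml(model: StoichiometricModel, path: str | Path) -> None:
    """Write a model as SBML L3V1 with fbc-v2 bounds and objective.

    ``load_sbml(write_sbml(m))`` reproduces ids, stoichiometry and bounds;
    coefficients are serialized as decimals with 12 significant digits.
    """
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(model.name or "model")
    fbc_model = sbml_model.getPlugin("fbc")
    fbc_model.setStrict(False)

    compartments = sorted({m.compartment for m in model.metabolites.values()}) or ["c"]
    for comp_id in compartments:
        comp = sbml_model.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    for met in model.metabolites.values():
        sp = sbml_model.createSpecies()
        sp.setId(f"M_{met.id}")
        if met.name:
            sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        fbc_sp = sp.getPlugin("fbc")
        if met.formula is not None:
            fbc_sp.setChemicalFormula(formula_to_string(met.formula))
        fbc_sp.setCharge(met.charge)

    bound_params: dict[float, str] = {}

    def _bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions.values():
        r = sbml_model.createReaction()
        r.setId(f"R_{rxn.id}")
        if rxn.label:
            r.setName(rxn.label)
        r.setReversible(rxn.lower_bound < 0)
        r.setFast(False)
        for met_id, coeff in rxn.stoichiometry.items():
            ref = r.createReactant() if coeff < 0 else r.createProduct()
            ref.setSpecies(f"M_{met_id}")
            ref.setStoichiometry(abs(_coefficient_to_float(coeff)))
            ref.setConstant(True)
        fbc_rxn = r.getPlugin("fbc")
        fbc_rxn.setLowerFluxBound(_bound_param(rxn.lower_bound))
        fbc_rxn.setUpperFluxBound(_bound_param(rxn.upper_bound))

    objective_id = model.objective_reaction_id or model.biomass_reaction_id
    if objective_id is not None:
        obj = fbc_model.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(f"R_{objective_id}")
        fo.setCoefficient(1.0)
        fbc_model.setActiveObjectiveId("obj")

    if not libsbml.writeSBMLToFile(doc, str(path)):
        raise OSError(f"could not write SBML to {path}")
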