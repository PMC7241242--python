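"""Genome-scale metabolic model core: load, validate, strip, serialize.

Models are read from and written to SBML (level 3 + fbc version 2 on
write; level 2 "notes dialect" files, as used by older plant GEMs, are
also understood on read). The in-memory representation is deliberately
plain: dataclasses plus a dense stoichiometric matrix accessor.
"""

from __future__ import annotations

import copy
import math
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from gemtailor._gpr import (
    GprParseError,
    gpr_to_string,
    normalize_gpr,
    parse_gpr,
)

INF = math.inf

#: Large finite bound substituted for +/-infinity when a consumer insists
#: on finite bounds. Far above any attainable flux in model units.
BIG_BOUND = 1.0e6


class SBMLParseError(ValueError):
    """Malformed SBML input."""


class SBMLValidationError(ValueError):
    """Structurally invalid model content (e.g. undeclared species)."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    external_id: Optional[str] = None


@dataclass
class Reaction:
    id: str
    name: str = ""
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = INF
    reversible: bool = False
    subsystem: str = ""
    gene_association: str = ""
    objective_coefficient: float = 0.0

    def gpr(self):
        """Parsed gene-association AST, or None if absent/unparsable."""
        try:
            return parse_gpr(self.gene_association)
        except GprParseError:
            return None


@dataclass
class MetabolicModel:
    id: str = "model"
    metabolites: List[Metabolite] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)
    compartments: Dict[str, str] = field(default_factory=dict)

    # -- indexing ---------------------------------------------------------

    def metabolite_index(self) -> Dict[str, int]:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    def reaction_index(self) -> Dict[str, int]:
        return {r.id: i for i, r in enumerate(self.reactions)}

    def get_reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(f"no reaction {rxn_id!r} in model {self.id!r}")

    def get_metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(f"no metabolite {met_id!r} in model {self.id!r}")

    @property
    def objective_reaction_id(self) -> Optional[str]:
        for r in self.reactions:
            if r.objective_coefficient != 0.0:
                return r.id
        return None

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(met_ids) != len(set(met_ids)):
            dupes = {m for m in met_ids if met_ids.count(m) > 1}
            raise SBMLValidationError(f"duplicate metabolite ids: {sorted(dupes)}")
        rxn_ids = [r.id for r in self.reactions]
        if len(rxn_ids) != len(set(rxn_ids)):
            dupes = {r for r in rxn_ids if rxn_ids.count(r) > 1}
            raise SBMLValidationError(f"duplicate reaction ids: {sorted(dupes)}")
        known = set(met_ids)
        for r in self.reactions:
            for met_id in r.stoichiometry:
                if met_id not in known:
                    raise SBMLValidationError(
                        f"reaction {r.id!r} references undeclared species {met_id!r}"
                    )
            if r.lower_bound > r.upper_bound:
                raise SBMLValidationError(
                    f"reaction {r.id!r} has lower_bound > upper_bound"
                )


def stoichiometric_matrix(model: MetabolicModel) -> np.ndarray:
    """Dense S with rows in metabolite order and columns in reaction order."""
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    met_idx = model.metabolite_index()
    for j, rxn in enumerate(model.reactions):
        for met_id, coef in rxn.stoichiometry.items():
            S[met_idx[met_id], j] = coef
    return S


def strip_constraints(model: MetabolicModel) -> MetabolicModel:
    """Remove preset flux constraints.

    Irreversible reactions get bounds [0, +inf); reversible ones
    (-inf, +inf). The input model is left untouched.
    """
    stripped = model.copy()
    for rxn in stripped.reactions:
        rxn.lower_bound = -INF if rxn.reversible else 0.0
        rxn.upper_bound = INF
    return stripped


def finite_bounds(model: MetabolicModel, big: float = BIG_BOUND) -> MetabolicModel:
    """Copy with infinite bounds capped at ``+-big`` (for finite-only solvers)."""
    capped = model.copy()
    for rxn in capped.reactions:
        rxn.lower_bound = max(rxn.lower_bound, -big)
        rxn.upper_bound = min(rxn.upper_bound, big)
    return capped


# ---------------------------------------------------------------------------
# SBML I/O (libsbml)
# ---------------------------------------------------------------------------

_NOTE_FIELD = re.compile(r"(GENE[ _]?ASSOCIATION|SUBSYSTEM|KEGG[ _]?ID)\s*:\s*([^<\n]*)", re.I)


def _notes_fields(sbase) -> Dict[str, str]:
    """Extract KEY: value fields from an SBML notes block."""
    if not sbase.isSetNotes():
        return {}
    text = sbase.getNotesString()
    out = {}
    for key, value in _NOTE_FIELD.findall(text):
        canon = key.upper().replace(" ", "_").replace("GENE_ASSOCIATION", "GENE_ASSOCIATION")
        out[canon.replace("KEGGID", "KEGG_ID")] = value.strip()
    return out


def _notes_string(fields: Dict[str, str]) -> str:
    rows = "".join(f"<p>{k}: {v}</p>" for k, v in fields.items() if v)
    return f'<body xmlns="http://www.w3.org/1999/xhtml">{rows}</body>'


def _bound_value(raw: float) -> float:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return 0.0
    return raw


def read_gem(source: str, kegg_map: Optional[str] = None) -> MetabolicModel:
    """Read an SBML file into a :class:`MetabolicModel`.

    Bounds are taken from fbc flux-bound parameters when present, falling
    back to the legacy kinetic-law ``LOWER_BOUND``/``UPPER_BOUND``
    parameters, and finally to the reversibility flag. Gene associations
    come from fbc geneProductAssociations or ``GENE_ASSOCIATION`` notes;
    subsystems from ``SUBSYSTEM`` notes.

    ``kegg_map`` optionally names a two-column TSV (model metabolite id,
    KEGG compound id) applied after parsing; no network calls are made.
    """
    import libsbml

    doc = libsbml.readSBML(str(source))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_FATAL) or doc.getModel() is None:
        msgs = [
            doc.getError(i).getMessage()
            for i in range(doc.getNumErrors())
        ]
        raise SBMLParseError(f"cannot parse SBML {source!r}: {'; '.join(msgs[:3])}")
    sbml_model = doc.getModel()

    model = MetabolicModel(id=sbml_model.getId() or "model")
    for i in range(sbml_model.getNumCompartments()):
        comp = sbml_model.getCompartment(i)
        model.compartments[comp.getId()] = comp.getName() or comp.getId()

    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        fields = _notes_fields(sp)
        model.metabolites.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or sp.getId(),
                compartment=sp.getCompartment(),
                external_id=fields.get("KEGG_ID") or None,
            )
        )
    known_species = {m.id for m in model.metabolites}

    fbc_obj_coefs: Dict[str, float] = {}
    model_fbc = sbml_model.getPlugin("fbc")
    if model_fbc is not None and model_fbc.getNumObjectives() > 0:
        active = model_fbc.getActiveObjective() or model_fbc.getObjective(0)
        if active is not None:
            for k in range(active.getNumFluxObjectives()):
                fo = active.getFluxObjective(k)
                fbc_obj_coefs[fo.getReaction()] = fo.getCoefficient()

    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        stoich: Dict[str, float] = {}
        for k in range(rxn.getNumReactants()):
            ref = rxn.getReactant(k)
            sid = ref.getSpecies()
            if sid not in known_species:
                raise SBMLValidationError(
                    f"reaction {rxn.getId()!r} references undeclared species {sid!r}"
                )
            stoich[sid] = stoich.get(sid, 0.0) - ref.getStoichiometry()
        for k in range(rxn.getNumProducts()):
            ref = rxn.getProduct(k)
            sid = ref.getSpecies()
            if sid not in known_species:
                raise SBMLValidationError(
                    f"reaction {rxn.getId()!r} references undeclared species {sid!r}"
                )
            stoich[sid] = stoich.get(sid, 0.0) + ref.getStoichiometry()

        reversible = rxn.getReversible()
        lower, upper = (-INF if reversible else 0.0), INF
        obj_coef = fbc_obj_coefs.get(rxn.getId(), 0.0)

        rxn_fbc = rxn.getPlugin("fbc")
        got_bounds = False
        if rxn_fbc is not None:
            lb_id, ub_id = rxn_fbc.getLowerFluxBound(), rxn_fbc.getUpperFluxBound()
            if lb_id or ub_id:
                lb_param = sbml_model.getParameter(lb_id) if lb_id else None
                ub_param = sbml_model.getParameter(ub_id) if ub_id else None
                if lb_param is not None:
                    lower = _bound_value(lb_param.getValue())
                if ub_param is not None:
                    upper = _bound_value(ub_param.getValue())
                got_bounds = True
        if not got_bounds and rxn.isSetKineticLaw():
            law = rxn.getKineticLaw()
            for k in range(law.getNumParameters()):
                par = law.getParameter(k)
                pid = par.getId().upper()
                if pid == "LOWER_BOUND":
                    lower = _bound_value(par.getValue())
                elif pid == "UPPER_BOUND":
                    upper = _bound_value(par.getValue())
                elif pid == "OBJECTIVE_COEFFICIENT" and not fbc_obj_coefs:
                    obj_coef = _bound_value(par.getValue())

        gene_assoc = ""
        if rxn_fbc is not None and rxn_fbc.isSetGeneProductAssociation():
            assoc = rxn_fbc.getGeneProductAssociation().getAssociation()
            if assoc is not None:
                gene_assoc = assoc.toInfix()
        fields = _notes_fields(rxn)
        if not gene_assoc:
            gene_assoc = fields.get("GENE_ASSOCIATION", "")

        model.reactions.append(
            Reaction(
                id=rxn.getId(),
                name=rxn.getName() or rxn.getId(),
                stoichiometry=stoich,
                lower_bound=lower,
                upper_bound=upper,
                reversible=reversible,
                subsystem=fields.get("SUBSYSTEM", ""),
                gene_association=gene_assoc,
                objective_coefficient=obj_coef,
            )
        )

    if kegg_map:
        mapping = {}
        with open(kegg_map) as handle:
            for line in handle:
                parts = line.rstrip("\n").split("\t")
                if len(parts) >= 2 and parts[0]:
                    mapping[parts[0]] = parts[1]
        for met in model.metabolites:
            if met.id in mapping:
                met.external_id = mapping[met.id]

    model.validate()
    return model


def write_gem(model: MetabolicModel, destination: str) -> None:
    """Write the model as SBML level 3 version 1 with fbc version 2.

    The output round-trips through :func:`read_gem` to a structurally
    equal model.
    """
    import libsbml

    model.validate()
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(model.id)
    model_fbc = sbml_model.getPlugin("fbc")
    model_fbc.setStrict(False)

    compartments = dict(model.compartments)
    for met in model.metabolites:
        compartments.setdefault(met.compartment or "default", met.compartment or "default")
    for cid, cname in compartments.items():
        comp = sbml_model.createCompartment()
        comp.setId(cid)
        comp.setName(cname)
        comp.setConstant(True)

    for met in model.metabolites:
        sp = sbml_model.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment or "default")
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        if met.external_id:
            sp.setNotes(_notes_string({"KEGG_ID": met.external_id}))

    bound_params: Dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = sbml_model.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    objective = model_fbc.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    has_objective = False

    for rxn in model.reactions:
        sr = sbml_model.createReaction()
        sr.setId(rxn.id)
        sr.setName(rxn.name or rxn.id)
        sr.setReversible(bool(rxn.reversible))
        sr.setFast(False)
        for met_id, coef in rxn.stoichiometry.items():
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies(met_id)
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rxn_fbc = sr.getPlugin("fbc")
        rxn_fbc.setLowerFluxBound(bound_param(rxn.lower_bound))
        rxn_fbc.setUpperFluxBound(bound_param(rxn.upper_bound))
        if rxn.gene_association:
            gpa = rxn_fbc.createGeneProductAssociation()
            if gpa.setAssociation(rxn.gene_association) != 0:
                # unparsable rule: keep it readable in notes instead
                sr.setNotes(_notes_string({
                    "SUBSYSTEM": rxn.subsystem,
                    "GENE_ASSOCIATION": rxn.gene_association,
                }))
        if rxn.subsystem and not sr.isSetNotes():
            sr.setNotes(_notes_string({"SUBSYSTEM": rxn.subsystem}))
        if rxn.objective_coefficient != 0.0:
            fo = objective.createFluxObjective()
            fo.setReaction(rxn.id)
            fo.setCoefficient(rxn.objective_coefficient)
            has_objective = True

    if has_objective:
        model_fbc.setActiveObjectiveId("obj")
    if libsbml.writeSBML(doc, str(destination)) != 1:
        raise IOError(f"cannot write SBML to {destination!r}")


def models_equal(a: MetabolicModel, b: MetabolicModel) -> bool:
    """Structural equality: same metabolites, reactions, bounds, GPRs."""
    if len(a.metabolites) != len(b.metabolites) or len(a.reactions) != len(b.reactions):
        return False
    mets_b = {m.id: m for m in b.metabolites}
    for met in a.metabolites:
        other = mets_b.get(met.id)
        if other is None or met.compartment != other.compartment:
            return False
        if (met.external_id or None) != (other.external_id or None):
            return False
    rxns_b = {r.id: r for r in b.reactions}
    for rxn in a.reactions:
        other = rxns_b.get(rxn.id)
        if other is None:
            return False
        if rxn.stoichiometry != other.stoichiometry:
            return False
        if (rxn.lower_bound, rxn.upper_bound) != (other.lower_bound, other.upper_bound):
            return False
        if bool(rxn.reversible) != bool(other.reversible):
            return False
        if rxn.subsystem != other.subsystem:
            return False
        if rxn.objective_coefficient != other.objective_coefficient:
            return False
        try:
            mine = normalize_gpr(parse_gpr(rxn.gene_association))
            theirs = normalize_gpr(parse_gpr(other.gene_association))
        except GprParseError:
            mine, theirs = rxn.gene_association, other.gene_association
        if gpr_to_string(mine) != gpr_to_string(theirs):
            return False
    return True
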