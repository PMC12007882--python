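"""Core network model, SBML I/O and boundary-reaction classification.

A metabolic network is a collection of reactions

    a1*M1 + ... + aa*Ma  <->  b1*N1 + ... + bb*Nb

over metabolites with strictly positive stoichiometric coefficients, each
reaction carrying lower/upper flux bounds.  Reversibility is represented
purely through the sign of the bounds (a negative lower bound allows the
reverse direction).  Boundary pseudo-reactions — exchanges, demands and
sinks — are the unbalanced productless reactions COBRA-style models use to
move metabolites across the system boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, Mapping, Optional, Set

import libsbml

from .errors import FormatError, InputError

logger = logging.getLogger("seedkit")

#: Compartment ids treated as extracellular unless the caller overrides them.
DEFAULT_EXTRACELLULAR = frozenset({"e", "extracellular"})

#: COBRA-convention default flux bound magnitude.
DEFAULT_BOUND = 1000.0


def derive_base_id(species_id: str, compartment: str) -> str:
    """Strip a trailing ``_<compartment>`` token so the same molecule in two
    compartments shares one identity (used for de-replicated statistics)."""
    suffix = "_" + compartment
    if compartment and species_id.endswith(suffix) and len(species_id) > len(suffix):
        return species_id[: -len(suffix)]
    return species_id


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str
    name: str = ""
    base_id: str = ""

    def __post_init__(self):
        if not self.compartment:
            raise FormatError(f"metabolite {self.id!r} has an empty compartment")
        if not self.base_id:
            object.__setattr__(self, "base_id", derive_base_id(self.id, self.compartment))


@dataclass
class Reaction:
    """A (possibly reversible) reaction with strictly positive coefficients on
    each side; a metabolite occurring on both sides is net-balanced in the
    stoichiometric matrix."""

    id: str
    reactants: Dict[str, float] = field(default_factory=dict)
    products: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND

    def __post_init__(self):
        if self.lower_bound > self.upper_bound:
            raise FormatError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        for side in (self.reactants, self.products):
            for mid, coef in side.items():
                if not coef > 0:
                    raise FormatError(
                        f"reaction {self.id!r}: non-positive coefficient {coef} for {mid!r}"
                    )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def participants(self) -> Set[str]:
        return set(self.reactants) | set(self.products)

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            reactants=dict(self.reactants),
            products=dict(self.products),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
        )


class BoundaryClass(str, Enum):
    EXCHANGE = "exchange"
    DEMAND = "demand"
    SINK = "sink"
    INTERNAL = "internal"


@dataclass
class MetabolicNetwork:
    metabolites: Dict[str, Metabolite] = field(default_factory=dict)
    reactions: Dict[str, Reaction] = field(default_factory=dict)
    objective_reaction_id: Optional[str] = None
    extracellular_compartments: frozenset = DEFAULT_EXTRACELLULAR

    # -- construction helpers -------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise FormatError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise FormatError(f"duplicate reaction id {rxn.id!r}")
        for mid in rxn.participants():
            if mid not in self.metabolites:
                raise FormatError(
                    f"reaction {rxn.id!r} references unknown metabolite {mid!r}"
                )
        self.reactions[rxn.id] = rxn

    def validate(self) -> None:
        for rxn in self.reactions.values():
            for mid in rxn.participants():
                if mid not in self.metabolites:
                    raise FormatError(
                        f"reaction {rxn.id!r} references unknown metabolite {mid!r}"
                    )
        if (
            self.objective_reaction_id is not None
            and self.objective_reaction_id not in self.reactions
        ):
            raise FormatError(
                f"objective reaction {self.objective_reaction_id!r} is not in the network"
            )

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            metabolites=dict(self.metabolites),
            reactions={rid: r.copy() for rid, r in self.reactions.items()},
            objective_reaction_id=self.objective_reaction_id,
            extracellular_compartments=self.extracellular_compartments,
        )

    def is_extracellular(self, metabolite_id: str) -> bool:
        met = self.metabolites[metabolite_id]
        return met.compartment in self.extracellular_compartments

    # -- indexes ---------------------------------------------------------------

    def producers_of(self) -> Dict[str, Set[str]]:
        """Map metabolite id -> ids of reactions listing it as a product."""
        out: Dict[str, Set[str]] = {mid: set() for mid in self.metabolites}
        for rid, rxn in self.reactions.items():
            for mid in rxn.products:
                out[mid].add(rid)
        return out

    def consumers_of(self) -> Dict[str, Set[str]]:
        """Map metabolite id -> ids of reactions listing it as a reactant."""
        out: Dict[str, Set[str]] = {mid: set() for mid in self.metabolites}
        for rid, rxn in self.reactions.items():
            for mid in rxn.reactants:
                out[mid].add(rid)
        return out

    def equal_structure(self, other: "MetabolicNetwork") -> bool:
        """Field-by-field equality on ids, stoichiometries and bounds."""
        if set(self.metabolites) != set(other.metabolites):
            return False
        for mid, met in self.metabolites.items():
            om = other.metabolites[mid]
            if (met.compartment, met.base_id) != (om.compartment, om.base_id):
                return False
        if set(self.reactions) != set(other.reactions):
            return False
        for rid, rxn in self.reactions.items():
            o = other.reactions[rid]
            if rxn.reactants != o.reactants or rxn.products != o.products:
                return False
            if (rxn.lower_bound, rxn.upper_bound) != (o.lower_bound, o.upper_bound):
                return False
        return self.objective_reaction_id == other.objective_reaction_id


# ---------------------------------------------------------------------------
# Boundary classification
# ---------------------------------------------------------------------------


def classify_boundaries(net: MetabolicNetwork) -> Dict[str, BoundaryClass]:
    """Assign each reaction exactly one boundary class.

    Exchange: productless, lb < 0 < ub, sole participant extracellular.
    Demand:   productless, lb = 0 < ub, sole participant intracellular.
    Sink:     productless, lb < 0 < ub, sole participant intracellular.
    Everything else (including ambiguous productless reactions with several
    reactants) is internal.
    """
    out: Dict[str, BoundaryClass] = {}
    for rid, rxn in net.reactions.items():
        cls = BoundaryClass.INTERNAL
        if not rxn.products and len(rxn.reactants) == 1:
            (mid,) = rxn.reactants
            extra = net.is_extracellular(mid)
            if rxn.lower_bound < 0 < rxn.upper_bound:
                cls = BoundaryClass.EXCHANGE if extra else BoundaryClass.SINK
            elif rxn.lower_bound == 0 and rxn.upper_bound > 0 and not extra:
                cls = BoundaryClass.DEMAND
        elif not rxn.products and len(rxn.reactants) > 1:
            logger.debug("productless multi-reactant reaction %s left internal", rid)
        out[rid] = cls
    return out


# ---------------------------------------------------------------------------
# SBML reading
# ---------------------------------------------------------------------------


def _reaction_bounds(model: libsbml.Model, rxn: libsbml.Reaction) -> tuple:
    """Resolve flux bounds: fbc parameters, then kinetic-law parameters, then
    the reversibility flag with COBRA default bounds."""
    fbc = rxn.getPlugin("fbc")
    if fbc is not None and fbc.isSetLowerFluxBound() and fbc.isSetUpperFluxBound():
        lo = model.getParameter(fbc.getLowerFluxBound())
        hi = model.getParameter(fbc.getUpperFluxBound())
        if lo is None or hi is None:
            raise FormatError(f"reaction {rxn.getId()!r}: dangling fbc bound parameter")
        return lo.getValue(), hi.getValue()
    kl = rxn.getKineticLaw()
    if kl is not None:
        lo = kl.getParameter("LOWER_BOUND")
        hi = kl.getParameter("UPPER_BOUND")
        if lo is not None and hi is not None:
            return lo.getValue(), hi.getValue()
    if not rxn.isSetReversible():
        raise FormatError(
            f"reaction {rxn.getId()!r}: no flux bounds and no reversibility flag"
        )
    if rxn.getReversible():
        return -DEFAULT_BOUND, DEFAULT_BOUND
    return 0.0, DEFAULT_BOUND


def _collect_side(refs: Iterable[libsbml.SpeciesReference], rid: str) -> Dict[str, float]:
    side: Dict[str, float] = {}
    for ref in refs:
        coef = ref.getStoichiometry()
        if coef != coef:  # NaN
            coef = 1.0
        if coef == 0:
            continue
        if coef < 0:
            raise FormatError(f"reaction {rid!r}: negative stoichiometry for {ref.getSpecies()!r}")
        side[ref.getSpecies()] = side.get(ref.getSpecies(), 0.0) + coef
    return side


def _declared_objective(model: libsbml.Model) -> Optional[str]:
    plug = model.getPlugin("fbc")
    if plug is None:
        return None
    obj = plug.getActiveObjective() or (
        plug.getObjective(0) if plug.getNumObjectives() else None
    )
    if obj is None or obj.getNumFluxObjectives() == 0:
        return None
    flux_objs = [obj.getFluxObjective(i) for i in range(obj.getNumFluxObjectives())]
    if len(flux_objs) > 1:
        logger.warning(
            "objective has %d weighted reactions; taking the largest |coefficient|",
            len(flux_objs),
        )
    best = max(flux_objs, key=lambda fo: abs(fo.getCoefficient()))
    if best.getCoefficient() < 0:
        logger.warning(
            "objective reaction %s has a negative coefficient (minimization "
            "objective); flagged, treated as the objective reaction",
            best.getReaction(),
        )
    return best.getReaction()


def parse_sbml(
    path: str,
    objective_override: Optional[str] = None,
    extracellular_compartments: Iterable[str] = DEFAULT_EXTRACELLULAR,
) -> MetabolicNetwork:
    """Parse an SBML level 2/3 file (fbc supported) into a MetabolicNetwork.

    Metabolite and reaction ids are preserved verbatim.  Raises InputError
    for a missing/unreadable file and FormatError for structural defects.
    A model without any objective is tolerated (full-network mode only);
    the caller decides whether that is acceptable.
    """
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getModel() is None or doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        first = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        detail = first.getMessage() if first is not None else "no model element"
        raise InputError(f"cannot read SBML from {path!r}: {detail.strip()}")
    model = doc.getModel()

    net = MetabolicNetwork(
        extracellular_compartments=frozenset(extracellular_compartments)
    )
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        net.add_metabolite(
            Metabolite(
                id=sp.getId(),
                compartment=sp.getCompartment() or "default",
                name=sp.getName() or "",
            )
        )
    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        rid = rxn.getId()
        lb, ub = _reaction_bounds(model, rxn)
        net.add_reaction(
            Reaction(
                id=rid,
                reactants=_collect_side(
                    (rxn.getReactant(j) for j in range(rxn.getNumReactants())), rid
                ),
                products=_collect_side(
                    (rxn.getProduct(j) for j in range(rxn.getNumProducts())), rid
                ),
                lower_bound=lb,
                upper_bound=ub,
            )
        )

    objective = objective_override or _declared_objective(model)
    if objective is not None and objective not in net.reactions:
        raise InputError(f"objective reaction {objective!r} not found in the model")
    if objective is None:
        logger.info("model declares no objective reaction (full-network mode only)")
    net.objective_reaction_id = objective
    net.validate()
    return net


# ---------------------------------------------------------------------------
# SBML writing (fixtures and normalized-network export)
# ---------------------------------------------------------------------------


def write_sbml(net: MetabolicNetwork, path: str) -> None:
    """Serialize as SBML L3v1 with the fbc (v2) package carrying bounds and
    the objective.  Round-trips losslessly through parse_sbml for the fields
    the model uses."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    model = doc.createModel()
    model.setId("seedkit_model")
    mplug = model.getPlugin("fbc")
    mplug.setStrict(True)

    for comp_id in sorted({m.compartment for m in net.metabolites.values()}):
        comp = model.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    for mid in sorted(net.metabolites):
        met = net.metabolites[mid]
        sp = model.createSpecies()
        sp.setId(met.id)
        sp.setCompartment(met.compartment)
        if met.name:
            sp.setName(met.name)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)

    def _bound_param(value: float, pid: str) -> str:
        par = model.createParameter()
        par.setId(pid)
        par.setValue(value)
        par.setConstant(True)
        return pid

    for rid in sorted(net.reactions):
        rxn = net.reactions[rid]
        sr = model.createReaction()
        sr.setId(rxn.id)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setFast(False)
        for mid, coef in sorted(rxn.reactants.items()):
            ref = sr.createReactant()
            ref.setSpecies(mid)
            ref.setStoichiometry(float(coef))
            ref.setConstant(True)
        for mid, coef in sorted(rxn.products.items()):
            ref = sr.createProduct()
            ref.setSpecies(mid)
            ref.setStoichiometry(float(coef))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(_bound_param(rxn.lower_bound, f"{rid}_lb"))
        rplug.setUpperFluxBound(_bound_param(rxn.upper_bound, f"{rid}_ub"))

    if net.objective_reaction_id is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(net.objective_reaction_id)
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise InputError(f"cannot write SBML to {path!r}")
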