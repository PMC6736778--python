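"""Model serialization: a JSON dialect and SBML Level 3 with flux bounds.

The JSON dialect mirrors the in-memory types one-to-one and is the
format used for fixtures and community-model output::

    {
      "id": "Escherichia_coli_str_K12",
      "genus": "Escherichia", "species": "coli",
      "biomass_reaction_id": "BIOMASS",
      "metabolites": [{"id": "arg_e", "name": "L-arginine",
                       "compartment": "e", "formula": null, "charge": null}],
      "reactions":   [{"id": "EX_arg_e", "stoichiometry": {"arg_e": -1},
                       "lower_bound": -10.0, "upper_bound": 1000.0,
                       "kind": "exchange", "name": ""}]
    }

SBML export/import goes through python-libsbml using the fbc package for
flux bounds; reaction kinds are carried on SBO terms (exchange 627,
biomass 629, transport 185, sink/outflow 632) and the biomass reaction is
registered as the fbc objective.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

from .core import (
    DEFAULT_LOWER,
    DEFAULT_UPPER,
    MetabolicModel,
    Metabolite,
    Reaction,
    ReactionKind,
)

__all__ = ["load_model", "write_model", "ModelFormatError"]

_SBO_BY_KIND = {
    ReactionKind.EXCHANGE: "SBO:0000627",
    ReactionKind.BIOMASS: "SBO:0000629",
    ReactionKind.TRANSPORT: "SBO:0000185",
    ReactionKind.OUTFLOW: "SBO:0000632",
}
_KIND_BY_SBO = {v: k for k, v in _SBO_BY_KIND.items()}


class ModelFormatError(ValueError):
    """The file does not parse in the requested dialect."""


def load_model(path: str | Path, dialect: str | None = None) -> MetabolicModel:
    """Read a model file; ``dialect`` is ``"json"`` or ``"sbml"``.

    When ``dialect`` is omitted it is inferred from the file suffix
    (``.json`` vs ``.xml``/``.sbml``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "json" if path.suffix == ".json" else "sbml"
    if dialect == "json":
        return _load_json(path)
    if dialect == "sbml":
        return _load_sbml(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_model(model: MetabolicModel, path: str | Path, dialect: str | None = None) -> None:
    path = Path(path)
    if dialect is None:
        dialect = "json" if path.suffix == ".json" else "sbml"
    if dialect == "json":
        _write_json(model, path)
    elif dialect == "sbml":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# --------------------------------------------------------------------- JSON

def _load_json(path: Path) -> MetabolicModel:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    return model_from_dict(doc, source=str(path))


def model_from_dict(doc: dict, source: str = "<dict>") -> MetabolicModel:
    try:
        model = MetabolicModel(
            id=doc["id"],
            genus=doc.get("genus", ""),
            species=doc.get("species", ""),
            biomass_reaction_id=doc.get("biomass_reaction_id"),
        )
        for m in doc["metabolites"]:
            model.add_metabolite(
                Metabolite(
                    id=m["id"],
                    name=m.get("name", ""),
                    compartment=m.get("compartment", "c"),
                    formula=m.get("formula"),
                    charge=m.get("charge"),
                )
            )
        for r in doc["reactions"]:
            model.add_reaction(
                Reaction(
                    id=r["id"],
                    stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                    lower_bound=float(r.get("lower_bound", DEFAULT_LOWER)),
                    upper_bound=float(r.get("upper_bound", DEFAULT_UPPER)),
                    kind=ReactionKind(r.get("kind", "internal")),
                    name=r.get("name", ""),
                )
            )
    except KeyError as exc:
        raise ModelFormatError(f"{source}: missing required field {exc}") from exc
    model.validate()
    return model


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "genus": model.genus,
        "species": model.species,
        "biomass_reaction_id": model.biomass_reaction_id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "charge": m.charge,
            }
            for m in (model.metabolites[k] for k in model.sorted_metabolite_ids())
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "kind": r.kind.value,
            }
            for r in (model.reactions[k] for k in model.sorted_reaction_ids())
        ],
    }


def _write_json(model: MetabolicModel, path: Path) -> None:
    path.write_text(json.dumps(model_to_dict(model), indent=1) + "\n")


# --------------------------------------------------------------------- SBML

def _load_sbml(path: Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelFormatError(
            f"{path}: SBML parse error at line {err.getLine()}: {err.getMessage()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelFormatError(f"{path}: no <model> element")

    model = MetabolicModel(id=sbml_model.getId() or path.stem)
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        model.add_metabolite(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or "",
                compartment=sp.getCompartment() or "c",
            )
        )

    fbc = sbml_model.getPlugin("fbc")
    biomass_id = None
    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getActiveObjective() or fbc.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            biomass_id = obj.getFluxObjective(0).getReaction()

    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()

        lb, ub = _sbml_bounds(sbml_model, rx)
        sbo = f"SBO:{rx.getSBOTerm():07d}" if rx.isSetSBOTerm() else None
        kind = _KIND_BY_SBO.get(sbo, ReactionKind.INTERNAL)
        if rx.getId() == biomass_id:
            kind = ReactionKind.BIOMASS
        model.add_reaction(
            Reaction(
                id=rx.getId(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                kind=kind,
                name=rx.getName() or "",
            )
        )
    model.biomass_reaction_id = biomass_id
    model.validate()
    return model


def _sbml_bounds(sbml_model, rx) -> tuple[float, float]:
    rfbc = rx.getPlugin("fbc")
    lb = ub = None
    if rfbc is not None:
        for getter, setv in ((rfbc.getLowerFluxBound, "lb"), (rfbc.getUpperFluxBound, "ub")):
            pid = getter()
            if pid:
                par = sbml_model.getParameter(pid)
                if par is not None:
                    val = par.getValue()
                    if setv == "lb":
                        lb = val
                    else:
                        ub = val
    if lb is None:
        lb = DEFAULT_LOWER if rx.getReversible() else 0.0
    if ub is None:
        ub = DEFAULT_UPPER
    if math.isnan(lb) or math.isnan(ub):
        raise ModelFormatError(f"reaction {rx.getId()!r}: NaN flux bound")
    return float(lb), float(ub)


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.id)
    mfbc = sm.getPlugin("fbc")
    mfbc.setStrict(True)

    compartments = sorted({m.compartment for m in model.metabolites.values()})
    for comp in compartments:
        c = sm.createCompartment()
        c.setId(comp)
        c.setConstant(True)

    for mid in model.sorted_metabolite_ids():
        met = model.metabolites[mid]
        sp = sm.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)

    bound_params: dict[float, str] = {}

    def _param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rid in model.sorted_reaction_ids():
        rxn = model.reactions[rid]
        rx = sm.createReaction()
        rx.setId(rxn.id)
        rx.setName(rxn.name)
        rx.setFast(False)
        rx.setReversible(rxn.lower_bound < 0)
        sbo = _SBO_BY_KIND.get(rxn.kind)
        if sbo:
            rx.setSBOTerm(sbo)
        for met_id in sorted(rxn.stoichiometry):
            coef = rxn.stoichiometry[met_id]
            ref = rx.createReactant() if coef < 0 else rx.createProduct()
            ref.setSpecies(met_id)
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rfbc = rx.getPlugin("fbc")
        rfbc.setLowerFluxBound(_param(rxn.lower_bound))
        rfbc.setUpperFluxBound(_param(rxn.upper_bound))

    if model.biomass_reaction_id:
        obj = mfbc.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(model.biomass_reaction_id)
        fo.setCoefficient(1.0)
        mfbc.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))
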