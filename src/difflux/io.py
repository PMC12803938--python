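"""Model input/output: canonical JSON dialect and an SBML Level 3 FBC subset.

The JSON dialect is the package's canonical interchange format and round-trips
bit-identically (``write_model`` emits canonical JSON: sorted object keys,
two-space indent, trailing newline).  SBML support covers the subset the
pipeline needs — species, reactions with stoichiometry, FBC v2 flux bounds
and one active objective; subsystem labels and the artificial-exchange flag
travel in reaction notes.  Everything else (kinetic laws, gene associations,
CV-term annotations) is ignored on read with a logged warning.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Union

import libsbml

from .exceptions import FormatError, ModelValidationError
from .model import MetabolicModel, Metabolite, Reaction, validate_model

logger = logging.getLogger(__name__)

_JSON_VERSION = 1


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "format": "difflux-model",
        "version": _JSON_VERSION,
        "id": model.id,
        "default_bound": model.default_bound,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": {k: float(v) for k, v in r.stoichiometry.items()},
                "lower_bound": float(r.lower_bound),
                "upper_bound": float(r.upper_bound),
                "subsystem": r.subsystem,
                "is_exchange": r.is_exchange,
                "is_artificial": r.is_artificial,
            }
            for r in model.reactions
        ],
        "objective": {k: float(v) for k, v in model.objective.items()},
    }


def model_from_dict(data: dict) -> MetabolicModel:
    try:
        metabolites = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
            )
            for m in data["metabolites"]
        ]
        reactions = [
            Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r["lower_bound"]),
                upper_bound=float(r["upper_bound"]),
                subsystem=r.get("subsystem", ""),
                is_exchange=bool(r.get("is_exchange", False)),
                is_artificial=bool(r.get("is_artificial", False)),
            )
            for r in data["reactions"]
        ]
        objective = {k: float(v) for k, v in data.get("objective", {}).items()}
    except (KeyError, TypeError) as exc:
        raise FormatError(f"malformed difflux JSON model: {exc}") from exc
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        objective=objective,
        default_bound=float(data.get("default_bound", 1000.0)),
        id=data.get("id", "model"),
    )


def _dumps_canonical(data: dict) -> str:
    return json.dumps(data, indent=2, sort_keys=True) + "\n"


# ---------------------------------------------------------------------------
# SBML subset
# ---------------------------------------------------------------------------

_NOTE_RE = re.compile(r"<p>\s*([^:<]+):\s*([^<]*)</p>")


def _notes_dict(sbase) -> dict:
    notes = {}
    if sbase.isSetNotes():
        for key, value in _NOTE_RE.findall(sbase.getNotesString()):
            notes[key.strip().lower()] = value.strip()
    return notes


def _set_notes(sbase, mapping: dict) -> None:
    if not mapping:
        return
    body = "".join(f"<p>{k}: {v}</p>" for k, v in mapping.items())
    sbase.setNotes(
        f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'
    )


def _sbml_errors(doc) -> list:
    msgs = []
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            msgs.append(f"line {err.getLine()}: {err.getMessage().strip()}")
    return msgs


def _model_to_sbml(model: MetabolicModel) -> "libsbml.SBMLDocument":
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    smodel = doc.createModel()
    smodel.setId(model.id or "model")
    mplug = smodel.getPlugin("fbc")
    mplug.setStrict(True)

    for comp_id in sorted({m.compartment for m in model.metabolites} or {"c"}):
        comp = smodel.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    for m in model.metabolites:
        sp = smodel.createSpecies()
        sp.setId(f"M_{m.id}")
        sp.setName(m.name)
        sp.setCompartment(m.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)

    for r in model.reactions:
        for suffix, value in (("lb", r.lower_bound), ("ub", r.upper_bound)):
            par = smodel.createParameter()
            par.setId(f"R_{r.id}_{suffix}")
            par.setValue(float(value))
            par.setConstant(True)

    for r in model.reactions:
        rxn = smodel.createReaction()
        rxn.setId(f"R_{r.id}")
        rxn.setFast(False)
        rxn.setReversible(r.lower_bound < 0)
        for mid, coef in r.stoichiometry.items():
            ref = rxn.createReactant() if coef < 0 else rxn.createProduct()
            ref.setSpecies(f"M_{mid}")
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
        rplug = rxn.getPlugin("fbc")
        rplug.setLowerFluxBound(f"R_{r.id}_lb")
        rplug.setUpperFluxBound(f"R_{r.id}_ub")
        notes = {"exchange": "true" if r.is_exchange else "false"}
        if r.subsystem:
            notes["subsystem"] = r.subsystem
        if r.is_artificial:
            notes["artificial"] = "true"
        _set_notes(rxn, notes)

    if model.objective:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        mplug.setActiveObjectiveId("obj")
        for rid, coef in model.objective.items():
            fo = obj.createFluxObjective()
            fo.setReaction(f"R_{rid}")
            fo.setCoefficient(float(coef))
    return doc


def _strip_prefix(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _model_from_sbml(doc) -> MetabolicModel:
    errors = _sbml_errors(doc)
    if errors:
        raise FormatError("SBML parse errors: " + "; ".join(errors))
    smodel = doc.getModel()
    if smodel is None:
        raise FormatError("SBML document contains no model element")

    for attr, label in (
        ("getNumRules", "rules"),
        ("getNumEvents", "events"),
        ("getNumConstraints", "constraint elements"),
    ):
        if getattr(smodel, attr)() > 0:
            logger.warning("ignoring unsupported SBML %s", label)

    metabolites = []
    for sp in smodel.getListOfSpecies():
        metabolites.append(
            Metabolite(
                id=_strip_prefix(sp.getId(), "M_"),
                name=sp.getName() or "",
                compartment=sp.getCompartment() or "c",
            )
        )

    params = {
        p.getId(): p.getValue() for p in smodel.getListOfParameters() if p.isSetValue()
    }

    reactions = []
    for rxn in smodel.getListOfReactions():
        if rxn.isSetKineticLaw():
            logger.warning("ignoring kinetic law on reaction %s", rxn.getId())
        rid = _strip_prefix(rxn.getId(), "R_")
        stoich: dict = {}
        for ref in rxn.getListOfReactants():
            mid = _strip_prefix(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for ref in rxn.getListOfProducts():
            mid = _strip_prefix(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        rplug = rxn.getPlugin("fbc")
        if rplug is None or not (
            rplug.isSetLowerFluxBound() and rplug.isSetUpperFluxBound()
        ):
            raise ModelValidationError(
                f"reaction {rid!r} is missing FBC flux bounds"
            )
        try:
            lb = params[rplug.getLowerFluxBound()]
            ub = params[rplug.getUpperFluxBound()]
        except KeyError as exc:
            raise ModelValidationError(
                f"reaction {rid!r} references undefined bound parameter {exc}"
            ) from exc
        notes = _notes_dict(rxn)
        if "exchange" in notes:
            is_exchange = notes["exchange"].lower() == "true"
        else:
            # heuristic for foreign SBML: boundary moves a single species,
            # and iMM1865-style ids use the EX_ prefix
            is_exchange = len(stoich) == 1 or rid.startswith("EX_")
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                subsystem=notes.get("subsystem", ""),
                is_exchange=is_exchange,
                is_artificial=notes.get("artificial", "").lower() == "true",
            )
        )

    mplug = smodel.getPlugin("fbc")
    objective: dict = {}
    if mplug is not None:
        active = mplug.getActiveObjective()
        if active is not None:
            for fo in active.getListOfFluxObjectives():
                objective[_strip_prefix(fo.getReaction(), "R_")] = fo.getCoefficient()
    if not objective:
        raise ModelValidationError("SBML model has no active FBC objective")

    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        objective=objective,
        id=smodel.getId() or "model",
    )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _validate_or_raise(model: MetabolicModel, where: str) -> MetabolicModel:
    report = validate_model(model)
    if report.errors:
        raise ModelValidationError(
            f"invalid model from {where}: " + "; ".join(report.errors)
        )
    for w in report.warnings:
        logger.warning("%s: %s", where, w)
    return model


def read_model(path: Union[str, Path], format: str = "json") -> MetabolicModel:
    """Read and validate a model from ``path`` in the given format.

    Raises :class:`FormatError` on parse failure and
    :class:`ModelValidationError` when the parsed model violates an
    invariant (e.g. ``lower_bound > upper_bound`` or missing bounds).
    """
    path = Path(path)
    if format == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(
                f"{path}: line {exc.lineno}: not valid JSON ({exc.msg})"
            ) from exc
        model = model_from_dict(data)
    elif format == "sbml":
        doc = libsbml.readSBMLFromFile(str(path))
        model = _model_from_sbml(doc)
    else:
        raise ValueError(f"unknown model format {format!r}")
    return _validate_or_raise(model, str(path))


def write_model(
    model: MetabolicModel, path: Union[str, Path], format: str = "json"
) -> None:
    """Write ``model`` to ``path``; the file re-reads to an equal model."""
    path = Path(path)
    if format == "json":
        path.write_text(_dumps_canonical(model_to_dict(model)))
    elif format == "sbml":
        doc = _model_to_sbml(model)
        if not libsbml.writeSBMLToFile(doc, str(path)):
            raise IOError(f"could not write SBML to {path}")
    else:
        raise ValueError(f"unknown model format {format!r}")
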