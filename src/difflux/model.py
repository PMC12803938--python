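"""Core data structures for constraint-based metabolic models.

A :class:`MetabolicModel` is a stoichiometric network: metabolites, reactions
with flux bounds, and a linear (biomass) objective.  The convention follows
the COBRA field standard: the stoichiometric matrix ``S`` has one row per
metabolite and one column per reaction, steady state means ``S @ v = 0``, and
exchange reactions move a single metabolite across the system boundary
(negative flux = uptake, positive flux = secretion).  Boundary species are
implicit: an exchange reaction simply has a one-metabolite stoichiometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional

import numpy as np
from scipy import sparse

DEFAULT_BOUND = 1000.0


@dataclass
class Metabolite:
    """A chemical species in one compartment."""

    id: str
    name: str = ""
    compartment: str = "c"


@dataclass
class Reaction:
    """A (pseudo-)reaction with stoichiometry and flux bounds.

    Negative stoichiometric coefficients denote consumption.  Bounds use the
    usual mmol·gDW⁻¹·h⁻¹ convention (dimensionless in toy models).
    """

    id: str
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    subsystem: str = ""
    is_exchange: bool = False
    is_artificial: bool = False

    @property
    def bounds(self) -> tuple:
        return (self.lower_bound, self.upper_bound)

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class ValidationReport:
    errors: List[str] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def __str__(self) -> str:  # pragma: no cover - display helper
        lines = [f"ERROR: {e}" for e in self.errors]
        lines += [f"WARNING: {w}" for w in self.warnings]
        return "\n".join(lines) if lines else "model OK"


class MetabolicModel:
    """A stoichiometric model with bounds and a linear objective.

    Parameters
    ----------
    metabolites, reactions
        Ordered collections; order is preserved and defines the row/column
        order of the stoichiometric matrix (and hence solver determinism).
    objective
        Map reaction id -> coefficient of the (biomass) objective.
    default_bound
        Magnitude standing in for "unbounded" fluxes (field convention 1000).
    """

    def __init__(
        self,
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        objective: Optional[Dict[str, float]] = None,
        default_bound: float = DEFAULT_BOUND,
        id: str = "model",
        notes: Optional[Dict] = None,
    ) -> None:
        self.id = id
        self.metabolites: List[Metabolite] = list(metabolites)
        self.reactions: List[Reaction] = list(reactions)
        self.objective: Dict[str, float] = dict(objective or {})
        self.default_bound = float(default_bound)
        self.notes: Dict = dict(notes or {})

    # -- indexing ---------------------------------------------------------
    @property
    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"no reaction with id {rid!r}")

    def get_metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(f"no metabolite with id {mid!r}")

    def has_reaction(self, rid: str) -> bool:
        return any(r.id == rid for r in self.reactions)

    def add_reaction(self, reaction: Reaction) -> None:
        if self.has_reaction(reaction.id):
            raise ValueError(f"duplicate reaction id {reaction.id!r}")
        self.reactions.append(reaction)

    def exchanges_for(self, metabolite_id: str) -> List[Reaction]:
        """All exchange reactions touching the given metabolite."""
        return [
            r
            for r in self.reactions
            if r.is_exchange and metabolite_id in r.stoichiometry
        ]

    # -- linear algebra ---------------------------------------------------
    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        """S with shape (n_metabolites, n_reactions) in declared order."""
        met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        rows, cols, data = [], [], []
        for j, rxn in enumerate(self.reactions):
            for mid, coef in rxn.stoichiometry.items():
                rows.append(met_index[mid])
                cols.append(j)
                data.append(float(coef))
        return sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        )

    def bounds_arrays(self) -> tuple:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    def objective_array(self) -> np.ndarray:
        c = np.zeros(len(self.reactions))
        for i, r in enumerate(self.reactions):
            if r.id in self.objective:
                c[i] = self.objective[r.id]
        return c

    # -- lifecycle --------------------------------------------------------
    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            objective=dict(self.objective),
            default_bound=self.default_bound,
            id=self.id,
            notes={k: (dict(v) if isinstance(v, dict) else v) for k, v in self.notes.items()},
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        return (
            self.metabolite_ids == other.metabolite_ids
            and [(m.name, m.compartment) for m in self.metabolites]
            == [(m.name, m.compartment) for m in other.metabolites]
            and self.reaction_ids == other.reaction_ids
            and all(
                a.stoichiometry == b.stoichiometry
                and a.lower_bound == b.lower_bound
                and a.upper_bound == b.upper_bound
                and a.subsystem == b.subsystem
                and a.is_exchange == b.is_exchange
                and a.is_artificial == b.is_artificial
                for a, b in zip(self.reactions, other.reactions)
            )
            and self.objective == other.objective
            and self.default_bound == other.default_bound
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions>"
        )


def validate_model(model: MetabolicModel) -> ValidationReport:
    """Check structural invariants; report errors and soft warnings.

    Errors make the model unusable for simulation (unknown metabolite ids,
    inverted bounds, duplicate ids, malformed exchanges, objective naming a
    missing reaction).  Warnings flag suspicious but legal structure:
    dead-end metabolites (never producible or never consumable given the
    bounds), reactions frozen at zero flux, and an empty objective.
    """
    report = ValidationReport()
    met_ids = model.metabolite_ids
    rxn_ids = model.reaction_ids
    met_set = set(met_ids)

    if len(met_set) != len(met_ids):
        dup = sorted({m for m in met_ids if met_ids.count(m) > 1})
        report.errors.append(f"duplicate metabolite ids: {dup}")
    if len(set(rxn_ids)) != len(rxn_ids):
        dup = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
        report.errors.append(f"duplicate reaction ids: {dup}")
    for m in model.metabolites:
        if not m.id:
            report.errors.append("metabolite with empty id")
        if not m.compartment:
            report.errors.append(f"metabolite {m.id!r} has empty compartment")

    for r in model.reactions:
        if not r.id:
            report.errors.append("reaction with empty id")
        if r.lower_bound > r.upper_bound:
            report.errors.append(
                f"reaction {r.id!r}: lower_bound {r.lower_bound} > "
                f"upper_bound {r.upper_bound}"
            )
        if not r.stoichiometry and not r.is_exchange:
            report.errors.append(f"reaction {r.id!r}: empty stoichiometry")
        if r.is_exchange and len(r.stoichiometry) != 1:
            report.errors.append(
                f"exchange reaction {r.id!r} must touch exactly one metabolite "
                f"(has {len(r.stoichiometry)})"
            )
        unknown = sorted(set(r.stoichiometry) - met_set)
        if unknown:
            report.errors.append(
                f"reaction {r.id!r} references unknown metabolites: {unknown}"
            )

    missing_obj = sorted(set(model.objective) - set(rxn_ids))
    if missing_obj:
        report.errors.append(f"objective references missing reactions: {missing_obj}")
    if not model.objective:
        report.warnings.append("model has an empty objective")
    if model.default_bound <= 0:
        report.errors.append("default_bound must be positive")

    # dead-end metabolites: cannot be both produced and consumed
    producible = {m: False for m in met_set}
    consumable = {m: False for m in met_set}
    for r in model.reactions:
        for mid, coef in r.stoichiometry.items():
            if mid not in met_set:
                continue
            if (coef > 0 and r.upper_bound > 0) or (coef < 0 and r.lower_bound < 0):
                producible[mid] = True
            if (coef < 0 and r.upper_bound > 0) or (coef > 0 and r.lower_bound < 0):
                consumable[mid] = True
    # sinks (pure-consumption pseudo-reactions like biomass) count as consumers
    for mid in sorted(met_set):
        if not producible[mid]:
            report.warnings.append(f"dead-end metabolite {mid!r}: never produced")
        elif not consumable[mid]:
            report.warnings.append(f"dead-end metabolite {mid!r}: never consumed")

    for r in model.reactions:
        if r.lower_bound == 0 and r.upper_bound == 0:
            report.warnings.append(f"reaction {r.id!r} is fixed at zero flux")

    return report
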