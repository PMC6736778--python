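"""Stoichiometric data model for constraint-based community simulations.

All fluxes are expressed in mmol per gram microbiota per day (mmol/gM/d):
dietary uptake is normalized to the compound amount available per gram of
colonic microbiota (total mass taken as 200 g) per day, and every reaction
flux inherits that unit through the steady-state balance.

Sign conventions
----------------
Stoichiometric coefficients are negative for consumed metabolites and
positive for produced ones.  An *exchange* reaction touches exactly one
metabolite with coefficient -1, so negative flux means uptake from the
environment and positive flux means secretion.  An *outflow* reaction is an
irreversible drain (e.g. the agmatine outflow added during model
refinement).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping

__all__ = [
    "ReactionKind",
    "SolverStatus",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "FluxSolution",
    "ModelValidationError",
    "DEFAULT_UPPER",
    "DEFAULT_LOWER",
]

#: Default flux bounds (mmol/gM/d) for reactions without explicit annotation.
DEFAULT_UPPER = 1000.0
DEFAULT_LOWER = -1000.0


class ModelValidationError(ValueError):
    """A model violates a structural invariant (dangling ids, bad bounds...)."""


class ReactionKind(str, enum.Enum):
    INTERNAL = "internal"
    EXCHANGE = "exchange"
    TRANSPORT = "transport"
    BIOMASS = "biomass"
    OUTFLOW = "outflow"


class SolverStatus(str, enum.Enum):
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"
    UNBOUNDED = "unbounded"


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None
    charge: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("metabolite id must be non-empty")
        if not self.compartment:
            raise ModelValidationError(f"metabolite {self.id!r}: empty compartment")

    @property
    def base_id(self) -> str:
        """Metabolite id with a trailing ``_<compartment>`` suffix stripped.

        ``arg_e`` in compartment ``e`` has base id ``arg``; used to match
        diet compounds against exchange reactions across compartments.
        """
        suffix = f"_{self.compartment}"
        if self.id.endswith(suffix):
            return self.id[: -len(suffix)]
        return self.id


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = DEFAULT_LOWER
    upper_bound: float = DEFAULT_UPPER
    kind: ReactionKind = ReactionKind.INTERNAL
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        self.kind = ReactionKind(self.kind)
        if self.kind in (ReactionKind.EXCHANGE, ReactionKind.OUTFLOW):
            if len(self.stoichiometry) != 1:
                raise ModelValidationError(
                    f"{self.kind.value} reaction {self.id!r} must touch exactly "
                    f"one metabolite, got {len(self.stoichiometry)}"
                )
            (coef,) = self.stoichiometry.values()
            if coef != -1:
                raise ModelValidationError(
                    f"{self.kind.value} reaction {self.id!r} must have "
                    f"coefficient -1 (negative flux = uptake), got {coef}"
                )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class MetabolicModel:
    """A genome-scale (or toy) metabolic network for one strain.

    ``metabolites`` and ``reactions`` are id-keyed ordered mappings; LP
    construction always iterates in sorted-id order so repeated solves of
    the same model visit the same vertex.
    """

    id: str
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    biomass_reaction_id: str | None = None
    genus: str = ""
    species: str = ""

    # ---- construction helpers -------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        missing = [m for m in rxn.stoichiometry if m not in self.metabolites]
        if missing:
            raise ModelValidationError(
                f"reaction {rxn.id!r} references undeclared metabolites: "
                + ", ".join(sorted(missing))
            )
        self.reactions[rxn.id] = rxn

    def validate(self) -> None:
        """Check all structural invariants; raise ModelValidationError."""
        dangling: list[str] = []
        for rxn in self.reactions.values():
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    dangling.append(f"{rxn.id}->{met_id}")
        if dangling:
            raise ModelValidationError(
                f"model {self.id!r}: dangling metabolite references: "
                + ", ".join(sorted(dangling))
            )
        if self.biomass_reaction_id is not None:
            bio = self.reactions.get(self.biomass_reaction_id)
            if bio is None:
                raise ModelValidationError(
                    f"model {self.id!r}: biomass reaction "
                    f"{self.biomass_reaction_id!r} not found"
                )
            if bio.kind is not ReactionKind.BIOMASS:
                raise ModelValidationError(
                    f"model {self.id!r}: reaction {bio.id!r} designated as "
                    f"biomass has kind {bio.kind.value!r}"
                )

    # ---- queries ---------------------------------------------------------
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.kind is ReactionKind.EXCHANGE]

    def exchange_for_compound(self, compound: str) -> Reaction | None:
        """Exchange reaction whose metabolite matches ``compound``.

        Matches the full metabolite id first, then the compartment-stripped
        base id (so diet key ``arg`` finds the exchange of ``arg_e`` or,
        in a community, ``arg_u``).
        """
        for rxn in self.exchanges():
            (met_id,) = rxn.stoichiometry
            met = self.metabolites[met_id]
            if compound == met_id or compound == met.base_id:
                return rxn
        return None

    def copy(self) -> "MetabolicModel":
        clone = MetabolicModel(
            id=self.id,
            metabolites={k: replace(v) for k, v in self.metabolites.items()},
            reactions={k: v.copy() for k, v in self.reactions.items()},
            biomass_reaction_id=self.biomass_reaction_id,
            genus=self.genus,
            species=self.species,
        )
        return clone

    def sorted_reaction_ids(self) -> list[str]:
        return sorted(self.reactions)

    def sorted_metabolite_ids(self) -> list[str]:
        return sorted(self.metabolites)


@dataclass
class FluxSolution:
    """Outcome of one LP solve.

    ``primary_objective`` is the flux of the target reaction (not the
    penalized LP objective); ``total_abs_flux`` is sum(|v_j|) over all
    reactions at the returned vertex.
    """

    status: SolverStatus
    fluxes: dict[str, float] = field(default_factory=dict)
    primary_objective: float = 0.0
    total_abs_flux: float = 0.0
    penalty_coefficient: float = 0.0
    message: str = ""

    @property
    def optimal(self) -> bool:
        return self.status is SolverStatus.OPTIMAL

    def flux(self, reaction_id: str) -> float:
        return self.fluxes.get(reaction_id, 0.0)


def steady_state_residual(model: MetabolicModel, fluxes: Mapping[str, float]) -> float:
    """max over metabolites of \\|sum_j S_ij v_j\\| for a candidate solution."""
    balance: dict[str, float] = {m: 0.0 for m in model.metabolites}
    for rxn_id, v in fluxes.items():
        rxn = model.reactions.get(rxn_id)
        if rxn is None:
            continue
        for met_id, coef in rxn.stoichiometry.items():
            balance[met_id] += coef * v
    return max((abs(x) for x in balance.values()), default=0.0)
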