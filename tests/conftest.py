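"""Shared fixtures: analytic toy networks and the independent LP oracle."""

from __future__ import annotations

import numpy as np
import pytest

from agmacap.core import MetabolicModel, Metabolite, Reaction, ReactionKind


def _chain_model(uptake_lb: float = -10.0, conversion_ub: float = 1000.0) -> MetabolicModel:
    """A_ext -> A -> agm -> agm_ext chain; optimum is the binding bound."""
    m = MetabolicModel(id="chain")
    for mid, comp in (("A_e", "e"), ("A_c", "c"), ("agm_c", "c"), ("agm_e", "e")):
        m.add_metabolite(Metabolite(id=mid, compartment=comp))
    m.add_reaction(Reaction("EX_A", {"A_e": -1.0}, uptake_lb, 1000.0, ReactionKind.EXCHANGE))
    m.add_reaction(Reaction("At", {"A_e": -1.0, "A_c": 1.0}, 0.0, 1000.0,
                            ReactionKind.TRANSPORT))
    m.add_reaction(Reaction("CONV", {"A_c": -1.0, "agm_c": 1.0}, 0.0, conversion_ub))
    m.add_reaction(Reaction("AGMt", {"agm_c": -1.0, "agm_e": 1.0}, 0.0, 1000.0,
                            ReactionKind.TRANSPORT))
    m.add_reaction(Reaction("EX_agm", {"agm_e": -1.0}, 0.0, 1000.0, ReactionKind.EXCHANGE))
    m.validate()
    return m


def _two_route_model() -> MetabolicModel:
    """Two alternative routes to agmatine with equal capacity.

    Short route: A_c -> agm_c (1 reaction).  Long route:
    A_c -> x1 -> x2 -> x3 -> agm_c (4 reactions).  Under the total-flux
    penalty the short route must win.
    """
    m = MetabolicModel(id="two_route")
    for mid, comp in (
        ("A_e", "e"), ("A_c", "c"), ("x1_c", "c"), ("x2_c", "c"), ("x3_c", "c"),
        ("agm_c", "c"), ("agm_e", "e"),
    ):
        m.add_metabolite(Metabolite(id=mid, compartment=comp))
    m.add_reaction(Reaction("EX_A", {"A_e": -1.0}, -5.0, 1000.0, ReactionKind.EXCHANGE))
    m.add_reaction(Reaction("At", {"A_e": -1.0, "A_c": 1.0}, 0.0, 1000.0,
                            ReactionKind.TRANSPORT))
    m.add_reaction(Reaction("SHORT", {"A_c": -1.0, "agm_c": 1.0}, 0.0, 1000.0))
    m.add_reaction(Reaction("L1", {"A_c": -1.0, "x1_c": 1.0}, 0.0, 1000.0))
    m.add_reaction(Reaction("L2", {"x1_c": -1.0, "x2_c": 1.0}, 0.0, 1000.0))
    m.add_reaction(Reaction("L3", {"x2_c": -1.0, "x3_c": 1.0}, 0.0, 1000.0))
    m.add_reaction(Reaction("L4", {"x3_c": -1.0, "agm_c": 1.0}, 0.0, 1000.0))
    m.add_reaction(Reaction("AGMt", {"agm_c": -1.0, "agm_e": 1.0}, 0.0, 1000.0,
                            ReactionKind.TRANSPORT))
    m.add_reaction(Reaction("EX_agm", {"agm_e": -1.0}, 0.0, 1000.0, ReactionKind.EXCHANGE))
    m.validate()
    return m


@pytest.fixture
def chain_model() -> MetabolicModel:
    return _chain_model()


@pytest.fixture
def two_route_model() -> MetabolicModel:
    return _two_route_model()


def cobra_optimum(model: MetabolicModel, objective: str, sense: str = "max") -> float | None:
    """Independent oracle: solve the same network with cobrapy + GLPK.

    Returns the optimal objective value, or None if infeasible.
    """
    import cobra

    cm = cobra.Model(model.id)
    cm.solver = "glpk"
    mets = {
        mid: cobra.Metabolite(mid, compartment=met.compartment)
        for mid, met in model.metabolites.items()
    }
    reactions = []
    for rid, rxn in model.reactions.items():
        cr = cobra.Reaction(rid, lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound)
        reactions.append(cr)
    cm.add_reactions(reactions)
    for rid, rxn in model.reactions.items():
        cm.reactions.get_by_id(rid).add_metabolites(
            {mets[m]: c for m, c in rxn.stoichiometry.items()}
        )
    cm.objective = cm.reactions.get_by_id(objective)
    cm.objective_direction = "max" if sense == "max" else "min"
    sol = cm.optimize()
    if sol.status != "optimal":
        return None
    return float(sol.objective_value)
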