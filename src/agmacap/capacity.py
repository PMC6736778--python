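"""Per-participant agmatine production capacity and downstream statistics.

Capacity is the maximal community-level secretion flux of agmatine
(mmol/gM/d) under the participant's diet, computed by FBA with the small
total-flux penalty.  The optimal flux distribution is further dissected
into per-species contributions (each member's net agmatine export into
the lumen, summed over strains of one species) and molar side-product
yields (other community secretions per mole of agmatine).  In-silico
supplementation screens relax one exchange bound at a time and report
the capacity ratio; group differences in capacity are tested with
pairwise Wilcoxon rank-sum tests under Benjamini-Hochberg control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .community import CommunityModel, LUMEN
from .core import FluxSolution, MetabolicModel, SolverStatus
from .fba import fba_with_flux_penalty
from .stats import benjamini_hochberg

__all__ = [
    "CapacityResult",
    "SupplementResult",
    "predict_capacity",
    "species_contributions",
    "side_product_yields",
    "supplement_screen",
    "op50_supplement_screen",
    "compare_groups",
    "AGMATINE",
]

log = logging.getLogger(__name__)

AGMATINE = "agm"


@dataclass
class CapacityResult:
    participant_id: str
    capacity: float  # mmol/gM/d
    solution: FluxSolution
    species_contributions: dict[str, float] = field(default_factory=dict)
    side_products: dict[str, float] = field(default_factory=dict)  # mol per mol agmatine


@dataclass
class SupplementResult:
    compound: str
    baseline_capacity: float
    supplemented_capacity: float

    @property
    def ratio(self) -> float | None:
        """supplemented / baseline; None when the baseline is zero."""
        if self.baseline_capacity <= 0:
            return None
        return self.supplemented_capacity / self.baseline_capacity


def _target_exchange(model: MetabolicModel, target: str) -> str | None:
    rxn = model.exchange_for_compound(target)
    if rxn is not None:
        return rxn.id
    # single-strain models drain agmatine through the refinement outflow
    from .refine import OUTFLOW_RXN_ID

    if OUTFLOW_RXN_ID in model.reactions:
        return OUTFLOW_RXN_ID
    return None


def predict_capacity(
    community: CommunityModel | MetabolicModel,
    target: str = AGMATINE,
    epsilon: float = 1e-6,
    attribute: bool = True,
) -> CapacityResult:
    """Maximal target secretion with the total-flux penalty.

    For a community the objective is the lumen exchange of ``target``;
    for a single-strain model the refinement outflow serves.  A model
    without any target boundary reaction gets capacity 0 with a warning.
    """
    pid = getattr(community, "id", "model").removeprefix("community_")
    target_rxn = _target_exchange(community, target)
    if target_rxn is None:
        log.warning("%s: no %s exchange/outflow; capacity set to 0", community.id, target)
        return CapacityResult(
            participant_id=pid, capacity=0.0,
            solution=FluxSolution(status=SolverStatus.INFEASIBLE,
                                  message=f"no {target} boundary reaction"),
        )
    sol = fba_with_flux_penalty(community, target_rxn, epsilon=epsilon)
    if not sol.optimal:
        log.warning("%s: capacity LP %s (%s)", community.id, sol.status.value, sol.message)
        return CapacityResult(participant_id=pid, capacity=0.0, solution=sol)
    capacity = max(sol.primary_objective, 0.0)
    result = CapacityResult(participant_id=pid, capacity=capacity, solution=sol)
    if attribute and isinstance(community, CommunityModel):
        result.species_contributions = species_contributions(community, sol, target)
        result.side_products = side_product_yields(community, sol, target)
    return result


def species_contributions(
    community: CommunityModel,
    solution: FluxSolution,
    target: str = AGMATINE,
    taxonomy: Mapping[str, str] | None = None,
) -> dict[str, float]:
    """Net per-species export of the target into the lumen.

    Each member's contribution is the net rate at which its reactions
    produce the lumen target metabolite; strains mapping to the same
    species (via ``taxonomy``, default: the strain id itself) are summed.
    Contributions total the community capacity at steady state.
    """
    if not solution.optimal:
        return {}
    lumen_met = f"{target}_{LUMEN}"
    out: dict[str, float] = {}
    for strain in sorted(community.members):
        net = 0.0
        for rid in community.member_reaction_ids[strain]:
            coef = community.reactions[rid].stoichiometry.get(lumen_met)
            if coef:
                net += coef * solution.flux(rid)
        species = (taxonomy or {}).get(strain, strain)
        out[species] = out.get(species, 0.0) + net
    return out


def side_product_yields(
    community: CommunityModel,
    solution: FluxSolution,
    target: str = AGMATINE,
    tol: float = 1e-9,
) -> dict[str, float]:
    """Moles of each co-secreted community product per mole of target.

    Only community-level secretions count (member-lumen transports are
    internal).  Empty when the target flux is ~0.
    """
    if not solution.optimal:
        return {}
    target_rxn = _target_exchange(community, target)
    target_flux = solution.flux(target_rxn) if target_rxn else 0.0
    if target_flux <= tol:
        return {}
    yields: dict[str, float] = {}
    for rxn in community.exchanges():
        if rxn.id == target_rxn:
            continue
        v = solution.flux(rxn.id)
        if v > tol:
            (met_id,) = rxn.stoichiometry
            yields[met_id] = v / target_flux
    return yields


def supplement_screen(
    community: CommunityModel | MetabolicModel,
    compounds: Sequence[str],
    amount: float = 1.0,
    target: str = AGMATINE,
    epsilon: float = 1e-6,
    ratio_tol: float = 1e-9,
) -> list[SupplementResult]:
    """Capacity change when each compound's uptake is relaxed by ``amount``.

    The exchange lower bound is shifted additively by ``-amount``
    (default 1 mmol/gM/d) one compound at a time; adding uptake can never
    reduce an LP maximum, which is asserted per run.
    """
    baseline = predict_capacity(community, target=target, epsilon=epsilon, attribute=False)
    results: list[SupplementResult] = []
    for compound in compounds:
        rxn = community.exchange_for_compound(compound)
        if rxn is None:
            log.warning("%s: no exchange for %s; skipped", community.id, compound)
            continue
        supplemented = community.copy()
        supplemented.reactions[rxn.id].lower_bound -= amount
        cap = predict_capacity(supplemented, target=target, epsilon=epsilon, attribute=False)
        if cap.capacity < baseline.capacity - ratio_tol - epsilon * baseline.capacity:
            raise AssertionError(
                f"supplementation of {compound} decreased capacity: "
                f"{baseline.capacity} -> {cap.capacity}"
            )
        results.append(
            SupplementResult(
                compound=compound,
                baseline_capacity=baseline.capacity,
                supplemented_capacity=cap.capacity,
            )
        )
    return results


def op50_supplement_screen(
    model: MetabolicModel,
    ngm_diet: Mapping[str, float] | "object",
    compounds: Sequence[str],
    amount: float = 5.0,
    target: str = AGMATINE,
    epsilon: float = 1e-6,
) -> list[SupplementResult]:
    """Single-strain supplementation screen on an NGM-style medium.

    The growth-medium variant of the screen: the diet is applied first,
    then each compound's inflow is extended by ``amount`` (default
    +5 mmol/L, the medium-supplementation convention for a single strain
    in liquid culture) and the agmatine yield ratio is reported.
    """
    from .fba import apply_diet

    base_model, _ = apply_diet(model, ngm_diet)
    return supplement_screen(
        base_model, compounds, amount=amount, target=target, epsilon=epsilon
    )


def compare_groups(
    capacities: Mapping[str, float],
    groups: Mapping[str, str],
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """All pairwise two-sided Wilcoxon rank-sum tests between groups.

    Returns one row per group pair with the rank-sum statistic, raw p,
    Benjamini-Hochberg adjusted p (across the pairs), and group medians.
    Requires at least two groups with at least two members each.
    """
    by_group: dict[str, list[float]] = {}
    for participant, value in capacities.items():
        label = groups.get(participant)
        if label is None:
            continue
        by_group.setdefault(label, []).append(value)
    labels = sorted(by_group)
    small = [g for g in labels if len(by_group[g]) < 2]
    if len(labels) < 2 or small:
        raise ValueError(
            f"need >= 2 groups with >= 2 members each; groups={ {g: len(v) for g, v in by_group.items()} }"
        )
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            res = stats.mannwhitneyu(
                by_group[a], by_group[b], alternative="two-sided", method="auto"
            )
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "n_a": len(by_group[a]),
                    "n_b": len(by_group[b]),
                    "median_a": float(pd.Series(by_group[a]).median()),
                    "median_b": float(pd.Series(by_group[b]).median()),
                    "statistic": float(res.statistic),
                    "p_value": float(res.pvalue),
                }
            )
    df = pd.DataFrame(rows)
    df["fdr"] = benjamini_hochberg(df["p_value"].to_numpy())
    df["significant"] = df["fdr"] < fdr_threshold
    return df
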