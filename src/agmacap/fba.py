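"""Flux balance analysis with an optional total-flux penalty.

Two solves are provided:

``fba``
    max/min a single reaction flux subject to S.v = 0 and bounds.

``fba_with_flux_penalty``
    maximize  v_target - epsilon * sum_j |v_j|
    the production-capacity objective: the target outflow dominates
    (epsilon defaults to 1e-6) while the tiny penalty removes loose
    futile cycles and makes the reported flux distribution parsimonious.

Absolute values are linearized through auxiliary epigraph variables
t_j >= |v_j|; because every t_j carries a positive cost the optimizer
pins t_j = |v_j|, so no complementarity constraint is needed and
reactions with strictly positive lower bounds (e.g. a community biomass
floor) are handled uniformly.

The LP is solved by HiGHS via :func:`scipy.optimize.linprog`.  Variable
order is id-sorted, so repeated solves of an identical model return the
identical vertex.  Only the objective value is contractual: degenerate
alternate optima may differ in individual fluxes.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .core import (
    FluxSolution,
    MetabolicModel,
    ReactionKind,
    SolverStatus,
)

__all__ = ["fba", "fba_with_flux_penalty", "apply_diet", "LeqRow"]

#: one extra linear inequality  sum_i coeffs[rxn_i] * v_i <= bound
LeqRow = tuple[dict[str, float], float]


def _model_extra_rows(model: MetabolicModel) -> list[LeqRow]:
    """Inequality rows attached to the model (community coupling constraints)."""
    getter = getattr(model, "extra_constraints", None)
    if getter is None:
        return []
    rows = getter() if callable(getter) else getter
    return list(rows)


def _status_from_linprog(status_code: int) -> SolverStatus:
    if status_code == 0:
        return SolverStatus.OPTIMAL
    if status_code == 3:
        return SolverStatus.UNBOUNDED
    return SolverStatus.INFEASIBLE


def _stoichiometric_matrix(
    model: MetabolicModel, rxn_ids: Sequence[str], n_extra_cols: int = 0
) -> sparse.csr_matrix:
    met_index = {m: i for i, m in enumerate(model.sorted_metabolite_ids())}
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for j, rid in enumerate(rxn_ids):
        for met_id, coef in model.reactions[rid].stoichiometry.items():
            rows.append(met_index[met_id])
            cols.append(j)
            vals.append(coef)
    shape = (len(met_index), len(rxn_ids) + n_extra_cols)
    return sparse.coo_matrix((vals, (rows, cols)), shape=shape).tocsr()


def _unbounded_suspects(model: MetabolicModel) -> str:
    names = [
        r.id
        for r in model.reactions.values()
        if not np.isfinite(r.lower_bound) or not np.isfinite(r.upper_bound)
    ]
    if names:
        return "reactions with infinite bounds (candidate ray members): " + ", ".join(
            sorted(names)[:10]
        )
    return "no infinite bounds; check for an unbounded cycle"


def fba(
    model: MetabolicModel,
    objective_reaction: str,
    sense: str = "max",
    extra_leq: Sequence[LeqRow] | None = None,
) -> FluxSolution:
    """Optimize a single reaction flux at steady state.

    Parameters
    ----------
    model : MetabolicModel
        Network with bounds already reflecting the diet.
    objective_reaction : str
        Reaction id to optimize (e.g. the biomass reaction or an
        agmatine outflow).
    sense : {"max", "min"}
    extra_leq : sequence of (coeffs, bound), optional
        Additional inequality rows ``sum coeffs[r]*v_r <= bound`` on top of
        any constraints attached to the model itself.
    """
    if objective_reaction not in model.reactions:
        raise KeyError(f"objective reaction {objective_reaction!r} not in model")
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")

    rxn_ids = model.sorted_reaction_ids()
    idx = {r: j for j, r in enumerate(rxn_ids)}
    n = len(rxn_ids)

    c = np.zeros(n)
    c[idx[objective_reaction]] = -1.0 if sense == "max" else 1.0

    A_eq = _stoichiometric_matrix(model, rxn_ids)
    b_eq = np.zeros(A_eq.shape[0])
    bounds = [
        (model.reactions[r].lower_bound, model.reactions[r].upper_bound)
        for r in rxn_ids
    ]

    rows = _model_extra_rows(model) + list(extra_leq or [])
    A_ub, b_ub = _leq_matrix(rows, idx, n_total=n)

    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs"
    )
    status = _status_from_linprog(res.status)
    if status is not SolverStatus.OPTIMAL:
        msg = res.message
        if status is SolverStatus.UNBOUNDED:
            msg = f"{res.message} {_unbounded_suspects(model)}"
        return FluxSolution(status=status, message=msg)

    fluxes = {r: float(res.x[j]) for j, r in enumerate(rxn_ids)}
    return FluxSolution(
        status=status,
        fluxes=fluxes,
        primary_objective=fluxes[objective_reaction],
        total_abs_flux=float(np.abs(res.x[:n]).sum()),
        penalty_coefficient=0.0,
    )


def fba_with_flux_penalty(
    model: MetabolicModel,
    target_outflow: str,
    epsilon: float = 1e-6,
    penalize_exchanges: bool = True,
    extra_leq: Sequence[LeqRow] | None = None,
) -> FluxSolution:
    """Maximize the target outflow with a small total-flux penalty.

    The objective is ``v_target - epsilon * sum_j |v_j|`` with the sum
    running over all reactions (set ``penalize_exchanges=False`` to leave
    boundary fluxes out of the penalty for sensitivity analysis).

    ``primary_objective`` reports the target flux itself, not the
    penalized objective value.
    """
    if target_outflow not in model.reactions:
        raise KeyError(f"target outflow {target_outflow!r} not in model")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")

    rxn_ids = model.sorted_reaction_ids()
    idx = {r: j for j, r in enumerate(rxn_ids)}
    n = len(rxn_ids)

    if penalize_exchanges:
        penalized = list(range(n))
    else:
        penalized = [
            j
            for j, r in enumerate(rxn_ids)
            if model.reactions[r].kind is not ReactionKind.EXCHANGE
        ]
    m = len(penalized)

    # variables: v_0..v_{n-1}, then t_k >= |v_{penalized[k]}|
    c = np.zeros(n + m)
    c[idx[target_outflow]] = -1.0
    c[n:] = epsilon

    A_eq = _stoichiometric_matrix(model, rxn_ids, n_extra_cols=m)
    b_eq = np.zeros(A_eq.shape[0])

    bounds: list[tuple[float, float]] = [
        (model.reactions[r].lower_bound, model.reactions[r].upper_bound)
        for r in rxn_ids
    ]
    for j in penalized:
        lb, ub = bounds[j]
        cap = max(abs(lb), abs(ub))
        bounds.append((0.0, cap if np.isfinite(cap) else np.inf))

    # epigraph rows: v_j - t_k <= 0 and -v_j - t_k <= 0
    rows_i: list[int] = []
    cols_i: list[int] = []
    vals: list[float] = []
    for k, j in enumerate(penalized):
        r0 = 2 * k
        rows_i += [r0, r0, r0 + 1, r0 + 1]
        cols_i += [j, n + k, j, n + k]
        vals += [1.0, -1.0, -1.0, -1.0]
    A_epi = sparse.coo_matrix((vals, (rows_i, cols_i)), shape=(2 * m, n + m)).tocsr()
    b_epi = np.zeros(2 * m)

    extra_rows = _model_extra_rows(model) + list(extra_leq or [])
    A_extra, b_extra = _leq_matrix(extra_rows, idx, n_total=n + m)
    if A_extra is not None:
        A_ub = sparse.vstack([A_epi, A_extra]).tocsr()
        b_ub = np.concatenate([b_epi, b_extra])
    else:
        A_ub, b_ub = A_epi, b_epi

    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs"
    )
    status = _status_from_linprog(res.status)
    if status is not SolverStatus.OPTIMAL:
        msg = res.message
        if status is SolverStatus.UNBOUNDED:
            msg = f"{res.message} {_unbounded_suspects(model)}"
        return FluxSolution(status=status, message=msg, penalty_coefficient=epsilon)

    v = res.x[:n]
    fluxes = {r: float(v[j]) for j, r in enumerate(rxn_ids)}
    return FluxSolution(
        status=status,
        fluxes=fluxes,
        primary_objective=fluxes[target_outflow],
        total_abs_flux=float(np.abs(v).sum()),
        penalty_coefficient=epsilon,
    )


def _leq_matrix(
    rows: Sequence[LeqRow], idx: Mapping[str, int], n_total: int
) -> tuple[sparse.csr_matrix | None, np.ndarray | None]:
    if not rows:
        return None, None
    ri: list[int] = []
    ci: list[int] = []
    vals: list[float] = []
    b = np.empty(len(rows))
    for i, (coeffs, bound) in enumerate(rows):
        b[i] = bound
        for rxn_id, coef in coeffs.items():
            ri.append(i)
            ci.append(idx[rxn_id])
            vals.append(coef)
    A = sparse.coo_matrix((vals, (ri, ci)), shape=(len(rows), n_total)).tocsr()
    return A, b


def apply_diet(
    model: MetabolicModel,
    diet: Mapping[str, float] | "object",
    inplace: bool = False,
) -> tuple[MetabolicModel, list[str]]:
    """Constrain exchange lower bounds by a diet.

    For every diet compound with a matching exchange reaction the uptake
    bound becomes ``-amount``; exchanges of compounds absent from the diet
    are closed to uptake (lower bound 0).  Secretion (upper) bounds are
    untouched.

    Returns the constrained model and the list of diet compounds that had
    no matching exchange reaction (skipped, not fatal).
    """
    amounts: Mapping[str, float] = getattr(diet, "amounts", diet)  # DietSpec or dict
    for compound, amount in amounts.items():
        if amount < 0:
            raise ValueError(f"diet amount for {compound!r} is negative: {amount}")

    out = model if inplace else model.copy()
    matched: dict[str, float] = {}
    used: set[str] = set()
    for rxn in out.exchanges():
        (met_id,) = rxn.stoichiometry
        met = out.metabolites[met_id]
        amount = None
        for key in (met_id, met.base_id):
            if key in amounts:
                amount = amounts[key]
                used.add(key)
                break
        rxn.lower_bound = -float(amount) if amount is not None else 0.0
        if amount is not None:
            matched[rxn.id] = amount
    skipped = sorted(set(amounts) - used)
    return out, skipped
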