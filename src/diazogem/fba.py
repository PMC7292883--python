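"""Linear-programming core: FBA, parsimonious FBA and blocked-reaction
detection.

Flux balance analysis solves

    max / min  c . v     s.t.  S v = 0,   lb <= v <= ub

with S the stoichiometric matrix, v the flux vector (mmol/gDW/h) and c
the indicator of the objective reaction (a biomass objective gives the
growth rate mu in 1/h).  All LPs go through scipy's HiGHS interface,
which is deterministic, so repeated solves return identical
distributions.

FBA optima are typically degenerate; parsimonious FBA (pFBA) fixes the
objective at its optimum and then minimizes the total absolute flux,
selecting a unique, biologically parsimonious distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Set

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .core_model import (
    DEFAULT_BOUND,
    DiazogemError,
    Medium,
    MetabolicModel,
    apply_medium,
    stoich_matrix,
)

__all__ = ["FluxDistribution", "SolverError", "fba", "pfba", "blocked_reactions"]

#: feasibility/optimality tolerance for the solver
SOLVE_TOL = 1e-9
#: reporting tolerance (steady-state residual, flux comparisons)
REPORT_TOL = 1e-6


class SolverError(DiazogemError):
    """The LP solver failed for a reason other than infeasibility."""


@dataclass
class FluxDistribution:
    """Reaction -> flux map with the objective value and solver status.

    ``status`` is one of ``optimal``, ``infeasible``, ``unbounded``.  The
    flux map is empty unless the status is ``optimal``.
    """

    fluxes: Dict[str, float] = field(default_factory=dict)
    objective_value: Optional[float] = None
    status: str = "optimal"
    objective_id: Optional[str] = None

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    def steady_state_residual(self, model: MetabolicModel) -> float:
        """``max_i |S v|_i`` — 0 for a mass-balanced flux distribution."""
        S, _, rxn_ids = stoich_matrix(model)
        v = np.array([self.fluxes.get(r, 0.0) for r in rxn_ids])
        if len(v) == 0:
            return 0.0
        return float(np.max(np.abs(S @ v))) if S.shape[0] else 0.0


def _bounds(model: MetabolicModel):
    lbs, ubs = [], []
    for rxn in model.reactions.values():
        lb, ub = rxn.lower_bound, rxn.upper_bound
        lb = -DEFAULT_BOUND if math.isinf(lb) else lb
        ub = DEFAULT_BOUND if math.isinf(ub) else ub
        lbs.append(lb)
        ubs.append(ub)
    return np.array(lbs), np.array(ubs)


_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded"}


def fba(
    model: MetabolicModel,
    objective_id: Optional[str] = None,
    sense: str = "max",
) -> FluxDistribution:
    """Optimize the flux of one reaction subject to S v = 0 and the bounds."""
    objective_id = objective_id or model.objective_id
    if objective_id is None or objective_id not in model.reactions:
        raise DiazogemError(f"objective reaction {objective_id!r} not in model")
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")

    S, _, rxn_ids = stoich_matrix(model)
    n = len(rxn_ids)
    c = np.zeros(n)
    c[rxn_ids.index(objective_id)] = -1.0 if sense == "max" else 1.0
    lb, ub = _bounds(model)

    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options={"primal_feasibility_tolerance": SOLVE_TOL,
                 "dual_feasibility_tolerance": SOLVE_TOL},
    )
    status = _STATUS.get(res.status, "error")
    if status in ("infeasible", "unbounded"):
        return FluxDistribution(status=status, objective_id=objective_id)
    if status != "optimal":
        raise SolverError(f"LP solve failed: {res.message}")
    fluxes = {rid: float(res.x[i]) for i, rid in enumerate(rxn_ids)}
    return FluxDistribution(
        fluxes=fluxes,
        objective_value=float(fluxes[objective_id]),
        status="optimal",
        objective_id=objective_id,
    )


def pfba(model: MetabolicModel, objective_id: Optional[str] = None) -> FluxDistribution:
    """Parsimonious FBA: fix the FBA optimum, then minimize total |v|.

    The returned distribution attains the same objective value as
    :func:`fba` (within solver tolerance) with the smallest total
    absolute flux, which removes the degeneracy of plain FBA.
    """
    objective_id = objective_id or model.objective_id
    base = fba(model, objective_id, "max")
    if base.status != "optimal":
        return base
    opt = base.objective_value

    S, _, rxn_ids = stoich_matrix(model)
    n = len(rxn_ids)
    j_obj = rxn_ids.index(objective_id)
    lb, ub = _bounds(model)
    # pin the objective reaction at its optimum (relative slack 1e-9)
    slack = 1e-9 * max(1.0, abs(opt))
    lb[j_obj] = opt - slack
    ub[j_obj] = max(ub[j_obj], opt)

    # variables [v, t]; minimize sum t with t >= v and t >= -v
    c = np.concatenate([np.zeros(n), np.ones(n)])
    A_eq = sparse.hstack([S, sparse.csc_matrix(S.shape)])
    eye = sparse.identity(n, format="csc")
    A_ub = sparse.vstack([sparse.hstack([eye, -eye]), sparse.hstack([-eye, -eye])])
    bounds = np.column_stack(
        [np.concatenate([lb, np.zeros(n)]),
         np.concatenate([ub, np.full(n, np.inf)])]
    )
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=np.zeros(2 * n),
        A_eq=A_eq,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": SOLVE_TOL,
                 "dual_feasibility_tolerance": SOLVE_TOL},
    )
    if res.status != 0:
        raise SolverError(f"pFBA minimization failed: {res.message}")
    fluxes = {rid: float(res.x[i]) for i, rid in enumerate(rxn_ids)}
    return FluxDistribution(
        fluxes=fluxes,
        objective_value=float(fluxes[objective_id]),
        status="optimal",
        objective_id=objective_id,
    )


def blocked_reactions(
    model: MetabolicModel, medium: Optional[Medium] = None, tol: float = SOLVE_TOL
) -> Set[str]:
    """Reactions whose flux maximum and minimum are both 0 under ``medium``.

    A blocked reaction cannot carry flux anywhere in the feasible region
    (flux-variability test at tolerance ``tol``).
    """
    constrained = apply_medium(model, medium) if medium is not None else model
    S, _, rxn_ids = stoich_matrix(constrained)
    n = len(rxn_ids)
    lb, ub = _bounds(constrained)
    bounds = np.column_stack([lb, ub])
    blocked = set()
    for j, rid in enumerate(rxn_ids):
        extreme = 0.0
        for sign in (-1.0, 1.0):
            c = np.zeros(n)
            c[j] = sign
            res = linprog(
                c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs"
            )
            if res.status == 3:  # unbounded in this direction: not blocked
                extreme = np.inf
                break
            if res.status == 0:
                extreme = max(extreme, abs(float(res.x[j])))
            if extreme > tol:
                break
        if extreme <= tol:
            blocked.add(rid)
    return blocked
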