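"""Flux balance analysis.

FBA solves the linear program

    maximize    v_biomass
    subject to  S v = 0          (steady state over all metabolites)
                lb <= v <= ub    (reaction bounds; medium sets exchange uptake)

with the HiGHS backend of :func:`scipy.optimize.linprog`.  Exchange
reactions follow the sign convention that uptake is negative flux, so a
medium's maximum uptake ``u`` for an exchange becomes a lower bound of
``-u``; exchanges absent from the medium are closed to uptake but remain
open to secretion.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import coo_matrix

from .errors import SolverError
from .network import (
    DEFAULT_BOUND,
    FluxDistribution,
    MediumCondition,
    MetabolicNetwork,
)

SOLVER_TOLERANCE = 1e-6
DEFAULT_EPSILON = 1e-3


def _stoichiometric_matrix(network: MetabolicNetwork,
                           reaction_ids: List[str]) -> Tuple[coo_matrix, List[str]]:
    met_ids = sorted(network.metabolites)
    met_index = {m: i for i, m in enumerate(met_ids)}
    rows, cols, data = [], [], []
    for j, rid in enumerate(reaction_ids):
        for mid, coef in network.reactions[rid].stoichiometry.items():
            rows.append(met_index[mid])
            cols.append(j)
            data.append(float(coef))
    S = coo_matrix((data, (rows, cols)), shape=(len(met_ids), len(reaction_ids)))
    return S, met_ids


def reaction_bounds(rxn, medium: MediumCondition,
                    secretion_bound: float = DEFAULT_BOUND) -> Tuple[float, float]:
    """Effective bounds of one reaction under a medium."""
    if rxn.is_exchange:
        uptake = float(medium.uptake_bounds.get(rxn.id, 0.0))
        return (-uptake, secretion_bound)
    return (rxn.lower_bound, rxn.upper_bound)


def fba(network: MetabolicNetwork, medium: MediumCondition, *,
        secretion_bound: float = DEFAULT_BOUND,
        validate: bool = True) -> FluxDistribution:
    """Maximize biomass flux; infeasible problems return objective 0 with
    ``feasible=False`` rather than raising.

    Raises
    ------
    ValidationError
        if the network violates its structural invariants.
    SolverError
        if the LP solver fails for any reason other than infeasibility.
    """
    if validate:
        network.validate()
    reaction_ids = sorted(network.reactions)
    S, _ = _stoichiometric_matrix(network, reaction_ids)
    bounds = [reaction_bounds(network.reactions[rid], medium, secretion_bound)
              for rid in reaction_ids]
    c = np.zeros(len(reaction_ids))
    c[reaction_ids.index(network.biomass_id)] = -1.0  # linprog minimizes

    res = linprog(c, A_eq=S.tocsr(), b_eq=np.zeros(S.shape[0]),
                  bounds=bounds, method="highs")
    if res.status == 2:  # infeasible
        return FluxDistribution({}, 0.0, feasible=False)
    if res.status != 0 or res.x is None:
        raise SolverError(
            f"LP solver failed on network {network.id!r}, medium {medium.id!r}: "
            f"status {res.status} ({res.message})"
        )
    objective = max(0.0, -res.fun)
    fluxes = {rid: float(v) for rid, v in zip(reaction_ids, res.x)}
    return FluxDistribution(fluxes, objective, feasible=True)


def steady_state_residual(network: MetabolicNetwork,
                          solution: FluxDistribution) -> float:
    """Max |S v| over metabolites; diagnostic for the steady-state invariant."""
    if not solution.fluxes:
        return 0.0
    reaction_ids = sorted(network.reactions)
    S, _ = _stoichiometric_matrix(network, reaction_ids)
    v = np.array([solution.fluxes[rid] for rid in reaction_ids])
    return float(np.abs(S @ v).max())


def predicts_growth(network: MetabolicNetwork, medium: MediumCondition,
                    epsilon: float = DEFAULT_EPSILON, *,
                    validate: bool = False,
                    solution: Optional[FluxDistribution] = None) -> bool:
    """True iff the FBA objective strictly exceeds ``epsilon``.

    ``epsilon`` separates numerical noise from genuine growth; an objective
    exactly equal to the threshold counts as no growth.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    sol = solution if solution is not None else fba(network, medium, validate=validate)
    return sol.objective_value > epsilon
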