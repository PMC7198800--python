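"""Positive and negative gapfilling of draft metabolic networks.

Positive gapfilling finds a minimum-cardinality set of reactions from the
universal database whose addition lets the draft grow on a medium.  The
search is a mixed-integer LP: one binary indicator per candidate reaction
gates its flux bounds, the biomass flux is constrained above a growth
target, and the number of switched-on candidates is minimized (HiGHS via
:func:`scipy.optimize.milp`, exact at the network scales used here).

Equal-cardinality ties are broken toward lexicographically earlier reaction
ids.  The default mode folds the preference into the MILP objective as tiny
rank-dependent costs (one solve; picks the lexicographically smaller id
whenever alternatives differ by a single reaction).  ``tie_break=
"lexicographic"`` instead certifies the lexicographically smallest sorted
id-tuple by a sequence of MILP feasibility solves — exact but linear in the
number of candidates, intended for small instances and oracle tests.

Negative gapfilling (trimming) makes a false-positive medium non-growing by
removing reactions, under the hard guarantee that every satisfied growth
condition keeps growing.  Only previously gapfilled additions are eligible
for removal; candidates are the eligible reactions carrying flux on the
negative condition, tried in a seeded random order, and each removal is kept
only if all positives still grow.  If the negative condition still grows
after the pass, the original network is returned with an ``unresolvable``
flag — a flagged result, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import coo_matrix

from .errors import SolverError, UngapfillableError, ValidationError
from .fba import DEFAULT_EPSILON, SOLVER_TOLERANCE, fba, predicts_growth, reaction_bounds
from .network import DEFAULT_BOUND, MediumCondition, MetabolicNetwork, UniversalDB

#: biomass flux the gapfilled network must reach (strictly above the default
#: growth threshold so the post-condition predicts_growth holds).
DEFAULT_MIN_GROWTH = 1e-2


@dataclass
class GapfillRecord:
    """Per-ensemble-member training provenance.

    ``added_reaction_ids`` are the net additions surviving negative trimming;
    ``removed_reaction_ids`` are additions trimmed away again, so the two
    lists are disjoint.
    """

    added_reaction_ids: List[str] = field(default_factory=list)
    removed_reaction_ids: List[str] = field(default_factory=list)
    positives_used: List[str] = field(default_factory=list)
    negatives_used: List[str] = field(default_factory=list)
    seed: int = 0
    unresolved_negatives: List[str] = field(default_factory=list)

    def __post_init__(self):
        overlap = set(self.added_reaction_ids) & set(self.removed_reaction_ids)
        if overlap:
            raise ValidationError(f"gapfill record: added/removed overlap {sorted(overlap)}")


@dataclass
class NegativeGapfillResult:
    network: MetabolicNetwork
    removed_ids: List[str]
    unresolvable: bool = False


def _candidate_ids(draft: MetabolicNetwork, db: UniversalDB) -> List[str]:
    return sorted(rid for rid in db.reactions
                  if rid not in draft.reactions and not db.reactions[rid].is_biomass)


def _merged_network(draft: MetabolicNetwork, db: UniversalDB,
                    candidate_ids: Sequence[str]) -> MetabolicNetwork:
    extra = [db.reactions[rid] for rid in candidate_ids]
    mets = [db.metabolites[m] for r in extra for m in r.stoichiometry
            if m not in draft.metabolites]
    return draft.with_reactions(extra, mets)


def _gapfill_milp(draft: MetabolicNetwork, db: UniversalDB, medium: MediumCondition,
                  candidate_ids: Sequence[str], min_growth: float,
                  *, candidate_costs: Optional[np.ndarray] = None,
                  force_in: Sequence[str] = (), force_out: Sequence[str] = (),
                  cardinality: Optional[int] = None,
                  secretion_bound: float = DEFAULT_BOUND):
    """Solve the indicator MILP; returns the selected candidate ids or None
    when infeasible."""
    merged = _merged_network(draft, db, candidate_ids)
    reaction_ids = sorted(merged.reactions)
    n_v = len(reaction_ids)
    n_c = len(candidate_ids)
    r_index = {rid: j for j, rid in enumerate(reaction_ids)}
    cand_set = set(candidate_ids)

    met_ids = sorted(merged.metabolites)
    met_index = {m: i for i, m in enumerate(met_ids)}
    rows, cols, data = [], [], []
    for rid in reaction_ids:
        j = r_index[rid]
        for mid, coef in merged.reactions[rid].stoichiometry.items():
            rows.append(met_index[mid]); cols.append(j); data.append(float(coef))
    n_var = n_v + n_c
    A_eq = coo_matrix((data, (rows, cols)), shape=(len(met_ids), n_var))

    lo = np.empty(n_var); hi = np.empty(n_var)
    for rid in reaction_ids:
        j = r_index[rid]
        lb, ub = reaction_bounds(merged.reactions[rid], medium, secretion_bound)
        if rid in cand_set:
            # candidates get their flux gated by the indicator instead
            lo[j], hi[j] = min(lb, 0.0), max(ub, 0.0)
        else:
            lo[j], hi[j] = lb, ub
    lo[n_v:], hi[n_v:] = 0.0, 1.0
    for k, rid in enumerate(candidate_ids):
        if rid in force_in:
            lo[n_v + k] = 1.0
        if rid in force_out:
            hi[n_v + k] = 0.0

    # indicator gating: v_j - ub_j*y_k <= 0 and v_j - lb_j*y_k >= 0
    g_rows, g_cols, g_data, g_lo, g_hi = [], [], [], [], []
    row = 0
    for k, rid in enumerate(candidate_ids):
        j = r_index[rid]
        lb, ub = reaction_bounds(merged.reactions[rid], medium, secretion_bound)
        g_rows += [row, row]; g_cols += [j, n_v + k]; g_data += [1.0, -max(ub, 0.0)]
        g_lo.append(-np.inf); g_hi.append(0.0); row += 1
        g_rows += [row, row]; g_cols += [j, n_v + k]; g_data += [1.0, -min(lb, 0.0)]
        g_lo.append(0.0); g_hi.append(np.inf); row += 1
    # growth requirement
    g_rows.append(row); g_cols.append(r_index[merged.biomass_id]); g_data.append(1.0)
    g_lo.append(min_growth); g_hi.append(np.inf); row += 1
    if cardinality is not None:
        for k in range(n_c):
            g_rows.append(row); g_cols.append(n_v + k); g_data.append(1.0)
        g_lo.append(cardinality); g_hi.append(cardinality); row += 1
    A_in = coo_matrix((g_data, (g_rows, g_cols)), shape=(row, n_var))

    c = np.zeros(n_var)
    if candidate_costs is not None:
        c[n_v:] = candidate_costs
    integrality = np.zeros(n_var)
    integrality[n_v:] = 1

    res = milp(c,
               constraints=[LinearConstraint(A_eq, 0.0, 0.0),
                            LinearConstraint(A_in, np.array(g_lo), np.array(g_hi))],
               integrality=integrality, bounds=Bounds(lo, hi))
    if res.status == 2:  # infeasible
        return None
    if not res.success or res.x is None:
        raise SolverError(
            f"MILP solver failed gapfilling {draft.id!r} on {medium.id!r}: {res.message}"
        )
    y = res.x[n_v:]
    return [candidate_ids[k] for k in range(n_c) if y[k] > 0.5]


def gapfill_positive(draft: MetabolicNetwork, db: UniversalDB, medium: MediumCondition,
                     *, epsilon: float = DEFAULT_EPSILON,
                     min_growth: float = DEFAULT_MIN_GROWTH,
                     tie_break: str = "weighted",
                     secretion_bound: float = DEFAULT_BOUND,
                     ) -> Tuple[MetabolicNetwork, List[str]]:
    """Add a minimum-cardinality set of database reactions so the draft grows.

    Returns the gapfilled network and the sorted list of added reaction ids
    (empty if the draft already grows).

    Raises
    ------
    UngapfillableError
        if no subset of the database enables growth on ``medium``.
    """
    if predicts_growth(draft, medium, epsilon):
        return draft.copy(), []
    candidates = _candidate_ids(draft, db)
    if tie_break not in ("weighted", "lexicographic"):
        raise ValueError(f"unknown tie_break {tie_break!r}")

    n_c = len(candidates)
    # rank weights small enough that total extra cost of any subset < 1,
    # so cardinality always dominates; ranks prefer earlier ids.
    delta = 0.5 / (n_c * (n_c + 1)) if n_c else 0.0
    costs = np.array([1.0 + delta * (k + 1) for k in range(n_c)])
    chosen = _gapfill_milp(draft, db, medium, candidates, min_growth,
                           candidate_costs=costs, secretion_bound=secretion_bound)
    if chosen is None:
        raise UngapfillableError(medium.id)

    if tie_break == "lexicographic" and len(chosen) > 0:
        k = len(chosen)
        forced_in: List[str] = []
        forced_out: List[str] = []
        for cid in candidates:
            if len(forced_in) == k:
                break
            trial = _gapfill_milp(draft, db, medium, candidates, min_growth,
                                  force_in=forced_in + [cid], force_out=forced_out,
                                  cardinality=k, secretion_bound=secretion_bound)
            if trial is not None:
                forced_in.append(cid)
            else:
                forced_out.append(cid)
        chosen = forced_in

    added = sorted(chosen)
    result = _merged_network(draft, db, added)
    if not predicts_growth(result, medium, epsilon):
        raise SolverError(
            f"gapfilled network for {medium.id!r} fails the growth check "
            "(min_growth below the growth threshold?)"
        )
    return result, added


def gapfill_negative(network: MetabolicNetwork, negative_medium: MediumCondition,
                     satisfied_positives: Sequence[MediumCondition],
                     removable_ids: Optional[Iterable[str]] = None,
                     *, epsilon: float = DEFAULT_EPSILON,
                     rng: Optional[np.random.Generator] = None,
                     flux_tolerance: float = SOLVER_TOLERANCE,
                     ) -> NegativeGapfillResult:
    """Trim reactions so ``negative_medium`` stops growing, never breaking a
    satisfied positive condition.

    ``removable_ids`` restricts candidate removals (typically to previously
    gapfilled additions); by default every non-biomass, non-exchange reaction
    is eligible.
    """
    if not predicts_growth(network, negative_medium, epsilon):
        return NegativeGapfillResult(network.copy(), [], unresolvable=False)

    if removable_ids is None:
        removable = [rid for rid, r in network.reactions.items()
                     if not r.is_biomass and not r.is_exchange]
    else:
        removable = [rid for rid in removable_ids if rid in network.reactions]
    rng = rng if rng is not None else np.random.default_rng(0)
    order = list(np.array(sorted(removable))[rng.permutation(len(removable))]) \
        if removable else []

    current = network.copy()
    removed: List[str] = []
    while True:
        sol = fba(current, negative_medium, validate=False)
        if sol.objective_value <= epsilon:
            break
        progressed = False
        for cid in order:
            if cid in removed or cid not in current.reactions:
                continue
            if abs(sol.fluxes.get(cid, 0.0)) <= flux_tolerance:
                continue
            trial = current.without(cid)
            if all(predicts_growth(trial, pos, epsilon) for pos in satisfied_positives):
                current = trial
                removed.append(cid)
                progressed = True
                break
        if not progressed:
            return NegativeGapfillResult(network.copy(), [], unresolvable=True)

    return NegativeGapfillResult(current, removed, unresolvable=False)
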