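"""Ensemble construction and ensemble-weighted prediction.

Rather than committing to a single gapfilled network, an ensemble holds many
alternative reconstructions of the same strain, each trained (positive plus
negative gapfilling) on a different random subset of the growth/no-growth
phenotype panel.  Predictions aggregate across members:

* growth on a medium is voted (fraction of members whose FBA objective
  exceeds the growth threshold), and
* quantitative "metabolic activity" is the mean member growth rate weighted
  by that fraction — equivalently the mean over all members with non-growing
  members contributing zero;
* per-reaction fluxes are averaged over the members in which the reaction
  carries flux, weighted by the fraction of members where it does.

The study-scale configuration is 50 members trained on 26 growth-supporting
and 11 non-supporting nitrogen substrates each.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import UngapfillableError, ValidationError
from .fba import DEFAULT_EPSILON, SOLVER_TOLERANCE, fba
from .gapfill import GapfillRecord, gapfill_negative, gapfill_positive
from .network import MediumCondition, MetabolicNetwork, UniversalDB

DEFAULT_VOTE_THRESHOLD = 0.5
FLUX_PSEUDOCOUNT = 1e-6  # floor applied to zero fluxes before log2 ratios


@dataclass
class Ensemble:
    networks: List[MetabolicNetwork]
    records: List[GapfillRecord]

    def __post_init__(self):
        if len(self.networks) != len(self.records):
            raise ValidationError("ensemble: networks and records must be parallel lists")
        if not self.networks:
            raise ValidationError("ensemble must be non-empty")

    @property
    def size(self) -> int:
        return len(self.networks)


@dataclass
class EnsemblePrediction:
    condition_id: str
    fraction_growing: float
    activity: float
    binary_call: bool
    member_rates: List[float] = field(default_factory=list)


def _member_seed(seed: int, member: int, attempt: int) -> int:
    ss = np.random.SeedSequence([int(seed), int(member), int(attempt)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def build_ensemble(draft: MetabolicNetwork, db: UniversalDB,
                   positives: Sequence[MediumCondition],
                   negatives: Sequence[MediumCondition],
                   size: int, n_pos: int, n_neg: int, seed: int,
                   *, epsilon: float = DEFAULT_EPSILON,
                   max_retries: int = 5,
                   tie_break: str = "weighted") -> Ensemble:
    """Train ``size`` gapfilled networks on random training subsets.

    Each member draws ``n_pos`` positive and ``n_neg`` negative conditions
    without replacement (stream seeded by the master seed and member index),
    applies positive gapfilling per positive in drawn order, then negative
    trimming per negative in drawn order.  A member whose draw contains an
    ungapfillable positive is regenerated with a fresh draw, up to
    ``max_retries`` attempts.
    """
    if size < 1:
        raise ValidationError("ensemble size must be >= 1")
    if n_pos > len(positives) or n_neg > len(negatives):
        raise ValidationError(
            f"training sizes ({n_pos}/{n_neg}) exceed panel sizes "
            f"({len(positives)}/{len(negatives)})"
        )
    networks: List[MetabolicNetwork] = []
    records: List[GapfillRecord] = []
    for i in range(size):
        last_error: Optional[Exception] = None
        for attempt in range(max_retries):
            mseed = _member_seed(seed, i, attempt)
            rng = np.random.default_rng(mseed)
            pos_draw = [positives[j] for j in rng.choice(len(positives), n_pos, replace=False)]
            neg_draw = [negatives[j] for j in rng.choice(len(negatives), n_neg, replace=False)]
            try:
                net = draft.copy(id=f"{draft.id}__m{i}")
                added: List[str] = []
                for cond in pos_draw:
                    net, new = gapfill_positive(net, db, cond, epsilon=epsilon,
                                                tie_break=tie_break)
                    added.extend(new)
                removed: List[str] = []
                unresolved: List[str] = []
                for cond in neg_draw:
                    res = gapfill_negative(net, cond, pos_draw, removable_ids=added,
                                           epsilon=epsilon, rng=rng)
                    net = res.network
                    if res.unresolvable:
                        unresolved.append(cond.id)
                    removed.extend(res.removed_ids)
                    added = [a for a in added if a not in res.removed_ids]
                _verify_member(net, pos_draw, neg_draw, unresolved, epsilon)
                networks.append(net)
                records.append(GapfillRecord(
                    added_reaction_ids=sorted(added),
                    removed_reaction_ids=sorted(removed),
                    positives_used=[c.id for c in pos_draw],
                    negatives_used=[c.id for c in neg_draw],
                    seed=mseed,
                    unresolved_negatives=unresolved,
                ))
                break
            except UngapfillableError as exc:
                last_error = exc
        else:
            raise UngapfillableError(
                getattr(last_error, "condition_id", "?"),
                f"member {i}: no gapfillable training draw after {max_retries} attempts "
                f"(last: {last_error})",
            )
    return Ensemble(networks, records)


def _verify_member(net: MetabolicNetwork, positives: Sequence[MediumCondition],
                   negatives: Sequence[MediumCondition], unresolved: Sequence[str],
                   epsilon: float) -> None:
    from .fba import predicts_growth
    for cond in positives:
        if not predicts_growth(net, cond, epsilon):
            raise ValidationError(
                f"member {net.id!r} lost growth on training positive {cond.id!r}"
            )
    for cond in negatives:
        if cond.id in unresolved:
            continue
        if predicts_growth(net, cond, epsilon):
            raise ValidationError(
                f"member {net.id!r} still grows on training negative {cond.id!r}"
            )


def ensemble_predict(ensemble: Ensemble, medium: MediumCondition,
                     epsilon: float = DEFAULT_EPSILON,
                     vote_threshold: float = DEFAULT_VOTE_THRESHOLD) -> EnsemblePrediction:
    """Fraction of members growing, weighted activity, and the binary call.

    activity = (mean growth rate over growing members) x fraction growing,
    which equals the mean over all members with non-growers contributing 0.
    """
    rates = [fba(net, medium, validate=False).objective_value for net in ensemble.networks]
    growing = [r for r in rates if r > epsilon]
    fraction = len(growing) / ensemble.size
    activity = sum(growing) / ensemble.size
    return EnsemblePrediction(medium.id, fraction, activity,
                              fraction >= vote_threshold, rates)


def ensemble_flux(ensemble: Ensemble, medium: MediumCondition,
                  *, flux_tolerance: float = SOLVER_TOLERANCE,
                  return_weights: bool = False):
    """Ensemble-weighted flux per reaction.

    For each reaction the weight is the fraction of members in which it
    carries non-zero flux; the weighted flux is the mean over those members
    times the weight.  Members lacking the reaction count in the denominator
    only.
    """
    per_member = [fba(net, medium, validate=False).fluxes for net in ensemble.networks]
    all_ids = sorted({rid for net in ensemble.networks for rid in net.reactions})
    weighted: Dict[str, float] = {}
    weights: Dict[str, float] = {}
    for rid in all_ids:
        vals = [fl[rid] for fl in per_member
                if rid in fl and abs(fl[rid]) > flux_tolerance]
        w = len(vals) / ensemble.size
        weights[rid] = w
        weighted[rid] = (float(np.mean(vals)) * w) if vals else 0.0
    if return_weights:
        return weighted, weights
    return weighted


def flux_fold_changes(flux_a: Dict[str, float], flux_b: Dict[str, float],
                      threshold: float = 1.0,
                      floor: float = FLUX_PSEUDOCOUNT) -> List[Tuple[str, float]]:
    """Reactions whose weighted-flux log2 ratio exceeds the threshold.

    Flux magnitudes are compared (reversible reactions can carry negative
    weighted flux) and zeros are floored at a pseudo-flux before the log, so
    appearing/disappearing reactions get large finite fold changes.  Returns
    (reaction id, log2FC) sorted by |log2FC| descending, ties by id.
    """
    out: List[Tuple[str, float]] = []
    for rid in sorted(set(flux_a) | set(flux_b)):
        a = max(abs(flux_a.get(rid, 0.0)), floor)
        b = max(abs(flux_b.get(rid, 0.0)), floor)
        lfc = math.log2(a / b)
        if abs(lfc) > threshold:
            out.append((rid, lfc))
    out.sort(key=lambda t: (-abs(t[1]), t[0]))
    return out
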