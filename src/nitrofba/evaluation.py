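"""Model-vs-experiment evaluation with training-condition masking.

An ensemble member that was gapfilled using a given condition abstains from
voting on that condition (per-member masking), so held-out accuracy is not
inflated by training leakage.  Metrics are compared against randomly
generated predictions, and quantitative activity against experimental
growth intensity by squared correlation of percentile ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .ensemble import DEFAULT_VOTE_THRESHOLD, Ensemble
from .errors import InputError
from .fba import DEFAULT_EPSILON, fba
from .network import MediumCondition


@dataclass
class PredictionRecord:
    condition_id: str
    member_votes: List[bool]          # one per voting (unmasked) member
    masked_members: List[int]         # indices of abstaining members
    fraction: float
    binary_call: bool
    activity: float


@dataclass
class MetricsReport:
    accuracy: float
    precision: Optional[float]
    recall: Optional[float]
    tp: int
    fp: int
    fn: int
    tn: int
    n_evaluated: int
    excluded_conditions: List[str] = field(default_factory=list)
    records: List[PredictionRecord] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "tp": self.tp, "fp": self.fp,
            "fn": self.fn, "tn": self.tn, "n_evaluated": self.n_evaluated,
            "excluded_conditions": self.excluded_conditions,
        }


def _metrics(tp: int, fp: int, fn: int, tn: int):
    n = tp + fp + fn + tn
    accuracy = (tp + tn) / n if n else float("nan")
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else None
    return accuracy, precision, recall


def evaluate_ensemble(ensemble: Ensemble, panel: Sequence[MediumCondition],
                      truth: Mapping[str, bool],
                      epsilon: float = DEFAULT_EPSILON,
                      vote_threshold: float = DEFAULT_VOTE_THRESHOLD,
                      *, global_holdout: Sequence[str] = ()) -> MetricsReport:
    """Masked confusion metrics of ensemble growth calls against truth.

    A member abstains on conditions present in its own training record.
    Conditions in ``global_holdout`` are evaluated by all members regardless
    of records (the alternative global-holdout mode, where the holdout was
    never used for training); conditions with every member masked are
    excluded with a warning entry in the report.
    """
    missing = [c.id for c in panel if c.id not in truth]
    if missing:
        raise InputError(f"truth table missing conditions: {missing[:5]}")
    training_sets = [set(rec.positives_used) | set(rec.negatives_used)
                     for rec in ensemble.records]
    tp = fp = fn = tn = 0
    records: List[PredictionRecord] = []
    excluded: List[str] = []
    for cond in panel:
        if cond.id in global_holdout:
            masked = []
        else:
            masked = [i for i, ts in enumerate(training_sets) if cond.id in ts]
        voters = [i for i in range(ensemble.size) if i not in masked]
        if not voters:
            excluded.append(cond.id)
            continue
        rates = [fba(ensemble.networks[i], cond, validate=False).objective_value
                 for i in voters]
        votes = [r > epsilon for r in rates]
        fraction = sum(votes) / len(voters)
        call = fraction >= vote_threshold
        activity = sum(r for r, v in zip(rates, votes) if v) / len(voters)
        records.append(PredictionRecord(cond.id, votes, masked, fraction, call, activity))
        actual = bool(truth[cond.id])
        if call and actual:
            tp += 1
        elif call and not actual:
            fp += 1
        elif not call and actual:
            fn += 1
        else:
            tn += 1
    accuracy, precision, recall = _metrics(tp, fp, fn, tn)
    return MetricsReport(accuracy, precision, recall, tp, fp, fn, tn,
                         n_evaluated=tp + fp + fn + tn,
                         excluded_conditions=excluded, records=records)


@dataclass
class BaselineDistribution:
    accuracy: np.ndarray
    precision: np.ndarray  # NaN where undefined in a draw
    recall: np.ndarray
    p_grow: float

    def summary(self) -> dict:
        def s(x):
            x = x[np.isfinite(x)]
            if len(x) == 0:
                return {"mean": None, "lo95": None, "hi95": None}
            return {"mean": float(np.mean(x)),
                    "lo95": float(np.percentile(x, 2.5)),
                    "hi95": float(np.percentile(x, 97.5))}
        return {"accuracy": s(self.accuracy), "precision": s(self.precision),
                "recall": s(self.recall), "p_grow": self.p_grow}

    def percentile(self, metric: str, q: float) -> float:
        x = getattr(self, metric)
        return float(np.percentile(x[np.isfinite(x)], q))


def random_baseline(truth: Mapping[str, bool], n_draws: int = 1000,
                    seed: int = 0, p_grow: Optional[float] = None) -> BaselineDistribution:
    """Empirical metric distribution of i.i.d. Bernoulli predictions.

    ``p_grow`` defaults to the prevalence of growth in the truth table; pass
    0.5 for an information-free coin.
    """
    if n_draws < 100:
        raise InputError("random baseline needs at least 100 draws")
    actual = np.array([bool(v) for v in truth.values()])
    if p_grow is None:
        p_grow = float(actual.mean())
    rng = np.random.default_rng(seed)
    preds = rng.random((n_draws, len(actual))) < p_grow
    tp = (preds & actual).sum(axis=1)
    fp = (preds & ~actual).sum(axis=1)
    fn = (~preds & actual).sum(axis=1)
    tn = (~preds & ~actual).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        accuracy = (tp + tn) / len(actual)
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), np.nan)
        recall = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), np.nan)
    return BaselineDistribution(accuracy, precision, recall, p_grow)


def rank_r2(activity: Mapping[str, float],
            experimental: Mapping[str, float]) -> Optional[float]:
    """Squared Pearson correlation of percentile ranks over shared
    conditions (average ranks for ties).  Returns None when either vector is
    constant (correlation undefined)."""
    shared = sorted(set(activity) & set(experimental))
    if len(shared) < 3:
        raise InputError(f"rank_r2 needs >= 3 shared conditions, got {len(shared)}")
    a = np.array([float(activity[c]) for c in shared])
    b = np.array([float(experimental[c]) for c in shared])
    if np.all(a == a[0]) or np.all(b == b[0]):
        return None
    ra = stats.rankdata(a) / len(a)
    rb = stats.rankdata(b) / len(b)
    r = stats.pearsonr(ra, rb)[0]
    return float(r ** 2)
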