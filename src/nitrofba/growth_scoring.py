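"""Phenotype-microarray and batch growth-curve scoring.

Kinetic absorbance series (tetrazolium A590 for phenotype microarrays,
OD600 for batch curves) are background-subtracted against a negative-control
well, fitted to the logistic growth model

    N(t) = K / (1 + ((K - N0) / N0) * exp(-r t))

and summarized by carrying capacity K, intrinsic rate r, initial value N0
and the area under the fitted curve.  A well is growth-positive when K
exceeds an absorbance threshold (default 0.1) in at least two of three
biological replicates.  Growth-positive AUCs are z-score normalized within
each strain and replicate assay, averaged across replicates, and binned into
quartiles, giving five growth intensities from 0 (no growth) to 4 (highest
AUC quartile).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import AlignmentError, InputError, QuartileError

MIN_POINTS = 10
#: series whose dynamic range is below this are treated as flat (no growth)
MIN_AMPLITUDE = 0.01
K_THRESHOLD = 0.1
MIN_REPLICATES = 2


@dataclass
class PlateWellSeries:
    """One well's kinetic series (times in hours, values in absorbance)."""

    plate_id: str
    well: str
    replicate: int
    substrate_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise InputError(f"well {self.well}: times/values length mismatch")
        if len(self.times) < MIN_POINTS:
            raise InputError(f"well {self.well}: need >= {MIN_POINTS} time points")
        if not np.all(np.diff(self.times) > 0):
            raise InputError(f"well {self.well}: times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise InputError(f"well {self.well}: non-finite absorbance values")


@dataclass
class LogisticFit:
    K: float
    r: float
    N0: float
    auc: float
    converged: bool
    rss: float


@dataclass
class GrowthMatrix:
    """Strains x substrates growth calls and 0-4 intensities, with the
    replicate AUC/z-score provenance used to derive them."""

    table: pd.DataFrame       # strain, substrate, call, intensity, mean_z
    provenance: pd.DataFrame  # strain, substrate, replicate, auc, z

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def logistic(t, K, r, N0):
    return K / (1.0 + ((K - N0) / N0) * np.exp(-r * np.asarray(t, dtype=float)))


def logistic_auc(K: float, r: float, N0: float, t0: float, t1: float) -> float:
    """Closed-form integral of the fitted logistic curve over [t0, t1]."""
    if r <= 0 or K <= 0 or N0 <= 0:
        return max(K, 0.0) * (t1 - t0)

    def antiderivative(t):
        # stable form of (K/r) * ln(N0 e^{rt} + K - N0)
        return (K / r) * (r * t + np.log(N0 + (K - N0) * np.exp(-r * t)))

    return float(antiderivative(t1) - antiderivative(t0))


def subtract_background(run: Iterable[PlateWellSeries],
                        control_well: str = "A1") -> List[PlateWellSeries]:
    """Subtract the negative-control well's series from every other well,
    per plate and replicate.  The control itself is retained unmodified for
    QC."""
    wells = list(run)
    controls: Dict[Tuple[str, int], PlateWellSeries] = {}
    for w in wells:
        if w.well == control_well:
            controls[(w.plate_id, w.replicate)] = w
    out: List[PlateWellSeries] = []
    for w in wells:
        if w.well == control_well:
            out.append(w)
            continue
        ctrl = controls.get((w.plate_id, w.replicate))
        if ctrl is None:
            raise AlignmentError(
                f"no control well {control_well!r} for plate {w.plate_id!r} "
                f"replicate {w.replicate}"
            )
        if len(ctrl.times) != len(w.times) or not np.allclose(ctrl.times, w.times):
            raise AlignmentError(
                f"time grid of well {w.well!r} does not match control "
                f"({w.plate_id!r}, replicate {w.replicate})"
            )
        out.append(PlateWellSeries(w.plate_id, w.well, w.replicate, w.substrate_id,
                                   w.times.copy(), w.values - ctrl.values))
    return out


def fit_logistic(series: PlateWellSeries, *,
                 min_amplitude: float = MIN_AMPLITUDE) -> LogisticFit:
    """Bounded nonlinear least squares of the logistic model.

    Background subtraction can leave small negative values; these are
    clipped at zero before fitting.  Flat or non-convergent series are
    flagged with K set to the maximum observed value and r = 0; their AUC is
    that of the degenerate flat curve.
    """
    t = series.times
    y = np.clip(series.values, 0.0, None)
    span = float(t[-1] - t[0])

    def degenerate() -> LogisticFit:
        K = float(y.max())
        return LogisticFit(K=K, r=0.0, N0=float(y[0]), auc=K * span,
                           converged=False, rss=float(((y - y.mean()) ** 2).sum()))

    if y.max() <= 0 or (y.max() - y.min()) < min_amplitude:
        return degenerate()

    ymax = float(y.max())
    p0 = (ymax, 0.2, max(float(y[0]), 1e-3))
    lower = (1e-6, 1e-6, 1e-6)
    upper = (2.0 * ymax, 5.0, max(ymax, 1e-3))
    p0 = tuple(np.clip(p0, lower, upper))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(logistic, t, y, p0=p0, bounds=(lower, upper),
                                maxfev=10000)
    except (RuntimeError, ValueError):
        return degenerate()
    K, r, N0 = (float(v) for v in popt)
    resid = y - logistic(t, K, r, N0)
    return LogisticFit(K=K, r=r, N0=N0,
                       auc=logistic_auc(K, r, N0, float(t[0]), float(t[-1])),
                       converged=True, rss=float((resid ** 2).sum()))


def call_growth(fits: Sequence[LogisticFit], k_threshold: float = K_THRESHOLD,
                min_replicates: int = MIN_REPLICATES) -> bool:
    """Growth-positive iff K exceeds the threshold in at least
    ``min_replicates`` replicates (invariant to replicate order)."""
    if not fits:
        raise InputError("call_growth needs at least one replicate fit")
    return sum(f.K > k_threshold for f in fits) >= min_replicates


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1) if len(x) > 1 else 0.0
    if sd == 0:
        warnings.warn("constant AUCs within a replicate assay; z-scores set to 0")
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def score_intensities(auc_table: pd.DataFrame, calls: pd.DataFrame,
                      exclude_substrates: Sequence[str] = ()) -> GrowthMatrix:
    """Derive the strains x substrates 0-4 intensity matrix.

    Parameters
    ----------
    auc_table
        Long-form frame with columns ``strain, substrate, replicate, auc``.
    calls
        Frame with columns ``strain, substrate, call`` (boolean).
    exclude_substrates
        Wells dropped before scoring (e.g. a known high-background well).

    Per strain, growth-positive AUCs are z-scored within each replicate
    assay, averaged across replicates, and split at the empirical quartiles
    of the averaged z-scores (linear-interpolation quantiles; values tied
    with a boundary fall in the lower bin).  Non-growth wells score 0.
    """
    for col in ("strain", "substrate", "replicate", "auc"):
        if col not in auc_table.columns:
            raise InputError(f"auc_table missing column {col!r}")
    auc = auc_table[~auc_table["substrate"].isin(exclude_substrates)].copy()
    calls = calls[~calls["substrate"].isin(exclude_substrates)]
    call_map = {(r.strain, r.substrate): bool(r.call) for r in calls.itertuples()}

    rows, prov = [], []
    for strain, sub in auc.groupby("strain", sort=True):
        positive = sorted({s for (st, s), c in call_map.items() if st == strain and c})
        if len(positive) < 4:
            raise QuartileError(
                f"strain {strain!r}: {len(positive)} growth-positive substrates; "
                "at least 4 are needed to define intensity quartiles"
            )
        pos = sub[sub["substrate"].isin(positive)].copy()
        pos["z"] = (pos.groupby("replicate")["auc"]
                    .transform(lambda x: _zscore(x.to_numpy())))
        mean_z = pos.groupby("substrate")["z"].mean()
        q1, q2, q3 = np.quantile(mean_z.to_numpy(), [0.25, 0.5, 0.75])
        for substrate in sorted({s for (st, s) in call_map if st == strain}):
            if substrate in mean_z.index:
                z = float(mean_z[substrate])
                intensity = 1 + int(z > q1) + int(z > q2) + int(z > q3)
                rows.append((strain, substrate, True, intensity, z))
            else:
                rows.append((strain, substrate, False, 0, np.nan))
        prov.append(pos[["strain", "substrate", "replicate", "auc", "z"]])

    table = pd.DataFrame(rows, columns=["strain", "substrate", "call",
                                        "intensity", "mean_z"])
    provenance = (pd.concat(prov, ignore_index=True) if prov
                  else pd.DataFrame(columns=["strain", "substrate", "replicate",
                                             "auc", "z"]))
    return GrowthMatrix(table, provenance)


def score_plate_run(run: Iterable[PlateWellSeries], *,
                    control_well: str = "A1",
                    exclude_substrates: Sequence[str] = (),
                    k_threshold: float = K_THRESHOLD,
                    min_replicates: int = MIN_REPLICATES,
                    strain: Optional[str] = None) -> GrowthMatrix:
    """Convenience pipeline: background-subtract, fit, call, score one
    strain's plate run (replicates distinguished by ``replicate``)."""
    corrected = subtract_background(run, control_well)
    fits: Dict[str, List[Tuple[int, LogisticFit]]] = {}
    for w in corrected:
        if w.well == control_well:
            continue
        fits.setdefault(w.substrate_id, []).append((w.replicate, fit_logistic(w)))
    strain = strain if strain is not None else next(iter(corrected)).plate_id
    auc_rows, call_rows = [], []
    for substrate, fit_list in sorted(fits.items()):
        reps = [f for _, f in sorted(fit_list)]
        call_rows.append((strain, substrate,
                          call_growth(reps, k_threshold, min_replicates)))
        for rep, f in sorted(fit_list):
            auc_rows.append((strain, substrate, rep, f.auc))
    auc_table = pd.DataFrame(auc_rows, columns=["strain", "substrate",
                                                "replicate", "auc"])
    calls = pd.DataFrame(call_rows, columns=["strain", "substrate", "call"])
    return score_intensities(auc_table, calls, exclude_substrates)


def load_plate_csv(path) -> List[PlateWellSeries]:
    """Read long-form plate CSV: plate_id, well, replicate, substrate_id,
    time_h, value."""
    df = pd.read_csv(path)
    required = {"plate_id", "well", "replicate", "substrate_id", "time_h", "value"}
    if not required.issubset(df.columns):
        raise InputError(f"plate CSV {path} missing columns {required - set(df.columns)}")
    out = []
    for (plate, well, rep, sub), grp in df.groupby(
            ["plate_id", "well", "replicate", "substrate_id"], sort=True):
        grp = grp.sort_values("time_h")
        out.append(PlateWellSeries(str(plate), str(well), int(rep), str(sub),
                                   grp["time_h"].to_numpy(),
                                   grp["value"].to_numpy()))
    return out


def save_plate_csv(run: Iterable[PlateWellSeries], path) -> None:
    frames = []
    for w in run:
        frames.append(pd.DataFrame({
            "plate_id": w.plate_id, "well": w.well, "replicate": w.replicate,
            "substrate_id": w.substrate_id, "time_h": w.times, "value": w.values,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
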