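"""Logistic fitting, growth calls and intensity scoring."""

import numpy as np
import pandas as pd
import pytest

from nitrofba import call_growth, fit_logistic, score_intensities, subtract_background
from nitrofba.growth_scoring import (
    LogisticFit,
    PlateWellSeries,
    logistic,
    logistic_auc,
)
from nitrofba.errors import AlignmentError, InputError, QuartileError

T = np.arange(0.0, 72.01, 1 / 6)


def _series(values, well="A2", substrate="s", rep=1, times=T):
    return PlateWellSeries("p1", well, rep, substrate, times, values)


# ------------------------------------------------------ background

def test_background_subtraction_examples():
    ctrl = _series(0.05 + 0.001 * T, well="A1", substrate="ctrl")
    same = _series(0.05 + 0.001 * T)
    offset = _series(0.05 + 0.001 * T + 0.2, well="A3", substrate="s2")
    out = subtract_background([ctrl, same, offset])
    by_well = {w.well: w for w in out}
    assert np.allclose(by_well["A2"].values, 0.0)
    assert np.allclose(by_well["A3"].values, 0.2)
    # control retained unmodified for QC
    assert np.allclose(by_well["A1"].values, ctrl.values)


def test_zero_control_leaves_run_unchanged():
    ctrl = _series(np.zeros_like(T), well="A1")
    well = _series(logistic(T, 0.4, 0.3, 0.02))
    out = subtract_background([ctrl, well])
    assert np.allclose([w for w in out if w.well == "A2"][0].values, well.values)


def test_time_grid_mismatch_raises():
    ctrl = _series(np.zeros_like(T), well="A1")
    other = PlateWellSeries("p1", "A2", 1, "s", T[:-1] + 0.01,
                            np.zeros(len(T) - 1))
    with pytest.raises(AlignmentError):
        subtract_background([ctrl, other])


# --------------------------------------------------------- fitting

def test_noiseless_logistic_recovered_exactly():
    y = logistic(T, 0.5, 0.3, 0.05)
    fit = fit_logistic(_series(y))
    assert fit.converged
    assert fit.K == pytest.approx(0.5, rel=1e-3)
    assert fit.r == pytest.approx(0.3, rel=1e-3)
    assert fit.N0 == pytest.approx(0.05, rel=1e-3)


def test_noisy_fit_matches_grid_search_oracle():
    """K from the nonlinear fit agrees with an independent coarse
    grid-search refit and stays within +-0.05 of truth."""
    rng = np.random.default_rng(1)
    y = logistic(T, 0.5, 0.3, 0.05) + rng.normal(0, 0.01, len(T))
    fit = fit_logistic(_series(y))
    assert abs(fit.K - 0.5) < 0.05

    grid_K = np.linspace(0.3, 0.7, 41)
    grid_r = np.linspace(0.1, 0.6, 26)
    yc = np.clip(y, 0, None)
    best = min(((np.sum((yc - logistic(T, K, r, 0.05)) ** 2), K)
                for K in grid_K for r in grid_r), key=lambda t: t[0])
    assert abs(fit.K - best[1]) < 0.02


def test_flat_series_flagged_degenerate():
    fit = fit_logistic(_series(np.full_like(T, 0.02)))
    assert not fit.converged
    assert fit.K == pytest.approx(0.02)
    assert fit.r == 0.0
    assert fit.auc == pytest.approx(0.02 * (T[-1] - T[0]))


def test_too_few_points_rejected():
    with pytest.raises(InputError):
        PlateWellSeries("p", "A2", 1, "s", np.arange(5.0), np.zeros(5))


def test_fitted_auc_matches_numeric_integral():
    K, r, N0 = 0.45, 0.25, 0.03
    analytic = logistic_auc(K, r, N0, 0.0, 72.0)
    tt = np.linspace(0, 72, 20001)
    numeric = np.trapezoid(logistic(tt, K, r, N0), tt)
    assert analytic == pytest.approx(numeric, rel=1e-6)


# ----------------------------------------------------------- calls

@pytest.mark.parametrize("ks,expected", [
    ([0.15, 0.12, 0.05], True),   # two of three above threshold
    ([0.15, 0.05, 0.05], False),  # only one above
    ([0.0, 0.0, 0.0], False),
])
def test_growth_call_threshold_rule(ks, expected):
    fits = [LogisticFit(K=k, r=0.2, N0=0.01, auc=1.0, converged=True, rss=0.0)
            for k in ks]
    assert call_growth(fits) is expected
    # invariant to replicate order
    assert call_growth(fits[::-1]) is expected


# ------------------------------------------------------ intensities

def _auc_frame(strain, aucs_by_substrate, reps=3):
    rows = []
    for sub, aucs in aucs_by_substrate.items():
        for rep in range(1, reps + 1):
            rows.append((strain, sub, rep, aucs[rep - 1]))
    return pd.DataFrame(rows, columns=["strain", "substrate", "replicate", "auc"])


def test_increasing_scores_fill_quartiles_in_order():
    subs = {f"s{i}": [float(i)] * 3 for i in range(8)}  # strictly increasing AUC
    calls = pd.DataFrame([("st", s, True) for s in subs] + [("st", "s_neg", False)],
                         columns=["strain", "substrate", "call"])
    auc = _auc_frame("st", subs)
    gm = score_intensities(auc, calls)
    by_sub = gm.table.set_index("substrate")
    assert [by_sub.loc[f"s{i}", "intensity"] for i in range(8)] == [1, 1, 2, 2, 3, 3, 4, 4]
    assert by_sub.loc["s_neg", "intensity"] == 0
    assert not by_sub.loc["s_neg", "call"]


def test_z_scores_have_zero_mean_unit_sd_per_replicate():
    rng = np.random.default_rng(7)
    subs = {f"s{i}": list(rng.uniform(5, 40, 3)) for i in range(10)}
    calls = pd.DataFrame([("st", s, True) for s in subs],
                         columns=["strain", "substrate", "call"])
    gm = score_intensities(_auc_frame("st", subs), calls)
    for _, grp in gm.provenance.groupby("replicate"):
        assert grp["z"].mean() == pytest.approx(0.0, abs=1e-9)
        assert grp["z"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)
    # intensity is monotone in the averaged z-score
    tab = gm.table.sort_values("mean_z")
    assert tab["intensity"].is_monotonic_increasing


def test_constant_aucs_collapse_to_intensity_one():
    subs = {f"s{i}": [2.0, 2.0, 2.0] for i in range(6)}
    calls = pd.DataFrame([("st", s, True) for s in subs],
                         columns=["strain", "substrate", "call"])
    with pytest.warns(UserWarning):
        gm = score_intensities(_auc_frame("st", subs), calls)
    assert set(gm.table["intensity"]) == {1}


def test_too_few_positive_wells_is_an_error():
    subs = {"s0": [1.0] * 3, "s1": [2.0] * 3, "s2": [3.0] * 3}
    calls = pd.DataFrame([("st", s, True) for s in subs],
                         columns=["strain", "substrate", "call"])
    with pytest.raises(QuartileError):
        score_intensities(_auc_frame("st", subs), calls)


def test_excluded_substrate_dropped_before_scoring():
    subs = {f"s{i}": [float(i + 1)] * 3 for i in range(5)}
    subs["high_bg"] = [1000.0] * 3
    calls = pd.DataFrame([("st", s, True) for s in subs],
                         columns=["strain", "substrate", "call"])
    gm = score_intensities(_auc_frame("st", subs), calls,
                           exclude_substrates=["high_bg"])
    assert "high_bg" not in set(gm.table["substrate"])


def test_parameter_recovery_over_many_wells():
    """Median relative K error < 5% over 200 simulated wells at noise
    sd 0.01."""
    rng = np.random.default_rng(42)
    errors = []
    for _ in range(200):
        K = rng.uniform(0.1, 0.6)
        r = rng.uniform(0.1, 0.5)
        n0 = rng.uniform(0.01, 0.05)
        y = logistic(T, K, r, min(n0, 0.8 * K)) + rng.normal(0, 0.01, len(T))
        fit = fit_logistic(_series(y))
        errors.append(abs(fit.K - K) / K)
    assert np.median(errors) < 0.05
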