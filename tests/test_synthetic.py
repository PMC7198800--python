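"""Ground-truth properties of the synthetic generators."""

import numpy as np
import pandas as pd
import pytest

from nitrofba import (
    fba,
    fit_logistic,
    generate_universe,
    n_source_concentration,
    predicts_growth,
    simulate_plate,
    simulate_proteomics,
    subtract_background,
)
from nitrofba.model_io import network_to_dict
from nitrofba.errors import InputError


# -------------------------------------------------------- concentrations

@pytest.mark.parametrize("target,n_atoms,expected", [
    (5.0, 2, 2.5),   # urea, lysine at 5 mM elemental-N
    (5.0, 1, 5.0),   # ammonium, glutamate, serine
    (0.0, 3, 0.0),
])
def test_elemental_nitrogen_dosing(target, n_atoms, expected):
    assert n_source_concentration(target, n_atoms) == pytest.approx(expected)


def test_dosing_rejects_bad_inputs():
    with pytest.raises(InputError):
        n_source_concentration(5.0, 0)
    with pytest.raises(InputError):
        n_source_concentration(-1.0, 1)


# -------------------------------------------------------------- universe

def test_zero_deletion_leaves_draft_identical():
    uni = generate_universe(n_sources=5, n_db_reactions=50,
                            deletion_fraction=0.0, seed=4)
    for strain, true_net in uni.true_networks.items():
        assert network_to_dict(uni.drafts[strain])["reactions"] == \
            network_to_dict(true_net.copy(id=uni.drafts[strain].id))["reactions"]


def test_same_seed_reproduces_universe_serialization():
    u1 = generate_universe(seed=8)
    u2 = generate_universe(seed=8)
    assert network_to_dict(u1.db) == network_to_dict(u2.db)
    for strain in u1.true_networks:
        assert network_to_dict(u1.drafts[strain]) == network_to_dict(u2.drafts[strain])
    assert u1.truth.equals(u2.truth)


def test_truth_matrix_matches_direct_fba_recomputation():
    uni = generate_universe(seed=6)
    for row in uni.truth.itertuples():
        recomputed = predicts_growth(uni.true_networks[row.strain],
                                     uni.panel[row.condition])
        assert recomputed == row.grows


def test_universe_structural_invariants():
    uni = generate_universe(seed=2)
    for strain, draft in uni.drafts.items():
        true_net = uni.true_networks[strain]
        assert set(draft.reactions) <= set(true_net.reactions)  # draft subset
        uni.db.check_covers(draft)
        assert predicts_growth(draft, uni.panel["ammonium"])
        # at least one positive and one negative nitrogen source each
        assert len(uni.positives(strain)) >= 2  # ammonium + one organic source
        assert len(uni.negatives(strain)) >= 1


# ----------------------------------------------------------------- plate

def test_noiseless_plate_calls_reproduce_truth_exactly():
    uni = generate_universe(seed=3)
    strain = sorted(uni.true_networks)[0]
    truth_row = uni.truth_row(strain)
    plate = simulate_plate(truth_row, seed=1, noise_sd=0.0)
    corrected = subtract_background(plate)
    for well in corrected:
        if well.substrate_id in ("negative_control", sorted(truth_row)[-1]):
            continue  # control + planted high-background well
        fit = fit_logistic(well)
        assert (fit.K > 0.1) == truth_row[well.substrate_id]


def test_plate_recovery_rate_with_noise():
    """At noise sd 0.01, fitted growth calls match truth for >= 95% of
    wells."""
    rng = np.random.default_rng(11)
    truth_row = {f"s{i:02d}": bool(rng.random() < 0.6) for i in range(33)}
    plate = simulate_plate(truth_row, seed=11, noise_sd=0.01,
                           background_well="s32")
    corrected = subtract_background(plate)
    hits = total = 0
    for well in corrected:
        if well.substrate_id in ("negative_control", "s32"):
            continue
        total += 1
        hits += (fit_logistic(well).K > 0.1) == truth_row[well.substrate_id]
    assert total >= 96  # 32 substrates x 3 replicates
    assert hits / total >= 0.95


def test_plate_contains_control_and_planted_background_well():
    truth_row = {"s0": True, "s1": False}
    plate = simulate_plate(truth_row, seed=0, background_well="s1",
                           background_offset=0.7)
    ctrl = [w for w in plate if w.well == "A1"]
    assert len(ctrl) == 3  # one per replicate
    bg = [w for w in plate if w.substrate_id == "s1"][0]
    assert bg.values.min() > 0.5  # offset dominates


def test_same_seed_reproduces_plate():
    truth_row = {"s0": True, "s1": False}
    p1 = simulate_plate(truth_row, seed=5)
    p2 = simulate_plate(truth_row, seed=5)
    for w1, w2 in zip(p1, p2):
        assert np.array_equal(w1.values, w2.values)


# ------------------------------------------------------------ proteomics

def test_zero_effects_zero_noise_give_zero_fold_changes():
    mats, truth = simulate_proteomics(strains=["s0"], n_proteins=40, seed=1,
                                      n_dep_per_treatment=0, n_coupled=0,
                                      n_anticoupled=0, n_presence_absence=0,
                                      n_null=0, noise_sd=0.0)
    m = mats["s0"]
    log2 = np.log2(m.data)
    for t in m.treatments[1:]:
        pii = truth.pii_ids["s0"]
        a = log2[m.samples_for(t)].mean(axis=1)
        b = log2[m.samples_for("ammonium")].mean(axis=1)
        diff = (a - b).drop(pii)  # only the PII protein has a profile
        assert np.allclose(diff.fillna(0.0), 0.0, atol=1e-9)


def test_same_seed_reproduces_matrices():
    m1, _ = simulate_proteomics(seed=3, n_proteins=150)
    m2, _ = simulate_proteomics(seed=3, n_proteins=150)
    for s in m1:
        pd.testing.assert_frame_equal(m1[s].data, m2[s].data)


def test_planted_truth_is_consistent():
    mats, truth = simulate_proteomics(seed=7)
    for strain, mat in mats.items():
        planted = truth.dep_truth[strain][("ammonium", "glutamate")]
        nulls = set(truth.null_proteins[strain])
        assert planted and not (set(planted) & nulls)
        assert set(planted) <= set(mat.data.index)
        # presence/absence block proteins are detected in the reference
        for p in truth.pa_proteins[strain]:
            assert mat.detected_counts("ammonium")[p] >= 3


def test_detection_limit_censors_low_values():
    mats, truth = simulate_proteomics(seed=9)
    for strain, mat in mats.items():
        observed = np.log2(mat.data.stack())
        assert observed.min() >= truth.detection_limit_log2 - 1e-9
        assert mat.data.isna().any().any()  # some censoring occurred
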