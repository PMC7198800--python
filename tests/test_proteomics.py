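"""Differential abundance, BH/Fisher oracles, KO matching and PII screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from nitrofba import (
    ProteomicsMatrix,
    benjamini_hochberg,
    differential_abundance,
    enumerate_comparisons,
    fisher_combined,
    match_kos,
    pathway_test,
    pii_screen,
)
from nitrofba.errors import InputError


def _matrix(values_by_treatment, strain="s1", n_reps=4):
    """Build a ProteomicsMatrix from {treatment: proteins x reps log2 array}."""
    cols, data = [], []
    meta = []
    for t, arr in values_by_treatment.items():
        arr = np.asarray(arr, dtype=float)
        for rep in range(arr.shape[1]):
            cols.append(f"{t}_r{rep+1}")
            meta.append((f"{t}_r{rep+1}", t, rep + 1))
            data.append(arr[:, rep])
    proteins = [f"p{i}" for i in range(len(next(iter(values_by_treatment.values()))))]
    df = pd.DataFrame(np.column_stack(data), index=proteins, columns=cols)
    meta = pd.DataFrame(meta, columns=["sample", "treatment", "replicate"]
                        ).set_index("sample")
    return ProteomicsMatrix(strain, np.power(2.0, df), meta)


# ------------------------------------------------------------------ DEA

def test_identical_groups_give_null_result():
    m = _matrix({"a": [[8, 8, 8, 8]], "b": [[8, 8, 8, 8]]})
    res = differential_abundance(m, "a", "b")
    assert res.loc["p0", "log2fc"] == pytest.approx(0.0)
    assert res.loc["p0", "pvalue"] == 1.0
    assert not res.loc["p0", "dep"]


def test_forced_effect_is_called_dep():
    rng = np.random.default_rng(0)
    a = 8.0 + rng.normal(0, 1e-6, (1, 4))
    b = 4.0 + rng.normal(0, 1e-6, (1, 4))
    res = differential_abundance(_matrix({"a": a, "b": b}), "a", "b")
    assert res.loc["p0", "log2fc"] == pytest.approx(4.0, abs=1e-4)
    assert res.loc["p0", "dep"]


def test_bh_step_up_matches_hand_oracle():
    # classic step-up example: (0.01, 0.02, 0.03, 0.04) with m=4 all adjust
    # to 0.04
    adj = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
    assert np.allclose(adj, 0.04)


def _bh_bruteforce(p):
    """Independent step-up implementation: p_(i) * m / i with cumulative
    minimum from the largest rank down."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=40))
def test_bh_matches_bruteforce_and_is_idempotent(pvals):
    p = np.array(pvals)
    adj = benjamini_hochberg(p)
    assert np.allclose(adj, _bh_bruteforce(p))
    assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0)
    # monotone in raw-p rank
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)
    # note: BH is NOT idempotent (e.g. [1.0, 0.25] -> [1.0, 0.5] -> [1.0, 1.0]);
    # re-adjusting can only inflate
    assert np.all(benjamini_hochberg(adj) >= adj - 1e-12)


def test_antisymmetry_of_pair_orientation():
    rng = np.random.default_rng(3)
    vals = {"a": rng.normal(20, 1, (30, 4)), "b": rng.normal(21, 1, (30, 4))}
    m = _matrix(vals)
    ab = differential_abundance(m, "a", "b")
    ba = differential_abundance(m, "b", "a")
    assert np.allclose(ab["log2fc"], -ba["log2fc"])
    assert np.allclose(ab["pvalue"], ba["pvalue"])
    assert (ab["dep"] == ba["dep"]).all()


def test_presence_absence_routing():
    a = np.full((2, 4), 22.0)
    b = np.full((2, 4), 22.0)
    b[0, :] = np.nan  # protein p0 never detected under b
    m = ProteomicsMatrix(
        "s", pd.DataFrame(np.power(2.0, np.column_stack([a, b])),
                          index=["p0", "p1"],
                          columns=[f"a_r{i}" for i in range(1, 5)]
                          + [f"b_r{i}" for i in range(1, 5)]),
        pd.DataFrame({"sample": [f"a_r{i}" for i in range(1, 5)]
                      + [f"b_r{i}" for i in range(1, 5)],
                      "treatment": ["a"] * 4 + ["b"] * 4,
                      "replicate": list(range(1, 5)) * 2}).set_index("sample"))
    res = differential_abundance(m, "a", "b")
    assert res.loc["p0", "status"] == "present_only_a"
    assert np.isnan(res.loc["p0", "pvalue"])
    assert res.loc["p1", "status"] == "tested"


def test_comparison_enumeration_counts():
    five = ["ammonium", "glutamate", "lysine", "serine", "urea"]
    assert len(enumerate_comparisons(five)) == 10
    assert enumerate_comparisons(["x", "y"]) == [("x", "y")]
    with pytest.raises(InputError):
        enumerate_comparisons(["only"])


# ------------------------------------------------------------------- KO

def _ko_fixture():
    rng = np.random.default_rng(5)
    mats = {}
    for strain in ("sA", "sB"):
        vals = {t: rng.normal(24, 0.5, (4, 4)) for t in ("ammonium", "urea")}
        m = _matrix(vals, strain=strain)
        m.data.index = [f"{strain}_p{i}" for i in range(4)]
        mats[strain] = ProteomicsMatrix(strain, m.data, m.metadata)
    return mats


def test_representative_is_highest_grand_mean():
    mats = _ko_fixture()
    # p0 and p1 share KO k0; make p1 clearly more abundant in sA
    mats["sA"].data.loc["sA_p1"] *= 8.0
    ko_map = {f"{s}_p{i}": ("k0" if i < 2 else f"k{i}")
              for s in ("sA", "sB") for i in range(4)}
    table = match_kos(mats, ko_map)
    reps = table.representatives.set_index(["ko", "strain"])["protein"]
    assert reps.loc[("k0", "sA")] == "sA_p1"


def test_ko_dropped_if_undetected_in_one_treatment_of_one_strain():
    mats = _ko_fixture()
    # knock out k2's protein in one treatment of one strain
    urea_cols = mats["sB"].samples_for("urea")
    mats["sB"].data.loc["sB_p2", urea_cols] = np.nan
    ko_map = {f"{s}_p{i}": f"k{i}" for s in ("sA", "sB") for i in range(4)}
    table = match_kos(mats, ko_map)
    assert "k2" not in table.abundance.index
    assert "k3" in table.abundance.index


def test_z_view_rows_standardized_and_ammonium_view_referenced():
    mats = _ko_fixture()
    ko_map = {f"{s}_p{i}": f"k{i}" for s in ("sA", "sB") for i in range(4)}
    table = match_kos(mats, ko_map)
    z = table.z_view()
    for strain in table.strains:
        block = z[strain]
        assert np.allclose(block.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(block.std(axis=1, ddof=1), 1.0, atol=1e-9)
    ratios = table.ammonium_view()
    expected = (table.abundance[("sA", "urea")]
                - table.abundance[("sA", "ammonium")])
    assert np.allclose(ratios[("sA", "urea")], expected)


# -------------------------------------------------------------- pathways

def test_fisher_combined_identity_and_oracle():
    # a single p-value combines to itself
    _, p1 = fisher_combined([0.37])
    assert p1 == pytest.approx(0.37, abs=1e-12)
    # closed-form oracle: k=3 equal p of 0.5
    x, p = fisher_combined([0.5, 0.5, 0.5])
    assert x == pytest.approx(-2 * 3 * np.log(0.5), rel=1e-12)
    assert p == pytest.approx(stats.chi2.sf(x, 6), rel=1e-12)
    # closed form: exp(-x/2) * sum_{j<3} (x/2)^j / j! = 0.655185...
    assert p == pytest.approx(0.655185, abs=1e-6)
    # cross-check against the library implementation of the same method
    ref = stats.combine_pvalues([0.5, 0.5, 0.5], method="fisher")
    assert p == pytest.approx(ref.pvalue, rel=1e-12)


def test_zero_pvalues_floored_with_warning():
    with pytest.warns(UserWarning):
        x, p = fisher_combined([0.0, 0.5])
    assert np.isfinite(x) and 0.0 <= p <= 1.0


def _comparison_frame(pvals, deps=None):
    idx = [f"p{i}" for i in range(len(pvals))]
    return pd.DataFrame({
        "log2fc": 2.0, "n_a": 4, "n_b": 4, "pvalue": pvals, "p_adj": pvals,
        "dep": deps if deps is not None else [False] * len(pvals),
        "status": "tested",
    }, index=idx)


def test_small_pathways_excluded_and_blacklist_respected():
    comp = _comparison_frame([0.1, 0.2, 0.3, 0.4, 0.5])
    ko_map = {f"p{i}": f"k{i}" for i in range(5)}
    pathway_map = {"k0": ["big"], "k1": ["big"], "k2": ["big", "tiny"],
                   "k3": ["tiny"], "k4": ["banned", "big"]}
    res = pathway_test(comp, ko_map, pathway_map, min_proteins=3,
                       blacklist=["banned"])
    assert list(res.index) == ["big"]  # tiny has 2 proteins, banned dropped
    x, p = fisher_combined([0.1, 0.2, 0.3, 0.5])
    assert res.loc["big", "combined_p"] == pytest.approx(p)


def test_enrichment_variant_runs_2x2_fisher():
    comp = _comparison_frame([0.001] * 3 + [0.9] * 5,
                             deps=[True] * 3 + [False] * 5)
    ko_map = {f"p{i}": f"k{i}" for i in range(8)}
    pathway_map = {f"k{i}": ["pw"] for i in range(3)}
    res = pathway_test(comp, ko_map, pathway_map, method="enrichment")
    odds_p = stats.fisher_exact([[3, 0], [0, 5]], alternative="greater")[1]
    assert res.loc["pw", "combined_p"] == pytest.approx(odds_p)


# ------------------------------------------------------------ PII screen

def _pii_table():
    treatments = ["ammonium", "glutamate", "lysine", "serine", "urea"]
    profile = np.array([-1.0, 0.9, 1.1, -0.4, -0.6])
    profile = (profile - profile.mean()) / profile.std(ddof=1)  # unit sd
    rng = np.random.default_rng(12)
    rows = {
        "PII": 20.0 + profile,                       # unit-sd PII profile
        "self_copy": 20.0 + profile,                 # slope 1, corr 1
        "coupled": 22.0 + 3.0 * profile,             # slope 3
        "anti": 24.0 - 3.0 * profile + rng.normal(0, 0.01, 5),
        "weak": 21.0 + 1.5 * profile,                # corr high, slope < 2
        "flat": np.full(5, 19.0),
    }
    return pd.DataFrame(rows, index=treatments).T


def test_pii_screen_classification_rules():
    res = pii_screen(_pii_table(), "PII")
    assert res.loc["self_copy", "correlation"] == pytest.approx(1.0)
    assert res.loc["self_copy", "slope"] == pytest.approx(1.0, abs=1e-9)
    assert res.loc["self_copy", "classification"] == "none"  # slope <= 2
    assert res.loc["coupled", "classification"] == "positive"
    assert res.loc["coupled", "slope"] == pytest.approx(3.0, abs=1e-9)
    assert res.loc["anti", "classification"] == "negative"
    assert res.loc["anti", "slope"] == pytest.approx(-3.0, abs=0.05)
    # corr 1 but slope 1.5: outside the positive class
    assert res.loc["weak", "classification"] == "none"
    assert res.loc["flat", "classification"] == "none"
    assert np.isnan(res.loc["flat", "slope"])


def test_pii_screen_requires_complete_pii_profile():
    table = _pii_table()
    table.loc["PII", "urea"] = np.nan
    with pytest.raises(InputError):
        pii_screen(table, "PII")
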