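"""Gapfilling against exhaustive-search oracles on small instances."""

import numpy as np
import pytest

from nitrofba import (
    MediumCondition,
    Metabolite,
    MetabolicNetwork,
    Reaction,
    UniversalDB,
    fba,
    gapfill_negative,
    gapfill_positive,
    generate_universe,
    predicts_growth,
)
from nitrofba.errors import UngapfillableError
from conftest import exhaustive_min_gapfill, exhaustive_min_removal


def _db_from(net: MetabolicNetwork, extra=()) -> UniversalDB:
    rxns = [r.copy() for r in net if not r.is_biomass] + [r.copy() for r in extra]
    return UniversalDB("db", list(net.metabolites.values()), rxns)


def test_single_missing_reaction_restored(chain_network, blocked_network, medium_a):
    db = _db_from(chain_network)
    filled, added = gapfill_positive(blocked_network, db, medium_a)
    assert added == ["AB"]
    assert predicts_growth(filled, medium_a)
    # matches the exhaustive single-addition enumeration
    k, subsets = exhaustive_min_gapfill(blocked_network, db, medium_a)
    assert k == 1 and ("AB",) in subsets


def test_already_growing_draft_is_noop(chain_network, medium_a):
    db = _db_from(chain_network)
    filled, added = gapfill_positive(chain_network, db, medium_a)
    assert added == []
    assert sorted(filled.reactions) == sorted(chain_network.reactions)


@pytest.mark.parametrize("tie_break", ["weighted", "lexicographic"])
def test_tie_between_single_fixes_prefers_lexicographic(blocked_network, medium_a,
                                                        tie_break):
    """Two alternative one-reaction fixes: the lexicographically smaller id
    is chosen deterministically."""
    fix1 = Reaction("FIX_a", {"A_e": -1.0, "B_c": 1.0})
    fix2 = Reaction("FIX_b", {"A_e": -1.0, "B_c": 1.0})
    db = UniversalDB("db", list(blocked_network.metabolites.values()),
                     [fix1, fix2])
    _, added = gapfill_positive(blocked_network, db, medium_a, tie_break=tie_break)
    assert added == ["FIX_a"]
    k, subsets = exhaustive_min_gapfill(blocked_network, db, medium_a, max_size=2)
    assert k == 1 and ("FIX_a",) in subsets


def test_multi_step_gap_matches_exhaustive_minimum(medium_a):
    """Draft missing a two-reaction path; decoys present.  MILP cardinality
    must equal the brute-force minimum."""
    mets = [Metabolite("A_e", "A", "e"), Metabolite("I_c", "I", "c"),
            Metabolite("B_c", "B", "c"), Metabolite("X_c", "X", "c")]
    draft = MetabolicNetwork(
        "draft", mets,
        [Reaction("EX_A", {"A_e": -1.0}, is_exchange=True),
         Reaction("BIO", {"B_c": -1.0}, is_biomass=True)])
    db = UniversalDB("db", mets, [
        Reaction("S1", {"A_e": -1.0, "I_c": 1.0}),
        Reaction("S2", {"I_c": -1.0, "B_c": 1.0}),
        Reaction("D1", {"X_c": -1.0, "B_c": 1.0}),   # dead end: X unproducible
        Reaction("D2", {"I_c": -1.0, "X_c": 1.0}),
    ])
    filled, added = gapfill_positive(draft, db, medium_a)
    k, subsets = exhaustive_min_gapfill(draft, db, medium_a)
    assert len(added) == k == 2
    assert tuple(added) in subsets
    assert predicts_growth(filled, medium_a)


def test_ungapfillable_condition_raises(blocked_network):
    db = UniversalDB("db", list(blocked_network.metabolites.values()),
                     [Reaction("NOP", {"B_c": -1.0, "A_e": 1.0})])
    medium = MediumCondition("mA", {"EX_A": 10.0}, "EX_A")
    with pytest.raises(UngapfillableError) as err:
        gapfill_positive(blocked_network, db, medium)
    assert err.value.condition_id == "mA"


def test_oracle_equivalence_on_random_small_instances():
    """On <= 12-reaction instances, the MILP addition-set cardinality always
    equals the exhaustive-search minimum."""
    rng = np.random.default_rng(1234)
    checked = 0
    for seed in range(6):
        uni = generate_universe(n_metabolites=10, n_db_reactions=14, n_strains=1,
                                n_sources=3, deletion_fraction=0.4, seed=seed)
        strain = next(iter(uni.drafts))
        draft = uni.drafts[strain]
        for cid in uni.positives(strain):
            medium = uni.panel[cid]
            if predicts_growth(draft, medium):
                continue
            try:
                _, added = gapfill_positive(draft, uni.db, medium)
            except UngapfillableError:
                added = None
            k, subsets = exhaustive_min_gapfill(draft, uni.db, medium, max_size=4)
            if added is None:
                assert k is None or k > 4
            else:
                assert len(added) == k
                checked += 1
    assert checked >= 3  # the fixture set exercised real gapfills


# ------------------------------------------------------------- negative

def _negative_toy():
    """Network growing on both A and N media; reaction T_N only serves the
    negative medium, so removing it silences N without breaking A."""
    mets = [Metabolite("A_e", "A", "e"), Metabolite("N_e", "N", "e"),
            Metabolite("B_c", "B", "c")]
    rxns = [
        Reaction("EX_A", {"A_e": -1.0}, is_exchange=True),
        Reaction("EX_N", {"N_e": -1.0}, is_exchange=True),
        Reaction("T_A", {"A_e": -1.0, "B_c": 1.0}),
        Reaction("T_N", {"N_e": -1.0, "B_c": 1.0}),
        Reaction("BIO", {"B_c": -1.0}, is_biomass=True),
    ]
    net = MetabolicNetwork("negtoy", mets, rxns)
    medium_a = MediumCondition("mA", {"EX_A": 10.0}, "EX_A")
    medium_n = MediumCondition("mN", {"EX_N": 10.0}, "EX_N")
    return net, medium_a, medium_n


def test_negative_trimming_removes_the_only_route():
    net, medium_a, medium_n = _negative_toy()
    res = gapfill_negative(net, medium_n, [medium_a], removable_ids=["T_N"],
                           rng=np.random.default_rng(0))
    assert res.removed_ids == ["T_N"]
    assert not res.unresolvable
    assert not predicts_growth(res.network, medium_n)
    assert predicts_growth(res.network, medium_a)
    # matches the exhaustive removal-set oracle
    k, subsets = exhaustive_min_removal(net, medium_n, [medium_a], ["T_N", "T_A"])
    assert k == 1 and ("T_N",) in subsets


def test_negative_already_silent_is_noop():
    net, medium_a, medium_n = _negative_toy()
    silent = net.without("T_N")
    res = gapfill_negative(silent, medium_n, [medium_a], removable_ids=["T_A"])
    assert res.removed_ids == [] and not res.unresolvable


def test_unresolvable_negative_returns_flagged_original():
    """Every candidate removal breaks the positive: network must come back
    unchanged with the flag set, positives intact."""
    mets = [Metabolite("A_e", "A", "e"), Metabolite("B_c", "B", "c")]
    net = MetabolicNetwork(
        "shared", mets,
        [Reaction("EX_A", {"A_e": -1.0}, is_exchange=True),
         Reaction("T", {"A_e": -1.0, "B_c": 1.0}),
         Reaction("BIO", {"B_c": -1.0}, is_biomass=True)])
    # the "negative" medium is the same input at lower uptake: the shared
    # route cannot be removed without losing the positive
    pos = MediumCondition("pos", {"EX_A": 10.0}, "EX_A")
    neg = MediumCondition("neg", {"EX_A": 5.0}, "EX_A")
    res = gapfill_negative(net, neg, [pos], removable_ids=["T"])
    assert res.unresolvable
    assert res.removed_ids == []
    assert sorted(res.network.reactions) == sorted(net.reactions)
    assert predicts_growth(res.network, pos)
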