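"""Shared toy networks and helpers.

The toys are small enough for hand-computed LP optima and exhaustive
gapfill-subset oracles.
"""

from __future__ import annotations

import itertools

import pytest

from nitrofba import (
    MediumCondition,
    Metabolite,
    MetabolicNetwork,
    Reaction,
    UniversalDB,
    fba,
    predicts_growth,
)


def make_chain_network() -> MetabolicNetwork:
    """EX_A (<=10 uptake) -> A_e -> B_c -> biomass, all coefficients 1."""
    mets = [Metabolite("A_e", "A", "e"), Metabolite("B_c", "B", "c")]
    rxns = [
        Reaction("EX_A", {"A_e": -1.0}, is_exchange=True),
        Reaction("AB", {"A_e": -1.0, "B_c": 1.0}),
        Reaction("BIO", {"B_c": -1.0}, is_biomass=True),
    ]
    return MetabolicNetwork("chain", mets, rxns)


def make_branched_network() -> MetabolicNetwork:
    """Two routes from A to biomass precursor with yields 1 and 2; with
    uptake <= 5 the optimum uses the yield-2 route: growth rate 10."""
    mets = [Metabolite("A_e", "A", "e"), Metabolite("A_c", "A", "c"),
            Metabolite("B_c", "B", "c")]
    rxns = [
        Reaction("EX_A", {"A_e": -1.0}, is_exchange=True),
        Reaction("T_A", {"A_e": -1.0, "A_c": 1.0}),
        Reaction("R1", {"A_c": -1.0, "B_c": 1.0}),
        Reaction("R2", {"A_c": -1.0, "B_c": 2.0}),
        Reaction("BIO", {"B_c": -1.0}, is_biomass=True),
    ]
    return MetabolicNetwork("branched", mets, rxns)


@pytest.fixture
def chain_network():
    return make_chain_network()


@pytest.fixture
def blocked_network(chain_network):
    return chain_network.without("AB")


@pytest.fixture
def branched_network():
    return make_branched_network()


@pytest.fixture
def medium_a():
    return MediumCondition("mA", {"EX_A": 10.0}, nitrogen_source_id="EX_A")


@pytest.fixture
def medium_a5():
    return MediumCondition("mA5", {"EX_A": 5.0}, nitrogen_source_id="EX_A")


def exhaustive_min_gapfill(draft: MetabolicNetwork, db: UniversalDB,
                           medium: MediumCondition, epsilon: float = 1e-3,
                           max_size: int | None = None):
    """Independent oracle: smallest addition subsets enabling growth, found
    by brute-force enumeration over the database in increasing cardinality.
    Returns (min_cardinality, list of all minimal subsets as sorted tuples),
    or (None, []) when no subset works."""
    candidates = sorted(r.id for r in db if r.id not in draft.reactions)
    limit = len(candidates) if max_size is None else min(max_size, len(candidates))
    for k in range(0, limit + 1):
        hits = []
        for combo in itertools.combinations(candidates, k):
            extra = [db.reactions[rid] for rid in combo]
            new_mets = [db.metabolites[m] for r in extra for m in r.stoichiometry
                        if m not in draft.metabolites]
            trial = draft.with_reactions(extra, new_mets)
            if predicts_growth(trial, medium, epsilon):
                hits.append(tuple(sorted(combo)))
        if hits:
            return k, hits
    return None, []


def exhaustive_min_removal(network: MetabolicNetwork, negative: MediumCondition,
                           positives, removable, epsilon: float = 1e-3):
    """Independent oracle for negative gapfilling: all minimal removal sets
    that silence the negative condition while keeping every positive
    growing."""
    removable = sorted(removable)
    for k in range(0, len(removable) + 1):
        hits = []
        for combo in itertools.combinations(removable, k):
            trial = network
            for rid in combo:
                trial = trial.without(rid)
            if predicts_growth(trial, negative, epsilon):
                continue
            if all(predicts_growth(trial, p, epsilon) for p in positives):
                hits.append(tuple(sorted(combo)))
        if hits:
            return k, hits
    return None, []
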