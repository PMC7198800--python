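"""Synthetic data with known ground truth for every pipeline stage.

The study's raw inputs (phenotype-microarray kinetics, KBase draft
reconstructions, MaxQuant LFQ matrices) are emulated at toy scale so that
recovery can be verified against planted truth:

* :func:`generate_universe` builds a universal reaction database of layered
  nitrogen-catabolic pathways, per-strain *true* networks (defining which
  nitrogen sources genuinely support growth), degraded *draft* networks
  (seeded deletion of reactions non-essential for ammonium growth), a media
  panel varying only the nitrogen source over a shared glucose backbone,
  and the FBA-derived truth growth matrix.
* :func:`simulate_plate` turns a truth row into three replicate plates of
  logistic kinetics with Gaussian noise, a shared background drift captured
  by the negative-control well A1, and one planted high-background well to
  exercise the exclusion rule.
* :func:`simulate_proteomics` builds per-strain LFQ matrices with
  log-normal baselines, planted differential-abundance effects, a block of
  proteins coupled to the PII nitrogen-stress protein with known slopes,
  and left-censored (detection-limit) missingness.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InputError, ValidationError
from .fba import DEFAULT_EPSILON, fba, predicts_growth
from .growth_scoring import PlateWellSeries, logistic
from .network import (
    CYTOSOL,
    EXTRACELLULAR,
    MediumCondition,
    Metabolite,
    MetabolicNetwork,
    Reaction,
    UniversalDB,
)
from .proteomics import ProteomicsMatrix

TREATMENTS = ("ammonium", "glutamate", "lysine", "serine", "urea")
DEFAULT_UPTAKE = 10.0


def n_source_concentration(target_elemental_n_mm: float,
                           n_atoms_per_molecule: int) -> float:
    """Substrate concentration (mM) delivering a target elemental-N dose.

    Media are dosed so total nitrogen *atoms* are equimolar across
    substrates: 5 mM elemental-N means 5 mM of single-N substrates
    (ammonium, glutamate, serine) but 2.5 mM of two-N substrates (urea,
    lysine).
    """
    if n_atoms_per_molecule < 1:
        raise InputError("a nitrogen source must contain at least one N atom")
    if target_elemental_n_mm < 0:
        raise InputError("target elemental-N concentration must be >= 0")
    return target_elemental_n_mm / n_atoms_per_molecule


# ------------------------------------------------------------- universes

@dataclass
class SyntheticUniverse:
    db: UniversalDB
    true_networks: Dict[str, MetabolicNetwork]
    drafts: Dict[str, MetabolicNetwork]
    panel: Dict[str, MediumCondition]
    truth: pd.DataFrame  # columns: strain, condition, grows
    seed: int

    def truth_row(self, strain: str) -> Dict[str, bool]:
        sub = self.truth[self.truth["strain"] == strain]
        return dict(zip(sub["condition"], sub["grows"]))

    def activity_row(self, strain: str) -> Dict[str, float]:
        """FBA growth rate of the strain's true network on every condition;
        the metabolic-activity ground truth behind the plate kinetics."""
        net = self.true_networks[strain]
        return {cid: fba(net, cond, validate=False).objective_value
                for cid, cond in self.panel.items()}

    def positives(self, strain: str) -> List[str]:
        return sorted(c for c, g in self.truth_row(strain).items() if g)

    def negatives(self, strain: str) -> List[str]:
        return sorted(c for c, g in self.truth_row(strain).items() if not g)


def _biomass_reaction() -> Reaction:
    # toy biomass: one nitrogen currency unit + one carbon precursor
    return Reaction("bio1", {"nh4_c": -1.0, "pre_c": -1.0},
                    0.0, 1000.0, is_biomass=True, name="toy biomass")


def _backbone() -> Tuple[List[Metabolite], List[Reaction]]:
    mets = [
        Metabolite("glc_e", "glucose", EXTRACELLULAR),
        Metabolite("glc_c", "glucose", CYTOSOL),
        Metabolite("pyr_c", "pyruvate", CYTOSOL),
        Metabolite("pre_c", "biomass precursor", CYTOSOL),
        Metabolite("nh4_e", "ammonium", EXTRACELLULAR),
        Metabolite("nh4_c", "ammonium", CYTOSOL),
    ]
    rxns = [
        Reaction("EX_glc", {"glc_e": -1.0}, is_exchange=True, name="glucose exchange"),
        Reaction("T_glc", {"glc_e": -1.0, "glc_c": 1.0}, name="glucose transport"),
        Reaction("GLYC", {"glc_c": -1.0, "pyr_c": 1.0}, name="glycolysis (lumped)"),
        Reaction("PREC", {"pyr_c": -1.0, "pre_c": 1.0}, name="precursor synthesis"),
        Reaction("EX_nh4", {"nh4_e": -1.0}, is_exchange=True, name="ammonium exchange"),
        Reaction("T_nh4", {"nh4_e": -1.0, "nh4_c": 1.0}, name="ammonium transport"),
    ]
    return mets, rxns


def _source_pathway(j: int, chain_len: int, alt_route: bool, n_atoms: int,
                    hub: Optional[str]
                    ) -> Tuple[List[Metabolite], List[Reaction], str]:
    """Pathway for nitrogen source j: exchange, transport, then a chain of
    ``chain_len`` catabolic steps whose final step releases ``n_atoms``
    nitrogen units (one per nitrogen atom of the substrate).  When ``hub``
    is given the chain feeds a shared deamination hub instead of releasing
    ammonium directly, so several substrates converge on common downstream
    reactions — gapfilling one substrate can then generalize to held-out
    ones.  An optional alternative transporter adds route redundancy."""
    name = f"nsrc{j:02d}"
    mets = [Metabolite(f"{name}_e", name, EXTRACELLULAR),
            Metabolite(f"{name}_c", name, CYTOSOL)]
    rxns = [Reaction(f"EX_{name}", {f"{name}_e": -1.0}, is_exchange=True),
            Reaction(f"T_{name}", {f"{name}_e": -1.0, f"{name}_c": 1.0})]
    prev = f"{name}_c"
    for step in range(chain_len - 1):
        mid = f"{name}_i{step}"
        mets.append(Metabolite(mid, f"{name} intermediate {step}", CYTOSOL))
        rxns.append(Reaction(f"D_{name}_{step}", {prev: -1.0, mid: 1.0}))
        prev = mid
    sink = hub if hub is not None else "nh4_c"
    rxns.append(Reaction(f"D_{name}_f", {prev: -1.0, sink: float(n_atoms)}))
    if alt_route:
        rxns.append(Reaction(f"T2_{name}", {f"{name}_e": -1.0, f"{name}_c": 1.0}))
    return mets, rxns, name


def generate_universe(n_metabolites: int = 40, n_db_reactions: int = 120,
                      n_strains: int = 3, n_sources: int = 12,
                      deletion_fraction: float = 0.3, seed: int = 0,
                      *, epsilon: float = DEFAULT_EPSILON,
                      uptake: float = DEFAULT_UPTAKE,
                      p_source_present: float = 0.6,
                      max_retries: int = 20) -> SyntheticUniverse:
    """Build a universal database, true and draft networks, media panel and
    FBA truth matrix.

    ``n_metabolites``/``n_db_reactions`` size the decoy pool on top of the
    structured pathways.  Drafts are derived from each true network by
    greedily deleting up to ``deletion_fraction`` of the reactions that are
    individually and jointly non-essential for ammonium growth, so every
    draft still grows on ammonium but has lost catabolic routes the
    gapfiller must restore.
    """
    if not 0 <= deletion_fraction <= 0.5:
        raise InputError("deletion_fraction must lie in [0, 0.5]")
    if min(n_metabolites, n_db_reactions, n_strains, n_sources) < 1:
        raise InputError("universe parameters must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA11CE]))

    bb_mets, bb_rxns = _backbone()
    db = UniversalDB("udb")
    for m in bb_mets:
        db.add_metabolite(m)
    for r in bb_rxns:
        db.add_reaction(r.copy())

    # shared deamination hubs: several substrates funnel through each, so a
    # hub reaction restored while training on one substrate also serves the
    # others that use it
    n_hubs = max(1, min(3, n_sources // 3))
    hub_rxn: Dict[str, str] = {}
    for h in range(n_hubs):
        hub_met = f"hub{h}_c"
        db.add_metabolite(Metabolite(hub_met, f"deamination hub {h}", CYTOSOL))
        db.add_reaction(Reaction(f"H_{h}", {hub_met: -1.0, "nh4_c": 1.0}))
        hub_rxn[hub_met] = f"H_{h}"

    source_rxn_ids: Dict[str, List[str]] = {}
    source_names: List[str] = []
    source_uptake: Dict[str, float] = {}
    for j in range(n_sources):
        chain_len = int(rng.integers(1, 3))
        alt = bool(rng.random() < 0.4)
        n_atoms = 2 if rng.random() < 0.4 else 1
        hub = f"hub{int(rng.integers(0, n_hubs))}_c" if rng.random() < 0.75 else None
        mets, rxns, name = _source_pathway(j, chain_len, alt, n_atoms, hub)
        for m in mets:
            db.add_metabolite(m)
        for r in rxns:
            db.add_reaction(r.copy())
        source_names.append(name)
        source_rxn_ids[name] = [r.id for r in rxns]
        if hub is not None:
            source_rxn_ids[name].append(hub_rxn[hub])
        # nitrogen-limited media: per-substrate uptake capacity below the
        # carbon limit, so growth rates differ across sources
        source_uptake[name] = float(np.round(rng.uniform(0.2, 0.8) * uptake, 3))

    # decoy reactions over a pool of dead-end metabolites
    n_decoy_mets = max(2, n_metabolites - len(db.metabolites))
    for k in range(n_decoy_mets):
        db.add_metabolite(Metabolite(f"x{k:02d}_c", f"decoy {k}", CYTOSOL))
    k = 0
    while len(db.reactions) < n_db_reactions:
        a, b = rng.choice(n_decoy_mets, 2, replace=False)
        db.add_reaction(Reaction(f"DEC_{k:03d}",
                                 {f"x{a:02d}_c": -1.0, f"x{b:02d}_c": 1.0}))
        k += 1
    db.validate()

    # media panel: shared glucose backbone, only the nitrogen source varies
    panel: Dict[str, MediumCondition] = {
        "ammonium": MediumCondition("ammonium",
                                    {"EX_glc": uptake, "EX_nh4": 0.6 * uptake},
                                    nitrogen_source_id="EX_nh4"),
    }
    for name in source_names:
        panel[name] = MediumCondition(
            name, {"EX_glc": uptake, f"EX_{name}": source_uptake[name]},
            nitrogen_source_id=f"EX_{name}")

    for attempt in range(max_retries):
        arng = np.random.default_rng(np.random.SeedSequence([int(seed), 1, attempt]))
        try:
            true_networks, drafts, truth = _build_strains(
                db, panel, source_names, source_rxn_ids, n_strains,
                deletion_fraction, p_source_present, arng, epsilon)
            return SyntheticUniverse(db, true_networks, drafts, panel, truth, seed)
        except ValidationError:
            continue
    raise ValidationError(
        f"could not satisfy universe constraints after {max_retries} attempts")


def _build_strains(db, panel, source_names, source_rxn_ids, n_strains,
                   deletion_fraction, p_source_present, rng, epsilon):
    bb_ids = [r.id for _, rs in [_backbone()] for r in rs]
    true_networks: Dict[str, MetabolicNetwork] = {}
    drafts: Dict[str, MetabolicNetwork] = {}
    truth_rows = []
    for s in range(n_strains):
        strain = f"strain{s:02d}"
        present = [n for n in source_names if rng.random() < p_source_present]
        if not present or len(present) == len(source_names):
            raise ValidationError("strain needs >= 1 positive and >= 1 negative source")
        rxn_ids = list(bb_ids)
        for name in present:
            rxn_ids += [rid for rid in source_rxn_ids[name]
                        if not rid.startswith("T2_")]  # true nets use the primary route
        rxn_ids = list(dict.fromkeys(rxn_ids))  # shared hub reactions dedup
        net = MetabolicNetwork(
            strain,
            [db.metabolites[m] for rid in rxn_ids
             for m in db.reactions[rid].stoichiometry],
            [db.reactions[rid].copy() for rid in rxn_ids] + [_biomass_reaction()],
        )
        net.validate()
        # truth by direct FBA on the true network
        grows = {cid: predicts_growth(net, cond, epsilon)
                 for cid, cond in panel.items()}
        if not grows["ammonium"] or not any(
                grows[c] for c in source_names) or all(grows[c] for c in source_names):
            raise ValidationError("degenerate truth row")
        for cid in sorted(panel):
            truth_rows.append((strain, cid, bool(grows[cid])))

        drafts[strain] = _degrade(net, panel["ammonium"], deletion_fraction,
                                  rng, epsilon)
        true_networks[strain] = net
    truth = pd.DataFrame(truth_rows, columns=["strain", "condition", "grows"])
    return true_networks, drafts, truth


def _degrade(net: MetabolicNetwork, ammonium: MediumCondition,
             deletion_fraction: float, rng: np.random.Generator,
             epsilon: float) -> MetabolicNetwork:
    """Greedy seeded deletion of reactions non-essential for ammonium
    growth; skips any deletion that would break it."""
    candidates = [rid for rid, r in net.reactions.items()
                  if not r.is_biomass and not r.is_exchange]
    order = [candidates[i] for i in rng.permutation(len(candidates))]
    n_target = int(np.floor(deletion_fraction * len(candidates)))
    draft = net.copy(id=f"{net.id}_draft")
    deleted = 0
    for rid in order:
        if deleted >= n_target:
            break
        trial = draft.without(rid)
        if predicts_growth(trial, ammonium, epsilon):
            draft = trial
            deleted += 1
    return draft


# ----------------------------------------------------------------- plates

WELL_ROWS = "ABCDEFGH"


def _well_name(index: int) -> str:
    # A1 is reserved for the negative control; substrates fill A2, A3, ...
    return f"{WELL_ROWS[(index + 1) // 12]}{(index + 1) % 12 + 1}"


def simulate_plate(truth_row: Mapping[str, bool], seed: int, *,
                   plate_id: str = "PM3B", noise_sd: float = 0.01,
                   n_replicates: int = 3, t_max_h: float = 72.0,
                   cycle_min: float = 10.0,
                   growth_k: Tuple[float, float] = (0.15, 0.6),
                   nongrowth_k: Tuple[float, float] = (0.005, 0.05),
                   growth_r: Tuple[float, float] = (0.1, 0.5),
                   background_well: Optional[str] = None,
                   background_offset: float = 0.5,
                   activity: Optional[Mapping[str, float]] = None,
                   activity_weight: float = 0.65) -> List[PlateWellSeries]:
    """Simulate one strain's phenotype-microarray run from a truth row.

    Every well shares a slowly drifting background captured by the control
    well A1; growth-positive substrates get logistic kinetics with K drawn
    from ``growth_k`` (all above the 0.1 call threshold), negatives from
    ``nongrowth_k`` (all below).  One substrate (``background_well``,
    default the last) is planted with a large constant background offset to
    exercise the exclusion rule.

    ``activity`` optionally maps substrates to a metabolic-activity proxy
    (e.g. FBA growth rate on the true network); growth-well carrying
    capacities then mix the substrate's activity percentile with uniform
    noise (``activity_weight`` sets the mix), emulating that dye reduction
    partly tracks metabolic rate.
    """
    substrates = sorted(truth_row)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB10106]))
    times = np.arange(0.0, t_max_h + 1e-9, cycle_min / 60.0)
    if background_well is None and substrates:
        background_well = substrates[-1]
    act_pct: Dict[str, float] = {}
    if activity:
        growing = [s for s in substrates if truth_row[s] and s in activity]
        vals = np.array([activity[s] for s in growing], dtype=float)
        if len(vals) > 1 and vals.std() > 0:
            order = vals.argsort().argsort()  # average-free ranks suffice here
            act_pct = {s: order[k] / (len(growing) - 1)
                       for k, s in enumerate(growing)}
    out: List[PlateWellSeries] = []
    for rep in range(1, n_replicates + 1):
        drift = 0.03 + 0.0004 * times + 0.005 * np.sin(times / 20.0)
        ctrl = drift + rng.normal(0.0, noise_sd, len(times))
        out.append(PlateWellSeries(plate_id, "A1", rep, "negative_control",
                                   times.copy(), ctrl))
        for i, sub in enumerate(substrates):
            if truth_row[sub]:
                u = rng.uniform(0.0, 1.0)
                if sub in act_pct:
                    u = activity_weight * act_pct[sub] + (1 - activity_weight) * u
                K = growth_k[0] + (growth_k[1] - growth_k[0]) * u
                r = rng.uniform(*growth_r)
                n0 = rng.uniform(0.01, 0.04)
            else:
                K = rng.uniform(*nongrowth_k)
                r = rng.uniform(0.05, 0.2)
                n0 = rng.uniform(0.002, min(0.01, K / 1.5))
            y = logistic(times, K, r, min(n0, 0.9 * K))
            y = y + drift + rng.normal(0.0, noise_sd, len(times))
            if sub == background_well:
                y = y + background_offset
            out.append(PlateWellSeries(plate_id, _well_name(i), rep, sub,
                                       times.copy(), y))
    return out


# ------------------------------------------------------------- proteomics

@dataclass
class SyntheticProteomeTruth:
    """Planted ground truth for the proteomics generator."""

    effects: Dict[str, pd.DataFrame]         # strain -> proteins x treatments log2 effects
    dep_truth: Dict[str, Dict[Tuple[str, str], List[str]]]  # strain -> pair -> proteins
    null_proteins: Dict[str, List[str]]      # planted exact nulls
    pii_ids: Dict[str, str]
    pii_slopes: Dict[str, Dict[str, float]]  # strain -> protein -> coupling slope
    pa_proteins: Dict[str, List[str]]        # planted presence/absence block
    detection_limit_log2: float
    ko_map: Dict[str, str]
    pathway_map: Dict[str, List[str]]


def simulate_proteomics(strains: Sequence[str] = ("strain00", "strain01", "strain02"),
                        treatments: Sequence[str] = TREATMENTS,
                        n_replicates: int = 4, n_proteins: int = 400,
                        seed: int = 0, *,
                        effect_size: float = 3.0,
                        n_dep_per_treatment: int = 12,
                        n_null: int = 50,
                        n_coupled: int = 15, n_anticoupled: int = 5,
                        coupling_slope: float = 3.0,
                        noise_sd: float = 0.25,
                        baseline_mean: float = 26.0, baseline_sd: float = 1.5,
                        detection_limit_log2: float = 19.0,
                        n_presence_absence: int = 8,
                        n_pathways: int = 10,
                        ) -> Tuple[Dict[str, ProteomicsMatrix], SyntheticProteomeTruth]:
    """Per-strain LFQ matrices with planted effects and known truth.

    Each protein gets a strain-specific log-normal baseline (log2 scale).
    For every non-reference treatment a disjoint set of proteins is planted
    with a +/- ``effect_size`` log2 shift; a further ``n_null`` proteins are
    exact planted nulls.  A PII protein with a strong, unit-SD treatment
    profile anchors a coupled block: coupled proteins follow
    ``coupling_slope`` x z(PII profile), anti-coupled ones the negative.
    A separate low-abundance block sits just above the detection limit and
    is pushed below it in one treatment, exercising the presence/absence
    route.  Replicate noise is i.i.d. Gaussian on the log2 scale and values
    below the detection limit are left-censored to missing.
    """
    if n_replicates < 3:
        raise InputError("need >= 3 replicates per treatment")
    treatments = list(treatments)
    reference = treatments[0]
    required = ((len(treatments) - 1) * n_dep_per_treatment + n_null + 1
                + n_coupled + n_anticoupled + n_presence_absence)
    if n_proteins < required:
        raise InputError(
            f"n_proteins={n_proteins} too small for the planted blocks "
            f"(need >= {required})"
        )
    proteins_base = [f"P{i:04d}" for i in range(n_proteins)]
    # KO map: same KO index across strains (protein ids are strain-prefixed)
    ko_map: Dict[str, str] = {}
    pathway_map: Dict[str, List[str]] = {}
    rng0 = np.random.default_rng(np.random.SeedSequence([int(seed), 0xFEED]))
    for i, p in enumerate(proteins_base):
        ko = f"K{i:05d}"
        pathway_map[ko] = [f"pw{int(rng0.integers(0, n_pathways)):02d}"]
    matrices: Dict[str, ProteomicsMatrix] = {}
    effects_all: Dict[str, pd.DataFrame] = {}
    dep_all: Dict[str, Dict[Tuple[str, str], List[str]]] = {}
    null_all: Dict[str, List[str]] = {}
    pii_ids: Dict[str, str] = {}
    pii_slopes: Dict[str, Dict[str, float]] = {}
    pa_all: Dict[str, List[str]] = {}

    # PII treatment profile in z units (mean 0, sd 1 across treatments)
    base_profile = np.array([-1.0, 0.9, 1.1, -0.4, -0.6])[: len(treatments)]
    z_profile = (base_profile - base_profile.mean()) / base_profile.std(ddof=1)

    for s_idx, strain in enumerate(strains):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2, s_idx]))
        proteins = [f"{strain}_{p}" for p in proteins_base]
        for p_base, p in zip(proteins_base, proteins):
            ko_map[p] = f"K{proteins_base.index(p_base):05d}"
        baselines = rng.normal(baseline_mean, baseline_sd, n_proteins)

        effects = pd.DataFrame(0.0, index=proteins, columns=treatments)
        cursor = 0
        for t in treatments:
            if t == reference:
                continue
            idx = list(range(cursor, cursor + n_dep_per_treatment))
            cursor += n_dep_per_treatment
            for k, i in enumerate(idx):
                effects.iloc[i, effects.columns.get_loc(t)] = (
                    effect_size if k % 2 == 0 else -effect_size)
        null_proteins = proteins[cursor:cursor + n_null]
        cursor += n_null

        # PII block: PII protein itself + coupled/anti-coupled proteins
        pii = proteins[cursor]; cursor += 1
        pii_amplitude = 1.0  # unit-SD profile: slopes are in log2 per PII-SD
        slopes: Dict[str, float] = {}
        coupled = proteins[cursor:cursor + n_coupled]; cursor += n_coupled
        anti = proteins[cursor:cursor + n_anticoupled]; cursor += n_anticoupled
        for p in coupled:
            slopes[p] = coupling_slope
        for p in anti:
            slopes[p] = -coupling_slope
        pii_row = proteins.index(pii)
        effects.iloc[pii_row] = pii_amplitude * z_profile
        for p, s in slopes.items():
            effects.loc[p] = s * z_profile

        # low-abundance presence/absence block: detected at baseline, fully
        # censored under one non-reference treatment
        pa_block = proteins[cursor:cursor + n_presence_absence]
        cursor += n_presence_absence
        non_ref = [t for t in treatments if t != reference]
        for k, p in enumerate(pa_block):
            baselines[proteins.index(p)] = detection_limit_log2 + 1.5
            effects.loc[p, non_ref[k % len(non_ref)]] = -(effect_size + 2.0)

        samples, columns = [], []
        meta_rows = []
        log2_matrix = np.empty((n_proteins, len(treatments) * n_replicates))
        col = 0
        for t_idx, t in enumerate(treatments):
            for rep in range(1, n_replicates + 1):
                sample = f"{strain}_{t}_r{rep}"
                columns.append(sample)
                meta_rows.append((sample, t, rep))
                log2_matrix[:, col] = (baselines + effects[t].to_numpy()
                                       + rng.normal(0.0, noise_sd, n_proteins))
                col += 1
        log2_df = pd.DataFrame(log2_matrix, index=proteins, columns=columns)
        data = np.power(2.0, log2_df)
        data[log2_df < detection_limit_log2] = np.nan
        meta = pd.DataFrame(meta_rows, columns=["sample", "treatment", "replicate"]
                            ).set_index("sample")
        matrices[strain] = ProteomicsMatrix(strain, data, meta)

        # planted DEP truth: pairs where the planted contrast reaches the
        # design effect size (coupled-block proteins have sub-threshold
        # contrasts for many pairs and are only listed where they qualify)
        dep_truth: Dict[Tuple[str, str], List[str]] = {}
        pa_set = set(pa_block)
        for a, b in itertools.combinations(sorted(treatments), 2):
            diff = (effects[a] - effects[b]).abs()
            qualifying = effects.index[diff >= effect_size * (1 - 1e-9)]
            dep_truth[(a, b)] = sorted(p for p in qualifying if p not in pa_set)
        effects_all[strain] = effects
        dep_all[strain] = dep_truth
        null_all[strain] = list(null_proteins)
        pii_ids[strain] = pii
        pii_slopes[strain] = slopes
        pa_all[strain] = list(pa_block)

    truth = SyntheticProteomeTruth(effects_all, dep_all, null_all, pii_ids,
                                   pii_slopes, pa_all, detection_limit_log2,
                                   ko_map, pathway_map)
    return matrices, truth
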