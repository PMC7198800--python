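"""I/O for networks, media panels, growth-truth tables and ensembles.

Networks and universal databases use a small JSON dialect::

    {
      "id": "...", "kind": "network" | "universal_db",
      "biomass_id": "...",                      # networks only
      "metabolites": [{"id", "name", "compartment"}, ...],
      "reactions": [{"id", "stoichiometry": {met: coef}, "lower_bound",
                     "upper_bound", "is_exchange", "is_biomass", "name"}, ...]
    }

Media panels are TSV with columns ``condition_id, exchange_id, max_uptake,
is_nitrogen_source``; growth-truth tables are TSV with ``condition, grows``
(optionally a leading ``strain`` column).  Ensembles serialize to a
directory of member JSONs plus a ``records.json`` manifest; serialization is
bit-stable for a given seed (sorted keys, fixed float repr).

SBML Level-3 FBC import/export is available through cobrapy when installed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Union

import pandas as pd

from .ensemble import Ensemble
from .errors import InputError
from .gapfill import GapfillRecord
from .network import MediumCondition, Metabolite, MetabolicNetwork, Reaction, UniversalDB

PathLike = Union[str, Path]


# ---------------------------------------------------------------- networks

def _reaction_to_dict(r: Reaction) -> dict:
    return {
        "id": r.id,
        "stoichiometry": {m: float(c) for m, c in sorted(r.stoichiometry.items())},
        "lower_bound": float(r.lower_bound),
        "upper_bound": float(r.upper_bound),
        "is_exchange": bool(r.is_exchange),
        "is_biomass": bool(r.is_biomass),
        "name": r.name,
    }


def _reaction_from_dict(d: dict) -> Reaction:
    return Reaction(
        id=d["id"], stoichiometry={m: float(c) for m, c in d["stoichiometry"].items()},
        lower_bound=float(d.get("lower_bound", 0.0)),
        upper_bound=float(d.get("upper_bound", 1000.0)),
        is_exchange=bool(d.get("is_exchange", False)),
        is_biomass=bool(d.get("is_biomass", False)),
        name=d.get("name", ""),
    )


def network_to_dict(net) -> dict:
    kind = "universal_db" if isinstance(net, UniversalDB) else "network"
    d = {
        "id": net.id,
        "kind": kind,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in sorted(net.metabolites.values(), key=lambda m: m.id)
        ],
        "reactions": [_reaction_to_dict(r)
                      for r in sorted(net.reactions.values(), key=lambda r: r.id)],
    }
    if kind == "network":
        d["biomass_id"] = net.biomass_id
    return d


def network_from_dict(d: dict):
    mets = [Metabolite(m["id"], m.get("name", ""), m.get("compartment", "c"))
            for m in d["metabolites"]]
    rxns = [_reaction_from_dict(r) for r in d["reactions"]]
    if d.get("kind", "network") == "universal_db":
        db = UniversalDB(d["id"], mets, rxns)
        db.validate()
        return db
    net = MetabolicNetwork(d["id"], mets, rxns, biomass_id=d.get("biomass_id"))
    net.validate()
    return net


def save_network(net, path: PathLike) -> None:
    Path(path).write_text(json.dumps(network_to_dict(net), indent=1, sort_keys=True) + "\n")


def load_network(path: PathLike):
    try:
        return network_from_dict(json.loads(Path(path).read_text()))
    except (KeyError, json.JSONDecodeError) as exc:
        raise InputError(f"malformed network JSON {path}: {exc}") from exc


# ------------------------------------------------------------------- media

def save_media_panel(panel: Dict[str, MediumCondition], path: PathLike) -> None:
    rows = []
    for cond in sorted(panel.values(), key=lambda c: c.id):
        for ex, ub in sorted(cond.uptake_bounds.items()):
            rows.append({
                "condition_id": cond.id, "exchange_id": ex, "max_uptake": ub,
                "is_nitrogen_source": int(ex == cond.nitrogen_source_id),
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_media_panel(path: PathLike) -> Dict[str, MediumCondition]:
    df = pd.read_csv(path, sep="\t")
    required = {"condition_id", "exchange_id", "max_uptake", "is_nitrogen_source"}
    if not required.issubset(df.columns):
        raise InputError(f"media panel {path} missing columns {required - set(df.columns)}")
    panel: Dict[str, MediumCondition] = {}
    for cid, grp in df.groupby("condition_id", sort=True):
        bounds = dict(zip(grp["exchange_id"], grp["max_uptake"].astype(float)))
        nsrc = grp.loc[grp["is_nitrogen_source"] == 1, "exchange_id"]
        panel[str(cid)] = MediumCondition(
            str(cid), bounds, nitrogen_source_id=str(nsrc.iloc[0]) if len(nsrc) else "")
    return panel


def save_truth(truth: pd.DataFrame, path: PathLike) -> None:
    """``truth``: columns (strain,) condition, grows."""
    truth.to_csv(path, sep="\t", index=False)


def load_truth(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "condition" not in df.columns or "grows" not in df.columns:
        raise InputError(f"truth table {path} needs 'condition' and 'grows' columns")
    df["grows"] = df["grows"].astype(bool)
    return df


# --------------------------------------------------------------- ensembles

def save_ensemble(ensemble: Ensemble, directory: PathLike) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = []
    for i, (net, rec) in enumerate(zip(ensemble.networks, ensemble.records)):
        member_file = f"member_{i:03d}.json"
        save_network(net, directory / member_file)
        records.append({
            "member": member_file,
            "added_reaction_ids": rec.added_reaction_ids,
            "removed_reaction_ids": rec.removed_reaction_ids,
            "positives_used": rec.positives_used,
            "negatives_used": rec.negatives_used,
            "seed": rec.seed,
            "unresolved_negatives": rec.unresolved_negatives,
        })
    (directory / "records.json").write_text(
        json.dumps({"size": ensemble.size, "records": records},
                   indent=1, sort_keys=True) + "\n")


def load_ensemble(directory: PathLike) -> Ensemble:
    directory = Path(directory)
    manifest = json.loads((directory / "records.json").read_text())
    networks: List[MetabolicNetwork] = []
    records: List[GapfillRecord] = []
    for rec in manifest["records"]:
        networks.append(load_network(directory / rec["member"]))
        records.append(GapfillRecord(
            added_reaction_ids=rec["added_reaction_ids"],
            removed_reaction_ids=rec["removed_reaction_ids"],
            positives_used=rec["positives_used"],
            negatives_used=rec["negatives_used"],
            seed=rec["seed"],
            unresolved_negatives=rec.get("unresolved_negatives", []),
        ))
    return Ensemble(networks, records)


# -------------------------------------------------------------------- SBML

def write_sbml(net: MetabolicNetwork, path: PathLike) -> None:
    """Export as SBML Level-3 FBC via cobrapy (optional dependency)."""
    cobra = _import_cobra()
    model = cobra.Model(net.id)
    mets = {m.id: cobra.Metabolite(m.id, name=m.name, compartment=m.compartment)
            for m in net.metabolites.values()}
    for r in sorted(net.reactions.values(), key=lambda r: r.id):
        rxn = cobra.Reaction(r.id, name=r.name,
                             lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        model.add_reactions([rxn])
        rxn.add_metabolites({mets[m]: c for m, c in r.stoichiometry.items()})
        if r.is_biomass:
            rxn.objective_coefficient = 1.0
    cobra.io.write_sbml_model(model, str(path))


def read_sbml(path: PathLike, id: str | None = None) -> MetabolicNetwork:
    cobra = _import_cobra()
    model = cobra.io.read_sbml_model(str(path))
    mets = [Metabolite(m.id, m.name or "", m.compartment or "c") for m in model.metabolites]
    objective_ids = {r.id for r in model.reactions if r.objective_coefficient}
    rxns = []
    for r in model.reactions:
        rxns.append(Reaction(
            id=r.id,
            stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
            lower_bound=float(r.lower_bound), upper_bound=float(r.upper_bound),
            is_exchange=bool(r.boundary),
            is_biomass=r.id in objective_ids,
            name=r.name or "",
        ))
    net = MetabolicNetwork(id or model.id or Path(path).stem, mets, rxns)
    net.validate()
    return net


def _import_cobra():
    try:
        import cobra  # noqa: PLC0415
    except ImportError as exc:  # pragma: no cover
        raise InputError("SBML support requires the optional 'cobra' dependency") from exc
    return cobra
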