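"""Pipeline orchestration: staged execution with a reproducible manifest.

Stages run in dependency order::

    simulate -> score-growth -> build-ensemble -> predict -> evaluate
             -> dea -> ko -> pathways -> pii -> report

Each stage writes its outputs under ``outdir/<stage>/`` together with a
small manifest recording the parameter/input hash; rerunning a stage whose
hash is unchanged reuses the cached outputs bit-for-bit.  The run manifest
collects package version, seeds, stage hashes and output paths.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .ensemble import build_ensemble, ensemble_flux, ensemble_predict, flux_fold_changes
from .errors import InputError, StageError
from .evaluation import evaluate_ensemble, random_baseline, rank_r2
from .growth_scoring import load_plate_csv, save_plate_csv, score_plate_run
from .model_io import (
    load_ensemble,
    load_media_panel,
    load_network,
    load_truth,
    save_ensemble,
    save_media_panel,
    save_network,
    save_truth,
)
from .proteomics import (
    ProteomicsMatrix,
    differential_abundance,
    enumerate_comparisons,
    load_ko_map,
    load_lfq,
    load_pathway_map,
    match_kos,
    pathway_test,
    pii_screen,
    save_lfq,
)
from .synthetic import generate_universe, simulate_plate, simulate_proteomics

STAGES = ["simulate", "score-growth", "build-ensemble", "predict", "evaluate",
          "dea", "ko", "pathways", "pii", "report"]


@dataclass
class RunConfig:
    """All tunable knobs of a pipeline run; round-trips through YAML."""

    seed: int = 0
    # thresholds
    epsilon: float = 1e-3
    vote_threshold: float = 0.5
    k_threshold: float = 0.1
    min_call_replicates: int = 2
    fc_threshold: float = 1.0
    alpha: float = 0.05
    corr_threshold: float = 0.75
    slope_threshold: float = 2.0
    min_reps: int = 3
    # ensemble training (study scale: 50 members, 26 positive / 11 negative)
    ensemble_size: int = 50
    n_pos: int = 26
    n_neg: int = 11
    # synthetic universe
    n_metabolites: int = 60
    n_db_reactions: int = 160
    n_strains: int = 3
    n_sources: int = 40
    deletion_fraction: float = 0.3
    # plate simulation
    plate_noise_sd: float = 0.01
    # proteomics simulation
    n_proteins: int = 400
    n_replicates: int = 4
    proteomics_noise_sd: float = 0.25
    effect_size: float = 3.0
    # scoring
    exclude_substrates: List[str] = field(default_factory=list)
    pathway_blacklist: List[str] = field(default_factory=list)

    def validate(self) -> None:
        if not (0 < self.vote_threshold <= 1):
            raise InputError("vote_threshold must lie in (0, 1]")
        if self.epsilon <= 0 or self.alpha <= 0 or self.alpha >= 1:
            raise InputError("epsilon must be > 0 and alpha in (0, 1)")
        if self.ensemble_size < 1 or self.n_pos < 0 or self.n_neg < 0:
            raise InputError("ensemble sizes must be non-negative, size >= 1")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class Pipeline:
    def __init__(self, config: RunConfig, outdir: Path):
        config.validate()
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.stage_info: Dict[str, dict] = {}

    # -------------------------------------------------------- stage cache
    def _stage_dir(self, stage: str) -> Path:
        d = self.outdir / stage.replace("-", "_")
        d.mkdir(parents=True, exist_ok=True)
        return d

    def _cached(self, stage: str, key: str) -> bool:
        mf = self._stage_dir(stage) / "stage_manifest.json"
        if not mf.exists():
            return False
        info = json.loads(mf.read_text())
        if info.get("key") != key:
            return False
        ok = all((self._stage_dir(stage) / f).exists() for f in info.get("outputs", []))
        if ok:
            self.stage_info[stage] = info
        return ok

    def _finish(self, stage: str, key: str, outputs: Sequence[str]) -> None:
        info = {"key": key, "outputs": sorted(outputs)}
        (self._stage_dir(stage) / "stage_manifest.json").write_text(
            json.dumps(info, indent=1, sort_keys=True) + "\n")
        self.stage_info[stage] = info

    def _require(self, stage: str, *files: Path) -> None:
        for f in files:
            if not f.exists():
                raise StageError(stage, f"missing input {f} (run earlier stages first)")

    # ------------------------------------------------------------- stages
    def simulate(self) -> None:
        cfg = self.config
        key = _hash(["simulate", cfg.seed, cfg.n_metabolites, cfg.n_db_reactions,
                     cfg.n_strains, cfg.n_sources, cfg.deletion_fraction,
                     cfg.plate_noise_sd, cfg.n_proteins, cfg.n_replicates,
                     cfg.proteomics_noise_sd, cfg.effect_size])
        if self._cached("simulate", key):
            return
        d = self._stage_dir("simulate")
        uni = generate_universe(cfg.n_metabolites, cfg.n_db_reactions,
                                cfg.n_strains, cfg.n_sources,
                                cfg.deletion_fraction, cfg.seed,
                                epsilon=cfg.epsilon)
        outputs = ["universal_db.json", "media_panel.tsv", "truth.tsv"]
        save_network(uni.db, d / "universal_db.json")
        save_media_panel(uni.panel, d / "media_panel.tsv")
        save_truth(uni.truth, d / "truth.tsv")
        for s_idx, strain in enumerate(sorted(uni.true_networks)):
            save_network(uni.true_networks[strain], d / f"true_{strain}.json")
            save_network(uni.drafts[strain], d / f"draft_{strain}.json")
            plate = simulate_plate(uni.truth_row(strain), cfg.seed * 1000 + s_idx,
                                   plate_id=strain, noise_sd=cfg.plate_noise_sd,
                                   activity=uni.activity_row(strain))
            save_plate_csv(plate, d / f"plate_{strain}.csv")
            outputs += [f"true_{strain}.json", f"draft_{strain}.json",
                        f"plate_{strain}.csv"]
        strains = sorted(uni.true_networks)
        matrices, truth = simulate_proteomics(
            strains, n_replicates=cfg.n_replicates, n_proteins=cfg.n_proteins,
            seed=cfg.seed, effect_size=cfg.effect_size,
            noise_sd=cfg.proteomics_noise_sd)
        for strain, mat in matrices.items():
            save_lfq(mat, d / f"lfq_{strain}.tsv", d / f"samples_{strain}.tsv")
            outputs += [f"lfq_{strain}.tsv", f"samples_{strain}.tsv"]
        pd.DataFrame([(p, k) for p, k in sorted(truth.ko_map.items())],
                     columns=["protein_id", "ko"]).to_csv(
            d / "ko_map.tsv", sep="\t", index=False)
        pd.DataFrame([(k, pw) for k, pws in sorted(truth.pathway_map.items())
                      for pw in pws],
                     columns=["ko", "pathway_id"]).to_csv(
            d / "pathway_map.tsv", sep="\t", index=False)
        pd.DataFrame(sorted(truth.pii_ids.items()),
                     columns=["strain", "pii_protein"]).to_csv(
            d / "pii_ids.tsv", sep="\t", index=False)
        outputs += ["ko_map.tsv", "pathway_map.tsv", "pii_ids.tsv"]
        self._finish("simulate", key, outputs)

    def _strains(self) -> List[str]:
        d = self._stage_dir("simulate")
        return sorted(p.stem.removeprefix("draft_")
                      for p in d.glob("draft_*.json"))

    def score_growth(self) -> None:
        cfg = self.config
        d_in = self._stage_dir("simulate")
        strains = self._strains()
        if not strains:
            raise StageError("score-growth", "no simulated plates found")
        key = _hash(["score-growth", cfg.k_threshold, cfg.min_call_replicates,
                     cfg.exclude_substrates,
                     [_file_hash(d_in / f"plate_{s}.csv") for s in strains]])
        if self._cached("score-growth", key):
            return
        d = self._stage_dir("score_growth")
        tables = []
        for strain in strains:
            run = load_plate_csv(d_in / f"plate_{strain}.csv")
            gm = score_plate_run(run, exclude_substrates=cfg.exclude_substrates,
                                 k_threshold=cfg.k_threshold,
                                 min_replicates=cfg.min_call_replicates,
                                 strain=strain)
            tables.append(gm.table)
        pd.concat(tables, ignore_index=True).to_csv(
            d / "growth_matrix.tsv", sep="\t", index=False)
        self._finish("score-growth", key, ["growth_matrix.tsv"])

    def build_ensembles(self) -> None:
        cfg = self.config
        d_in = self._stage_dir("simulate")
        strains = self._strains()
        self._require("build-ensemble", d_in / "universal_db.json",
                      d_in / "media_panel.tsv", d_in / "truth.tsv")
        key = _hash(["build-ensemble", cfg.seed, cfg.ensemble_size, cfg.n_pos,
                     cfg.n_neg, cfg.epsilon,
                     [_file_hash(d_in / f"draft_{s}.json") for s in strains]])
        if self._cached("build-ensemble", key):
            return
        d = self._stage_dir("build_ensemble")
        db = load_network(d_in / "universal_db.json")
        panel = load_media_panel(d_in / "media_panel.tsv")
        truth = load_truth(d_in / "truth.tsv")
        for strain in strains:
            draft = load_network(d_in / f"draft_{strain}.json")
            row = truth[truth["strain"] == strain]
            positives = [panel[c] for c in sorted(row[row["grows"]]["condition"])]
            negatives = [panel[c] for c in sorted(row[~row["grows"]]["condition"])]
            n_pos = min(cfg.n_pos, len(positives))
            n_neg = min(cfg.n_neg, len(negatives))
            ens = build_ensemble(draft, db, positives, negatives,
                                 cfg.ensemble_size, n_pos, n_neg, cfg.seed,
                                 epsilon=cfg.epsilon)
            save_ensemble(ens, d / f"ensemble_{strain}")
        self._finish("build-ensemble", key,
                     [f"ensemble_{s}/records.json" for s in strains])

    def predict(self) -> None:
        cfg = self.config
        d_in = self._stage_dir("simulate")
        d_ens = self._stage_dir("build_ensemble")
        strains = self._strains()
        self._require("predict", d_in / "media_panel.tsv",
                      *[d_ens / f"ensemble_{s}" / "records.json" for s in strains])
        key = _hash(["predict", cfg.epsilon, cfg.vote_threshold,
                     [_file_hash(d_ens / f"ensemble_{s}" / "records.json")
                      for s in strains]])
        if self._cached("predict", key):
            return
        d = self._stage_dir("predict")
        panel = load_media_panel(d_in / "media_panel.tsv")
        rows = []
        for strain in strains:
            ens = load_ensemble(d_ens / f"ensemble_{strain}")
            for cid in sorted(panel):
                pred = ensemble_predict(ens, panel[cid], cfg.epsilon,
                                        cfg.vote_threshold)
                rows.append((strain, cid, pred.fraction_growing, pred.activity,
                             pred.binary_call))
        pd.DataFrame(rows, columns=["strain", "condition", "fraction",
                                    "activity", "call"]).to_csv(
            d / "predictions.tsv", sep="\t", index=False)
        self._finish("predict", key, ["predictions.tsv"])

    def evaluate(self) -> None:
        cfg = self.config
        d_in = self._stage_dir("simulate")
        d_ens = self._stage_dir("build_ensemble")
        strains = self._strains()
        self._require("evaluate", d_in / "truth.tsv", d_in / "media_panel.tsv")
        key = _hash(["evaluate", cfg.epsilon, cfg.vote_threshold, cfg.seed,
                     [_file_hash(d_ens / f"ensemble_{s}" / "records.json")
                      for s in strains]])
        if self._cached("evaluate", key):
            return
        d = self._stage_dir("evaluate")
        panel = load_media_panel(d_in / "media_panel.tsv")
        truth = load_truth(d_in / "truth.tsv")
        report = {}
        for strain in strains:
            ens = load_ensemble(d_ens / f"ensemble_{strain}")
            row = truth[truth["strain"] == strain]
            tmap = dict(zip(row["condition"], row["grows"]))
            conditions = [panel[c] for c in sorted(tmap)]
            metrics = evaluate_ensemble(ens, conditions, tmap,
                                        cfg.epsilon, cfg.vote_threshold)
            baseline = random_baseline(tmap, n_draws=1000, seed=cfg.seed)
            report[strain] = {"metrics": metrics.to_dict(),
                              "baseline": baseline.summary()}
        (d / "evaluation.json").write_text(
            json.dumps(report, indent=1, sort_keys=True) + "\n")
        self._finish("evaluate", key, ["evaluation.json"])

    def _load_matrices(self) -> Dict[str, ProteomicsMatrix]:
        d_in = self._stage_dir("simulate")
        return {s: load_lfq(d_in / f"lfq_{s}.tsv", d_in / f"samples_{s}.tsv", s)
                for s in self._strains()}

    def dea(self) -> None:
        cfg = self.config
        d_in = self._stage_dir("simulate")
        strains = self._strains()
        self._require("dea", *[d_in / f"lfq_{s}.tsv" for s in strains])
        key = _hash(["dea", cfg.min_reps, cfg.fc_threshold, cfg.alpha,
                     [_file_hash(d_in / f"lfq_{s}.tsv") for s in strains]])
        if self._cached("dea", key):
            return
        d = self._stage_dir("dea")
        outputs = []
        for strain, matrix in self._load_matrices().items():
            for a, b in enumerate_comparisons(matrix.treatments):
                res = differential_abundance(matrix, a, b, cfg.min_reps,
                                             cfg.fc_threshold, cfg.alpha)
                fname = f"dea_{strain}_{a}_vs_{b}.tsv"
                res.rename_axis("protein_id").to_csv(d / fname, sep="\t")
                outputs.append(fname)
        self._finish("dea", key, outputs)

    def ko(self) -> None:
        cfg = self.config
        d_in = self._stage_dir("simulate")
        self._require("ko", d_in / "ko_map.tsv")
        key = _hash(["ko", cfg.min_reps,
                     [_file_hash(d_in / f"lfq_{s}.tsv") for s in self._strains()]])
        if self._cached("ko", key):
            return
        d = self._stage_dir("ko")
        ko_map = load_ko_map(d_in / "ko_map.tsv")
        table = match_kos(self._load_matrices(), ko_map, cfg.min_reps)
        flat = table.abundance.copy()
        flat.columns = [f"{s}|{t}" for s, t in flat.columns]
        flat.to_csv(d / "ko_table.tsv", sep="\t")
        table.representatives.to_csv(d / "ko_representatives.tsv", sep="\t",
                                     index=False)
        self._finish("ko", key, ["ko_table.tsv", "ko_representatives.tsv"])

    def pathways(self) -> None:
        cfg = self.config
        d_in = self._stage_dir("simulate")
        self._require("pathways", d_in / "ko_map.tsv", d_in / "pathway_map.tsv")
        key = _hash(["pathways", cfg.min_reps, cfg.fc_threshold, cfg.alpha,
                     cfg.pathway_blacklist,
                     [_file_hash(d_in / f"lfq_{s}.tsv") for s in self._strains()]])
        if self._cached("pathways", key):
            return
        d = self._stage_dir("pathways")
        ko_map = load_ko_map(d_in / "ko_map.tsv")
        pathway_map = load_pathway_map(d_in / "pathway_map.tsv")
        outputs = []
        for strain, matrix in self._load_matrices().items():
            frames = []
            for a, b in enumerate_comparisons(matrix.treatments):
                res = differential_abundance(matrix, a, b, cfg.min_reps,
                                             cfg.fc_threshold, cfg.alpha)
                pw = pathway_test(res, ko_map, pathway_map,
                                  blacklist=cfg.pathway_blacklist)
                pw.insert(0, "comparison", f"{a}_vs_{b}")
                frames.append(pw.reset_index())
            fname = f"pathways_{strain}.tsv"
            pd.concat(frames, ignore_index=True).to_csv(d / fname, sep="\t",
                                                        index=False)
            outputs.append(fname)
        self._finish("pathways", key, outputs)

    def pii(self) -> None:
        cfg = self.config
        d_in = self._stage_dir("simulate")
        self._require("pii", d_in / "pii_ids.tsv")
        key = _hash(["pii", cfg.corr_threshold, cfg.slope_threshold,
                     [_file_hash(d_in / f"lfq_{s}.tsv") for s in self._strains()]])
        if self._cached("pii", key):
            return
        d = self._stage_dir("pii")
        pii_ids = dict(pd.read_csv(d_in / "pii_ids.tsv", sep="\t").values)
        outputs = []
        for strain, matrix in self._load_matrices().items():
            means = matrix.treatment_log2_means(min_reps=1)
            res = pii_screen(means, pii_ids[strain],
                             cfg.corr_threshold, cfg.slope_threshold)
            fname = f"pii_{strain}.tsv"
            res.to_csv(d / fname, sep="\t")
            outputs.append(fname)
        self._finish("pii", key, outputs)

    def report(self) -> None:
        key = _hash(["report", sorted((s, i.get("key")) for s, i in
                                      self.stage_info.items())])
        d = self._stage_dir("report")
        summary = {
            "package_version": __version__,
            "seed": self.config.seed,
            "stages": {s: i.get("key") for s, i in sorted(self.stage_info.items())},
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        (d / "run_manifest.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True) + "\n")
        self._finish("report", key, ["run_manifest.json"])

    # --------------------------------------------------------------- run
    def run(self, stages: Optional[Sequence[str]] = None) -> dict:
        requested = list(stages) if stages else list(STAGES)
        unknown = set(requested) - set(STAGES)
        if unknown:
            raise InputError(f"unknown stages: {sorted(unknown)}")
        dispatch = {
            "simulate": self.simulate, "score-growth": self.score_growth,
            "build-ensemble": self.build_ensembles, "predict": self.predict,
            "evaluate": self.evaluate, "dea": self.dea, "ko": self.ko,
            "pathways": self.pathways, "pii": self.pii, "report": self.report,
        }
        for stage in STAGES:  # dependency order
            if stage in requested:
                dispatch[stage]()
        manifest = {
            "package_version": __version__,
            "seed": self.config.seed,
            "config": dataclasses.asdict(self.config),
            "stages": {s: self.stage_info.get(s, {}).get("key")
                       for s in requested},
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        (self.outdir / "run_manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n")
        return manifest


def run_pipeline(config: RunConfig, outdir, stages: Optional[Sequence[str]] = None
                 ) -> dict:
    return Pipeline(config, Path(outdir)).run(stages)
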