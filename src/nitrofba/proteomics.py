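"""Label-free proteomics statistics.

Works on MaxQuant-style LFQ intensity matrices (proteins x samples, missing
values = not detected).  Provides per-treatment-pair differential abundance
(Welch's t on log2 intensities, Benjamini-Hochberg FDR, the field's standard
DEP thresholds |log2FC| > 1 and BH p < 0.05), presence/absence calls for
proteins detected in only one treatment, cross-strain KEGG-ortholog
matching with representative-protein selection, per-pathway combination of
member BH p-values (Fisher's method), and a screen for proteins whose
abundance tracks the PII nitrogen-stress protein.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError

FC_THRESHOLD = 1.0
ALPHA = 0.05
MIN_REPS = 3
CORR_THRESHOLD = 0.75
SLOPE_THRESHOLD = 2.0
REFERENCE_TREATMENT = "ammonium"
P_FLOOR = 1e-300


@dataclass
class ProteomicsMatrix:
    """LFQ intensities (raw scale, NaN = undetected) plus sample metadata.

    ``data``: DataFrame proteins x samples.  ``metadata``: DataFrame indexed
    by sample with columns ``treatment`` and ``replicate``.
    """

    strain: str
    data: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self):
        if not set(self.data.columns) <= set(self.metadata.index):
            raise InputError(f"strain {self.strain}: samples missing from metadata")
        if self.metadata["treatment"].nunique() < 2:
            raise InputError(f"strain {self.strain}: need >= 2 treatments")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if (self.data.to_numpy() < 0).any():
                raise InputError(f"strain {self.strain}: negative LFQ intensities")

    @property
    def treatments(self) -> List[str]:
        return sorted(self.metadata["treatment"].unique())

    def samples_for(self, treatment: str) -> List[str]:
        samples = self.metadata.index[self.metadata["treatment"] == treatment]
        return [s for s in samples if s in self.data.columns]

    def detected_counts(self, treatment: str) -> pd.Series:
        """Detected replicates per protein in one treatment."""
        return self.data[self.samples_for(treatment)].notna().sum(axis=1)

    def treatment_log2_means(self, min_reps: int = 1) -> pd.DataFrame:
        """Proteins x treatments mean log2 intensity over detected
        replicates (NaN when fewer than ``min_reps`` detections)."""
        cols = {}
        for t in self.treatments:
            block = np.log2(self.data[self.samples_for(t)])
            m = block.mean(axis=1)
            m[block.notna().sum(axis=1) < min_reps] = np.nan
            cols[t] = m
        return pd.DataFrame(cols)


def enumerate_comparisons(treatments: Sequence[str]) -> List[Tuple[str, str]]:
    """All unordered treatment pairs in canonical (sorted) order; five
    treatments give the study's 10 pairwise comparisons."""
    uniq = sorted(set(treatments))
    if len(uniq) < 2:
        raise InputError("need at least two treatments to compare")
    return list(itertools.combinations(uniq, 2))


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (delegates to statsmodels)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if len(pvalues) == 0:
        return pvalues
    return multipletests(pvalues, method="fdr_bh")[1]


def differential_abundance(matrix: ProteomicsMatrix, treat_a: str, treat_b: str,
                           min_reps: int = MIN_REPS,
                           fc_threshold: float = FC_THRESHOLD,
                           alpha: float = ALPHA,
                           equal_var: bool = False) -> pd.DataFrame:
    """Per-protein log2 fold change, Welch p, BH-adjusted p and DEP flag for
    one treatment pair.

    Proteins with >= ``min_reps`` detections in both groups are tested;
    log2FC = mean(log2 A) - mean(log2 B).  Proteins detected in one group
    (>= ``min_reps``) and never in the other are classed present/absent and
    excluded from the test.  Returns a frame indexed by protein with columns
    ``log2fc, n_a, n_b, pvalue, p_adj, dep, status``.
    """
    for t in (treat_a, treat_b):
        if t not in matrix.treatments:
            raise InputError(f"treatment {t!r} absent from strain {matrix.strain}")
    a = np.log2(matrix.data[matrix.samples_for(treat_a)])
    b = np.log2(matrix.data[matrix.samples_for(treat_b)])
    n_a = a.notna().sum(axis=1)
    n_b = b.notna().sum(axis=1)

    status = pd.Series("insufficient", index=matrix.data.index, dtype=object)
    tested = (n_a >= min_reps) & (n_b >= min_reps)
    status[tested] = "tested"
    status[(n_a >= min_reps) & (n_b == 0)] = "present_only_a"
    status[(n_b >= min_reps) & (n_a == 0)] = "present_only_b"

    log2fc = pd.Series(np.nan, index=matrix.data.index)
    log2fc[tested] = a[tested].mean(axis=1) - b[tested].mean(axis=1)

    pvalue = pd.Series(np.nan, index=matrix.data.index)
    if tested.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.ttest_ind(a[tested].to_numpy(), b[tested].to_numpy(),
                                   axis=1, equal_var=equal_var, nan_policy="omit")
        p = np.asarray(p, dtype=float)
        diff = log2fc[tested].to_numpy()
        # zero-variance groups: identical means are maximally unsurprising,
        # distinct means maximally surprising
        p = np.where(np.isnan(p) & (np.abs(diff) < 1e-12), 1.0, p)
        p = np.where(np.isnan(p), 0.0, p)
        pvalue[tested] = p

    p_adj = pd.Series(np.nan, index=matrix.data.index)
    p_adj[tested] = benjamini_hochberg(pvalue[tested].to_numpy())

    dep = tested & (log2fc.abs() > fc_threshold) & (p_adj < alpha)
    return pd.DataFrame({
        "log2fc": log2fc, "n_a": n_a, "n_b": n_b, "pvalue": pvalue,
        "p_adj": p_adj, "dep": dep.fillna(False), "status": status,
    })


# ---------------------------------------------------------------- KO table

@dataclass
class KOTable:
    """KO x (strain, treatment) mean log2 abundances after the detection
    filter, plus the representative protein chosen per (KO, strain)."""

    abundance: pd.DataFrame             # index KO, columns MultiIndex (strain, treatment)
    representatives: pd.DataFrame       # columns: ko, strain, protein, grand_mean
    reference: str = REFERENCE_TREATMENT

    @property
    def strains(self) -> List[str]:
        return sorted({s for s, _ in self.abundance.columns})

    def z_view(self) -> pd.DataFrame:
        """Within-strain view: each (KO, strain) profile z-scored across
        treatments (mean 0, sd 1)."""
        out = self.abundance.copy()
        for strain in self.strains:
            block = out[strain]
            mu = block.mean(axis=1)
            sd = block.std(axis=1, ddof=1)
            out[strain] = block.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0)
        return out

    def ammonium_view(self) -> pd.DataFrame:
        """Each (KO, strain, treatment) log2 abundance minus the strain's
        reference (ammonium) value; the reference column is dropped."""
        for strain in self.strains:
            if self.reference not in self.abundance[strain].columns:
                raise InputError(
                    f"reference treatment {self.reference!r} absent for strain {strain!r}"
                )
        out = self.abundance.copy()
        for strain in self.strains:
            ref = out[(strain, self.reference)]
            for col in list(out[strain].columns):
                out[(strain, col)] = out[(strain, col)] - ref
        return out.drop(columns=[(s, self.reference) for s in self.strains])


def match_kos(matrices: Mapping[str, ProteomicsMatrix],
              ko_map: Mapping[str, str],
              min_reps: int = MIN_REPS,
              reference: str = REFERENCE_TREATMENT) -> KOTable:
    """Cross-strain KO table.

    A KO is kept only when it is detected (>= ``min_reps`` replicates) in
    every treatment of every strain.  When several proteins of a strain map
    to the same KO, the one with the highest grand-mean LFQ across all
    samples (undetected counted as 0, as MaxQuant reports) represents it.
    Unmapped proteins are skipped; their count is recorded in
    ``representatives.attrs['n_unmapped']``.
    """
    per_strain_ko: Dict[str, Dict[str, str]] = {}
    detected: Dict[str, set] = {}
    n_unmapped = 0
    for strain, matrix in matrices.items():
        counts = {t: matrix.detected_counts(t) for t in matrix.treatments}
        grand_mean = matrix.data.fillna(0.0).mean(axis=1)
        best: Dict[str, Tuple[float, str]] = {}
        ok_kos = set()
        for protein in matrix.data.index:
            ko = ko_map.get(protein)
            if ko is None:
                n_unmapped += 1
                continue
            cand = (float(grand_mean[protein]), protein)
            if ko not in best or cand[0] > best[ko][0]:
                best[ko] = cand
        for ko, (_, protein) in best.items():
            if all(counts[t][protein] >= min_reps for t in matrix.treatments):
                ok_kos.add(ko)
        per_strain_ko[strain] = {ko: protein for ko, (_, protein) in best.items()}
        detected[strain] = ok_kos

    shared = sorted(set.intersection(*detected.values())) if detected else []
    columns, data, rep_rows = [], [], []
    for strain in sorted(matrices):
        matrix = matrices[strain]
        means = matrix.treatment_log2_means(min_reps=1)
        grand_mean = matrix.data.fillna(0.0).mean(axis=1)
        for t in matrix.treatments:
            columns.append((strain, t))
            data.append([means.at[per_strain_ko[strain][ko], t] for ko in shared])
        for ko in shared:
            protein = per_strain_ko[strain][ko]
            rep_rows.append((ko, strain, protein, float(grand_mean[protein])))
    abundance = pd.DataFrame(
        np.array(data).T if data else np.empty((0, 0)),
        index=pd.Index(shared, name="ko"),
        columns=pd.MultiIndex.from_tuples(columns, names=["strain", "treatment"]),
    )
    representatives = pd.DataFrame(rep_rows, columns=["ko", "strain", "protein",
                                                      "grand_mean"])
    representatives.attrs["n_unmapped"] = n_unmapped
    return KOTable(abundance, representatives, reference=reference)


# ---------------------------------------------------------------- pathways

def fisher_combined(pvalues: Sequence[float]) -> Tuple[float, float]:
    """Fisher's combined-probability method: X = -2 sum(ln p_i), p from
    chi-square with 2k degrees of freedom.  Zero p-values are floored at
    1e-300 with a warning."""
    p = np.asarray(list(pvalues), dtype=float)
    if len(p) == 0:
        raise InputError("fisher_combined needs at least one p-value")
    if (p <= 0).any():
        warnings.warn("p-values of 0 floored at 1e-300 before combining")
        p = np.maximum(p, P_FLOOR)
    x = float(-2.0 * np.log(p).sum())
    return x, float(stats.chi2.sf(x, 2 * len(p)))


def pathway_test(comparison: pd.DataFrame, ko_map: Mapping[str, str],
                 pathway_map: Mapping[str, Sequence[str]],
                 min_proteins: int = 3,
                 blacklist: Sequence[str] = (),
                 method: str = "fisher",
                 alpha: float = ALPHA) -> pd.DataFrame:
    """Per-pathway significance for one treatment-pair comparison.

    ``method="fisher"`` (default) combines the BH-adjusted p-values of each
    pathway's tested constituent proteins with Fisher's method.
    ``method="enrichment"`` instead runs a 2x2 Fisher exact test of DEP
    membership against pathway membership.  Pathways with fewer than
    ``min_proteins`` tested proteins, or on the ``blacklist`` (e.g.
    non-bacterial processes), are excluded.
    """
    if method not in ("fisher", "enrichment"):
        raise InputError(f"unknown pathway test method {method!r}")
    tested = comparison[comparison["status"] == "tested"]
    members: Dict[str, List[str]] = {}
    for protein in tested.index:
        ko = ko_map.get(protein)
        if ko is None:
            continue
        for pw in pathway_map.get(ko, ()):
            members.setdefault(pw, []).append(protein)
    rows = []
    blacklist = set(blacklist)
    n_dep_total = int(tested["dep"].sum())
    for pw in sorted(members):
        if pw in blacklist:
            continue
        prots = members[pw]
        if len(prots) < min_proteins:
            continue
        if method == "fisher":
            x, p = fisher_combined(tested.loc[prots, "p_adj"].to_numpy())
            rows.append((pw, len(prots), x, p))
        else:
            in_dep = int(tested.loc[prots, "dep"].sum())
            table = [[in_dep, len(prots) - in_dep],
                     [n_dep_total - in_dep,
                      len(tested) - len(prots) - (n_dep_total - in_dep)]]
            _, p = stats.fisher_exact(table, alternative="greater")
            rows.append((pw, len(prots), np.nan, float(p)))
    return (pd.DataFrame(rows, columns=["pathway", "n_proteins", "statistic",
                                        "combined_p"])
            .set_index("pathway"))


# --------------------------------------------------------------- PII screen

def pii_screen(table: pd.DataFrame, pii_id: str,
               corr_threshold: float = CORR_THRESHOLD,
               slope_threshold: float = SLOPE_THRESHOLD) -> pd.DataFrame:
    """Screen for proteins whose abundance profile tracks the PII protein.

    ``table``: rows = proteins (or KOs), columns = treatments, values = mean
    log2 abundance.  For each protein, the Pearson correlation with the PII
    profile and the OLS slope of the protein's profile on the *z-scored*
    PII profile (log2 units per PII standard deviation) are computed over
    the treatments.  Classification: positive if corr > ``corr_threshold``
    and slope > ``slope_threshold``; negative if corr < -``corr_threshold``
    and slope < -``slope_threshold``; otherwise none.  Constant or
    incomplete profiles are unclassifiable (class none, NaN statistics).
    """
    if pii_id not in table.index:
        raise InputError(f"PII profile {pii_id!r} absent from the table")
    x = table.loc[pii_id].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise InputError("PII profile must be present across all treatments")
    if np.std(x, ddof=1) == 0:
        raise InputError("PII profile is constant; screen undefined")
    xz = (x - x.mean()) / np.std(x, ddof=1)

    rows = []
    for protein in table.index:
        y = table.loc[protein].to_numpy(dtype=float)
        if np.isnan(y).any() or np.std(y) == 0:
            rows.append((protein, np.nan, np.nan, "none"))
            continue
        corr = float(stats.pearsonr(x, y)[0])
        slope = float(np.polyfit(xz, y, 1)[0])
        if corr > corr_threshold and slope > slope_threshold:
            cls = "positive"
        elif corr < -corr_threshold and slope < -slope_threshold:
            cls = "negative"
        else:
            cls = "none"
        rows.append((protein, corr, slope, cls))
    return (pd.DataFrame(rows, columns=["protein", "correlation", "slope",
                                        "classification"])
            .set_index("protein"))


# -------------------------------------------------------------------- I/O

def load_lfq(data_path, metadata_path, strain: str) -> ProteomicsMatrix:
    """LFQ TSV (protein_id + sample columns) and sample-metadata TSV
    (sample, treatment, replicate); zeros are treated as not detected."""
    data = pd.read_csv(data_path, sep="\t").set_index("protein_id")
    data = data.replace(0.0, np.nan)
    meta = pd.read_csv(metadata_path, sep="\t").set_index("sample")
    return ProteomicsMatrix(strain, data, meta)


def save_lfq(matrix: ProteomicsMatrix, data_path, metadata_path) -> None:
    out = matrix.data.fillna(0.0)
    out.index.name = "protein_id"
    out.to_csv(data_path, sep="\t")
    matrix.metadata.to_csv(metadata_path, sep="\t")


def load_ko_map(path) -> Dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    if not {"protein_id", "ko"}.issubset(df.columns):
        raise InputError(f"ko map {path} needs columns protein_id, ko")
    return dict(zip(df["protein_id"], df["ko"]))


def load_pathway_map(path) -> Dict[str, List[str]]:
    df = pd.read_csv(path, sep="\t")
    if not {"ko", "pathway_id"}.issubset(df.columns):
        raise InputError(f"pathway map {path} needs columns ko, pathway_id")
    out: Dict[str, List[str]] = {}
    for r in df.itertuples():
        out.setdefault(r.ko, []).append(r.pathway_id)
    return out
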