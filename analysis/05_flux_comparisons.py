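"""Compare ensemble-weighted fluxes between nitrogen sources.

For each strain, reaction fluxes are averaged across ensemble members and
weighted by the fraction of members in which the reaction carries flux;
each organic nitrogen source is then compared against ammonium and filtered
for reactions with |log2 fold change| > 1.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from config import CONFIG, OUTDIR

import pandas as pd

from nitrofba.ensemble import ensemble_flux, flux_fold_changes
from nitrofba.model_io import load_ensemble, load_media_panel
from nitrofba.pipeline import Pipeline


def main() -> None:
    Pipeline(CONFIG, OUTDIR).run(["simulate", "build-ensemble"])
    panel = load_media_panel(OUTDIR / "simulate" / "media_panel.tsv")
    rows = []
    for ens_dir in sorted((OUTDIR / "build_ensemble").glob("ensemble_*")):
        strain = ens_dir.name.removeprefix("ensemble_")
        ens = load_ensemble(ens_dir)
        reference = ensemble_flux(ens, panel["ammonium"])
        organic = [c for c in sorted(panel) if c != "ammonium"][:4]
        for cond in organic:
            changes = flux_fold_changes(ensemble_flux(ens, panel[cond]),
                                        reference, threshold=1.0)
            for rid, lfc in changes:
                rows.append((strain, cond, rid, round(lfc, 3)))
            print(f"{strain} {cond} vs ammonium: "
                  f"{len(changes)} reactions with |log2FC| > 1")
    out = OUTDIR / "flux_fold_changes.tsv"
    pd.DataFrame(rows, columns=["strain", "condition", "reaction", "log2fc"]
                 ).to_csv(out, sep="\t", index=False)
    print(f"fold-change table written to {out}")


if __name__ == "__main__":
    main()
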