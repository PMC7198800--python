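"""Cross-strain KO table, pathway-level statistics and the PII screen.

Matches proteins across strains via KEGG-ortholog ids (representative =
highest grand-mean LFQ), combines constituent BH p-values per pathway with
Fisher's method, and screens for proteins whose abundance tracks the PII
nitrogen-stress protein (correlation > 0.75 and slope > 2).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from config import CONFIG, OUTDIR

import pandas as pd

from nitrofba.pipeline import Pipeline


def main() -> None:
    Pipeline(CONFIG, OUTDIR).run(["simulate", "ko", "pathways", "pii", "report"])
    ko = pd.read_csv(OUTDIR / "ko" / "ko_table.tsv", sep="\t", index_col=0)
    print(f"{ko.shape[0]} KOs detected in all treatments of all strains")
    for f in sorted((OUTDIR / "pathways").glob("pathways_*.tsv")):
        pw = pd.read_csv(f, sep="\t")
        sig = pw[pw["combined_p"] < 0.01]
        strain = f.stem.removeprefix("pathways_")
        print(f"{strain}: {len(sig)} (pathway, comparison) pairs with "
              f"combined p < 0.01 of {len(pw)} tested")
    for f in sorted((OUTDIR / "pii").glob("pii_*.tsv")):
        res = pd.read_csv(f, sep="\t")
        strain = f.stem.removeprefix("pii_")
        pos = (res["classification"] == "positive").sum()
        neg = (res["classification"] == "negative").sum()
        print(f"{strain}: {pos} PII-correlated and {neg} anti-correlated proteins")
    print(f"run manifest: {OUTDIR / 'run_manifest.json'}")


if __name__ == "__main__":
    main()
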