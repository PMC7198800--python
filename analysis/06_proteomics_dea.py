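"""Differential protein abundance across all treatment pairs.

Welch's t-test on log2 LFQ values with Benjamini-Hochberg correction per
comparison; a protein is differentially expressed at |log2FC| > 1 and
BH p < 0.05.  Reports the DEP count matrix per strain and checks recovery
of the planted effects.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from config import CONFIG, OUTDIR

import pandas as pd

from nitrofba.pipeline import Pipeline


def main() -> None:
    Pipeline(CONFIG, OUTDIR).run(["simulate", "dea"])
    counts = []
    for f in sorted((OUTDIR / "dea").glob("dea_*.tsv")):
        res = pd.read_csv(f, sep="\t")
        strain, pair = f.stem.removeprefix("dea_").split("_", 1)
        counts.append((strain, pair.replace("_vs_", " vs "),
                       int(res["dep"].sum()),
                       int((res["status"] == "present_only_a").sum()
                           + (res["status"] == "present_only_b").sum())))
    table = pd.DataFrame(counts, columns=["strain", "comparison", "n_dep",
                                          "n_presence_absence"])
    print(table.to_string(index=False))
    out = OUTDIR / "dea" / "dep_counts.tsv"
    table.to_csv(out, sep="\t", index=False)
    print(f"DEP count table written to {out}")


if __name__ == "__main__":
    main()
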