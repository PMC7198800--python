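"""Generate the synthetic study inputs.

Builds the universal reaction database, per-strain true and draft metabolic
networks, the nitrogen-source media panel, FBA-derived truth growth matrix,
phenotype-microarray kinetics and LFQ proteome matrices, all with known
ground truth.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from config import CONFIG, OUTDIR

import pandas as pd

from nitrofba.pipeline import Pipeline


def main() -> None:
    pipe = Pipeline(CONFIG, OUTDIR)
    pipe.run(["simulate"])
    truth = pd.read_csv(OUTDIR / "simulate" / "truth.tsv", sep="\t")
    summary = truth.groupby("strain")["grows"].agg(["sum", "count"])
    print(f"simulated {summary.shape[0]} strains over "
          f"{summary['count'].iloc[0]} nitrogen conditions")
    for strain, row in summary.iterrows():
        print(f"  {strain}: {int(row['sum'])} growth-positive / {int(row['count'])}")
    print(f"outputs in {OUTDIR / 'simulate'}")


if __name__ == "__main__":
    main()
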