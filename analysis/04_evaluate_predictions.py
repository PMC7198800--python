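"""Evaluate ensemble growth predictions against the truth matrix.

Per-member masking: a member abstains on any condition it was trained on.
Accuracy, precision and recall are compared to the distribution obtained
from prevalence-matched random predictions, and quantitative metabolic
activity to the experimental intensity z-scores via percentile-rank r².
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from config import CONFIG, OUTDIR

import pandas as pd

from nitrofba.evaluation import rank_r2
from nitrofba.pipeline import Pipeline


def main() -> None:
    pipe = Pipeline(CONFIG, OUTDIR)
    pipe.run(["simulate", "score-growth", "build-ensemble", "predict", "evaluate"])
    report = json.loads((OUTDIR / "evaluate" / "evaluation.json").read_text())
    preds = pd.read_csv(OUTDIR / "predict" / "predictions.tsv", sep="\t")
    gm = pd.read_csv(OUTDIR / "score_growth" / "growth_matrix.tsv", sep="\t")
    rows = []
    for strain, rep in sorted(report.items()):
        m = rep["metrics"]
        base = rep["baseline"]["accuracy"]
        activity = dict(preds[preds["strain"] == strain]
                        [["condition", "activity"]].values)
        intensity = {r.substrate: r.mean_z
                     for r in gm[gm["strain"] == strain].itertuples()
                     if r.mean_z == r.mean_z}
        r2 = rank_r2(activity, intensity)
        rows.append((strain, m["accuracy"], m["precision"], m["recall"],
                     base["mean"], r2))
        print(f"{strain}: accuracy {m['accuracy']:.2f} "
              f"(random baseline mean {base['mean']:.2f}), "
              f"precision {m['precision']}, recall {m['recall']}, "
              f"activity-vs-intensity rank r2 "
              f"{'n/a' if r2 is None else f'{r2:.2f}'}")
    out = OUTDIR / "evaluate" / "summary.tsv"
    pd.DataFrame(rows, columns=["strain", "accuracy", "precision", "recall",
                                "baseline_mean_accuracy", "rank_r2"]
                 ).to_csv(out, sep="\t", index=False)
    print(f"summary written to {out}")


if __name__ == "__main__":
    main()
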